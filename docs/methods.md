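# Methods

## Scope and data model

The package processes reflectron positive-mode MALDI-TOF spectra of
released serum *N*-glycans whose sialic acids were linkage-specifically
derivatised (α2,6 → ethyl ester, residue C₁₁H₁₇NO₈ + C₂H₄; α2,3 →
lactone, residue − H₂O). All ions are singly charged sodium adducts of
free-reducing-end glycans; m/z of the lightest isotopologue is the sum
of residue monoisotopic formulas plus H₂O and Na minus one electron
mass. Spectra arrive as text (x,y) files, one `m/z<TAB>intensity` pair
per line, together with a sample manifest (subject, time point, path).

## Structure assignment

Derived traits need feature counts, not topology. Compositions are
classified by HexNAc count: N=2 (H≥4, undecorated) oligomannose, N=3
hybrid, N≥4 complex. For complex glycans the bisected reading
(antennae A = N−3, bisecting GlcNAc present) is preferred over the
non-bisected one (A = N−2) whenever it satisfies 2 ≤ A ≤ 4,
0 ≤ G = H−3 ≤ A and E+L ≤ G; this "most common structure" preference
makes H5N5 a bisected diantennary and H4N5F1E1 a bisected,
core-fucosylated, monogalactosylated, α2,6-monosialylated diantennary
glycan. The first fucose of a diantennary glycan is core; additional
fucoses are antennary; a single fucose on a tri/tetraantennary glycan
counts as antennary only in an α2,3-sialylated (sialyl-Lewis) context.
Hybrids get antennae = 1, one galactose iff sialylated, at most one
fucose (core) and at most one sialic acid; these choices only affect
the class-fraction traits, since per-antenna traits are defined over
complex glycans.

## Isotopic envelopes and the QC score

Envelopes are computed by element-wise convolution of IUPAC isotope
abundances with binary exponentiation; isotopologues are binned by
nominal neutron shift and each bin carries its abundance-weighted
centroid mass (pruning threshold 10⁻¹⁵ in probability). Extraction
includes isotopologues until the cumulative theoretical fraction
reaches 95 %; observed and theoretical fractions are renormalised over
the included set before the quality score QC = Σ (obs − theo)² is
formed, so truncation does not bias QC. The analyte area is divided by
the included theoretical coverage ("truncation correction", on by
default) so that relative abundances are not biased against heavier
analytes with wider envelopes.

## Calibration

Seven glycan calibrants spanning m/z 1,983–3,578 are searched within
±0.4 Da; a calibrant is accepted when its apex S/N ≥ 9, with S/N
estimated exactly as in extraction. A spectrum is recalibrated only if
≥5 calibrants are accepted, of which ≥3 below m/z 2,333 and ≥1 in
[2,333, 3,667) — only three of the seven calibrants lie below 2,333, so
the low-mass minimum demands all of them; the rule set is policy data.
The fit is theoretical = P(observed) by least squares, quadratic by
default (TOF axes are mildly nonlinear) with a degree-1 fallback when
the scaled Vandermonde condition number exceeds 10⁸; the fit is applied
to the whole axis and must leave it strictly increasing. The apex is
the maximum of the 3-point-smoothed window refined by a parabola
through its three surrounding samples — a raw grid maximum would
quantise observed masses to the sampling step (±0.01 Da ≈ 5 ppm at m/z
2,000), which alone would consume the residual budget.

## Extraction

Per-isotopologue windows are ±0.49 Da, clipped at the midpoint between
neighbouring theoretical isotopologue positions of any library analyte
(a point exactly on a midpoint belongs to the lower-m/z window).
Background is the median, and noise 1.4826 × MAD, of the intensities in
an m/z 15 region centred on the analyte with every library window
masked out; if fewer than 30 points survive the region is doubled (up
to 4×). These robust estimators resist contamination by neighbouring
peaks; the field's tooling names but does not define its estimators.
Background-subtracted per-isotopologue areas may be negative and are
not clipped, keeping the area estimator unbiased for absent analytes.
Spectrum-level summaries are the fraction of raw spectral area captured
by analyte windows and the fraction of analyte area at S/N ≥ 9.

## Curation

Spectra are retained when both summaries lie within mean ± 3 SD
(arithmetic, single pass, the sample included in its own statistics;
with inclusive statistics |z| cannot exceed (n−1)/√n, so the rule is
only informative for n ≥ 11). Analytes are retained when the
cross-sample mean QC ≤ 1.8×10⁻⁴ AND mean S/N ≥ 6; values strictly
beyond either bound discard. Near-isobaric composition pairs (e.g.
H5N4E2 / H6N5L1, Δ = 0.036 Da) share windows, fail QC and are curated
out — the intended behaviour on real profiles, where an initial
~100–150-composition library is reduced to the consistently quantified
subset.

## Traits

Relative abundances are analyte areas as a percentage of the summed
retained-analyte area. The default catalogue holds exactly 42 traits:
class fractions (M, Hy), antennarity (A2/A3/A4), fucosylation (F and
per-antennarity variants, plus antenna-fucosylation Fa), bisection (B
variants), and per-antenna galactosylation/sialylation over the
denominator grammar {complex, A2, A3, A4} × {any, fucosylated,
non-fucosylated}. Per-antenna traits divide the feature count by the
antenna count (so AE ≈ 77 % means 0.77 α2,6-sialic acids per antenna),
which keeps AE + AL ≤ AG ≤ 100 for non-negative profiles. F and B use
the complex-glycan denominator (hybrid/oligomannose excluded). Traits
with zero denominator abundance propagate as missing, never as zero.
Selectors are plain boolean expressions over feature names and the
catalogue round-trips through CSV, so the list can be replaced.

## Statistics

Comparisons are paired by subject: pregnancy (1st vs 3rd trimester),
short-term recovery (3rd trimester vs 6 weeks post-partum) and
long-term recovery (3rd trimester vs 26+ weeks). The Wilcoxon
signed-rank test drops zero differences, mid-ranks ties, and uses the
exact null distribution of the positive-rank sum (subset-sum dynamic
programming over doubled mid-ranks) up to 25 pairs, the tie-corrected
normal approximation above; p-values are two-sided. Significance is
Bonferroni-controlled within each comparison (α = 0.05/42 ≈ 0.0012 for
the trait family; 0.05/77 for an individual-glycan family). Shapiro–
Wilk normality is recorded per trait but never gates the method — the
analysis is nonparametric throughout. SEM uses the n−1 sample SD.

## Synthetic cohort

The generator emulates the study conditions: 29 subjects × 6 time
points (three trimesters; 6, 12, 26+ weeks post-partum) plus 10
technical replicates of a pooled sample, m/z 1,000–5,000. Peaks are
Gaussian with FWHM = m/R (R = 20,000), on a gentle quadratic baseline
with additive Gaussian noise (σ = 1 intensity unit against a default
total ion area of 2×10⁵) and a smooth ppm-scale mass-axis
miscalibration with per-spectrum jitter (σ = 5 ppm). The serum-like
base profile is a deterministic heuristic over structure features
(diantennary, galactosylated, α2,6-sialylated species dominate;
fucosylated diantennary species are less galactosylated/sialylated and
carry most bisection, as IgG-type glycans do). Programmed trait
trajectories follow the reported longitudinal magnitudes (e.g. AL
9.4 → 10.8 % across pregnancy, galactosylation falling and
fucosylation/bisection rising after delivery). Subject-visit targets =
time-point mean + subject random effect (σ = 1.5 pp) + visit noise
(σ = 0.5 pp), clipped to the attainable range; the profile is tilted
multiplicatively (w ← w·f^x per trait, f solved by 1-D root finding,
sweeps to 0.05 pp tolerance, ≤100 rounds) and then perturbed by
per-analyte log-normal subject (σ = 0.10) and visit (σ = 0.05)
effects, so traits not being programmed fluctuate biologically instead
of tracking the tilts deterministically. The exact traits of each final
profile are emitted as ground truth.

What the simulator does not emulate: ionisation suppression and
analyte-dependent response factors, detector saturation, isotope-
resolved peak-shape asymmetry, chemical (matrix-cluster) background
structure, and real biological covariance between traits beyond what
the tilt and log-normal noise induce. Passing tests therefore show that
the processing chain is correct and unbiased under these conditions,
not that real serum effect sizes will be recovered with the same power.

## Reduced problem sizes

The validation suite uses reduced designs chosen to exercise every
stage: a 40-analyte mass-resolved library (all 7 calibrants plus the
most abundant non-overlapping compositions, m/z 1,950–3,650) on a
1,900–3,700 axis at 0.02 Da sampling for cohort-level checks, and a
10-analyte version across ≥100 seeded null cohorts (12 subjects, two
visits) for family-wise error control. Mass-resolved subsets are used
because overlapping analytes are deliberately curated away, which would
otherwise decouple the pipeline's denominator from the generator's.

## Known limitations

* The default analyte library is a combinatorial serum-plausible
  enumeration (~150 compositions), not a curated clinical list; it is
  swappable via CSV.
* The exact trait-list and QC formula of the original tooling are not
  public; the catalogue's fill-in grammar and the sum-of-squares QC are
  this package's definitions, with the QC threshold configurable.
* Quadratic calibration is a choice, not an instrument fact; the
  degree is policy.
* Hybrid-glycan feature rules are minimal (see above).
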