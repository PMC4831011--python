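# tsng — total serum N-glycome MALDI-TOF-MS processing

`tsng` turns text-exported MALDI-TOF mass spectra of enzymatically
released, linkage-specifically derivatised serum *N*-glycans into
quality-curated relative abundances, derived glycosylation traits and
longitudinal paired statistics. It is aimed at glycomics groups running
high-throughput ethyl-esterification workflows, where sialic-acid
derivatisation encodes linkage in mass: an α2,6-linked
*N*-acetylneuraminic acid becomes an ethyl ester (**E**, residue
+C₂H₄) and an α2,3-linked one a lactone (**L**, residue −H₂O), so
[M+Na]⁺ masses separate the two isomers.

## What it computes

Compositions are written in single-letter code (H hexose, N
*N*-acetylhexosamine, F fucose, E/L derivatised sialic acids), e.g.
`H5N4F1E2L1`. For each composition the package computes, from IUPAC
monoisotopic atomic masses, the singly sodiated ion mass

  m/z = Σ residues + H₂O (free reducing end) + Na⁺ − e⁻

and the aggregated isotopic envelope by element-wise convolution. The
processing chain then mirrors the established targeted-integration
scheme:

1. **Internal calibration** — ≥5 of 7 glycan calibrants above S/N 9,
   with low/high m/z coverage rules, detected within ±0.4 Da; a
   least-squares polynomial recalibrates the axis.
2. **Extraction** — per analyte, isotopologues covering ≥95 % of the
   theoretical envelope are integrated in ±0.49 Da windows; background =
   median and noise = 1.4826·MAD of a flanking m/z 15 region with all
   library peaks masked; QC = Σₖ (observed fractionₖ − theoretical
   fractionₖ)².
3. **Curation** — spectra kept within mean ± 3 SD on "fraction of
   spectrum in analytes" and "fraction of analyte area above S/N 9";
   analytes kept when mean QC ≤ 1.8×10⁻⁴ and mean S/N ≥ 6.
4. **Traits** — total-area normalisation, then 42 derived traits over
   structure features (antennarity A, galactosylation G per antenna,
   bisection B, fucosylation F, linkage-specific sialylation E/L per
   antenna), using most-common-structure assignment (e.g. H5N5 is read
   as a bisected diantennary glycan).
5. **Statistics** — per-trait paired two-sided Wilcoxon signed-rank
   tests between time points (exact null distribution up to n = 25),
   Bonferroni-adjusted α (0.05/42 ≈ 0.0012), Shapiro–Wilk recorded.

A synthetic-data module generates a longitudinal cohort (by default 29
subjects × 6 time points plus 10 technical replicates) with programmed
trait trajectories, realistic envelopes, baseline, noise and mass-axis
miscalibration — every stage is validated end-to-end against its exact
ground truth.

## Worked example

```python
>>> from tsng import monoisotopic_mz, parse_composition, assign_structure
>>> monoisotopic_mz(parse_composition("H5N4E2"))
2301.834825844091
>>> assign_structure(parse_composition("H5N5"))
StructureAssignment(glycan_class='complex', antennae=2, galactoses=2,
bisected=True, core_fucoses=0, antenna_fucoses=0, sialic_23=0, sialic_26=0)
```

A reduced simulated cohort (29 subjects, two visits, 40 analytes, a
programmed rise of α2,3-sialylation AL from 9.4 % to 10.8 %):

```python
from tsng.calibration import DEFAULT_CALIBRANTS
from tsng.glycans import default_library
from tsng.simulate import CohortDesign, InstrumentModel, select_resolved_subset, simulate_cohort
from tsng.workflow import RunConfig, run_pipeline

lib = select_resolved_subset(
    [e for e in default_library() if 1950 < e.mz < 3650], 40,
    must_include=DEFAULT_CALIBRANTS)
inst = InstrumentModel(mz_range=(1900, 3700), step=0.02,
                       miscalibration_ppm=(30.0,), seed=1)
design = CohortDesign(n_subjects=29, time_points=("trim1", "trim3"),
                      trait_targets={"AL": {"trim1": 9.4, "trim3": 10.8}},
                      n_technical=0, seed=1)
cohort = simulate_cohort(design, lib, inst)
res = run_pipeline(RunConfig(), spectra={s.sample_id: s for s in cohort.spectra},
                   manifest=cohort.manifest, library=lib, write=False)
print(res.stats.summary(significant_only=True))
```

prints (excerpt)

```
Paired Wilcoxon signed-rank tests (family alpha 0.05, 42 tests per comparison, adjusted alpha 0.0012)
----------------------------------------------------------------------------------------
trait   comparison               n       mean1±SEM       mean2±SEM           p  sig dir
...
AL      pregnancy               29     9.20±0.25     10.43±0.25    5.322e-06  *   up
A2L     pregnancy               29     6.73±0.19      7.70±0.20    5.897e-06  *   up
A3L     pregnancy               29    29.87±0.54     32.09±0.54    2.849e-06  *   up
...
```

The programmed AL increase is recovered (9.20 → 10.43 % across the
pipeline, matching the generator's exact ground truth to < 0.01
percentage points) and flagged significant at the Bonferroni-adjusted
level; traits biologically coupled to α2,3-sialylation (A3, A2L, …)
move with it, while uncoupled traits stay non-significant.

From the shell the same pipeline runs as `tsng simulate` / `tsng run`
(see `tsng --help`); all policies live in a single YAML config.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the simulator does and does not emulate, and numerical choices.
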