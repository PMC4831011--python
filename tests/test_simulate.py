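"""Spectrum renderer and cohort generator against closed-form ground truth."""

import numpy as np
import pandas as pd
import pytest

from tsng.glycans import default_library
from tsng.simulate import (
    CohortDesign,
    InstrumentModel,
    select_resolved_subset,
    serum_base_profile,
    simulate_cohort,
    simulate_spectrum,
    tilt_profile,
)
from tsng.traits import compute_traits, trait_catalogue


def test_single_analyte_area_matches_injected_abundance(quiet_instrument, resolved_lib40):
    entry = next(e for e in resolved_lib40 if e.name == "H5N4E2")
    spec, truth = simulate_spectrum(
        {entry.name: 5000.0}, [entry], quiet_instrument, sample_id="one"
    )
    total = np.trapezoid(spec.intensity, spec.mz)
    assert total == pytest.approx(5000.0, rel=0.005)
    assert truth == {"H5N4E2": 5000.0}


def test_zero_abundances_give_baseline_plus_noise(resolved_lib40):
    inst = InstrumentModel(
        mz_range=(1900.0, 2100.0), step=0.05, noise_sd=0.0, seed=3
    )
    spec, _ = simulate_spectrum({e.name: 0.0 for e in resolved_lib40[:3]},
                               resolved_lib40, inst)
    assert np.allclose(spec.intensity, inst.baseline(spec.mz))


def test_fixed_seed_is_bit_identical(resolved_lib40, reduced_instrument):
    areas = {resolved_lib40[0].name: 100.0}
    a, _ = simulate_spectrum(areas, resolved_lib40, reduced_instrument)
    b, _ = simulate_spectrum(areas, resolved_lib40, reduced_instrument)
    assert np.array_equal(a.intensity, b.intensity)


def test_miscalibration_shifts_peaks_by_ppm(quiet_instrument, resolved_lib40):
    inst = InstrumentModel(
        mz_range=(1900.0, 3700.0),
        step=0.02,
        baseline_coeffs=(0.0,),
        noise_sd=0.0,
        miscalibration_ppm=(100.0,),
    )
    entry = next(e for e in resolved_lib40 if e.name == "H5N4E2")
    spec, _ = simulate_spectrum({entry.name: 1000.0}, [entry], inst)
    expected = entry.mz * (1 + 100e-6)
    mz_w, int_w = spec.slice(expected - 0.45, expected + 0.45)
    apex = mz_w[np.argmax(int_w)]
    assert apex == pytest.approx(expected, abs=inst.step)


def test_tilt_hits_targets_and_unreachable_raises(resolved_lib40):
    base = serum_base_profile(resolved_lib40)
    targets = {"AL": 12.0, "F": 30.0}
    prof = tilt_profile(base, targets, resolved_lib40)
    traits = compute_traits(pd.Series(prof) * 100.0, resolved_lib40)
    assert traits["AL"] == pytest.approx(12.0, abs=0.05)
    assert traits["F"] == pytest.approx(30.0, abs=0.05)
    with pytest.raises(ValueError, match="unreachable"):
        tilt_profile(base, {"AL": 100.0}, resolved_lib40)


def _reduced_design(**kw):
    from tsng.simulate import DEFAULT_TRAIT_TARGETS

    targets = {
        k: {tp: v[tp] for tp in ("trim1", "trim3")}
        for k, v in DEFAULT_TRAIT_TARGETS.items()
    }
    kw.setdefault("n_subjects", 8)
    kw.setdefault("time_points", ("trim1", "trim3"))
    kw.setdefault("trait_targets", targets)
    kw.setdefault("n_technical", 0)
    kw.setdefault("seed", 11)
    return CohortDesign(**kw)


def test_programmed_effect_recovered_in_ground_truth_means(resolved_lib40, reduced_instrument):
    design = _reduced_design(n_subjects=20)
    cohort = simulate_cohort(design, resolved_lib40, reduced_instrument, render=False)
    gt = cohort.ground_truth_traits
    ids = cohort.manifest.set_index("sample_id")
    for tp, target in (("trim1", 9.4), ("trim3", 10.8)):
        sel = ids[ids["time_point"] == tp].index
        # Monte-Carlo error of the mean at n=20 with 1.5 pp between-subject SD
        assert gt.loc[sel, "AL"].mean() == pytest.approx(target, abs=1.2)


def test_zero_effect_design_is_constant_up_to_noise(resolved_lib40, reduced_instrument):
    targets = {"AL": {"trim1": 9.4, "trim3": 9.4}}
    design = _reduced_design(
        trait_targets=targets,
        n_subjects=10,
        within_subject_sd=0.0,
        analyte_subject_sd=0.0,
        analyte_visit_sd=0.0,
    )
    cohort = simulate_cohort(design, resolved_lib40, reduced_instrument, render=False)
    gt = cohort.ground_truth_traits
    ids = cohort.manifest.set_index("sample_id")
    wide = pd.DataFrame(
        {
            tp: gt.loc[ids[ids["time_point"] == tp].index, "AL"].to_numpy()
            for tp in ("trim1", "trim3")
        }
    )
    # per-subject AL identical across visits when visit noise is off
    assert np.allclose(wide["trim1"], wide["trim3"], atol=0.11)


def test_cohort_fixed_seed_identical(resolved_lib40, reduced_instrument):
    design = _reduced_design(n_subjects=2)
    a = simulate_cohort(design, resolved_lib40, reduced_instrument)
    b = simulate_cohort(design, resolved_lib40, reduced_instrument)
    pd.testing.assert_frame_equal(a.ground_truth_traits, b.ground_truth_traits)
    for sa, sb in zip(a.spectra, b.spectra):
        assert np.array_equal(sa.intensity, sb.intensity)


def test_ground_truth_consistent_with_noise_free_pipeline(resolved_lib40):
    """End-to-end: noise-free, perfectly calibrated renderings re-extracted
    by the pipeline reproduce the generator's exact trait values."""
    from tsng.workflow import RunConfig, run_pipeline

    design = _reduced_design(n_subjects=2, miscal_jitter_ppm=0.0)
    inst = InstrumentModel(
        mz_range=(1900.0, 3700.0), step=0.02, baseline_coeffs=(0.0,), noise_sd=0.0
    )
    cohort = simulate_cohort(design, resolved_lib40, inst)
    cfg = RunConfig(skip_calibration=True)
    res = run_pipeline(
        cfg,
        spectra={s.sample_id: s for s in cohort.spectra},
        manifest=cohort.manifest,
        library=resolved_lib40,
        write=False,
    )
    gt = cohort.ground_truth_traits.loc[res.trait_table.index]
    err = (res.trait_table - gt).abs().to_numpy()
    assert np.nanmax(err) < 0.1


def test_unreachable_cohort_target_names_trait():
    with pytest.raises(ValueError, match="AL"):
        _reduced_design(trait_targets={"AL": {"trim1": 120.0, "trim3": 9.0}})
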