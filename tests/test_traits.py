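"""Relative quantification and the derived-trait algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsng.glycans import default_library
from tsng.traits import (
    compute_traits,
    normalize,
    read_catalogue,
    replicate_rsd,
    trait_catalogue,
    trait_value,
    write_catalogue,
)


def _by_name(catalogue):
    return {d.name: d for d in catalogue}


class TestNormalize:
    def test_simple_ratio(self):
        p = normalize({"a": 3.0, "b": 1.0})
        assert p["a"] == pytest.approx(75.0)
        assert p["b"] == pytest.approx(25.0)

    def test_equal_areas(self):
        p = normalize({c: 5.0 for c in "abcd"})
        assert np.allclose(p.to_numpy(), 25.0)

    def test_scale_invariance(self):
        a = normalize({"a": 3.0, "b": 1.0})
        b = normalize({"a": 21.0, "b": 7.0})
        pd.testing.assert_series_equal(a, b)

    def test_non_positive_total_raises(self):
        with pytest.raises(ValueError, match="total area"):
            normalize({"a": -1.0, "b": 1.0})


class TestTraitValues:
    def test_fully_galactosylated_profile(self, library):
        cat = _by_name(trait_catalogue())
        p = pd.Series({"H5N4": 100.0})
        assert trait_value(p, cat["AG"], library) == pytest.approx(100.0)

    def test_per_antenna_sialylation_mixture(self, library):
        cat = _by_name(trait_catalogue())
        p = pd.Series({"H5N4E1": 50.0, "H5N4E2": 50.0})
        # (0.5 * 1/2 + 0.5 * 2/2) * 100
        assert trait_value(p, cat["AE"], library) == pytest.approx(75.0)

    def test_antennarity_split_and_al(self, library):
        cat = _by_name(trait_catalogue())
        p = pd.Series({"H5N4E2": 80.0, "H6N5E2L1": 20.0})
        assert trait_value(p, cat["A2"], library) == pytest.approx(80.0)
        assert trait_value(p, cat["A3"], library) == pytest.approx(20.0)
        assert trait_value(p, cat["AL"], library) == pytest.approx(
            (0.8 * 0 + 0.2 * (1 / 3)) * 100
        )

    def test_zero_denominator_is_nan_not_zero(self, library):
        cat = _by_name(trait_catalogue())
        p = pd.Series({"H5N2": 100.0})  # oligomannose only
        assert np.isnan(trait_value(p, cat["A2"], library))


class TestCatalogue:
    def test_exactly_42_traits(self):
        assert len(trait_catalogue()) == 42

    def test_named_traits_present(self):
        names = {d.name for d in trait_catalogue()}
        required = {
            "A2", "A3", "AG", "A2G", "A2FG", "F", "A2F", "B", "A2B", "A2FB",
            "AE", "AL", "A2E", "A2L", "A2FE", "A2FL", "A2F0L", "A3L", "A3F0L",
            "A3FE", "Fa", "M", "Hy",
        }
        assert required <= names

    def test_a2fg_definition(self):
        d = _by_name(trait_catalogue())["A2FG"]
        assert d.kind == "per_antenna" and d.feature == "galactoses"
        assert "A == 2" in d.denominator and "Ftot >= 1" in d.denominator

    def test_a3f0l_definition(self):
        d = _by_name(trait_catalogue())["A3F0L"]
        assert d.kind == "per_antenna" and d.feature == "sialic_23"
        assert "A == 3" in d.denominator and "Ftot == 0" in d.denominator

    def test_denominators_non_empty_on_default_library(self, library):
        from tsng.traits import feature_fractions

        for d in trait_catalogue():
            mask, _ = feature_fractions(d, library)
            assert mask.any(), d.name

    def test_file_round_trip(self, tmp_path):
        cat = trait_catalogue()
        write_catalogue(cat, tmp_path / "cat.csv")
        back = read_catalogue(tmp_path / "cat.csv")
        assert back == cat


@st.composite
def random_profiles(draw, library_names):
    n = draw(st.integers(5, 20))
    idx = draw(
        st.lists(
            st.integers(0, len(library_names) - 1), min_size=n, max_size=n, unique=True
        )
    )
    vals = draw(
        st.lists(st.floats(0.01, 100.0), min_size=n, max_size=n)
    )
    return pd.Series(dict(zip([library_names[i] for i in idx], vals)))


class TestInvariants:
    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_sialylation_bounded_by_galactosylation(self, data):
        library = default_library()
        names = [e.name for e in library]
        profile = data.draw(random_profiles(names))
        profile = 100 * profile / profile.sum()
        cat = _by_name(trait_catalogue())
        ae = trait_value(profile, cat["AE"], library)
        al = trait_value(profile, cat["AL"], library)
        ag = trait_value(profile, cat["AG"], library)
        if not (np.isnan(ae) or np.isnan(al) or np.isnan(ag)):
            assert ae + al <= ag + 1e-9
            assert ag <= 100 + 1e-9

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_antennarity_fractions_sum_to_100(self, data):
        library = default_library()
        names = [e.name for e in library]
        profile = data.draw(random_profiles(names))
        cat = _by_name(trait_catalogue())
        vals = [
            trait_value(profile, cat[t], library) for t in ("A2", "A3", "A4")
        ]
        if not any(np.isnan(v) for v in vals):
            assert sum(vals) == pytest.approx(100.0, abs=1e-9)

    def test_invariance_to_rescaling_and_order(self, library):
        rng = np.random.default_rng(1)
        names = [e.name for e in library][:30]
        vals = rng.uniform(0.1, 10, size=30)
        p1 = pd.Series(dict(zip(names, vals)))
        p2 = (7.7 * p1).sample(frac=1.0, random_state=2)
        t1 = compute_traits(p1, library)
        t2 = compute_traits(p2, library)
        pd.testing.assert_series_equal(t1, t2, check_names=False)


class TestReplicateRsd:
    def test_identical_replicates(self):
        assert replicate_rsd([5.0, 5.0, 5.0]) == 0.0

    def test_two_values(self):
        assert replicate_rsd([9.0, 11.0]) == pytest.approx(14.142, abs=0.01)

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError):
            replicate_rsd([5.0])
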