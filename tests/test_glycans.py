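"""Composition parsing, derivatised masses and structure assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsng.glycans import (
    GlycanComposition,
    GlycanParseError,
    StructureError,
    assign_structure,
    default_library,
    elemental_composition,
    generate_library,
    monoisotopic_mz,
    parse_composition,
    read_library,
    write_library,
)

# printed [M+Na]+ calibrant masses of the ethyl-esterified serum N-glycome
CALIBRANT_MASSES = {
    "H5N4E1": 1982.708,
    "H5N4F1E1": 2128.766,
    "H5N4E2": 2301.835,
    "H6N5E2L1": 2940.052,
    "H6N5F1E2L1": 3086.110,
    "H7N6E1L3": 3532.227,
    "H7N6E2L2": 3578.269,
}


class TestParsing:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("H5N4E2", dict(hex=5, hexnac=4, neuac_26=2)),
            ("H6N5F1E2L1", dict(hex=6, hexnac=5, fuc=1, neuac_26=2, neuac_23=1)),
            ("H4N2", dict(hex=4, hexnac=2)),
        ],
    )
    def test_examples(self, code, expected):
        assert parse_composition(code) == GlycanComposition(**expected)

    @pytest.mark.parametrize(
        "bad", ["H5X4", "H5N", "H5N4H1", "", "5H4N", "H5,N4"]
    )
    def test_errors(self, bad):
        with pytest.raises(GlycanParseError):
            parse_composition(bad)

    @given(
        st.fixed_dictionaries(
            {
                "hex": st.integers(0, 12),
                "hexnac": st.integers(0, 8),
                "fuc": st.integers(0, 3),
                "neuac_26": st.integers(0, 4),
                "neuac_23": st.integers(0, 4),
            }
        ).filter(lambda d: sum(d.values()) >= 1)
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, counts):
        g = GlycanComposition(**counts)
        assert parse_composition(str(g)) == g


class TestMasses:
    def test_empty_glycan_is_water_plus_sodium(self):
        # residue-free formula: only the free reducing end's water + Na
        g = GlycanComposition(hex=0, hexnac=0, fuc=1)  # minimal valid
        comp = elemental_composition(g)
        from tsng.glycans import RESIDUES, SODIUM, WATER

        assert comp.counts == (RESIDUES["F"] + WATER + SODIUM).counts

    def test_summed_residue_formula(self):
        # independent hand summation: 5xC6H10O5 + 4xC8H13NO5 + 2xC13H21NO8
        # + H2O + Na
        comp = elemental_composition(parse_composition("H5N4E2"))
        assert comp.counts == {"C": 88, "H": 146, "N": 6, "O": 62, "Na": 1}
        minus_e = elemental_composition(parse_composition("H5N4E1"))
        assert minus_e.counts == {"C": 75, "H": 125, "N": 5, "O": 54, "Na": 1}

    @pytest.mark.parametrize("code,mass", sorted(CALIBRANT_MASSES.items()))
    def test_printed_calibrant_masses(self, code, mass):
        assert monoisotopic_mz(parse_composition(code)) == pytest.approx(
            mass, abs=0.001
        )

    def test_cross_check_against_pyteomics(self):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for code in CALIBRANT_MASSES:
            comp = elemental_composition(parse_composition(code))
            ref = pyteomics_mass.calculate_mass(
                formula=comp.formula().replace("Na", "Na1"), charge=0
            )
            assert monoisotopic_mz(parse_composition(code)) == pytest.approx(
                ref - 0.000548579909, abs=2e-3
            )

    @pytest.mark.parametrize(
        "letter,delta",
        [("neuac_26", 319.1267), ("neuac_23", 273.0849), ("fuc", 146.0579)],
    )
    def test_residue_mass_increments(self, letter, delta):
        g = parse_composition("H5N4")
        g2 = GlycanComposition(**{**g.__dict__, letter: 1})
        assert monoisotopic_mz(g2) - monoisotopic_mz(g) == pytest.approx(
            delta, abs=1e-4
        )

    def test_mass_strictly_increasing_in_every_residue(self):
        g = parse_composition("H5N4F1E1L1")
        for field in ("hex", "hexnac", "fuc", "neuac_26", "neuac_23"):
            g2 = GlycanComposition(**{**g.__dict__, field: getattr(g, field) + 1})
            assert monoisotopic_mz(g2) > monoisotopic_mz(g)


class TestStructureAssignment:
    def test_h5n5_prefers_bisected_diantennary(self):
        s = assign_structure(parse_composition("H5N5"))
        assert (s.glycan_class, s.bisected, s.antennae, s.galactoses) == (
            "complex",
            True,
            2,
            2,
        )

    def test_h6n5_is_triantennary(self):
        s = assign_structure(parse_composition("H6N5"))
        assert (s.glycan_class, s.bisected, s.antennae, s.galactoses) == (
            "complex",
            False,
            3,
            3,
        )

    def test_h4n5f1e1_is_fa2bg1s1(self):
        s = assign_structure(parse_composition("H4N5F1E1"))
        assert s.glycan_class == "complex"
        assert s.bisected and s.antennae == 2 and s.galactoses == 1
        assert s.core_fucoses == 1 and s.antenna_fucoses == 0
        assert s.sialic_26 == 1 and s.sialic_23 == 0

    def test_oligomannose_and_hybrid(self):
        assert assign_structure(parse_composition("H6N2")).glycan_class == "oligomannose"
        assert assign_structure(parse_composition("H5N3E1")).glycan_class == "hybrid"

    def test_sialyl_lewis_context_fucose_is_antennary(self):
        with_l = assign_structure(parse_composition("H6N5F1E1L1"))
        assert with_l.antenna_fucoses == 1 and with_l.core_fucoses == 0
        without_l = assign_structure(parse_composition("H6N5F1E2"))
        assert without_l.core_fucoses == 1 and without_l.antenna_fucoses == 0

    def test_implausible_composition_raises(self):
        with pytest.raises(StructureError):
            assign_structure(parse_composition("H12N4"))  # G > A both readings
        with pytest.raises(StructureError):
            assign_structure(parse_composition("H3N2F1"))

    def test_total_and_deterministic_over_default_library(self, library):
        for e in library:
            s = assign_structure(e.composition)
            assert s == e.structure
            if s.glycan_class == "complex":
                assert s.sialic_23 + s.sialic_26 <= s.galactoses <= s.antennae


class TestLibrary:
    def test_contains_all_calibrants(self, library):
        names = {e.name for e in library}
        assert set(CALIBRANT_MASSES) <= names

    def test_sorted_unique_in_range(self, library):
        mzs = [e.mz for e in library]
        assert mzs == sorted(mzs)
        assert len({e.name for e in library}) == len(library)
        assert all(1000 <= m <= 5000 for m in mzs)

    def test_restricted_enumeration_matches_counting_oracle(self):
        # A2-only, F<=1, no bisection, E-only sialylation:
        # count = sum over G in 0..2, F in 0..1, E in 0..G of 1
        lib = generate_library(
            antennae=(2,),
            max_fucoses={2: 1},
            allow_bisection=False,
            sialylation="E",
            include_oligomannose=False,
            include_hybrids=False,
        )
        expected = sum(
            1 for g, f, e in itertools.product(range(3), range(2), range(3)) if e <= g
        )
        assert len(lib) == expected

    def test_file_round_trip(self, library, tmp_path):
        path = tmp_path / "library.csv"
        write_library(library, path)
        back = read_library(path)
        assert [e.name for e in back] == [e.name for e in library]
        assert all(
            a.mz == pytest.approx(b.mz, abs=1e-3) for a, b in zip(back, library)
        )
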