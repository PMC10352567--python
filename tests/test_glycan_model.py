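"""Composition grammar, residue-mass chemistry, classification, library."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoquant.glycan_model import (
    ACETYL,
    CALIBRANT_PANEL,
    DEFAULT_PANEL,
    HEAVY_LABEL,
    MZ_WINDOW,
    RESIDUE_MASSES,
    SODIUM_CATION,
    SYMBOL_ORDER,
    WATER,
    CompositionError,
    GlycanComposition,
    build_library,
    classify_structure,
    internal_standard_mz,
    load_panel,
    neutral_mass,
    parse_composition,
    sodiated_mz,
)

PPM = 1e-6

# printed calibrant m/z of the seven calibration glycans
CALIBRANT_MZ = {
    "H4N4F1": 1647.5865,
    "H4N4Ge1": 1836.65066,
    "H5N4F1Ge2": 2479.88342,
    "H5N4Ge1": 1998.70346,
    "H5N4Ge1Gl1": 2287.77848,
    "H5N4Ge2": 2333.82552,
    "H5N4Ge2Gl1": 2622.90054,
}

compositions = st.builds(
    GlycanComposition,
    H=st.integers(0, 9),
    N=st.integers(0, 6),
    F=st.integers(0, 3),
    E=st.integers(0, 2),
    L=st.integers(0, 2),
    Ge=st.integers(0, 2),
    Gl=st.integers(0, 2),
)


class TestResidueChemistry:
    def test_all_masses_positive(self):
        assert all(m > 0 for m in RESIDUE_MASSES.values())

    def test_neu5gc_is_neu5ac_plus_oxygen(self):
        o = 15.9949146
        assert RESIDUE_MASSES["Ge"] - RESIDUE_MASSES["E"] == pytest.approx(o, abs=1e-6)
        assert RESIDUE_MASSES["Gl"] - RESIDUE_MASSES["L"] == pytest.approx(o, abs=1e-6)

    def test_ester_lactone_difference(self):
        # ethyl ester (+C2H4) vs lactone (-H2O): +C2H4 + H2O = 46.0419 Da
        diff = 46.041865
        assert RESIDUE_MASSES["E"] - RESIDUE_MASSES["L"] == pytest.approx(diff, abs=1e-6)
        assert RESIDUE_MASSES["Ge"] - RESIDUE_MASSES["Gl"] == pytest.approx(diff, abs=1e-6)


class TestParser:
    @pytest.mark.parametrize(
        "name,counts",
        [
            ("H4N4F1", dict(H=4, N=4, F=1)),
            ("H5N4Ge2Ac1", dict(H=5, N=4, Ge=2, Ac=1)),
            ("H5N4Ge1Gl1", dict(H=5, N=4, Ge=1, Gl=1)),
            ("H5N4E1L1", dict(H=5, N=4, E=1, L=1)),
        ],
    )
    def test_examples(self, name, counts):
        comp = parse_composition(name)
        for sym in SYMBOL_ORDER:
            assert getattr(comp, sym) == counts.get(sym, 0)
        assert comp.name == name

    @pytest.mark.parametrize(
        "bad,fragment",
        [
            ("H1X1", "position 2"),       # unknown symbol
            ("H", "position 0"),          # missing count
            ("H0N2", "zero count"),
            ("H1H2", "repeated symbol"),
            ("H5N4Ac1", "exceeds sialic"),  # acetyl without sialic acid
            ("", "empty"),
        ],
    )
    def test_rejections_name_offense(self, bad, fragment):
        with pytest.raises(CompositionError, match=fragment):
            parse_composition(bad)

    @settings(derandomize=True, max_examples=100)
    @given(compositions)
    def test_roundtrip(self, comp):
        if comp.name:  # the all-zero composition has no printable name
            assert parse_composition(comp.name) == comp

    def test_panel_roundtrip(self):
        for name in DEFAULT_PANEL:
            assert parse_composition(name).name == name


class TestMasses:
    def test_water_only(self):
        assert neutral_mass(GlycanComposition()) == pytest.approx(18.01056, abs=1e-5)

    def test_neutral_hand_sum(self):
        # 4 x 162.052824 + 4 x 203.079373 + 146.057909 + 18.010565
        assert neutral_mass("H4N4F1") == pytest.approx(1624.5973, abs=5e-4)

    def test_sodiated_empty(self):
        assert sodiated_mz(GlycanComposition()) == pytest.approx(41.0000, abs=5e-4)

    @pytest.mark.parametrize("name,mz", CALIBRANT_MZ.items())
    def test_calibrants_within_5ppm(self, name, mz):
        assert abs(sodiated_mz(name) - mz) / mz < 5 * PPM

    def test_heavy_shift_value(self):
        assert HEAVY_LABEL == pytest.approx(3.02193, abs=1e-5)
        assert internal_standard_mz("H4N4F1") == pytest.approx(1650.6084, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(compositions, compositions)
    def test_additivity(self, a, b):
        combined = GlycanComposition(
            **{s: getattr(a, s) + getattr(b, s) for s in SYMBOL_ORDER}
        )
        assert neutral_mass(a) + neutral_mass(b) - WATER == pytest.approx(
            neutral_mass(combined), abs=1e-9
        )

    @settings(derandomize=True, max_examples=50)
    @given(compositions, st.sampled_from(["H", "N", "F", "E", "L", "Ge", "Gl"]))
    def test_monotonic_in_every_count(self, comp, sym):
        bumped = GlycanComposition(
            **{s: getattr(comp, s) + (s == sym) for s in SYMBOL_ORDER}
        )
        assert neutral_mass(bumped) > neutral_mass(comp)

    def test_acetyl_adds_42(self):
        assert neutral_mass("H5N4Ge2Ac1") - neutral_mass("H5N4Ge2") == pytest.approx(
            ACETYL, abs=1e-9
        )


class TestClassification:
    @pytest.mark.parametrize(
        "name,label,antennae,galactoses,sialic,branched",
        [
            ("H5N2", "high_mannose", 0, 0, 0, False),
            ("H9N2", "high_mannose", 0, 0, 0, False),
            ("H5N4Ge2", "complex", 2, 2, 2, False),
            ("H6N5Ge1Gl2", "complex", 3, 3, 3, False),
            ("H5N4Ge3", "complex", 2, 2, 3, True),
            ("H5N3Ge1", "hybrid", 1, 0, 1, False),
            ("H6N3", "hybrid", 1, 1, 0, False),
            ("H3N4", "complex", 2, 0, 0, False),
            ("H3N3", "complex", 1, 0, 0, False),
            ("H3N2", "other", 0, 0, 0, False),
            ("H5N2F1", "other", 0, 0, 0, False),
        ],
    )
    def test_rules(self, name, label, antennae, galactoses, sialic, branched):
        s = classify_structure(name)
        assert (s.label, s.antennae, s.galactoses, s.sialic, s.branched) == (
            label, antennae, galactoses, sialic, branched
        )

    def test_linkage_counts(self):
        s = classify_structure("H5N4F1Ge1Gl1")
        assert (s.a23, s.a26, s.neu5ac, s.neu5gc) == (1, 1, 0, 2)
        assert s.fucosylated and not s.acetylated

    def test_not_an_nglycan(self):
        with pytest.raises(CompositionError, match="HexNAc"):
            classify_structure("H5N1")

    def test_total_function_over_panel(self):
        labels = {classify_structure(n).label for n in DEFAULT_PANEL}
        assert labels <= {"high_mannose", "hybrid", "complex", "other"}


class TestLibrary:
    def test_default_panel(self, library):
        assert len(library) == len(DEFAULT_PANEL)
        light = library.light_mz
        assert (np.diff(light) > 0).all()
        assert light.min() >= MZ_WINDOW[0]
        assert library.heavy_mz.max() <= MZ_WINDOW[1]
        assert library.collisions == []

    def test_heavy_shift_constant(self, library):
        shift = library.heavy_mz - library.light_mz
        assert np.ptp(shift) < 1e-6
        assert shift[0] == pytest.approx(HEAVY_LABEL, abs=1e-9)

    def test_calibrant_library_no_collisions(self):
        lib = build_library(CALIBRANT_PANEL, tol_ppm=10)
        assert len(lib) == 7 and lib.collisions == []

    def test_single_glycan(self):
        lib = build_library(["H5N4"])
        assert len(lib) == 1 and lib.collisions == []

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_library(["H5N4", "H5N4"])

    def test_out_of_window_excluded(self):
        lib = build_library(["H5N4", "H1N2"])  # H1N2 sits below m/z 700
        assert lib.names == ["H5N4"]
        assert lib.excluded[0][0] == "H1N2"

    def test_collision_report_triggers(self):
        # 0.5 Da apart at m/z ~1500 is ~330 ppm; a huge tolerance must flag it
        lib = build_library(["H4N4", "H5N4"], tol_ppm=1e5)
        assert lib.collisions

    def test_export_columns(self, library, tmp_path):
        path = tmp_path / "lib.tsv"
        library.write_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == [
            "name", "light_mz", "heavy_mz", "class", "antennae", "galactoses",
            "sialic_23", "sialic_26", "neu5ac", "neu5gc", "acetylated",
            "fucosylated",
        ]

    def test_load_panel(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("# comment\nH5N4\nH4N4F1  # trailing\n\n")
        assert load_panel(p) == ["H5N4", "H4N4F1"]

    def test_load_empty_panel_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("# nothing here\n")
        with pytest.raises(ValueError, match="no compositions"):
            load_panel(p)
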