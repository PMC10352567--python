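"""Peak-list reading, S/N filtering, recalibration, pair matching."""
import numpy as np
import pandas as pd
import pytest

from glycoquant.glycan_model import build_library, sodiated_mz
from glycoquant.peak_processing import (
    AMBIGUOUS,
    HEAVY_MISSING,
    OK,
    CalibrationFit,
    PeakListError,
    aggregate_replicates,
    estimate_snr,
    match_pairs,
    process_peaklists,
    read_peaklist,
    recalibrate,
    snr_filter,
)
from glycoquant.synthetic_data import SpectrumModel, StudyDesign, generate_dataset
from tests.conftest import NOISELESS_EFFECTS


def peaks_frame(*rows):
    df = pd.DataFrame(rows, columns=["mz", "intensity"])
    return df.sort_values("mz", ignore_index=True)


class TestReadPeaklist:
    def test_sorted_output(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("1000.0\t5.0\n900.0\t2.0\n")
        df = read_peaklist(p)
        assert df["mz"].tolist() == [900.0, 1000.0]
        assert df["intensity"].tolist() == [2.0, 5.0]

    def test_window_drop(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("650.0\t1.0\n1000.0\t5.0\n3600.0\t1.0\n")
        df = read_peaklist(p)
        assert df["mz"].tolist() == [1000.0]

    def test_header_tolerated_comma_separated(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n1000.0,5.0\n")
        assert len(read_peaklist(p)) == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("1000.0\t5.0\nnot-a-number\tx\n")
        with pytest.raises(PeakListError, match="line 2"):
            read_peaklist(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with pytest.raises(PeakListError, match="no peaks"):
            read_peaklist(p)


class TestSnr:
    def test_strictly_greater_than_threshold(self):
        peaks = peaks_frame((1000.0, 1.0), (1100.0, 2.0), (1200.0, 3.0))
        peaks["snr"] = [10.0, 3.0, 4.0]
        out = snr_filter(peaks, threshold=3)
        # S/N exactly 3 is dropped
        assert out["snr"].tolist() == [10.0, 4.0]

    def test_negative_threshold_rejected(self):
        peaks = peaks_frame((1000.0, 1.0))
        peaks["snr"] = [1.0]
        with pytest.raises(ValueError):
            snr_filter(peaks, threshold=-1)

    def test_empty_result_allowed(self):
        peaks = peaks_frame((1000.0, 1.0))
        peaks["snr"] = [1.0]
        assert snr_filter(peaks, threshold=3).empty

    def test_estimate_from_decoys(self, library):
        entry = library.entries[0]
        rows = [(entry.light_mz, 50.0), (entry.heavy_mz, 100.0)]
        rows += [(entry.light_mz + 20 + i * 7.0, 1.0) for i in range(10)]
        peaks = estimate_snr(peaks_frame(*rows), library)
        snr = peaks.set_index("mz")["snr"]
        assert snr[entry.light_mz] == pytest.approx(50.0)
        assert snr[entry.heavy_mz] == pytest.approx(100.0)

    def test_all_library_peaks_get_infinite_snr(self, library):
        rows = [(e.light_mz, 10.0) for e in library.entries]
        peaks = estimate_snr(peaks_frame(*rows), library)
        assert np.isinf(peaks["snr"]).all()


class TestRecalibrate:
    CALS = ("H4N4F1", "H5N4Ge1", "H5N4Ge2")

    def test_recovers_uniform_offset(self):
        true = [sodiated_mz(c) for c in self.CALS]
        peaks = peaks_frame(*[(t + 0.5, 10.0) for t in true])
        # 0.5 Da is beyond the default 0.3 Da search; widen it
        corrected, fit = recalibrate(peaks, self.CALS, tol=0.6)
        assert fit.n_matched == 3
        assert fit.offset + fit.slope * np.mean(true) == pytest.approx(0.5, abs=1e-6)
        assert max(abs(r) for r in fit.residuals_post) < 1e-9
        assert corrected["mz"].to_numpy() == pytest.approx(np.array(true), abs=1e-9)

    def test_identity_on_calibrated_data(self):
        true = [sodiated_mz(c) for c in self.CALS]
        peaks = peaks_frame(*[(t, 10.0) for t in true])
        corrected, fit = recalibrate(peaks, self.CALS)
        assert not fit.identity
        assert corrected["mz"].to_numpy() == pytest.approx(
            peaks["mz"].to_numpy(), abs=1e-9
        )

    def test_single_calibrant_gives_identity_and_warning(self, caplog):
        peaks = peaks_frame((sodiated_mz("H4N4F1"), 10.0))
        with caplog.at_level("WARNING"):
            corrected, fit = recalibrate(peaks, self.CALS)
        assert fit.identity and fit.n_matched == 1
        pd.testing.assert_frame_equal(corrected, peaks)
        assert any("identity" in r.message for r in caplog.records)

    def test_affine_drift_fully_recovered(self):
        true = np.array([sodiated_mz(c) for c in self.CALS])
        drifted = true * (1 + 50e-6) + 0.05  # 50 ppm slope + 0.05 Da offset
        corrected, fit = recalibrate(peaks_frame(*[(m, 10.0) for m in drifted]),
                                     self.CALS)
        assert corrected["mz"].to_numpy() == pytest.approx(true, abs=1e-9)


class TestMatchPairs:
    def test_ppm_matching_and_ratio(self, library):
        entry = library.get("H4N4F1")
        peaks = peaks_frame(
            (1647.5869, 1000.0),          # 0.26 ppm from the light target
            (entry.heavy_mz, 500.0),
        )
        out = match_pairs(peaks, build_library(["H4N4F1"]))
        row = out.iloc[0]
        assert row["status"] == OK
        assert row["ratio"] == pytest.approx(2.0)
        assert abs(row["light_ppm"]) < 10

    def test_heavy_missing(self):
        lib = build_library(["H4N4F1"])
        peaks = peaks_frame((lib.entries[0].light_mz, 1000.0))
        row = match_pairs(peaks, lib).iloc[0]
        assert row["status"] == HEAVY_MISSING
        assert np.isnan(row["ratio"])

    def test_ambiguous_on_competing_peak(self):
        lib = build_library(["H4N4F1"])
        e = lib.entries[0]
        peaks = peaks_frame(
            (e.light_mz, 1000.0),
            (e.light_mz + 0.008, 900.0),  # within 10 ppm, similar intensity
            (e.heavy_mz, 500.0),
        )
        row = match_pairs(peaks, lib).iloc[0]
        assert row["status"] == AMBIGUOUS and np.isnan(row["ratio"])

    def test_weak_competitor_is_not_ambiguous(self):
        lib = build_library(["H4N4F1"])
        e = lib.entries[0]
        peaks = peaks_frame(
            (e.light_mz, 1000.0),
            (e.light_mz + 0.008, 10.0),  # 100x weaker: ignored
            (e.heavy_mz, 500.0),
        )
        assert match_pairs(peaks, lib).iloc[0]["status"] == OK

    def test_full_panel_recovery_with_drift(self, library):
        # zero jitter + affine drift within limits: 100% of glycans recovered
        spectrum = SpectrumModel(
            mz_jitter_sd=0.0, drift_offset=0.2, drift_slope_ppm=30.0,
            n_noise_peaks=0,
        )
        ds = generate_dataset(
            StudyDesign(mice_per_group_sex=1, weeks=(15,), seed=2),
            NOISELESS_EFFECTS, spectrum, library=library, include_pooled=False,
        )
        peaks = next(iter(ds.peaklists.values()))
        from glycoquant.peak_processing import process_spot
        from glycoquant.glycan_model import CALIBRANT_PANEL
        pairs, fit = process_spot(peaks, library, CALIBRANT_PANEL)
        assert not fit.identity and fit.n_matched == 7
        assert (pairs["status"] == OK).all()


class TestAggregate:
    def table(self, *ratios, status=OK):
        return pd.DataFrame(
            {"glycan": ["g"] * len(ratios), "status": status, "ratio": ratios}
        )

    def test_equal_replicates(self):
        out = aggregate_replicates([self.table(2.0), self.table(2.0), self.table(2.0)])
        assert out.loc[0, "ratio"] == 2.0
        assert out.loc[0, "technical_cv"] == 0.0
        assert out.loc[0, "n_replicates"] == 3

    def test_cv_of_1_2_3(self):
        out = aggregate_replicates([self.table(1.0), self.table(2.0), self.table(3.0)])
        assert out.loc[0, "ratio"] == pytest.approx(2.0)
        assert out.loc[0, "technical_cv"] == pytest.approx(0.5)  # sd 1.0 / mean 2.0

    def test_missing_spot_reduces_count(self):
        bad = self.table(np.nan, status=HEAVY_MISSING)
        out = aggregate_replicates([self.table(1.0), self.table(3.0), bad])
        assert out.loc[0, "ratio"] == pytest.approx(2.0)
        assert out.loc[0, "n_replicates"] == 2

    def test_no_usable_replicate_gives_missing(self):
        bad = self.table(np.nan, status=HEAVY_MISSING)
        out = aggregate_replicates([bad, bad])
        assert np.isnan(out.loc[0, "ratio"])
        assert out.loc[0, "n_replicates"] == 0
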