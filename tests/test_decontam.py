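"""Contaminant detectors: slope, plate and date rules, union removal."""

import numpy as np
import pandas as pd
import pytest

from mycoarch.decontam import (
    DetectorError,
    build_report,
    combine_and_remove,
    date_contaminant_scan,
    plate_contaminant_scan,
    render_diagnostics,
    scan_all,
    slope_contaminant_scan,
)
from mycoarch.transform import AbundanceTable, clr_transform

from conftest import make_count_table, make_metadata


def varying_depth_counts(n_samples=12):
    """One constant taxon over a depth-varying background."""
    background = np.outer([5, 20], np.arange(1, n_samples + 1) * 10)
    constant = np.full((1, n_samples), 5)
    return make_count_table(np.vstack([constant, background]))


class TestSlopeScan:
    def test_constant_taxon_flagged(self):
        table = varying_depth_counts()
        result = slope_contaminant_scan(table)
        assert result.loc["T000", "slope_flag"]
        assert result.loc["T000", "slope_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_depth_tracking_taxon_not_flagged(self):
        table = varying_depth_counts()
        assert not slope_contaminant_scan(table).loc["T002", "slope_flag"]

    @pytest.mark.parametrize("slope,expected_flag", [(0.1, True), (0.5, False)])
    def test_exact_slope_boundary_inclusive(self, slope, expected_flag):
        # construct abundance = slope * ln(total) exactly on the CLR scale
        table = varying_depth_counts(10)
        x = np.log(table.counts.to_numpy(float).sum(axis=0))
        values = pd.DataFrame(
            np.tile(slope * x, (3, 1)),
            index=table.counts.index, columns=table.counts.columns,
        )
        abund = AbundanceTable(values=values, pseudocount=1.0)
        result = slope_contaminant_scan(table, scale="clr", abund=abund)
        assert result.loc["T000", "slope_stat"] == pytest.approx(slope)
        assert bool(result.loc["T000", "slope_flag"]) is expected_flag

    def test_rare_taxon_skipped_with_nan(self):
        matrix = np.outer([5, 20], np.arange(1, 13) * 10)
        rare = np.zeros((1, 12), dtype=int)
        rare[0, 0] = 3  # present in one sample only
        table = make_count_table(np.vstack([rare, matrix]))
        result = slope_contaminant_scan(table)
        assert np.isnan(result.loc["T000", "slope_stat"])
        assert not result.loc["T000", "slope_flag"]

    def test_constant_totals_are_degenerate(self):
        table = make_count_table(np.full((3, 6), 7))
        with pytest.raises(DetectorError, match="variance"):
            slope_contaminant_scan(table)


class TestPlateScan:
    def make_plated(self, matrix, n_plates=10, per_plate=2):
        n = n_plates * per_plate
        plates = [f"PLATE{i:02d}" for i in range(n_plates) for _ in range(per_plate)]
        table = make_count_table(matrix)
        meta = make_metadata(table.sample_ids, plates=plates)
        return table, meta

    def test_single_plate_taxon_flagged(self):
        matrix = np.ones((2, 20), dtype=int) * 5
        concentrated = np.zeros(20, dtype=int)
        concentrated[:2] = 100  # plate 0 only (1 of 10 plates)
        matrix = np.vstack([concentrated, matrix])
        table, meta = self.make_plated(matrix)
        result = plate_contaminant_scan(table, meta)
        assert result.loc["T000", "plate_top2_share"] == pytest.approx(1.0)
        assert result.loc["T000", "plate_flag"]

    def test_uniform_taxon_share_is_two_tenths(self):
        table, meta = self.make_plated(np.full((1, 20), 5))
        result = plate_contaminant_scan(table, meta)
        assert result.loc["T000", "plate_top2_share"] == pytest.approx(0.2)
        assert not result.loc["T000", "plate_flag"]

    def test_two_plates_total_abstains(self):
        table, meta = self.make_plated(np.full((2, 4), 5), n_plates=2)
        result = plate_contaminant_scan(table, meta)
        assert not result["plate_flag"].any()
        assert result["plate_top2_share"].isna().all()


class TestDateScan:
    def test_single_date_cluster_flagged(self):
        # the hot date holds 10% of samples
        dates = ["2021-05-01"] * 2 + [f"2021-06-{d:02d}" for d in range(1, 19)]
        concentrated = np.zeros(20, dtype=int)
        concentrated[:2] = 50
        matrix = np.vstack([concentrated, np.full((1, 20), 5)])
        table = make_count_table(matrix)
        meta = make_metadata(table.sample_ids, dates=dates)
        result = date_contaminant_scan(table, meta)
        assert result.loc["T000", "date_modal_share"] == pytest.approx(1.0)
        assert result.loc["T000", "date_flag"]
        assert not result.loc["T001", "date_flag"]

    def test_uniform_across_twenty_dates_not_flagged(self):
        dates = [f"2021-06-{d:02d}" for d in range(1, 21)]
        table = make_count_table(np.full((1, 20), 5))
        meta = make_metadata(table.sample_ids, dates=dates)
        result = date_contaminant_scan(table, meta)
        assert result.loc["T000", "date_modal_share"] == pytest.approx(0.05)
        assert not result.loc["T000", "date_flag"]

    def test_single_shared_date_guard(self):
        table = make_count_table(np.full((1, 6), 5))
        meta = make_metadata(table.sample_ids)  # all one date
        result = date_contaminant_scan(table, meta)
        assert not result["date_flag"].any()


class TestCombineAndRemove:
    def make_report(self, index, slope, plate, date):
        frame = pd.DataFrame(index=index)
        frame["slope_stat"] = 0.0
        frame["slope_flag"] = slope
        frame["plate_top2_share"] = 0.0
        frame["plate_flag"] = plate
        frame["date_modal_share"] = 0.0
        frame["date_flag"] = date
        return build_report(frame[["slope_stat", "slope_flag"]],
                            frame[["plate_top2_share", "plate_flag"]],
                            frame[["date_modal_share", "date_flag"]])

    def test_union_counts_with_overlap(self):
        # flags: 3 slope (one shared with date), 2 date-only -> 5 removals
        table = make_count_table(np.ones((10, 4), dtype=int))
        slope = [True, True, True] + [False] * 7
        date = [False, False, True, True, True] + [False] * 5
        report = self.make_report(table.counts.index, slope, False, date)
        filtered, removed = combine_and_remove(table, report)
        # brute-force set union oracle
        expected = {t for t, s in zip(table.taxon_ids, slope) if s} | {
            t for t, d in zip(table.taxon_ids, date) if d
        }
        assert set(removed) == expected
        assert len(removed) == 5 and filtered.shape == (5, 4)

    def test_no_flags_is_identity(self):
        table = make_count_table(np.ones((4, 3), dtype=int))
        report = self.make_report(table.counts.index, False, False, False)
        filtered, removed = combine_and_remove(table, report)
        assert removed == []
        pd.testing.assert_frame_equal(filtered.counts, table.counts)

    def test_all_flagged_empties_table_with_warning(self, caplog):
        table = make_count_table(np.ones((3, 3), dtype=int))
        report = self.make_report(table.counts.index, True, False, False)
        with caplog.at_level("WARNING"):
            filtered, removed = combine_and_remove(table, report)
        assert filtered.shape == (0, 3) and len(removed) == 3
        assert any("all" in m for m in caplog.messages)

    def test_random_flags_match_brute_force(self, rng):
        table = make_count_table(np.ones((30, 3), dtype=int))
        for _ in range(20):
            s, p, d = (rng.random(30) < 0.3 for _ in range(3))
            report = self.make_report(table.counts.index, s, p, d)
            _, removed = combine_and_remove(table, report)
            expected = {
                t for t, f in zip(table.taxon_ids, s | p | d) if f
            }
            assert set(removed) == expected


def test_sample_permutation_equivariance(rng):
    from mycoarch.synthetic_data import SimulationConfig, simulate_dataset

    cfg = SimulationConfig.null_da(seed=5, n_taxa=40, n_tumor=30, n_normal=10)
    cfg.n_slope_contaminants = 3
    dataset = simulate_dataset(cfg)
    report = scan_all(dataset.counts, dataset.meta)

    perm = rng.permutation(dataset.counts.sample_ids)
    shuffled = dataset.counts.subset_samples(list(perm))
    report_perm = scan_all(shuffled, dataset.meta.loc[perm])
    for column in ("slope_flag", "plate_flag", "date_flag", "flagged"):
        pd.testing.assert_series_equal(report[column], report_perm[column])


def test_render_diagnostics_three_plots_per_taxon(tmp_path):
    table = varying_depth_counts()
    meta = make_metadata(table.sample_ids,
                         plates=["PLATE01", "PLATE02", "PLATE03"] * 4,
                         dates=["2021-01-01", "2021-02-01"] * 6)
    report = scan_all(table, meta)
    files = render_diagnostics(table, meta, report, tmp_path,
                               taxa=["T000", "T001"])
    assert len(files) == 6 and all(f.exists() for f in files)
    with pytest.raises(KeyError):
        render_diagnostics(table, meta, report, tmp_path, taxa=["nope"])
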