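"""Unit and property tests for the four-bin screen.

The brute-force oracle below re-implements the bin definitions with plain
Python sets and loops, independently of the vectorised implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crustscreen import (
    Bin,
    SampleMetadata,
    ScreenConfig,
    apply_screen,
    assign_bins,
    compute_relative_abundance,
    exclude_contaminated_samples,
)
from crustscreen.errors import ConfigurationError, DegenerateSampleError

from conftest import make_table

# matrices whose columns all have at least one positive entry
screen_matrices = (
    arrays(
        np.int64,
        shape=st.tuples(st.integers(1, 20), st.integers(2, 5)),
        elements=st.integers(0, 100),
    )
    .filter(lambda a: (a.sum(axis=0) > 0).all() and (a.sum(axis=1) > 0).all())
)


def brute_force_bins(counts: np.ndarray, control_col: int, T: float, ge: bool):
    """Independent enumeration of the bin definitions (oracle)."""
    n_otus, n_samples = counts.shape
    sizes = counts.sum(axis=0)
    out = {}
    for i in range(n_otus):
        ctrl = counts[i, control_col]
        sample_cols = [j for j in range(n_samples) if j != control_col]
        present = [j for j in sample_cols if counts[i, j] > 0]
        if ctrl > 0 and not present:
            out[i] = Bin.CONTROL_ONLY
        elif ctrl == 0 and present:
            out[i] = Bin.SAMPLES_ONLY
        else:
            r_ctrl = ctrl / sizes[control_col]
            best = max((counts[i, j] / sizes[j]) / r_ctrl for j in sample_cols)
            hit = best >= T if ge else best > T
            out[i] = Bin.TENFOLD_SAMPLE if hit else Bin.CONTROL_SAMPLE
    return out


class TestRelativeAbundance:
    def test_simple_division(self):
        table = make_table([[2], [3], [5]])
        r = compute_relative_abundance(table)
        assert r["S0"].tolist() == [0.2, 0.3, 0.5]

    @given(screen_matrices)
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_one(self, arr):
        r = compute_relative_abundance(make_table(arr))
        assert np.allclose(r.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_is_an_error(self):
        table = make_table([[1, 0], [2, 0]])
        with pytest.raises(DegenerateSampleError, match="S1"):
            compute_relative_abundance(table)


class TestAssignBins:
    def test_four_bins_on_fixture(self, small_table, default_config):
        abund = compute_relative_abundance(small_table)
        bins = assign_bins(abund, "CTRL", default_config)
        assert bins.bins == {
            "OtuA": Bin.SAMPLES_ONLY,
            "OtuB": Bin.CONTROL_ONLY,
            "OtuC": Bin.TENFOLD_SAMPLE,
            "OtuD": Bin.CONTROL_SAMPLE,
        }
        assert bins.ratio["OtuC"] == pytest.approx(12.0)

    def test_ratio_twenty_is_tenfold(self):
        # r_control = 0.001, max sample r = 0.02 -> R = 20 >= 10
        table = make_table([[1, 20], [999, 980]], sample_ids=["CTRL", "S1"],
                           control="CTRL")
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        assert bins.bins["Otu0000"] is Bin.TENFOLD_SAMPLE
        assert bins.ratio["Otu0000"] == pytest.approx(20.0)

    def test_ratio_three_is_control_sample(self):
        table = make_table([[10, 30], [990, 970]], sample_ids=["CTRL", "S1"],
                           control="CTRL")
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        assert bins.bins["Otu0000"] is Bin.CONTROL_SAMPLE
        assert bins.ratio["Otu0000"] == pytest.approx(3.0)

    def test_comparison_mode_at_exact_threshold(self):
        # equal library sizes, counts 1 vs 10 -> R exactly 10
        table = make_table([[1, 10], [99, 90]], sample_ids=["CTRL", "S1"],
                           control="CTRL")
        abund = compute_relative_abundance(table)
        ge = assign_bins(abund, "CTRL", ScreenConfig(ratio_comparison="GE"))
        gt = assign_bins(abund, "CTRL", ScreenConfig(ratio_comparison="GT"))
        assert ge.bins["Otu0000"] is Bin.TENFOLD_SAMPLE
        assert gt.bins["Otu0000"] is Bin.CONTROL_SAMPLE

    def test_missing_control_is_config_error(self, small_table):
        abund = compute_relative_abundance(small_table)
        with pytest.raises(ConfigurationError):
            assign_bins(abund, "NOPE")
        with pytest.raises(ConfigurationError):
            assign_bins(abund, None)

    def test_all_zero_otu_rejected(self):
        abund = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["OtuZ", "OtuY"],
                             columns=["CTRL", "S1"])
        with pytest.raises(ValueError, match="OtuZ"):
            assign_bins(abund, "CTRL")

    @given(screen_matrices, st.sampled_from(["GE", "GT"]))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, arr, cmp):
        table = make_table(arr, control="S0")
        cfg = ScreenConfig(ratio_comparison=cmp)
        bins = assign_bins(compute_relative_abundance(table), "S0", cfg)
        oracle = brute_force_bins(arr, 0, cfg.ratio_threshold, cmp == "GE")
        for i, otu in enumerate(table.otu_ids):
            assert bins.bins[otu] is oracle[i], (otu, arr)

    @given(screen_matrices)
    @settings(max_examples=100, deadline=None)
    def test_partition_invariant(self, arr):
        table = make_table(arr, control="S0")
        bins = assign_bins(compute_relative_abundance(table), "S0")
        assert sum(bins.bin_sizes().values()) == len(table.otu_ids)
        assert set(bins.bins) == set(table.otu_ids)

    @given(screen_matrices, st.floats(1.5, 50), st.floats(1.5, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_threshold(self, arr, t1, t2):
        lo, hi = sorted((t1, t2))
        table = make_table(arr, control="S0")
        abund = compute_relative_abundance(table)
        b_lo = assign_bins(abund, "S0", ScreenConfig(ratio_threshold=lo))
        b_hi = assign_bins(abund, "S0", ScreenConfig(ratio_threshold=hi))
        # only the TENFOLD <-> CONTROL_SAMPLE boundary may move
        assert set(b_hi.otus_in(Bin.TENFOLD_SAMPLE)) <= set(b_lo.otus_in(Bin.TENFOLD_SAMPLE))
        assert b_lo.otus_in(Bin.CONTROL_ONLY) == b_hi.otus_in(Bin.CONTROL_ONLY)
        assert b_lo.otus_in(Bin.SAMPLES_ONLY) == b_hi.otus_in(Bin.SAMPLES_ONLY)


class TestApplyScreen:
    def _screen(self, table, metadata=None, cfg=None):
        cfg = cfg or ScreenConfig()
        bins = assign_bins(compute_relative_abundance(table), table.control_id, cfg)
        return apply_screen(table, bins, metadata, cfg)

    def test_pure_sample_is_untouched(self):
        table = make_table([[5, 0], [0, 7], [0, 3]], sample_ids=["CTRL", "S1"],
                           control="CTRL")
        result = self._screen(table)
        assert result.overlap_fraction["S1"] == 0
        assert result.screened.counts["S1"].tolist() == [7, 3]

    def test_control_column_dropped_and_overlap_otus_removed(
        self, small_table, default_config
    ):
        result = self._screen(small_table)
        assert "CTRL" not in result.screened.sample_ids
        assert result.screened.otu_ids == ["OtuA"]
        # overlap = reads in OtuC+OtuD over library size (per sample)
        assert result.overlap_fraction["S1"] == pytest.approx(46 / 66)
        assert result.group4_fraction["S1"] == pytest.approx(6 / 66)
        assert result.overlap_fraction["S2"] == pytest.approx(35 / 40)

    def test_screened_has_no_control_positive_otu(self, small_table):
        result = self._screen(small_table)
        ctrl_counts = small_table.counts.loc[result.screened.otu_ids, "CTRL"]
        assert (ctrl_counts == 0).all()

    @given(screen_matrices)
    @settings(max_examples=50, deadline=None)
    def test_no_reads_created(self, arr):
        table = make_table(arr, control="S0")
        result = self._screen(table)
        for sid in result.screened.sample_ids:
            assert result.post_read_counts[sid] <= result.pre_read_counts[sid]

    def test_bins_from_other_table_rejected(self, small_table):
        bins = assign_bins(compute_relative_abundance(small_table), "CTRL")
        bigger = make_table([[1, 2, 3], [4, 5, 6], [7, 8, 9], [1, 1, 1], [2, 2, 2]],
                            sample_ids=["CTRL", "S1", "S2"], control="CTRL")
        with pytest.raises(ValueError, match="bins were not computed"):
            apply_screen(bigger, bins)

    def test_no_control_pass_through(self):
        table = make_table([[5, 1], [2, 7]])
        result = apply_screen(table, None)
        assert result.unscreened
        assert result.screened == table
        assert result.post_read_counts.tolist() == [7, 8]


class TestSampleExclusion:
    def _meta(self, spheres):
        return {
            "S1": SampleMetadata("S1", microsphere_count=spheres),
            "S2": SampleMetadata("S2", microsphere_count=0.0),
        }

    def _table_with_dominant_overlap(self):
        # S1 reads are ~100% in the shared OTU; S2 is mostly its own
        return make_table(
            [[50, 999, 10], [5, 1, 90]],
            sample_ids=["CTRL", "S1", "S2"],
            control="CTRL",
        )

    def test_spheres_plus_high_overlap_excluded(self):
        table = self._table_with_dominant_overlap()
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        excl = exclude_contaminated_samples(table, self._meta(1.3e4), bins)
        assert set(excl) == {"S1"}
        assert "microspheres" in excl["S1"]

    def test_spheres_with_low_overlap_retained(self):
        # microsphere-positive but only 10% overlap: QC flag, not exclusion
        table = make_table(
            [[50, 10, 10], [0, 90, 90]],
            sample_ids=["CTRL", "S1", "S2"],
            control="CTRL",
        )
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        assert exclude_contaminated_samples(table, self._meta(5.8e3), bins) == {}

    def test_no_spheres_never_excluded(self):
        table = self._table_with_dominant_overlap()
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        assert exclude_contaminated_samples(table, self._meta(0.0), bins) == {}

    def test_unmeasured_spheres_never_excluded(self):
        table = self._table_with_dominant_overlap()
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        assert exclude_contaminated_samples(table, self._meta(None), bins) == {}

    def test_excluded_sample_dropped_from_screened_table(self):
        table = self._table_with_dominant_overlap()
        bins = assign_bins(compute_relative_abundance(table), "CTRL")
        result = apply_screen(table, bins, self._meta(1.3e4))
        assert "S1" not in result.screened.sample_ids
        assert "S1" in result.excluded
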