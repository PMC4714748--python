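import math

import numpy as np
import pytest

import bsmethyl as bm
from bsmethyl.regionstats import RegionLookupError
from conftest import make_table


class TestWeightedLevel:
    def test_coverage_weighted_not_mean_of_fractions(self):
        t = make_table([
            ("chr1", 10, "+", "CG", 5, 10),
            ("chr1", 20, "-", "CG", 15, 20),
        ])
        wl = bm.weighted_level(t, ("chr1", 0, 100))
        assert wl.level == pytest.approx(20 / 30)
        assert (wl.mc, wl.cov) == (20, 30)

    def test_all_unmethylated_gives_zero(self):
        t = make_table([("chr1", i, "+", "CHH", 0, 8) for i in range(1, 6)])
        assert bm.weighted_level(t, ("chr1", 0, 10)).level == 0.0

    def test_uncovered_region_is_missing_not_zero(self):
        t = make_table([("chr1", 1, "+", "CG", 2, 4)])
        wl = bm.weighted_level(t, ("chr1", 500, 600))
        assert math.isnan(wl.level) and wl.cov == 0

    def test_unknown_contig_raises(self):
        t = make_table([("chr1", 1, "+", "CG", 2, 4)])
        with pytest.raises(RegionLookupError):
            bm.weighted_level(t, ("chrX", 0, 10))

    def test_half_open_interval_convention(self):
        t = make_table([
            ("chr1", 10, "+", "CG", 1, 1),  # 0-based 9
            ("chr1", 11, "+", "CG", 0, 1),  # 0-based 10, excluded by [0, 10)
        ])
        wl = bm.weighted_level(t, ("chr1", 9, 10))
        assert (wl.mc, wl.cov) == (1, 1)

    def test_pooling_identity_over_disjoint_union(self, small_world):
        _, _, table = small_world
        parts = [("contig_1", 0, 5_000), ("contig_1", 5_000, 12_000), ("contig_1", 12_000, 40_000)]
        whole = bm.weighted_level(table, ("contig_1", 0, 40_000))
        mc = sum(bm.weighted_level(table, p).mc for p in parts)
        cov = sum(bm.weighted_level(table, p).cov for p in parts)
        assert (mc, cov) == (whole.mc, whole.cov)
        assert whole.level == pytest.approx(mc / cov)


class TestNotchStats:
    def test_singleton_notch_collapses_to_median(self):
        st = bm.boxplot_notch_stats([0.4])
        assert st.median == 0.4 and st.iqr == 0.0 and st.notch_half_width == 0.0

    def test_linear_interpolation_quartiles(self):
        st = bm.boxplot_notch_stats([0.2, 0.4, 0.6, 0.8])
        assert st.median == pytest.approx(0.5)
        assert st.q1 == pytest.approx(0.35)
        assert st.q3 == pytest.approx(0.65)
        assert st.notch_half_width == pytest.approx(1.58 * 0.3 / 2.0)

    def test_identical_samples_overlap(self):
        a = bm.boxplot_notch_stats([0.1, 0.5, 0.9])
        assert bm.notches_overlap(a, a)

    def test_well_separated_samples_do_not_overlap(self, rng):
        a = bm.boxplot_notch_stats(rng.uniform(0.0, 0.1, size=100))
        b = bm.boxplot_notch_stats(rng.uniform(0.8, 0.9, size=100))
        assert not bm.notches_overlap(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bm.boxplot_notch_stats([])

    def test_region_level_matrix_long_format(self, small_world):
        _, truth, table = small_world
        regions = [(c, s, e) for c, s, e, _ in truth.regions]
        mat = bm.region_level_matrix({"wt": table}, regions)
        assert len(mat) == len(regions)
        assert ((mat["level"] >= 0) & (mat["level"] <= 1)).all()
        assert (mat["level"] > 0.5).all()  # planted at m = 0.8


class TestMetaplot:
    def test_exactly_60_bins_with_expected_layout(self, small_world):
        _, truth, table = small_world
        profile = bm.metaplot_profile(table, [(c, s, e) for c, s, e, _ in truth.regions])
        assert len(profile.frame) == 60
        assert list(profile.frame["segment"]).count("body") == 20
        assert profile.frame["bin"].tolist() == list(range(60))

    def test_step_function_truth_body_high_flank_low(self, small_world):
        """Body bins sit at m + (1-m)r and flank bins at r, to a family-wise
        4-SE bound (Sidak-adjusted for testing 60 bins at once)."""
        _, truth, table = small_world
        profile = bm.metaplot_profile(table, [(c, s, e) for c, s, e, _ in truth.regions])
        df = profile.frame
        body = df[df["segment"] == "body"]
        flank = df[df["segment"] != "body"]
        r, m = 0.005, 0.8
        exp_body = m + (1 - m) * r
        for _, row in body.iterrows():
            se = math.sqrt(exp_body * (1 - exp_body) / row["cov"])
            assert abs(row["level"] - exp_body) <= 4 * se
        for _, row in flank.iterrows():
            se = math.sqrt(r * (1 - r) / row["cov"])
            assert abs(row["level"] - r) <= 4 * se

    def test_bins_partition_counts(self, small_world):
        """Total binned coverage equals coverage of the regions plus flanks."""
        _, truth, table = small_world
        c, s, e, _ = truth.regions[0]
        profile = bm.metaplot_profile(table, [(c, s, e)])
        window = bm.weighted_level(table, (c, s - 1_000, e + 1_000))
        assert profile.frame["cov"].sum() == window.cov
        assert profile.frame["mc"].sum() == window.mc

    def test_profile_invariant_to_region_order(self, small_world):
        _, truth, table = small_world
        regions = [(c, s, e) for c, s, e, _ in truth.regions]
        a = bm.metaplot_profile(table, regions)
        b = bm.metaplot_profile(table, regions[::-1])
        assert a.frame.equals(b.frame)

    def test_zero_coverage_sample_gives_all_missing_bins(self, small_world):
        _, truth, _ = small_world
        t = make_table([("contig_1", 1, "+", "CG", 0, 0)])
        profile = bm.metaplot_profile(t, [(c, s, e) for c, s, e, _ in truth.regions])
        assert np.isnan(profile.levels).all()

    def test_too_short_regions_skipped_with_warning(self, small_world, caplog):
        _, truth, table = small_world
        c, s, e, _ = truth.regions[0]
        with caplog.at_level("WARNING"):
            profile = bm.metaplot_profile(table, [(c, s, e), ("contig_1", 0, 5)])
        assert profile.n_regions == 1
        assert "skipping region" in caplog.text

    def test_all_regions_too_short_raises(self, small_world):
        _, _, table = small_world
        with pytest.raises(ValueError):
            bm.metaplot_profile(table, [("contig_1", 0, 5)])

    def test_mean_aggregate_close_to_pooled_for_homogeneous_regions(self, small_world):
        _, truth, table = small_world
        regions = [(c, s, e) for c, s, e, _ in truth.regions]
        pooled = bm.metaplot_profile(table, regions, aggregate="pooled")
        mean = bm.metaplot_profile(table, regions, aggregate="mean")
        body = pooled.frame["segment"] == "body"
        np.testing.assert_allclose(
            pooled.frame.loc[body, "level"], mean.frame.loc[body, "level"], atol=0.05
        )
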