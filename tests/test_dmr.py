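import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bsmethyl as bm
from bsmethyl.dmr import fisher_pvalues
from conftest import make_table
from oracles import chain_positions, fisher_two_sided


class TestUnmethylatedControl:
    def test_every_cytosine_gets_uniform_coverage_and_zero_mc(self, small_world):
        genome, _, _ = small_world
        ctrl = bm.make_unmethylated_control(genome, coverage=60)
        assert len(ctrl) == len(genome.cytosines())
        assert (ctrl.frame["mc"] == 0).all() and (ctrl.frame["cov"] == 60).all()

    def test_custom_coverage(self, small_world):
        genome, _, _ = small_world
        assert (bm.make_unmethylated_control(genome, coverage=1).frame["cov"] == 1).all()

    def test_empty_genome_gives_empty_table(self):
        cfg = bm.SimulationConfig(
            n_contigs=1, contig_length=1_000, control_contig_length=0,
            n_regions=0, gc_fraction=0.0, seed=1,
        )
        genome, _ = bm.generate_genome(cfg)
        assert len(bm.make_unmethylated_control(genome)) == 0

    def test_nonpositive_coverage_rejected(self, small_world):
        genome, _, _ = small_world
        with pytest.raises(ValueError):
            bm.make_unmethylated_control(genome, coverage=0)


class TestFindDMS:
    def test_identical_tables_give_zero_dms(self):
        rows = [("chr1", i + 1, "+", "CG", 5, 10) for i in range(50)]
        t = make_table(rows)
        dms = bm.find_dms(t, t)
        assert len(dms) == 50 and not dms["is_dms"].any()

    def test_extreme_site_is_dms_with_oracle_pvalue(self):
        a = make_table([("chr1", 1, "+", "CG", 0, 60)])
        b = make_table([("chr1", 1, "+", "CG", 30, 30)])
        dms = bm.find_dms(a, b, min_cov=3)
        strict, loose = fisher_two_sided(0, 60, 30, 30)
        p = dms["p"].item()
        assert strict - 1e-12 <= p <= loose + 1e-12
        assert dms["is_dms"].item()

    def test_identical_cells_give_p_one(self):
        a = make_table([("chr1", 1, "+", "CG", 5, 10)])
        b = make_table([("chr1", 1, "+", "CG", 5, 10)])
        dms = bm.find_dms(a, b)
        assert dms["p"].item() == pytest.approx(1.0)
        assert not dms["is_dms"].item()

    def test_strand_counts_pooled_per_position(self):
        a = make_table([
            ("chr1", 10, "+", "CG", 2, 10),
            ("chr1", 10, "-", "CG", 3, 10),
        ])
        b = make_table([("chr1", 10, "+", "CG", 0, 20)])
        dms = bm.find_dms(a, b)
        assert len(dms) == 1
        assert dms["mc_a"].item() == 5 and dms["cov_a"].item() == 20

    def test_no_shared_sites_warns_and_returns_empty(self):
        a = make_table([("chr1", 1, "+", "CG", 1, 10)])
        b = make_table([("chr2", 1, "+", "CG", 1, 10)])
        with pytest.warns(UserWarning, match="no shared sites"):
            dms = bm.find_dms(a, b)
        assert len(dms) == 0

    def test_fisher_pvalues_match_oracle_brackets(self, rng):
        cov_a = rng.integers(3, 31, size=300)
        cov_b = rng.integers(3, 31, size=300)
        mc_a = rng.binomial(cov_a, 0.3)
        mc_b = rng.binomial(cov_b, 0.1)
        p = fisher_pvalues(mc_a, cov_a, mc_b, cov_b)
        for i in range(300):
            strict, loose = fisher_two_sided(mc_a[i], cov_a[i], mc_b[i], cov_b[i])
            assert strict - 1e-9 <= p[i] <= loose + 1e-9


class TestMergeDMS:
    def test_ten_dms_within_gap_form_one_region(self):
        pos = np.arange(100, 1_001, 100)  # 10 sites, gaps of 100
        regions = bm.merge_dms_to_dmr({"chr1": pos}, max_gap=1_000, min_dms=10)
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.start, reg.end, reg.n_dms) == (99, 1_000, 10)

    def test_nine_dms_fall_below_min_dms(self):
        pos = np.arange(100, 901, 100)
        assert bm.merge_dms_to_dmr({"chr1": pos}, min_dms=10) == []

    def test_gap_over_1kb_splits_clusters(self):
        first = np.arange(100, 1_001, 100)
        second = first[-1] + 1_001 + np.arange(0, 901, 100)
        regions = bm.merge_dms_to_dmr({"chr1": np.concatenate([first, second])})
        assert [r.n_dms for r in regions] == [10, 10]

    def test_duplicates_collapsed_and_unsorted_input_ok(self):
        pos = [500, 100, 100, 300, 200, 400, 600, 700, 800, 900, 1_000]
        regions = bm.merge_dms_to_dmr({"chr1": pos}, min_dms=10)
        assert len(regions) == 1 and regions[0].n_dms == 10

    def test_accepts_dms_frame_and_filters_on_flag(self):
        df = pd.DataFrame({
            "contig": ["chr1"] * 12,
            "pos": list(range(100, 1_300, 100)),
            "is_dms": [True] * 10 + [False] * 2,
        })
        regions = bm.merge_dms_to_dmr(df)
        assert len(regions) == 1 and regions[0].n_dms == 10

    def test_matches_quadratic_chaining_oracle_on_1000_random_sets(self, rng):
        for _ in range(1_000):
            n = int(rng.integers(0, 60))
            pos = rng.integers(1, 10_000, size=n)
            max_gap = int(rng.integers(50, 2_000))
            min_dms = int(rng.integers(1, 8))
            got = [
                (r.start + 1, r.end, r.n_dms)
                for r in bm.merge_dms_to_dmr({"c": pos}, max_gap=max_gap, min_dms=min_dms)
            ]
            assert sorted(got) == chain_positions(pos, max_gap, min_dms)

    def test_region_invariants_reconstructed(self, rng):
        pos = np.sort(rng.choice(50_000, size=800, replace=False)) + 1
        regions = bm.merge_dms_to_dmr({"c": pos}, max_gap=300, min_dms=5)
        spans = [(r.start, r.end) for r in regions]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1  # disjoint
            member1 = pos[(pos - 1 >= s1) & (pos <= e1)]
            member2 = pos[(pos - 1 >= s2) & (pos <= e2)]
            assert member2.min() - member1.max() > 300
        for s, e in spans:
            inside = pos[(pos - 1 >= s) & (pos <= e)]
            assert np.diff(inside).max(initial=0) <= 300

    def test_monotone_in_min_dms(self, rng):
        pos = rng.integers(1, 20_000, size=300)
        counts = [
            len(bm.merge_dms_to_dmr({"c": pos}, max_gap=500, min_dms=k)) for k in (1, 3, 5, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDMRPipeline:
    def test_reference_equal_to_sample_gives_zero_dmrs(self, small_world):
        _, _, table = small_world
        regions, dms = bm.dmr_pipeline([table], table)
        assert regions == [] and not dms["is_dms"].any()

    def test_recovery_of_planted_regions(self, small_world):
        genome, truth, table = small_world
        rep2 = bm.simulate_count_table(truth, 20.0, 0.005, seed=99)
        ref = bm.make_unmethylated_control(genome)
        regions, _ = bm.dmr_pipeline([table, rep2], ref)
        planted = sorted((c, s, e) for c, s, e, _ in truth.regions)
        planted_bases = sum(e - s for _, s, e in planted)
        covered = 0
        for reg in regions:
            for c, s, e in planted:
                if reg.contig == c:
                    covered += max(0, min(reg.end, e) - max(reg.start, s))
        assert covered / planted_bases >= 0.9
        # per-sample weighted levels attached and high inside regions
        for reg in regions:
            for name in ("sample_1", "sample_2"):
                assert reg.levels[name].level > 0.5
            assert reg.levels["reference"].level == 0.0

    def test_smaller_alpha_never_adds_dms(self, small_world):
        genome, _, table = small_world
        ref = bm.make_unmethylated_control(genome)
        loose = bm.find_dms(table, ref, alpha=0.05)
        tight = bm.find_dms(table, ref, alpha=0.001)
        loose_set = set(zip(loose.loc[loose["is_dms"], "contig"], loose.loc[loose["is_dms"], "pos"]))
        tight_set = set(zip(tight.loc[tight["is_dms"], "contig"], tight.loc[tight["is_dms"], "pos"]))
        assert tight_set <= loose_set
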