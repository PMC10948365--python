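"""Interval algebra vs brute-force membership, consensus peaks, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from remodel3d import intervals as iv


def brute_force_union(df, size=10_000):
    covered = np.zeros(size, bool)
    for r in df.itertuples():
        covered[r.start : r.end] = True
    return covered


class TestAlgebra:
    def test_merge_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 9_000, 40)
        df = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + rng.integers(1, 500, 40)})
        merged = iv.merge_intervals(df)
        oracle = brute_force_union(df)
        got = brute_force_union(merged)
        assert (oracle == got).all()
        assert (merged["start"].to_numpy()[1:] > merged["end"].to_numpy()[:-1]).all()

    def test_intersect_matches_per_base_oracle(self):
        rng = np.random.default_rng(8)
        def rand_set(n):
            s = rng.integers(0, 9_000, n)
            return pd.DataFrame({"chrom": "c", "start": s, "end": s + rng.integers(1, 400, n)})
        a, b = rand_set(25), rand_set(25)
        inter = iv.intersect_intervals(a, b)
        oracle = brute_force_union(a) & brute_force_union(b)
        assert (brute_force_union(inter) == oracle).all()

    def test_overlap_count_and_bp(self):
        q = pd.DataFrame({"chrom": "c", "start": [0, 1000], "end": [100, 1100]})
        ann = pd.DataFrame({"chrom": "c", "start": [50], "end": [70]})
        assert iv.overlap_count(q, ann) == 1
        assert iv.overlap_bp(q, ann) == 20

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            iv.sort_intervals(pd.DataFrame({"chrom": ["c"], "start": [10], "end": [10]}))


class TestConsensusPeaks:
    def test_fraction_arithmetic(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200]})
        b_low = pd.DataFrame({"chrom": ["c"], "start": [150], "end": [400]})  # 50/100
        b_high = pd.DataFrame({"chrom": ["c"], "start": [110], "end": [250]})  # 90/100
        assert iv.consensus_peaks([a, b_low]).empty
        kept = iv.consensus_peaks([a, b_high])
        assert len(kept) == 1 and kept["support"].iloc[0] == 2

    def test_identical_replicates_idempotent(self):
        a = pd.DataFrame({"chrom": "c", "start": [100, 500], "end": [200, 700]})
        out = iv.consensus_peaks([a, a.copy(), a.copy()])
        assert out[["chrom", "start", "end"]].equals(iv.sort_intervals(a))
        assert (out["support"] == 3).all()

    def test_output_subset_and_monotone_in_fraction(self):
        rng = np.random.default_rng(9)
        def rand_set(n):
            s = rng.integers(0, 9_000, n)
            return pd.DataFrame({"chrom": "c", "start": s, "end": s + rng.integers(50, 300, n)})
        reps = [rand_set(30) for _ in range(3)]
        loose = iv.consensus_peaks(reps, min_overlap_frac=0.3)
        strict = iv.consensus_peaks(reps, min_overlap_frac=0.8)
        assert len(strict) <= len(loose) <= len(reps[0])

    def test_bad_fraction_rejected(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            iv.consensus_peaks([a, a], min_overlap_frac=1.5)


class TestPermutationEnrichment:
    ws = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1_000_000]})
    ann_half = pd.DataFrame(
        {"chrom": "c", "start": np.arange(0, 1_000_000, 20_000),
         "end": np.arange(0, 1_000_000, 20_000) + 10_000}
    )

    def test_embedded_query_fold_two_bp_mode(self):
        # query fully inside an annotation covering 50% of the workspace
        s = np.arange(5_000, 400_000, 20_000)[:10]
        q = pd.DataFrame({"chrom": "c", "start": s, "end": s + 1_000})
        res = iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=500, seed=1, mode="bp")
        assert res.fold == pytest.approx(2.0, rel=0.1)

    def test_empirical_p_formula(self):
        # near-full-width query intervals inside annotation intervals: the
        # observed shared bp is essentially never matched by a permutation
        s = np.arange(500, 400_000, 20_000)[:10]
        q = pd.DataFrame({"chrom": "c", "start": s, "end": s + 9_000})
        res = iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=1000, seed=2, mode="bp")
        assert res.p_enriched == pytest.approx(1 / 1001)

    def test_deterministic_under_seed(self):
        s = np.arange(5_000, 200_000, 20_000)
        q = pd.DataFrame({"chrom": "c", "start": s, "end": s + 500})
        r1 = iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=100, seed=42)
        r2 = iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=100, seed=42)
        assert (r1.fold, r1.p_enriched) == (r2.fold, r2.p_enriched)

    def test_null_calibration(self):
        rng = np.random.default_rng(12)
        folds = []
        for d in range(50):
            starts = rng.integers(0, 1_000_000 - 500, 20)
            q = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 500})
            folds.append(
                iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=200, seed=500 + d).fold
            )
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_missing_workspace_chromosome_rejected(self):
        q = pd.DataFrame({"chrom": ["cX"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            iv.permutation_enrichment(q, self.ann_half, self.ws, n_perm=10, seed=0)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(iv.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_ties(self):
        assert iv.bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(iv.bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_q_never_below_p_and_order_preserved(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 30)
        q = iv.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            iv.bh_adjust([0.0, 0.5])


class TestGeneSetOverlap:
    def test_worked_table_against_hypergeom_oracle(self):
        universe = {f"g{i}" for i in range(1000)}
        a = {f"g{i}" for i in range(100)}  # 100 genes
        b = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(100, 105)}  # 10 in A, 5 out
        res = iv.gene_set_overlap_test(a, b, universe)
        assert res["odds_ratio"] == pytest.approx((10 * 895) / (90 * 5), rel=1e-9)
        # brute-force two-sided hypergeometric tail sum
        n11 = 10
        rv = hypergeom(1000, 100, 15)
        p_obs = rv.pmf(n11)
        p_brute = sum(rv.pmf(k) for k in range(16) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert res["p"] == pytest.approx(p_brute, rel=1e-6)

    def test_independent_partitions_or_near_one(self):
        universe = {f"g{i}" for i in range(400)}
        a = {f"g{i}" for i in range(0, 400, 2)}  # every other gene
        b = {f"g{i}" for i in range(100, 300)}  # a contiguous half, independent of parity
        res = iv.gene_set_overlap_test(a, b, universe)
        assert 0.5 < res["odds_ratio"] < 2.0

    def test_degenerate_table(self):
        universe = {"a", "b", "c"}
        res = iv.gene_set_overlap_test({"a"}, universe, universe)
        assert res["degenerate"] and res["p"] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            iv.gene_set_overlap_test(set(), set(), set())


def test_null_empirical_p_super_uniform():
    """Type-I error of the permutation test at the 5% level under the null."""
    ws = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1_000_000]})
    ann = pd.DataFrame(
        {"chrom": "c", "start": np.arange(0, 1_000_000, 20_000),
         "end": np.arange(0, 1_000_000, 20_000) + 10_000}
    )
    rng = np.random.default_rng(31)
    rejections = 0
    n_rep = 200
    for d in range(n_rep):
        starts = rng.integers(0, 1_000_000 - 500, 15)
        q = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 500})
        res = iv.permutation_enrichment(q, ann, ws, n_perm=99, seed=2_000 + d)
        if res.p_enriched <= 0.05:
            rejections += 1
    assert rejections / n_rep <= 0.07
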