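"""Compartment eigenvector, switch classes, saddle and A:B ratio."""

import numpy as np
import pandas as pd
import pytest

from remodel3d import compartments as comp
from remodel3d.matrix import OEMatrix


def checkerboard_oe(n=40, gamma=0.5, block=10):
    labels = np.array([1 if (i // block) % 2 == 0 else -1 for i in range(n)])
    same = labels[:, None] == labels[None, :]
    oe = np.where(same, 1 + gamma, 1 - gamma).astype(float)
    return OEMatrix("c", 50_000, oe, np.ones(n), np.ones(n, bool)), labels


def make_track(pc1, bin_size=50_000):
    pc1 = np.asarray(pc1, dtype=float)
    labels = np.full(pc1.shape, "NA", dtype=object)
    labels[pc1 > 0] = "A"
    labels[pc1 < 0] = "B"
    return comp.CompartmentTrack("c", bin_size, pc1, labels, 1.0, False)


class TestComputePc1:
    def test_checkerboard_blocks_and_eigh_oracle(self):
        oe, labels = checkerboard_oe()
        gd = np.where(labels > 0, 5.0, 1.0)
        track = comp.compute_pc1(oe, gd, smooth_bins=0)
        # sign constant within blocks, opposite between blocks
        assert (np.sign(track.pc1) == labels).all()
        # oracle: dense eigendecomposition of the same correlation matrix
        c = np.corrcoef(oe.oe, rowvar=False)
        w, v = np.linalg.eigh(c)
        oracle = v[:, -1] * np.sqrt(w[-1])
        agree = np.allclose(track.pc1, oracle, atol=1e-8) or np.allclose(
            track.pc1, -oracle, atol=1e-8
        )
        assert agree

    def test_gene_density_orients_a_compartment(self):
        oe, labels = checkerboard_oe()
        gd = np.where(labels > 0, 1.0, 5.0)  # denser in the other block set
        track = comp.compute_pc1(oe, gd, smooth_bins=0)
        assert (track.labels[labels < 0] == "A").all()
        assert track.gene_density_corr >= 0

    def test_constant_oe_flagged_ambiguous(self):
        n = 30
        oe = OEMatrix("c", 50_000, np.ones((n, n)), np.ones(n), np.ones(n, bool))
        track = comp.compute_pc1(oe, np.linspace(0, 1, n), smooth_bins=0)
        assert track.ambiguous

    def test_scale_invariance(self):
        oe, labels = checkerboard_oe()
        gd = np.where(labels > 0, 5.0, 1.0)
        t1 = comp.compute_pc1(oe, gd, smooth_bins=0)
        oe2 = OEMatrix("c", 50_000, 7.0 * oe.oe, np.ones(40), np.ones(40, bool))
        t2 = comp.compute_pc1(oe2, gd, smooth_bins=0)
        assert (t1.labels == t2.labels).all()

    def test_too_few_bins_rejected(self):
        oe = OEMatrix("c", 50_000, np.ones((4, 4)), np.ones(4), np.ones(4, bool))
        with pytest.raises(ValueError):
            comp.compute_pc1(oe, np.ones(4))


class TestClassifySwitches:
    def test_class_enumeration(self):
        t1 = [make_track([1, 1, -1, -1])]
        t2 = [make_track([1, -1, -1, 1])]
        sw = comp.classify_switches(t1, t2)
        assert sw["class"].tolist() == ["A->A", "A->B", "B->B", "B->A"]

    def test_disagreeing_replicate_gives_na(self):
        t1 = [make_track([1.0]), make_track([1.0]), make_track([-0.5])]
        t2 = [make_track([1.0]), make_track([1.0]), make_track([1.0])]
        sw = comp.classify_switches(t1, t2, min_rep_agree=1.0)
        assert sw["class"].iloc[0] == "NA"
        sw2 = comp.classify_switches(t1, t2, min_rep_agree=0.6)
        assert sw2["class"].iloc[0] == "A->A"

    def test_condition_swap_maps_classes(self):
        t1 = [make_track([1, 1, -1, -1])]
        t2 = [make_track([1, -1, -1, 1])]
        fwd = comp.classify_switches(t1, t2)["class"]
        rev = comp.classify_switches(t2, t1)["class"]
        mapping = {"A->B": "B->A", "B->A": "A->B", "A->A": "A->A", "B->B": "B->B"}
        assert rev.tolist() == [mapping[c] for c in fwd]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            comp.classify_switches([make_track([1, 1])], [make_track([1, 1, 1])])

    def test_segment_runs(self):
        track = make_track([1, 1, -1, -1, -1, 1])
        seg = comp.segment_track(track)
        assert seg["label"].tolist() == ["A", "B", "A"]
        assert seg["end"].iloc[0] == 2 * 50_000


class TestSaddle:
    def test_printed_formula_on_block_oe(self):
        # corner means AA=2, BB=2, AB=1 -> strength log2(4/2) = 1
        n = 40
        labels = np.array([1] * 20 + [-1] * 20)
        oe = np.where(labels[:, None] == labels[None, :], 2.0, 1.0)
        track = make_track(labels.astype(float))
        res = comp.saddle_strength(
            OEMatrix("c", 50_000, oe, np.ones(n), np.ones(n, bool)), track, n_quantiles=10
        )
        assert res.corner_means["AA"] == pytest.approx(2.0)
        assert res.corner_means["AB"] == pytest.approx(1.0)
        assert res.strength == pytest.approx(1.0)

    def test_uniform_oe_strength_zero(self):
        n = 40
        track = make_track(np.linspace(-1, 1, n))
        res = comp.saddle_strength(
            OEMatrix("c", 50_000, np.ones((n, n)), np.ones(n), np.ones(n, bool)),
            track,
            n_quantiles=10,
        )
        assert res.strength == pytest.approx(0.0)
        assert np.allclose(res.saddle[np.isfinite(res.saddle)], 0.0)

    def test_sign_flip_invariance(self):
        oe, labels = checkerboard_oe()
        res1 = comp.saddle_strength(oe, make_track(labels.astype(float)), n_quantiles=10)
        res2 = comp.saddle_strength(oe, make_track(-labels.astype(float)), n_quantiles=10)
        assert res1.strength == pytest.approx(res2.strength)

    def test_strength_monotone_in_gamma(self):
        strengths = []
        for gamma in (0.2, 0.4, 0.6):
            oe, labels = checkerboard_oe(gamma=gamma)
            res = comp.saddle_strength(oe, make_track(labels.astype(float)), n_quantiles=10)
            strengths.append(res.strength)
        assert strengths[0] < strengths[1] < strengths[2]


class TestAbRatio:
    def test_checkerboard_signs(self):
        oe, labels = checkerboard_oe()
        track = make_track(labels.astype(float))
        tab = comp.ab_interaction_ratio(oe, track, window_bp=100_000)
        for row in tab.itertuples():
            bin0 = row.start // 50_000
            if labels[bin0] > 0:
                assert row.log2_ab_ratio > 0
            else:
                assert row.log2_ab_ratio < 0

    def test_all_a_flagged_missing(self):
        n = 20
        oe = OEMatrix("c", 50_000, np.ones((n, n)), np.ones(n), np.ones(n, bool))
        track = make_track(np.ones(n))
        tab = comp.ab_interaction_ratio(oe, track, window_bp=100_000)
        assert tab["no_b_contact"].all()
        assert tab["log2_ab_ratio"].isna().all()

    def test_balanced_contact_gives_zero(self):
        # equal total O/E to A and B bins -> log2 ratio 0
        labels = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        oe = np.ones((6, 6))
        track = make_track(labels)
        tab = comp.ab_interaction_ratio(
            OEMatrix("c", 50_000, oe, np.ones(6), np.ones(6, bool)), track, window_bp=100_000
        )
        last = tab.iloc[-1]  # the NA-labeled window sees 2 A and 2 B bins equally
        assert last.log2_ab_ratio == pytest.approx(0.0)


def test_switch_summary_partitions_and_percentage():
    sw = pd.DataFrame({"class": ["A->A", "B->A", "B->A", "A->B", "NA"]})
    s = comp.switch_summary(sw)
    assert s["n_classified"] == 4
    assert s["switch_fraction"] == pytest.approx(3 / 4)
    assert s["pct_activation"] == pytest.approx(100 * 2 / 3)
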