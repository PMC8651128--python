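"""Loss functions vs closed forms and straight-line oracles."""

import warnings

import numpy as np
import pytest

from stdgnn import losses as L
from stdgnn.autodiff import Tensor


class TestTumorLoss:
    def test_perfect_one_hot_prediction_is_zero(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        assert L.tumor_loss(probs, np.array([0, 1, 2, 0])).item() \
            == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_closed_form(self):
        D = 7
        probs = np.full((D, 3), 1 / 3)
        val = L.tumor_loss(probs, np.arange(D) % 3).item()
        assert val == pytest.approx(D * np.log(3), rel=1e-12)

    def test_matches_scalar_loop(self, rng):
        D, C = 6, 3
        probs = rng.dirichlet(np.ones(C), size=D)
        targets = rng.integers(0, C, size=D)
        weights = rng.random(D)
        ref = 0.0
        for i in range(D):
            ref += -weights[i] * np.log(probs[i, targets[i]])
        val = L.tumor_loss(probs, targets, weights=weights).item()
        assert val == pytest.approx(ref, rel=1e-9)

    def test_voxelwise_mask_mode_averages_over_voxels(self, rng):
        fg = rng.random((2, 4, 4, 2))
        probs = np.stack([1 - fg, fg], axis=1)
        tgt = (rng.random((2, 4, 4, 2)) > 0.5).astype(float)
        onehot = np.stack([1 - tgt, tgt], axis=1)
        ref = 0.0
        for i in range(2):
            ce = -(onehot[i] * np.log(np.maximum(probs[i], 1e-12))).sum(0)
            ref += ce.mean()
        assert L.tumor_loss(probs, onehot).item() == pytest.approx(ref,
                                                                   rel=1e-9)

    def test_zero_probabilities_clamped(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        val = L.tumor_loss(probs, np.array([1])).item()
        assert np.isfinite(val) and val > 0


class TestSlicedWasserstein:
    def test_identical_sets_give_exact_zero(self, rng):
        a = rng.normal(size=(20, 3))
        assert L.sliced_wasserstein(a, a.copy(), seed=0) == 0.0

    def test_one_dimensional_two_point_closed_form(self):
        assert L.sliced_wasserstein([[0.0]], [[1.0]], n_projections=17) \
            == pytest.approx(1.0, rel=1e-12)

    def test_translation_of_1d_sets(self):
        a = np.array([[0.0], [2.0], [4.0]])
        assert L.sliced_wasserstein(a, a + 3.0) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(15, 4)), rng.normal(size=(25, 4))
        d1 = L.sliced_wasserstein(a, b, seed=5)
        d2 = L.sliced_wasserstein(b, a, seed=5)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_triangle_inequality_spot_checks(self, rng):
        for _ in range(5):
            a, b, c = (rng.normal(size=(30, 3)) + rng.normal(size=3)
                       for _ in range(3))
            kw = dict(n_projections=256, seed=2)
            dab = L.sliced_wasserstein(a, b, **kw)
            dbc = L.sliced_wasserstein(b, c, **kw)
            dac = L.sliced_wasserstein(a, c, **kw)
            assert dac <= dab + dbc + 1e-6

    def test_matches_fine_projection_grid_oracle(self, rng):
        """2-D Gaussian pairs vs a dense fixed-angle grid of exact sorted
        1-D W2 distances."""
        a = rng.normal([0, 0], [1.0, 0.5], size=(300, 2))
        b = rng.normal([1.5, -0.5], [0.7, 1.2], size=(300, 2))
        angles = np.linspace(0.0, np.pi, 2000, endpoint=False)
        grid = np.stack([np.cos(angles), np.sin(angles)])
        pa = np.sort(a @ grid, axis=0)
        pb = np.sort(b @ grid, axis=0)
        ref = np.sqrt(np.mean((pa - pb) ** 2))
        val = L.sliced_wasserstein(a, b, n_projections=10_000, seed=7)
        assert val == pytest.approx(ref, rel=0.02)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            L.sliced_wasserstein(np.empty((0, 2)), np.ones((3, 2)))


class TestAdversarialLoss:
    def test_reduces_to_standard_loss_at_phi_zero_xi_one(self, rng):
        real = rng.uniform(0.1, 0.9, size=6)
        fake = rng.uniform(0.1, 0.9, size=6)
        feats = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        e, c = L.adversarial_loss(real, fake, feats, labels, phi=0.0, xi=1.0)
        ref = -np.mean(np.log(real)) - np.mean(np.log(1 - fake))
        assert e.item() == pytest.approx(ref, rel=1e-9)

    def test_identical_class_distributions_zero_cost(self, rng):
        pts = rng.normal(size=(4, 3))
        feats = np.vstack([pts, pts, pts])
        labels = np.repeat([0, 1, 2], 4)
        real = np.full(12, 0.7)
        fake = np.full(12, 0.4)
        e, c = L.adversarial_loss(real, fake, feats, labels,
                                  phi=30.0, xi=0.35)
        assert c == pytest.approx(0.0, abs=1e-12)
        ref = -np.log(0.7) - 0.35 * np.log(0.6)
        assert e.item() == pytest.approx(ref, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        real = rng.uniform(0.2, 0.8, size=8)
        fake = rng.uniform(0.2, 0.8, size=8)
        feats = rng.normal(size=(8, 5))
        labels = rng.integers(0, 3, size=8)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, size=8)
        e, c = L.adversarial_loss(real, fake, feats, labels, phi=30.0,
                                  xi=0.35, n_projections=64, seed=3)
        ref = -np.mean([np.log(r) for r in real]) \
            - (30.0 * c + 0.35) * np.mean([np.log(1 - f) for f in fake])
        assert e.item() == pytest.approx(ref, rel=1e-6)

    def test_single_class_batch_warns_and_uses_zero_cost(self, rng):
        with pytest.warns(UserWarning):
            e, c = L.adversarial_loss(
                np.full(3, 0.5), np.full(3, 0.5),
                rng.normal(size=(3, 2)), np.zeros(3), phi=30.0, xi=0.35)
        assert c == 0.0


class TestWeightDivergence:
    def test_disjoint_binary_edge_sets_give_zero(self):
        Wb = np.array([[0, 1], [1, 0.0]])
        Ww = np.array([[0, 0], [0, 0.0]])
        with pytest.warns(UserWarning):
            assert L.weight_divergence(Wb, Ww).item() == 0.0

    def test_equal_nonzero_graphs_give_one(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        assert L.weight_divergence(W, W).item() == pytest.approx(1.0)

    def test_soft_graphs_match_hand_cosine(self, rng):
        A = rng.random((5, 5))
        B = rng.random((5, 5))
        ref = (A.ravel() @ B.ravel()) / (np.linalg.norm(A)
                                         * np.linalg.norm(B))
        assert L.weight_divergence(A, B).item() == pytest.approx(ref,
                                                                 rel=1e-9)


def brute_force_triplet(X, labels, margin):
    """Exhaustive batch-hard mining over all anchors."""
    n = len(X)
    D = np.sum((X[:, None] - X[None]) ** 2, axis=-1)
    vals = []
    for a in range(n):
        pos = [j for j in range(n) if j != a and labels[j] == labels[a]]
        neg = [j for j in range(n) if labels[j] != labels[a]]
        if not pos or not neg:
            continue
        d_pos = max(D[a, j] for j in pos)
        d_neg = min(D[a, j] for j in neg)
        vals.append(max(0.0, d_pos - d_neg + margin))
    return float(np.mean(vals)) if vals else 0.0


class TestTripletLoss:
    def test_separated_clusters_beyond_margin_give_zero(self):
        X = np.vstack([np.zeros((3, 2)), 10 + np.zeros((3, 2))])
        labels = np.repeat([0, 1], 3)
        assert L.triplet_loss(X, labels, margin=0.3).item() == 0.0

    def test_three_point_coincident_fixture_gives_margin(self):
        # anchor == positive, negative == anchor -> d_pos = d_neg = 0
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        labels = np.array([0, 0, 1])
        assert L.triplet_loss(X, labels, margin=0.3).item() \
            == pytest.approx(0.3)

    def test_matches_exhaustive_mining_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(10, 4))
            labels = rng.integers(0, 3, size=10)
            if len(np.unique(labels)) < 2:
                continue
            ref = brute_force_triplet(X, labels, 0.3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = L.triplet_loss(X, labels, margin=0.3).item()
            assert val == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_unmineable_batch_warns_and_returns_zero(self, rng):
        with pytest.warns(UserWarning):
            v = L.triplet_loss(rng.normal(size=(3, 2)),
                               np.array([0, 1, 2]), 0.3)
        assert v.item() == 0.0


class TestOverallLoss:
    def test_all_zero_parts_give_zero(self):
        total, rep = L.overall_loss(0, 0, 0, 0, 0, 0)
        assert total.item() == 0.0 and rep.E_overall == 0.0

    def test_zero_weights_reduce_global_term_to_tumor(self):
        total, rep = L.overall_loss(2.0, 5.0, 7.0, 0, 0, 0,
                                    lambda_w=0.0, lambda_a=0.0)
        assert rep.E_triplet_global == pytest.approx(2.0)

    def test_published_weighting(self):
        total, rep = L.overall_loss(1.0, 2.0, 3.0, 0.5, 0.25, 0.125,
                                    lambda_w=0.2, lambda_a=0.5)
        e_global = 1.0 + 0.2 * 2.0 + 0.5 * 3.0
        assert rep.E_triplet_global == pytest.approx(e_global)
        assert rep.E_overall == pytest.approx(e_global + 0.5 + 0.25 + 0.125)
        assert rep.check_decomposition(0.2, 0.5)

    def test_decomposition_check_detects_corruption(self):
        _, rep = L.overall_loss(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        rep.E_overall += 1.0
        assert not rep.check_decomposition(0.2, 0.5)
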