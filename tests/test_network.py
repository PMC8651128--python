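"""Forward-model identities: GCN algebra, shapes, determinism."""

import numpy as np
import pytest

from stdgnn import autodiff as ad
from stdgnn.autodiff import Tensor
from stdgnn.graphs import normalize_adjacency
from stdgnn.io_core import desk_config
from stdgnn.network import (STDGNN, Backbone, Discriminator,
                            GraphConvBranch, StructuralBranch,
                            TemporalBranch)


@pytest.fixture()
def cfg():
    return desk_config(seed=3)


def random_graphs(rng, n):
    W = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
    W = W + W.T
    Wb = np.triu((rng.random((n, n)) < 0.2).astype(float), 1)
    return normalize_adjacency(W), normalize_adjacency(Wb + Wb.T)


def dense_branch_oracle(X, Wb, Ww, lift_w, lift_b, layers, residual=True):
    """Straight-line dense recomputation of the graph-conv branch without
    normalization or nonlinearity."""
    h = X @ lift_w + lift_b
    for k, B in enumerate(layers):
        out = Wb @ h @ B - Ww @ h @ B
        if residual and k >= 1 and out.shape == h.shape:
            out = out + h
        h = out
    return h.max(axis=0)


class TestTemporalBranch:
    def test_equal_graphs_cancel_pre_activation(self, rng):
        """W_b = W_w makes every layer's pre-activation exactly zero."""
        n, d = 12, 8
        Wn, _ = random_graphs(rng, n)
        br = TemporalBranch(d, 16, K=3, rng=rng, norm=False,
                            activation=False, residual=False)
        X = Tensor(rng.normal(size=(n, d)))
        out = br(X, Wn, Wn)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_residual_identity_with_zero_later_layers(self, rng):
        """B_k = 0 for k >= 2 collapses the stack onto the first layer."""
        n, d, dk = 10, 6, 12
        Wb, Ww = random_graphs(rng, n)
        br = TemporalBranch(d, dk, K=3, rng=rng, norm=False,
                            activation=False)
        for B in br.layers[1:]:
            B.data[:] = 0.0
        X = rng.normal(size=(n, d))
        out = br(Tensor(X), Wb, Ww)
        h1 = (X @ br.lift.weight.data + br.lift.bias.data)
        h1 = Wb @ h1 @ br.layers[0].data - Ww @ h1 @ br.layers[0].data
        np.testing.assert_allclose(out.data, h1.max(axis=0), atol=1e-9)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            n, d, dk = 14, 5, 9
            Wb, Ww = random_graphs(rng, n)
            br = TemporalBranch(d, dk, K=3, rng=rng, norm=False,
                                activation=False)
            X = rng.normal(size=(n, d))
            ref = dense_branch_oracle(
                X, Wb, Ww, br.lift.weight.data, br.lift.bias.data,
                [B.data for B in br.layers])
            np.testing.assert_allclose(br(Tensor(X), Wb, Ww).data, ref,
                                       atol=1e-6)

    def test_permutation_invariance_of_pooled_feature(self, rng):
        n, d = 12, 6
        Wb, Ww = random_graphs(rng, n)
        br = TemporalBranch(d, 8, K=2, rng=rng, norm=False)
        X = rng.normal(size=(n, d))
        perm = rng.permutation(n)
        out1 = br(Tensor(X), Wb, Ww)
        out2 = br(Tensor(X[perm]), Wb[np.ix_(perm, perm)],
                  Ww[np.ix_(perm, perm)])
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)


class TestStructuralBranch:
    def test_dims_halve_to_target(self, rng):
        br = StructuralBranch(6, d_m=32, M=2, rng=rng)
        assert br.lift.weight.shape == (6, 128)
        assert br.layers[0].shape == (128, 64)
        assert br.layers[1].shape == (64, 32)

    def test_single_volume_reduces_to_one_graph_pass(self, rng):
        n, d = 8, 5
        Wb, Ww = random_graphs(rng, n)
        br = StructuralBranch(d, 16, M=2, rng=rng, norm=False,
                              activation=False)
        X = rng.normal(size=(n, d))
        ref = dense_branch_oracle(
            X, Wb, Ww, br.lift.weight.data, br.lift.bias.data,
            [B.data for B in br.layers])
        np.testing.assert_allclose(br(Tensor(X), Wb, Ww).data, ref,
                                   atol=1e-6)


class TestBackbone:
    def test_zero_input_zero_bias_gives_zero_maps(self, cfg, rng):
        bb = Backbone(cfg, rng, pool_input=False)
        for name, p in bb.named_parameters():
            if "beta" in name or "bias" in name:
                p.data[:] = 0.0
        out = bb.eval() or bb(Tensor(np.zeros((1, 2, 8, 8, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_two_pools_quarter_spatial_dims(self, cfg, rng):
        bb = Backbone(cfg, rng, pool_input=False)
        out = bb(Tensor(np.random.default_rng(0).normal(
            size=(1, 2, 16, 12, 8))))
        assert out.shape[2:] == (4, 3, 2)
        assert out.shape[1] == cfg.backbone_channels[-1]

    def test_too_small_volume_rejected(self, cfg, rng):
        bb = Backbone(cfg, rng)
        with pytest.raises(ValueError, match="receptive field"):
            bb(Tensor(np.zeros((1, 2, 4, 4, 4))))

    def test_fixed_weights_bit_identical_repeats(self, cfg, rng):
        bb = Backbone(cfg, rng)
        bb.eval()
        x = Tensor(rng.normal(size=(2, 2, 16, 16, 8)))
        np.testing.assert_array_equal(bb(x).data, bb(x).data)


class TestDiscriminator:
    def test_score_in_unit_interval(self, cfg, rng):
        d = Discriminator(cfg, in_channels=6, rng=rng)
        x = Tensor(rng.normal(size=(3, 6, 24, 24, 8)).astype(np.float32))
        s = d(x).data
        assert np.all((s > 0) & (s < 1))

    def test_zero_weight_net_gives_sigmoid_bias(self, cfg, rng):
        d = Discriminator(cfg, in_channels=2, rng=rng)
        for _, p in d.named_parameters():
            p.data[:] = 0.0
        s = d(Tensor(np.random.default_rng(1).normal(
            size=(2, 2, 8, 8, 4)).astype(np.float32))).data
        np.testing.assert_allclose(s, 0.5, atol=1e-7)

    def test_geometry_mismatch_rejected(self, cfg, rng):
        d = Discriminator(cfg, in_channels=2, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            d(Tensor(np.zeros((1, 2, 10, 10, 6))))


class TestFullModel:
    def test_forward_shapes_and_mask_softmax(self, cfg, small_cohort):
        model = STDGNN(cfg, n_phases_out=5)
        pre = small_cohort[0][0]
        vols = pre.volumes[: cfg.T_sample][None]
        masks = pre.tumor_mask[None]
        out = model.forward(vols, masks)
        assert out["f_t"].shape == (1, cfg.d_k)
        assert out["f_s"].shape == (1, cfg.T_sample * cfg.d_m)
        assert out["class_probs"].shape == (1, 3)
        assert out["class_probs"].data.sum() == pytest.approx(1.0, abs=1e-6)
        # voxelwise mask softmax sums to one
        np.testing.assert_allclose(out["mask_probs"].data.sum(axis=1), 1.0,
                                   atol=1e-6)
        # half-resolution generator grid
        assert out["pred_intensity"].shape == (1, 5, 24, 24, 8)

    def test_prediction_restores_input_grid_and_is_deterministic(
            self, cfg, small_cohort):
        model = STDGNN(cfg, n_phases_out=5)
        pre = small_cohort[0][0]
        vols = pre.volumes[: cfg.T_sample][None]
        masks = pre.tumor_mask[None]
        p1 = model.predict_sequence(vols, masks)[0]
        p2 = model.predict_sequence(vols, masks)[0]
        assert p1.post_sequence.shape == (5,) + pre.shape
        assert p1.post_mask.shape == pre.shape
        assert np.all((p1.post_mask >= 0) & (p1.post_mask <= 1))
        np.testing.assert_array_equal(p1.post_sequence, p2.post_sequence)
        np.testing.assert_array_equal(p1.post_mask, p2.post_mask)
        assert p1.viability_class in ("V", "E", "NV")
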