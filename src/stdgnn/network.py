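"""The STDGNN forward model.

A shared convolutional trunk maps each 3-D phase volume (plus the baseline
tumor mask as a second input channel) to a feature map.  Patch features
pooled from the maps feed two discriminant graph-convolution branches:

* the temporal branch runs K graph-conv layers over all N = T x P patches
  of the sequence, each layer computing
  ``X_k = W_b_hat X_{k-1} B_k - W_w_hat X_{k-1} B_k`` (between-class
  propagation minus within-class propagation, shared weights B_k) with
  batch-norm + leaky rectifier and residual shortcuts for k >= 2, followed
  by a max-pool over nodes -> f_t;
* the structural branch runs M layers per volume over its P patches, with
  feature dimensionality halved per layer, max-pools per volume and
  concatenates across volumes -> f_s.

A global branch pools the trunk into a domain-translation feature
f_global.  The decoder consumes the trunk map modulated by the fused
vector [f_global, f_t, f_s] and upsamples through 4 convolutional layers
to emit the predicted follow-up phases, a 2-class voxel softmax tumor
mask, and the 3-class viability softmax.  A small convolutional
discriminator scores real/generated follow-up sequences in (0, 1).

All sizes are configurable; the defaults in
:func:`stdgnn.io_core.desk_config` are a CPU-scale profile of the
published architecture (which used ResNet-scale trunks on GPUs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import (Adam, BatchNorm, Conv3d, Linear, Module, Tensor,
                       avg_pool3d, concat, conv3d, leaky_relu, max_pool3d,
                       sigmoid, softmax, take_rows, upsample_nearest3d)
from .graphs import PatchFeatureSet, build_sequence_graph
from .io_core import RunConfig, VIABILITY_CLASSES, child_rng

#: intensity normalization: raw units -> roughly [-1, 2]
INTENSITY_SCALE = 100.0


def normalize_intensity(v):
    return v / INTENSITY_SCALE - 1.0


def denormalize_intensity(v):
    return (v + 1.0) * INTENSITY_SCALE


@dataclass
class BranchOutputs:
    f_t: np.ndarray
    f_s: np.ndarray
    f_global: np.ndarray
    class_logits: np.ndarray
    class_probabilities: np.ndarray


@dataclass
class Prediction:
    post_sequence: np.ndarray       # (T, X, Y, Z) intensity units
    post_mask: np.ndarray           # (X, Y, Z) probabilistic mask in [0,1]
    viability_class: str
    class_probabilities: dict


# ---------------------------------------------------------------------------

class Backbone(Module):
    """Small 3-conv trunk with 2 max-pools (channels/kernels configurable).

    With ``pool_input`` an initial fixed 2x average pool halves the grid
    before any convolution — the desk-scale default for 48x48x16 volumes.
    Two 2x max-pools sit between the three conv layers, so spatial dims
    shrink by 4 (or 8 with the input pool).
    """

    def __init__(self, cfg: RunConfig, rng, in_channels=2, pool_input=True):
        c1, c2, c3 = cfg.backbone_channels
        k = cfg.backbone_kernel
        self.pool_input = pool_input
        self.conv1 = Conv3d(in_channels, c1, k, rng)
        self.bn1 = BatchNorm(c1)
        self.conv2 = Conv3d(c1, c2, k, rng)
        self.bn2 = BatchNorm(c2)
        self.conv3 = Conv3d(c2, c3, k, rng)
        self.bn3 = BatchNorm(c3)
        self.out_channels = c3

    def __call__(self, x):
        min_dim = 8 if self.pool_input else 4
        if min(x.shape[2:]) < min_dim:
            raise ValueError(
                f"volume spatial dims {x.shape[2:]} smaller than the "
                f"receptive field (need >= {min_dim} per axis)")
        if self.pool_input:
            x = avg_pool3d(x)
        x = leaky_relu(self.bn1(self.conv1(x)))
        x = max_pool3d(x)
        x = leaky_relu(self.bn2(self.conv2(x)))
        x = max_pool3d(x)
        x = leaky_relu(self.bn3(self.conv3(x)))
        return x


class GraphConvBranch(Module):
    """Shared implementation of the discriminant graph-conv branches.

    ``dims`` gives the feature width after each layer; layer weights B_k
    map dims[k-1] -> dims[k] and are shared between the between-class and
    within-class propagation terms, exactly as the update is printed.
    """

    def __init__(self, d_in, dims, rng, norm=True, activation=True,
                 residual=True):
        self.lift = Linear(d_in, dims[0], rng)
        self.layers = [Tensor(
            rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1])),
            requires_grad=True) for i in range(len(dims) - 1)]
        self.norms = [BatchNorm(dims[i + 1]) for i in range(len(dims) - 1)] \
            if norm else None
        self.activation = activation
        self.residual = residual

    def __call__(self, x, W_b_hat, W_w_hat):
        """x: (N, d_in) node features; graphs: (N, N) numpy adjacencies."""
        h = self.lift(x)
        dt = h.data.dtype
        Wb, Ww = Tensor(W_b_hat.astype(dt)), Tensor(W_w_hat.astype(dt))
        for k, B in enumerate(self.layers):
            prev = h
            pre = ad.matmul(Wb, h) @ B - ad.matmul(Ww, h) @ B
            if self.norms is not None:
                pre = self.norms[k](pre)
            h = leaky_relu(pre, 0.01) if self.activation else pre
            if self.residual and k >= 1 and h.shape == prev.shape:
                h = h + prev
        return h.max(axis=0)       # max-pool over nodes


class TemporalBranch(GraphConvBranch):
    def __init__(self, d_in, d_k, K, rng, **kw):
        super().__init__(d_in, [d_k] * (K + 1), rng, **kw)


class StructuralBranch(GraphConvBranch):
    """Per-volume branch; dims halve per layer down to d_m."""

    def __init__(self, d_in, d_m, M, rng, **kw):
        dims = [d_m * 2 ** (M - m) for m in range(M)] + [d_m]
        dims = [max(d, d_m) for d in dims]
        super().__init__(d_in, dims, rng, **kw)


class GlobalBranch(Module):
    """Domain-translation generator feature.

    Consumes the spatially pooled trunk features together with the
    lesion's own enhancement curve (mean normalized intensity inside the
    annotated tumor per sampled phase).  At desk scale the trunk grid is
    coarse enough that a small lesion occupies ~1 cell, so the ROI curve
    carries the class-discriminative enhancement kinetics explicitly —
    the lesion annotation is an input of the method by design.
    """

    def __init__(self, d_in, d_global, rng):
        self.fc1 = Linear(d_in, d_global, rng)
        self.fc2 = Linear(d_global, d_global, rng)

    def __call__(self, x):
        return self.fc2(leaky_relu(self.fc1(x), 0.01))


class Decoder(Module):
    """4 conv layers (3 up-sampling stages + 1x1 head) with dual output:
    per-phase intensity volumes and a 2-class voxel softmax mask."""

    def __init__(self, cfg: RunConfig, d_fused, trunk_channels, n_phases_out,
                 rng):
        dc = cfg.decoder_channels
        k = (3, 3, 3)
        self.film = Linear(d_fused, 2 * trunk_channels, rng)
        self.conv0 = Conv3d(trunk_channels, dc[0], k, rng)
        self.bn0 = BatchNorm(dc[0])
        self.conv1 = Conv3d(dc[0], dc[1], k, rng)
        self.bn1 = BatchNorm(dc[1])
        # finest pre-upsample stage: in-plane kernel only (thin z, and the
        # copy cost of a full 3-D kernel at this grid dominates the pass)
        self.conv2 = Conv3d(dc[1], dc[2], (3, 3, 1), rng)
        self.bn2 = BatchNorm(dc[2])
        self.head = Conv3d(dc[2], n_phases_out + 2, (1, 1, 1), rng)
        self.n_phases_out = n_phases_out

    def forward(self, trunk_map, fused):
        b, c = trunk_map.shape[:2]
        gb = self.film(fused).reshape(b, 2 * c, 1, 1, 1)
        gamma = take_cols5(gb, 0, c)
        beta = take_cols5(gb, c, 2 * c)
        x = trunk_map * (1.0 + gamma) + beta
        x = leaky_relu(self.bn0(self.conv0(x)))
        x = upsample_nearest3d(x)
        x = leaky_relu(self.bn1(self.conv1(x)))
        x = upsample_nearest3d(x)
        x = leaky_relu(self.bn2(self.conv2(x)))
        # heads run on the half-resolution grid; the final 2x nearest
        # upsample happens only at inference (softmax commutes with it)
        out = self.head(x)                             # (B, T+2, X/2, Y/2, Z/2)
        intensity = take_cols5(out, 0, self.n_phases_out)
        mask_logits = take_cols5(out, self.n_phases_out,
                                 self.n_phases_out + 2)
        mask_probs = softmax(mask_logits, axis=1)
        return intensity, mask_probs


def take_cols5(x, lo, hi):
    """Channel slice of a (B, C, ...) tensor, differentiable."""
    perm = (1, 0) + tuple(range(2, x.ndim))
    xt = x.transpose(*perm)
    sl = take_rows(xt, np.arange(lo, hi))
    return sl.transpose(*perm)


class Discriminator(Module):
    """Convolutional real/fake critic on (phases + mask) channel stacks."""

    def __init__(self, cfg: RunConfig, in_channels, rng):
        d = cfg.disc_channels
        k = (3, 3, 3)
        self.conv1 = Conv3d(in_channels, d[0], k, rng)
        self.conv2 = Conv3d(d[0], d[1], k, rng)
        self.conv3 = Conv3d(d[1], d[2], k, rng)
        self.conv4 = Conv3d(d[2], d[3], k, rng)
        self.fc = Linear(d[3], 1, rng)
        self.astype(np.float32)

    def __call__(self, x):
        """x: (B, C, X, Y, Z) stack on the generator's half-resolution grid."""
        if any(s % 4 != 0 for s in x.shape[2:]):
            raise ValueError(f"discriminator needs dims divisible by 4, "
                             f"got {x.shape[2:]}")
        x = avg_pool3d(x)          # critic operates on a pooled grid
        x = leaky_relu(self.conv1(x), 0.2)
        x = avg_pool3d(x)
        x = leaky_relu(self.conv2(x), 0.2)
        x = leaky_relu(self.conv3(x), 0.2)
        x = leaky_relu(self.conv4(x), 0.2)
        x = x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)
        return sigmoid(self.fc(x))                       # (B, 1) in (0, 1)


# ---------------------------------------------------------------------------

class STDGNN(Module):
    """Full spatio-temporal discriminant graph network."""

    def __init__(self, cfg: RunConfig, n_phases_out: int = 5,
                 seed: Optional[int] = None):
        self.cfg = cfg
        seed = cfg.seed if seed is None else seed
        rng = child_rng(seed, "init")
        self.backbone = Backbone(cfg, rng)
        c3 = self.backbone.out_channels
        self.temporal = TemporalBranch(c3, cfg.d_k, cfg.K, rng)
        self.structural = StructuralBranch(c3, cfg.d_m, cfg.M, rng)
        self.global_branch = GlobalBranch(c3 + cfg.T_sample, cfg.d_global,
                                          rng)
        self.d_fused = cfg.d_global + cfg.d_k + cfg.T_sample * cfg.d_m
        self.classifier = Linear(self.d_fused, 3, rng)
        self.decoder = Decoder(cfg, self.d_fused, c3, n_phases_out, rng)
        self.n_phases_out = n_phases_out
        self.astype(np.float32)   # single precision is ample for training

    # -- helpers ----------------------------------------------------------
    def _trunk(self, volumes, masks):
        """volumes: (B, T, X, Y, Z) raw intensities; masks: (B, X, Y, Z)."""
        b, t = volumes.shape[:2]
        vol = normalize_intensity(volumes.astype(np.float32))
        m = np.repeat(masks[:, None].astype(np.float32), t, axis=1)
        x = np.stack([vol, m], axis=2).reshape((b * t, 2) + volumes.shape[2:])
        return self.backbone(Tensor(x)), b, t

    def _patch_nodes(self, maps, b, t):
        """Pool trunk maps into per-sequence node features.

        Returns a (B*T, P, c) tensor of patch features, pooled over the
        configured patch grid.
        """
        g = self.cfg.patch_grid
        s = maps.shape[2:]
        factor = tuple(max(1, s[i] // g[i]) for i in range(3))
        pooled = avg_pool3d(maps, factor)                # (B*T, c, gx, gy, gz)
        c = pooled.shape[1]
        nodes = pooled.reshape(b * t, c, -1).transpose(0, 2, 1)  # (B*T, P, c)
        return nodes

    def forward(self, volumes, masks):
        """Run the full forward pass on a batch.

        volumes: (B, T_sample, X, Y, Z) raw intensities
        masks:   (B, X, Y, Z) binary baseline tumor masks
        Returns a dict of Tensors/arrays used by training and inference.
        """
        cfg = self.cfg
        maps, b, t = self._trunk(volumes, masks)
        nodes = self._patch_nodes(maps, b, t)            # (B*T, P, c)
        P = nodes.shape[1]
        c = nodes.shape[2]

        f_t_list, f_s_list = [], []
        nodes_np = nodes.data
        for i in range(b):
            rows = np.arange(i * t, (i + 1) * t)
            seq_nodes = take_rows(nodes, rows).reshape(t * P, c)
            feats = PatchFeatureSet(
                nodes_np[rows].reshape(t * P, c),
                np.repeat(np.arange(t), P), np.tile(np.arange(P), t))
            Wb_hat, Ww_hat = build_sequence_graph(feats, k_w=cfg.k_w)
            f_t_list.append(self.temporal(seq_nodes, Wb_hat, Ww_hat)
                            .reshape(1, -1))
            vol_feats = []
            for j in range(t):
                vnodes = take_rows(nodes, np.array([i * t + j]))\
                    .reshape(P, c)
                vf = PatchFeatureSet(nodes_np[i * t + j],
                                     np.zeros(P, int), np.arange(P))
                Wbv, Wwv = build_sequence_graph(vf, k_w=min(cfg.k_w, P - 1))
                vol_feats.append(self.structural(vnodes, Wbv, Wwv)
                                 .reshape(1, -1))
            f_s_list.append(concat(vol_feats, axis=1))
        f_t = concat(f_t_list, axis=0)                   # (B, d_k)
        f_s = concat(f_s_list, axis=0)                   # (B, T*d_m)

        pooled = maps.reshape(b * t, maps.shape[1], -1).mean(axis=2)
        pooled = pooled.reshape(b, t, maps.shape[1]).mean(axis=1)
        roi_curves = np.stack([
            normalize_intensity(volumes[i].astype(np.float32))
            [:, masks[i].astype(bool)].mean(axis=1)
            for i in range(b)])                          # (B, T)
        f_global = self.global_branch(
            concat([pooled, Tensor(roi_curves)], axis=1))  # (B, d_global)

        fused = concat([f_global, f_t, f_s], axis=1)
        logits = self.classifier(fused)
        probs = softmax(logits, axis=1)

        trunk_mean = maps.reshape((b, t) + maps.shape[1:]).mean(axis=1)
        intensity, mask_probs = self.decoder.forward(trunk_mean, fused)
        # generated volumes and masks live on the half-resolution grid
        # during training; predict_sequence restores the input grid
        return dict(f_t=f_t, f_s=f_s, f_global=f_global,
                    class_logits=logits, class_probs=probs,
                    pred_intensity=intensity, mask_probs=mask_probs)

    def branch_outputs(self, volumes, masks) -> BranchOutputs:
        out = self.forward(volumes, masks)
        return BranchOutputs(
            f_t=out["f_t"].data, f_s=out["f_s"].data,
            f_global=out["f_global"].data,
            class_logits=out["class_logits"].data,
            class_probabilities=out["class_probs"].data)

    def predict_sequence(self, volumes, masks) -> list:
        """Eval-mode inference; returns one Prediction per batch item."""
        self.eval()
        with ad.no_grad():
            out = self.forward(volumes, masks)
        up = lambda a: np.repeat(np.repeat(np.repeat(
            a, 2, axis=-3), 2, axis=-2), 2, axis=-1)
        preds = []
        for i in range(volumes.shape[0]):
            probs = out["class_probs"].data[i]
            preds.append(Prediction(
                post_sequence=denormalize_intensity(
                    up(out["pred_intensity"].data[i])),
                post_mask=up(out["mask_probs"].data[i, 1]),
                viability_class=VIABILITY_CLASSES[int(np.argmax(probs))],
                class_probabilities={c: float(p) for c, p in
                                     zip(VIABILITY_CLASSES, probs)}))
        return preds
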