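"""Training objectives.

The overall objective combines a global domain-translation part with the
metric-learning parts of the two graph branches and a classification term:

    E_triplet_global = E_tumor + lambda_w * E_weight + lambda_a * E_adv
    E_overall        = E_triplet_global + E_triplet_t + E_triplet_s
                       + E_softmax

* E_tumor  — weighted multi-class cross-entropy on predicted masks/labels;
* E_adv    — adversarial loss whose fake term is weighted by
  (phi * c + xi), where c is the mean pairwise sliced-Wasserstein distance
  between the class-conditional feature distributions of the batch (the
  optimal-transport cost of mapping between viability groups); with
  phi = 0, xi = 1 it reduces to the standard adversarial loss;
* E_weight — cosine similarity between the flattened between- and
  within-class adjacencies; identically 0 for strictly binary disjoint
  graphs, so it only acts on soft-weighted graph variants;
* E_triplet_* — batch-hard triplet losses on branch features;
* E_softmax — cross-entropy on logits from [f_global, f_t, f_s].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-12


@dataclass
class LossReport:
    E_tumor: float = 0.0
    E_adv: float = 0.0
    E_weight: float = 0.0
    E_triplet_global: float = 0.0
    E_triplet_t: float = 0.0
    E_triplet_s: float = 0.0
    E_softmax: float = 0.0
    E_overall: float = 0.0
    transport_cost: float = 0.0

    def check_decomposition(self, lambda_w, lambda_a, atol=1e-6):
        """Verify the reported total against its recomputed weighted sum."""
        e_global = self.E_tumor + lambda_w * self.E_weight \
            + lambda_a * self.E_adv
        e_total = e_global + self.E_triplet_t + self.E_triplet_s \
            + self.E_softmax
        return (abs(e_global - self.E_triplet_global) <= atol
                and abs(e_total - self.E_overall) <= atol)

    def to_dict(self):
        return {k: float(getattr(self, k)) for k in (
            "E_tumor", "E_adv", "E_weight", "E_triplet_global",
            "E_triplet_t", "E_triplet_s", "E_softmax", "E_overall",
            "transport_cost")}


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------

def cross_entropy(logits, labels, reduction="mean"):
    """Softmax cross-entropy on integer labels; differentiable."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    logp = ad.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    nll = -(logp * Tensor(onehot)).sum(axis=-1)
    return nll.mean() if reduction == "mean" else nll.sum()


def tumor_loss(probs, targets, weights=None, voxel_weights=None):
    """Weighted multi-class cross-entropy, summed over the D samples.

    ``probs``: (D, C) class probabilities, or (D, C, ...) voxelwise mask
    probabilities.  ``targets``: integer labels (D,) or one-hot/binary
    arrays matching ``probs``.  For voxelwise inputs the cross-entropy is
    averaged over voxels so each sample contributes one term, scaled by its
    baseline weight (default 1); ``voxel_weights`` (D, ...) optionally
    re-weights voxels inside that average (e.g. to balance the small
    tumor foreground against the background).  Probabilities are clamped
    at 1e-12.
    """
    probs = _as_tensor(probs)
    targets = np.asarray(targets)
    D = probs.shape[0]
    if targets.ndim == 1 and targets.shape == (D,) and probs.ndim == 2:
        onehot = np.zeros(probs.shape)
        onehot[np.arange(D), targets.astype(int)] = 1.0
    else:
        onehot = targets.astype(float)
        if onehot.shape != tuple(probs.shape):
            raise ValueError("targets must match probs shape or be labels")
    logp = ad.log(probs, eps=EPS)
    per_sample = -(Tensor(onehot) * logp)
    per_sample = per_sample.sum(axis=1)          # over classes -> (D, ...)
    if per_sample.ndim > 1:
        if voxel_weights is not None:
            vw = np.asarray(voxel_weights, dtype=probs.data.dtype)
            per_sample = per_sample * Tensor(vw)
        per_sample = per_sample.reshape(D, -1).mean(axis=1)
    if weights is not None:
        per_sample = per_sample * Tensor(np.asarray(weights, float))
    return per_sample.sum()


# ---------------------------------------------------------------------------

def _quantiles(sorted_vals, m):
    n = sorted_vals.shape[0]
    if n == m:
        return sorted_vals
    src = (np.arange(n) + 0.5) / n
    dst = (np.arange(m) + 0.5) / m
    return np.interp(dst, src, sorted_vals)


def sliced_wasserstein(samples_a, samples_b, n_projections=64, seed=0,
                       projections=None):
    """Sliced 2-Wasserstein distance between two point sets in R^d.

    Averages the squared exact 1-D W2 distance between the projected,
    sorted samples over random unit directions (seeded) and returns the
    square root.  Point sets of unequal size are compared through their
    interpolated empirical quantile functions.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch")
    d = a.shape[1]
    if projections is None:
        rng = np.random.default_rng(seed)
        projections = rng.normal(size=(d, n_projections))
        projections /= np.linalg.norm(projections, axis=0, keepdims=True)
    pa = np.sort(a @ projections, axis=0)
    pb = np.sort(b @ projections, axis=0)
    m = max(pa.shape[0], pb.shape[0])
    if pa.shape[0] != pb.shape[0]:
        pa = np.stack([_quantiles(pa[:, j], m) for j in range(pa.shape[1])], axis=1)
        pb = np.stack([_quantiles(pb[:, j], m) for j in range(pb.shape[1])], axis=1)
    w2_sq = np.mean((pa - pb) ** 2, axis=0)
    return float(np.sqrt(np.mean(w2_sq)))


def transport_cost(features, labels, n_projections=64, seed=0):
    """Mean pairwise sliced-Wasserstein distance between the
    class-conditional feature distributions present in the batch."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    present = [c for c in np.unique(labels) if np.sum(labels == c) > 0]
    if len(present) < 2:
        warnings.warn("fewer than two classes in batch; transport cost 0")
        return 0.0
    dists = [
        sliced_wasserstein(features[labels == ca], features[labels == cb],
                           n_projections=n_projections, seed=seed)
        for ca, cb in combinations(present, 2)]
    return float(np.mean(dists))


def adversarial_loss(disc_real_scores, disc_fake_scores, features=None,
                     labels=None, phi=30.0, xi=0.35, n_projections=64,
                     seed=0, cost=None):
    """Generator-side adversarial loss with optimal-transport weighting.

        E_adv = -E[log D(real)] - E[(phi*c + xi) * log(1 - D(fake))]

    ``c`` is the transport cost between class-conditional feature
    distributions (supplied via ``cost`` or computed from
    ``features``/``labels``); with phi = 0, xi = 1 this is the standard
    adversarial loss.  Returns (E_adv, c).
    """
    real = _as_tensor(disc_real_scores)
    fake = _as_tensor(disc_fake_scores)
    if cost is None:
        cost = 0.0 if features is None else transport_cost(
            features, labels, n_projections=n_projections, seed=seed)
    w = phi * cost + xi
    e = -(ad.log(real, eps=EPS).mean()) \
        - w * (ad.log(1.0 - fake, eps=EPS).mean())
    return e, float(cost)


def weight_divergence(W_b, W_w):
    """Cosine similarity of the flattened graph weight matrices.

    For strictly binary graphs the edge sets are disjoint by construction
    and the value is identically 0; the term only acts on soft-weighted
    variants.  A zero matrix yields 0 (flagged by warning).
    """
    tb, tw = _as_tensor(W_b), _as_tensor(W_w)
    nb = float(np.linalg.norm(tb.data))
    nw = float(np.linalg.norm(tw.data))
    if nb == 0.0 or nw == 0.0:
        warnings.warn("zero graph weight matrix; cosine divergence set to 0")
        return Tensor(0.0)
    num = (tb * tw).sum()
    den = ad.sqrt((tb * tb).sum()) * ad.sqrt((tw * tw).sum())
    return num / den


def triplet_loss(features, labels, margin=0.3):
    """Batch-hard triplet loss with squared Euclidean distances.

    Per anchor, the hardest positive is its most distant same-class sample
    and the hardest negative its closest other-class sample; the loss is
    the mean hinge max(0, d_pos - d_neg + margin) over anchors that have
    both.  An unmineable batch yields 0 with a warning.
    """
    feats = _as_tensor(features)
    labels = np.asarray(labels)
    n = feats.shape[0]
    X = feats.data
    sq = np.sum(X ** 2, axis=1)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    same = labels[:, None] == labels[None, :]
    anchors, pos, neg = [], [], []
    for i in range(n):
        pmask = same[i].copy()
        pmask[i] = False
        nmask = ~same[i]
        if not pmask.any() or not nmask.any():
            continue
        anchors.append(i)
        pos.append(np.nonzero(pmask)[0][np.argmax(D[i][pmask])])
        neg.append(np.nonzero(nmask)[0][np.argmin(D[i][nmask])])
    if not anchors:
        warnings.warn("batch not mineable for triplets; loss 0")
        return Tensor(0.0)
    fa = ad.take_rows(feats, np.asarray(anchors))
    fp = ad.take_rows(feats, np.asarray(pos))
    fn = ad.take_rows(feats, np.asarray(neg))
    d_pos = ((fa - fp) ** 2).sum(axis=1)
    d_neg = ((fa - fn) ** 2).sum(axis=1)
    return ad.relu(d_pos - d_neg + margin).mean()


def overall_loss(e_tumor, e_weight, e_adv, e_triplet_t, e_triplet_s,
                 e_softmax, lambda_w=0.2, lambda_a=0.5,
                 transport=0.0):
    """Combine the loss parts; returns (total Tensor, LossReport)."""
    parts = [_as_tensor(x) for x in
             (e_tumor, e_weight, e_adv, e_triplet_t, e_triplet_s, e_softmax)]
    e_tumor, e_weight, e_adv, e_t, e_s, e_sm = parts
    e_global = e_tumor + lambda_w * e_weight + lambda_a * e_adv
    total = e_global + e_t + e_s + e_sm
    report = LossReport(
        E_tumor=float(e_tumor.data), E_adv=float(e_adv.data),
        E_weight=float(e_weight.data),
        E_triplet_global=float(e_global.data),
        E_triplet_t=float(e_t.data), E_triplet_s=float(e_s.data),
        E_softmax=float(e_sm.data), E_overall=float(total.data),
        transport_cost=float(transport))
    return total, report
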