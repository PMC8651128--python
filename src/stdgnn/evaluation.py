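"""Segmentation and outcome metrics.

Per-case: Dice overlap (%), Hausdorff distance (mm), mean squared
symmetric surface distance (mm^2 reported as mm-scale MSE), and voxel
intensity MSE of generated images.  Cohort-level: 3x3 confusion matrix in
fixed class order (V, E, NV), accuracy, macro one-vs-rest AUC, and paired
two-sided Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .io_core import VIABILITY_CLASSES


def dice(mask_a, mask_b) -> float:
    """Dice similarity in percent: 100 * 2|A&B| / (|A| + |B|)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 100.0   # both empty: flagged as perfect by convention
    return float(100.0 * 2.0 * np.logical_and(a, b).sum() / denom)


def _surface_points(mask, spacing):
    mask = np.asarray(mask).astype(bool)
    interior = binary_erosion(mask)
    surf = mask & ~interior
    pts = np.argwhere(surf).astype(float)
    return pts * np.asarray(spacing, float)


def hausdorff(mask_a, mask_b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric surface Hausdorff distance in mm."""
    pa = _surface_points(mask_a, spacing)
    pb = _surface_points(mask_b, spacing)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("empty mask")
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa)[0].max()
    d_ba = ta.query(pb)[0].max()
    return float(max(d_ab, d_ba))


def surface_mse(mask_a, mask_b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean squared symmetric surface distance (mm^2)."""
    pa = _surface_points(mask_a, spacing)
    pb = _surface_points(mask_b, spacing)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("empty mask")
    ta, tb = cKDTree(pa), cKDTree(pb)
    d = np.concatenate([tb.query(pa)[0], ta.query(pb)[0]])
    return float(np.mean(d ** 2))


def intensity_mse(vol_a, vol_b) -> float:
    a, b = np.asarray(vol_a, float), np.asarray(vol_b, float)
    if a.shape != b.shape:
        raise ValueError("volume shapes differ")
    return float(np.mean((a - b) ** 2))


def classification_report(pred_labels, true_labels, class_scores=None):
    """Confusion matrix (fixed order V, E, NV), accuracy (%), macro AUC."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label arrays differ in length")
    for lab in np.concatenate([pred, true]):
        if lab not in VIABILITY_CLASSES:
            raise ValueError(f"unknown label {lab!r}")
    k = len(VIABILITY_CLASSES)
    conf = np.zeros((k, k), dtype=int)
    for p, t in zip(pred, true):
        conf[VIABILITY_CLASSES.index(t), VIABILITY_CLASSES.index(p)] += 1
    acc = 100.0 * np.trace(conf) / conf.sum()
    auc = None
    if class_scores is not None:
        y = np.array([VIABILITY_CLASSES.index(t) for t in true])
        scores = np.asarray(class_scores, float)
        present = np.unique(y)
        if present.size == k:
            auc = float(roc_auc_score(y, scores, multi_class="ovr",
                                      average="macro"))
        elif present.size == 2:
            auc = float(roc_auc_score(y == present[1],
                                      scores[:, present[1]]))
    return dict(confusion=conf, accuracy=float(acc), auc=auc)


def paired_wilcoxon(values_a, values_b):
    """Two-sided Wilcoxon signed-rank p-value; zero differences dropped."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(a == b):
        return dict(p_value=1.0, flag="all_differences_zero")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return dict(p_value=float(res.pvalue), flag="")


def evaluate_cohort(predictions, references, spacing=(1.0, 1.0, 1.0),
                    mask_threshold=0.5):
    """Per-case and cohort report for lists of predictions vs truth.

    ``predictions``: list of (post_mask_prob, pred_class, class_probs,
    pred_volumes or None); ``references``: list of (true_mask, true_class,
    true_volumes or None).
    """
    rows = []
    pred_labels, true_labels, scores = [], [], []
    for (pm, pc, probs, pv), (tm, tc, tv) in zip(predictions, references):
        pmask = np.asarray(pm) > mask_threshold
        row = dict(dice=dice(pmask, tm), predicted=pc, truth=tc)
        try:
            row["hausdorff"] = hausdorff(pmask, tm, spacing)
            row["surface_mse"] = surface_mse(pmask, tm, spacing)
        except ValueError:
            row["hausdorff"] = np.nan
            row["surface_mse"] = np.nan
        if pv is not None and tv is not None:
            row["intensity_mse"] = intensity_mse(pv, tv)
        rows.append(row)
        pred_labels.append(pc)
        true_labels.append(tc)
        scores.append(probs)
    report = classification_report(pred_labels, true_labels,
                                   np.asarray(scores))
    report["per_case"] = rows
    report["mean_dice"] = float(np.mean([r["dice"] for r in rows]))
    return report
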