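"""ROI-level perfusion analysis of DCE-MRI sequences.

Two complementary descriptions of an enhancement time-course are computed:

* non-parametric: contrast arrival time T0, time-to-peak TTP, intensity
  difference dS = S_max - S0, peak enhancement ratio PER = dS/S0, the
  normalized intensity-time ratio nMITR = PER/TTP, and wash-in / wash-out
  slopes on S0-normalized intensity;
* parametric: the dual-input single-compartment model
  dC/dt = Ka*AIF(t) + Kp*PIF(t) - K2*C(t) fitted by bounded nonlinear
  least squares, reporting the transfer constants (1/s), the distribution
  volume DV = 100*(Ka+Kp)/K2 (%) and the arterial fraction
  ART = Ka/(Ka+Kp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_core import DceSequence
from .phantom import simulate_tissue_curve

#: number of baseline samples used for S0 and the arrival-noise estimate
N_BASELINE = 2
#: arrival threshold in baseline standard deviations
KAPPA = 3.0


@dataclass
class PerfusionResult:
    Ka: float = np.nan
    Kp: float = np.nan
    K2: float = np.nan
    DV: float = np.nan
    ART: float = np.nan
    T0: float = np.nan
    TTP: float = np.nan
    delta_S: float = np.nan
    PER: float = np.nan
    nMITR: float = np.nan
    wash_in: float = np.nan
    wash_out: float = np.nan
    fit_residual: float = np.nan
    flags: list = field(default_factory=list)

    def to_dict(self):
        d = {k: getattr(self, k) for k in
             ("Ka", "Kp", "K2", "DV", "ART", "T0", "TTP", "delta_S", "PER",
              "nMITR", "wash_in", "wash_out", "fit_residual")}
        d["flags"] = ";".join(self.flags)
        return d


def roi_curve(seq: DceSequence, roi: np.ndarray):
    """Mean intensity over the ROI per phase -> (curve, times)."""
    roi = np.asarray(roi).astype(bool)
    if roi.shape != seq.shape:
        raise ValueError(f"ROI shape {roi.shape} != volume shape {seq.shape}")
    if roi.sum() == 0:
        raise ValueError("ROI is empty")
    curve = seq.volumes[:, roi].mean(axis=1)
    return curve, np.asarray(seq.acquisition_times, float)


def nonparametric_metrics(curve, times, kappa: float = KAPPA):
    """Model-free enhancement descriptors of a single ROI curve.

    S0 is the first sample; the arrival time T0 is the first time the curve
    exceeds S0 + kappa * sigma_baseline, with sigma_baseline the standard
    deviation of the first two samples.  Wash-in runs from T0 to the peak,
    wash-out from the peak to the last sample; both are normalized by S0.
    """
    curve = np.asarray(curve, float)
    times = np.asarray(times, float)
    if curve.size < 3:
        raise ValueError("need at least 3 time points")
    flags = []
    S0 = curve[0]
    sigma = float(np.std(curve[:N_BASELINE]))
    i_peak = int(np.argmax(curve))
    TTP = float(times[i_peak])
    S_max = float(curve[i_peak])
    delta_S = max(S_max - S0, 0.0)
    if delta_S == 0.0:
        flags.append("flat_curve")
        return dict(T0=0.0, TTP=0.0, delta_S=0.0, PER=0.0, nMITR=0.0,
                    wash_in=0.0, wash_out=0.0, flags=flags)
    above = np.nonzero(curve > S0 + kappa * sigma)[0]
    if above.size == 0:
        flags.append("no_arrival")
        T0 = 0.0
    else:
        T0 = float(times[above[0]])
    PER = delta_S / S0 if S0 != 0 else np.inf
    nMITR = PER / TTP if TTP > 0 else 0.0
    if TTP > T0:
        wash_in = PER / (TTP - T0)
    else:
        wash_in = 0.0
        flags.append("instant_peak")
    if i_peak == curve.size - 1:
        wash_out = 0.0
        flags.append("no_washout")
    else:
        wash_out = ((S_max - curve[-1]) / S0) / (times[-1] - TTP) \
            if S0 != 0 else 0.0
    return dict(T0=T0, TTP=TTP, delta_S=delta_S, PER=PER, nMITR=nMITR,
                wash_in=wash_in, wash_out=wash_out, flags=flags)


def _init_grid(lo=1e-3, hi=3e-2, n=3):
    """Small geometric grid of initial guesses per rate constant."""
    vals = np.geomspace(lo, hi, n)
    return list(itertools.product(vals, vals, vals))


def fit_dual_input_model(curve, aif, pif, times, inits=None,
                         bounds=(0.0, 0.5)):
    """Fit (Ka, Kp, K2) to a concentration curve by least squares.

    Multi-start over a small geometric grid of initial guesses; the best
    solution by residual (ties broken toward lower K2) is returned together
    with DV, ART and the RMS residual.  If AIF and PIF are numerically
    indistinguishable Ka and Kp are individually unidentifiable; the result
    is flagged (their sum remains meaningful).
    """
    curve = np.asarray(curve, float)
    aif = np.asarray(aif, float)
    pif = np.asarray(pif, float)
    times = np.asarray(times, float)
    if not (curve.shape == aif.shape == pif.shape == times.shape):
        raise ValueError("curve, aif, pif and times must be co-sampled")
    if np.all(aif == 0) and np.all(pif == 0):
        raise ValueError("AIF and PIF are both identically zero")
    flags = []
    denom = np.linalg.norm(aif) * np.linalg.norm(pif)
    if denom > 0 and abs(float(aif @ pif)) / denom > 0.999:
        flags.append("art_unidentifiable")

    def residual(p):
        return simulate_tissue_curve(p[0], p[1], p[2], aif, pif, times) - curve

    best = None
    for x0 in (inits or _init_grid()):
        try:
            sol = least_squares(residual, x0, bounds=bounds, method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        key = (round(float(np.sqrt(np.mean(sol.fun ** 2))), 12),
               float(sol.x[2]))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        flags.append("fit_failed")
        return PerfusionResult(flags=flags)
    sol = best[1]
    if not sol.success:
        flags.append("non_convergence")
    Ka, Kp, K2 = (float(v) for v in sol.x)
    total = Ka + Kp
    ART = Ka / total if total > 0 else 0.0
    DV = 100.0 * total / K2 if K2 > 0 else np.inf
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return PerfusionResult(Ka=Ka, Kp=Kp, K2=K2, DV=DV, ART=ART,
                           fit_residual=rms, flags=flags)


def parameter_map(seq: DceSequence, roi, aif, pif, inits=None):
    """Voxelwise (Ka, Kp, K2) maps over an ROI — optional, slow path.

    Fits every voxel time-course inside ``roi`` independently (reduced
    2-point-per-decade multi-start); returns a dict of 3-D maps with NaN
    outside the ROI.  ROI-level :func:`analyze_roi` is the default
    analysis; this exists for small regions only.
    """
    roi = np.asarray(roi).astype(bool)
    if roi.sum() == 0:
        raise ValueError("ROI is empty")
    inits = inits or _init_grid(n=2)
    maps = {k: np.full(seq.shape, np.nan) for k in ("Ka", "Kp", "K2")}
    times = np.asarray(seq.acquisition_times, float)
    for idx in np.argwhere(roi):
        curve = seq.volumes[(slice(None),) + tuple(idx)]
        fit = fit_dual_input_model(curve - curve[0], aif, pif, times,
                                   inits=inits)
        for k in maps:
            maps[k][tuple(idx)] = getattr(fit, k)
    return maps


def analyze_roi(seq: DceSequence, roi, aif_roi=None, pif_roi=None,
                aif=None, pif=None, baseline=None,
                enhancement_gain=1.0) -> PerfusionResult:
    """Full perfusion analysis of one ROI.

    Input functions may be supplied directly (``aif``/``pif`` arrays) or as
    vessel ROIs from which curves are extracted; vessel curves are converted
    to concentration-like inputs by subtracting their first sample and
    dividing by ``enhancement_gain``.  The tissue curve is treated the same
    way before the kinetic fit, while the non-parametric metrics operate on
    raw intensities.
    """
    curve, times = roi_curve(seq, roi)
    np_metrics = nonparametric_metrics(curve, times)
    result = PerfusionResult(
        T0=np_metrics["T0"], TTP=np_metrics["TTP"],
        delta_S=np_metrics["delta_S"], PER=np_metrics["PER"],
        nMITR=np_metrics["nMITR"], wash_in=np_metrics["wash_in"],
        wash_out=np_metrics["wash_out"], flags=list(np_metrics["flags"]))
    if aif is None and aif_roi is not None:
        a, _ = roi_curve(seq, aif_roi)
        aif = (a - a[0]) / enhancement_gain
    if pif is None and pif_roi is not None:
        p, _ = roi_curve(seq, pif_roi)
        pif = (p - p[0]) / enhancement_gain
    if aif is not None and pif is not None:
        conc = (curve - (curve[0] if baseline is None else baseline)) \
            / enhancement_gain
        fit = fit_dual_input_model(conc, np.maximum(aif, 0.0),
                                   np.maximum(pif, 0.0), times)
        result.Ka, result.Kp, result.K2 = fit.Ka, fit.Kp, fit.K2
        result.DV, result.ART = fit.DV, fit.ART
        result.fit_residual = fit.fit_residual
        result.flags.extend(fit.flags)
    return result
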