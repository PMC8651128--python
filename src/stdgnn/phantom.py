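"""Synthetic DCE-MRI phantoms with known viability class and kinetics.

The generator emulates the structure of a pre/post chemoembolization study
pair: a liver-like background with smooth spatial texture, a spherical
tumor whose voxel time-courses follow the dual-input single-compartment
model with class-specific transfer constants, two small vessel regions
carrying the arterial and portal input functions, and measurement noise.
The post-treatment sequence applies a class-specific transformation —
shrinkage plus devascularization for non-viable tumors, a partial effect
for equivocal ones, growth with preserved enhancement for viable ones —
in the pre-treatment frame (sequences are treated as registered).

Default transfer constants sit in the 1e-3..1e-2 1/s range typical of
liver perfusion studies, and default acquisition times are the clinical
5-phase protocol (10, 60, 100, 145, 320 s post-injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_core import DceSequence, child_rng

DEFAULT_TIMES = (10.0, 60.0, 100.0, 145.0, 320.0)
DEFAULT_SHAPE = (48, 48, 16)
DEFAULT_SPACING = (1.9, 1.9, 2.5)

#: class -> (Ka, Kp, K2) in 1/s for tumor tissue.  Viable tumors show
#: arterial hyperenhancement with washout (early peak, fast clearance),
#: equivocal ones slow portal-dominant accumulation, and non-viable ones
#: are devascularized (weak transfer overall); the three enhancement
#: patterns differ in both timing and amplitude.
CLASS_KINETICS = {
    "V": (0.020, 0.003, 0.012),
    "E": (0.005, 0.009, 0.007),
    "NV": (0.0015, 0.003, 0.010),
}

#: liver parenchyma is portally dominant
PARENCHYMA_KINETICS = (0.004, 0.012, 0.010)

#: class -> (radius scale, enhancement scale) applied at follow-up
POST_EFFECT = {
    "V": (1.15, 1.0),
    "E": (0.85, 0.6),
    "NV": (0.60, 0.2),
}


@dataclass
class PhantomSpec:
    """Full description of one synthetic tumor study."""

    volume_shape: tuple = DEFAULT_SHAPE
    voxel_spacing: tuple = DEFAULT_SPACING
    times: tuple = DEFAULT_TIMES
    class_label: str = "V"
    tumor_center: Optional[tuple] = None   # voxels; default = volume center
    tumor_radius_mm: float = 12.0
    kinetic_params: Optional[tuple] = None  # (Ka, Kp, K2); default per class
    parenchyma_params: tuple = PARENCHYMA_KINETICS
    baseline_intensity: float = 100.0
    enhancement_gain: float = 120.0
    texture_amplitude: float = 0.04
    texture_sigma_vox: float = 3.0
    noise_sigma: float = 2.0
    rician: bool = False
    post_effect: dict = field(default_factory=lambda: dict(POST_EFFECT))
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_KINETICS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.kinetic_params is None:
            self.kinetic_params = CLASS_KINETICS[self.class_label]
        if any(k < 0 for k in self.kinetic_params):
            raise ValueError("kinetic params must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.tumor_center is None:
            self.tumor_center = tuple(s / 2.0 for s in self.volume_shape)
        r_vox = self.tumor_radius_mm / min(self.voxel_spacing)
        if r_vox < 2:
            raise ValueError("tumor radius must span at least 2 voxels")
        for scale, enh in self.post_effect.values():
            if not (0 <= enh <= 2):
                raise ValueError("enhancement scale must lie in [0, 2]")


# ---------------------------------------------------------------------------
# input functions and kinetic model

def _gamma_variate(t, t0, tp, alpha, amplitude):
    """Gamma-variate bolus, peak `amplitude` at t0 + tp, zero before t0."""
    tt = np.maximum(np.asarray(t, dtype=float) - t0, 0.0)
    x = tt / tp
    return amplitude * x ** alpha * np.exp(alpha * (1.0 - x))


def make_input_functions(times, seed=0, aif_amplitude=1.0, pif_amplitude=0.85,
                         aif_arrival=8.0, pif_arrival=16.0,
                         aif_tp=14.0, pif_tp=45.0, jitter=0.0):
    """Arterial and portal input functions sampled at `times` (seconds).

    The AIF is a sharp gamma-variate bolus; the PIF is a delayed, dispersed
    bolus of the same family (the portal signal is the splanchnic return of
    the arterial one).  With ``jitter`` > 0 the timing/amplitude parameters
    are perturbed reproducibly under ``seed``.
    """
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if jitter > 0:
        rng = child_rng(seed, "input-functions")
        f = lambda: float(rng.uniform(1 - jitter, 1 + jitter))
        aif_amplitude *= f(); pif_amplitude *= f()
        aif_tp *= f(); pif_tp *= f()
        aif_arrival *= f(); pif_arrival *= f()
    aif = _gamma_variate(times, aif_arrival, aif_tp, 3.0, aif_amplitude)
    pif = _gamma_variate(times, pif_arrival, pif_tp, 2.0, pif_amplitude)
    return aif, pif


def simulate_tissue_curve(Ka, Kp, K2, aif, pif, times):
    """Tissue concentration for dC/dt = Ka*AIF + Kp*PIF - K2*C, C(0) = 0.

    ``aif``/``pif`` are sampled on ``times``; between samples the combined
    input is linearly interpolated and each step is advanced with the exact
    exponential update for a linear-in-time forcing, so the solution on the
    sample grid is exact for the interpolated input.  Parameters may be
    scalars or arrays (broadcast against each other) — the result then has
    shape ``params_shape + (len(times),)``.
    """
    Ka, Kp, K2 = np.broadcast_arrays(
        np.asarray(Ka, float), np.asarray(Kp, float), np.asarray(K2, float))
    if np.any(Ka < 0) or np.any(Kp < 0) or np.any(K2 < 0):
        raise ValueError("kinetic parameters must be nonnegative")
    times = np.asarray(times, dtype=float)
    aif = np.asarray(aif, dtype=float)
    pif = np.asarray(pif, dtype=float)
    u = Ka[..., None] * aif + Kp[..., None] * pif   # (..., T)
    C = np.zeros(Ka.shape + (times.size,))
    k = K2[..., None]
    for i in range(1, times.size):
        h = times[i] - times[i - 1]
        u0 = u[..., i - 1:i]
        s = (u[..., i:i + 1] - u0) / h
        kh = k * h
        small = kh < 1e-12
        ekh = np.exp(-kh)
        with np.errstate(divide="ignore", invalid="ignore"):
            g1 = np.where(small, h, (1.0 - ekh) / np.where(small, 1.0, k))
            g2 = np.where(small, h * h / 2.0,
                          (h - g1) / np.where(small, 1.0, k))
        C[..., i:i + 1] = C[..., i - 1:i] * ekh + u0 * g1 + s * g2
    return np.maximum(C, 0.0)


# ---------------------------------------------------------------------------
# volume assembly

def _ellipsoid_mask(shape, spacing, center_vox, radius_mm):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    d2 = sum(((g - c) * sp) ** 2
             for g, c, sp in zip(grids, center_vox, spacing))
    return d2 <= radius_mm ** 2


def _fine_times(times, dt=1.0):
    fine = np.arange(0.0, float(times[-1]) + dt, dt)
    return np.union1d(fine, np.asarray(times, float))


def _sample_at(fine_t, fine_c, times):
    return np.interp(np.asarray(times, float), fine_t, fine_c)


def _tissue_curve_at(params, aif_f, pif_f, fine_t, times):
    c = simulate_tissue_curve(*params, aif_f, pif_f, fine_t)
    return _sample_at(fine_t, c, times)


def _build_sequence(spec, radius_mm, enh_scale, texture, tumor_curve,
                    par_curve, aif_curve, pif_curve, vessel_centers, rng,
                    phase_of):
    shape = spec.volume_shape
    mask = _ellipsoid_mask(shape, spec.voxel_spacing, spec.tumor_center,
                           radius_mm)
    aorta = _ellipsoid_mask(shape, spec.voxel_spacing, vessel_centers[0], 5.0)
    portal = _ellipsoid_mask(shape, spec.voxel_spacing, vessel_centers[1], 5.0)
    T = len(spec.times)
    vols = np.empty((T,) + shape)
    base = spec.baseline_intensity * (1.0 + texture)
    g = spec.enhancement_gain
    for t in range(T):
        v = base + g * par_curve[t] * (1.0 + texture)
        v[mask] = base[mask] + enh_scale * g * tumor_curve[t] * (1.0 + texture[mask])
        v[aorta] = spec.baseline_intensity + g * aif_curve[t]
        v[portal] = spec.baseline_intensity + g * pif_curve[t]
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, size=shape)
            if spec.rician:
                n2 = rng.normal(0.0, spec.noise_sigma, size=shape)
                v = np.sqrt((v + noise) ** 2 + n2 ** 2)
            else:
                v = v + noise
        vols[t] = v
    return DceSequence(vols, spec.times, spec.voxel_spacing,
                       tumor_mask=mask, label=spec.class_label,
                       phase_of=phase_of), aorta, portal


def generate_pair(spec: PhantomSpec):
    """One (pre, post, truth) study pair.

    The pre-treatment tumor follows the class kinetic curve; the follow-up
    applies the class post-treatment effect (radius and enhancement scale)
    in the same frame.  ``truth`` records everything a test needs: masks,
    class, kinetic parameters, input functions and noiseless ROI curves.
    """
    shape = spec.volume_shape
    r_vox = [spec.tumor_radius_mm / s for s in spec.voxel_spacing]
    for c, r, s in zip(spec.tumor_center, r_vox, shape):
        if c - r < 0 or c + r > s:
            raise ValueError("tumor exceeds volume bounds")
    rng = child_rng(spec.seed, "phantom")
    texture = gaussian_filter(
        rng.normal(0.0, 1.0, size=shape), spec.texture_sigma_vox)
    if texture.std() > 0:
        texture *= spec.texture_amplitude / texture.std()

    fine_t = _fine_times(spec.times)
    aif_f, pif_f = make_input_functions(fine_t, seed=spec.seed)
    tumor_curve = _tissue_curve_at(spec.kinetic_params, aif_f, pif_f,
                                   fine_t, spec.times)
    par_curve = _tissue_curve_at(spec.parenchyma_params, aif_f, pif_f,
                                 fine_t, spec.times)
    aif_curve = _sample_at(fine_t, aif_f, spec.times)
    pif_curve = _sample_at(fine_t, pif_f, spec.times)

    margin = 7.0 / min(spec.voxel_spacing)
    vessel_centers = ((margin, margin, shape[2] / 2.0),
                      (shape[0] - margin, margin, shape[2] / 2.0))

    pre, aorta, portal = _build_sequence(
        spec, spec.tumor_radius_mm, 1.0, texture, tumor_curve, par_curve,
        aif_curve, pif_curve, vessel_centers, rng, "pre")
    r_scale, e_scale = spec.post_effect[spec.class_label]
    post, _, _ = _build_sequence(
        spec, spec.tumor_radius_mm * r_scale, e_scale, texture, tumor_curve,
        par_curve, aif_curve, pif_curve, vessel_centers, rng, "post")
    truth = dict(
        class_label=spec.class_label,
        kinetic_params=tuple(spec.kinetic_params),
        parenchyma_params=tuple(spec.parenchyma_params),
        tumor_center=tuple(spec.tumor_center),
        radius_mm_pre=spec.tumor_radius_mm,
        radius_mm_post=spec.tumor_radius_mm * r_scale,
        enhancement_scale_post=e_scale,
        pre_mask=pre.tumor_mask,
        post_mask=post.tumor_mask,
        aif_mask=aorta,
        pif_mask=portal,
        times=np.asarray(spec.times, float),
        aif=aif_curve,
        pif=pif_curve,
        tumor_curve_pre=spec.baseline_intensity
        + spec.enhancement_gain * tumor_curve,
        tumor_curve_post=spec.baseline_intensity
        + e_scale * spec.enhancement_gain * tumor_curve,
        seed=spec.seed,
    )
    return pre, post, truth


def generate_cohort(n_per_class: int, base_spec: Optional[PhantomSpec] = None,
                    seed: int = 0, center_jitter_vox: float = 3.0,
                    radius_jitter_mm: float = 2.0, param_jitter: float = 0.15):
    """A balanced list of (pre, post, truth) pairs, ``n_per_class`` each.

    Per-sample jitter: tumor center uniform within +-`center_jitter_vox`
    voxels in-plane (half that through-plane), radius uniform within
    +-`radius_jitter_mm`, and each transfer constant scaled by a uniform
    factor in [1 - param_jitter, 1 + param_jitter].  Deterministic under
    ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec or PhantomSpec()
    rng = child_rng(seed, "cohort")
    cohort = []
    for label in ("V", "E", "NV"):
        for i in range(n_per_class):
            c0 = tuple(s / 2.0 for s in base.volume_shape)
            jc = (rng.uniform(-center_jitter_vox, center_jitter_vox),
                  rng.uniform(-center_jitter_vox, center_jitter_vox),
                  rng.uniform(-center_jitter_vox / 2, center_jitter_vox / 2))
            radius = base.tumor_radius_mm + rng.uniform(
                -radius_jitter_mm, radius_jitter_mm)
            params = tuple(
                k * rng.uniform(1 - param_jitter, 1 + param_jitter)
                for k in CLASS_KINETICS[label])
            spec = replace(
                base, class_label=label,
                tumor_center=tuple(a + b for a, b in zip(c0, jc)),
                tumor_radius_mm=radius, kinetic_params=params,
                seed=int(rng.integers(0, 2 ** 31)))
            cohort.append(generate_pair(spec))
    return cohort
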