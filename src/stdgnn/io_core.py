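"""Sequence and configuration I/O.

A DCE-MRI study is carried around as a :class:`DceSequence` — T timed 3-D
volumes plus a binary tumor mask on the same grid.  Volumes are stored as
NIfTI-1 (one file per phase), acquisition times and labels in a plain CSV
sidecar, and run configuration in YAML.  All internal indexing is 0-based
with axis order (x, y, z) fixed at read time.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stdgnn")

VIABILITY_CLASSES = ("V", "E", "NV")


class SequenceError(ValueError):
    """Structured error for geometrically inconsistent or invalid sequences."""


# ---------------------------------------------------------------------------
# seeding

def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-component seed from the run seed.

    Every stochastic element (phantom, frame sampling, weight init, random
    projections, ...) draws from its own child seed so that components stay
    reproducible independently of call order.
    """
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2 ** 31)


def child_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))


# ---------------------------------------------------------------------------
# domain types

@dataclass
class DceSequence:
    """T timed 3-D volumes + tumor mask (+ optional viability label)."""

    volumes: np.ndarray            # (T, X, Y, Z) float
    acquisition_times: np.ndarray  # (T,) seconds post-injection
    voxel_spacing: tuple           # (sx, sy, sz) in mm
    tumor_mask: Optional[np.ndarray] = None  # (X, Y, Z) binary
    label: Optional[str] = None    # one of V / E / NV
    phase_of: str = "pre"

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.volumes.ndim != 4 or self.volumes.shape[0] < 1:
            raise SequenceError(
                f"expected (T, X, Y, Z) volume stack, got {self.volumes.shape}")
        self.acquisition_times = np.asarray(self.acquisition_times, dtype=float)
        if self.acquisition_times.shape != (self.volumes.shape[0],):
            raise SequenceError("one acquisition time per volume required")
        if self.volumes.shape[0] > 1 and np.any(np.diff(self.acquisition_times) <= 0):
            raise SequenceError("acquisition times must be strictly increasing")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise SequenceError("voxel spacing must be 3 positive lengths (mm)")
        if self.tumor_mask is not None:
            self.tumor_mask = np.asarray(self.tumor_mask).astype(bool)
            if self.tumor_mask.shape != self.volumes.shape[1:]:
                raise SequenceError(
                    f"mask shape {self.tumor_mask.shape} != volume shape "
                    f"{self.volumes.shape[1:]}")
            if self.tumor_mask.sum() < 1:
                raise SequenceError("tumor mask has no foreground voxels")
        if self.label is not None and self.label not in VIABILITY_CLASSES:
            raise SequenceError(f"label must be one of {VIABILITY_CLASSES}")

    @property
    def n_phases(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[1:]


_CONFIG_DEFAULTS = dict(
    # loss weights and transport weights
    lambda_w=0.2,
    lambda_a=0.5,
    phi=30.0,
    xi=0.35,
    triplet_margin=0.3,
    n_projections=64,
    # graph construction
    k_w=5,
    k_b=3,
    # architecture
    K=3,              # temporal GCN layers
    M=2,              # structural GCN layers
    d_k=512,          # temporal feature dim
    d_m=256,          # structural feature dim
    d_global=64,      # global/domain branch feature dim
    T_sample=4,       # frames randomly sampled per sequence
    patch_grid=(3, 3, 2),
    patch_size=(5, 5, 5),
    backbone_channels=(8, 16, 16),
    backbone_kernel=(3, 3, 3),
    decoder_channels=(16, 16, 8),
    disc_channels=(4, 8, 16, 32),
    # optimizer
    lr=5e-5,
    weight_decay=5e-4,
    momentum=0.09,    # printed momentum-analog; see use_paper_momentum
    use_paper_momentum=False,
    epochs=100,
    batch_size=6,
    seed=0,
)


@dataclass
class RunConfig:
    """Hyperparameters of a training / inference run.

    Default loss weights are the published operating point
    (lambda_w = 0.2, lambda_a = 0.5, phi = 30, xi = 0.35); architecture
    sizes are configurable so the backbone can be shrunk to desk scale.
    """

    lambda_w: float = _CONFIG_DEFAULTS["lambda_w"]
    lambda_a: float = _CONFIG_DEFAULTS["lambda_a"]
    phi: float = _CONFIG_DEFAULTS["phi"]
    xi: float = _CONFIG_DEFAULTS["xi"]
    triplet_margin: float = _CONFIG_DEFAULTS["triplet_margin"]
    n_projections: int = _CONFIG_DEFAULTS["n_projections"]
    k_w: int = _CONFIG_DEFAULTS["k_w"]
    k_b: int = _CONFIG_DEFAULTS["k_b"]
    K: int = _CONFIG_DEFAULTS["K"]
    M: int = _CONFIG_DEFAULTS["M"]
    d_k: int = _CONFIG_DEFAULTS["d_k"]
    d_m: int = _CONFIG_DEFAULTS["d_m"]
    d_global: int = _CONFIG_DEFAULTS["d_global"]
    T_sample: int = _CONFIG_DEFAULTS["T_sample"]
    patch_grid: tuple = _CONFIG_DEFAULTS["patch_grid"]
    patch_size: tuple = _CONFIG_DEFAULTS["patch_size"]
    backbone_channels: tuple = _CONFIG_DEFAULTS["backbone_channels"]
    backbone_kernel: tuple = _CONFIG_DEFAULTS["backbone_kernel"]
    decoder_channels: tuple = _CONFIG_DEFAULTS["decoder_channels"]
    disc_channels: tuple = _CONFIG_DEFAULTS["disc_channels"]
    lr: float = _CONFIG_DEFAULTS["lr"]
    weight_decay: float = _CONFIG_DEFAULTS["weight_decay"]
    momentum: float = _CONFIG_DEFAULTS["momentum"]
    use_paper_momentum: bool = _CONFIG_DEFAULTS["use_paper_momentum"]
    epochs: int = _CONFIG_DEFAULTS["epochs"]
    batch_size: int = _CONFIG_DEFAULTS["batch_size"]
    seed: int = _CONFIG_DEFAULTS["seed"]

    def __post_init__(self):
        for name in ("lambda_w", "lambda_a", "phi", "xi", "triplet_margin",
                     "lr", "weight_decay", "momentum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("K", "M", "d_k", "d_m", "d_global", "T_sample",
                     "n_projections", "k_w", "k_b", "epochs", "batch_size"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("patch_grid", "patch_size", "backbone_channels",
                     "decoder_channels", "disc_channels", "backbone_kernel"):
            val = tuple(int(v) for v in getattr(self, name))
            if any(v < 1 for v in val):
                raise ValueError(f"{name} entries must be positive")
            setattr(self, name, val)

    @property
    def P(self) -> int:
        """Number of patches per feature map."""
        return int(np.prod(self.patch_grid))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def desk_config(**overrides) -> RunConfig:
    """Desk-scale profile: small backbone and feature dims for CPU training
    on 48x48x16 phantoms.  The learning rate is raised accordingly (the
    published schedule targets a far larger model and image grid)."""
    desk = dict(d_k=48, d_m=32, d_global=32, lr=1e-3, epochs=100,
                batch_size=6, backbone_channels=(8, 12, 12),
                decoder_channels=(12, 12, 8))
    desk.update(overrides)
    return RunConfig(**desk)


def load_config(path) -> RunConfig:
    """Read a YAML config; missing fields fall back to published defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in cfg.to_dict().items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


# ---------------------------------------------------------------------------
# sequence I/O

def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_sequence(paths: Sequence, times: Sequence[float],
                  mask_path=None, label: Optional[str] = None,
                  phase_of: str = "pre") -> DceSequence:
    """Load one NIfTI volume per phase plus an optional mask.

    Geometry (shape and header spacing) must agree across all files; a
    mismatch raises :class:`SequenceError` naming the offending file.
    """
    if len(paths) == 0:
        raise SequenceError("no volume files given")
    if len(paths) != len(times):
        raise SequenceError("need one acquisition time per volume file")
    vols, ref_shape, ref_zoom = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zoom = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
        if ref_shape is None:
            ref_shape, ref_zoom = data.shape, zoom
        elif data.shape != ref_shape:
            raise SequenceError(
                f"{p}: shape {data.shape} != first volume {ref_shape}")
        elif zoom != ref_zoom:
            raise SequenceError(
                f"{p}: spacing {zoom} != first volume {ref_zoom}")
        vols.append(data)
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mdata = np.asarray(mimg.dataobj)
        if mdata.shape != ref_shape:
            raise SequenceError(
                f"{mask_path}: mask shape {mdata.shape} != volume {ref_shape}")
        mask = mdata > 0.5
    return DceSequence(np.stack(vols), np.asarray(times, dtype=float),
                       ref_zoom, tumor_mask=mask, label=label,
                       phase_of=phase_of)


def write_sequence(seq: DceSequence, out_dir, prefix: str = "phase") -> list:
    """Write one NIfTI per phase, the mask, and a CSV metadata sidecar.

    Returns the list of files written.  ``read_sequence`` on the returned
    phase files reproduces the voxel arrays bit-exactly (float64 on disk).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(seq.voxel_spacing)
    written = []
    rows = []
    for i in range(seq.n_phases):
        f = out_dir / f"{prefix}_{i:02d}.nii.gz"
        img = nib.Nifti1Image(seq.volumes[i], aff)
        img.header.set_zooms(seq.voxel_spacing)
        nib.save(img, str(f))
        written.append(f)
        rows.append(dict(phase_index=i, time_s=float(seq.acquisition_times[i]),
                         label=seq.label or "", role=seq.phase_of))
    if seq.tumor_mask is not None:
        f = out_dir / f"{prefix}_mask.nii.gz"
        img = nib.Nifti1Image(seq.tumor_mask.astype(np.uint8), aff)
        img.header.set_zooms(seq.voxel_spacing)
        nib.save(img, str(f))
        written.append(f)
    meta = out_dir / f"{prefix}_meta.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    written.append(meta)
    return written


def read_written_sequence(out_dir, prefix: str = "phase") -> DceSequence:
    """Read back a sequence written by :func:`write_sequence`."""
    out_dir = Path(out_dir)
    meta = pd.read_csv(out_dir / f"{prefix}_meta.csv")
    paths = [out_dir / f"{prefix}_{i:02d}.nii.gz"
             for i in meta["phase_index"]]
    mask_path = out_dir / f"{prefix}_mask.nii.gz"
    label = meta["label"].iloc[0]
    label = None if (isinstance(label, float) or label == "") else str(label)
    return read_sequence(
        paths, meta["time_s"].tolist(),
        mask_path=mask_path if mask_path.exists() else None,
        label=label, phase_of=str(meta["role"].iloc[0]))
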