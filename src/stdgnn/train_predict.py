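"""Training loop, frame sampling, augmentation, checkpointing, inference.

Training alternates one generator/branches update with one discriminator
update per batch.  Batches are stratified so every viability class is
present (the triplet and transport terms need at least two classes).  All
randomness derives from per-epoch child seeds of the run seed, which makes
fixed-seed runs bit-identical and lets a resumed checkpoint reproduce the
remaining loss trajectory exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import autodiff as ad
from . import losses as L
from .autodiff import Adam, Tensor
from .graphs import PatchFeatureSet, build_between_graph, build_within_graph
from .io_core import DceSequence, RunConfig, VIABILITY_CLASSES, child_rng
from .network import (STDGNN, Discriminator, denormalize_intensity,
                      normalize_intensity)

LABEL_TO_INT = {c: i for i, c in enumerate(VIABILITY_CLASSES)}


# ---------------------------------------------------------------------------
# sampling & augmentation

def sample_frames(seq: DceSequence, T_sample: int, seed: int = 0,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Indices of T_sample frames drawn without replacement, time-ordered."""
    T = seq.n_phases
    if T_sample > T:
        raise ValueError(f"T_sample={T_sample} exceeds sequence length {T}")
    if T_sample == T:
        return np.arange(T)
    rng = rng if rng is not None else child_rng(seed, "frame-sampling")
    return np.sort(rng.choice(T, size=T_sample, replace=False))


def even_frames(T: int, T_sample: int) -> np.ndarray:
    """Deterministic evenly spaced frame choice for inference."""
    return np.unique(np.round(np.linspace(0, T - 1, T_sample)).astype(int))


def _displacement_field(shape, seed, max_disp=3.0, smooth=6.0):
    rng = child_rng(seed, "warp")
    field_ = [gaussian_filter(rng.normal(size=shape), smooth)
              for _ in range(3)]
    mag = np.sqrt(sum(f ** 2 for f in field_))
    peak = mag.max()
    if peak > 0:
        amp = rng.uniform(0.3, 1.0) * max_disp / peak
        field_ = [f * amp for f in field_]
    return field_


def augment(volume: np.ndarray, seed: int, max_disp: float = 3.0,
            is_mask: bool = False, field_=None) -> np.ndarray:
    """Non-linear warp: smooth random displacement (<= max_disp voxels),
    linear interpolation for intensities, nearest-neighbour for masks.

    The field is a function of ``seed`` alone, so every volume of one study
    warped with the same seed stays spatially consistent.
    """
    if field_ is None:
        field_ = _displacement_field(volume.shape, seed, max_disp)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in volume.shape],
                         indexing="ij")
    warped_coords = [c + f for c, f in zip(coords, field_)]
    order = 0 if is_mask else 1
    vol = np.asarray(volume)
    if vol.dtype.kind != "f":
        vol = vol.astype(float)
    out = map_coordinates(vol, warped_coords, order=order, mode="nearest")
    return out > 0.5 if is_mask else out


def _augment_study(pre_vols, pre_mask, post_vols, post_mask, seed):
    field_ = _displacement_field(pre_vols.shape[1:], seed)
    pre = np.stack([augment(v, seed, field_=field_) for v in pre_vols])
    post = np.stack([augment(v, seed, field_=field_) for v in post_vols])
    pm = augment(pre_mask, seed, is_mask=True, field_=field_)
    qm = augment(post_mask, seed, is_mask=True, field_=field_)
    if pm.sum() == 0:
        return pre_vols, pre_mask, post_vols, post_mask  # degenerate warp
    return pre, pm, post, qm


# ---------------------------------------------------------------------------
# train state

@dataclass
class TrainState:
    model: STDGNN
    disc: Discriminator
    opt_g: Adam
    opt_d: Adam
    cfg: RunConfig
    epoch: int = 0
    history: list = field(default_factory=list)
    best_dice: float = -1.0
    best_weights: Optional[dict] = None

    def save(self, path):
        path = Path(path)
        arrays = {}
        for prefix, mod in (("model", self.model), ("disc", self.disc)):
            for k, v in mod.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        for prefix, opt in (("optg", self.opt_g), ("optd", self.opt_d)):
            for k, v in opt.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        if self.best_weights is not None:
            for k, v in self.best_weights.items():
                arrays[f"best/{k}"] = v
        import hashlib
        cfg_dict = self.cfg.to_dict()
        cfg_hash = hashlib.sha1(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:12]
        meta = dict(epoch=self.epoch, history=self.history,
                    best_dice=self.best_dice, cfg=cfg_dict,
                    cfg_hash=cfg_hash,
                    n_phases_out=self.model.n_phases_out)
        np.savez(str(path), **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = meta["cfg"]
        for k in ("patch_grid", "patch_size", "backbone_channels",
                  "backbone_kernel", "decoder_channels", "disc_channels"):
            cfgd[k] = tuple(cfgd[k])
        cfg = RunConfig(**cfgd)
        npz = np.load(str(path) if str(path).endswith(".npz")
                      else str(path) + ".npz")
        state = _init_state(cfg, meta["n_phases_out"])
        groups = {"model": {}, "disc": {}, "optg": {}, "optd": {},
                  "best": {}}
        for key in npz.files:
            prefix, name = key.split("/", 1)
            groups[prefix][name] = npz[key]
        state.model.load_state_dict(groups["model"])
        state.disc.load_state_dict(groups["disc"])
        state.opt_g.load_state_dict(groups["optg"])
        state.opt_d.load_state_dict(groups["optd"])
        state.epoch = int(meta["epoch"])
        state.history = meta["history"]
        state.best_dice = float(meta["best_dice"])
        if groups["best"]:
            state.best_weights = groups["best"]
        return state


def _init_state(cfg: RunConfig, n_phases_out: int) -> TrainState:
    model = STDGNN(cfg, n_phases_out=n_phases_out)
    rng = child_rng(cfg.seed, "disc-init")
    disc = Discriminator(cfg, in_channels=n_phases_out + 1, rng=rng)
    beta1 = cfg.momentum if cfg.use_paper_momentum else 0.9
    opt_g = Adam(model.parameters(), lr=cfg.lr, beta1=beta1,
                 weight_decay=cfg.weight_decay)
    # slower critic keeps the adversarial game from saturating early
    opt_d = Adam(disc.parameters(), lr=0.5 * cfg.lr, beta1=beta1,
                 weight_decay=cfg.weight_decay)
    return TrainState(model, disc, opt_g, opt_d, cfg)


# ---------------------------------------------------------------------------
# batch assembly

def _study_arrays(pre: DceSequence, post: DceSequence):
    return (pre.volumes, pre.tumor_mask.astype(float),
            post.volumes, post.tumor_mask.astype(float))


def _halve(a):
    """2x block average over the last three axes (targets for the
    half-resolution generator grid)."""
    s = a.shape
    v = a.reshape(s[:-3] + (s[-3] // 2, 2, s[-2] // 2, 2, s[-1] // 2, 2))
    return v.mean(axis=(-5, -3, -1))


def _soft_graphs(f_embed, labels, cfg):
    """Soft-weighted discriminant graphs over batch embeddings.

    The binary k-NN edge structure is fixed from detached features; edge
    weights are differentiable heat-kernel values, so the cosine
    weight-divergence term has nonzero gradients.
    """
    X = f_embed.data
    n = X.shape[0]
    feats = PatchFeatureSet(X, np.zeros(n, int), np.arange(n),
                            class_label=np.asarray(labels))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Ww = build_within_graph(feats, k_w=min(cfg.k_w, n - 1))
        Wb = build_between_graph(feats, k_b=min(cfg.k_b, n - 1))
    sq = (f_embed * f_embed).sum(axis=1)
    D2 = sq.reshape(n, 1) + sq.reshape(1, n) \
        - 2.0 * ad.matmul(f_embed, f_embed.transpose())
    d2 = np.maximum(D2.data, 0)
    nz = d2[d2 > 0]
    sigma2 = float(np.median(nz)) if nz.size else 1.0
    heat = ad.exp(D2 * (-1.0 / max(sigma2, 1e-12)))
    return heat * Tensor(Wb), heat * Tensor(Ww)


def _stratified_split(labels, val_fraction, seed):
    rng = child_rng(seed, "split")
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in VIABILITY_CLASSES:
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(val_fraction * idx.size))) \
            if idx.size > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def _stratified_batches(labels, batch_size, rng):
    """Shuffled batches that keep all present classes represented."""
    labels = np.asarray(labels)
    per_class = [np.nonzero(labels == c)[0] for c in VIABILITY_CLASSES]
    per_class = [idx[rng.permutation(idx.size)] for idx in per_class
                 if idx.size]
    interleaved = []
    maxlen = max(len(x) for x in per_class)
    for i in range(maxlen):
        for idx in per_class:
            interleaved.append(idx[i % len(idx)] if i < len(idx) else None)
    interleaved = [i for i in interleaved if i is not None]
    return [np.asarray(interleaved[i:i + batch_size])
            for i in range(0, len(interleaved), batch_size)]


# ---------------------------------------------------------------------------
# training

def train(cohort, cfg: RunConfig, out_dir=None, val_fraction=0.2,
          augment_prob=0.5, state: Optional[TrainState] = None,
          log_every=0, val_every=5, adv_warmup_epochs=15) -> TrainState:
    """Train the STDGNN on a cohort of (pre, post, truth) studies.

    Alternates one generator/branches step and one discriminator step per
    batch; logs a full LossReport per step; retains the best weights by
    validation Dice.  The generator's adversarial gradient is enabled
    after ``adv_warmup_epochs`` (mask/class supervision first — standard
    adversarial warm-up; the discriminator trains and E_adv is reported
    from the start).  Raises on NaN loss with a diagnostic dump.
    """
    labels = [pre.label for pre, _, _ in cohort]
    if len(set(labels)) < 3:
        raise ValueError("cohort must contain all three viability classes")
    n_phases = cohort[0][1].n_phases
    import hashlib
    import json as _json
    from .io_core import logger
    cfg_hash = hashlib.sha1(
        _json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:8]
    logger.info("run %s seed=%d cohort=%d epochs=%d",
                cfg_hash, cfg.seed, len(cohort), cfg.epochs)
    if state is None:
        state = _init_state(cfg, n_phases)
    model, disc = state.model, state.disc
    train_idx, val_idx = _stratified_split(labels, val_fraction, cfg.seed)
    t_labels = np.asarray(labels)
    # cache single-precision study arrays once; epochs only index them
    studies = [tuple(np.asarray(a, dtype=np.float32) for a in
                     _study_arrays(pre, post)) for pre, post, _ in cohort]

    for epoch in range(state.epoch, cfg.epochs):
        rng = child_rng(cfg.seed, f"epoch-{epoch}")
        model.train()
        disc.train()
        batches = _stratified_batches(t_labels[train_idx], cfg.batch_size,
                                      rng)
        for batch_local in batches:
            batch = train_idx[batch_local]
            if np.unique(t_labels[batch]).size < 2:
                continue
            vols, masks, tgt_masks, tgt_vols, y = [], [], [], [], []
            for idx in batch:
                pre = cohort[idx][0]
                pv, pm, qv, qm = studies[idx]
                if rng.random() < augment_prob:
                    pv, pm, qv, qm = _augment_study(
                        pv, pm, qv, qm, int(rng.integers(2 ** 31)))
                frames = sample_frames(pre, cfg.T_sample, rng=rng)
                vols.append(pv[frames])
                masks.append(pm)
                tgt_masks.append(qm)
                tgt_vols.append(qv)
                y.append(LABEL_TO_INT[pre.label])
            vols = np.stack(vols)
            masks = np.stack(masks) > 0.5
            # generator targets live on the half-resolution output grid
            tgt_masks = _halve(np.stack(tgt_masks).astype(np.float32))
            tgt_vols = _halve(np.stack(tgt_vols).astype(np.float32))
            y = np.asarray(y)
            y_str = t_labels[batch]

            # ---- generator / branches step
            out = model.forward(vols, masks)
            onehot_mask = np.stack([1.0 - tgt_masks, tgt_masks],
                                   axis=1).astype(np.float32)
            # balance the ~2% tumor foreground against the background
            fg = tgt_masks.reshape(len(batch), -1).mean(axis=1)
            fg = np.clip(fg, 1e-4, None)[:, None, None, None]
            vw = np.where(tgt_masks > 0.5, 0.5 / fg, 0.5 / (1.0 - fg))
            e_tumor = L.tumor_loss(out["mask_probs"], onehot_mask,
                                   voxel_weights=vw.astype(np.float32))
            Wb_soft, Ww_soft = _soft_graphs(out["f_global"], y_str, cfg)
            e_weight = L.weight_divergence(Wb_soft, Ww_soft)
            real_stack = np.concatenate(
                [normalize_intensity(tgt_vols), tgt_masks[:, None]], axis=1)
            fake_stack = ad.concat(
                [out["pred_intensity"], _mask_channel(out["mask_probs"])],
                axis=1)
            with ad.no_grad():
                d_real = disc(Tensor(real_stack))
            d_fake = disc(fake_stack)
            # reported adversarial objective: the printed discriminator
            # cross-entropy with the optimal-transport weight
            e_adv, cost = L.adversarial_loss(
                Tensor(d_real.data), Tensor(d_fake.data),
                features=out["class_probs"].data, labels=y,
                phi=cfg.phi, xi=cfg.xi, n_projections=cfg.n_projections,
                seed=int(rng.integers(2 ** 31)))
            # generator plays the opposite direction (non-saturating form)
            # after the warm-up; the transport weight belongs to the
            # critic's objective and is not amplified onto the generator
            if epoch >= adv_warmup_epochs:
                e_adv_gen = -ad.log(d_fake, eps=1e-12).mean()
            else:
                e_adv_gen = Tensor(0.0)
            e_trip_t = L.triplet_loss(out["f_t"], y, cfg.triplet_margin)
            e_trip_s = L.triplet_loss(out["f_s"], y, cfg.triplet_margin)
            e_softmax = L.cross_entropy(out["class_logits"], y)
            total_grad = e_tumor + cfg.lambda_w * e_weight \
                + cfg.lambda_a * e_adv_gen + e_trip_t + e_trip_s + e_softmax
            _, report = L.overall_loss(
                e_tumor, e_weight, e_adv, e_trip_t, e_trip_s, e_softmax,
                lambda_w=cfg.lambda_w, lambda_a=cfg.lambda_a,
                transport=cost)
            if not np.isfinite(report.E_overall) \
                    or not np.isfinite(float(total_grad.data)):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: {report.to_dict()}")
            state.opt_g.zero_grad()
            state.opt_d.zero_grad()
            total_grad.backward()
            ad.clip_grad_norm(state.opt_g.params, 50.0)
            state.opt_g.step()

            # ---- discriminator step (1:1 alternation); the critic
            # minimizes the printed transport-weighted objective
            d_real2 = disc(Tensor(real_stack))
            d_fake2 = disc(Tensor(fake_stack.data))
            d_loss = -(ad.log(d_real2, eps=1e-12).mean()) \
                - (cfg.phi * cost + cfg.xi) \
                * (ad.log(1.0 - d_fake2, eps=1e-12).mean())
            state.opt_d.zero_grad()
            d_loss.backward()
            state.opt_d.step()

            rd = report.to_dict()
            rd["epoch"] = epoch
            rd["d_loss"] = float(d_loss.data)
            state.history.append(rd)

        # ---- validation (every val_every epochs, and on the final epoch)
        if val_idx.size and ((epoch + 1) % val_every == 0
                             or epoch + 1 == cfg.epochs):
            dice, acc = _validate(state, cohort, val_idx)
            state.history[-1]["val_dice"] = dice
            state.history[-1]["val_acc"] = acc
            if dice >= state.best_dice:
                state.best_dice = dice
                state.best_weights = model.state_dict()
        state.epoch = epoch + 1
        if log_every and (epoch + 1) % log_every == 0:
            last = state.history[-1]
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"E_overall={last['E_overall']:.3f} "
                  f"val_dice={last.get('val_dice', float('nan')):.3f} "
                  f"val_acc={last.get('val_acc', float('nan')):.3f}",
                  flush=True)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            state.save(Path(out_dir) / "checkpoint.npz")
    return state


def _mask_channel(mask_probs):
    """(B, 2, ...) softmax -> (B, 1, ...) foreground channel, differentiable."""
    from .network import take_cols5
    return take_cols5(mask_probs, 1, 2)


def _validate(state: TrainState, cohort, idx):
    dices, hits = [], []
    for i in idx:
        pre, post, _ = cohort[i]
        pred = predict(pre, state)
        pm = pred.post_mask > 0.5
        tm = post.tumor_mask
        denom = pm.sum() + tm.sum()
        dices.append(2.0 * np.logical_and(pm, tm).sum() / denom
                     if denom else 1.0)
        hits.append(pred.viability_class == pre.label)
    state.model.train()
    state.disc.train()
    return float(np.mean(dices)), float(np.mean(hits))


# ---------------------------------------------------------------------------
# inference

def predict(seq: DceSequence, state: TrainState, use_best=False):
    """End-to-end inference on a pre-treatment sequence."""
    model = state.model
    if use_best and state.best_weights is not None:
        model.load_state_dict(state.best_weights)
    frames = even_frames(seq.n_phases, state.cfg.T_sample)
    if frames.size != state.cfg.T_sample:
        raise ValueError("sequence too short for configured T_sample")
    vols = seq.volumes[frames][None]
    masks = seq.tumor_mask[None]
    return model.predict_sequence(vols, masks)[0]
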