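"""Stage orchestration: pre-training, semi-supervised learning, self-training.

The training procedure tolerates two annotation defects by construction:

* *scarcity* — only a few volumes carry expert labels.  Semi-supervised
  learning predicts the unlabeled pool with the pre-trained slice network
  and merges confidently predicted slices (max probability strictly above
  TH-S = 0.9) into the training pool as pseudo-labels, then retrains.
* *noise* — slice labels are inherited from volume annotations, so a mixed
  volume mislabels some of its slices.  Self-training keeps a sample only
  if the model's prediction agrees with its current label OR is confident;
  confident disagreements are relabeled, the rest are removed, and the
  model is retrained.  The same mechanism runs at the volume level.

Volume labels for the unlabeled pool are initialized from predicted slice
labels via the rule-based aggregation, then refined by volume self-training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import aggregation
from .data_model import (
    DatasetSplit,
    ProbTriple,
    Provenance,
    QualityLabel,
    SliceRecord,
    VolumeRecord,
)
from .loss import LossParams, class_weights, focal_data_term, focal_grad_logits, l2_term
from .networks import NetSpec, SQANet, VQANet
from .preprocessing import augment

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "RMSprop",
    "pretrain_sqa",
    "ssl_round",
    "semi_supervised_fit",
    "slice_self_train_round",
    "volume_self_train_round",
    "fit_vqa",
    "fit_full_pipeline",
    "predict_hierarchy",
]


@dataclass
class TrainConfig:
    """Thresholds, loss, optimizer and iteration settings for all stages.

    Defaults follow the full-scale training recipe (confidence thresholds
    0.9, two rounds of each refinement, RMSprop at 1e-5 with decay 5e-8);
    desk-scale runs typically raise the learning rate and shrink epochs.
    """

    th_s: float = 0.9
    th_v: float = 0.9
    ssl_iters: int = 2
    st_iters: int = 2
    optimizer: str = "rmsprop"
    lr: float = 1e-5
    decay: float = 5e-8
    epochs: int = 5
    batch_size: int = 32
    kappa: float = 2.0
    lam: float = 0.01
    use_augmentation: bool = True
    pretrain_epochs: Optional[int] = None  # defaults to ``epochs``; base
    # training must reach the high-confidence regime before refinement
    vqa_epochs: Optional[int] = None  # defaults to ``epochs``; the volume
    # network sees few, cheap batches per epoch and tolerates many more
    refine_lr_scale: float = 1.0  # self-training fine-tunes a converged
    # model; a reduced step keeps noisy relabeled minorities from dominating
    ema_rho: float = 0.0  # Polyak weight averaging per step; stage-end
    # weights are the EMA when > 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.th_s < 1.0 and 0.0 < self.th_v < 1.0):
            raise ValueError("confidence thresholds must lie in (0, 1)")
        if self.ssl_iters < 0 or self.st_iters < 0:
            raise ValueError("iteration counts must be >= 0")

    @classmethod
    def toy(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale settings: a few hundred samples need a larger step
        size and only a few epochs; thresholds and round counts unchanged."""
        kwargs = {"lr": 1e-3, "decay": 2e-2, "epochs": 2, "pretrain_epochs": 16,
                  "vqa_epochs": 30, "refine_lr_scale": 0.1, "kappa": 1.0,
                  "use_augmentation": False, "ema_rho": 0.95, "seed": seed}
        kwargs.update(overrides)
        return cls(**kwargs)


class RMSprop:
    """RMSprop with the classic 1/(1 + decay * t) learning-rate schedule.

    The L2 penalty is applied as decoupled weight decay: feeding it through
    the adaptive per-coordinate normalization would turn it into a constant
    lr-sized shrinkage of every small-gradient weight, which wrecks trained
    models at desk-scale learning rates.
    """

    def __init__(self, lr: float, decay: float = 0.0, rho: float = 0.9, eps: float = 1e-7,
                 ema_rho: float = 0.0):
        self.lr, self.decay, self.rho, self.eps = lr, decay, rho, eps
        self.ema_rho = ema_rho
        self.t = 0
        self._cache: dict[int, dict[str, np.ndarray]] = {}
        self._ema: dict[int, dict[str, np.ndarray]] = {}

    def step(self, model, l2_coef: float = 0.0, l2_targets: set | None = None) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        for layer in model.walk():
            sq = self._cache.setdefault(id(layer), {})
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                s = sq.setdefault(name, np.zeros_like(p))
                s *= self.rho
                s += (1.0 - self.rho) * g * g
                p -= lr_t * g / (np.sqrt(s) + self.eps)
                if l2_coef and l2_targets and (id(layer), name) in l2_targets:
                    p -= lr_t * l2_coef * p
                if self.ema_rho:
                    ema = self._ema.setdefault(id(layer), {})
                    e = ema.setdefault(name, p.copy())
                    e *= self.ema_rho
                    e += (1.0 - self.ema_rho) * p

    def load_ema(self, model) -> None:
        """Overwrite model parameters with their Polyak (EMA) averages.

        Averaging over the recent weight trajectory collapses the epoch-scale
        oscillation that noisy-label class rebalancing induces, so stage-end
        snapshots are representative rather than a lottery draw.
        """
        if not self.ema_rho:
            return
        for layer in model.walk():
            ema = self._ema.get(id(layer))
            if not ema:
                continue
            for name in layer.params:
                if name in ema:
                    layer.params[name][...] = ema[name]


def _conv_weight_params(model):
    """(layer, name) of every convolution weight matrix (L2 targets)."""
    return [
        (layer, name)
        for layer in model.walk()
        for name in layer.params
        if name.startswith("W")
    ]


def _loss_params(labels: Sequence[int], cfg: TrainConfig, strict: bool = True) -> LossParams:
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=3)
    if np.any(counts == 0):
        if strict:
            missing = [str(QualityLabel(i)) for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty class in training data: {', '.join(missing)}")
        # retraining sets may lose a class to cleansing; its weight is unused
        counts = np.maximum(counts, 1)
    return LossParams(kappa=cfg.kappa, lam=cfg.lam, alpha=tuple(class_weights(counts)))


def _fit(
    model,
    inputs: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    opt: RMSprop,
    rng: np.random.Generator,
    augment_fn=None,
    strict_classes: bool = True,
) -> list[dict]:
    """Generic mini-batch fit of either network with the balanced focal loss."""
    params = _loss_params(labels, cfg, strict=strict_classes)
    l2_targets = _conv_weight_params(model)
    n_w = len(l2_targets)
    history = []
    n = len(inputs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, correct, loss_sum = 0, 0, 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = inputs[idx]
            yb = labels[idx]
            if augment_fn is not None:
                xb = np.stack([augment_fn(x, rng) for x in xb])
            out = model.forward(xb, training=True)
            probs = out[0] if isinstance(out, tuple) else out
            model.zero_grads()
            dlogits = focal_grad_logits(probs, yb, params).astype(np.float32)
            model.backward_from_logits(dlogits)
            opt.step(model, l2_coef=params.lam / n_w if n_w else 0.0,
                     l2_targets={(id(l), m) for l, m in l2_targets})
            loss_sum += focal_data_term(probs, yb, params) * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
            total += len(idx)
        reg = l2_term((l.params[m] for l, m in l2_targets), params.lam)
        history.append(
            {"epoch": epoch, "loss": loss_sum / total + reg, "acc": correct / total}
        )
    opt.load_ema(model)
    return history


def _slice_arrays(slices: Sequence[SliceRecord]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([s.image for s in slices])
    ys = np.array([int(s.label) for s in slices])
    return xs, ys


def pretrain_sqa(
    labeled_slices: Sequence[SliceRecord],
    cfg: TrainConfig,
    spec: Optional[NetSpec] = None,
    model: Optional[SQANet] = None,
    opt: Optional[RMSprop] = None,
) -> tuple[SQANet, list[dict]]:
    """Supervised fit of the slice network on (weakly) labeled slices."""
    pool = [s for s in labeled_slices if s.trainable]
    if not pool:
        raise ValueError("no trainable labeled slices")
    if model is None:
        model = SQANet(spec or NetSpec.toy(seed=cfg.seed))
    opt = opt or RMSprop(cfg.lr, cfg.decay, ema_rho=cfg.ema_rho)
    rng = np.random.default_rng(cfg.seed)
    xs, ys = _slice_arrays(pool)
    aug = augment if cfg.use_augmentation else None
    pcfg = replace(cfg, epochs=cfg.pretrain_epochs or cfg.epochs)
    history = _fit(model, xs, ys, pcfg, opt, rng, augment_fn=aug)
    model.optimizer = opt  # later stages continue from the fitted state
    logger.info("pretrain: %d slices, final acc %.3f", len(pool), history[-1]["acc"])
    return model, history


def ssl_round(
    model: SQANet,
    labeled: list[SliceRecord],
    unlabeled: Sequence[SliceRecord],
    th_s: float,
) -> tuple[list[SliceRecord], dict]:
    """Pseudo-label the unlabeled pool; merge confident slices.

    A slice joins the labeled pool when its maximal predicted probability is
    strictly greater than ``th_s``; its label becomes the argmax and its
    provenance ``pseudo``.  Returns the augmented pool and selection counts.
    """
    merged = list(labeled)
    selected = skipped = 0
    if unlabeled:
        probs = model.predict_proba(np.stack([s.image for s in unlabeled]))
        for s, p in zip(unlabeled, probs):
            pt = ProbTriple(p)
            s.last_pred = pt
            if pt.max_prob > th_s:
                s.label = pt.argmax
                s.provenance = Provenance.PSEUDO
                merged.append(s)
                selected += 1
            else:
                skipped += 1
    return merged, {"selected": selected, "skipped": skipped}


def semi_supervised_fit(
    labeled: Sequence[SliceRecord],
    unlabeled: Sequence[SliceRecord],
    cfg: TrainConfig,
    spec: Optional[NetSpec] = None,
) -> tuple[SQANet, dict]:
    """Pre-train, then alternate pseudo-labeling and retraining.

    Pseudo-labels are refreshed each round from the current model; with an
    empty unlabeled pool this degenerates to plain supervised pre-training.
    """
    opt = RMSprop(cfg.lr, cfg.decay, ema_rho=cfg.ema_rho)
    # one optimizer across pre-training and every retraining round: fresh
    # second-moment estimates on a trained model cause large, damaging steps
    model, history = pretrain_sqa(labeled, cfg, spec=spec, opt=opt)
    report = {"pretrain": history, "rounds": []}
    unlabeled = list(unlabeled)
    if not unlabeled:
        return model, report
    rng = np.random.default_rng(cfg.seed + 1)
    aug = augment if cfg.use_augmentation else None
    for rnd in range(cfg.ssl_iters):
        merged, counts = ssl_round(model, list(labeled), unlabeled, cfg.th_s)
        xs, ys = _slice_arrays([s for s in merged if s.trainable])
        hist = _fit(model, xs, ys, cfg, opt, rng, augment_fn=aug, strict_classes=False)
        report["rounds"].append({**counts, "history": hist})
        logger.info("ssl round %d: selected %d / skipped %d", rnd, counts["selected"], counts["skipped"])
    return model, report


def _self_train_partition(records, preds: Sequence[ProbTriple], threshold: float):
    """Apply the keep/relabel/remove rule shared by both self-training levels.

    Keep a record if (argmax equals its current label) OR (max prob strictly
    above threshold); relabel kept records whose confidence clears the
    threshold; remove the rest.  Returns (kept records, counts).
    """
    kept, counts = [], {"kept": 0, "relabeled": 0, "removed": 0}
    for rec, pt in zip(records, preds):
        rec.last_pred = pt
        agrees = rec.label is not None and pt.argmax == rec.label
        confident = pt.max_prob > threshold
        if agrees or confident:
            if confident and not agrees:
                rec.label = pt.argmax
                rec.provenance = Provenance.RELABELED
                counts["relabeled"] += 1
            kept.append(rec)
            counts["kept"] += 1
        else:
            rec.provenance = Provenance.REMOVED
            counts["removed"] += 1
    if not kept:
        raise RuntimeError("self-training removed every record (degenerate selection)")
    return kept, counts


def slice_self_train_round(
    model: SQANet,
    slices: Sequence[SliceRecord],
    th_s: float,
    cfg: TrainConfig,
    opt: Optional[RMSprop] = None,
    retrain: bool = True,
) -> tuple[list[SliceRecord], dict]:
    """One round of slice-label cleansing followed by retraining.

    Retraining continues with the model's fitted optimizer state by default;
    restarting the second-moment estimates mid-way destabilizes training."""
    active = [s for s in slices if s.trainable]
    probs = model.predict_proba(np.stack([s.image for s in active]))
    kept, counts = _self_train_partition(active, [ProbTriple(p) for p in probs], th_s)
    if retrain:
        opt = opt or getattr(model, "optimizer", None) or RMSprop(
            cfg.lr, cfg.decay, ema_rho=cfg.ema_rho)
        opt.lr = cfg.lr * cfg.refine_lr_scale
        rng = np.random.default_rng(cfg.seed + 2)
        xs, ys = _slice_arrays(kept)
        aug = augment if cfg.use_augmentation else None
        counts["history"] = _fit(model, xs, ys, cfg, opt, rng, augment_fn=aug,
                                 strict_classes=False)
    return kept, counts


def _volume_features(model: SQANet, split_slices, volumes: Sequence[VolumeRecord],
                     slices_by_id) -> np.ndarray:
    """Stack frozen slice feature maps per volume: (n_vol, n_s, h, w, c)."""
    feats = []
    for vol in volumes:
        imgs = np.stack([slices_by_id[sid].image for sid in vol.slice_ids])
        _, f = model.forward(imgs, training=False)
        feats.append(f)
    return np.stack(feats)


def volume_self_train_round(
    model: VQANet,
    volumes: Sequence[VolumeRecord],
    features: np.ndarray,
    th_v: float,
    cfg: TrainConfig,
    opt: Optional[RMSprop] = None,
    retrain: bool = True,
) -> tuple[list[VolumeRecord], dict]:
    """One round of volume-label cleansing followed by retraining.

    ``features`` are the per-volume slice feature stacks aligned with
    ``volumes`` (the slice network is frozen, so they are computed once)."""
    active_idx = [i for i, v in enumerate(volumes) if v.trainable]
    active = [volumes[i] for i in active_idx]
    probs = model.predict_proba(features[active_idx])
    kept, counts = _self_train_partition(active, [ProbTriple(p) for p in probs], th_v)
    if retrain:
        opt = opt or getattr(model, "optimizer", None) or RMSprop(
            cfg.lr, cfg.decay, ema_rho=cfg.ema_rho)
        opt.lr = cfg.lr * cfg.refine_lr_scale
        rng = np.random.default_rng(cfg.seed + 3)
        kept_ids = {id(v) for v in kept}
        kept_idx = [i for i in active_idx if id(volumes[i]) in kept_ids]
        ys = np.array([int(volumes[i].label) for i in kept_idx])
        vcfg = replace(cfg, epochs=cfg.vqa_epochs or cfg.epochs)
        counts["history"] = _fit(model, features[kept_idx], ys, vcfg, opt, rng,
                                 strict_classes=False)
    return kept, counts


def fit_vqa(
    sqa: SQANet,
    volumes: Sequence[VolumeRecord],
    slices_by_id,
    cfg: TrainConfig,
    spec: Optional[NetSpec] = None,
) -> tuple[VQANet, np.ndarray, list[dict]]:
    """Train the volume network on frozen slice features."""
    trainable = [v for v in volumes if v.trainable]
    if not trainable:
        raise ValueError("no trainable labeled volumes")
    n_s = len(trainable[0].slice_ids)
    feats = _volume_features(sqa, None, trainable, slices_by_id)
    model = VQANet(spec or sqa.spec, n_slices=n_s)
    opt = RMSprop(cfg.lr, cfg.decay, ema_rho=cfg.ema_rho)
    rng = np.random.default_rng(cfg.seed + 4)
    ys = np.array([int(v.label) for v in trainable])
    vcfg = replace(cfg, epochs=cfg.vqa_epochs or cfg.epochs)
    history = _fit(model, feats, ys, vcfg, opt, rng, strict_classes=False)
    model.optimizer = opt
    return model, feats, history


def fit_full_pipeline(
    splits: dict[str, DatasetSplit],
    cfg: TrainConfig,
    spec: Optional[NetSpec] = None,
) -> tuple[SQANet, VQANet, dict]:
    """Run every training stage in sequence and audit all label changes.

    pretrain -> semi-supervised learning -> slice self-training ->
    rule-based volume label initialization -> VQA training -> volume
    self-training.  Operates on copies of the provided splits; the report
    records per-round counts and the final label of every record.
    """
    labeled = splits["labeled_train"].copy()
    unlabeled = splits["unlabeled"].copy()
    spec = spec or NetSpec.toy(seed=cfg.seed)
    report: dict = {"config": vars(cfg).copy()}

    train_slices = list(labeled.slices.values())
    sqa, ssl_report = semi_supervised_fit(
        train_slices, list(unlabeled.slices.values()), cfg, spec=spec
    )
    report["ssl"] = _strip_histories(ssl_report)

    st_slices = train_slices
    opt = getattr(sqa, "optimizer", None) or RMSprop(cfg.lr, cfg.decay)
    report["slice_self_training"] = []
    for _ in range(cfg.st_iters):
        st_slices, counts = slice_self_train_round(sqa, st_slices, cfg.th_s, cfg, opt=opt)
        report["slice_self_training"].append({k: counts[k] for k in ("kept", "relabeled", "removed")})

    # initialize labels of unlabeled volumes from predicted slice ratings
    for vol in unlabeled.volumes.values():
        imgs = np.stack([unlabeled.slices[sid].image for sid in vol.slice_ids])
        preds = sqa.predict_proba(imgs)
        slice_labels = [ProbTriple(p).argmax for p in preds]
        vol.label = aggregation.init_volume_label(slice_labels)
        vol.provenance = Provenance.PSEUDO

    all_volumes = list(labeled.volumes.values()) + list(unlabeled.volumes.values())
    slices_by_id = {**labeled.slices, **unlabeled.slices}
    vqa, feats, vqa_hist = fit_vqa(sqa, all_volumes, slices_by_id, cfg, spec=spec)
    report["vqa_final_acc"] = vqa_hist[-1]["acc"]

    vopt = getattr(vqa, "optimizer", None) or RMSprop(cfg.lr, cfg.decay)
    trainable_vols = [v for v in all_volumes if v.trainable]
    report["volume_self_training"] = []
    for _ in range(cfg.st_iters):
        _, counts = volume_self_train_round(vqa, trainable_vols, feats, cfg.th_v, cfg, opt=vopt)
        report["volume_self_training"].append({k: counts[k] for k in ("kept", "relabeled", "removed")})

    report["final_labels"] = {
        "slices": {s.slice_id: (str(s.label) if s.label else "", s.provenance.value if s.provenance else "")
                    for s in slices_by_id.values()},
        "volumes": {v.volume_id: (str(v.label) if v.label else "", v.provenance.value if v.provenance else "")
                     for v in all_volumes},
    }
    return sqa, vqa, report


def _strip_histories(report: dict) -> dict:
    out = {"pretrain_final_acc": report["pretrain"][-1]["acc"], "rounds": []}
    for r in report["rounds"]:
        out["rounds"].append({"selected": r["selected"], "skipped": r["skipped"],
                              "final_acc": r["history"][-1]["acc"]})
    return out


def predict_hierarchy(
    sqa: SQANet, vqa: VQANet, split: DatasetSplit
) -> dict[str, dict[str, QualityLabel]]:
    """Predict slice, volume and subject ratings for a split.

    Volume ratings come from the volume network on agglomerated slice
    features; subject ratings from the rule-based ensemble of predicted
    volume ratings.
    """
    out = {"slices": {}, "volumes": {}, "subjects": {}}
    for vol in split.volumes.values():
        imgs = np.stack([split.slices[sid].image for sid in vol.slice_ids])
        probs, feats = sqa.forward(imgs, training=False)
        for sid, p in zip(vol.slice_ids, probs):
            out["slices"][sid] = ProbTriple(p).argmax
        vp = vqa.forward(feats[None, ...], training=False)[0]
        out["volumes"][vol.volume_id] = ProbTriple(vp).argmax
    for sub in split.subjects.values():
        vol_labels = [out["volumes"][v] for v in sub.volume_ids]
        out["subjects"][sub.subject_id] = aggregation.subject_label(vol_labels)
    return out
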