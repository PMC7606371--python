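"""Desk-scale behavioral experiments on synthetic data.

The label-recovery experiment reproduces, at toy scale, the regime the
training procedure targets: a small labeled pool whose volume annotations
are partly wrong (random flips) and inherited by every slice, plus a larger
unlabeled pool.  It tracks held-out accuracy after each refinement stage so
the contribution of semi-supervised learning, slice self-training, and
volume self-training can be read off directly.

Volume-level accuracy at the intermediate slice stages uses the rule-based
aggregation of predicted slice labels (the same rule that initializes
volume labels); the final stage uses the trained volume network.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from . import aggregation
from .data_model import DatasetSplit, ProbTriple, Provenance, QualityLabel
from .networks import NetSpec, SQANet, VQANet
from .synthetic_data import SimConfig, generate_study
from .training_loops import (
    TrainConfig,
    fit_vqa,
    predict_hierarchy,
    pretrain_sqa,
    semi_supervised_fit,
    slice_self_train_round,
    volume_self_train_round,
)

__all__ = ["label_recovery_experiment"]


def _slice_accuracy(model: SQANet, split: DatasetSplit) -> float:
    slices = list(split.slices.values())
    probs = model.predict_proba(np.stack([s.image for s in slices]))
    pred = probs.argmax(axis=1)
    truth = np.array([int(s.true_label) for s in slices])
    return float((pred == truth).mean())


def _rule_volume_accuracy(model: SQANet, split: DatasetSplit) -> float:
    """Volume accuracy from rule-aggregated predicted slice labels."""
    correct = 0
    for vol in split.volumes.values():
        imgs = np.stack([split.slices[sid].image for sid in vol.slice_ids])
        pred_labels = [ProbTriple(p).argmax for p in model.predict_proba(imgs)]
        if aggregation.init_volume_label(pred_labels) == vol.true_label:
            correct += 1
    return correct / len(split.volumes)


def label_recovery_experiment(
    seed: int,
    flip_rate: float = 0.2,
    n_labeled_subjects: int = 2,
    n_unlabeled_subjects: int = 2,
    n_test_subjects: int = 1,
    sim: Optional[SimConfig] = None,
    cfg: Optional[TrainConfig] = None,
) -> dict:
    """Run every stage once, measuring held-out accuracy after each.

    Returns a dict with slice accuracy on the test split after pre-training
    (``slice_acc_pretrain``), semi-supervised learning (``slice_acc_ssl``)
    and slice self-training (``slice_acc_self_train``); rule-aggregated
    volume accuracy at the same stages (``vol_acc_*``); and volume-network
    accuracy before and after volume self-training (``vol_acc_vqa``,
    ``vol_acc_vqa_self_train``).
    """
    sim = sim or SimConfig(flip_rate=flip_rate, seed=seed)
    sim = replace(sim, flip_rate=flip_rate, seed=seed)
    cfg = cfg or TrainConfig.toy(seed=seed)
    spec = NetSpec.toy(seed=seed)

    splits = generate_study(sim, n_labeled_subjects, n_unlabeled_subjects, n_test_subjects)
    labeled = splits["labeled_train"].copy()
    unlabeled = splits["unlabeled"].copy()
    test = splits["test"]
    out: dict = {"seed": seed, "flip_rate": flip_rate}

    # stage 1: supervised pre-training on weak, partly flipped labels
    train_slices = list(labeled.slices.values())
    baseline, _ = pretrain_sqa(train_slices, cfg, spec=spec)
    out["slice_acc_pretrain"] = _slice_accuracy(baseline, test)
    out["vol_acc_pretrain"] = _rule_volume_accuracy(baseline, test)

    # stage 2: semi-supervised learning (includes its own fresh pre-training
    # so the baseline above stays untouched for the paired comparison)
    sqa, ssl_report = semi_supervised_fit(
        train_slices, list(unlabeled.slices.values()), cfg, spec=spec
    )
    out["slice_acc_ssl"] = _slice_accuracy(sqa, test)
    out["vol_acc_ssl"] = _rule_volume_accuracy(sqa, test)
    out["ssl_selected"] = [r["selected"] for r in ssl_report["rounds"]]

    # stage 3: slice self-training (continues the SSL optimizer state)
    st_slices = train_slices
    for _ in range(cfg.st_iters):
        st_slices, _ = slice_self_train_round(sqa, st_slices, cfg.th_s, cfg)
    out["slice_acc_self_train"] = _slice_accuracy(sqa, test)
    out["vol_acc_self_train"] = _rule_volume_accuracy(sqa, test)

    # recovered-label quality on the training pool itself
    kept = [s for s in labeled.slices.values() if s.trainable]
    out["train_label_acc_recovered"] = float(
        np.mean([s.label == s.true_label for s in kept])
    )

    # stage 4: volume label init for the unlabeled pool, volume network fit
    for vol in unlabeled.volumes.values():
        imgs = np.stack([unlabeled.slices[sid].image for sid in vol.slice_ids])
        pred = [ProbTriple(p).argmax for p in sqa.predict_proba(imgs)]
        vol.label = aggregation.init_volume_label(pred)
        vol.provenance = Provenance.PSEUDO
    all_vols = list(labeled.volumes.values()) + list(unlabeled.volumes.values())
    slices_by_id = {**labeled.slices, **unlabeled.slices}
    vqa, feats, _ = fit_vqa(sqa, all_vols, slices_by_id, cfg, spec=spec)

    def _vqa_volume_acc() -> float:
        preds = predict_hierarchy(sqa, vqa, test)
        truth = {v.volume_id: v.true_label for v in test.volumes.values()}
        return float(np.mean([preds["volumes"][k] == truth[k] for k in truth]))

    out["vol_acc_vqa"] = _vqa_volume_acc()

    # stage 5: volume self-training (continues the VQA optimizer state)
    trainable = [v for v in all_vols if v.trainable]  # aligned with feats rows
    for _ in range(cfg.st_iters):
        volume_self_train_round(vqa, trainable, feats, cfg.th_v, cfg)
    out["vol_acc_vqa_self_train"] = _vqa_volume_acc()

    return out
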