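"""Domain types and dataset containers shared by every assessment stage.

The data model mirrors the acquisition hierarchy of a diffusion MRI session:
a *subject* is scanned as a series of 3D *volumes* (one per diffusion
gradient), each of which is read as an ordered stack of 2D sagittal *slices*.
Quality ratings live at all three levels and use the same three-valued scale
(pass < questionable < fail, ordered by artifact severity).

Label *provenance* is tracked explicitly because the training procedure
rewrites labels: expert annotations are ``given``; slice labels copied from a
volume annotation (weak labeling) are ``inherited``; confident model
predictions merged in during semi-supervised learning are ``pseudo``;
self-training may mark records ``relabeled`` or ``removed``.  Removed records
stay in their container but are excluded from any training batch.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "QualityLabel",
    "Provenance",
    "ProbTriple",
    "SliceRecord",
    "VolumeRecord",
    "SubjectRecord",
    "DatasetSplit",
    "validate_dataset",
    "save_split",
    "load_split",
]


class QualityLabel(enum.IntEnum):
    """Three-level quality rating, totally ordered by artifact severity."""

    PASS = 0
    QUESTIONABLE = 1
    FAIL = 2

    @classmethod
    def from_string(cls, s: str) -> "QualityLabel":
        key = s.strip().lower()
        aliases = {
            "pass": cls.PASS,
            "questionable": cls.QUESTIONABLE,
            "ques": cls.QUESTIONABLE,
            "fail": cls.FAIL,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown quality label {s!r}") from None

    def __str__(self) -> str:  # CSV-friendly
        return {0: "pass", 1: "questionable", 2: "fail"}[int(self)]


class Provenance(str, enum.Enum):
    """Where a record's current label came from."""

    GIVEN = "given"          # expert annotation at the record's own level
    INHERITED = "inherited"  # slice label copied from its volume (weak label)
    PSEUDO = "pseudo"        # confident model prediction (semi-supervised)
    RELABELED = "relabeled"  # replaced by a confident prediction (self-training)
    REMOVED = "removed"      # excluded from training by self-training


@dataclass(frozen=True)
class ProbTriple:
    """Predicted class probabilities (p_pass, p_questionable, p_fail)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3,):
            raise ValueError("ProbTriple needs exactly 3 components")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(p.sum()) - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1 within 1e-6")
        object.__setattr__(self, "p", p)

    @property
    def argmax(self) -> QualityLabel:
        """Most probable label; ties break toward the more severe label."""
        p = self.p
        best = np.flatnonzero(p >= p.max() - 1e-12)
        return QualityLabel(int(best.max()))

    @property
    def max_prob(self) -> float:
        return float(self.p.max())


@dataclass(eq=False)
class SliceRecord:
    slice_id: str
    volume_id: str
    image: Optional[np.ndarray] = None  # 2D, intensities in [0, 1]
    label: Optional[QualityLabel] = None
    provenance: Optional[Provenance] = None
    last_pred: Optional[ProbTriple] = None
    true_label: Optional[QualityLabel] = None  # simulator ground truth, if any

    @property
    def trainable(self) -> bool:
        return self.label is not None and self.provenance is not Provenance.REMOVED


@dataclass(eq=False)
class VolumeRecord:
    volume_id: str
    subject_id: str
    slice_ids: list[str] = field(default_factory=list)
    label: Optional[QualityLabel] = None
    provenance: Optional[Provenance] = None
    last_pred: Optional[ProbTriple] = None
    true_label: Optional[QualityLabel] = None

    @property
    def trainable(self) -> bool:
        return self.label is not None and self.provenance is not Provenance.REMOVED


@dataclass(eq=False)
class SubjectRecord:
    subject_id: str
    volume_ids: list[str] = field(default_factory=list)
    label: Optional[QualityLabel] = None
    true_label: Optional[QualityLabel] = None


@dataclass
class DatasetSplit:
    """One of the three pools a study is divided into.

    ``labeled_train`` carries volume annotations; ``unlabeled`` has none at
    load time; ``test`` carries them for evaluation only.
    """

    name: str  # labeled_train | unlabeled | test
    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    volumes: dict[str, VolumeRecord] = field(default_factory=dict)
    slices: dict[str, SliceRecord] = field(default_factory=dict)

    VALID_NAMES = ("labeled_train", "unlabeled", "test")

    def slices_of(self, volume_id: str) -> list[SliceRecord]:
        return [self.slices[s] for s in self.volumes[volume_id].slice_ids]

    def copy(self) -> "DatasetSplit":
        return DatasetSplit(
            name=self.name,
            subjects={k: replace(v, volume_ids=list(v.volume_ids)) for k, v in self.subjects.items()},
            volumes={k: replace(v, slice_ids=list(v.slice_ids)) for k, v in self.volumes.items()},
            slices={k: replace(v) for k, v in self.slices.items()},
        )


def validate_dataset(split: DatasetSplit) -> list[str]:
    """Check every container invariant; return one message per violation."""
    msgs: list[str] = []
    if split.name not in DatasetSplit.VALID_NAMES:
        msgs.append(f"unknown split name {split.name!r}")

    for sub in split.subjects.values():
        if not sub.volume_ids:
            msgs.append(f"subject {sub.subject_id}: empty volume list")
        if len(set(sub.volume_ids)) != len(sub.volume_ids):
            msgs.append(f"subject {sub.subject_id}: duplicate volume ids")
        for vid in sub.volume_ids:
            if vid not in split.volumes:
                msgs.append(f"subject {sub.subject_id}: missing volume {vid}")

    for vol in split.volumes.values():
        if not vol.slice_ids:
            msgs.append(f"volume {vol.volume_id}: empty slice list")
        if len(set(vol.slice_ids)) != len(vol.slice_ids):
            msgs.append(f"volume {vol.volume_id}: duplicate slice ids")
        for sid in vol.slice_ids:
            if sid not in split.slices:
                msgs.append(f"volume {vol.volume_id}: missing slice {sid}")
        if vol.subject_id not in split.subjects:
            msgs.append(f"volume {vol.volume_id}: unknown subject {vol.subject_id}")
        if split.name == "labeled_train" and vol.label is None:
            msgs.append(f"unlabeled volume in labeled split: {vol.volume_id}")
        if split.name == "unlabeled" and vol.label is not None and vol.provenance in (
            Provenance.GIVEN,
            Provenance.INHERITED,
        ):
            msgs.append(f"annotated volume in unlabeled split: {vol.volume_id}")

    for sl in split.slices.values():
        if sl.volume_id not in split.volumes:
            msgs.append(f"slice {sl.slice_id}: unknown volume {sl.volume_id}")
        if sl.label is None and sl.provenance in (Provenance.GIVEN, Provenance.INHERITED):
            msgs.append(f"slice {sl.slice_id}: provenance {sl.provenance.value} without a label")
        if sl.image is not None:
            img = np.asarray(sl.image)
            if img.ndim != 2:
                msgs.append(f"slice {sl.slice_id}: image is not 2D")
            elif not np.all(np.isfinite(img)):
                msgs.append(f"slice {sl.slice_id}: non-finite intensities")

    return msgs


# ---------------------------------------------------------------------------
# Disk layout: labels.csv + slices.csv + arrays/<slice_id>.npy + index.json
# ---------------------------------------------------------------------------

def _label_str(lab: Optional[QualityLabel]) -> str:
    return "" if lab is None else str(lab)


def _label_opt(s) -> Optional[QualityLabel]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    return QualityLabel.from_string(str(s))


def save_split(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write a split as CSV tables plus one .npy array per slice image."""
    out = Path(out_dir)
    arr_dir = out / "arrays"
    arr_dir.mkdir(parents=True, exist_ok=True)

    vol_rows = [
        {
            "subject_id": v.subject_id,
            "volume_id": v.volume_id,
            "label": _label_str(v.label),
            "provenance": v.provenance.value if v.provenance else "",
            "true_label": _label_str(v.true_label),
        }
        for v in split.volumes.values()
    ]
    pd.DataFrame(vol_rows).to_csv(out / "volumes.csv", index=False)

    sub_rows = [
        {
            "subject_id": s.subject_id,
            "label": _label_str(s.label),
            "true_label": _label_str(s.true_label),
        }
        for s in split.subjects.values()
    ]
    pd.DataFrame(sub_rows).to_csv(out / "subjects.csv", index=False)

    slice_rows = []
    index: dict[str, str] = {}
    for s in split.slices.values():
        slice_rows.append(
            {
                "subject_id": split.volumes[s.volume_id].subject_id,
                "volume_id": s.volume_id,
                "slice_id": s.slice_id,
                "label": _label_str(s.label),
                "provenance": s.provenance.value if s.provenance else "",
                "true_label": _label_str(s.true_label),
            }
        )
        if s.image is not None:
            rel = f"arrays/{s.slice_id.replace('/', '_')}.npy"
            np.save(out / rel, np.asarray(s.image, dtype=np.float32))
            index[s.slice_id] = rel
    pd.DataFrame(slice_rows).to_csv(out / "slices.csv", index=False)
    (out / "index.json").write_text(json.dumps({"name": split.name, "images": index}, indent=1))


def load_split(in_dir: str | Path) -> DatasetSplit:
    """Reload a split written by :func:`save_split`, field-for-field."""
    src = Path(in_dir)
    meta = json.loads((src / "index.json").read_text())
    split = DatasetSplit(name=meta["name"])

    vols = pd.read_csv(src / "volumes.csv", keep_default_na=False)
    for _, r in vols.iterrows():
        v = VolumeRecord(
            volume_id=r["volume_id"],
            subject_id=r["subject_id"],
            label=_label_opt(r["label"]),
            provenance=Provenance(r["provenance"]) if r["provenance"] else None,
            true_label=_label_opt(r["true_label"]),
        )
        split.volumes[v.volume_id] = v
        sub = split.subjects.setdefault(r["subject_id"], SubjectRecord(subject_id=r["subject_id"]))
        sub.volume_ids.append(v.volume_id)

    subs = pd.read_csv(src / "subjects.csv", keep_default_na=False)
    for _, r in subs.iterrows():
        sub = split.subjects.setdefault(r["subject_id"], SubjectRecord(subject_id=r["subject_id"]))
        sub.label = _label_opt(r["label"])
        sub.true_label = _label_opt(r["true_label"])

    sls = pd.read_csv(src / "slices.csv", keep_default_na=False)
    for _, r in sls.iterrows():
        sid = r["slice_id"]
        img = None
        if sid in meta["images"]:
            img = np.load(src / meta["images"][sid]).astype(np.float64)
        s = SliceRecord(
            slice_id=sid,
            volume_id=r["volume_id"],
            image=img,
            label=_label_opt(r["label"]),
            provenance=Provenance(r["provenance"]) if r["provenance"] else None,
            true_label=_label_opt(r["true_label"]),
        )
        split.slices[sid] = s
        split.volumes[s.volume_id].slice_ids.append(sid)

    return split
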