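"""Synthetic dMRI-like slices, volumes and subjects with graded artifacts.

The simulator produces the regime the training procedure is designed for:
brain-like 2D phantoms corrupted at a graded *severity* by motion-style
artifacts (EPI ghosting, signal-dropout bands, blur, Rician-style noise),
grouped into volumes whose slices mix severities, with *weak* annotation
(every slice inherits its volume's label) and optional random volume-label
flips.  Weak labels on mixed-quality volumes are exactly the "inaccurate
slice labels" that slice self-training is meant to clean up.

Severity maps to the three-level rating through two thresholds (s1, s2):
pass below s1, questionable in [s1, s2), fail at or above s2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
from scipy import ndimage

from .aggregation import init_volume_label, subject_label
from .data_model import (
    DatasetSplit,
    Provenance,
    QualityLabel,
    SliceRecord,
    SubjectRecord,
    VolumeRecord,
)

__all__ = [
    "ArtifactParams",
    "SimConfig",
    "make_phantom",
    "corrupt_slice",
    "true_slice_label",
    "generate_split",
    "generate_study",
]


@dataclass(frozen=True)
class ArtifactParams:
    """Artifact magnitudes for one slice, all monotone in ``severity``.

    ghost_weight   intensity of the cyclically shifted ghost replica
    dropout_band_count  number of zeroed horizontal bands
    blur_sigma     Gaussian blur width in pixels
    noise_sigma    Rician noise scale; sits at a small floor at severity 0
    """

    severity: float
    ghost_weight: float
    dropout_band_count: int
    blur_sigma: float
    noise_sigma: float
    seed: int = 0

    NOISE_FLOOR = 0.01

    @classmethod
    def from_severity(cls, severity: float, seed: int = 0) -> "ArtifactParams":
        if not 0.0 <= severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        return cls(
            severity=severity,
            ghost_weight=0.5 * severity,
            dropout_band_count=min(int(4.0 * severity), 3),
            blur_sigma=1.5 * severity,
            noise_sigma=cls.NOISE_FLOOR + 0.08 * severity,
            seed=seed,
        )


@dataclass
class SimConfig:
    """Study geometry, per-class severity mixtures, and annotation regime.

    ``severity_mixture`` maps each intended volume class to Beta(a, b)
    parameters from which that volume's slice severities are drawn; the
    defaults put pass-volumes mostly below s1, questionable volumes around
    the middle (hence genuinely mixed slice quality), and fail volumes high.
    ``class_probs`` mirrors the imbalance of a clinical pool where most
    acquisitions pass.
    """

    n_subjects: int = 4
    n_volumes_per_subject: int = 12
    n_slices_per_volume: int = 16
    image_size: int = 64
    severity_mixture: dict = field(
        default_factory=lambda: {
            "pass": (1.2, 8.0),
            "questionable": (5.0, 5.0),
            "fail": (8.0, 2.5),
        }
    )
    class_probs: tuple = (0.57, 0.16, 0.27)
    label_thresholds: tuple = (0.3, 0.6)
    weak_labeling: bool = True
    flip_rate: float = 0.0
    split_name: str = "labeled_train"
    seed: int = 0

    def __post_init__(self) -> None:
        s1, s2 = self.label_thresholds
        if not 0.0 < s1 < s2 < 1.0:
            raise ValueError("label thresholds must satisfy 0 < s1 < s2 < 1")
        if not 0.0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must lie in [0, 0.5)")


def make_phantom(size: int, seed: int) -> np.ndarray:
    """Deterministic brain-like phantom: elliptical support with smooth blobs.

    Intensities lie in [0, 1]; the background outside the ellipse is 0.
    """
    if size < 32:
        raise ValueError("phantom size must be at least 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    # slightly anisotropic head-like ellipse, radii jittered per seed
    ry = size * (0.40 + 0.03 * rng.uniform(-1, 1))
    rx = size * (0.33 + 0.03 * rng.uniform(-1, 1))
    support = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    blobs = rng.uniform(0.0, 1.0, size=(size, size))
    blobs = ndimage.gaussian_filter(blobs, sigma=size / 12.0)
    lo, hi = blobs.min(), blobs.max()
    blobs = (blobs - lo) / (hi - lo) if hi > lo else np.zeros_like(blobs)

    # bright rim mimicking cortical band, darker interior structure
    dist = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    rim = np.clip(1.0 - np.abs(dist - 0.85) / 0.15, 0.0, 1.0)
    img = support * np.clip(0.25 + 0.55 * blobs + 0.35 * rim, 0.0, 1.0)
    return img.astype(np.float64)


def corrupt_slice(phantom: np.ndarray, params: ArtifactParams) -> np.ndarray:
    """Apply ghosting, dropout bands, blur, then Rician-style noise.

    Ghosting adds a half-FOV cyclically shifted replica scaled by
    ``ghost_weight`` (the phase-error ghost of echo-planar imaging).
    Dropout zeroes ``dropout_band_count`` disjoint horizontal bands.
    The result is clipped to [0, 1].
    """
    img = np.asarray(phantom, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("phantom must be finite-valued")
    rng = np.random.default_rng(params.seed)
    h, w = img.shape

    if params.ghost_weight > 0:
        ghost = np.roll(img, h // 2, axis=0)
        img = (img + params.ghost_weight * ghost) / (1.0 + params.ghost_weight)

    k = params.dropout_band_count
    if k > 0:
        # one band inside each of k equal row-segments keeps bands disjoint
        band_h = max(1, h // 32)
        seg = h // k
        for b in range(k):
            start = b * seg + int(rng.integers(0, max(1, seg - band_h)))
            img[start : start + band_h, :] = 0.0

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=params.blur_sigma)

    if params.noise_sigma > 0:
        n1 = rng.normal(0.0, params.noise_sigma, size=img.shape)
        n2 = rng.normal(0.0, params.noise_sigma, size=img.shape)
        img = np.sqrt((img + n1) ** 2 + n2**2)

    return np.clip(img, 0.0, 1.0)


def true_slice_label(severity: float, thresholds: tuple) -> QualityLabel:
    """Map artifact severity to the three-level rating via (s1, s2)."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    s1, s2 = thresholds
    if severity < s1:
        return QualityLabel.PASS
    if severity < s2:
        return QualityLabel.QUESTIONABLE
    return QualityLabel.FAIL


_CLASS_KEYS = ("pass", "questionable", "fail")


def generate_split(cfg: SimConfig) -> DatasetSplit:
    """Generate one fully seeded split under the configured regime.

    Each volume draws an intended class from ``class_probs``, then slice
    severities from that class's Beta mixture.  The volume's *true* label is
    recomputed from its slices' true labels with the volume-initialization
    rule (so mixed volumes may land in a different class than intended).
    Under weak labeling every slice's stored label is its volume's stored
    label.  ``flip_rate`` then reassigns exactly ``round(flip_rate * n_vol)``
    volume labels (and their slices' inherited labels) to a different class.
    """
    rng = np.random.default_rng(cfg.seed)
    split = DatasetSplit(name=cfg.split_name)
    labeled = cfg.split_name != "unlabeled"

    for si in range(cfg.n_subjects):
        sub_id = f"s{si:03d}"
        subject = SubjectRecord(subject_id=sub_id)
        split.subjects[sub_id] = subject
        for vi in range(cfg.n_volumes_per_subject):
            vol_id = f"{sub_id}/v{vi:03d}"
            cls = rng.choice(3, p=np.asarray(cfg.class_probs) / np.sum(cfg.class_probs))
            a, b = cfg.severity_mixture[_CLASS_KEYS[cls]]
            sev = rng.beta(a, b, size=cfg.n_slices_per_volume)

            vol = VolumeRecord(volume_id=vol_id, subject_id=sub_id)
            true_labels = []
            for ki in range(cfg.n_slices_per_volume):
                sl_id = f"{vol_id}/sl{ki:03d}"
                params = ArtifactParams.from_severity(
                    float(sev[ki]), seed=int(rng.integers(0, 2**31 - 1))
                )
                phantom = make_phantom(cfg.image_size, seed=int(rng.integers(0, 2**31 - 1)))
                image = corrupt_slice(phantom, params)
                t = true_slice_label(float(sev[ki]), cfg.label_thresholds)
                true_labels.append(t)
                split.slices[sl_id] = SliceRecord(
                    slice_id=sl_id, volume_id=vol_id, image=image, true_label=t
                )
                vol.slice_ids.append(sl_id)

            vol.true_label = init_volume_label(true_labels)
            if labeled:
                vol.label = vol.true_label
                vol.provenance = Provenance.GIVEN
            split.volumes[vol_id] = vol
            subject.volume_ids.append(vol_id)

        subject.true_label = subject_label(
            [split.volumes[v].true_label for v in subject.volume_ids]
        )

    if labeled and cfg.flip_rate > 0:
        vol_ids = sorted(split.volumes)
        n_flip = int(round(cfg.flip_rate * len(vol_ids)))
        for vol_id in rng.choice(vol_ids, size=n_flip, replace=False):
            vol = split.volumes[vol_id]
            others = [l for l in QualityLabel if l != vol.label]
            vol.label = others[int(rng.integers(0, 2))]

    if labeled and cfg.weak_labeling:
        for sl in split.slices.values():
            sl.label = split.volumes[sl.volume_id].label
            sl.provenance = Provenance.INHERITED

    return split


def generate_study(
    base_cfg: SimConfig,
    n_labeled_subjects: int,
    n_unlabeled_subjects: int,
    n_test_subjects: int,
) -> dict[str, DatasetSplit]:
    """Three disjoint splits (labeled_train / unlabeled / test) from one seed.

    The test split is generated without label flips: it plays the role of
    the carefully annotated evaluation pool.
    """
    from dataclasses import replace as _rep

    seeds = np.random.SeedSequence(base_cfg.seed).generate_state(3)
    splits = {}
    splits["labeled_train"] = generate_split(
        _rep(base_cfg, n_subjects=n_labeled_subjects, split_name="labeled_train",
             seed=int(seeds[0] % (2**31 - 1)))
    )
    splits["unlabeled"] = generate_split(
        _rep(base_cfg, n_subjects=n_unlabeled_subjects, split_name="unlabeled",
             seed=int(seeds[1] % (2**31 - 1)))
    )
    splits["test"] = generate_split(
        _rep(base_cfg, n_subjects=n_test_subjects, split_name="test",
             flip_rate=0.0, seed=int(seeds[2] % (2**31 - 1)))
    )
    # splits come from independent streams; prefix ids to keep them disjoint
    for name, split in splits.items():
        prefix = {"labeled_train": "L", "unlabeled": "U", "test": "T"}[name]
        _prefix_ids(split, prefix)
    return splits


def _prefix_ids(split: DatasetSplit, prefix: str) -> None:
    split.subjects = {f"{prefix}{k}": v for k, v in split.subjects.items()}
    split.volumes = {f"{prefix}{k}": v for k, v in split.volumes.items()}
    split.slices = {f"{prefix}{k}": v for k, v in split.slices.items()}
    for sub in split.subjects.values():
        sub.subject_id = f"{prefix}{sub.subject_id}"
        sub.volume_ids = [f"{prefix}{v}" for v in sub.volume_ids]
    for vol in split.volumes.values():
        vol.subject_id = f"{prefix}{vol.subject_id}"
        vol.volume_id = f"{prefix}{vol.volume_id}"
        vol.slice_ids = [f"{prefix}{s}" for s in vol.slice_ids]
    for sl in split.slices.values():
        sl.slice_id = f"{prefix}{sl.slice_id}"
        sl.volume_id = f"{prefix}{sl.volume_id}"


def write_manifest(cfg: SimConfig, out_dir: str | Path) -> None:
    """Record the generator configuration next to the written split."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sim_manifest.json").write_text(json.dumps(asdict(cfg), indent=1, default=list))
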