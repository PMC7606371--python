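import numpy as np
import pytest

from dmriqa.data_model import (
    DatasetSplit,
    Provenance,
    QualityLabel,
    SliceRecord,
    SubjectRecord,
    VolumeRecord,
)
from dmriqa.synthetic_data import SimConfig, generate_split


@pytest.fixture(scope="session")
def tiny_split() -> DatasetSplit:
    """Small deterministic labeled split (2 subjects x 4 volumes x 6 slices)."""
    cfg = SimConfig(
        n_subjects=2, n_volumes_per_subject=4, n_slices_per_volume=6, seed=7
    )
    return generate_split(cfg)


def manual_split(name: str = "labeled_train") -> DatasetSplit:
    """Hand-built minimal split: 1 subject, 1 volume, 2 slices, all pass."""
    split = DatasetSplit(name=name)
    split.subjects["s0"] = SubjectRecord(subject_id="s0", volume_ids=["s0/v0"])
    split.volumes["s0/v0"] = VolumeRecord(
        volume_id="s0/v0",
        subject_id="s0",
        slice_ids=["s0/v0/sl0", "s0/v0/sl1"],
        label=QualityLabel.PASS,
        provenance=Provenance.GIVEN,
    )
    for i in range(2):
        sid = f"s0/v0/sl{i}"
        split.slices[sid] = SliceRecord(
            slice_id=sid,
            volume_id="s0/v0",
            image=np.full((8, 8), 0.5),
            label=QualityLabel.PASS,
            provenance=Provenance.INHERITED,
        )
    return split
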