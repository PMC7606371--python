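"""Rule-based label propagation across the slice / volume / subject hierarchy.

Volume labels are initialized from slice labels, and subject labels are
ensembled from volume labels, using fixed majority-style rules with strict
percentage thresholds.  Boundary cases (exactly at a threshold) fall through
to ``questionable``, the conservative middle rating.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Literal, Sequence

from .data_model import QualityLabel

__all__ = ["init_volume_label", "subject_label"]

FailRule = Literal["each", "sum"]


def _counts(labels: Sequence[QualityLabel]) -> tuple[int, int, int]:
    c = Counter(labels)
    return (
        c.get(QualityLabel.PASS, 0),
        c.get(QualityLabel.QUESTIONABLE, 0),
        c.get(QualityLabel.FAIL, 0),
    )


def init_volume_label(
    slice_labels: Sequence[QualityLabel], fail_rule: FailRule = "each"
) -> QualityLabel:
    """Initial volume rating from its slices' ratings.

    Rules, applied in order:

    1. *pass* if strictly more than 60% of the slices are rated pass;
    2. *fail* if more slices are rated fail than pass and questionable —
       by default read as the fail count strictly exceeding **each** of the
       other two counts (``fail_rule="each"``); ``fail_rule="sum"`` instead
       requires the fail count to exceed their sum;
    3. *questionable* otherwise.
    """
    if len(slice_labels) == 0:
        raise ValueError("cannot rate a volume with no slices")
    n_pass, n_ques, n_fail = _counts(slice_labels)
    n = n_pass + n_ques + n_fail
    if n_pass > 0.6 * n:
        return QualityLabel.PASS
    if fail_rule == "each":
        fail_fires = n_fail > n_pass and n_fail > n_ques
    elif fail_rule == "sum":
        fail_fires = n_fail > n_pass + n_ques
    else:
        raise ValueError(f"unknown fail_rule {fail_rule!r}")
    if fail_fires:
        return QualityLabel.FAIL
    return QualityLabel.QUESTIONABLE


def subject_label(volume_labels: Sequence[QualityLabel]) -> QualityLabel:
    """Subject rating from its volumes' ratings.

    1. *pass* if strictly more than 80% of the volumes are rated pass;
    2. *fail* if strictly more than 20% of the volumes are rated fail;
    3. *questionable* otherwise.

    Rules 1 and 2 are mutually exclusive: a pass fraction above 0.8 forces
    the fail fraction below 0.2.
    """
    if len(volume_labels) == 0:
        raise ValueError("cannot rate a subject with no volumes")
    n_pass, _, n_fail = _counts(volume_labels)
    n = len(volume_labels)
    if n_pass > 0.8 * n:
        return QualityLabel.PASS
    if n_fail > 0.2 * n:
        return QualityLabel.FAIL
    return QualityLabel.QUESTIONABLE
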