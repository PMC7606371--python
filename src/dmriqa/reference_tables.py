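"""Reported reference results shipped with the package.

The originating pediatric dMRI quality-assessment study reports held-out
confusion matrices for four slice-network variants (DSR only, DSR+NLR,
NLDR+NLR, and the full DSR+NLDR+NLR network) at volume and subject level,
together with the cohort geometry.  These printed counts are inputs here:
feeding them through :mod:`dmriqa.evaluation` recomputes the corresponding
sensitivity/specificity/accuracy tables and validates the metric
definitions without access to the (private) cohort itself.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = ["load_reference_tables", "reference_confusion", "cohort_geometry"]

VARIANTS = ("DSR", "DSR+NLR", "NLDR+NLR", "DSR+NLDR+NLR")
LEVELS = ("volume", "subject")


def load_reference_tables() -> dict:
    """Raw JSON contents of the shipped reference tables."""
    with resources.files("dmriqa.data").joinpath("reference_tables.json").open() as fh:
        return json.load(fh)


def reference_confusion(variant: str, level: str) -> ConfusionMatrix:
    """Reported confusion matrix for one network variant and hierarchy level."""
    tables = load_reference_tables()["confusion_matrices"]
    if variant not in tables:
        raise KeyError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if level not in LEVELS:
        raise KeyError(f"unknown level {level!r}; choose from {LEVELS}")
    return ConfusionMatrix(np.array(tables[variant][level]))


def cohort_geometry() -> dict:
    """Subject/volume/slice geometry of the originating cohort."""
    return load_reference_tables()["cohort_geometry"]
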