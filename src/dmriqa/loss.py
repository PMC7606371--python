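"""Multi-class balanced focal loss with L2 weight regularization.

For a sample of true class t with predicted probability p_t,

    L(p_t) = -alpha_t * (1 - p_t)^kappa * log(p_t)
             + (lambda / (2 n_w)) * sum_w ||W_w||^2

where kappa >= 0 focuses training on hard (low p_t) samples, the class
weights alpha_t = max(N_1, N_2, N_3) / N_t rebalance unequal class sizes,
lambda (default 0.01) scales the L2 penalty over the n_w convolution weight
matrices W_w (batch-norm scale/shift and biases are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["LossParams", "class_weights", "focal_loss", "focal_data_term", "focal_grad_logits"]

_EPS = 1e-7


@dataclass(frozen=True)
class LossParams:
    kappa: float = 2.0
    lam: float = 0.01
    alpha: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if min(self.alpha) < 1.0 - 1e-12:
            raise ValueError("class weights must be >= 1 (min class achieves 1)")


def class_weights(counts: Sequence[float]) -> np.ndarray:
    """alpha_t = max(N_1, N_2, N_3) / N_t from per-class sample counts."""
    n = np.asarray(counts, dtype=float)
    if n.shape != (3,):
        raise ValueError("need exactly three class counts")
    if np.any(n < 1):
        raise ValueError("every class needs at least one sample")
    return n.max() / n


def focal_data_term(probs: np.ndarray, targets: np.ndarray, params: LossParams) -> float:
    """Mean focal data term over a batch; p_t is clamped away from 0."""
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets, dtype=int)
    p_t = np.clip(probs[np.arange(len(targets)), targets], _EPS, 1.0)
    a_t = np.asarray(params.alpha)[targets]
    return float(np.mean(-a_t * (1.0 - p_t) ** params.kappa * np.log(p_t)))


def l2_term(weight_matrices: Iterable[np.ndarray], lam: float) -> float:
    ws = list(weight_matrices)
    if not ws or lam == 0:
        return 0.0
    return lam / (2.0 * len(ws)) * sum(float(np.sum(w**2)) for w in ws)


def focal_loss(
    probs: np.ndarray,
    targets: np.ndarray,
    params: LossParams,
    weight_matrices: Iterable[np.ndarray] = (),
) -> float:
    """Full loss: mean focal data term plus the L2 regularizer."""
    return focal_data_term(probs, targets, params) + l2_term(weight_matrices, params.lam)


def focal_grad_logits(probs: np.ndarray, targets: np.ndarray, params: LossParams) -> np.ndarray:
    """Gradient of the mean focal data term w.r.t. pre-softmax logits.

    With p = softmax(z) and t the true class,
        dL/dp_t = -alpha_t * [ (1-p_t)^kappa / p_t - kappa (1-p_t)^(kappa-1) log p_t ]
        dp_t/dz_k = p_t (delta_tk - p_k).
    """
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets, dtype=int)
    n = len(targets)
    idx = np.arange(n)
    p_t = np.clip(probs[idx, targets], _EPS, 1.0)
    a_t = np.asarray(params.alpha)[targets]
    k = params.kappa
    one_m = np.maximum(1.0 - p_t, _EPS)  # avoids 0^(k-1) blow-ups for k < 1
    dL_dpt = -a_t * (one_m**k / p_t - (k * one_m ** (k - 1) * np.log(p_t) if k > 0 else 0.0))
    delta = np.zeros_like(probs)
    delta[idx, targets] = 1.0
    dpt_dz = p_t[:, None] * (delta - probs)
    return dL_dpt[:, None] * dpt_dz / n
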