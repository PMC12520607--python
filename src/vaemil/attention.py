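"""Attention-based MIL pooling and bag classification.

The bag representation is a softmax-weighted average of instance
embeddings: raw attention scores f_i = tanh(z_i W^T) w are normalized
over the instances of the bag and used as convex-combination weights.
The pooled vector is classified by a single-logit linear head with a
sigmoid, matching a Bernoulli bag-label likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, bce_with_logits, constant, softmax

__all__ = [
    "AttentionParams",
    "ClassifierParams",
    "AttentionOutput",
    "attention_scores",
    "attend_pool",
    "classify",
]


@dataclass
class AttentionParams:
    """Learnable attention weights W (L, D) and w (L,)."""

    W: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.W.ndim != 2 or self.w.ndim != 1 or self.W.shape[0] != self.w.shape[0]:
            raise ValueError(
                f"inconsistent attention shapes W{self.W.shape}, w{self.w.shape}"
            )

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def D(self) -> int:
        return self.W.shape[1]


@dataclass
class ClassifierParams:
    """Linear bag classifier: logit = weight . B + bias."""

    weight: np.ndarray
    bias: float

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (np.all(np.isfinite(self.weight)) and np.isfinite(self.bias)):
            raise ValueError("non-finite classifier parameters")


@dataclass
class AttentionOutput:
    """Intermediate and pooled quantities for one bag."""

    mid_activations: np.ndarray | None = None  # (N_b, L), in (-1, 1)
    raw_scores: np.ndarray | None = None  # (N_b,)
    weights: np.ndarray | None = None  # (N_b,), positive, sums to 1
    bag_representation: np.ndarray | None = None  # (D,)


def attention_scores(Z: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Raw (pre-softmax) attention scores for each instance embedding."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != params.D:
        raise ValueError(f"Z shape {Z.shape} incompatible with D={params.D}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite instance embeddings")
    mid = np.tanh(Z @ params.W.T)
    return AttentionOutput(mid_activations=mid, raw_scores=mid @ params.w)


def attend_pool(Z: np.ndarray, raw_scores: np.ndarray) -> AttentionOutput:
    """Softmax-normalize scores and pool embeddings into one bag vector."""
    Z = np.asarray(Z, dtype=np.float64)
    raw = np.asarray(raw_scores, dtype=np.float64)
    if raw.shape != (Z.shape[0],):
        raise ValueError("raw_scores length must match the number of instances")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite attention scores")
    shifted = raw - raw.max()  # max-shift: arbitrary-scale scores never overflow
    e = np.exp(shifted)
    weights = e / e.sum()
    return AttentionOutput(
        raw_scores=raw, weights=weights, bag_representation=Z.T @ weights
    )


def classify(
    bag_representation: np.ndarray, params: ClassifierParams
) -> tuple[float, float]:
    """Return (logit, probability) for one pooled bag representation."""
    B = np.asarray(bag_representation, dtype=np.float64)
    if B.shape != params.weight.shape:
        raise ValueError(
            f"bag representation shape {B.shape} != classifier {params.weight.shape}"
        )
    logit = float(params.weight @ B + params.bias)
    # stable sigmoid
    prob = 1.0 / (1.0 + np.exp(-logit)) if logit >= 0 else float(
        np.exp(logit) / (1.0 + np.exp(logit))
    )
    return logit, prob


# -- differentiable path (used inside the training losses) --------------


def attention_logit_t(Z: Tensor, W: Tensor, w: Tensor, cw: Tensor, cb: Tensor) -> Tensor:
    """Tensor-valued bag logit: pool Z by attention, apply the linear head."""
    raw = (Z @ W.T).tanh() @ w  # f = tanh(Z W^T) w
    weights = softmax(raw)
    pooled = Z.T @ weights
    return cw @ pooled + cb


def classification_nll_t(
    Z: Tensor, y: int, W: Tensor, w: Tensor, cw: Tensor, cb: Tensor
) -> Tensor:
    """Bernoulli bag-label NLL of one pooled latent bag, in logit space."""
    return bce_with_logits(attention_logit_t(Z, W, w, cw, cb), float(y))
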