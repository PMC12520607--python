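"""Bag-level out-of-distribution scores and their evaluation.

Tailored scores (trained on the in-distribution data):

* ``logpx`` — negative importance-sampled log marginal likelihood of
  each instance under the variational model, aggregated over the bag.
* ``recerr`` — squared instance reconstruction error of the
  deterministic autoencoder, aggregated over the bag.

Model-agnostic post-hoc baselines computed from the bag logit:

* ``entropy`` — Shannon entropy of the predicted bag probability.
* ``mls`` — negative absolute logit (low confidence = more OOD).

Every score is oriented so that *higher means more OOD*.  Detection
quality is summarized by the AUC of the score against an OOD-vs-IND
indicator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .bags import FeatureBag

__all__ = [
    "OODScoreResult",
    "log_marginal_is",
    "logpx_score",
    "recerr_score",
    "entropy_score",
    "mls_score",
    "auc",
    "evaluate_ood",
    "export_instance_scores",
]

AGGREGATORS = ("mean", "max")


@dataclass
class OODScoreResult:
    """Per-bag OOD score with optional per-instance scores."""

    bag_id: str
    score_name: str  # logpx | recerr | entropy | mls
    aggregator: str  # mean | max | none
    bag_score: float  # higher = more OOD
    instance_scores: np.ndarray | None = None


def _aggregate(instance_scores: np.ndarray, aggregator: str) -> float:
    if aggregator == "mean":
        return float(np.mean(instance_scores))
    if aggregator == "max":
        return float(np.max(instance_scores))
    raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")


def log_marginal_is(model, x: np.ndarray, S: int, rng) -> float:
    """Importance-sampled log marginal likelihood of one instance.

    log p(x) ~= logsumexp_s [ log p(x|z_s) + log p(z_s) - log q(z_s|x) ] - log S
    with z_s drawn from the variational posterior q(z|x).  ``model``
    needs ``encode_np``/``decode_np`` (any object exposing the Gaussian
    posterior and decoder, e.g. a fitted model's ``autoencoder``).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ae = getattr(model, "autoencoder", model)
    x = np.asarray(x, dtype=np.float64)
    mean, scale = ae.encode_np(x[None, :])
    mean, scale = mean[0], float(scale[0, 0])
    D, P = mean.size, x.size
    Z = mean[None, :] + scale * rng.standard_normal((S, D))  # (S, D)
    dec_means, dec_vars = ae.decode_np(Z)
    dec_vars = dec_vars[:, 0]
    log_lik = -0.5 * P * (np.log(2 * np.pi) + np.log(dec_vars)) - (
        ((x[None, :] - dec_means) ** 2).sum(axis=1) / (2.0 * dec_vars)
    )
    log_prior = -0.5 * D * np.log(2 * np.pi) - 0.5 * (Z**2).sum(axis=1)
    log_q = -0.5 * D * (np.log(2 * np.pi) + 2.0 * np.log(scale)) - (
        ((Z - mean[None, :]) ** 2).sum(axis=1) / (2.0 * scale**2)
    )
    log_w = log_lik + log_prior - log_q
    return float(logsumexp(log_w) - np.log(S))


def logpx_score(
    model, bag: FeatureBag, S: int = 1, aggregator: str = "mean", rng=None
) -> OODScoreResult:
    """Tailored probabilistic OOD score: instance-wise -log p(x_i).

    The S standard-normal draws are shared across the instances of the
    bag (common random numbers): each per-instance estimate is still a
    valid importance-sampling estimate, the bag-level score becomes
    invariant to instance order, and instance scores are directly
    comparable within the bag.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ae = getattr(model, "autoencoder", model)
    X = bag.features.astype(np.float64)
    N, P = X.shape
    means, scales = ae.encode_np(X)  # (N, D), (N, 1)
    D = means.shape[1]
    eps = rng.standard_normal((S, D))
    Z = means[None, :, :] + scales[None, :, :] * eps[:, None, :]  # (S, N, D)
    dec_means, dec_vars = ae.decode_np(Z.reshape(S * N, D))
    dec_means = dec_means.reshape(S, N, P)
    dec_vars = dec_vars.reshape(S, N)
    log_lik = -0.5 * P * (np.log(2 * np.pi) + np.log(dec_vars)) - (
        ((X[None, :, :] - dec_means) ** 2).sum(axis=2) / (2.0 * dec_vars)
    )
    log_prior = -0.5 * D * np.log(2 * np.pi) - 0.5 * (Z**2).sum(axis=2)
    # log q(z|x) with z = m + s*eps: the quadratic term reduces to |eps|^2/2
    log_q = (
        -0.5 * D * np.log(2 * np.pi)
        - D * np.log(scales[:, 0])[None, :]
        - 0.5 * (eps**2).sum(axis=1)[:, None]
    )
    log_w = log_lik + log_prior - log_q  # (S, N)
    scores = -(logsumexp(log_w, axis=0) - np.log(S))
    return OODScoreResult(
        bag_id=bag.bag_id,
        score_name="logpx",
        aggregator=aggregator,
        bag_score=_aggregate(scores, aggregator),
        instance_scores=scores,
    )


def recerr_score(model, bag: FeatureBag, aggregator: str = "mean") -> OODScoreResult:
    """Tailored deterministic OOD score: squared reconstruction error."""
    ae = getattr(model, "autoencoder", model)
    X = bag.features.astype(np.float64)
    means, _ = ae.encode_np(X)
    recon, _ = ae.decode_np(means)
    scores = ((X - recon) ** 2).sum(axis=1)
    return OODScoreResult(
        bag_id=bag.bag_id,
        score_name="recerr",
        aggregator=aggregator,
        bag_score=_aggregate(scores, aggregator),
        instance_scores=scores,
    )


def entropy_score(probability: float) -> float:
    """Shannon entropy of the bag prediction; maximal at p = 0.5."""
    p = float(np.clip(probability, 1e-12, 1.0 - 1e-12))
    return float(-(p * np.log(p) + (1.0 - p) * np.log(1.0 - p)))


def mls_score(logit: float) -> float:
    """Negative absolute logit: confident predictions (large |logit|)
    score low, ambiguous ones score high."""
    if not np.isfinite(logit):
        raise ValueError("logit must be finite")
    return -abs(float(logit))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg), ties credited 0.5."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


def _bag_logit(model, bag: FeatureBag, S: int, rng) -> float:
    """Bag logit for the post-hoc scores (probability back-mapped)."""
    p = model.predict_bag(bag, S=S, rng=rng) if model.is_probabilistic else model.predict_bag(bag)
    p = float(np.clip(p, 1e-12, 1.0 - 1e-12))
    return float(np.log(p / (1.0 - p)))


def evaluate_ood(
    model,
    ind_bags: list[FeatureBag],
    ood_bags: list[FeatureBag],
    score_specs: list[tuple[str, str]] | None = None,
    S: int = 32,
    rng=None,
) -> pd.DataFrame:
    """AUC of each requested score at separating OOD (1) from IND (0).

    ``score_specs`` is a list of (score_name, aggregator); aggregator
    is ignored ("none") for the post-hoc scores.  Default: the model's
    tailored score with mean aggregation plus both post-hoc baselines.
    """
    if not ind_bags or not ood_bags:
        raise ValueError("both IND and OOD bag sets must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if score_specs is None:
        tailored = "logpx" if model.is_probabilistic else "recerr"
        score_specs = [(tailored, "mean"), ("entropy", "none"), ("mls", "none")]
    labels = np.concatenate([np.zeros(len(ind_bags)), np.ones(len(ood_bags))])
    all_bags = list(ind_bags) + list(ood_bags)
    rows = []
    for name, aggregator in score_specs:
        if name == "logpx":
            if not model.is_probabilistic:
                raise ValueError("logpx requires the probabilistic (VAE) model")
            scores = [
                logpx_score(model, b, S=S, aggregator=aggregator, rng=rng).bag_score
                for b in all_bags
            ]
        elif name == "recerr":
            scores = [recerr_score(model, b, aggregator=aggregator).bag_score for b in all_bags]
        elif name == "entropy":
            aggregator = "none"
            scores = [
                entropy_score(1.0 / (1.0 + np.exp(-_bag_logit(model, b, S, rng))))
                for b in all_bags
            ]
        elif name == "mls":
            aggregator = "none"
            scores = [mls_score(_bag_logit(model, b, S, rng)) for b in all_bags]
        else:
            raise ValueError(f"unknown score {name!r}")
        rows.append(
            {
                "score_name": name,
                "aggregator": aggregator,
                "auc": auc(np.array(scores), labels),
                "n_ind": len(ind_bags),
                "n_ood": len(ood_bags),
            }
        )
    return pd.DataFrame(rows)


def export_instance_scores(result: OODScoreResult, path, instance_ids=None) -> None:
    """Write raw per-instance scores as CSV (no normalization applied)."""
    if result.instance_scores is None:
        raise ValueError("result has no instance scores")
    n = len(result.instance_scores)
    if instance_ids is None:
        instance_ids = [f"{result.bag_id}:{i}" for i in range(n)]
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["bag_id", "instance_index", "instance_id", "score"])
        for i, (iid, s) in enumerate(zip(instance_ids, result.instance_scores)):
            writer.writerow([result.bag_id, i, iid, repr(float(s))])
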