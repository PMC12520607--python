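"""OOD-aware attention-MIL models with a variational or deterministic
autoencoder as the feature refiner.

Two models are provided, both sharing one architecture (Gaussian
autoencoder + attention pooling + linear bag classifier):

``VAEAttentionMIL``
    Joint probabilistic model: the bag label depends on the instances
    only through their random latent codes.  Trained by maximizing the
    ELBO, whose negative decomposes into a bag-classification NLL, an
    expected reconstruction NLL, and a closed-form KL to the N(0, I)
    prior.  Predictions average the classifier output over S posterior
    samples; the marginal likelihood of each instance supplies an OOD
    score.

``DeterministicAEAttentionMIL``
    The posterior collapsed to its mean (a Dirac delta): a weighted sum
    of classification NLL, squared reconstruction error, and a latent
    L2 penalty.  With reconstruction and latent weights at zero it is
    exactly classical attention-based MIL; the reconstruction error
    supplies its OOD score.

Both expose a statsmodels-style surface: construct from bags, call
``fit`` to get a :class:`MILResults` with the training log, the
selected epoch (highest validation AUC), and prediction helpers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .attention import attend_pool, attention_scores, classify, classification_nll_t
from .attention import AttentionParams, ClassifierParams
from .autodiff import Tensor, bce_with_logits, constant
from .bags import FeatureBag
from .variational import (
    Autoencoder,
    LOG_2PI,
    SCALE_FLOOR,
    _init_linear,
)

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "VAEAttentionMIL",
    "DeterministicAEAttentionMIL",
    "MILResults",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the reference training recipe: Adam at learning
    rate 1e-4, one bag per step, 100 epochs with no early stopping,
    single-sample Monte Carlo estimates, loss weights mu=1 and
    alpha=beta=0.3 for the deterministic model, and a 20% stratified
    validation split used to select the best epoch by validation AUC.
    """

    epochs: int = 100
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    S_train: int = 1
    S_test: int = 1
    mu: float = 1.0
    alpha: float = 0.3
    beta: float = 0.3
    val_fraction: float = 0.2
    instance_term_reduction: str = "sum"
    n_restarts: int = 1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or not (0 < self.val_fraction < 1):
            raise ValueError("learning_rate and val_fraction must be positive")
        if self.instance_term_reduction not in ("sum", "mean"):
            raise ValueError("instance_term_reduction must be 'sum' or 'mean'")
        if min(self.mu, self.alpha, self.beta) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.S_train < 1 or self.S_test < 1:
            raise ValueError("S_train and S_test must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class LossBreakdown:
    """The three loss terms (unweighted) and their weighted total."""

    classification_term: float
    reconstruction_term: float
    kl_or_latent_term: float
    total: float
    weights: tuple = (1.0, 1.0, 1.0)


class _Adam:
    """Adam over a flat name -> array parameter dict."""

    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _MILModelBase:
    """Shared architecture, parameter handling, and training loop."""

    is_probabilistic: bool

    def __init__(
        self,
        bags: list[FeatureBag] | None = None,
        *,
        n_features: int | None = None,
        layer_sizes: tuple = (512, 256, 128),
        attention_dim: int = 128,
    ):
        if bags is not None:
            if not bags:
                raise ValueError("empty bag list")
            n_features = bags[0].n_features
            if any(b.n_features != n_features for b in bags):
                raise ValueError("bags have inconsistent feature dimension")
        if n_features is None:
            raise ValueError("provide bags or n_features")
        self.bags = bags
        self.autoencoder = Autoencoder(n_features=n_features, layer_sizes=layer_sizes)
        self.attention_dim = int(attention_dim)
        self.params: dict[str, np.ndarray] = {}

    # -- basic properties ------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.autoencoder.n_features

    @property
    def latent_dim(self) -> int:
        return self.autoencoder.latent_dim

    def initialize(self, seed_or_rng=0) -> "_MILModelBase":
        rng = np.random.default_rng(seed_or_rng)
        self.autoencoder.initialize(rng)
        p = self.autoencoder.params
        p["att_W"], _ = _init_linear(rng, self.attention_dim, self.latent_dim)
        p["att_w"] = _init_linear(rng, 1, self.attention_dim)[0][0]
        p["cls_w"] = _init_linear(rng, 1, self.latent_dim)[0][0]
        p["cls_b"] = np.zeros(())
        self.params = p
        return self

    def _require_params(self):
        if not self.params:
            raise RuntimeError("model parameters not initialized; call initialize()")

    def _leaves(self) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=True) for k, v in self.params.items()}

    def attention_params(self) -> AttentionParams:
        self._require_params()
        return AttentionParams(W=self.params["att_W"], w=self.params["att_w"])

    def classifier_params(self) -> ClassifierParams:
        self._require_params()
        return ClassifierParams(
            weight=self.params["cls_w"], bias=float(self.params["cls_b"])
        )

    def _forward_logit(self, Z: np.ndarray) -> float:
        """Deterministic attention pool + classify on given embeddings."""
        att = self.attention_params()
        out = attention_scores(Z, att)
        pooled = attend_pool(Z, out.raw_scores)
        return classify(pooled.bag_representation, self.classifier_params())[0]

    # -- training --------------------------------------------------------
    def fit(self, config: TrainConfig | None = None, bags=None) -> "MILResults":
        """Train with one bag per optimizer step and select the epoch
        with the highest validation classification AUC (earliest on ties).

        With ``config.n_restarts > 1`` the whole run is repeated from
        independent initializations (on the same split) and the run
        with the best validation AUC is kept -- the same selection rule
        applied across restarts instead of only across epochs.  This
        guards against the occasional optimization failure of the joint
        classification + reconstruction objective.
        """
        config = config or TrainConfig()
        bags = bags if bags is not None else self.bags
        if not bags:
            raise ValueError("no bags to train on")
        ss = np.random.SeedSequence(config.seed)
        seed_split = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        restart_seeds = ss.spawn(config.n_restarts)

        train_bags = [b for b in bags if b.split == "train"]
        val_bags = [b for b in bags if b.split == "val"]
        if not val_bags:
            train_bags, val_bags = _stratified_bag_split(
                train_bags or [b for b in bags if b.split in (None, "train")],
                config.val_fraction,
                seed_split,
            )
        if any(b.label is None for b in train_bags + val_bags):
            raise ValueError("all train/val bags must be labelled")
        labels = {b.label for b in train_bags}
        if labels != {0, 1}:
            raise ValueError("training data must contain both classes")

        best = None
        for r_ss in restart_seeds:
            run = self._fit_once(config, train_bags, val_bags, r_ss)
            if best is None or run[1] > best[1]:
                best = run
        best_params, best_auc, best_epoch, history = best
        self.params = best_params
        self.autoencoder.params = best_params
        return MILResults(
            model=self,
            config=config,
            history=pd.DataFrame(history),
            selected_epoch=best_epoch,
            val_auc=best_auc,
            train_bags=train_bags,
            val_bags=val_bags,
        )

    def _fit_once(self, config, train_bags, val_bags, seed_seq):
        seed_init, seed_shuffle, seed_mc = (
            int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(3)
        )
        self.initialize(seed_init)
        opt = _Adam(self.params, lr=config.learning_rate)
        rng_shuffle = np.random.default_rng(seed_shuffle)
        rng_mc = np.random.default_rng(seed_mc)

        history = []
        best_auc, best_epoch, best_params = -np.inf, -1, None
        val_labels = np.array([b.label for b in val_bags])
        for epoch in range(config.epochs):
            order = rng_shuffle.permutation(len(train_bags))
            losses = []
            for idx in order:
                bag = train_bags[idx]
                loss_t, leaves = self._loss_tensor(bag, config, rng_mc)
                loss_t.backward()
                grads = {k: t.grad for k, t in leaves.items() if t.grad is not None}
                opt.step(self.params, grads)
                losses.append(float(loss_t.value))
            val_probs = np.array(
                [self.predict_bag(b, S=config.S_test, rng=rng_mc) for b in val_bags]
            )
            val_auc = float(roc_auc_score(val_labels, val_probs))
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
            )
            if val_auc > best_auc:
                best_auc, best_epoch = val_auc, epoch
                best_params = {k: v.copy() for k, v in self.params.items()}
        return best_params, best_auc, best_epoch, history

    # subclasses implement
    def _loss_tensor(self, bag, config, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_bag(self, bag, S: int = 1, rng=None) -> float:  # pragma: no cover
        raise NotImplementedError


def _stratified_bag_split(bags, val_fraction: float, seed: int):
    """In-memory stratified train/val partition of labelled bags."""
    if len(bags) < 2:
        raise ValueError("need at least 2 bags to split")
    n_val = int(round(val_fraction * len(bags)))
    if n_val < 1 or n_val >= len(bags):
        raise ValueError(f"val_fraction {val_fraction} infeasible for {len(bags)} bags")
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, b in enumerate(bags):
        by_label.setdefault(int(b.label), []).append(i)
    val_idx: list[int] = []
    for lab in sorted(by_label):
        idx = np.array(by_label[lab])
        k = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(rng.permutation(idx)[:k].tolist())
    val_set = set(val_idx)
    train = [b for i, b in enumerate(bags) if i not in val_set]
    val = [b for i, b in enumerate(bags) if i in val_set]
    for b in train:
        b.split = "train"
    for b in val:
        b.split = "val"
    return train, val


class VAEAttentionMIL(_MILModelBase):
    """Variational autoencoder + attention MIL (probabilistic model)."""

    is_probabilistic = True

    def loss(
        self, bag: FeatureBag, S: int = 1, rng=None, reduction: str = "sum"
    ) -> LossBreakdown:
        """Negative ELBO of one labelled bag (see ``_loss_tensor``)."""
        self._require_params()
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        cfg = TrainConfig(S_train=S, instance_term_reduction=reduction)
        loss_t, _ = self._loss_tensor(bag, cfg, rng, build_graph=False)
        return self._last_breakdown

    def _loss_tensor(self, bag: FeatureBag, config: TrainConfig, rng, build_graph=True):
        if bag.label is None:
            raise ValueError(f"bag {bag.bag_id!r} has no label; cannot train on it")
        S = config.S_train
        N, P = bag.features.shape
        D = self.latent_dim
        leaves = self._leaves()
        X = constant(bag.features.astype(np.float64))
        means, scales = self.autoencoder.encode_t(X, leaves)
        # closed-form KL per instance, summed over the bag
        kl = (
            means.square().sum()
            + (scales.square() * float(D)).sum()
            - float(N * D)
            - (scales.log() * (2.0 * D)).sum()
        ) * 0.5
        class_terms = []
        recon_terms = []
        for _ in range(S):
            eps = constant(rng.standard_normal((N, D)))
            Z = means + scales * eps  # reparameterized joint draw for the bag
            dec_means, dec_vars = self.autoencoder.decode_t(Z, leaves)
            log_px = (
                (dec_vars.log() + LOG_2PI) * (-0.5 * P)
            ).sum() - (
                (X - dec_means).square().sum(axis=1, keepdims=True) / (dec_vars * 2.0)
            ).sum()
            recon_terms.append(-log_px)
            class_terms.append(
                classification_nll_t(
                    Z, bag.label, leaves["att_W"], leaves["att_w"],
                    leaves["cls_w"], leaves["cls_b"],
                )
            )
        class_nll = _mean_tensors(class_terms)
        recon_nll = _mean_tensors(recon_terms)
        if config.instance_term_reduction == "mean":
            recon_nll = recon_nll * (1.0 / N)
            kl = kl * (1.0 / N)
        total = class_nll + recon_nll + kl
        self._last_breakdown = LossBreakdown(
            classification_term=float(class_nll.value),
            reconstruction_term=float(recon_nll.value),
            kl_or_latent_term=float(kl.value),
            total=float(total.value),
            weights=(1.0, 1.0, 1.0),
        )
        return total, leaves

    def predict_bag(
        self, bag: FeatureBag, S: int = 1, rng=None, use_posterior_mean: bool = False
    ) -> float:
        """Monte-Carlo bag probability: mean over S joint posterior draws."""
        self._require_params()
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        if S < 1:
            raise ValueError("S must be >= 1")
        means, scales = self.autoencoder.encode_np(bag.features)
        if use_posterior_mean:
            logit = self._forward_logit(means)
            return 1.0 / (1.0 + np.exp(-logit))
        probs = []
        for _ in range(S):
            Z = means + scales * rng.standard_normal(means.shape)
            logit = self._forward_logit(Z)
            probs.append(1.0 / (1.0 + np.exp(-logit)))
        return float(np.mean(probs))


class DeterministicAEAttentionMIL(_MILModelBase):
    """Deterministic autoencoder + attention MIL.

    The latent code of each instance is the encoder mean; the loss is
    mu * classification NLL + alpha * sum_i ||x_i - dec(z_i)||^2
    + beta * sum_i ||z_i||^2.  With alpha = beta = 0 this is exactly
    classical attention-based MIL.
    """

    is_probabilistic = False

    def loss(
        self,
        bag: FeatureBag,
        weights: tuple[float, float, float] = (1.0, 0.3, 0.3),
        reduction: str = "sum",
    ) -> LossBreakdown:
        self._require_params()
        mu, alpha, beta = weights
        cfg = TrainConfig(mu=mu, alpha=alpha, beta=beta, instance_term_reduction=reduction)
        self._loss_tensor(bag, cfg, rng=None)
        return self._last_breakdown

    def _loss_tensor(self, bag: FeatureBag, config: TrainConfig, rng, build_graph=True):
        if bag.label is None:
            raise ValueError(f"bag {bag.bag_id!r} has no label; cannot train on it")
        N = bag.n_instances
        leaves = self._leaves()
        X = constant(bag.features.astype(np.float64))
        Z, _ = self.autoencoder.encode_t(X, leaves)  # scale head unused
        dec_means, _ = self.autoencoder.decode_t(Z, leaves)
        class_nll = classification_nll_t(
            Z, bag.label, leaves["att_W"], leaves["att_w"],
            leaves["cls_w"], leaves["cls_b"],
        )
        recon = (X - dec_means).square().sum()
        latent = Z.square().sum()
        if config.instance_term_reduction == "mean":
            recon = recon * (1.0 / N)
            latent = latent * (1.0 / N)
        total = class_nll * config.mu + recon * config.alpha + latent * config.beta
        self._last_breakdown = LossBreakdown(
            classification_term=float(class_nll.value),
            reconstruction_term=float(recon.value),
            kl_or_latent_term=float(latent.value),
            total=float(total.value),
            weights=(config.mu, config.alpha, config.beta),
        )
        return total, leaves

    def predict_bag(self, bag: FeatureBag, S: int = 1, rng=None) -> float:
        """Deterministic forward pass through encoder means."""
        self._require_params()
        means, _ = self.autoencoder.encode_np(bag.features)
        logit = self._forward_logit(means)
        return float(1.0 / (1.0 + np.exp(-logit)))


def _mean_tensors(terms: list[Tensor]) -> Tensor:
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


@dataclass
class MILResults:
    """Fitted-model results: training log and prediction helpers."""

    model: _MILModelBase
    config: TrainConfig
    history: pd.DataFrame
    selected_epoch: int
    val_auc: float
    train_bags: list = field(default_factory=list, repr=False)
    val_bags: list = field(default_factory=list, repr=False)

    def predict(self, bags: list[FeatureBag], S: int | None = None, rng=None):
        """Bag probabilities for a list of bags."""
        S = S if S is not None else self.config.S_test
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return np.array([self.model.predict_bag(b, S=S, rng=rng) for b in bags])

    def classification_auc(self, bags: list[FeatureBag], S: int | None = None, rng=None):
        labels = np.array([b.label for b in bags])
        return float(roc_auc_score(labels, self.predict(bags, S=S, rng=rng)))

    def summary(self) -> str:
        cls = type(self.model).__name__
        lines = [
            f"{cls} fit results",
            "=" * 40,
            f"feature dim (P):        {self.model.n_features}",
            f"latent dim (D):         {self.model.latent_dim}",
            f"attention width (L):    {self.model.attention_dim}",
            f"epochs trained:         {len(self.history)}",
            f"selected epoch:         {self.selected_epoch}",
            f"best validation AUC:    {self.val_auc:.4f}",
            f"final train loss:       {self.history['train_loss'].iloc[-1]:.4f}",
            f"train / val bags:       {len(self.train_bags)} / {len(self.val_bags)}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        save_checkpoint(self, path)


def save_checkpoint(results: MILResults, path) -> None:
    """Single-file checkpoint: parameters + config echo + training log."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_class": type(results.model).__name__,
        "n_features": results.model.n_features,
        "layer_sizes": list(results.model.autoencoder.layer_sizes),
        "attention_dim": results.model.attention_dim,
        "config": asdict(results.config),
        "selected_epoch": int(results.selected_epoch),
        "val_auc": float(results.val_auc),
        "history": results.history.to_dict(orient="list"),
    }
    np.savez(
        path,
        _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **results.model.params,
    )


def load_checkpoint(path) -> MILResults:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"].tobytes()).decode())
        params = {k: data[k].copy() for k in data.files if k != "_meta"}
    if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
    cls = {
        "VAEAttentionMIL": VAEAttentionMIL,
        "DeterministicAEAttentionMIL": DeterministicAEAttentionMIL,
    }[meta["model_class"]]
    model = cls(
        n_features=meta["n_features"],
        layer_sizes=tuple(meta["layer_sizes"]),
        attention_dim=meta["attention_dim"],
    )
    model.params = params
    model.autoencoder.params = params
    return MILResults(
        model=model,
        config=TrainConfig(**meta["config"]),
        history=pd.DataFrame(meta["history"]),
        selected_epoch=meta["selected_epoch"],
        val_auc=meta["val_auc"],
    )
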