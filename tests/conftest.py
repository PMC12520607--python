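import numpy as np
import pytest

from vaemil import (
    FeatureBag,
    VAEAttentionMIL,
    DeterministicAEAttentionMIL,
    train_benchmark_models,
)

BENCH_SEEDS = (1, 2, 3)


class LinearGaussianVAE:
    """Synthetic linear-Gaussian stand-in with a known marginal likelihood.

    Decoder mean W z + b with fixed observation variance sigma2; the
    columns of W are orthogonal with equal squared norm c, so the exact
    posterior N( W^T (x - b) / (sigma2 + c), sigma2/(sigma2+c) I ) is
    isotropic and representable by the shared-scale posterior family.
    ``scale_mult`` / ``mean_bias`` perturb the posterior away from
    exactness to exercise the importance-sampling estimator.
    """

    is_probabilistic = True

    def __init__(self, P=10, d=2, sigma2=0.5, col_norm2=4.0, seed=0,
                 scale_mult=1.0, mean_bias=0.0):
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.standard_normal((P, d)))
        self.W = Q * np.sqrt(col_norm2)
        self.b = rng.standard_normal(P)
        self.sigma2 = float(sigma2)
        self.c = float(col_norm2)
        self.scale_mult = float(scale_mult)
        self.mean_bias = float(mean_bias)
        self.autoencoder = self

    def encode_np(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean = (X - self.b) @ self.W / (self.sigma2 + self.c) + self.mean_bias
        s = np.sqrt(self.sigma2 / (self.sigma2 + self.c)) * self.scale_mult
        return mean, np.full((X.shape[0], 1), s)

    def decode_np(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.W.T + self.b, np.full((Z.shape[0], 1), self.sigma2)

    def log_marginal(self, x):
        from scipy.stats import multivariate_normal

        cov = self.W @ self.W.T + self.sigma2 * np.eye(self.W.shape[0])
        return float(multivariate_normal(mean=self.b, cov=cov).logpdf(x))

    def sample_x(self, n, rng):
        d = self.W.shape[1]
        Z = rng.standard_normal((n, d))
        eps = rng.standard_normal((n, self.W.shape[0]))
        return Z @ self.W.T + self.b + np.sqrt(self.sigma2) * eps


def make_small_vae(n_features=6, sizes=(12, 8), attention_dim=8, seed=0):
    return VAEAttentionMIL(
        n_features=n_features, layer_sizes=sizes, attention_dim=attention_dim
    ).initialize(seed)


def make_small_dae(n_features=6, sizes=(12, 8), attention_dim=8, seed=0):
    return DeterministicAEAttentionMIL(
        n_features=n_features, layer_sizes=sizes, attention_dim=attention_dim
    ).initialize(seed)


def random_bag(rng, n_instances=5, n_features=6, label=1, bag_id="bag"):
    return FeatureBag(
        bag_id=bag_id,
        features=rng.standard_normal((n_instances, n_features)),
        label=label,
    )


@pytest.fixture(scope="session")
def benchmark_runs():
    """Both models trained on the standard synthetic benchmark for
    three dataset seeds; shared across the recovery-style tests."""
    return {seed: train_benchmark_models(seed) for seed in BENCH_SEEDS}
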