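"""Gaussian autoencoder primitives: encoder/decoder MLPs, the
reparameterization trick, closed-form KL against the N(0, I) prior, and
isotropic Gaussian log-densities.

The variational posterior q(z|x) = N(m(x), s(x)^2 I) uses a *single*
scale shared across all latent dimensions, predicted per instance; the
decoder likelihood p(x|z) = N(m_dec(z), v(z) I) mirrors this with one
variance shared across the feature dimensions.  Positivity of both is
enforced with softplus plus a small floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, constant

__all__ = [
    "SCALE_FLOOR",
    "VARIANCE_FLOOR",
    "GaussianPosterior",
    "DecoderOutput",
    "Autoencoder",
    "gaussian_log_density",
    "kl_standard_normal",
    "sample_posterior",
]

SCALE_FLOOR = 1e-6
VARIANCE_FLOOR = 1e-6
LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianPosterior:
    """Per-instance variational posterior N(mean, scale^2 I)."""

    mean: np.ndarray
    scale: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if self.scale < SCALE_FLOOR:
            raise ValueError(f"posterior scale {self.scale} below floor {SCALE_FLOOR}")


@dataclass
class DecoderOutput:
    """Decoder observation model N(mean, variance I) for one instance."""

    mean: np.ndarray
    variance: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if self.variance < VARIANCE_FLOOR:
            raise ValueError(f"decoder variance {self.variance} below floor")


def gaussian_log_density(x, mean, variance: float) -> float:
    """log N(x; mean, variance * I) for an n-vector x and scalar variance."""
    x = np.asarray(x, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    if x.shape != mean.shape:
        raise ValueError("x and mean must have equal length")
    if variance <= 0:
        raise ValueError("variance must be positive")
    n = x.size
    return float(-0.5 * n * (LOG_2PI + np.log(variance)) - ((x - mean) ** 2).sum() / (2.0 * variance))


def kl_standard_normal(post: GaussianPosterior) -> float:
    """Closed-form KL( N(mean, scale^2 I) || N(0, I) ), always >= 0."""
    m, s = post.mean, post.scale
    d = m.size
    return float(0.5 * ((m**2).sum() + d * (s**2 - 1.0 - 2.0 * np.log(s))))


def sample_posterior(
    post: GaussianPosterior, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw S reparameterized samples z_s = mean + scale * eps_s, (S, D)."""
    if S < 1:
        raise ValueError("S must be >= 1")
    eps = rng.standard_normal((S, post.mean.size))
    return post.mean[None, :] + post.scale * eps


def _init_linear(rng: np.random.Generator, n_out: int, n_in: int):
    """Glorot-uniform weight and zero bias."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    W = rng.uniform(-limit, limit, size=(n_out, n_in))
    b = np.zeros(n_out)
    return W, b


@dataclass
class Autoencoder:
    """Parameter container + forward passes for the Gaussian autoencoder.

    ``layer_sizes`` lists the encoder layer output widths; the last entry
    is the latent dimension D.  The decoder mirrors the encoder.  ReLU
    between linear layers.  Parameters live in ``params`` as a flat
    name -> float64 array dict so one optimizer can drive the whole model.
    """

    n_features: int
    layer_sizes: tuple = (512, 256, 128)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) < 1:
            raise ValueError("layer_sizes must be non-empty")

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[-1]

    @property
    def hidden_sizes(self) -> tuple:
        return self.layer_sizes[:-1]

    def initialize(self, rng: np.random.Generator) -> "Autoencoder":
        p: dict[str, np.ndarray] = {}
        # encoder trunk
        widths = (self.n_features, *self.hidden_sizes)
        for i in range(len(widths) - 1):
            p[f"enc_W{i}"], p[f"enc_b{i}"] = _init_linear(rng, widths[i + 1], widths[i])
        h = widths[-1]
        p["enc_mean_W"], p["enc_mean_b"] = _init_linear(rng, self.latent_dim, h)
        p["enc_scale_W"], p["enc_scale_b"] = _init_linear(rng, 1, h)
        # decoder trunk mirrors the encoder
        dwidths = (self.latent_dim, *reversed(self.hidden_sizes))
        for i in range(len(dwidths) - 1):
            p[f"dec_W{i}"], p[f"dec_b{i}"] = _init_linear(rng, dwidths[i + 1], dwidths[i])
        dh = dwidths[-1]
        p["dec_mean_W"], p["dec_mean_b"] = _init_linear(rng, self.n_features, dh)
        p["dec_var_W"], p["dec_var_b"] = _init_linear(rng, 1, dh)
        self.params = p
        return self

    # -- numpy forward passes -------------------------------------------
    def _trunk_np(self, X: np.ndarray, prefix: str, n_layers: int) -> np.ndarray:
        H = X
        for i in range(n_layers):
            H = H @ self.params[f"{prefix}_W{i}"].T + self.params[f"{prefix}_b{i}"]
            H = np.maximum(H, 0.0)
        return H

    def encode_np(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters for a batch: means (N, D), scales (N, 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-dim features, got {X.shape[1]}"
            )
        H = self._trunk_np(X, "enc", len(self.hidden_sizes))
        means = H @ self.params["enc_mean_W"].T + self.params["enc_mean_b"]
        raw = H @ self.params["enc_scale_W"].T + self.params["enc_scale_b"]
        scales = _softplus_np(raw) + SCALE_FLOOR
        return means, scales

    def decode_np(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Decoder parameters for a batch: means (N, P), variances (N, 1)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(
                f"expected {self.latent_dim}-dim latents, got {Z.shape[1]}"
            )
        H = self._trunk_np(Z, "dec", len(self.hidden_sizes))
        means = H @ self.params["dec_mean_W"].T + self.params["dec_mean_b"]
        raw = H @ self.params["dec_var_W"].T + self.params["dec_var_b"]
        variances = _softplus_np(raw) + VARIANCE_FLOOR
        return means, variances

    def encode(self, x: np.ndarray) -> GaussianPosterior:
        means, scales = self.encode_np(np.asarray(x)[None, :])
        return GaussianPosterior(mean=means[0], scale=float(scales[0, 0]))

    def decode(self, z: np.ndarray) -> DecoderOutput:
        means, variances = self.decode_np(np.asarray(z)[None, :])
        return DecoderOutput(mean=means[0], variance=float(variances[0, 0]))

    # -- differentiable forward passes ----------------------------------
    def _trunk_t(self, X: Tensor, pt: dict, prefix: str, n_layers: int) -> Tensor:
        H = X
        for i in range(n_layers):
            H = (H @ pt[f"{prefix}_W{i}"].T + pt[f"{prefix}_b{i}"]).relu()
        return H

    def encode_t(self, X: Tensor, pt: dict) -> tuple[Tensor, Tensor]:
        H = self._trunk_t(X, pt, "enc", len(self.hidden_sizes))
        means = H @ pt["enc_mean_W"].T + pt["enc_mean_b"]
        scales = (H @ pt["enc_scale_W"].T + pt["enc_scale_b"]).softplus() + SCALE_FLOOR
        return means, scales

    def decode_t(self, Z: Tensor, pt: dict) -> tuple[Tensor, Tensor]:
        H = self._trunk_t(Z, pt, "dec", len(self.hidden_sizes))
        means = H @ pt["dec_mean_W"].T + pt["dec_mean_b"]
        variances = (H @ pt["dec_var_W"].T + pt["dec_var_b"]).softplus() + VARIANCE_FLOOR
        return means, variances


def _softplus_np(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
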