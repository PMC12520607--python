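"""Synthetic feature-bag generator.

Emulates the statistical structure of whole-slide-image patch feature
bags: instance feature vectors live near a low-rank linear manifold
(x = A h + noise, with h a latent factor of small rank), instance
classes are Gaussian clusters in latent space separated by a
controllable distance, and bags are labelled by the standard MIL rule
(positive iff at least one instance is positive).  OOD sets are
produced by shifting the latent factors before mixing: a whole-bag
shift of small magnitude emulates Near-OOD (similar tissue), a large
one Far-OOD (different tissue), and shifting only a subset of the
instances emulates slide artifacts covering part of a slide.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .bags import DatasetManifest, FeatureBag, ManifestEntry, write_bag, write_manifest

__all__ = [
    "SimulationConfig",
    "ShiftSpec",
    "SHIFT_PRESETS",
    "simulate_ind_dataset",
    "simulate_ood_dataset",
    "write_dataset",
    "benchmark_suite",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``class_separation`` is the distance between the negative and
    positive instance-class centroids in latent units (the latent
    within-class standard deviation is 1); ``witness_rate`` is the
    fraction of positive instances inside each positive bag.
    """

    n_bags: int
    P: int = 64
    latent_rank: int = 8
    bag_size_range: tuple[int, int] = (20, 80)
    witness_rate: float = 0.2
    class_separation: float = 4.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid bag_size_range {self.bag_size_range}")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.n_bags < 1 or self.P < 1 or self.latent_rank < 1:
            raise ValueError("n_bags, P and latent_rank must be positive")
        if self.class_separation < 0 or self.noise_scale < 0:
            raise ValueError("class_separation and noise_scale must be >= 0")


@dataclass(frozen=True)
class ShiftSpec:
    """Distribution shift applied in latent space to create OOD bags."""

    mode: str = "whole_bag"  # whole_bag | instance_subset
    magnitude: float = 8.0  # shift length in latent units
    contaminated_fraction: float = 0.15  # instance_subset only
    direction_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("whole_bag", "instance_subset"):
            raise ValueError(f"unknown shift mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if not 0.0 < self.contaminated_fraction <= 1.0:
            raise ValueError("contaminated_fraction must be in (0, 1]")


# Near: overlapping instance-score densities; Far: well separated;
# artifact: a contaminated patch subset, like slide artifacts covering
# a minority of a slide.
SHIFT_PRESETS = {
    "near": ShiftSpec(mode="whole_bag", magnitude=2.0),
    "far": ShiftSpec(mode="whole_bag", magnitude=8.0),
    "artifact": ShiftSpec(mode="instance_subset", magnitude=8.0, contaminated_fraction=0.15),
}


def _geometry(config: SimulationConfig):
    """Seed-fixed mixing map A (P, r) and class-separation direction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11A]))
    A = rng.standard_normal((config.P, config.latent_rank)) / math.sqrt(
        config.latent_rank
    )
    u = rng.standard_normal(config.latent_rank)
    u /= np.linalg.norm(u)
    return A, u


def _draw_bags(config: SimulationConfig, n_bags: int, rng, prefix: str):
    """Latent factors + instance labels for n_bags bags (pre-mixing).

    Half of the bags are positive; positive bags contain
    ceil(witness_rate * N_b) positive instances (always >= 1).
    """
    _, u_sep = _geometry(config)
    lo, hi = config.bag_size_range
    out = []
    for b in range(n_bags):
        bag_label = int(b % 2 == 1)  # half the bags positive
        n = int(rng.integers(lo, hi + 1))
        n_pos = max(1, math.ceil(config.witness_rate * n)) if bag_label else 0
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:n_pos]] = 1
        H = rng.standard_normal((n, config.latent_rank))
        H[labels == 1] += config.class_separation * u_sep
        out.append((f"{prefix}{b:04d}", H, labels))
    return out


def _mix(config: SimulationConfig, H: np.ndarray, rng) -> np.ndarray:
    A, _ = _geometry(config)
    noise = config.noise_scale * rng.standard_normal((H.shape[0], config.P))
    return (H @ A.T + noise).astype(np.float32)


def simulate_ind_dataset(
    config: SimulationConfig, split: str = "train", prefix: str | None = None
) -> list[FeatureBag]:
    """In-distribution bags; every bag satisfies y = max(instance labels)."""
    prefix = prefix if prefix is not None else f"{split}-"
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(split.encode()), 0x1D])
    )
    bags = []
    for bag_id, H, labels in _draw_bags(config, config.n_bags, rng, prefix):
        X = _mix(config, H, rng)
        bags.append(
            FeatureBag(
                bag_id=bag_id,
                features=X,
                label=int(labels.max()),
                split=split,
                instance_labels=labels,
            )
        )
    return bags


def simulate_ood_dataset(
    config: SimulationConfig, shift: ShiftSpec, n_bags: int | None = None
) -> list[FeatureBag]:
    """OOD bags: same generative process and mixing map as the IND
    dataset of ``config``, with latent factors displaced by the shift.

    At magnitude 0 the IND distribution is reproduced exactly.  OOD
    bags carry no label (OOD detection is a test-time task).
    """
    n_bags = n_bags if n_bags is not None else config.n_bags
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x00D, 0x2F]))
    dir_rng = np.random.default_rng(
        np.random.SeedSequence([shift.direction_seed, 0xD12])
    )
    direction = dir_rng.standard_normal(config.latent_rank)
    direction /= np.linalg.norm(direction)
    bags = []
    for bag_id, H, _labels in _draw_bags(config, n_bags, rng, "ood-"):
        H = H.copy()
        if shift.mode == "whole_bag":
            H += shift.magnitude * direction
        else:
            n = H.shape[0]
            k = max(1, math.ceil(shift.contaminated_fraction * n))
            idx = rng.permutation(n)[:k]
            H[idx] += shift.magnitude * direction
        X = _mix(config, H, rng)
        bags.append(FeatureBag(bag_id=bag_id, features=X, label=None, split="ood"))
    return bags


def write_dataset(bags: list[FeatureBag], outdir, manifest_name="manifest.csv"):
    """Write bags as one HDF5 file each plus a CSV manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for bag in bags:
        path = outdir / f"{bag.bag_id}.h5"
        write_bag(bag, path)
        entries.append(
            ManifestEntry(bag.bag_id, str(path), bag.label, bag.split or "train")
        )
    manifest = DatasetManifest(entries)
    write_manifest(manifest, outdir / manifest_name)
    return manifest


def benchmark_suite(
    seed: int,
    n_train: int = 200,
    n_test: int = 100,
    n_ood: int = 100,
    config: SimulationConfig | None = None,
) -> dict:
    """The standard synthetic experiment: train/test IND sets plus
    near, far, artifact, and null (zero-shift) OOD sets sharing one
    mixing map."""
    base = config or SimulationConfig(n_bags=n_train, seed=seed)
    base = replace(base, n_bags=n_train, seed=seed)
    train = simulate_ind_dataset(base, split="train")
    test = simulate_ind_dataset(replace(base, n_bags=n_test), split="test")
    ood = {
        name: simulate_ood_dataset(base, spec, n_bags=n_ood)
        for name, spec in SHIFT_PRESETS.items()
    }
    ood["null"] = simulate_ood_dataset(
        base, ShiftSpec(mode="whole_bag", magnitude=0.0), n_bags=n_ood
    )
    return {"config": base, "train": train, "test": test, "ood": ood}
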