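"""Feature-bag data model and I/O.

A *bag* is one whole-slide image represented by the feature vectors of
its patches: an (N_b, P) float32 matrix plus an optional binary bag
label.  Bags are stored one per HDF5 file; a dataset is indexed by a
CSV manifest with columns ``bag_id,path,label,split``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureBag",
    "ManifestEntry",
    "DatasetManifest",
    "read_bag",
    "write_bag",
    "read_manifest",
    "write_manifest",
    "split_train_val",
]

VALID_SPLITS = ("train", "val", "test", "ood")


class BagFormatError(ValueError):
    """Raised when a bag file does not conform to the expected layout."""


@dataclass
class FeatureBag:
    """One bag of instance feature vectors.

    Parameters
    ----------
    bag_id : str
        Unique identifier of the bag (e.g. a slide name).
    features : ndarray, shape (N_b, P)
        Instance feature matrix; stored as float32.
    label : int or None
        Binary bag label under the standard MIL rule (a bag is positive
        iff at least one instance is positive).  ``None`` for
        label-free OOD bags.
    split : str or None
        One of ``train``, ``val``, ``test``, ``ood``.
    instance_ids : list of str, optional
        Per-instance identifiers (length N_b).
    instance_labels : ndarray, optional
        Hidden per-instance binary labels.  Real MIL data does not have
        them; the synthetic generator records them so instance-level
        diagnostics (attention quality) can be evaluated.
    """

    bag_id: str
    features: np.ndarray
    label: int | None = None
    split: str | None = None
    instance_ids: list[str] | None = None
    instance_labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(
                f"bag {self.bag_id!r}: features must be a (N_b >= 1, P) matrix, "
                f"got shape {self.features.shape}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"bag {self.bag_id!r}: non-finite feature entries")
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise ValueError(f"bag {self.bag_id!r}: label must be 0 or 1")
        if self.instance_ids is not None and len(self.instance_ids) != self.n_instances:
            raise ValueError(f"bag {self.bag_id!r}: instance_ids length mismatch")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    bag_id: str
    path: str
    label: int | None
    split: str


@dataclass
class DatasetManifest:
    """Index of a bag dataset; bag_id is unique within a manifest."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.bag_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate bag_id in manifest")

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([e for e in self.entries if e.split == split])

    def load_bags(self) -> list[FeatureBag]:
        bags = []
        for e in self.entries:
            bag = read_bag(e.path)
            bag.split = e.split
            if e.label is not None:
                bag.label = e.label
            bags.append(bag)
        return bags


def write_bag(bag: FeatureBag, path: str | Path) -> None:
    """Write a bag to one HDF5 file (dataset ``features``, float32)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.attrs["bag_id"] = bag.bag_id
        if bag.label is not None:
            f.attrs["label"] = int(bag.label)
        if bag.instance_ids is not None:
            f.create_dataset(
                "instance_ids", data=np.array(bag.instance_ids, dtype="S")
            )
        if bag.instance_labels is not None:
            f.create_dataset(
                "instance_labels", data=np.asarray(bag.instance_labels, dtype=np.int8)
            )


def read_bag(path: str | Path) -> FeatureBag:
    """Read a bag written by :func:`write_bag`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bag file not found: {path}")
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise BagFormatError(f"{path}: missing 'features' dataset")
        features = f["features"][...]
        bag_id = f.attrs.get("bag_id", path.stem)
        if isinstance(bag_id, bytes):
            bag_id = bag_id.decode()
        label = f.attrs.get("label", None)
        label = int(label) if label is not None else None
        instance_ids = None
        if "instance_ids" in f:
            instance_ids = [s.decode() for s in f["instance_ids"][...]]
        instance_labels = None
        if "instance_labels" in f:
            instance_labels = f["instance_labels"][...].astype(int)
    return FeatureBag(
        bag_id=str(bag_id),
        features=features,
        label=label,
        instance_ids=instance_ids,
        instance_labels=instance_labels,
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bag_id": [e.bag_id for e in manifest.entries],
            "path": [e.path for e in manifest.entries],
            "label": [e.label if e.label is not None else "" for e in manifest.entries],
            "split": [e.split for e in manifest.entries],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, dtype={"bag_id": str, "path": str, "split": str})
    entries = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) or row.label == "" else int(row.label)
        entries.append(ManifestEntry(row.bag_id, row.path, label, row.split))
    return DatasetManifest(entries)


def split_train_val(
    manifest: DatasetManifest, val_fraction: float, seed: int
) -> DatasetManifest:
    """Carve a stratified validation set out of the training bags.

    Only bags tagged ``train`` participate; bags on other splits pass
    through untouched.  OOD bags are never placed in train or val
    (OOD detection is a test-time task).  The split is deterministic in
    ``seed`` and stratified by bag label.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    train = [e for e in manifest.entries if e.split == "train"]
    rest = [e for e in manifest.entries if e.split != "train"]
    n_val = int(round(val_fraction * len(train)))
    if len(train) < 2 or n_val < 1 or n_val >= len(train):
        raise ValueError(
            f"cannot split {len(train)} train bags into train+val at "
            f"val_fraction={val_fraction}"
        )
    labels = [e.label for e in train]
    stratify = labels if all(l is not None for l in labels) else None
    if stratify is not None:
        # stratification needs >= 1 bag of each class on each side
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any() or n_val < counts.size:
            stratify = None
    tr, va = train_test_split(
        train, test_size=n_val, random_state=seed, stratify=stratify
    )
    new = [replace(e) for e in tr]
    new += [ManifestEntry(e.bag_id, e.path, e.label, "val") for e in va]
    return DatasetManifest(new + rest)
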