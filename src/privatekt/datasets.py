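"""Dataset containers, synthetic data generation, public-pool splitting and
client partitioning for federated-learning simulations.

The containers are deliberately minimal: a labeled dataset is a feature
matrix, integer class labels and stable integer sample identifiers; the
public pool carries *no* labels, by construction, so no server-side code
path can ever consult them. All cross-module references to public samples
are by id, never by row position.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "PublicPool",
    "PartitionSpec",
    "FederatedDataset",
    "make_synthetic_classification",
    "split_public_pool",
    "partition_clients",
    "build_federation",
    "read_csv_dataset",
    "write_csv_dataset",
    "read_idx_images",
    "read_idx_labels",
    "write_partition_manifest",
    "read_partition_manifest",
]

_PARTITION_RETRIES = 25


@dataclasses.dataclass(frozen=True)
class LabeledDataset:
    """A labeled classification dataset with stable sample identifiers.

    Parameters
    ----------
    features
        Real matrix of shape ``(n_samples, n_features)``.
    labels
        Integer class ids in ``[0, n_classes)``.
    n_classes
        Number of classes ``C``.
    sample_ids
        Unique integer identifiers, one per row.
    """

    features: np.ndarray
    labels: np.ndarray
    n_classes: int
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        sample_ids = np.asarray(self.sample_ids, dtype=np.int64)
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not (len(features) == len(labels) == len(sample_ids)):
            raise ValueError("features, labels and sample_ids must have equal length")
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_classes):
            raise ValueError("labels must lie in [0, n_classes)")
        if len(np.unique(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row-subset by positional indices, keeping ids."""
        indices = np.asarray(indices, dtype=np.int64)
        return LabeledDataset(
            features=self.features[indices],
            labels=self.labels[indices],
            n_classes=self.n_classes,
            sample_ids=self.sample_ids[indices],
        )


@dataclasses.dataclass(frozen=True)
class PublicPool:
    """An unlabeled public dataset shared across parties for knowledge transfer."""

    features: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        sample_ids = np.asarray(self.sample_ids, dtype=np.int64)
        if len(features) != len(sample_ids):
            raise ValueError("features and sample_ids must have equal length")
        if len(np.unique(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows_for(self, ids: np.ndarray) -> np.ndarray:
        """Feature rows for the given sample ids (order preserved)."""
        index = {int(s): i for i, s in enumerate(self.sample_ids)}
        rows = [index[int(s)] for s in np.asarray(ids).ravel()]
        return self.features[rows]


@dataclasses.dataclass(frozen=True)
class PartitionSpec:
    """How to shard a dataset across simulated clients.

    ``scheme`` selects the construction: ``iid`` is a uniform round-robin
    after shuffling; ``class_noniid`` draws per-class client allocations from
    a Dirichlet(alpha) (label skew); ``size_noniid`` draws client sizes from
    a log-normal(0, sigma) (size skew); ``mixed_noniid`` composes both.
    """

    scheme: Literal["iid", "class_noniid", "size_noniid", "mixed_noniid"]
    n_clients: int
    alpha: float = 0.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 2:
            raise ValueError("n_clients must be >= 2")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.scheme not in ("iid", "class_noniid", "size_noniid", "mixed_noniid"):
            raise ValueError(f"unknown partition scheme: {self.scheme!r}")


@dataclasses.dataclass(frozen=True)
class FederatedDataset:
    """Client shards plus the disjoint unlabeled public pool."""

    clients: tuple[LabeledDataset, ...]
    pool: PublicPool

    def __post_init__(self) -> None:
        pool_ids = set(self.pool.sample_ids.tolist())
        for i, shard in enumerate(self.clients):
            overlap = pool_ids.intersection(shard.sample_ids.tolist())
            if overlap:
                raise ValueError(f"client {i} shares sample ids with the public pool")

    @property
    def n_clients(self) -> int:
        return len(self.clients)

    @property
    def n_classes(self) -> int:
        return self.clients[0].n_classes


def _class_mean_directions(n_classes: int, n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm class mean directions with large minimum pairwise distance.

    For C <= 2d the vertices of the hyperoctahedron (+-e_i) are used, giving a
    minimum pairwise distance of sqrt(2) between directions; beyond that,
    seeded random unit vectors.
    """
    if n_classes <= 2 * n_features:
        eye = np.eye(n_features)
        verts = np.concatenate([eye, -eye], axis=0)
        return verts[:n_classes]
    dirs = rng.normal(size=(n_classes, n_features))
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def make_synthetic_classification(
    n_samples: int,
    n_classes: int,
    n_features: int,
    separation: float,
    seed: int,
) -> LabeledDataset:
    """Draw a class-conditional Gaussian mixture with unit covariance.

    Class means sit on hyperoctahedron vertices scaled so the minimum
    distance between any two means is ``2 * separation``; ``separation`` is
    therefore the half-margin between nearest classes in units of the noise
    standard deviation. ``separation=0`` collapses all means to the origin
    (chance-level task). Labels are balanced to within one sample per class
    and rows are shuffled. Fully reproducible from ``seed``.
    """
    if n_samples < n_classes:
        raise ValueError("n_samples must be >= n_classes")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.sqrt(2.0) * separation * _class_mean_directions(n_classes, n_features, rng)
    # balanced labels: counts differ by at most one
    base, extra = divmod(n_samples, n_classes)
    counts = np.full(n_classes, base, dtype=np.int64)
    counts[:extra] += 1
    labels = np.repeat(np.arange(n_classes), counts)
    features = means[labels] + rng.normal(size=(n_samples, n_features))
    order = rng.permutation(n_samples)
    return LabeledDataset(
        features=features[order],
        labels=labels[order],
        n_classes=n_classes,
        sample_ids=np.arange(n_samples),
    )


def split_public_pool(
    data: LabeledDataset, fraction: float, seed: int
) -> tuple[LabeledDataset, PublicPool]:
    """Carve an unlabeled public pool out of a labeled training set.

    Uniformly samples ``floor(fraction * n)`` records into the pool and
    permanently discards their labels; the remainder is returned as the
    private training set. The two id sets are disjoint and their union is
    the input id set.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = data.n_samples
    pool_size = int(np.floor(fraction * n))
    if pool_size == 0 or pool_size == n:
        raise ValueError(
            f"fraction={fraction} yields an empty pool or empty remainder for n={n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pool_idx, private_idx = order[:pool_size], order[pool_size:]
    pool = PublicPool(features=data.features[pool_idx], sample_ids=data.sample_ids[pool_idx])
    private = data.subset(private_idx)
    return private, pool


def _iid_partition(n: int, n_clients: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i::n_clients] for i in range(n_clients)]


def _sizes_from_lognormal(
    n: int, n_clients: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    weights = rng.lognormal(mean=0.0, sigma=sigma, size=n_clients)
    weights = weights / weights.sum()
    sizes = np.floor(weights * n).astype(np.int64)
    # largest-remainder rounding so sizes sum to n
    remainder = weights * n - sizes
    short = n - sizes.sum()
    for i in np.argsort(remainder)[::-1][:short]:
        sizes[i] += 1
    return sizes

def _class_allocation(
    labels: np.ndarray,
    n_classes: int,
    proportions: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Assign each class's rows to clients with the given per-class proportions."""
    n_clients = proportions.shape[1]
    assigned: list[list[np.ndarray]] = [[] for _ in range(n_clients)]
    for c in range(n_classes):
        rows = np.flatnonzero(labels == c)
        rng.shuffle(rows)
        counts = rng.multinomial(len(rows), proportions[c])
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for i in range(n_clients):
            assigned[i].append(rows[offsets[i] : offsets[i + 1]])
    return [np.concatenate(parts) if parts else np.empty(0, np.int64) for parts in assigned]


def _draw_partition(
    data: LabeledDataset, spec: PartitionSpec, rng: np.random.Generator
) -> list[np.ndarray]:
    n, N = data.n_samples, spec.n_clients
    if spec.scheme == "iid":
        return _iid_partition(n, N, rng)
    if spec.scheme == "size_noniid":
        sizes = _sizes_from_lognormal(n, N, spec.sigma, rng)
        order = rng.permutation(n)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        return [order[offsets[i] : offsets[i + 1]] for i in range(N)]
    # class_noniid / mixed_noniid: per-class Dirichlet(alpha) allocation
    proportions = rng.dirichlet(np.full(N, spec.alpha), size=data.n_classes)
    if spec.scheme == "mixed_noniid":
        size_weights = rng.lognormal(mean=0.0, sigma=spec.sigma, size=N)
        proportions = proportions * size_weights
        proportions = proportions / proportions.sum(axis=1, keepdims=True)
    return _class_allocation(data.labels, data.n_classes, proportions, rng)


def partition_clients(data: LabeledDataset, spec: PartitionSpec) -> list[LabeledDataset]:
    """Shard a dataset across ``spec.n_clients`` simulated clients.

    Shards are disjoint and cover the input. If a draw leaves any shard
    empty (possible under strong skew), the draw is repeated with fresh
    randomness up to a bounded retry count before raising.
    """
    if data.n_samples < spec.n_clients:
        raise ValueError("dataset smaller than the number of clients")
    rng = np.random.default_rng(spec.seed)
    for _ in range(_PARTITION_RETRIES):
        shards = _draw_partition(data, spec, rng)
        if all(len(s) > 0 for s in shards):
            return [data.subset(np.sort(idx)) for idx in shards]
    raise RuntimeError(
        f"could not draw a partition without empty shards after {_PARTITION_RETRIES} tries"
    )


def build_federation(
    data: LabeledDataset, pool_fraction: float, spec: PartitionSpec, seed: int
) -> FederatedDataset:
    """Split off the public pool, then partition the private remainder."""
    private, pool = split_public_pool(data, pool_fraction, seed)
    clients = partition_clients(private, spec)
    return FederatedDataset(clients=tuple(clients), pool=pool)


# ---------------------------------------------------------------------------
# External interfaces: CSV, MNIST IDX, partition manifests


def write_csv_dataset(data: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as CSV with columns ``f0..f{d-1}, label``."""
    frame = pd.DataFrame(
        data.features, columns=[f"f{i}" for i in range(data.n_features)]
    )
    frame["label"] = data.labels
    frame.insert(0, "sample_id", data.sample_ids)
    frame.to_csv(path, index=False)


def read_csv_dataset(path: str | Path, n_classes: int | None = None) -> LabeledDataset:
    """Read a CSV dataset (header row, last column = label).

    An optional leading ``sample_id`` column is honored; otherwise dense
    integer ids are assigned in row order.
    """
    frame = pd.read_csv(path)
    labels = frame.iloc[:, -1].to_numpy(dtype=np.int64)
    frame = frame.iloc[:, :-1]
    if frame.columns[0] == "sample_id":
        sample_ids = frame.pop("sample_id").to_numpy(dtype=np.int64)
    else:
        sample_ids = np.arange(len(frame))
    return LabeledDataset(
        features=frame.to_numpy(dtype=np.float64),
        labels=labels,
        n_classes=int(labels.max()) + 1 if n_classes is None else n_classes,
        sample_ids=sample_ids,
    )


def read_idx_images(path: str | Path) -> np.ndarray:
    """Read an MNIST IDX image file (magic 0x00000803) into (n, rows*cols) floats in [0,1]."""
    raw = Path(path).read_bytes()
    if len(raw) < 16:
        raise ValueError("file too short for an IDX image header")
    magic, n, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != 0x00000803:
        raise ValueError(f"not an IDX image file (magic {magic:#010x})")
    pixels = np.frombuffer(raw, dtype=np.uint8, offset=16)
    return pixels.reshape(n, rows * cols).astype(np.float64) / 255.0


def read_idx_labels(path: str | Path) -> np.ndarray:
    """Read an MNIST IDX label file (magic 0x00000801)."""
    raw = Path(path).read_bytes()
    if len(raw) < 8:
        raise ValueError("file too short for an IDX label header")
    magic, n = struct.unpack(">II", raw[:8])
    if magic != 0x00000801:
        raise ValueError(f"not an IDX label file (magic {magic:#010x})")
    return np.frombuffer(raw, dtype=np.uint8, offset=8).astype(np.int64)


def write_partition_manifest(clients: list[LabeledDataset], path: str | Path) -> None:
    """Write a JSON audit manifest mapping client index -> sample id list."""
    manifest = {str(i): shard.sample_ids.tolist() for i, shard in enumerate(clients)}
    Path(path).write_text(json.dumps(manifest, indent=1))


def read_partition_manifest(path: str | Path) -> dict[int, list[int]]:
    raw = json.loads(Path(path).read_text())
    return {int(k): [int(v) for v in ids] for k, ids in raw.items()}
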