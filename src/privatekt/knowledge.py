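"""Uncertainty-driven sample selection and the FIFO knowledge buffer.

The server scores every public-pool sample by the predictive entropy of
the current global model. Knowledge-transfer (KT) data is drawn with
probability increasing in entropy (softmax of entropies: uncertain samples
carry more information for training), while self-training data is drawn
with probability decreasing in entropy (softmax of negated entropies:
confident pseudo-labels). Debiased targets are retained across rounds in a
bounded first-in-first-out buffer so the global model is fine-tuned on
more than one round's worth of knowledge.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import deque
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax, xlogy

__all__ = [
    "KnowledgeRecord",
    "KnowledgeBuffer",
    "prediction_entropy",
    "entropy_rows",
    "importance_weights",
    "selftrain_weights",
    "weighted_sample_ids",
    "buffer_push_round",
]


def prediction_entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a probability vector, with 0*ln 0 := 0."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("expected a 1-D probability vector")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()})")
    return float(-xlogy(p, p).sum())


def entropy_rows(probs: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy (nats) of a matrix of probability rows."""
    probs = np.asarray(probs, dtype=np.float64)
    return -xlogy(probs, probs).sum(axis=1)


def _validate_entropies(entropies: np.ndarray) -> np.ndarray:
    entropies = np.asarray(entropies, dtype=np.float64)
    if entropies.size == 0:
        raise ValueError("entropies must be non-empty")
    if not np.isfinite(entropies).all():
        raise ValueError("entropies must be finite")
    return entropies


def importance_weights(entropies: Sequence[float] | np.ndarray) -> np.ndarray:
    """KT sampling weights: softmax of entropies (uncertain samples favored)."""
    return softmax(_validate_entropies(entropies))


def selftrain_weights(entropies: Sequence[float] | np.ndarray) -> np.ndarray:
    """Self-training weights: softmax of negated entropies (confident samples favored)."""
    return softmax(-_validate_entropies(entropies))


def weighted_sample_ids(
    pool_ids: Sequence[int] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
    count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``count`` distinct ids without replacement, sequentially.

    Each draw picks an id with probability proportional to its weight among
    the ids still available, then removes it (draw-and-remove). Ties in
    weight are broken by the draw itself.
    """
    pool_ids = np.asarray(pool_ids)
    weights = np.asarray(weights, dtype=np.float64)
    if pool_ids.shape != weights.shape:
        raise ValueError("pool_ids and weights must have equal length")
    if count > len(pool_ids):
        raise ValueError(f"cannot draw {count} ids from a pool of {len(pool_ids)}")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    available = np.arange(len(pool_ids))
    w = weights.copy()
    chosen = np.empty(count, dtype=np.int64)
    for i in range(count):
        probs = w[available] / w[available].sum()
        pick = rng.choice(len(available), p=probs)
        chosen[i] = available[pick]
        available = np.delete(available, pick)
    return pool_ids[chosen]


@dataclasses.dataclass(frozen=True)
class KnowledgeRecord:
    """One public sample's aggregated knowledge from one round.

    ``estimate`` is the raw debiased vector (kept for audit; may have
    negative entries); ``target`` is its simplex projection used for
    fine-tuning.
    """

    sample_id: int
    estimate: np.ndarray
    target: np.ndarray
    round_index: int

    def __post_init__(self) -> None:
        target = np.asarray(self.target, dtype=np.float64)
        if (target < 0).any() or abs(target.sum() - 1.0) > 1e-6:
            raise ValueError("target must lie on the probability simplex")
        object.__setattr__(self, "estimate", np.asarray(self.estimate, dtype=np.float64))
        object.__setattr__(self, "target", target)


class KnowledgeBuffer:
    """Bounded FIFO store of knowledge records.

    Capacity counts records, not rounds, so it is independent of K. When a
    push would exceed capacity the oldest records are evicted; a single
    batch larger than the capacity keeps only its newest records (with a
    warning).
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._records: deque[KnowledgeRecord] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[KnowledgeRecord]:
        return iter(self._records)

    @property
    def records(self) -> list[KnowledgeRecord]:
        return list(self._records)

    def push_round(self, records: Iterable[KnowledgeRecord]) -> "KnowledgeBuffer":
        records = list(records)
        if records and self._records and records[0].round_index < self._records[-1].round_index:
            raise ValueError("round index must be non-decreasing within the buffer")
        if len(records) > self.capacity:
            warnings.warn(
                f"batch of {len(records)} records exceeds buffer capacity "
                f"{self.capacity}; keeping only the newest {self.capacity}",
                stacklevel=2,
            )
        self._records.extend(records)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Buffer contents as a table: sample id, round, one column per class target."""
        if not self._records:
            return pd.DataFrame(columns=["sample_id", "round"])
        n_classes = len(self._records[0].target)
        rows = [
            {"sample_id": r.sample_id, "round": r.round_index}
            | {f"target_{j}": r.target[j] for j in range(n_classes)}
            for r in self._records
        ]
        return pd.DataFrame(rows)

    def dump_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def buffer_push_round(
    buffer: KnowledgeBuffer, records: Iterable[KnowledgeRecord]
) -> KnowledgeBuffer:
    """Functional alias for :meth:`KnowledgeBuffer.push_round`."""
    return buffer.push_round(records)
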