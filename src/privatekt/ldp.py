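"""Local differential privacy primitives for categorical knowledge transfer.

A client's answer on one public sample is a one-hot class prediction. The
randomized response channel keeps it with probability ``beta`` and
otherwise replaces it with a uniformly random class (which may coincide
with the true one). The keep probability for a total per-round budget
``epsilon`` split evenly over ``K`` answered samples with ``C`` classes is

    beta = (exp(epsilon/K) - 1) / (exp(epsilon/K) - 1 + C),

which makes each individual answer exactly (epsilon/K)-LDP and the round
epsilon-LDP by composition. The server inverts the channel in expectation:
given the mean of the perturbed uploads, the debiased estimate

    (1/beta) * (mean - (1-beta)/C * 1)

is unbiased for the mean of the clean one-hot predictions. Because it can
leave the probability simplex, a clip-and-renormalize projection is
provided for use as a training target; the raw estimate is preserved for
auditing.

``verify_ldp`` is an exhaustive oracle: it enumerates every
(input, input', output) triple of the channel and returns the worst-case
log-likelihood ratio, i.e. the realized per-answer budget.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "PrivacyParams",
    "OneHotPrediction",
    "DebiasedEstimate",
    "beta_for_budget",
    "one_hot",
    "perturb_prediction",
    "perturb_batch",
    "debias_aggregate",
    "clip_to_simplex",
    "verify_ldp",
]

_BETA_TOL = 1e-12


def beta_for_budget(epsilon: float, k: int, n_classes: int) -> float:
    """Keep probability realizing an even epsilon/K split per answered sample.

    Monotonically increasing in ``epsilon``, decreasing in ``k`` and in
    ``n_classes``. ``epsilon=0`` gives 0 (every upload replaced: perfect
    privacy, no information).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    per_sample = epsilon / k
    if per_sample > 700:  # expm1 overflows; the ratio is 1 to fp precision
        return 1.0
    expm = math.expm1(per_sample)
    return expm / (expm + n_classes)


@dataclasses.dataclass(frozen=True)
class PrivacyParams:
    """The privacy contract of one knowledge-transfer round.

    ``epsilon`` is the total per-round budget (nats), ``k`` the number of
    public samples each client answers, ``n_classes`` the label
    cardinality. ``beta`` is derived; supplying it explicitly is allowed
    only if consistent to 1e-12.
    """

    epsilon: float
    k: int
    n_classes: int
    beta: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        derived = beta_for_budget(self.epsilon, self.k, self.n_classes)
        if self.beta is None:
            object.__setattr__(self, "beta", derived)
        elif abs(self.beta - derived) > _BETA_TOL:
            raise ValueError(
                f"beta={self.beta} inconsistent with epsilon={self.epsilon}, "
                f"k={self.k}, n_classes={self.n_classes} (expected {derived})"
            )

    @property
    def per_sample_epsilon(self) -> float:
        return self.epsilon / self.k


def one_hot(label: int, n_classes: int) -> np.ndarray:
    vec = np.zeros(n_classes, dtype=np.int64)
    vec[label] = 1
    return vec


@dataclasses.dataclass(frozen=True)
class OneHotPrediction:
    """A single client's (possibly perturbed) class vote."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=np.int64)
        if vec.ndim != 1 or not np.isin(vec, (0, 1)).all() or vec.sum() != 1:
            raise ValueError("vector must be one-hot")
        object.__setattr__(self, "vector", vec)

    @property
    def label(self) -> int:
        return int(np.argmax(self.vector))


@dataclasses.dataclass(frozen=True)
class DebiasedEstimate:
    """Debiased aggregate of perturbed votes; entries may be negative."""

    vector: np.ndarray
    n_contributors: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=np.float64)
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("debiased estimate must sum to 1")
        object.__setattr__(self, "vector", vec)


def perturb_prediction(
    y: OneHotPrediction | np.ndarray,
    params: PrivacyParams,
    rng: np.random.Generator,
) -> OneHotPrediction:
    """Randomized response on one one-hot vote.

    With probability ``beta`` the vote is kept; otherwise it is replaced by
    a one-hot drawn uniformly over all C classes, including possibly the
    original one. Hence Pr[out = y] = beta + (1-beta)/C.
    """
    vec = y.vector if isinstance(y, OneHotPrediction) else np.asarray(y)
    if vec.shape != (params.n_classes,):
        raise ValueError(
            f"prediction has length {vec.shape}, expected ({params.n_classes},)"
        )
    keep = rng.random() < params.beta
    replacement = int(rng.integers(params.n_classes))
    if keep:
        return OneHotPrediction(np.asarray(vec, dtype=np.int64).copy())
    return OneHotPrediction(one_hot(replacement, params.n_classes))


def perturb_batch(
    labels: np.ndarray, params: PrivacyParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized randomized response on integer labels; returns perturbed labels.

    Equivalent in law to `perturb_prediction` applied elementwise; used for
    Monte-Carlo studies where per-vote object overhead matters.
    """
    labels = np.asarray(labels, dtype=np.int64)
    keep = rng.random(labels.shape) < params.beta
    replacement = rng.integers(params.n_classes, size=labels.shape)
    return np.where(keep, labels, replacement)


def debias_aggregate(
    uploads: list[OneHotPrediction] | list[np.ndarray] | np.ndarray,
    params: PrivacyParams,
) -> DebiasedEstimate:
    """Unbiased estimate of the mean clean vote from perturbed uploads.

    Computes ``(mean(uploads) - (1-beta)/C) / beta``; the output always
    sums to one but individual entries may be negative.
    """
    if params.beta == 0:
        raise ValueError("beta is 0: the estimator is undefined (divide by zero)")
    rows = np.stack(
        [u.vector if isinstance(u, OneHotPrediction) else np.asarray(u) for u in uploads]
    )
    if rows.size == 0:
        raise ValueError("uploads must be non-empty")
    if rows.shape[1] != params.n_classes:
        raise ValueError("upload length differs from n_classes")
    mean = rows.mean(axis=0)
    est = (mean - (1.0 - params.beta) / params.n_classes) / params.beta
    # exact-sum correction: analytic sum is 1, remove fp residue
    est = est / est.sum()
    return DebiasedEstimate(vector=est, n_contributors=rows.shape[0])


def clip_to_simplex(estimate: DebiasedEstimate | np.ndarray) -> np.ndarray:
    """Project a sum-to-one vector onto the simplex by clipping negatives.

    Negative entries are set to zero and the rest renormalized. Inputs
    already on the simplex are returned unchanged (up to dtype).
    """
    vec = estimate.vector if isinstance(estimate, DebiasedEstimate) else np.asarray(estimate, dtype=np.float64)
    clipped = np.clip(vec, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("cannot project: no positive mass")
    return clipped / total


def verify_ldp(beta: float, n_classes: int) -> float:
    """Realized per-answer LDP budget of the randomized-response channel.

    Exhaustively enumerates every (input y, input y', output o) triple and
    returns the maximum log-likelihood ratio ln(Pr[o|y]/Pr[o|y']). For
    ``beta`` from `beta_for_budget` this equals exactly ``epsilon/K``.
    ``beta=1`` is a deterministic channel: returns ``inf``.
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    if beta == 1:
        return math.inf
    # channel[y, o] = Pr[output o | input y]
    channel = np.full((n_classes, n_classes), (1.0 - beta) / n_classes)
    channel[np.diag_indices(n_classes)] += beta
    worst = 0.0
    for y in range(n_classes):
        for y2 in range(n_classes):
            for o in range(n_classes):
                ratio = math.log(channel[y, o] / channel[y2, o])
                worst = max(worst, ratio)
    return worst
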