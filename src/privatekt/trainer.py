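"""The federated knowledge-transfer loop and its comparators.

One round proceeds: the server distributes the global model and the ids of
K actively sampled public (knowledge-transfer) samples; each selected
client trains the model on its private shard, predicts a hard class for
each KT sample, perturbs every prediction with randomized response, and
uploads only those K perturbed one-hots; the server debiases the vote
means, pushes the resulting targets into a FIFO knowledge buffer,
fine-tunes the global model on the buffered soft targets, optionally
self-trains on confident pseudo-labeled pool samples, and finally draws
the next round's KT ids by predictive-entropy importance sampling.

Comparators: centralized training on the pooled shards (upper reference)
and FedAvg parameter averaging, optionally with per-coordinate Laplace
noise on L2-clipped updates for an LDP-protected variant.

All client-to-server traffic is routed through a ``Transport`` so tests
can assert that nothing but the K perturbed one-hots ever crosses the
boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import f1_score

from .config import RunConfig
from .datasets import FederatedDataset, LabeledDataset, PublicPool
from .knowledge import (
    KnowledgeBuffer,
    KnowledgeRecord,
    entropy_rows,
    importance_weights,
    selftrain_weights,
    weighted_sample_ids,
)
from .ldp import (
    DebiasedEstimate,
    OneHotPrediction,
    PrivacyParams,
    clip_to_simplex,
    debias_aggregate,
    one_hot,
    perturb_prediction,
)
from .models import ClassifierHandle, MLPClassifier

__all__ = [
    "RoundMetrics",
    "Transport",
    "RecordingTransport",
    "FedAvgLDP",
    "rng_for",
    "select_clients",
    "client_round",
    "server_update",
    "run_privatekt",
    "run_centralized",
    "run_fedavg",
    "evaluate",
    "pooled_clients",
]

logger = logging.getLogger(__name__)

# stream codes for per-purpose generator derivation
_INIT, _SELECT, _CLIENT, _SERVER, _KT, _NOISE = range(6)


def rng_for(seed: int, *path: int) -> np.random.Generator:
    """Independent generator for (master seed, purpose, round, client...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


@dataclasses.dataclass(frozen=True)
class RoundMetrics:
    """Evaluation record emitted after every round."""

    round_index: int
    accuracy: float
    macro_f1: float
    selected_clients: tuple[int, ...]
    kt_ids: tuple[int, ...]
    wall_time: float
    realized_epsilon: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.macro_f1 <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")


class Transport:
    """Client-to-server channel; subclass to instrument or intercept."""

    def send(self, client_id: int, payload: list[OneHotPrediction]) -> list[OneHotPrediction]:
        return payload


class RecordingTransport(Transport):
    """Records every message for boundary audits in tests."""

    def __init__(self) -> None:
        self.messages: list[tuple[int, list[OneHotPrediction]]] = []

    def send(self, client_id: int, payload: list[OneHotPrediction]) -> list[OneHotPrediction]:
        self.messages.append((client_id, payload))
        return payload


@dataclasses.dataclass(frozen=True)
class FedAvgLDP:
    """LDP protection for FedAvg updates: L2 clip then Laplace noise."""

    clip: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.clip <= 0:
            raise ValueError("clip must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def evaluate(model: ClassifierHandle, test: LabeledDataset) -> tuple[float, float]:
    """(accuracy, macro-F1) on a labeled test set; macro-F1 uses 0/0 := 0."""
    pred = np.argmax(model.predict_proba(test.features), axis=1)
    acc = float(np.mean(pred == test.labels))
    f1 = float(f1_score(test.labels, pred, average="macro", zero_division=0))
    return acc, f1


def select_clients(n_clients: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample (without replacement) of max(1, round(fraction*N)) clients."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    size = max(1, int(round(fraction * n_clients)))
    return np.sort(rng.choice(n_clients, size=size, replace=False))


def client_round(
    global_model: ClassifierHandle,
    shard: LabeledDataset,
    kt_features: np.ndarray,
    params: PrivacyParams,
    local_epochs: int,
    lr: float,
    rng: np.random.Generator,
    use_ldp: bool = True,
) -> Optional[list[OneHotPrediction]]:
    """One client's contribution: local training, prediction, perturbation.

    Returns the K perturbed one-hot votes, or ``None`` for an empty shard
    (the client is skipped). The locally trained parameters and the clean
    predictions never leave this function; with ``use_ldp=False`` (the
    no-privacy comparator) the clean votes themselves are uploaded.
    """
    if shard.n_samples == 0:
        logger.warning("client shard is empty; skipping")
        return None
    local = global_model.clone().fit_hard(
        shard.features, shard.labels, local_epochs, lr, rng
    )
    hard = np.argmax(local.predict_proba(kt_features), axis=1)  # lowest index wins ties
    votes = [OneHotPrediction(one_hot(int(c), params.n_classes)) for c in hard]
    if not use_ldp:
        return votes
    return [perturb_prediction(v, params, rng) for v in votes]


def server_update(
    global_model: ClassifierHandle,
    buffer: KnowledgeBuffer,
    pool: PublicPool,
    records: Sequence[KnowledgeRecord],
    selftrain_m: int,
    finetune_epochs: int,
    selftrain_epochs: int,
    lr: float,
    rng: np.random.Generator,
    use_buffer: bool = True,
    use_selftrain: bool = True,
) -> ClassifierHandle:
    """Knowledge aggregation: buffer push, soft fine-tune, self-training.

    With ``use_buffer`` the round's records join the FIFO buffer and the
    model is fine-tuned on everything buffered; otherwise only on the
    current round's records. Self-training then draws ``selftrain_m``
    low-entropy pool samples and fits on their argmax pseudo-labels.
    """
    if use_buffer:
        buffer.push_round(records)
        train_records = buffer.records
    else:
        train_records = list(records)
    model = global_model
    if train_records:
        feats = pool.rows_for(np.array([r.sample_id for r in train_records]))
        targets = np.stack([r.target for r in train_records])
        model = model.fit_soft(feats, targets, finetune_epochs, lr, rng)
    else:
        logger.warning("knowledge buffer empty; skipping fine-tune")
    if use_selftrain and selftrain_m > 0:
        probs = model.predict_proba(pool.features)
        weights = selftrain_weights(entropy_rows(probs))
        ids = weighted_sample_ids(pool.sample_ids, weights, selftrain_m, rng)
        feats = pool.rows_for(ids)
        pseudo = np.argmax(model.predict_proba(feats), axis=1)
        model = model.fit_hard(feats, pseudo, selftrain_epochs, lr, rng)
    return model


def _init_model(config: RunConfig, n_features: int, n_classes: int) -> MLPClassifier:
    return MLPClassifier.create(
        n_features, n_classes, rng_for(config.seed, _INIT), hidden=config.hidden
    )


def run_privatekt(
    config: RunConfig,
    fed: FederatedDataset,
    test: LabeledDataset,
    transport: Optional[Transport] = None,
) -> list[RoundMetrics]:
    """Full knowledge-transfer simulation; returns one metrics record per round."""
    n_classes = fed.n_classes
    params = PrivacyParams(config.epsilon, config.k, n_classes)
    if config.use_ldp and params.beta == 0:
        raise ValueError(
            "epsilon=0 gives keep probability 0: the debiased estimator is undefined"
        )
    if config.k > fed.pool.n_samples or config.selftrain_m > fed.pool.n_samples:
        raise ValueError("k and selftrain_m must not exceed the public pool size")
    if config.n_clients != fed.n_clients:
        raise ValueError("config.n_clients differs from the federation")
    transport = transport or Transport()
    buffer = KnowledgeBuffer(config.buffer_capacity)
    model = _init_model(config, fed.clients[0].n_features, n_classes)
    # round 1: KT data drawn uniformly (no model knowledge yet)
    kt_ids = weighted_sample_ids(
        fed.pool.sample_ids,
        np.full(fed.pool.n_samples, 1.0 / fed.pool.n_samples),
        config.k,
        rng_for(config.seed, _KT, 0),
    )
    history: list[RoundMetrics] = []
    for t in range(1, config.rounds + 1):
        tic = time.perf_counter()
        selected = select_clients(
            config.n_clients, config.client_fraction, rng_for(config.seed, _SELECT, t)
        )
        kt_features = fed.pool.rows_for(kt_ids)
        uploads: list[list[OneHotPrediction]] = []
        for c in selected:
            votes = client_round(
                model,
                fed.clients[c],
                kt_features,
                params,
                config.local_epochs,
                config.lr,
                rng_for(config.seed, _CLIENT, t, c),
                use_ldp=config.use_ldp,
            )
            if votes is None:
                continue
            uploads.append(transport.send(int(c), votes))
        records = []
        for i, sid in enumerate(kt_ids):
            column = [u[i] for u in uploads]
            if not column:
                continue
            if config.use_ldp:
                est = debias_aggregate(column, params)
            else:  # clean votes: the mean itself is the estimate
                mean = np.stack([v.vector for v in column]).mean(axis=0)
                est = DebiasedEstimate(vector=mean, n_contributors=len(column))
            records.append(
                KnowledgeRecord(
                    sample_id=int(sid),
                    estimate=est.vector,
                    target=clip_to_simplex(est),
                    round_index=t,
                )
            )
        model = server_update(
            model,
            buffer,
            fed.pool,
            records,
            config.selftrain_m,
            config.finetune_epochs,
            config.selftrain_epochs,
            config.lr,
            rng_for(config.seed, _SERVER, t),
            use_buffer=config.use_buffer,
            use_selftrain=config.use_selftrain,
        )
        acc, f1 = evaluate(model, test)
        history.append(
            RoundMetrics(
                round_index=t,
                accuracy=acc,
                macro_f1=f1,
                selected_clients=tuple(int(c) for c in selected),
                kt_ids=tuple(int(s) for s in kt_ids),
                wall_time=time.perf_counter() - tic,
                realized_epsilon=config.epsilon if config.use_ldp else None,
            )
        )
        logger.info("round %d: accuracy %.4f macro-F1 %.4f", t, acc, f1)
        # draw next round's KT data (entropy-weighted unless ablated)
        if config.use_importance_sampling:
            weights = importance_weights(entropy_rows(model.predict_proba(fed.pool.features)))
        else:
            weights = np.full(fed.pool.n_samples, 1.0 / fed.pool.n_samples)
        kt_ids = weighted_sample_ids(
            fed.pool.sample_ids, weights, config.k, rng_for(config.seed, _KT, t)
        )
    return history


def pooled_clients(fed: FederatedDataset) -> LabeledDataset:
    """Union of all client shards (the centralized comparator's training set)."""
    return LabeledDataset(
        features=np.concatenate([c.features for c in fed.clients]),
        labels=np.concatenate([c.labels for c in fed.clients]),
        n_classes=fed.n_classes,
        sample_ids=np.concatenate([c.sample_ids for c in fed.clients]),
    )


def run_centralized(
    config: RunConfig, pooled: LabeledDataset, test: LabeledDataset
) -> list[RoundMetrics]:
    """Centralized training on pooled data for an equivalent epoch schedule."""
    model = _init_model(config, pooled.n_features, pooled.n_classes)
    history = []
    for t in range(1, config.rounds + 1):
        tic = time.perf_counter()
        model = model.fit_hard(
            pooled.features, pooled.labels, config.local_epochs, config.lr,
            rng_for(config.seed, _CLIENT, t, 0),
        )
        acc, f1 = evaluate(model, test)
        history.append(
            RoundMetrics(t, acc, f1, (), (), time.perf_counter() - tic)
        )
    return history


def run_fedavg(
    config: RunConfig,
    fed: FederatedDataset,
    test: LabeledDataset,
    ldp: Optional[FedAvgLDP] = None,
) -> list[RoundMetrics]:
    """Parameter-averaging rounds, optionally with LDP-protected updates.

    With ``ldp`` set, each client's update vector is L2-clipped to
    ``ldp.clip`` and per-coordinate Laplace noise of scale
    ``2 * clip * n_params / epsilon`` is added before averaging (L1
    sensitivity of an L2-ball-bounded vector in n_params dimensions is at
    most ``2 * clip * sqrt(n_params) <= 2 * clip * n_params`` — the
    conservative bound is used). The realized budget is recorded per round.
    """
    n_classes = fed.n_classes
    model = _init_model(config, fed.clients[0].n_features, n_classes)
    history = []
    for t in range(1, config.rounds + 1):
        tic = time.perf_counter()
        selected = select_clients(
            config.n_clients, config.client_fraction, rng_for(config.seed, _SELECT, t)
        )
        base = model.params_vector()
        deltas = []
        for c in selected:
            shard = fed.clients[c]
            if shard.n_samples == 0:
                continue
            local = model.fit_hard(
                shard.features, shard.labels, config.local_epochs, config.lr,
                rng_for(config.seed, _CLIENT, t, c),
            )
            delta = local.params_vector() - base
            if ldp is not None:
                norm = np.linalg.norm(delta)
                if norm > ldp.clip:
                    delta = delta * (ldp.clip / norm)
                scale = 2.0 * ldp.clip * delta.size / ldp.epsilon
                delta = delta + rng_for(config.seed, _NOISE, t, c).laplace(
                    0.0, scale, size=delta.shape
                )
            deltas.append(delta)
        if deltas:
            model = model.with_params_vector(base + np.mean(deltas, axis=0))
        acc, f1 = evaluate(model, test)
        history.append(
            RoundMetrics(
                t, acc, f1, tuple(int(c) for c in selected), (),
                time.perf_counter() - tic,
                realized_epsilon=ldp.epsilon if ldp is not None else None,
            )
        )
    return history
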