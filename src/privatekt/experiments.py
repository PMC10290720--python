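"""Experiment orchestration: single runs, replicated suites, (epsilon, K) sweeps.

A run's inputs are fully determined by its ``RunConfig``: the synthetic
task, the public-pool split and the client partition are all derived from
the config's seed through fixed stream codes, so two runs with equal
configs are bit-identical. Suite replication seeds are derived as
``crc32(f"{variant}:{rep}") XOR master`` (kept below 2**31), so a suite's
master seed fully determines every per-run seed.
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, SuiteConfig
from .datasets import PartitionSpec, build_federation, make_synthetic_classification
from .trainer import (
    FedAvgLDP,
    RoundMetrics,
    Transport,
    pooled_clients,
    run_centralized,
    run_fedavg,
    run_privatekt,
)

__all__ = [
    "derive_seed",
    "prepare_inputs",
    "execute_run",
    "run_metadata",
    "metrics_frame",
    "run_suite",
    "summarize_suite",
    "pairwise_differences",
    "run_sweep",
]

# stream codes for data-generation seeds (disjoint from trainer's small codes)
_DATA, _TEST, _PARTITION, _POOL = 100, 101, 102, 103


def _sub_seed(seed: int, code: int) -> int:
    return int(np.random.SeedSequence([int(seed), code]).generate_state(1)[0] % 2**31)


def derive_seed(master: int, variant: str, rep: int) -> int:
    """Per-run seed for a suite replication; stable across sessions."""
    return (zlib.crc32(f"{variant}:{rep}".encode()) ^ int(master)) % 2**31


def prepare_inputs(config: RunConfig):
    """Generate the train/test task and federate it, all from config.seed."""
    d = config.data
    train = make_synthetic_classification(
        d.n_samples, d.n_classes, d.n_features, d.separation, _sub_seed(config.seed, _DATA)
    )
    test = make_synthetic_classification(
        d.n_test, d.n_classes, d.n_features, d.separation, _sub_seed(config.seed, _TEST)
    )
    spec = PartitionSpec(
        scheme=config.partition.scheme,
        n_clients=config.n_clients,
        alpha=config.partition.alpha,
        sigma=config.partition.sigma,
        seed=_sub_seed(config.seed, _PARTITION),
    )
    fed = build_federation(train, d.pool_fraction, spec, _sub_seed(config.seed, _POOL))
    return fed, test


def execute_run(
    config: RunConfig, transport: Optional[Transport] = None
) -> list[RoundMetrics]:
    """Run the method named by ``config.method`` on freshly derived inputs."""
    fed, test = prepare_inputs(config)
    if config.method == "privatekt":
        return run_privatekt(config, fed, test, transport=transport)
    if config.method == "centrain":
        return run_centralized(config, pooled_clients(fed), test)
    ldp = None
    if config.fedavg_epsilon is not None:
        ldp = FedAvgLDP(clip=config.fedavg_clip, epsilon=config.fedavg_epsilon)
    return run_fedavg(config, fed, test, ldp=ldp)


def run_metadata(config: RunConfig) -> dict:
    """Audit record written alongside metrics: config, realized privacy."""
    meta = {
        "config": config.model_dump(),
        "seed": config.seed,
        "beta": config.beta,
        "per_round_epsilon": config.epsilon if config.use_ldp else None,
        "per_sample_epsilon": config.epsilon / config.k if config.use_ldp else None,
        "buffer_capacity": config.buffer_capacity,
    }
    if config.method == "fedavg":
        meta["fedavg_ldp_epsilon"] = config.fedavg_epsilon
        meta["fedavg_clip"] = config.fedavg_clip
    return meta


def metrics_frame(history: list[RoundMetrics]) -> pd.DataFrame:
    """Per-round metrics as a table (wall time excluded: reruns must be byte-identical)."""
    return pd.DataFrame(
        {
            "round": [m.round_index for m in history],
            "accuracy": [m.accuracy for m in history],
            "macro_f1": [m.macro_f1 for m in history],
            "n_clients": [len(m.selected_clients) for m in history],
            "kt_ids": [";".join(map(str, m.kt_ids)) for m in history],
        }
    )


def run_suite(suite: SuiteConfig) -> pd.DataFrame:
    """All variants x replications; failures are recorded, not fatal."""
    rows = []
    for name, base in suite.variants.items():
        for rep in range(suite.replications):
            seed = derive_seed(suite.seed, name, rep)
            cfg = base.model_copy(update={"seed": seed})
            row = {"variant": name, "rep": rep, "seed": seed}
            try:
                history = execute_run(cfg)
                row["final_accuracy"] = history[-1].accuracy
                row["final_macro_f1"] = history[-1].macro_f1
                row["error"] = ""
            except Exception as exc:  # suite keeps going per contract
                row["final_accuracy"] = np.nan
                row["final_macro_f1"] = np.nan
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_suite(results: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean and sd of final metrics (sd = 0 for one replication)."""
    def _sd(x):
        return 0.0 if len(x) < 2 else float(np.std(x, ddof=1))

    grouped = results.groupby("variant", sort=False)
    return pd.DataFrame(
        {
            "variant": list(grouped.groups),
            "mean_accuracy": grouped["final_accuracy"].mean().to_numpy(),
            "sd_accuracy": grouped["final_accuracy"].apply(_sd).to_numpy(),
            "mean_macro_f1": grouped["final_macro_f1"].mean().to_numpy(),
            "sd_macro_f1": grouped["final_macro_f1"].apply(_sd).to_numpy(),
            "n": grouped.size().to_numpy(),
        }
    )


def pairwise_differences(results: pd.DataFrame) -> pd.DataFrame:
    """Welch mean-difference summary for every ordered variant pair."""
    rows = []
    variants = list(results["variant"].unique())
    for a in variants:
        for b in variants:
            if a == b:
                continue
            xa = results.loc[results["variant"] == a, "final_accuracy"].dropna()
            xb = results.loc[results["variant"] == b, "final_accuracy"].dropna()
            row = {
                "variant_a": a,
                "variant_b": b,
                "mean_diff_accuracy": float(xa.mean() - xb.mean()),
            }
            if len(xa) > 1 and len(xb) > 1 and (xa.std() > 0 or xb.std() > 0):
                row["welch_p"] = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            else:
                row["welch_p"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(
    base: RunConfig, epsilons: list[float], ks: list[int], reps: int, master_seed: int
) -> pd.DataFrame:
    """Long-format (epsilon, K, rep, final_accuracy, beta) grid results."""
    if not epsilons or not ks or reps < 1:
        raise ValueError("epsilon grid, K grid and reps must be non-empty")
    rows = []
    for eps in epsilons:
        for k in ks:
            for rep in range(reps):
                seed = derive_seed(master_seed, f"eps{eps}_k{k}", rep)
                cfg = base.model_copy(update={"epsilon": eps, "k": k, "seed": seed})
                cfg = RunConfig.model_validate(cfg.model_dump())  # re-check cross fields
                history = execute_run(cfg)
                rows.append(
                    {
                        "epsilon": eps,
                        "K": k,
                        "rep": rep,
                        "seed": seed,
                        "final_accuracy": history[-1].accuracy,
                        "final_macro_f1": history[-1].macro_f1,
                        "beta": cfg.beta,
                    }
                )
    return pd.DataFrame(rows)
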