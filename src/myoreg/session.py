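"""Experiment orchestration: cohorts, provenance, offline replay.

Composes the other modules into the full pipeline — generate a virtual
user, train it under a protocol, run the frozen-controller 27-target
test, compute stratified metrics — and repeats it over a simulated
cohort, aggregating mean +/- sd per metric per stratum per protocol.
Every random decision traces to a seed derived from the experiment's
master seed, and all outputs embed the config hash, so identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigurationError, InvalidInputError
from .features import WindowingConfig
from .metrics import SessionMetrics, metrics_frame, stratify
from .protocols import PROTOCOL_IDS, ProtocolSpec, protocol_sequence
from .regressor import (
    AdaptationConfig,
    CoefficientMatrix,
    SessionLog,
    read_training_pairs,
    save_coefficients,
    train_closed_loop,
    train_open_loop,
    write_training_pairs,
)
from .task import TaskConfig, TrialRecord, run_test, write_trials_csv, write_trials_jsonl
from .user import VirtualUser, make_virtual_user

__all__ = [
    "ExperimentConfig",
    "SessionResult",
    "CohortReport",
    "derive_seeds",
    "run_session",
    "run_experiment",
    "replay_open_loop",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that determines a cohort experiment."""

    protocols: tuple[str, ...] = ("II",)
    cohort_size: int = 1
    difficulty: str = "medium"
    seed: int = 0
    prompt_duration: float = 3.0
    rest_duration: float = 2.0
    sample_rate: float = 200.0
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    include_trajectories: bool = False

    def __post_init__(self) -> None:
        for pid in self.protocols:
            if pid not in PROTOCOL_IDS:
                raise ConfigurationError(f"protocols: unknown protocol {pid!r}")
        if self.cohort_size < 1:
            raise ConfigurationError(f"cohort_size must be >= 1, got {self.cohort_size}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocols"] = list(self.protocols)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "protocols" in data:
            data["protocols"] = tuple(data["protocols"])
        for key, sub in (("adaptation", AdaptationConfig),
                         ("task", TaskConfig),
                         ("windowing", WindowingConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def derive_seeds(master_seed: int, cohort_size: int) -> list[dict[str, int]]:
    """Per-participant (user, protocol-order, test-order) seeds.

    Spawned from the master seed via numpy's SeedSequence so cohort
    members are statistically independent; each seed fits in 31 bits.
    """
    children = np.random.SeedSequence(master_seed).spawn(cohort_size)
    out = []
    for child in children:
        u, p, t = (int(s) & 0x7FFFFFFF for s in child.generate_state(3, dtype=np.uint32))
        out.append({"user_seed": u, "protocol_seed": p, "test_seed": t})
    return out


@dataclass
class SessionResult:
    """One participant under one protocol: weights, logs, trials, metrics."""

    protocol_id: str
    seeds: dict[str, int]
    controller: CoefficientMatrix
    training_log: SessionLog
    trials: list[TrialRecord]
    metrics: dict[str, SessionMetrics]


def run_session(
    protocol_id: str,
    user: VirtualUser,
    protocol_seed: int,
    test_seed: int,
    cfg: ExperimentConfig | None = None,
) -> SessionResult:
    """Train one user under one protocol, then run the frozen test."""
    cfg = cfg or ExperimentConfig()
    spec = ProtocolSpec(
        protocol_id=protocol_id,
        seed=protocol_seed,
        prompt_duration=cfg.prompt_duration,
        rest_duration=cfg.rest_duration,
    )
    prompts = protocol_sequence(spec)
    controller, log = train_closed_loop(
        prompts, user, cfg.adaptation, cfg.windowing, cfg.sample_rate
    )
    trials = run_test(
        controller, user, test_seed, cfg.task, cfg.windowing, cfg.sample_rate
    )
    return SessionResult(
        protocol_id=protocol_id,
        seeds={"protocol_seed": protocol_seed, "test_seed": test_seed},
        controller=controller,
        training_log=log,
        trials=trials,
        metrics=stratify(trials),
    )


@dataclass
class CohortReport:
    """Aggregated outcome of a cohort experiment."""

    config: ExperimentConfig
    seeds: list[dict[str, int]]
    per_user: pd.DataFrame  # one row per (protocol, user, stratum)
    summary: pd.DataFrame  # mean +/- sd per (protocol, stratum)
    friedman: dict | None = None
    results: dict[tuple[str, int], SessionResult] = field(default_factory=dict)


def _aggregate(per_user: pd.DataFrame) -> pd.DataFrame:
    grouped = per_user.groupby(["protocol", "stratum"], sort=False)
    summary = grouped.agg(
        n_users=("user", "size"),
        cr_mean=("CR", "mean"),
        cr_sd=("CR", "std"),
        pe_mean=("PE_mean", "mean"),
        pe_sd=("PE_mean", "std"),
        ar_mean=("AR", "mean"),
        ar_sd=("AR", "std"),
    ).reset_index()
    return summary


def _friedman(per_user: pd.DataFrame, protocols: Sequence[str]) -> dict:
    """Friedman test across protocols, paired by user, on the 3-DoF stratum."""
    out: dict[str, dict[str, float]] = {}
    sub = per_user[per_user["stratum"] == "3-dof"]
    for metric in ("CR", "PE_mean", "AR"):
        wide = sub.pivot(index="user", columns="protocol", values=metric)[list(protocols)]
        wide = wide.dropna()
        if len(wide) < 2:
            continue
        stat, p = stats.friedmanchisquare(*[wide[c].to_numpy() for c in protocols])
        out[metric] = {"statistic": float(stat), "p_value": float(p), "n_users": int(len(wide))}
    return out


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> CohortReport:
    """Run the configured cohort under every configured protocol.

    Each cohort member keeps the same user seed across protocols (the
    same simulated participant trains under each protocol), while the
    protocol-order and test-order seeds are shared across protocols so
    comparisons are paired.
    """
    seeds = derive_seeds(cfg.seed, cfg.cohort_size)
    rows = []
    results: dict[tuple[str, int], SessionResult] = {}
    for protocol_id in cfg.protocols:
        for u, s in enumerate(seeds):
            user = make_virtual_user(s["user_seed"], cfg.difficulty)
            res = run_session(protocol_id, user, s["protocol_seed"], s["test_seed"], cfg)
            results[(protocol_id, u)] = res
            for stratum, m in res.metrics.items():
                rows.append(
                    {
                        "protocol": protocol_id,
                        "user": u,
                        "stratum": stratum,
                        "n_trials": m.n_trials,
                        "n_hits": m.n_hits,
                        "CR": m.completion_rate,
                        "PE_mean": m.path_efficiency,
                        "AR": m.attempt_ratio,
                    }
                )
    per_user = pd.DataFrame(rows)
    summary = _aggregate(per_user)
    friedman = _friedman(per_user, cfg.protocols) if len(cfg.protocols) >= 3 else None
    report = CohortReport(
        config=cfg,
        seeds=seeds,
        per_user=per_user,
        summary=summary,
        friedman=friedman,
        results=results,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: CohortReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    meta = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seeds": report.seeds,
        "friedman_3dof": report.friedman,
    }
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    report.per_user.to_csv(out_dir / "per_user.csv", index=False)
    report.summary.to_csv(out_dir / "summary.csv", index=False)
    trials_dir = out_dir / "trials"
    weights_dir = out_dir / "weights"
    pairs_dir = out_dir / "pairs"
    for d in (trials_dir, weights_dir, pairs_dir):
        d.mkdir(exist_ok=True)
    for (protocol_id, u), res in report.results.items():
        tag = f"protocol_{protocol_id}_user_{u:02d}"
        write_trials_csv(trials_dir / f"{tag}.csv", res.trials)
        write_trials_jsonl(
            trials_dir / f"{tag}.jsonl", res.trials, cfg.include_trajectories
        )
        save_coefficients(
            weights_dir / f"{tag}.csv",
            res.controller,
            {"config_hash": cfg.config_hash(), **res.seeds, **res.training_log.metadata},
        )
        write_training_pairs(pairs_dir / f"{tag}.csv", res.training_log)


def replay_open_loop(
    recording: str | Path,
    cfg: AdaptationConfig | None = None,
    passes: int = 1,
) -> CoefficientMatrix:
    """Re-fit the decoder offline from a recorded (feature, target) log.

    Reproduces an online open-loop session bit-for-bit given the same
    pair order and config.  Refuses recordings flagged as closed-loop:
    those sessions depend on the live interaction and cannot stand in
    for retraining ("personal and non-transferable").
    """
    pairs, metadata = read_training_pairs(recording)
    if metadata.get("closed_loop"):
        raise ConfigurationError(
            f"{recording}: closed-loop session logs are not replayable offline"
        )
    if not pairs:
        raise InvalidInputError(f"{recording}: recording contains no pairs")
    B, _ = train_open_loop(pairs, cfg, passes=passes)
    return B
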