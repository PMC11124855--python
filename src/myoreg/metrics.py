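"""Task performance metrics: completion rate, path efficiency, attempt ratio.

Offline error measures (MSE, R^2) say little about whether a user can
actually acquire targets in real time, so performance is summarised by:

* Completion rate (CR) — hits over trials: can the target be acquired
  at all within the time allowed?
* Path efficiency (PE) — straight-line distance from the trial's
  starting cursor position to the target, divided by the distance the
  cursor actually travelled: how direct was the movement?
* Attempt ratio (AR) — total entrances into the hit region divided by
  the number of hits: how many approaches did a successful acquisition
  cost on average?  Undefined (reported absent) when nothing was hit.

Metrics are reported overall and stratified by the number of active
DoFs in the target (rest / 1 / 2 / 3), the axis along which task
difficulty grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .task import TrialRecord, path_length

__all__ = [
    "SessionMetrics",
    "completion_rate",
    "path_efficiency",
    "attempt_ratio",
    "stratify",
    "metrics_frame",
    "write_metrics_csv",
]

STRATA = ("all", "rest", "1-dof", "2-dof", "3-dof")

_EPS = 1e-12


@dataclass(frozen=True)
class SessionMetrics:
    """Summary of one stratum of one test session.

    ``path_efficiency`` is the mean over trials with a defined PE;
    ``attempt_ratio`` and ``path_efficiency`` are None when undefined.
    """

    stratum: str
    n_trials: int
    n_hits: int
    completion_rate: float
    path_efficiency: float | None
    attempt_ratio: float | None


def completion_rate(trials: Sequence[TrialRecord]) -> float:
    """Fraction of trials that were hits."""
    trials = list(trials)
    if not trials:
        raise InvalidInputError("completion_rate needs at least one trial")
    return sum(t.hit for t in trials) / len(trials)


def path_efficiency(trial: TrialRecord, upto_hit: bool = True) -> float | None:
    """Straight-line distance to the target over the distance travelled.

    The numerator uses the trial's actual starting cursor position (it
    carries over from the previous trial).  On a hit the path is taken
    up to the moment the hold completed; on a miss the whole trajectory
    counts.  Capped at 1.0; None when the start already coincides with
    the target or the cursor never moved.
    """
    required = float(np.linalg.norm(np.asarray(trial.target, dtype=float) - trial.start_position))
    if required < _EPS:
        return None
    traj = trial.trajectory
    if upto_hit and trial.hit and trial.time_to_hit is not None:
        end = int(round(trial.time_to_hit / trial.tick))
        traj = traj[: end + 1]
    traveled = path_length(traj)
    if traveled < _EPS:
        return None
    return min(1.0, required / traveled)


def attempt_ratio(trials: Sequence[TrialRecord]) -> float | None:
    """Total target entrances over the number of hit trials; None at 0 hits."""
    trials = list(trials)
    if not trials:
        raise InvalidInputError("attempt_ratio needs at least one trial")
    hits = sum(t.hit for t in trials)
    if hits == 0:
        return None
    return sum(t.entrances for t in trials) / hits


def _summarize(stratum: str, trials: Sequence[TrialRecord]) -> SessionMetrics:
    pes = [pe for t in trials if (pe := path_efficiency(t)) is not None]
    return SessionMetrics(
        stratum=stratum,
        n_trials=len(trials),
        n_hits=sum(t.hit for t in trials),
        completion_rate=completion_rate(trials),
        path_efficiency=float(np.mean(pes)) if pes else None,
        attempt_ratio=attempt_ratio(trials),
    )


def stratify(trials: Sequence[TrialRecord]) -> dict[str, SessionMetrics]:
    """Metrics overall and per active-DoF count (rest / 1 / 2 / 3)."""
    trials = list(trials)
    if not trials:
        raise InvalidInputError("stratify needs at least one trial")
    out = {"all": _summarize("all", trials)}
    by_k = {0: "rest", 1: "1-dof", 2: "2-dof", 3: "3-dof"}
    for k, name in by_k.items():
        subset = [t for t in trials if t.active_dofs == k]
        if subset:
            out[name] = _summarize(name, subset)
    return out


def metrics_frame(metrics: dict[str, SessionMetrics]) -> pd.DataFrame:
    """Tabular view, one row per stratum in canonical order."""
    rows = []
    for name in STRATA:
        if name not in metrics:
            continue
        m = metrics[name]
        rows.append(
            {
                "stratum": m.stratum,
                "n_trials": m.n_trials,
                "n_hits": m.n_hits,
                "CR": m.completion_rate,
                "PE_mean": m.path_efficiency,
                "AR": m.attempt_ratio,
            }
        )
    return pd.DataFrame(rows)


def write_metrics_csv(path: str | Path, metrics: dict[str, SessionMetrics]) -> None:
    metrics_frame(metrics).to_csv(path, index=False)
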