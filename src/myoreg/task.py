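"""The virtual target-acquisition test: 27 targets, 20 s, 10% hit radius.

After training, the decoder is frozen and the user steers the cursor —
the decoder output, refreshed every control tick — onto each of the 27
grid targets in pseudo-random order.  A target counts as a hit when the
cursor stays within the hit radius for one uninterrupted second, the
hold completing within the 20 s allowed per target.

The "10% Euclidean error in the 3-D space" is normalised by the
workspace diagonal (2 sqrt(3) in units where each DoF spans [-1, 1]),
the one scalar that makes the criterion well-defined for all targets
including rest; the normaliser is a config knob.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError
from .features import RollingWindow, WindowingConfig
from .protocols import all_targets
from .regressor import CoefficientMatrix, predict

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "detect_hit",
    "run_test",
    "path_length",
    "write_trials_jsonl",
    "write_trials_csv",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the acquisition test.

    hit radius = hit_fraction x workspace diagonal
               = hit_fraction x 2 sqrt(3) x workspace_half_range
    (~0.346 normalized units at the defaults).  ``radius_normalizer``
    may be set to "axis" to normalise by one axis span (2 x half range)
    instead of the diagonal.
    """

    timeout: float = 20.0
    hold_duration: float = 1.0
    hit_fraction: float = 0.10
    workspace_half_range: float = 1.0
    cursor_clip: float = 1.5
    tick: float = 0.040
    reset_cursor: bool = False
    radius_normalizer: str = "diagonal"

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise ConfigurationError(f"tick must be > 0, got {self.tick}")
        if not (0 < self.hold_duration <= self.timeout):
            raise ConfigurationError("need 0 < hold_duration <= timeout")
        if self.hit_fraction <= 0 or self.workspace_half_range <= 0:
            raise ConfigurationError("hit_fraction and workspace_half_range must be > 0")
        if self.radius_normalizer not in ("diagonal", "axis"):
            raise ConfigurationError(
                f"radius_normalizer must be 'diagonal' or 'axis', got {self.radius_normalizer!r}"
            )

    @property
    def hit_radius(self) -> float:
        if self.radius_normalizer == "diagonal":
            return self.hit_fraction * 2.0 * math.sqrt(3.0) * self.workspace_half_range
        return self.hit_fraction * 2.0 * self.workspace_half_range


@dataclass
class TrialRecord:
    """One test target's full bookkeeping.

    ``trajectory`` holds the cursor at times ``i * tick`` with sample 0
    the carried-over cursor at trial start; ``time_to_hit`` is the time
    at which the first qualifying hold completed (None on a miss).
    """

    target: np.ndarray
    trajectory: np.ndarray  # (n, 3)
    hit: bool
    time_to_hit: float | None
    entrances: int
    path_length: float
    tick: float = 0.040

    @property
    def start_position(self) -> np.ndarray:
        return self.trajectory[0]

    @property
    def active_dofs(self) -> int:
        return int(np.count_nonzero(self.target))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.trajectory.shape[0]) * self.tick


def path_length(trajectory: np.ndarray) -> float:
    """Summed Euclidean step lengths along a trajectory."""
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(trajectory, axis=0), axis=1)))


def detect_hit(
    trajectory: np.ndarray,
    target: np.ndarray,
    cfg: TaskConfig | None = None,
) -> tuple[bool, float | None, int]:
    """Scan a trajectory for the hold-to-hit criterion.

    Sample ``i`` sits at time ``i * tick``.  A qualifying hold is a run
    of consecutive samples inside the hit radius whose time span (last
    minus first timestamp) reaches ``hold_duration``, completing at or
    before ``timeout``.  Entrances count outside-to-inside transitions
    over the whole trajectory; starting inside counts as one.

    Returns ``(hit, time_to_hit, entrances)`` with ``time_to_hit`` the
    end time of the first qualifying hold, or None.
    """
    cfg = cfg or TaskConfig()
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[0] < 1 or trajectory.shape[1] != 3:
        raise InvalidInputError(
            f"trajectory must be a non-empty (n, 3) array, got shape {trajectory.shape}"
        )
    target = np.asarray(target, dtype=float)
    inside = np.linalg.norm(trajectory - target, axis=1) < cfg.hit_radius

    entrances = int(inside[0]) + int(np.sum(inside[1:] & ~inside[:-1]))

    # samples needed so the run spans >= hold_duration
    need = int(math.ceil(cfg.hold_duration / cfg.tick - 1e-9)) + 1
    run = 0
    for i, ok in enumerate(inside):
        run = run + 1 if ok else 0
        if run >= need:
            t = i * cfg.tick
            if t <= cfg.timeout + 1e-9:
                return True, t, entrances
            break
    return False, None, entrances


def run_test(
    controller: CoefficientMatrix,
    user,
    seed: int,
    cfg: TaskConfig | None = None,
    windowing: WindowingConfig | None = None,
    sample_rate: float = 200.0,
) -> list[TrialRecord]:
    """Run the frozen-controller acquisition test against a user.

    Presents all 27 targets in a seeded pseudo-random order.  Per tick
    the user forms its intent from the prompted target and the visible
    cursor, emits one hop of EMG, and the cursor becomes the decoder
    output clipped to ``cursor_clip``; the decoder never adapts.  A
    trial ends at the first completed hold or at the timeout, and the
    cursor (and EMG window buffer) carry over to the next trial unless
    ``reset_cursor`` is set.
    """
    cfg = cfg or TaskConfig()
    windowing = windowing or WindowingConfig()
    if abs(windowing.hop_duration - cfg.tick) > 1e-12:
        raise ConfigurationError(
            f"control tick ({cfg.tick}) must equal the window hop ({windowing.hop_duration})"
        )
    hop = windowing.hop_samples(sample_rate)
    win = RollingWindow(windowing.window_samples(sample_rate), user.channel_count, sample_rate)
    order = np.random.default_rng(seed).permutation(27)
    targets = [np.asarray(all_targets()[k], dtype=float) for k in order]

    need = int(math.ceil(cfg.hold_duration / cfg.tick - 1e-9)) + 1
    max_ticks = int(round(cfg.timeout / cfg.tick))
    cursor = np.zeros(3)
    records: list[TrialRecord] = []
    for target in targets:
        if cfg.reset_cursor:
            cursor = np.zeros(3)
            win.reset()
        traj = [cursor.copy()]
        run = 1 if np.linalg.norm(cursor - target) < cfg.hit_radius else 0
        for _ in range(max_ticks):
            if getattr(user, "feedback_gain", None) is not None:
                intent = user.closed_loop_intent(target, cursor)
            else:
                intent = target
            feat = win.push(user.emit_emg(intent, hop))
            if feat is not None:
                cursor = np.clip(predict(controller, feat), -cfg.cursor_clip, cfg.cursor_clip)
            traj.append(cursor.copy())
            if np.linalg.norm(cursor - target) < cfg.hit_radius:
                run += 1
                if run >= need:
                    break
            else:
                run = 0
        trajectory = np.asarray(traj)
        hit, time_to_hit, entrances = detect_hit(trajectory, target, cfg)
        records.append(
            TrialRecord(
                target=target,
                trajectory=trajectory,
                hit=hit,
                time_to_hit=time_to_hit,
                entrances=entrances,
                path_length=path_length(trajectory),
                tick=cfg.tick,
            )
        )
    return records


# ---------------------------------------------------------------------------
# session logs

def _trial_row(trial: TrialRecord, include_trajectory: bool) -> dict:
    row = {
        "target": trial.target.tolist(),
        "active_dofs": trial.active_dofs,
        "hit": bool(trial.hit),
        "time_to_hit": trial.time_to_hit,
        "entrances": trial.entrances,
        "path_length": trial.path_length,
        "start_position": trial.start_position.tolist(),
        "tick": trial.tick,
    }
    if include_trajectory:
        row["trajectory"] = trial.trajectory.tolist()
    return row


def write_trials_jsonl(
    path: str | Path, trials: list[TrialRecord], include_trajectory: bool = False
) -> None:
    """One JSON record per trial (optionally with the full trajectory)."""
    with open(path, "w") as fh:
        for trial in trials:
            fh.write(json.dumps(_trial_row(trial, include_trajectory), sort_keys=True) + "\n")


def write_trials_csv(path: str | Path, trials: list[TrialRecord]) -> None:
    """Compact per-trial summary (no trajectories)."""
    rows = []
    for k, trial in enumerate(trials):
        rows.append(
            {
                "trial": k,
                "d1": trial.target[0],
                "d2": trial.target[1],
                "d3": trial.target[2],
                "active_dofs": trial.active_dofs,
                "hit": bool(trial.hit),
                "time_to_hit": trial.time_to_hit,
                "entrances": trial.entrances,
                "path_length": trial.path_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
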