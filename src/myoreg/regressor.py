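"""Per-DoF adaptive linear decoding of motor intent from RMS features.

The controller is a bank of three independent linear regressors, one per
degree of freedom (wrist flexion-extension, radial-ulnar deviation, hand
open-close)::

    y_i(t) = sum_j  b_ij(t) * x_j(t),        i = 1, 2, 3

where ``x`` is the per-channel RMS feature vector and ``B = (b_ij)`` is
a 3 x M coefficient matrix estimated online by minimising the mean
squared error between the prompted target ``d(t)`` and the estimate
``y(t)``.  The adaptive rule is normalised least-mean-squares (NLMS):
its step size is scale-free with respect to EMG amplitude, which matters
because RMS amplitudes vary widely across channels and users.

Two training modes are provided:

* :func:`train_open_loop` — sequential NLMS over recorded
  (feature, target) pairs; fully replayable offline.
* :func:`train_closed_loop` — the co-adaptive loop: at every 40 ms
  control tick a (virtual) user emits EMG given the current prompt and,
  when the prompt carries feedback, the live cursor estimate; the
  decoder updates against the prompted target and the cursor refreshes.
  Because the user's behaviour depends on the evolving decoder, a
  closed-loop session is inherently online and non-transferable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError
from .features import FeatureVector, RollingWindow, WindowingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientMatrix",
    "AdaptationConfig",
    "SessionLog",
    "predict",
    "nlms_update",
    "train_open_loop",
    "train_closed_loop",
    "save_coefficients",
    "load_coefficients",
    "write_training_pairs",
    "read_training_pairs",
]

DOF_COUNT = 3


@dataclass
class CoefficientMatrix:
    """The decoder state: a (3, M) weight matrix, entry (i, j) = b_ij."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != DOF_COUNT:
            raise InvalidInputError(
                f"weights must be ({DOF_COUNT}, M), got shape {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InvalidInputError("weights must be finite")

    @classmethod
    def zeros(cls, channel_count: int = 8) -> "CoefficientMatrix":
        return cls(np.zeros((DOF_COUNT, channel_count)))

    @property
    def dof_count(self) -> int:
        return self.weights.shape[0]

    @property
    def channel_count(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "CoefficientMatrix":
        return CoefficientMatrix(self.weights.copy())


@dataclass(frozen=True)
class AdaptationConfig:
    """NLMS hyper-parameters.

    learning_rate : dimensionless step mu in (0, 2); 0.5 by default, the
        middle of the fast-and-stable range.
    regularizer : small epsilon added to the window input power in the
        NLMS denominator so silent windows cannot blow up the step.
    onset_ramp : seconds over which the desired target ramps linearly
        from 0 at each prompt onset (0 disables; the default, so the
        desired signal is a step over the prompt duration).
    transition_guard : seconds after each prompt onset during which
        adaptation is paused (the cursor still refreshes).  Windows that
        straddle a prompt boundary mix EMG from two intents, and because
        NLMS normalises by input power those few inconsistent windows
        can erase a learned row outright; guarding one full window
        length (0.2 s, on the order of human reaction time) keeps every
        update a consistent (feature, target) pair.
    """

    learning_rate: float = 0.5
    regularizer: float = 1e-6
    onset_ramp: float = 0.0
    transition_guard: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.learning_rate < 2.0):
            raise ConfigurationError(
                f"learning_rate must be in [0, 2) for NLMS stability, got {self.learning_rate}"
            )
        if self.regularizer < 0.0:
            raise ConfigurationError(f"regularizer must be >= 0, got {self.regularizer}")
        if self.onset_ramp < 0.0:
            raise ConfigurationError(f"onset_ramp must be >= 0, got {self.onset_ramp}")
        if self.transition_guard < 0.0:
            raise ConfigurationError(
                f"transition_guard must be >= 0, got {self.transition_guard}"
            )


def _as_values(x: FeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.values
    return np.asarray(x, dtype=float)


def predict(B: CoefficientMatrix, x: FeatureVector | np.ndarray) -> np.ndarray:
    """Decode a 3-DoF position estimate ``y = B x`` from one feature vector."""
    xv = _as_values(x)
    if xv.shape != (B.channel_count,):
        raise InvalidInputError(
            f"feature vector of shape {xv.shape} does not match {B.channel_count} channels"
        )
    return B.weights @ xv


def nlms_update(
    B: CoefficientMatrix,
    x: FeatureVector | np.ndarray,
    d: np.ndarray,
    cfg: AdaptationConfig | None = None,
) -> CoefficientMatrix:
    """One NLMS step against the desired 3-DoF target ``d``.

    Each DoF row is updated independently with the same input::

        e_i = d_i - (B x)_i
        B'[i, :] = B[i, :] + mu * e_i * x / (eps + ||x||^2)

    Non-finite inputs skip the update (with a warning) so a corrupt
    window can never destroy the decoder state.
    """
    cfg = cfg or AdaptationConfig()
    xv = _as_values(x)
    dv = np.asarray(d, dtype=float)
    if dv.shape != (B.dof_count,):
        raise InvalidInputError(f"target of shape {dv.shape} does not match {B.dof_count} DoFs")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(dv))):
        logger.warning("non-finite feature or target; NLMS update skipped")
        return B
    e = dv - predict(B, xv)
    power = cfg.regularizer + float(xv @ xv)
    if power <= 0.0:
        return B
    return CoefficientMatrix(B.weights + cfg.learning_rate * np.outer(e, xv) / power)


def train_open_loop(
    pairs: Sequence[tuple[FeatureVector | np.ndarray, np.ndarray]],
    cfg: AdaptationConfig | None = None,
    passes: int = 1,
) -> tuple[CoefficientMatrix, np.ndarray]:
    """Sequential NLMS over recorded (feature, target) pairs.

    Starts from zero weights and is deterministic given the pair order.
    Returns the final coefficient matrix and the per-step squared-error
    trace ``||e||^2`` (error measured before each update).
    """
    cfg = cfg or AdaptationConfig()
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("train_open_loop needs at least one (feature, target) pair")
    channel_count = _as_values(pairs[0][0]).shape[0]
    B = CoefficientMatrix.zeros(channel_count)
    trace = []
    for _ in range(passes):
        for x, d in pairs:
            e = np.asarray(d, dtype=float) - predict(B, x)
            trace.append(float(e @ e))
            B = nlms_update(B, x, d, cfg)
    return B, np.asarray(trace)


@dataclass
class SessionLog:
    """Per-update record of one training session.

    One row per decoder update (ticks before the first full EMG window
    are not logged; no update happened there).  ``targets`` holds the
    effective desired signal the update used, so replaying the rows
    through :func:`train_open_loop` reproduces the weights exactly —
    unless the session used feedback, in which case the rows are a
    faithful log but the interaction could not be regenerated.
    """

    times: np.ndarray
    targets: np.ndarray
    intents: np.ndarray
    features: np.ndarray
    cursors: np.ndarray
    squared_errors: np.ndarray
    feedback_used: bool
    metadata: dict = field(default_factory=dict)

    def to_pairs_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.times}
        for j in range(self.features.shape[1]):
            cols[f"x{j + 1}"] = self.features[:, j]
        for i in range(self.targets.shape[1]):
            cols[f"d{i + 1}"] = self.targets[:, i]
        return pd.DataFrame(cols)


def train_closed_loop(
    protocol: Sequence,
    user,
    cfg: AdaptationConfig | None = None,
    windowing: WindowingConfig | None = None,
    sample_rate: float = 200.0,
) -> tuple[CoefficientMatrix, SessionLog]:
    """Run one real-time training session against a (virtual) user.

    ``protocol`` is a sequence of target prompts (see
    :mod:`myoreg.protocols`); ``user`` must provide ``channel_count``,
    ``emit_emg(intent, n_samples)`` and, if any prompt carries feedback,
    ``closed_loop_intent(prompt, cursor)`` with a configured gain.

    At each control tick (one window hop): the user forms an intent from
    the prompt (corrected by the visible cursor when feedback is on),
    emits one hop of EMG, the trailing window's RMS is extracted, the
    decoder does one NLMS step toward the prompted target, and the
    cursor estimate refreshes.
    """
    cfg = cfg or AdaptationConfig()
    windowing = windowing or WindowingConfig()
    prompts = list(protocol)
    if not prompts:
        raise InvalidInputError("empty protocol")
    feedback_used = any(p.feedback for p in prompts)
    if feedback_used and getattr(user, "feedback_gain", None) is None:
        raise ConfigurationError(
            "protocol requests user feedback but the user has no feedback model "
            "(feedback_gain is None)"
        )
    hop = windowing.hop_samples(sample_rate)
    win = RollingWindow(windowing.window_samples(sample_rate), user.channel_count, sample_rate)
    tick = windowing.hop_duration

    B = CoefficientMatrix.zeros(user.channel_count)
    cursor = np.zeros(DOF_COUNT)
    rows_t, rows_d, rows_i, rows_x, rows_y, rows_e = [], [], [], [], [], []
    t = 0.0
    for prompt in prompts:
        target = np.asarray(prompt.target, dtype=float)
        n_ticks = int(round(prompt.duration / tick))
        for k in range(n_ticks):
            if prompt.feedback:
                intent = user.closed_loop_intent(target, cursor)
            else:
                intent = target
            feat = win.push(user.emit_emg(intent, hop))
            t += tick
            if feat is None:
                continue
            elapsed = (k + 1) * tick
            if elapsed + 1e-12 < cfg.transition_guard:
                # window still straddles the prompt boundary: no update,
                # but the cursor keeps tracking for the user's feedback
                cursor = predict(B, feat)
                continue
            if cfg.onset_ramp > 0.0:
                desired = target * min(1.0, elapsed / cfg.onset_ramp)
            else:
                desired = target
            e = desired - predict(B, feat)
            B = nlms_update(B, feat, desired, cfg)
            cursor = predict(B, feat)
            rows_t.append(t)
            rows_d.append(desired)
            rows_i.append(intent)
            rows_x.append(feat.values)
            rows_y.append(cursor)
            rows_e.append(float(e @ e))

    log = SessionLog(
        times=np.asarray(rows_t),
        targets=np.asarray(rows_d),
        intents=np.asarray(rows_i),
        features=np.asarray(rows_x),
        cursors=np.asarray(rows_y),
        squared_errors=np.asarray(rows_e),
        feedback_used=feedback_used,
        metadata={
            "learning_rate": cfg.learning_rate,
            "regularizer": cfg.regularizer,
            "onset_ramp": cfg.onset_ramp,
            "window_duration": windowing.window_duration,
            "hop_duration": windowing.hop_duration,
            "sample_rate": sample_rate,
            "n_prompts": len(prompts),
        },
    )
    return B, log


# ---------------------------------------------------------------------------
# serialization

def save_coefficients(
    path: str | Path, B: CoefficientMatrix, metadata: dict | None = None
) -> None:
    """Write weights as a 3 x M CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    frame = pd.DataFrame(B.weights, columns=[f"ch{j + 1}" for j in range(B.channel_count)])
    frame.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, indent=2, sort_keys=True))


def load_coefficients(path: str | Path) -> tuple[CoefficientMatrix, dict]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    B = CoefficientMatrix(frame.to_numpy(dtype=float))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return B, metadata


def write_training_pairs(path: str | Path, log: SessionLog) -> None:
    """Write a session's (feature, target) rows as CSV with a JSON sidecar.

    The sidecar records whether the session used feedback; closed-loop
    sessions are flagged so offline replay can refuse them.
    """
    path = Path(path)
    log.to_pairs_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"closed_loop": bool(log.feedback_used), **log.metadata},
                   indent=2, sort_keys=True)
    )


def read_training_pairs(
    path: str | Path,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict]:
    """Read a pair recording (columns t, x1..xM, d1..d3), sorted by time."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty pair recording") from exc
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: malformed pair recording: {exc}") from exc
    x_cols = [c for c in frame.columns if c.startswith("x")]
    d_cols = [c for c in frame.columns if c.startswith("d")]
    if "t" not in frame.columns or not x_cols or len(d_cols) != DOF_COUNT:
        raise InvalidInputError(
            f"{path}: expected columns t, x1..xM, d1..d{DOF_COUNT}, got {list(frame.columns)}"
        )
    bad = frame[frame.isna().any(axis=1)]
    if not bad.empty:
        # +2: header line plus 1-based numbering
        raise InvalidInputError(f"{path}: unparseable value at line {int(bad.index[0]) + 2}")
    frame = frame.sort_values("t", kind="stable").reset_index(drop=True)
    xs = frame[x_cols].to_numpy(dtype=float)
    ds = frame[d_cols].to_numpy(dtype=float)
    pairs = [(xs[k], ds[k]) for k in range(len(frame))]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return pairs, metadata
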