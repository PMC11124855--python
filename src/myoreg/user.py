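"""A virtual user: synthetic surface EMG from 3-DoF motor intent.

The whole pipeline consumes only window RMS, so EMG is modelled as
amplitude-modulated noise — the standard surface-EMG envelope model —
rather than motor-unit spike trains.  A muscle synergy matrix ``S``
(8 x 3) maps intent ``d`` to per-channel activation::

    a = max(0, S d + baseline)

and each emitted sample on channel j is zero-mean with standard
deviation ``a_j * (1 + jitter)``, jitter drawn once per emitted block
from uniform(-noise_scale, +noise_scale).  A window's expected RMS is
therefore ~ ``a_j`` — exactly the statistical structure the RMS feature
and the linear decoder assume.

Synergies are built from antagonist channel pairs: for each DoF one
channel loads +1 and its partner -1, so pushing a DoF to +1 or -1
activates a distinct dominant channel (rectification silences the
antagonist), loosely matching electrodes over antagonist muscle groups.
Crosstalk adds random off-structure loadings; two spare channels carry
crosstalk only.

When the user can see the cursor it corrects its intent proportionally::

    intent = prompt + g * (prompt - cursor)

modelling a human exaggerating contractions in the direction of the
residual error.  With g = 0 (or ``feedback_gain=None``) the user is
purely feed-forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = ["VirtualUser", "make_virtual_user", "make_ideal_user", "DIFFICULTY_PRESETS"]

# noise_scale: multiplicative RMS jitter per window; crosstalk: sd of the
# random loadings added to the antagonist-pair synergy structure;
# baseline: resting activation per channel.
DIFFICULTY_PRESETS: dict[str, dict[str, float]] = {
    "easy": {"noise_scale": 0.05, "crosstalk": 0.10, "baseline": 0.02},
    "medium": {"noise_scale": 0.10, "crosstalk": 0.30, "baseline": 0.05},
    "hard": {"noise_scale": 0.20, "crosstalk": 0.50, "baseline": 0.10},
}

EMISSION_MODES = ("gaussian", "deterministic")


@dataclass
class VirtualUser:
    """State of one simulated participant.

    ``emission`` selects the sample carrier: "gaussian" (default) draws
    zero-mean Gaussian samples, so window RMS scatters around the
    activation with the chi-distribution concentration of the window
    length; "deterministic" emits a zero-mean alternating-sign carrier
    whose window RMS equals the activation exactly — the noise-free
    construction used for parameter-recovery validation.
    """

    synergy: np.ndarray  # (channels, 3)
    baseline: np.ndarray  # (channels,)
    noise_scale: float = 0.1
    feedback_gain: float | None = 0.5
    adaptation_rate: float = 0.0
    rng_seed: int = 0
    emission: str = "gaussian"
    intent_clip: float = 1.5
    rng: np.random.Generator = field(init=False, repr=False)
    _phase: int = field(init=False, default=0, repr=False)

    def __post_init__(self) -> None:
        self.synergy = np.asarray(self.synergy, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.synergy.ndim != 2 or self.synergy.shape[1] != 3:
            raise ConfigurationError(f"synergy must be (channels, 3), got {self.synergy.shape}")
        if self.baseline.shape != (self.synergy.shape[0],):
            raise ConfigurationError("baseline length must match synergy channel count")
        if np.any(self.baseline < 0):
            raise ConfigurationError("baseline activations must be non-negative")
        if self.noise_scale < 0:
            raise ConfigurationError(f"noise_scale must be >= 0, got {self.noise_scale}")
        if self.feedback_gain is not None and not (0.0 <= self.feedback_gain <= 1.0):
            raise ConfigurationError(f"feedback_gain must be in [0, 1], got {self.feedback_gain}")
        if self.emission not in EMISSION_MODES:
            raise ConfigurationError(f"emission must be one of {EMISSION_MODES}")
        self.rng = np.random.default_rng(self.rng_seed)

    @property
    def channel_count(self) -> int:
        return self.synergy.shape[0]

    def activation(self, intent: np.ndarray) -> np.ndarray:
        """Rectified per-channel activation for an intent: max(0, S d + baseline)."""
        intent = np.asarray(intent, dtype=float)
        return np.maximum(0.0, self.synergy @ intent + self.baseline)

    def emit_emg(self, intent: np.ndarray, n_samples: int) -> np.ndarray:
        """One block of raw EMG samples for a held intent.

        Returns an (n_samples, channels) array whose per-channel RMS
        concentrates on ``activation(intent)`` (exactly equal to it in
        deterministic mode with zero jitter).
        """
        if n_samples < 1:
            raise InvalidInputError(f"n_samples must be >= 1, got {n_samples}")
        if self.adaptation_rate > 0.0:
            # slow random drift of the synergy: fatigue / electrode shift stand-in
            self.synergy = self.synergy + self.adaptation_rate * self.rng.normal(
                0.0, 1e-3, size=self.synergy.shape
            )
        a = self.activation(intent)
        if self.noise_scale > 0.0:
            a = a * (1.0 + self.rng.uniform(-self.noise_scale, self.noise_scale))
        if self.emission == "gaussian":
            return self.rng.normal(0.0, 1.0, size=(n_samples, self.channel_count)) * a
        # deterministic: alternating-sign carrier, continuous across calls
        signs = np.where((self._phase + np.arange(n_samples)) % 2 == 0, 1.0, -1.0)
        self._phase = (self._phase + n_samples) % 2
        return signs[:, None] * a[None, :]

    def closed_loop_intent(self, prompt: np.ndarray, cursor: np.ndarray) -> np.ndarray:
        """Feedback-corrected intent: prompt + g (prompt - cursor), clipped."""
        prompt = np.asarray(prompt, dtype=float)
        if self.feedback_gain is None:
            return prompt
        cursor = np.asarray(cursor, dtype=float)
        intent = prompt + self.feedback_gain * (prompt - cursor)
        return np.clip(intent, -self.intent_clip, self.intent_clip)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "synergy": self.synergy.tolist(),
                "baseline": self.baseline.tolist(),
                "noise_scale": self.noise_scale,
                "feedback_gain": self.feedback_gain,
                "adaptation_rate": self.adaptation_rate,
                "rng_seed": self.rng_seed,
                "emission": self.emission,
                "intent_clip": self.intent_clip,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "VirtualUser":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(
            synergy=np.asarray(data["synergy"], dtype=float),
            baseline=np.asarray(data["baseline"], dtype=float),
            noise_scale=data["noise_scale"],
            feedback_gain=data["feedback_gain"],
            adaptation_rate=data.get("adaptation_rate", 0.0),
            rng_seed=data["rng_seed"],
            emission=data.get("emission", "gaussian"),
            intent_clip=data.get("intent_clip", 1.5),
        )


def _base_synergy(channel_count: int = 8) -> np.ndarray:
    """Antagonist-pair structure: channel 2i loads +1 and channel 2i+1
    loads -1 on DoF i; remaining channels load nothing."""
    S = np.zeros((channel_count, 3))
    for i in range(3):
        S[2 * i, i] = 1.0
        S[2 * i + 1, i] = -1.0
    return S


def make_virtual_user(
    seed: int,
    difficulty: str = "medium",
    channel_count: int = 8,
    max_condition: float = 10.0,
    **overrides,
) -> VirtualUser:
    """Draw a random virtual user of the given difficulty.

    The synergy is the antagonist-pair structure plus Gaussian crosstalk
    and per-channel gain variation, redrawn (deterministically, from the
    same stream) until it has full column rank with condition number
    below ``max_condition`` — so the 3 intents are decodable from the
    8 channels.  ``overrides`` replace any :class:`VirtualUser` field.
    """
    if difficulty not in DIFFICULTY_PRESETS:
        raise ConfigurationError(
            f"unknown difficulty {difficulty!r}; expected one of {sorted(DIFFICULTY_PRESETS)}"
        )
    preset = DIFFICULTY_PRESETS[difficulty]
    rng = np.random.default_rng(seed)
    for _ in range(100):
        gains = rng.uniform(0.8, 1.2, size=channel_count)
        S = gains[:, None] * (
            _base_synergy(channel_count)
            + preset["crosstalk"] * rng.normal(0.0, 1.0, size=(channel_count, 3))
        )
        if np.linalg.matrix_rank(S) == 3 and np.linalg.cond(S) < max_condition:
            break
    else:  # pragma: no cover - practically unreachable
        raise ConfigurationError("could not draw a well-conditioned synergy")
    fields = dict(
        synergy=S,
        baseline=np.full(channel_count, preset["baseline"]),
        noise_scale=preset["noise_scale"],
        feedback_gain=0.5,
        rng_seed=seed,
    )
    fields.update(overrides)
    return VirtualUser(**fields)


def make_ideal_user(seed: int, feedback_gain: float | None = 0.5) -> VirtualUser:
    """The noise-free, exactly decodable construction used for validation.

    Pure antagonist-pair synergy (no crosstalk), zero baseline, zero RMS
    jitter and the deterministic carrier: every window's RMS equals the
    activation exactly, and the map from intent to expected RMS is
    exactly invertible by a 3 x 8 matrix on the target grid.
    """
    return VirtualUser(
        synergy=_base_synergy(),
        baseline=np.zeros(8),
        noise_scale=0.0,
        feedback_gain=feedback_gain,
        rng_seed=seed,
        emission="deterministic",
    )
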