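"""Target spaces and prompt sequences for the three training protocols.

Targets live on the 27-point grid {-1, 0, +1}^3 over the three DoFs
(flexion-extension, radial-ulnar deviation, hand open-close): the rest
position, 6 one-DoF targets, 12 two-DoF targets and 8 three-DoF targets.

A *lap* visits the 6 one-DoF targets once in pseudo-random order, with a
rest prompt after each.  The protocols differ in what follows and in
whether the user sees the decoder output:

* Protocol I   — five laps, no user feedback (blind baseline).
* Protocol II  — one lap, then the 20 combined (2- and 3-DoF) targets
  once each with rests, still blind.
* Protocol III — identical target ordering to Protocol II at the same
  seed, but the cursor is shown to the user during the combined targets
  (co-adaptive training).  Rest prompts stay blind: showing the cursor
  at rest makes the user push against it, which generates corrective
  EMG labelled "rest" and unlearns the mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "TargetPrompt",
    "ProtocolSpec",
    "enumerate_targets",
    "all_targets",
    "make_lap",
    "protocol_sequence",
    "export_protocol_csv",
]

PROTOCOL_IDS = ("I", "II", "III")
REST = (0, 0, 0)


@dataclass(frozen=True)
class TargetPrompt:
    """One visual cue: a grid target held for ``duration`` seconds.

    ``feedback`` says whether the user sees the live cursor during the
    prompt; ``phase_label`` is one of {"lap", "combined", "rest"}.
    """

    target: tuple[int, int, int]
    duration: float
    feedback: bool = False
    phase_label: str = "lap"

    def __post_init__(self) -> None:
        if self.phase_label not in ("lap", "combined", "rest"):
            raise ConfigurationError(f"unknown phase_label {self.phase_label!r}")
        if self.phase_label == "rest" and tuple(self.target) != REST:
            raise ConfigurationError("rest prompts must target (0, 0, 0)")
        if any(v not in (-1, 0, 1) for v in self.target):
            raise ConfigurationError(f"target components must be in {{-1,0,1}}, got {self.target}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Everything that determines a prompt sequence.

    The sequence is a pure function of (protocol_id, seed, durations).
    """

    protocol_id: str
    seed: int = 0
    prompt_duration: float = 3.0
    rest_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.protocol_id not in PROTOCOL_IDS:
            raise ConfigurationError(
                f"unknown protocol {self.protocol_id!r}; expected one of {PROTOCOL_IDS}"
            )
        if self.prompt_duration <= 0 or self.rest_duration <= 0:
            raise ConfigurationError("prompt and rest durations must be positive")


def enumerate_targets(active_dofs: int) -> list[tuple[int, int, int]]:
    """All grid targets with exactly ``active_dofs`` nonzero components.

    Canonical (lexicographic) order.  Counts: 1 / 6 / 12 / 8 for
    0 / 1 / 2 / 3 active DoFs — 27 targets in total.
    """
    if not 0 <= active_dofs <= 3:
        raise InvalidInputError(f"active_dofs must be in 0..3, got {active_dofs}")
    return [
        t
        for t in itertools.product((-1, 0, 1), repeat=3)
        if sum(v != 0 for v in t) == active_dofs
    ]


def all_targets() -> list[tuple[int, int, int]]:
    """The full 27-target space in canonical (lexicographic) order."""
    return list(itertools.product((-1, 0, 1), repeat=3))


def _shuffled(items: list, rng: np.random.Generator) -> list:
    order = rng.permutation(len(items))
    return [items[k] for k in order]


def _lap(
    rng: np.random.Generator,
    prompt_duration: float,
    rest_duration: float,
    feedback: bool = False,
) -> list[TargetPrompt]:
    prompts: list[TargetPrompt] = []
    for target in _shuffled(enumerate_targets(1), rng):
        prompts.append(TargetPrompt(target, prompt_duration, feedback, "lap"))
        prompts.append(TargetPrompt(REST, rest_duration, feedback, "rest"))
    return prompts


def make_lap(
    seed: int,
    prompt_duration: float = 3.0,
    rest_duration: float = 2.0,
    feedback: bool = False,
) -> list[TargetPrompt]:
    """One lap: the 6 one-DoF targets in seeded pseudo-random order,
    each followed by a rest prompt (12 prompts)."""
    return _lap(np.random.default_rng(seed), prompt_duration, rest_duration, feedback)


def protocol_sequence(spec: ProtocolSpec) -> list[TargetPrompt]:
    """Generate the full prompt sequence for one training session.

    Protocol I: 5 laps (60 prompts), all blind.  Protocol II: 1 lap plus
    the 20 combined targets each followed by rest (52 prompts), all
    blind.  Protocol III: the same targets in the same order as Protocol
    II at the same seed, with feedback on during the 20 combined
    targets.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.protocol_id == "I":
        prompts: list[TargetPrompt] = []
        for _ in range(5):
            prompts.extend(_lap(rng, spec.prompt_duration, spec.rest_duration))
        return prompts

    feedback_on_combined = spec.protocol_id == "III"
    prompts = _lap(rng, spec.prompt_duration, spec.rest_duration)
    combined = _shuffled(enumerate_targets(2) + enumerate_targets(3), rng)
    for target in combined:
        prompts.append(
            TargetPrompt(target, spec.prompt_duration, feedback_on_combined, "combined")
        )
        prompts.append(TargetPrompt(REST, spec.rest_duration, False, "rest"))
    return prompts


def export_protocol_csv(path: str | Path, prompts: list[TargetPrompt]) -> None:
    """Write a prompt sequence for audit / offline re-training."""
    rows = [
        {
            "index": k,
            "d1": p.target[0],
            "d2": p.target[1],
            "d3": p.target[2],
            "duration_s": p.duration,
            "feedback": p.feedback,
            "phase_label": p.phase_label,
        }
        for k, p in enumerate(prompts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
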