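"""Performance metrics: closed-form constructions and invariants."""

import numpy as np
import pytest

from myoreg.exceptions import InvalidInputError
from myoreg.metrics import (
    attempt_ratio,
    completion_rate,
    metrics_frame,
    path_efficiency,
    stratify,
)
from myoreg.protocols import all_targets
from myoreg.task import TaskConfig, TrialRecord, detect_hit, path_length

CFG = TaskConfig()


def make_trial(target, trajectory, cfg=CFG):
    """Build a TrialRecord from a raw trajectory via the hit detector."""
    traj = np.asarray(trajectory, dtype=float)
    target = np.asarray(target, dtype=float)
    hit, tth, entrances = detect_hit(traj, target, cfg)
    return TrialRecord(
        target=target,
        trajectory=traj,
        hit=hit,
        time_to_hit=tth,
        entrances=entrances,
        path_length=path_length(traj),
        tick=cfg.tick,
    )


def straight_trial(target, start=(0.0, 0.0, 0.0), steps=25, dwell=30):
    """Constant-velocity approach to the target, then a hold there."""
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    approach = start + np.linspace(0, 1, steps + 1)[:, None] * (target - start)
    return make_trial(target, np.concatenate([approach, np.tile(target, (dwell, 1))]))


def synthetic_record(target, hit, entrances):
    """Hand-assembled record for counting metrics (CR, AR)."""
    return TrialRecord(
        target=np.asarray(target, dtype=float),
        trajectory=np.zeros((2, 3)),
        hit=hit,
        time_to_hit=1.0 if hit else None,
        entrances=entrances,
        path_length=1.0,
        tick=CFG.tick,
    )


class TestCompletionRate:
    def test_extremes_and_exact_fraction(self):
        hits = [synthetic_record((1, 0, 0), True, 1) for _ in range(18)]
        misses = [synthetic_record((1, 0, 0), False, 0) for _ in range(9)]
        assert completion_rate(hits) == 1.0
        assert completion_rate(misses) == 0.0
        assert completion_rate(hits + misses) == pytest.approx(2 / 3, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            completion_rate([])


class TestPathEfficiency:
    def test_straight_constant_velocity_path_is_one(self):
        trial = straight_trial((1.0, 0.0, 0.0))
        assert trial.hit
        assert path_efficiency(trial) == pytest.approx(1.0)

    def test_path_twice_as_long_gives_half(self):
        # out to 1.5 along x, back to the target at 1.0: traveled 2.0
        target = np.array([1.0, 0.0, 0.0])
        out = np.linspace(0, 1.5, 31)[:, None] * np.array([1.0, 0, 0])
        back = np.linspace(1.5, 1.0, 11)[1:, None] * np.array([1.0, 0, 0])
        dwell = np.tile(target, (30, 1))
        trial = make_trial(target, np.concatenate([out, back, dwell]))
        assert trial.hit
        # the hold begins while still inside the radius on the way out;
        # compute PE over the full path for the closed form
        assert path_efficiency(trial, upto_hit=False) == pytest.approx(0.5)

    def test_three_four_five_construction(self):
        target = np.array([3.0, 4.0, 0.0])
        legs = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        dwell = np.tile(target, (30, 1))
        trial = make_trial(target, np.concatenate([legs, dwell]))
        assert trial.hit
        assert path_efficiency(trial) == pytest.approx(5 / 7, abs=1e-12)

    def test_start_on_target_is_undefined(self):
        target = np.array([1.0, 0.0, 0.0])
        trial = make_trial(target, np.tile(target, (40, 1)))
        assert path_efficiency(trial) is None

    def test_capped_at_one_when_cursor_undershoots(self):
        # cursor creeps a little toward a far target and stops: a miss
        # whose traveled distance is below the required distance
        target = np.array([1.0, 1.0, 1.0])
        traj = np.linspace(0, 0.1, 20)[:, None] * np.ones(3)
        trial = make_trial(target, traj)
        assert not trial.hit
        assert path_efficiency(trial) == 1.0

    def test_rotation_invariance(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        target = np.array([3.0, 4.0, 0.0])
        legs = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        traj = np.concatenate([legs, np.tile(target, (30, 1))])
        trial = make_trial(target, traj)
        rotated = make_trial(target @ q.T, traj @ q.T)
        assert path_efficiency(rotated) == pytest.approx(path_efficiency(trial))


class TestAttemptRatio:
    def test_clean_hits(self):
        trials = [synthetic_record((1, 0, 0), True, 1) for _ in range(5)]
        assert attempt_ratio(trials) == 1.0

    def test_counts_entrances_over_hits(self):
        trials = [synthetic_record((1, 0, 0), True, 2) for _ in range(10)]
        trials += [synthetic_record((1, 0, 0), False, 1) for _ in range(5)]
        assert attempt_ratio(trials) == pytest.approx(2.5)

    def test_undefined_without_hits(self):
        trials = [synthetic_record((1, 0, 0), False, 3) for _ in range(4)]
        assert attempt_ratio(trials) is None

    def test_at_least_one_when_hits_entered(self, rng):
        trials = [
            synthetic_record((1, 0, 0), hit, int(rng.integers(1, 4)) if hit else int(rng.integers(0, 4)))
            for hit in rng.uniform(size=30) < 0.5
        ]
        if any(t.hit for t in trials):
            assert attempt_ratio(trials) >= 1.0


class TestStratify:
    def _full_session(self, miss_targets=()):
        trials = []
        for target in all_targets():
            if tuple(target) in miss_targets:
                trials.append(synthetic_record(target, False, 0))
            elif sum(v != 0 for v in target) == 0:
                # rest with carried-over start: straight return to center
                trials.append(straight_trial(target, start=(1.0, 0.0, 0.0)))
            else:
                trials.append(straight_trial(target))
        return trials

    def test_all_hit_session(self):
        metrics = stratify(self._full_session())
        assert set(metrics) == {"all", "rest", "1-dof", "2-dof", "3-dof"}
        sizes = {name: m.n_trials for name, m in metrics.items()}
        assert sizes == {"all": 27, "rest": 1, "1-dof": 6, "2-dof": 12, "3-dof": 8}
        assert all(m.completion_rate == 1.0 for m in metrics.values())

    def test_overall_cr_is_weighted_stratum_mean(self):
        missed = {(1, 0, 0), (1, 1, 0), (1, 1, 1), (-1, -1, -1)}
        metrics = stratify(self._full_session(miss_targets=missed))
        weighted = sum(
            metrics[name].completion_rate * metrics[name].n_trials
            for name in ("rest", "1-dof", "2-dof", "3-dof")
        ) / 27
        assert metrics["all"].completion_rate == pytest.approx(weighted, abs=1e-12)

    def test_frame_layout(self):
        frame = metrics_frame(stratify(self._full_session()))
        assert list(frame.columns) == ["stratum", "n_trials", "n_hits", "CR", "PE_mean", "AR"]
        assert list(frame["stratum"]) == ["all", "rest", "1-dof", "2-dof", "3-dof"]
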