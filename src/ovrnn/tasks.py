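"""Conditioning and choice task environments as concatenated step streams.

All tasks run continuously: trials are concatenated with no gap, and the
inter-trial interval (ITI, reward to next cue) is drawn uniformly from
{4, 5, 6, 7} steps.  Observations are row vectors with the layout
(cue, reward[, distractor][, action1, action2]); the reward element carries
the reward size.  A timing label is attached to every step: if the cue (or
reward) observation arrives at step t, step t+1 is the cue (reward) timing,
so the label ``rel_cue`` counts steps from the cue timing (cue timing = 0,
cue observation step = -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["TaskSpec", "TaskStream", "conditioning_stream", "with_distractor",
           "choice_stream", "TRIAL_TYPES"]

#: integer codes of trial types in the probabilistic tasks
TRIAL_TYPES = {"early": 0, "late": 1, "none": 2}

_KINDS = ("pavlovian", "prob-task1", "prob-task2", "choice-1", "choice-2")


@dataclass(frozen=True)
class TaskSpec:
    """Task family and its timing parameters.

    Pavlovian trials: cue observation at trial time 1, reward observation at
    time 1+delay, trial end uniform on {4+delay, ..., 7+delay}.  The
    probabilistic tasks put the reward observation at time 3 (early) or 5
    (late) with trial end uniform on {7..10} as in the Pavlovian task;
    task 1 rewards every trial (1/2, 1/2), task 2 omits the reward in 40%
    of trials (.3, .3, .4).  Choice tasks deliver reward at time 4
    (action 1, size 2; action 2 in choice-1, size 1) or time 3 (action 2 in
    choice-2, size 1).
    """

    kind: str = "pavlovian"
    delay: int = 3
    iti_set: tuple[int, ...] = (4, 5, 6, 7)
    distractor_p: float = 0.0
    n_trials: int = 1000

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "pavlovian" and not (3 <= self.delay <= 6):
            raise ValueError("pavlovian cue-reward delay must be 3..6")
        if not (0.0 <= self.distractor_p < 1.0):
            raise ValueError("distractor probability must lie in [0, 1)")

    @property
    def reward_slots(self) -> tuple[int, ...]:
        """Possible reward-observation trial times."""
        if self.kind == "pavlovian":
            return (1 + self.delay,)
        if self.kind in ("prob-task1", "prob-task2"):
            return (3, 5)
        return (3, 4)  # choice tasks

    @property
    def last_slot(self) -> int:
        return max(self.reward_slots)


@dataclass
class TaskStream:
    """Flat per-step record of one generated task run."""

    obs: np.ndarray           # (T, m) observation vectors
    r: np.ndarray             # (T,) scalar rewards
    trial: np.ndarray         # (T,) 0-based trial index
    t_in_trial: np.ndarray    # (T,) 1-based time within trial
    rel_cue: np.ndarray       # (T,) steps from the trial's cue timing
    trial_start: np.ndarray   # (n_trials,) global index of trial time 1
    trial_len: np.ndarray     # (n_trials,)
    trial_type: np.ndarray    # (n_trials,) type code (TRIAL_TYPES; 0 if n/a)
    reward_obs_time: np.ndarray  # (n_trials,) trial time of reward obs, -1 if none
    spec: TaskSpec = field(default=None)
    action: Optional[np.ndarray] = None  # (n_trials,) chosen action, choice tasks

    @property
    def n_steps(self) -> int:
        return self.r.size

    @property
    def n_trials(self) -> int:
        return self.trial_start.size

    def check_labels(self) -> None:
        """Label convention invariant: obs step of cue/reward precedes its timing."""
        cue_col = self.obs[:, 0]
        (cue_steps,) = np.nonzero(cue_col)
        if not np.all(self.rel_cue[cue_steps] == -1):
            raise AssertionError("cue observation must sit at rel_cue == -1")


def _draw_trial_lengths(end_lo: int, end_hi: int, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    return rng.integers(end_lo, end_hi + 1, size=n)


def conditioning_stream(spec: TaskSpec, rng: np.random.Generator,
                        ) -> TaskStream:
    """Generate a Pavlovian or probabilistic-timing conditioning stream."""
    if spec.kind not in ("pavlovian", "prob-task1", "prob-task2"):
        raise ValueError("conditioning_stream handles conditioning tasks only")
    n = spec.n_trials
    if spec.kind == "pavlovian":
        reward_time = np.full(n, 1 + spec.delay)
        ttype = np.zeros(n, dtype=int)
        # trial ends 3..6 steps after the reward observation (ITI 4..7)
        lengths = _draw_trial_lengths(4 + spec.delay, 7 + spec.delay, n, rng)
    else:
        probs = (0.5, 0.5, 0.0) if spec.kind == "prob-task1" else (0.3, 0.3, 0.4)
        ttype = rng.choice(3, size=n, p=probs)
        reward_time = np.where(ttype == TRIAL_TYPES["early"], 3,
                               np.where(ttype == TRIAL_TYPES["late"], 5, -1))
        # trial end as in the Pavlovian task (time 7..10), whatever the
        # realized reward slot
        lengths = _draw_trial_lengths(7, 10, n, rng)
    return _assemble(spec, lengths, reward_time,
                     reward_size=np.ones(n), ttype=ttype, m=2,
                     cue_time=np.ones(n, dtype=int))


def _assemble(spec: TaskSpec, lengths: np.ndarray, reward_time: np.ndarray,
              reward_size: np.ndarray, ttype: np.ndarray, m: int,
              cue_time: np.ndarray, action: Optional[np.ndarray] = None,
              ) -> TaskStream:
    n = lengths.size
    T = int(lengths.sum())
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(int)
    obs = np.zeros((T, m))
    r = np.zeros(T)
    trial = np.repeat(np.arange(n), lengths)
    t_in_trial = np.concatenate([np.arange(1, L + 1) for L in lengths])
    rel_cue = t_in_trial - 2  # cue obs at time 1 -> cue timing at time 2
    obs[starts + cue_time - 1, 0] = 1.0
    has_rw = reward_time > 0
    rw_steps = starts[has_rw] + reward_time[has_rw] - 1
    obs[rw_steps, 1] = reward_size[has_rw]
    r[rw_steps] = reward_size[has_rw]
    if action is not None:
        # action unit active exactly at the selection step (trial time 2)
        sel_steps = starts + 1
        obs[sel_steps, 2 + (action - 1)] = 1.0
    return TaskStream(obs=obs, r=r, trial=trial, t_in_trial=t_in_trial,
                      rel_cue=rel_cue, trial_start=starts,
                      trial_len=lengths.astype(int), trial_type=ttype,
                      reward_obs_time=np.where(has_rw, reward_time, -1),
                      spec=spec, action=action)


def with_distractor(stream: TaskStream, p: float,
                    rng: np.random.Generator) -> TaskStream:
    """Append an independent Bernoulli(p) distractor element to every step."""
    if not (0.0 <= p < 1.0):
        raise ValueError("distractor probability must lie in [0, 1)")
    d = (rng.random(stream.n_steps) < p).astype(float)
    return TaskStream(obs=np.column_stack([stream.obs, d]), r=stream.r,
                      trial=stream.trial, t_in_trial=stream.t_in_trial,
                      rel_cue=stream.rel_cue, trial_start=stream.trial_start,
                      trial_len=stream.trial_len, trial_type=stream.trial_type,
                      reward_obs_time=stream.reward_obs_time, spec=stream.spec,
                      action=stream.action)


def choice_trial_structure(spec: TaskSpec, action: int,
                           ) -> tuple[int, float]:
    """(reward observation time, reward size) implied by the chosen action."""
    if action not in (1, 2):
        raise ValueError(f"invalid action {action!r}")
    if action == 1:
        return 4, 2.0
    return (4, 1.0) if spec.kind == "choice-1" else (3, 1.0)


def choice_stream(spec: TaskSpec, policy_callback: Callable[[int], int],
                  rng: np.random.Generator) -> TaskStream:
    """Open-loop generation of a choice-task stream.

    ``policy_callback(trial_index)`` supplies the action (1 or 2) chosen at
    the selection step (trial time 2).  The closed-loop actor-critic runner
    instead builds trials incrementally with the same structure.
    """
    if spec.kind not in ("choice-1", "choice-2"):
        raise ValueError("choice_stream handles choice tasks only")
    n = spec.n_trials
    actions = np.array([policy_callback(i) for i in range(n)], dtype=int)
    if not np.all(np.isin(actions, (1, 2))):
        raise ValueError("policy callback returned an invalid action")
    rw = np.array([choice_trial_structure(spec, a) for a in actions])
    reward_time = rw[:, 0].astype(int)
    reward_size = rw[:, 1]
    # end 3..6 steps after the action-1 reward slot (time 4), as in the
    # Pavlovian task
    lengths = _draw_trial_lengths(7, 10, n, rng)
    return _assemble(spec, lengths, reward_time, reward_size,
                     ttype=np.zeros(n, dtype=int), m=4,
                     cue_time=np.ones(n, dtype=int), action=actions)
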