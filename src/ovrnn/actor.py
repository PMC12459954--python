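"""Actor-critic extension: action-value readouts and soft-max choice.

On top of a value-RNN critic, two non-negative preference rows U (dorsal
striatum in the circuit mapping) read action values q = U x from the RNN
activity.  One of two actions is chosen by soft-max at the time step after
cue presentation; the chosen action is echoed back to the network through
two appended action observation units (1 at the selection step only).
Preferences are updated by the same TD-RPE that trains the critic,
u_kj <- u_kj + a_pref * delta(t) * x_j(t) for the selected row, and all
preferences decay slightly every step to stay bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import AgentConfig, ValueRNNAgent, decay_vector
from .tasks import TaskSpec, choice_trial_structure

__all__ = ["ActorState", "ActorCriticAgent", "action_values",
           "softmax_select", "update_preferences",
           "build_action_observation", "run_choice_task", "ChoiceLog"]


@dataclass
class ActorState:
    """Preference matrix and selection bookkeeping for two actions."""

    U: np.ndarray               # (2, n), non-negative
    beta: float = 2.0
    a_pref: float = 0.1
    dr: float = 0.001
    selected_action: Optional[int] = None  # 1-based, current trial


def action_values(U: np.ndarray, x: np.ndarray) -> np.ndarray:
    """q = U x, the two action values read from the RNN activity."""
    U = np.asarray(U, float)
    x = np.asarray(x, float)
    if U.shape != (2, x.size):
        raise ValueError("U must be 2 x n with n = len(x)")
    return U @ x


def softmax_select(q: np.ndarray, beta: float,
                   rng: np.random.Generator) -> tuple[int, float]:
    """Soft-max draw over two actions; returns (action in {1,2}, P(action 1)).

    P(k) = exp(beta q_k) / (exp(beta q_1) + exp(beta q_2)).
    """
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    z = beta * (np.asarray(q, float) - np.max(q))
    p = np.exp(z)
    p /= p.sum()
    action = 1 if rng.random() < p[0] else 2
    return action, float(p[0])


def update_preferences(U: np.ndarray, selected_k: int, delta: float,
                       x: np.ndarray, a_pref: float) -> np.ndarray:
    """Update (and rectify) the selected action's preference row only."""
    if selected_k not in (1, 2):
        raise ValueError("no valid selected action for preference update")
    U2 = U.copy()
    U2[selected_k - 1] = np.maximum(
        0.0, U2[selected_k - 1] + a_pref * delta * np.asarray(x, float))
    return U2


def build_action_observation(base_o: np.ndarray,
                             selected_action: Optional[int]) -> np.ndarray:
    """Append the two action units; the chosen one is 1 at the selection step."""
    act = np.zeros(2)
    if selected_action is not None:
        if selected_action not in (1, 2):
            raise ValueError(f"invalid action {selected_action!r}")
        act[selected_action - 1] = 1.0
    return np.concatenate([np.asarray(base_o, float), act])


@dataclass
class ChoiceLog:
    """Per-trial record of a closed-loop choice-task run."""

    action: np.ndarray          # (n_trials,)
    p_action1: np.ndarray       # (n_trials,) soft-max P(action 1) at selection
    reward_size: np.ndarray
    reward_time: np.ndarray
    trial_len: np.ndarray

    def frac_action1(self, trials: slice = slice(None)) -> float:
        return float(np.mean(self.action[trials] == 1))


class ActorCriticAgent:
    """Value-RNN critic plus soft-max actor over two actions.

    ``update_schedule`` is "to-trial-end" (the selected row is updated with
    every TD-RPE from the selection step to the end of the trial, letting
    the reward's TD-RPE reach the preference through the action-conditioned
    RNN activity) or "selection-only".
    """

    def __init__(self, critic_config: AgentConfig, m: int, beta: float = 2.0,
                 a_pref: Optional[float] = None, u_decay: float = 0.001,
                 update_schedule: str = "to-trial-end",
                 rng: Optional[np.random.Generator] = None,
                 source: Optional[tuple] = None):
        if update_schedule not in ("to-trial-end", "selection-only"):
            raise ValueError(f"unknown schedule {update_schedule!r}")
        self.critic = ValueRNNAgent(critic_config, m, rng=rng, source=source)
        self.actor = ActorState(
            U=np.zeros((2, critic_config.n)), beta=beta,
            a_pref=critic_config.a_value if a_pref is None else a_pref,
            dr=u_decay)
        self.update_schedule = update_schedule

    def select(self, rng: np.random.Generator) -> tuple[int, float]:
        q = action_values(self.actor.U, self.critic.x)
        action, p1 = softmax_select(q, self.actor.beta, rng)
        self.actor.selected_action = action
        return action, p1

    def step(self, base_o: np.ndarray, r: float, *, selection_step: bool,
             in_selection_window: bool):
        """One closed-loop step; the action units echo the current choice."""
        o = build_action_observation(
            base_o, self.actor.selected_action if selection_step else None)
        out = self.critic.step(o, r)
        act = self.actor
        do_update = act.selected_action is not None and (
            selection_step if self.update_schedule == "selection-only"
            else in_selection_window)
        if do_update:
            # x(t) of this step is the critic's pre-advance activity
            act.U = update_preferences(act.U, act.selected_action, out.delta,
                                       self.critic.state.x_prev, act.a_pref)
        act.U = decay_vector(act.U, act.dr)
        return out


def run_choice_task(agent: ActorCriticAgent, spec: TaskSpec, n_trials: int,
                    rng: np.random.Generator) -> ChoiceLog:
    """Run a two-alternative choice task closed-loop for ``n_trials``.

    Trial layout: cue observation at time 1, soft-max selection at time 2,
    reward per the chosen action (size 2 at time 4 for action 1; size 1 at
    time 4 or, in the inter-temporal task, time 3 for action 2), trial end
    uniform on {7..10}.
    """
    if spec.kind not in ("choice-1", "choice-2"):
        raise ValueError("choice runner needs a choice task")
    actions = np.zeros(n_trials, int)
    p1s = np.zeros(n_trials)
    rsizes = np.zeros(n_trials)
    rtimes = np.zeros(n_trials, int)
    lens = rng.integers(7, 11, size=n_trials)
    for i in range(n_trials):
        L = int(lens[i])
        agent.actor.selected_action = None
        rw_time, rw_size = 0, 0.0
        for t in range(1, L + 1):
            if t == 2:
                action, p1 = agent.select(rng)
                actions[i], p1s[i] = action, p1
                rw_time, rw_size = choice_trial_structure(spec, action)
                rsizes[i], rtimes[i] = rw_size, rw_time
            base_o = np.zeros(2)
            r = 0.0
            if t == 1:
                base_o[0] = 1.0
            if t == rw_time and rw_time > 0:
                base_o[1] = rw_size  # reward element carries the size
                r = rw_size
            agent.step(base_o, r, selection_step=(t == 2),
                       in_selection_window=(t >= 2))
    return ChoiceLog(action=actions, p_action1=p1s, reward_size=rsizes,
                     reward_time=rtimes, trial_len=lens.astype(int))
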