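"""Online value-RNN agents trained by TD reward-prediction error.

The model family simulated here learns a state representation and a state
value simultaneously, online, in the cortico-basal-ganglia mapping: an RNN
(cortex) receives observations ``o`` and maintains activity ``x``; a linear
readout ``v = w.T x`` (striatum) estimates the state value; a scalar TD
reward-prediction error (TD-RPE, dopamine)

    delta(t) = r(t) + gamma * v(t+1) - v(t)

drives the updates of the readout weights ``w`` and of the recurrent and
feed-forward connections ``A`` and ``B``.  The update of ``A``/``B`` needs a
per-unit feedback weight: either the readout weight itself (backprop-type
variants, ``fb = w``) or a fixed random vector (``fb = c``, feedback
alignment variants).  Biologically constrained variants use a positive
sigmoid, non-negative ``w`` and ``c``, and a monotone-saturating
post-synaptic factor in place of the sigmoid derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "AgentConfig",
    "AgentState",
    "StepOutcome",
    "ValueRNNAgent",
    "PunctateAgent",
    "VARIANTS",
    "activation",
    "rnn_step",
    "state_value",
    "td_rpe",
    "update_value_weights",
    "postsyn_factor",
    "update_rnn_connections",
    "decay_vector",
    "init_agent",
    "agent_step",
    "punctate_td_step",
    "default_value_lr",
]

# ---------------------------------------------------------------------------
# variant registry
# ---------------------------------------------------------------------------

#: Per-variant structural settings.  ``lr_divisor`` is the reference network
#: size used to normalise the value-weight learning rate (a_value scales as
#: 0.1 / (n / divisor) so that total readout plasticity is comparable across
#: network sizes).
VARIANTS: dict[str, dict] = {
    # centered-sigmoid family (activity in (-0.5, 0.5), signed weights)
    "oVRNNbp": dict(activation="centered", factor="deriv-centered",
                    feedback="w", nonneg_w=False, c_init=None,
                    train_rnn=True, lr_divisor=7),
    "oVRNNrf": dict(activation="centered", factor="deriv-centered",
                    feedback="c", nonneg_w=False, c_init="normal",
                    train_rnn=True, lr_divisor=7),
    "oVRNNrf-uniform": dict(activation="centered", factor="deriv-centered",
                            feedback="c", nonneg_w=False,
                            c_init="normal-uniform-direction",
                            train_rnn=True, lr_divisor=7),
    "untrained-naive": dict(activation="centered", factor="deriv-centered",
                            feedback="c", nonneg_w=False, c_init="normal",
                            train_rnn=False, lr_divisor=7),
    # biologically constrained family (positive sigmoid, non-negative w)
    "oVRNNbp-rev": dict(activation="positive", factor="deriv-positive",
                        feedback="w", nonneg_w=True, c_init=None,
                        train_rnn=True, lr_divisor=12),
    "oVRNNrf-bio": dict(activation="positive", factor="monotone-saturating",
                        feedback="c", nonneg_w=True, c_init="uniform",
                        train_rnn=True, lr_divisor=12),
    "oVRNNrf-rev": dict(activation="positive", factor="deriv-positive",
                        feedback="c", nonneg_w=True, c_init="uniform",
                        train_rnn=True, lr_divisor=12),
    "oVRNNrf-bio-uniform": dict(activation="positive",
                                factor="monotone-saturating",
                                feedback="c",
                                c_init="uniform-uniform-direction",
                                nonneg_w=True, train_rnn=True, lr_divisor=12),
    "oVRNNrf-bio-uniform-fixed": dict(activation="positive",
                                      factor="monotone-saturating",
                                      feedback="c", c_init="fixed-0.5",
                                      nonneg_w=True, train_rnn=True,
                                      lr_divisor=12),
    "untrained-naive-bio": dict(activation="positive",
                                factor="monotone-saturating",
                                feedback="c", c_init="uniform",
                                nonneg_w=True, train_rnn=False,
                                lr_divisor=12),
    "untrained-shuffled-bio": dict(activation="positive",
                                   factor="monotone-saturating",
                                   feedback="c", c_init="uniform",
                                   nonneg_w=True, train_rnn=False,
                                   lr_divisor=12, needs_source=True),
}


def default_value_lr(n: int, lr_divisor: int, scale: float = 1.0) -> float:
    """Value-weight learning rate 0.1/(n/divisor), optionally scaled."""
    return scale * 0.1 / (n / lr_divisor)


@dataclass(frozen=True)
class AgentConfig:
    """Full configuration of one agent variant.

    Parameters not given explicitly are filled in from the variant registry
    and from the standard learning-rate scheme (``a_RNN = 0.1``,
    ``a_value = 0.1/(n/divisor)``, both multiplied by ``lr_scale``).
    """

    variant: str
    n: int
    gamma: float = 0.8
    a_value: Optional[float] = None
    a_RNN: Optional[float] = None
    lr_scale: float = 1.0
    w_decay: float = 0.0  # per-step decay rate of w (dr)
    seed: Optional[int] = None
    #: sensitivity toggle: use the post-update w as backprop feedback
    #: (default False: the connection update sees the pre-update readout)
    fb_post_update: bool = False
    # structural fields; resolved from the variant if left as None
    activation_kind: Optional[str] = None
    factor_kind: Optional[str] = None
    feedback: Optional[str] = None
    nonneg_w: Optional[bool] = None
    c_init: Optional[str] = field(default=None)
    train_rnn: Optional[bool] = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("need at least one RNN unit")
        if not (0.0 <= self.w_decay < 1.0):
            raise ValueError("w_decay must lie in [0, 1)")
        spec = VARIANTS[self.variant]
        object.__setattr__(self, "activation_kind",
                           self.activation_kind or spec["activation"])
        object.__setattr__(self, "factor_kind",
                           self.factor_kind or spec["factor"])
        object.__setattr__(self, "feedback", self.feedback or spec["feedback"])
        if self.nonneg_w is None:
            object.__setattr__(self, "nonneg_w", spec["nonneg_w"])
        if self.c_init is None:
            object.__setattr__(self, "c_init", spec["c_init"])
        if self.train_rnn is None:
            object.__setattr__(self, "train_rnn", spec["train_rnn"])
        if self.a_RNN is None:
            object.__setattr__(self, "a_RNN", 0.1 * self.lr_scale)
        if self.a_value is None:
            object.__setattr__(
                self, "a_value",
                default_value_lr(self.n, spec["lr_divisor"], self.lr_scale))
        if self.a_value < 0 or self.a_RNN < 0:
            raise ValueError("learning rates must be non-negative")

    @property
    def needs_source(self) -> bool:
        return VARIANTS[self.variant].get("needs_source", False)


@dataclass
class AgentState:
    """Mutable state of one agent: weights, activity and one-step buffers.

    ``c`` is fixed at initialization and never modified afterwards; ``x_prev``
    and ``o_prev`` are None before the first step (connection updates that
    need them are skipped then).
    """

    x: np.ndarray
    A: np.ndarray
    B: np.ndarray
    w: np.ndarray
    c: Optional[np.ndarray] = None
    x_prev: Optional[np.ndarray] = None
    o_prev: Optional[np.ndarray] = None
    t: int = 0


class StepOutcome(NamedTuple):
    """Per-step record: value, next value, TD-RPE, reward, time index."""

    v: float
    v_next: float
    delta: float
    r: float
    t: int


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def activation(z: np.ndarray, kind: str) -> np.ndarray:
    """Sigmoidal unit input-output function.

    ``centered``: 1/(1+exp(-z)) - 0.5, range (-0.5, 0.5);
    ``positive``: 1/(1+exp(-z)), range (0, 1).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite pre-activation: invalid network state")
    s = 1.0 / (1.0 + np.exp(-z))
    if kind == "centered":
        return s - 0.5
    if kind == "positive":
        return s
    raise ValueError(f"unknown activation kind {kind!r}")


def rnn_step(x: np.ndarray, o: np.ndarray, A: np.ndarray, B: np.ndarray,
             kind: str) -> np.ndarray:
    """One recurrent update x(t+1) = f(A x(t) + B o(t)).  Pure."""
    x = np.asarray(x, float)
    o = np.asarray(o, float)
    if A.shape != (x.size, x.size) or B.shape != (x.size, o.size):
        raise ValueError(
            f"dimension mismatch: A{A.shape}, B{B.shape}, x({x.size},), o({o.size},)")
    return activation(A @ x + B @ o, kind)


def state_value(w: np.ndarray, x: np.ndarray) -> float:
    """Linear value readout v = w.T x."""
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    if w.shape != x.shape:
        raise ValueError("w and x must have equal length")
    return float(w @ x)


def td_rpe(r: float, v_next: float, v: float, gamma: float) -> float:
    """TD reward-prediction error delta = r + gamma*v(t+1) - v(t)."""
    return r + gamma * v_next - v


def update_value_weights(w: np.ndarray, delta: float, x: np.ndarray,
                         a_value: float, nonneg: bool) -> np.ndarray:
    """Readout update w_j += a_value * delta * x_j, optionally rectified."""
    if a_value < 0:
        raise ValueError("a_value must be non-negative")
    w2 = w + a_value * delta * x
    if nonneg:
        np.maximum(w2, 0.0, out=w2)
    return w2


def postsyn_factor(x_post: np.ndarray, kind: str) -> np.ndarray:
    """Post-synaptic activity factor of the connection update.

    ``deriv-centered``: (0.5+x)(0.5-x), the centered-sigmoid derivative;
    ``deriv-positive``: x(1-x), the positive-sigmoid derivative;
    ``monotone-saturating``: x(1-x) for x <= 0.5, constant 0.25 above
    (the biologically motivated monotone + saturation rule).
    """
    x_post = np.asarray(x_post, float)
    if kind == "deriv-centered":
        return (0.5 + x_post) * (0.5 - x_post)
    if kind == "deriv-positive":
        return x_post * (1.0 - x_post)
    if kind == "monotone-saturating":
        return np.where(x_post <= 0.5, x_post * (1.0 - x_post), 0.25)
    raise ValueError(f"unknown factor kind {kind!r}")


def update_rnn_connections(A: np.ndarray, B: np.ndarray, delta: float,
                           x_pre: np.ndarray, o_pre: np.ndarray,
                           x_post: np.ndarray, fb: np.ndarray, a_RNN: float,
                           factor_kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Rank-1 update of recurrent and feed-forward connections.

    A_ij += a_RNN * delta * x_pre_j * factor(x_post_i) * fb_i and the
    analogous update of B with o_pre; fb is w for backprop-type variants and
    the fixed random vector c for feedback-alignment variants.
    """
    n = A.shape[0]
    if x_pre.size != n or x_post.size != n or fb.size != n or B.shape[1] != o_pre.size:
        raise ValueError("dimension mismatch in connection update")
    g = (a_RNN * delta) * postsyn_factor(x_post, factor_kind) * fb
    return A + np.outer(g, x_pre), B + np.outer(g, o_pre)


def decay_vector(u: np.ndarray, dr: float) -> np.ndarray:
    """Multiplicative per-step decay u' = (1-dr) u."""
    if not (0.0 <= dr < 1.0):
        raise ValueError("decay rate must lie in [0, 1)")
    return (1.0 - dr) * u


# ---------------------------------------------------------------------------
# initialization and the online step
# ---------------------------------------------------------------------------

def _init_feedback(c_init: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if c_init == "normal":
        return rng.standard_normal(n)
    if c_init == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if c_init == "normal-uniform-direction":
        # uniform direction (1,...,1) with a standard-normal coefficient
        return float(rng.standard_normal()) * np.ones(n)
    if c_init == "uniform-uniform-direction":
        return float(rng.uniform(0.0, 1.0)) * np.ones(n)
    if c_init == "fixed-0.5":
        return 0.5 * np.ones(n)
    raise ValueError(f"unknown c_init {c_init!r}")


def init_agent(config: AgentConfig, m: int,
               rng: Optional[np.random.Generator] = None,
               source: Optional[tuple[np.ndarray, np.ndarray]] = None,
               ) -> AgentState:
    """Initialize an agent of dimension ``m`` observations.

    A and B start from standard normal draws; x from standard normal
    (centered activation) or uniform [0,1] (positive activation); w from 0;
    c per the variant.  For the shuffled-untrained control, A and B are
    independent element permutations of the supplied learned ``source``
    matrices.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    if config.needs_source:
        if source is None:
            raise ValueError("shuffled-untrained variant needs source (A, B)")
        A_src, B_src = source
        A = rng.permutation(np.asarray(A_src, float).ravel()).reshape(n, n)
        B = rng.permutation(np.asarray(B_src, float).ravel()).reshape(n, m)
    else:
        A = rng.standard_normal((n, n))
        B = rng.standard_normal((n, m))
    if config.activation_kind == "centered":
        x = rng.standard_normal(n)
    else:
        x = rng.uniform(0.0, 1.0, n)
    w = np.zeros(n)
    c = None
    if config.feedback == "c":
        c = _init_feedback(config.c_init, n, rng)
    return AgentState(x=x, A=A, B=B, w=w, c=c)


def agent_step(state: AgentState, o_cur: np.ndarray, r_cur: float,
               config: AgentConfig) -> tuple[AgentState, StepOutcome]:
    """One online TD step; mutates and returns ``state``.

    Ordering within a step: (1) x(t+1) from x(t) and o(t); (2) v(t) and
    v(t+1) from the pre-update w; (3) TD-RPE; (4) w update; (5) A,B update
    with pre-synaptic x(t-1), o(t-1) and post-synaptic x(t), using the same
    TD-RPE; (6) optional w decay; (7) buffer advance.  The very first step
    skips (5) since no pre-synaptic activity exists yet.  For backprop-type
    variants the feedback in (5) is the pre-update w of this step (all
    updates read the same pre-update state); using the post-update w
    instead (``fb_post_update``) adds a delta**2-proportional Hebbian drift
    to the connection update that degrades learning.
    """
    o_cur = np.asarray(o_cur, float)
    x = state.x
    # hot path: the arithmetic below restates rnn_step/state_value/td_rpe/
    # update_value_weights/update_rnn_connections without their per-call
    # validation; the straight-line regression oracle pins the semantics
    s = 1.0 / (1.0 + np.exp(-(state.A @ x + state.B @ o_cur)))
    x_next = s - 0.5 if config.activation_kind == "centered" else s
    w_pre = state.w
    v = float(w_pre @ x)
    v_next = float(w_pre @ x_next)
    delta = r_cur + config.gamma * v_next - v
    w = w_pre + (config.a_value * delta) * x
    if config.nonneg_w:
        np.maximum(w, 0.0, out=w)
    state.w = w
    if config.train_rnn and state.x_prev is not None:
        if config.feedback == "w":
            fb = w if config.fb_post_update else w_pre
        else:
            fb = state.c
        g = (config.a_RNN * delta) * postsyn_factor(x, config.factor_kind) * fb
        state.A += np.outer(g, state.x_prev)
        state.B += np.outer(g, state.o_prev)
    if config.w_decay > 0.0:
        state.w = (1.0 - config.w_decay) * state.w
    outcome = StepOutcome(v=v, v_next=v_next, delta=delta, r=float(r_cur),
                          t=state.t)
    state.x_prev = x
    state.x = x_next
    state.o_prev = o_cur
    state.t += 1
    return state, outcome


class ValueRNNAgent:
    """Convenience wrapper binding an :class:`AgentConfig` to its state."""

    def __init__(self, config: AgentConfig, m: int,
                 rng: Optional[np.random.Generator] = None,
                 source: Optional[tuple[np.ndarray, np.ndarray]] = None):
        self.config = config
        self.m = m
        self.state = init_agent(config, m, rng=rng, source=source)

    def step(self, o: np.ndarray, r: float) -> StepOutcome:
        _, out = agent_step(self.state, o, r, self.config)
        return out

    # direct views, used by analyses
    @property
    def x(self):
        return self.state.x

    @property
    def w(self):
        return self.state.w

    @property
    def c(self):
        return self.state.c

    @property
    def A(self):
        return self.state.A

    @property
    def B(self):
        return self.state.B


# ---------------------------------------------------------------------------
# punctate (complete-serial-compound) TD baseline
# ---------------------------------------------------------------------------

@dataclass
class PunctateAgent:
    """Classical tabular TD(0) baseline over one-hot timing states.

    Each timing from the cue is one of 10 punctate states.  In episodic mode
    the value of the last state of a trial is not updated by the TD-RPE of
    the transition into the next trial.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros(10))
    episodic: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.size != 10:
            raise ValueError("punctate value table has exactly 10 entries")


def punctate_td_step(agent: PunctateAgent, state_idx: int,
                     next_state_idx: Optional[int], r: float, gamma: float,
                     a_value: float, *, boundary: bool = False,
                     ) -> tuple[PunctateAgent, float]:
    """One tabular TD(0) transition; returns (agent, delta).

    ``next_state_idx`` may be None only at a boundary in episodic mode
    (the update is skipped and delta is reported as 0).
    """
    V = agent.values
    if not (0 <= state_idx < V.size):
        raise IndexError("state index out of range")
    if boundary and agent.episodic:
        return agent, 0.0
    if next_state_idx is None or not (0 <= next_state_idx < V.size):
        raise IndexError("next state index out of range")
    delta = r + gamma * V[next_state_idx] - V[state_idx]
    V[state_idx] += a_value * delta
    return agent, delta
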