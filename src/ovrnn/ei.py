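"""Excitatory/inhibitory extension of the online value-RNN (Dale's law).

The RNN is split into n excitatory E-units (positive sigmoid) and n paired
linear I-units.  Excitation from observations and E-units takes one time
step; inhibition from each E-unit's paired I-unit acts within the step:

    x_I(t+1) = A_I x_E(t) + B_I o(t)
    x_E(t+1) = f(A_E x_E(t) + B_E o(t) - h * x_I(t+1))

with h = 1.  All weights are initialized non-negatively (max(0, 3+z), z
standard normal); only the connections onto E-units (A_E, B_E) are plastic,
with the same TD-RPE rules as the single-population models.  Combining the
two equations shows the forward pass equals a plain RNN with effective
weights (A_E - h*A_I, B_E - h*B_I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (StepOutcome, activation, decay_vector, td_rpe,
                   update_rnn_connections, update_value_weights,
                   default_value_lr, _init_feedback)

__all__ = ["EIConfig", "EIState", "EIAgent", "ei_init", "ei_step",
           "ei_update", "EI_VARIANTS"]

EI_VARIANTS = {
    "oVRNNbp-rev-ei": dict(feedback="w", factor="deriv-positive",
                           c_init=None),
    "oVRNNrf-bio-ei": dict(feedback="c", factor="monotone-saturating",
                           c_init="uniform"),
    "untrained-naive-ei": dict(feedback="c", factor="monotone-saturating",
                               c_init="uniform", train_rnn=False),
    "untrained-shuffled-ei": dict(feedback="c", factor="monotone-saturating",
                                  c_init="uniform", train_rnn=False,
                                  needs_source=True),
}


@dataclass(frozen=True)
class EIConfig:
    variant: str
    n: int                      # number of E-units (= number of I-units)
    gamma: float = 0.8
    a_value: Optional[float] = None
    a_RNN: Optional[float] = None
    lr_scale: float = 1.0
    h: float = 1.0
    w_decay: float = 0.0

    def __post_init__(self):
        if self.variant not in EI_VARIANTS:
            raise ValueError(f"unknown E/I variant {self.variant!r}")
        if self.a_RNN is None:
            object.__setattr__(self, "a_RNN", 0.1 * self.lr_scale)
        if self.a_value is None:
            object.__setattr__(self, "a_value",
                               default_value_lr(self.n, 12, self.lr_scale))

    @property
    def feedback(self) -> str:
        return EI_VARIANTS[self.variant]["feedback"]

    @property
    def factor_kind(self) -> str:
        return EI_VARIANTS[self.variant]["factor"]

    @property
    def train_rnn(self) -> bool:
        return EI_VARIANTS[self.variant].get("train_rnn", True)

    @property
    def needs_source(self) -> bool:
        return EI_VARIANTS[self.variant].get("needs_source", False)


@dataclass
class EIState:
    """E/I network state; A_I, B_I and h are frozen after initialization."""

    x_E: np.ndarray
    x_I: np.ndarray
    A_E: np.ndarray
    A_I: np.ndarray
    B_E: np.ndarray
    B_I: np.ndarray
    h: float
    w: np.ndarray
    c: Optional[np.ndarray] = None
    x_prev: Optional[np.ndarray] = None
    o_prev: Optional[np.ndarray] = None
    t: int = 0

    @property
    def effective_A(self) -> np.ndarray:
        return self.A_E - self.h * self.A_I

    @property
    def effective_B(self) -> np.ndarray:
        return self.B_E - self.h * self.B_I


def _nonneg_normal(shape, rng) -> np.ndarray:
    return np.maximum(0.0, 3.0 + rng.standard_normal(shape))


def ei_init(config: EIConfig, m: int,
            rng: Optional[np.random.Generator] = None,
            source: Optional[tuple] = None) -> EIState:
    """Initialize an E/I agent with non-negative weights max(0, 3+z).

    The initial I activity is computed from the initial E activity and a
    zero observation.  For the shuffled control, ``source`` supplies
    learned (A_E, A_I, B_E, B_I) whose elements are permuted per matrix.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = config.n
    if config.needs_source:
        if source is None:
            raise ValueError("shuffled E/I control needs source matrices")
        A_E, A_I, B_E, B_I = (
            rng.permutation(np.asarray(M, float).ravel()).reshape(M.shape)
            for M in source)
    else:
        A_E = _nonneg_normal((n, n), rng)
        A_I = _nonneg_normal((n, n), rng)
        B_E = _nonneg_normal((n, m), rng)
        B_I = _nonneg_normal((n, m), rng)
    x_E = rng.uniform(0.0, 1.0, n)
    x_I = A_I @ x_E  # zero observation at t = 0
    c = None
    if config.feedback == "c":
        c = _init_feedback(EI_VARIANTS[config.variant]["c_init"], n, rng)
    return EIState(x_E=x_E, x_I=x_I, A_E=A_E, A_I=A_I, B_E=B_E, B_I=B_I,
                   h=config.h, w=np.zeros(n), c=c)


def ei_step(state: EIState, o_cur: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass only: returns (x_I(t+1), x_E(t+1)); state unmodified."""
    o_cur = np.asarray(o_cur, float)
    x_I_next = state.A_I @ state.x_E + state.B_I @ o_cur
    x_E_next = activation(state.A_E @ state.x_E + state.B_E @ o_cur
                          - state.h * x_I_next, "positive")
    return x_I_next, x_E_next


def ei_update(state: EIState, delta: float, x_E_pre: np.ndarray,
              o_pre: np.ndarray, x_E_post: np.ndarray, fb: np.ndarray,
              a_RNN: float, factor_kind: str) -> EIState:
    """TD-RPE update of the plastic pathways A_E, B_E only (in place)."""
    state.A_E, state.B_E = update_rnn_connections(
        state.A_E, state.B_E, delta, x_E_pre, o_pre, x_E_post, fb, a_RNN,
        factor_kind)
    return state


class EIAgent:
    """Online value-RNN agent with separate E- and I-populations.

    The per-step ordering matches the single-population agent: forward
    pass, TD-RPE from the pre-update readout, readout update (rectified),
    then the connection update onto E-units with pre-synaptic activity from
    the previous step.
    """

    def __init__(self, config: EIConfig, m: int,
                 rng: Optional[np.random.Generator] = None,
                 source: Optional[tuple] = None):
        self.config = config
        self.m = m
        self.state = ei_init(config, m, rng=rng, source=source)

    def step(self, o: np.ndarray, r: float) -> StepOutcome:
        cfg = self.config
        st = self.state
        x = st.x_E
        x_I_next, x_E_next = ei_step(st, o)
        w_pre = st.w
        v = float(w_pre @ x)
        v_next = float(w_pre @ x_E_next)
        delta = td_rpe(r, v_next, v, cfg.gamma)
        st.w = update_value_weights(st.w, delta, x, cfg.a_value, True)
        if cfg.train_rnn and st.x_prev is not None:
            # backprop-type feedback reads the pre-update readout
            fb = w_pre if cfg.feedback == "w" else st.c
            ei_update(st, delta, st.x_prev, st.o_prev, x, fb, cfg.a_RNN,
                      cfg.factor_kind)
        if cfg.w_decay > 0.0:
            st.w = decay_vector(st.w, cfg.w_decay)
        out = StepOutcome(v=v, v_next=v_next, delta=delta, r=float(r),
                          t=st.t)
        st.x_prev = x
        st.x_E = x_E_next
        st.x_I = x_I_next
        st.o_prev = np.asarray(o, float)
        st.t += 1
        return out

    @property
    def w(self):
        return self.state.w

    @property
    def c(self):
        return self.state.c
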