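"""Tiny deterministic fixtures and a straight-line regression oracle.

``make_fixture`` emits hand-checkable task streams of at most 50 steps.
``reference_trace`` recomputes the exact per-step value/TD-RPE trace of a
small feedback-alignment agent on the two-trial fixture with deliberately
plain, loop-by-loop code that shares no implementation with the agent
classes; it serves as an independent regression oracle for the online step
ordering.
"""

from __future__ import annotations

import numpy as np

from .tasks import TaskSpec, TaskStream

__all__ = ["make_fixture", "reference_trace", "FIXTURES"]


def _manual_stream(trial_lens, reward_times, kind="pavlovian", delay=3,
                   reward_sizes=None) -> TaskStream:
    lens = np.asarray(trial_lens, int)
    T = int(lens.sum())
    starts = np.concatenate(([0], np.cumsum(lens)[:-1])).astype(int)
    obs = np.zeros((T, 2))
    r = np.zeros(T)
    trial = np.repeat(np.arange(lens.size), lens)
    t_in = np.concatenate([np.arange(1, L + 1) for L in lens])
    obs[starts, 0] = 1.0
    sizes = np.ones(lens.size) if reward_sizes is None else reward_sizes
    rts = np.asarray(reward_times, int)
    has = rts > 0
    obs[starts[has] + rts[has] - 1, 1] = sizes[has]
    r[starts[has] + rts[has] - 1] = sizes[has]
    return TaskStream(obs=obs, r=r, trial=trial, t_in_trial=t_in,
                      rel_cue=t_in - 2, trial_start=starts,
                      trial_len=lens, trial_type=np.zeros(lens.size, int),
                      reward_obs_time=np.where(has, rts, -1),
                      spec=TaskSpec(kind=kind, delay=delay,
                                    n_trials=int(lens.size)))


def _two_trial_pavlovian() -> TaskStream:
    # delay 3, ITIs 4 and 5: trial lengths 7 and 8, reward observed at time 4
    return _manual_stream([7, 8], [4, 4])


def _all_zero() -> TaskStream:
    s = _manual_stream([10], [-1])
    s.obs[:] = 0.0
    return s


def _three_trial_varied() -> TaskStream:
    # lengths 7..9 with reward at time 4; 24 steps total
    return _manual_stream([7, 8, 9], [4, 4, 4])


FIXTURES = {
    "two-trial-pavlovian": _two_trial_pavlovian,
    "all-zero": _all_zero,
    "three-trial-varied": _three_trial_varied,
}


def make_fixture(name: str) -> TaskStream:
    """Return a registered deterministic fixture stream (<= 50 steps)."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(FIXTURES)}") from None
    return factory()


def reference_trace(seed: int = 12345, n: int = 2,
                    stream: TaskStream | None = None,
                    gamma: float = 0.8, a_value: float = 0.35,
                    a_rnn: float = 0.1) -> np.ndarray:
    """Straight-line recomputation of the per-step (v, delta) trace.

    Simulates a centered-sigmoid agent with fixed random feedback on the
    given fixture stream (two-trial Pavlovian by default), writing out the
    update equations element by element.  Initialization draws follow the
    documented convention and order: A, B, x standard normal, w zero, c
    standard normal.  Returns an array of shape (T, 2) with columns
    (value, TD-RPE).
    """
    if stream is None:
        stream = make_fixture("two-trial-pavlovian")
    rng = np.random.default_rng(seed)
    m = stream.obs.shape[1]
    A = rng.standard_normal((n, n))
    B = rng.standard_normal((n, m))
    x = rng.standard_normal(n)
    w = np.zeros(n)
    c = rng.standard_normal(n)
    x_prev = None
    o_prev = None
    out = np.zeros((stream.n_steps, 2))
    for t in range(stream.n_steps):
        o = stream.obs[t]
        r = stream.r[t]
        z = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += A[i, j] * x[j]
            for k in range(m):
                acc += B[i, k] * o[k]
            z[i] = acc
        x_next = 1.0 / (1.0 + np.exp(-z)) - 0.5
        v = sum(w[j] * x[j] for j in range(n))
        v_next = sum(w[j] * x_next[j] for j in range(n))
        delta = r + gamma * v_next - v
        w_new = np.array([w[j] + a_value * delta * x[j] for j in range(n)])
        if x_prev is not None:
            for i in range(n):
                fac = (0.5 + x[i]) * (0.5 - x[i])
                for j in range(n):
                    A[i, j] += a_rnn * delta * x_prev[j] * fac * c[i]
                for k in range(m):
                    B[i, k] += a_rnn * delta * o_prev[k] * fac * c[i]
        w = w_new
        out[t, 0] = v
        out[t, 1] = delta
        x_prev = x
        x = x_next
        o_prev = o.copy()
    return out
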