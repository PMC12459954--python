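"""Oracle state values and expected TD-RPE for the conditioning tasks.

Two independent routes compute the "true" (asymptotic) value of every
labelled state:

* :func:`mc_true_values` — Monte-Carlo rollouts: sequences of trials are
  simulated and the cumulative discounted future reward is averaged, with
  rewards counted from one step after the start state (a reward arriving
  exactly one step later contributes ``gamma**1``).
* :func:`dp_true_values` — exact renewal/dynamic-programming solution of
  the same quantities (closed-form geometric sums over the task's renewal
  structure), no sampling.

State labelling follows the observation lag of the agent: the cue (reward)
observation at step t makes step t+1 the cue (reward) timing, and belief
about the latent trial type in the probabilistic tasks collapses at the
timing itself.  Pre-cue states (cue timing and one and two steps before it)
are valued by averaging first-ITI-specific values over the ITIs the agent
still considers possible.

Value convention: the stored values count rewards from +1, so
``V_stored = gamma * V_std`` where ``V_std`` is the standard fixed point of
the TD recursion.  Expected TD-RPE is therefore formed from
``V_stored / gamma`` (equivalently, the transition reward enters
undiscounted), which makes the TD-RPE vanish at fully predicted rewards;
the raw convention is available behind ``convention="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .tasks import TaskSpec

__all__ = ["TrueValueTable", "BeliefState", "mc_true_values",
           "dp_true_values", "belief_states", "precue_belief_values",
           "expected_td_rpe"]

StateKey = Union[int, tuple[str, int]]

#: trial-type priors of the probabilistic tasks (early, late, none)
PRIORS = {"prob-task1": (0.5, 0.5, 0.0), "prob-task2": (0.3, 0.3, 0.4)}

#: timings from cue of the early/late reward (observation step + 1)
EARLY_TIMING, LATE_TIMING = 2, 4


@dataclass
class TrueValueTable:
    """Per-state oracle values (rewards counted from +1) and their MC SEs."""

    kind: str
    gamma: float
    values: dict[StateKey, float]
    se: Optional[dict[StateKey, float]] = None
    delay: Optional[int] = None
    reward_size: float = 1.0

    def value(self, key: StateKey) -> float:
        return self.values[key]

    def std_value(self, key: StateKey) -> float:
        """Value under the standard TD convention (V_stored / gamma)."""
        return self.values[key] / self.gamma

    def cue_to_reward_values(self) -> np.ndarray:
        """Values of the states from cue timing to reward timing inclusive
        (Pavlovian only); the state set of the mean squared value-error."""
        if self.kind != "pavlovian":
            raise ValueError("cue-to-reward state set is Pavlovian-specific")
        return np.array([self.values[s] for s in range(0, self.delay + 1)])


@dataclass
class BeliefState:
    """Posterior over latent trial types at one labelled timing."""

    branch: str
    timing: int
    posterior: tuple[float, float, float]  # (early, late, none)


# ---------------------------------------------------------------------------
# shared assembly of pre-cue states from first-ITI-specific values
# ---------------------------------------------------------------------------

def precue_belief_values(iti1_specific: dict[int, dict[int, float]],
                         iti_set: tuple[int, ...] = (4, 5, 6, 7),
                         ) -> dict[int, float]:
    """Cue-timing value and the two pre-cue values from ITI1-specific tables.

    ``iti1_specific[j][p]`` is the value of the state ``p`` steps after the
    (last) reward timing in sequences whose first ITI is ``j``.  The agent
    does not track elapsed ITI time, so a state ``p`` steps after reward is
    valued by averaging over every first ITI ``j >= p`` for which that state
    exists; the cue value averages, over the realized ITI ``k``, the value
    of the state ``k`` steps after reward, and the states one and two steps
    before the cue average the states ``k-1`` and ``k-2`` steps after.
    Returns ``{0: cue value, -1: ..., -2: ...}``.
    """
    lo = min(iti_set)

    def f(p: int) -> float:
        js = [j for j in iti_set if j >= max(p, lo)]
        return float(np.mean([iti1_specific[j][p] for j in js]))

    out = {}
    for offset, key in ((0, 0), (1, -1), (2, -2)):
        out[key] = float(np.mean([f(k - offset) for k in iti_set]))
    return out


# ---------------------------------------------------------------------------
# exact (renewal / dynamic-programming) oracle
# ---------------------------------------------------------------------------

def _pav_cue_value(gamma: float, delay: int, iti_set, reward_size: float,
                   ) -> float:
    # renewal equation v = gamma^d * r + gamma^d * E[gamma^ITI] * v
    e_iti = np.mean([gamma ** j for j in iti_set])
    return gamma ** delay * reward_size / (1.0 - gamma ** delay * e_iti)


def dp_true_values(spec: TaskSpec, gamma: float = 0.8,
                   reward_size: float = 1.0) -> TrueValueTable:
    """Exact oracle values by solving the task's renewal equations."""
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must lie in (0, 1): the renewal sum must contract")
    iti = spec.iti_set
    if spec.kind == "pavlovian":
        d = spec.delay
        v_cue = _pav_cue_value(gamma, d, iti, reward_size)
        v_rw = float(np.mean([gamma ** j for j in iti])) * v_cue
        vals: dict[StateKey, float] = {d: v_rw}
        for s in range(0, d):
            vals[s] = gamma ** (d - s) * (reward_size + v_rw)
        # ITI1-specific post-reward states: gamma^(j-p) * v_cue
        v1 = {j: {p: gamma ** (j - p) * v_cue for p in range(1, j + 1)}
              for j in iti}
        for p in range(1, min(iti) + 1):  # marginal post-reward states
            vals[d + p] = float(np.mean([v1[j][p] for j in iti if j >= p]))
        vals.update(precue_belief_values(v1, iti))
        # cue state conditioned on the cue having been observed (renewal
        # value); the plain key 0 carries the elapsed-time-agnostic average
        vals[("known", 0)] = v_cue
        return TrueValueTable(kind=spec.kind, gamma=gamma, values=vals,
                              delay=d, reward_size=reward_size)
    if spec.kind not in PRIORS:
        raise ValueError(f"no oracle for task kind {spec.kind!r}")
    pe, pl, pn = PRIORS[spec.kind]
    # trial ends at time 7..10, so the next cue timing sits 3..6 steps
    # after the late reward slot timing (+4)
    gaps = _prob_gaps(spec)
    e_gap = float(np.mean([gamma ** j for j in gaps]))
    v_cue = (pe * gamma ** EARLY_TIMING + pl * gamma ** LATE_TIMING) \
        * reward_size / (1.0 - gamma ** LATE_TIMING * e_gap)

    def v_type(ttype: str, s: int) -> float:
        tail = gamma ** (LATE_TIMING - s) * e_gap * v_cue if s <= LATE_TIMING \
            else float(np.mean([gamma ** (LATE_TIMING + j - s) for j in gaps
                                if LATE_TIMING + j > s])) * v_cue
        rw = {"early": EARLY_TIMING, "late": LATE_TIMING}.get(ttype)
        if rw is not None and rw > s:
            tail += gamma ** (rw - s) * reward_size
        return tail

    vals = {1: pe * v_type("early", 1) + pl * v_type("late", 1)
            + pn * v_type("none", 1)}
    for s in range(EARLY_TIMING, 7):
        vals[("early", s)] = v_type("early", s)
    if spec.kind == "prob-task1":
        for s in range(EARLY_TIMING, 7):
            vals[("late", s)] = v_type("late", s)  # no-early => late for sure
    else:
        post = np.array([0.0, pl, pn]) / (pl + pn)
        for s in (EARLY_TIMING, EARLY_TIMING + 1):
            vals[("noearly", s)] = post[1] * v_type("late", s) \
                + post[2] * v_type("none", s)
        for s in range(LATE_TIMING, 7):
            vals[("late", s)] = v_type("late", s)
            vals[("none", s)] = v_type("none", s)
    v1 = {j: {p: gamma ** (j - p) * v_cue for p in range(1, j + 1)}
          for j in gaps}
    vals.update(precue_belief_values(v1, gaps))
    vals[("known", 0)] = v_cue
    return TrueValueTable(kind=spec.kind, gamma=gamma, values=vals,
                          reward_size=reward_size)


def _prob_gaps(spec: TaskSpec) -> tuple[int, ...]:
    """Steps from the late-slot timing to the next cue timing (ends 7..10)."""
    return tuple(L + 2 - (LATE_TIMING + 2) for L in (7, 8, 9, 10))


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def _discounted_returns(reward_at_timing: np.ndarray, gamma: float,
                        ) -> np.ndarray:
    """G(t) = sum_{k>=1} gamma^k * r_timing(t+k) by a backward pass."""
    G = np.zeros(reward_at_timing.size)
    acc = 0.0
    for t in range(reward_at_timing.size - 2, -1, -1):
        acc = gamma * (reward_at_timing[t + 1] + acc)
        G[t] = acc
    return G


def _sequence_returns(gamma: float, reward_size: float, n_trials: int,
                      first_len: int, first_rw: Optional[int],
                      draw_trial, rng) -> np.ndarray:
    """Reward-timing array and per-step returns for one simulated sequence.

    ``draw_trial(rng) -> (length, reward timing rel. to cue timing or None)``
    samples every trial after the first; the first trial is pinned to
    ``first_len`` and ``first_rw`` so that condition-specific values can be
    estimated.  Each trial's cue timing sits one step after its start.
    """
    lens = [first_len]
    rws = [first_rw]
    for _ in range(n_trials - 1):
        L, rw = draw_trial(rng)
        lens.append(L)
        rws.append(rw)
    T = int(np.sum(lens))
    r_timing = np.zeros(T + 2)
    start = 0
    for L, rw in zip(lens, rws):
        if rw is not None:
            r_timing[start + 1 + rw] = reward_size
        start += L
    return _discounted_returns(r_timing, gamma)


def mc_true_values(spec: TaskSpec, gamma: float = 0.8,
                   n_sequences: int = 1000, trials_per_sequence: int = 1000,
                   rng: Optional[np.random.Generator] = None,
                   reward_size: float = 1.0) -> TrueValueTable:
    """Monte-Carlo oracle values, per the rollout-and-average recipe.

    For each first-ITI (and, in the probabilistic tasks, first-trial-type)
    condition, ``n_sequences`` sequences of ``trials_per_sequence`` trials
    are simulated and the discounted return from each labelled start state
    is averaged.  Standard errors across sequences are stored in ``se``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if spec.kind not in ("pavlovian", "prob-task1", "prob-task2"):
        raise ValueError("oracle defined for conditioning tasks only")
    iti = spec.iti_set
    samples: dict[StateKey, list] = {}
    v1_samples: dict[int, dict[int, list]] = {j: {} for j in iti}

    if spec.kind == "pavlovian":
        d = spec.delay

        def draw_trial(rng):
            return d + int(rng.choice(iti)), d  # reward timing = +d from cue

        for j in iti:
            for _ in range(n_sequences):
                G = _sequence_returns(gamma, reward_size, trials_per_sequence,
                                      first_len=d + j, first_rw=d,
                                      draw_trial=draw_trial, rng=rng)
                # cue timing of trial 1 sits at global index 1
                for s in range(0, min(iti) + d + 1):
                    samples.setdefault(("post", j, s), []).append(G[1 + s])
                for p in range(1, j + 1):
                    v1_samples[j].setdefault(p, []).append(G[1 + d + p])
        vals: dict[StateKey, float] = {}
        ses: dict[StateKey, float] = {}
        for s in range(0, min(iti) + d + 1):
            per_j = [samples[("post", j, s)] for j in iti]
            m = np.array([np.mean(v) for v in per_j])
            sd = np.array([np.std(v, ddof=1) / np.sqrt(len(v)) for v in per_j])
            vals[s] = float(m.mean())
            ses[s] = float(np.sqrt(np.sum(sd ** 2)) / len(iti))
        v1_mean = {j: {p: float(np.mean(v)) for p, v in v1_samples[j].items()}
                   for j in iti}
        vals.update(precue_belief_values(v1_mean, iti))
        for k in (0, -1, -2):
            ses[k] = _precue_se(v1_samples, iti, k)
        vals[("known", 0)], ses[("known", 0)] = _known_cue(v1_samples, iti)
        return TrueValueTable(kind=spec.kind, gamma=gamma, values=vals,
                              se=ses, delay=d, reward_size=reward_size)

    # probabilistic tasks ---------------------------------------------------
    pe, pl, pn = PRIORS[spec.kind]
    gaps = _prob_gaps(spec)
    v1_samples = {j: {} for j in gaps}

    def draw_trial(rng):
        u = rng.random()
        if u < pe:
            rw = EARLY_TIMING
        elif u < pe + pl:
            rw = LATE_TIMING
        else:
            rw = None
        return LATE_TIMING + int(rng.choice(gaps)), rw

    type_rw = {"early": EARLY_TIMING, "late": LATE_TIMING, "none": None}
    type_list = ["early", "late"] + (["none"] if pn > 0 else [])
    per_type: dict[str, dict[int, list]] = {T: {} for T in type_list}
    for T in type_list:
        for _ in range(n_sequences):
            gap = int(rng.choice(gaps))
            G = _sequence_returns(gamma, reward_size, trials_per_sequence,
                                  first_len=LATE_TIMING + gap,
                                  first_rw=type_rw[T],
                                  draw_trial=draw_trial, rng=rng)
            for s in range(1, 7):
                per_type[T].setdefault(s, []).append(G[1 + s])
            for p in range(1, gap + 1):
                v1_samples[gap].setdefault(p, []).append(
                    G[1 + LATE_TIMING + p])
    tmean = {T: {s: float(np.mean(v)) for s, v in per_type[T].items()}
             for T in type_list}
    tse = {T: {s: float(np.std(v, ddof=1) / np.sqrt(len(v)))
               for s, v in per_type[T].items()} for T in type_list}

    def mix(weights, s):
        w = dict(zip(("early", "late", "none"), weights))
        m = sum(w[T] * tmean[T][s] for T in type_list if w[T] > 0)
        se = np.sqrt(sum((w[T] * tse[T][s]) ** 2
                         for T in type_list if w[T] > 0))
        return float(m), float(se)

    vals, ses = {}, {}
    vals[1], ses[1] = mix((pe, pl, pn), 1)
    for s in range(EARLY_TIMING, 7):
        vals[("early", s)], ses[("early", s)] = mix((1, 0, 0), s)
    if spec.kind == "prob-task1":
        for s in range(EARLY_TIMING, 7):
            vals[("late", s)], ses[("late", s)] = mix((0, 1, 0), s)
    else:
        post = (0.0, pl / (pl + pn), pn / (pl + pn))
        for s in (EARLY_TIMING, EARLY_TIMING + 1):
            vals[("noearly", s)], ses[("noearly", s)] = mix(post, s)
        for s in range(LATE_TIMING, 7):
            vals[("late", s)], ses[("late", s)] = mix((0, 1, 0), s)
            vals[("none", s)], ses[("none", s)] = mix((0, 0, 1), s)
    v1_mean = {j: {p: float(np.mean(v)) for p, v in v1_samples[j].items()}
               for j in gaps}
    vals.update(precue_belief_values(v1_mean, gaps))
    for k in (0, -1, -2):
        ses[k] = _precue_se(v1_samples, gaps, k)
    vals[("known", 0)], ses[("known", 0)] = _known_cue(v1_samples, gaps)
    return TrueValueTable(kind=spec.kind, gamma=gamma, values=vals, se=ses,
                          reward_size=reward_size)


def _known_cue(v1_samples, iti) -> tuple[float, float]:
    """Cue-known value: the next-cue-timing return averaged over first ITIs."""
    means, var = [], 0.0
    for j in iti:
        v = v1_samples[j][j]
        means.append(np.mean(v))
        var += (np.std(v, ddof=1) / np.sqrt(len(v))) ** 2
    return float(np.mean(means)), float(np.sqrt(var) / len(iti))


def _precue_se(v1_samples, iti, key: int) -> float:
    """Standard error of the assembled pre-cue estimate.

    The estimate is a linear combination of per-(first-ITI, offset) means;
    offsets within one first-ITI condition share sequences and are strongly
    correlated, so the variance is computed from the per-sequence linear
    combination within each condition (conditions are independent).
    """
    offset = -key
    lo = min(iti)
    K = len(iti)
    var_total = 0.0
    for j in iti:
        coeff: dict[int, float] = {}
        for k in iti:
            p = k - offset
            js = [jj for jj in iti if jj >= max(p, lo)]
            if j in js:
                coeff[p] = coeff.get(p, 0.0) + 1.0 / (K * len(js))
        if not coeff:
            continue
        n = len(v1_samples[j][next(iter(coeff))])
        U = np.zeros(n)
        for p, a in coeff.items():
            U += a * np.asarray(v1_samples[j][p])
        if n > 1:
            var_total += np.var(U, ddof=1) / n
    return float(np.sqrt(var_total))


# ---------------------------------------------------------------------------
# beliefs and expected TD-RPE
# ---------------------------------------------------------------------------

def belief_states(task: int) -> list[BeliefState]:
    """Bayes posteriors over trial types at each labelled timing.

    The posterior at timing s conditions on the observations the network has
    received by then (reward/no-reward at the early and late slots, each
    visible from one step after its observation).
    """
    kind = {1: "prob-task1", 2: "prob-task2"}[task]
    pe, pl, pn = PRIORS[kind]
    out = [BeliefState("", 0, (pe, pl, pn)),
           BeliefState("", 1, (pe, pl, pn))]
    for s in range(EARLY_TIMING, 7):
        out.append(BeliefState("early", s, (1.0, 0.0, 0.0)))
    if kind == "prob-task1":
        for s in range(EARLY_TIMING, 7):
            out.append(BeliefState("late", s, (0.0, 1.0, 0.0)))
    else:
        q = (0.0, pl / (pl + pn), pn / (pl + pn))
        for s in (EARLY_TIMING, EARLY_TIMING + 1):
            out.append(BeliefState("noearly", s, q))
        for s in range(LATE_TIMING, 7):
            out.append(BeliefState("late", s, (0.0, 1.0, 0.0)))
            out.append(BeliefState("none", s, (0.0, 0.0, 1.0)))
    return out


@dataclass
class Transition:
    frm: StateKey
    to: StateKey
    r: float
    delta: float
    label: str = ""


def expected_td_rpe(table: TrueValueTable, spec: TaskSpec,
                    convention: str = "transition-reward",
                    ) -> list[Transition]:
    """Expected TD-RPE on every labelled transition of the task.

    Under the default convention delta = r + V(to) - V(from)/gamma with the
    stored (from +1) values V; this makes delta vanish at fully predicted
    rewards.  ``convention="raw"`` uses delta = r + gamma*V(to) - V(from)
    on the stored values directly.  The cue state enters the chain through
    its cue-known (renewal) value, so the positive TD-RPE at the cue
    reflects only ITI/trial-type uncertainty.
    """
    g = table.gamma
    V = table.values

    def delta(frm, to, r):
        a, b = V[frm], V[to]
        if convention == "transition-reward":
            return r + b - a / g
        if convention == "raw":
            return r + g * b - a
        raise ValueError(f"unknown convention {convention!r}")

    def K(s):
        return ("known", 0) if s == 0 else s

    rs = table.reward_size
    out = []
    if spec.kind == "pavlovian":
        d = spec.delay
        chain = list(range(-2, d + min(spec.iti_set) + 1))
        for frm, to in zip(chain[:-1], chain[1:]):
            r = rs if to == d else 0.0
            lbl = {0: "cue", d: "reward"}.get(to, "")
            out.append(Transition(K(frm), K(to), r, delta(K(frm), K(to), r),
                                  lbl))
        return out
    # probabilistic tasks
    for frm, to in ((-2, -1), (-1, 0), (0, 1)):
        out.append(Transition(K(frm), K(to), 0.0, delta(K(frm), K(to), 0.0),
                              "cue" if to == 0 else ""))
    e, ne = ("early", "late") if spec.kind == "prob-task1" \
        else ("early", "noearly")
    out.append(Transition(1, (e, 2), rs, delta(1, (e, 2), rs),
                          "early reward"))
    out.append(Transition(1, (ne, 2), 0.0, delta(1, (ne, 2), 0.0),
                          "no early reward"))
    for s in (2, 3, 4, 5):
        out.append(Transition((e, s), (e, s + 1), 0.0,
                              delta((e, s), (e, s + 1), 0.0)))
    if spec.kind == "prob-task1":
        for s in (2, 3, 4, 5):
            r = rs if s + 1 == LATE_TIMING else 0.0
            out.append(Transition(("late", s), ("late", s + 1), r,
                                  delta(("late", s), ("late", s + 1), r),
                                  "late reward" if r else ""))
    else:
        out.append(Transition(("noearly", 2), ("noearly", 3), 0.0,
                              delta(("noearly", 2), ("noearly", 3), 0.0)))
        out.append(Transition(("noearly", 3), ("late", LATE_TIMING), rs,
                              delta(("noearly", 3), ("late", LATE_TIMING), rs),
                              "late reward"))
        out.append(Transition(("noearly", 3), ("none", LATE_TIMING), 0.0,
                              delta(("noearly", 3), ("none", LATE_TIMING),
                                    0.0), "reward omitted"))
        for br in ("late", "none"):
            for s in (4, 5):
                out.append(Transition((br, s), (br, s + 1), 0.0,
                                      delta((br, s), (br, s + 1), 0.0)))
    return out


def delta_at(transitions: list[Transition], label: str) -> float:
    """Expected TD-RPE of the uniquely labelled transition."""
    hits = [t for t in transitions if t.label == label]
    if len(hits) != 1:
        raise KeyError(f"label {label!r} matched {len(hits)} transitions")
    return hits[0].delta
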