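"""Oracle state values: closed forms, MC/DP cross-checks, belief states."""

import numpy as np
import pytest

from ovrnn.tasks import TaskSpec
from ovrnn.true_values import (belief_states, delta_at, dp_true_values,
                               expected_td_rpe, mc_true_values,
                               precue_belief_values)

GAMMA = 0.8


def closed_form_cue_value(gamma=GAMMA, delay=3, itis=(4, 5, 6, 7)):
    # renewal equation v = gamma^d + gamma^d * E[gamma^ITI] * v, solved
    # independently of the implementation under test
    e = sum(gamma ** j for j in itis) / len(itis)
    return gamma ** delay / (1 - gamma ** delay * e)


class TestPavlovianDP:
    def setup_method(self):
        self.spec = TaskSpec(kind="pavlovian", delay=3)
        self.table = dp_true_values(self.spec, gamma=GAMMA)

    def test_cue_and_prereward_closed_forms(self):
        v_cue = closed_form_cue_value()
        assert self.table.values[("known", 0)] == pytest.approx(v_cue)
        assert v_cue == pytest.approx(0.605752, abs=1e-6)
        e = sum(GAMMA ** j for j in (4, 5, 6, 7)) / 4
        v_pre = GAMMA * (1 + e * v_cue)
        assert self.table.values[2] == pytest.approx(v_pre)
        assert v_pre == pytest.approx(0.9464877, abs=1e-6)

    def test_reward_linearity(self):
        doubled = dp_true_values(self.spec, gamma=GAMMA, reward_size=2.0)
        for k, v in self.table.values.items():
            assert doubled.values[k] == pytest.approx(2.0 * v)

    def test_small_gamma_kills_future_value(self):
        t = dp_true_values(self.spec, gamma=1e-8)
        assert t.values[2] < 1e-6  # pre-reward state, "+1-start" count

    def test_contraction_required(self):
        with pytest.raises(ValueError):
            dp_true_values(self.spec, gamma=1.0)

    def test_expected_tdrpe_anchors(self):
        trs = expected_td_rpe(self.table, self.spec)
        by_to = {t.to: t for t in trs}
        assert by_to[3].r == 1.0
        assert by_to[3].delta == pytest.approx(0.0, abs=1e-12)
        # deterministic within-trial and post-reward transitions are predicted
        for to in (1, 2, 4, 5, 6, 7):
            assert by_to[to].delta == pytest.approx(0.0, abs=1e-12)
        # positive TD-RPE at the cue reflects the ITI uncertainty only
        assert by_to[("known", 0)].label == "cue"
        assert by_to[("known", 0)].delta > 0

    def test_raw_convention(self):
        trs = expected_td_rpe(self.table, self.spec, convention="raw")
        V = self.table.values
        t01 = [t for t in trs if t.to == 1][0]
        assert t01.delta == pytest.approx(
            GAMMA * V[1] - V[("known", 0)])


def test_precue_surviving_sets():
    """Cue value averages ITI1-specific values over the still-possible ITIs."""
    # distinguishable entries: v1[j][p] = 100*j + p
    itis = (4, 5, 6, 7)
    v1 = {j: {p: 100 * j + p for p in range(1, j + 1)} for j in itis}
    out = precue_belief_values(v1, itis)
    # realized ITI k: cue averages {j >= k}, e.g. 4 candidates at k=4 and
    # 3 candidates at k=5
    expect_cue = np.mean([np.mean([100 * j + k for j in itis if j >= k])
                          for k in itis])
    assert out[0] == pytest.approx(expect_cue)
    expect_m1 = np.mean([np.mean([100 * j + (k - 1) for j in itis
                                  if j >= max(k - 1, 4)]) for k in itis])
    assert out[-1] == pytest.approx(expect_m1)
    const = {j: {p: 2.5 for p in range(1, j + 1)} for j in itis}
    assert precue_belief_values(const, itis) == pytest.approx(
        {0: 2.5, -1: 2.5, -2: 2.5})


@pytest.mark.parametrize("kind", ["pavlovian", "prob-task1", "prob-task2"])
def test_mc_matches_dp_within_three_sigma(kind):
    spec = TaskSpec(kind=kind)
    dp = dp_true_values(spec, gamma=GAMMA)
    mc = mc_true_values(spec, gamma=GAMMA, n_sequences=250,
                        trials_per_sequence=100,
                        rng=np.random.default_rng(42))
    assert set(map(str, mc.values)) == set(map(str, dp.values))
    for k, v_dp in dp.values.items():
        se = mc.se.get(k)
        if se is None or se == 0.0:
            continue
        z = (mc.values[k] - v_dp) / se
        assert abs(z) < 3.0, f"{kind} state {k}: z={z:.2f}"


def test_belief_posteriors():
    b1 = {(s.branch, s.timing): s.posterior for s in belief_states(1)}
    assert b1[("", 1)] == pytest.approx((0.5, 0.5, 0.0))
    assert b1[("late", 2)] == pytest.approx((0.0, 1.0, 0.0))
    b2 = {(s.branch, s.timing): s.posterior for s in belief_states(2)}
    assert b2[("", 1)] == pytest.approx((0.3, 0.3, 0.4))
    assert b2[("noearly", 3)] == pytest.approx((0.0, 3 / 7, 4 / 7))
    for s in belief_states(2):
        assert sum(s.posterior) == pytest.approx(1.0)


def test_belief_posteriors_match_simulated_frequencies():
    spec = TaskSpec(kind="prob-task2", n_trials=20_000)
    from ovrnn.tasks import conditioning_stream
    s = conditioning_stream(spec, np.random.default_rng(8))
    noearly = s.trial_type != 0
    # P(late | no early reward) should be 3/7
    p_late = np.mean(s.trial_type[noearly] == 1)
    assert p_late == pytest.approx(3 / 7, abs=3 * np.sqrt(0.25 / noearly.sum()))


class TestProbTaskTDRPE:
    def test_task1_late_reward_fully_predicted(self):
        spec = TaskSpec(kind="prob-task1")
        trs = expected_td_rpe(dp_true_values(spec, GAMMA), spec)
        assert delta_at(trs, "late reward") == pytest.approx(0.0, abs=1e-12)
        assert delta_at(trs, "early reward") > delta_at(trs, "late reward")

    def test_task2_late_exceeds_early(self):
        spec = TaskSpec(kind="prob-task2")
        trs = expected_td_rpe(dp_true_values(spec, GAMMA), spec)
        d_late = delta_at(trs, "late reward")
        d_early = delta_at(trs, "early reward")
        assert d_late > d_early > 0
        # after no early reward, omission leaves P(late)=3/7 unexplained
        assert d_late == pytest.approx(4 / 7)
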