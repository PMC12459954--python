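"""Unit and property tests of the online TD step and its primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovrnn.core import (AgentConfig, PunctateAgent, ValueRNNAgent, activation,
                        agent_step, decay_vector, init_agent, postsyn_factor,
                        punctate_td_step, rnn_step, state_value, td_rpe,
                        update_rnn_connections, update_value_weights)

finite = st.floats(-30, 30, allow_nan=False)


@pytest.mark.parametrize("z, kind, expected", [
    (0.0, "centered", 0.0),
    (0.0, "positive", 0.5),
    (np.log(3), "centered", 0.25),
    (1.0, "positive", 1 / (1 + np.exp(-1.0))),
])
def test_activation_values(z, kind, expected):
    assert activation(np.array([z]), kind)[0] == pytest.approx(expected)


@given(z=st.lists(finite, min_size=1, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_activation_range_and_monotonicity(z):
    z = np.sort(np.array(z))
    for kind, lo, hi in (("centered", -0.5, 0.5), ("positive", 0.0, 1.0)):
        y = activation(z, kind)
        assert np.all(y > lo) and np.all(y < hi)
        assert np.all(np.diff(y) >= 0)


def test_activation_rejects_nonfinite():
    with pytest.raises(FloatingPointError):
        activation(np.array([np.nan]), "centered")


def test_rnn_step_examples():
    x = np.array([0.3, -0.2])
    o = np.array([1.0, 0.0])
    zero = rnn_step(x, o, np.zeros((2, 2)), np.zeros((2, 2)), "centered")
    assert np.allclose(zero, 0.0)
    one = rnn_step(np.array([0.2]), np.array([0.0]), np.array([[1.0]]),
                   np.array([[0.0]]), "centered")
    assert one[0] == pytest.approx(1 / (1 + np.exp(-0.2)) - 0.5)
    # one-hot observation through an identity feed-forward matrix
    y = rnn_step(np.zeros(2), np.array([1.0, 0.0]), np.zeros((2, 2)),
                 np.eye(2), "positive")
    assert y[0] == pytest.approx(1 / (1 + np.exp(-1.0)))
    assert y[1] == pytest.approx(0.5)
    x_before = x.copy()
    rnn_step(x, o, np.ones((2, 2)), np.ones((2, 2)), "centered")
    assert np.array_equal(x, x_before)  # pure function
    with pytest.raises(ValueError):
        rnn_step(x, o, np.zeros((3, 3)), np.zeros((3, 2)), "centered")


def test_state_value_linear():
    assert state_value(np.zeros(3), np.ones(3)) == 0.0
    assert state_value(np.array([1.0, 1.0]),
                       np.array([0.2, 0.3])) == pytest.approx(0.5)
    w = np.array([0.4, -1.2])
    x = np.array([0.3, 0.8])
    assert state_value(3.0 * w, x) == pytest.approx(3.0 * state_value(w, x))
    with pytest.raises(ValueError):
        state_value(np.zeros(2), np.zeros(3))


def test_td_rpe_formula():
    assert td_rpe(0.0, 0.0, 0.0, 0.8) == 0.0
    assert td_rpe(1.0, 0.0, 0.0, 0.8) == 1.0
    assert td_rpe(0.0, 1.0, 0.0, 0.8) == pytest.approx(0.8)


def test_value_weight_update_and_rectification():
    w = np.array([0.5, 0.05, 0.0])
    x = np.array([1.0, 1.0, 0.3])
    assert np.array_equal(update_value_weights(w, 0.0, x, 0.1, False), w)
    up = update_value_weights(w, -1.0, x, 0.1, True)
    assert up[1] == 0.0  # clipped from -0.05
    assert up[0] == pytest.approx(0.4)
    assert update_value_weights(np.zeros(3), 1.0, x, 0.1, False)[2] == \
        pytest.approx(0.03)


@pytest.mark.parametrize("x, kind, expected", [
    (0.0, "deriv-centered", 0.25),
    (0.5, "monotone-saturating", 0.25),
    (0.9, "monotone-saturating", 0.25),
    (0.9, "deriv-positive", 0.09),
    (0.3, "deriv-positive", 0.21),
])
def test_postsyn_factor(x, kind, expected):
    assert postsyn_factor(np.array([x]), kind)[0] == pytest.approx(expected)


def test_postsyn_factor_monotone_is_continuous_at_half():
    below = postsyn_factor(np.array([0.5 - 1e-12]), "monotone-saturating")
    above = postsyn_factor(np.array([0.5 + 1e-12]), "monotone-saturating")
    assert below[0] == pytest.approx(above[0], abs=1e-10)


class TestConnectionUpdate:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.A = rng.standard_normal((3, 3))
        self.B = rng.standard_normal((3, 2))
        self.x_pre = rng.standard_normal(3)
        self.o_pre = np.array([1.0, 0.0])
        self.x_post = rng.uniform(-0.49, 0.49, 3)
        self.c = rng.standard_normal(3)

    def test_zero_delta_no_change(self):
        A2, B2 = update_rnn_connections(self.A, self.B, 0.0, self.x_pre,
                                        self.o_pre, self.x_post, self.c, 0.1,
                                        "deriv-centered")
        assert np.array_equal(A2, self.A) and np.array_equal(B2, self.B)

    def test_saturated_row_unchanged(self):
        x_post = self.x_post.copy()
        x_post[1] = 0.5  # derivative vanishes at saturation
        A2, _ = update_rnn_connections(self.A, self.B, 1.0, self.x_pre,
                                       self.o_pre, x_post, self.c, 0.1,
                                       "deriv-centered")
        assert np.array_equal(A2[1], self.A[1])
        assert not np.array_equal(A2[0], self.A[0])

    def test_induced_preactivation_change_is_along_feedback(self):
        # (A' - A) x_pre = a*delta*(sum_j x_pre_j^2)*factor_i*c_i, exactly
        a, delta = 0.05, 0.7
        A2, _ = update_rnn_connections(self.A, self.B, delta, self.x_pre,
                                       self.o_pre, self.x_post, self.c, a,
                                       "deriv-centered")
        induced = (A2 - self.A) @ self.x_pre
        expected = a * delta * np.sum(self.x_pre ** 2) \
            * (0.5 + self.x_post) * (0.5 - self.x_post) * self.c
        assert np.allclose(induced, expected, rtol=1e-12)


@pytest.mark.parametrize("factor_kind, act_kind", [
    ("deriv-centered", "centered"),
    ("deriv-positive", "positive"),
])
def test_connection_update_matches_value_gradient(factor_kind, act_kind):
    """The update direction equals d(w.T f(Ax+Bo))/dA_ij by finite differences."""
    rng = np.random.default_rng(3)
    n, m = 4, 3
    A = 0.5 * rng.standard_normal((n, n))
    B = 0.5 * rng.standard_normal((n, m))
    x = rng.uniform(-0.4, 0.4, n) if act_kind == "centered" \
        else rng.uniform(0.1, 0.9, n)
    o = rng.uniform(0, 1, m)
    w = rng.standard_normal(n)

    def value(Amat, Bmat):
        return w @ activation(Amat @ x + Bmat @ o, act_kind)

    x_post = activation(A @ x + B @ o, act_kind)
    A2, B2 = update_rnn_connections(A, B, 1.0, x, o, x_post, w, 1.0,
                                    factor_kind)
    h = 1e-6
    for i in range(n):
        for j in range(n):
            Ap, Am = A.copy(), A.copy()
            Ap[i, j] += h
            Am[i, j] -= h
            g = (value(Ap, B) - value(Am, B)) / (2 * h)
            assert (A2 - A)[i, j] == pytest.approx(g, rel=1e-6, abs=1e-10)
        for k in range(m):
            Bp, Bm = B.copy(), B.copy()
            Bp[i, k] += h
            Bm[i, k] -= h
            g = (value(A, Bp) - value(A, Bm)) / (2 * h)
            assert (B2 - B)[i, k] == pytest.approx(g, rel=1e-6, abs=1e-10)


@given(dr=st.floats(0, 0.5), reps=st.integers(1, 20))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_decay_is_geometric(dr, reps):
    u = np.array([1.0, 2.0])
    out = u.copy()
    for _ in range(reps):
        out = decay_vector(out, dr)
    assert np.allclose(out, (1 - dr) ** reps * u)
    assert np.array_equal(decay_vector(u, 0.0), u)
    assert decay_vector(np.ones(1), 0.001)[0] == pytest.approx(0.999)


class TestInitAgent:
    def test_readout_starts_at_zero_and_ranges(self):
        for variant in ("oVRNNbp", "oVRNNrf", "oVRNNbp-rev", "oVRNNrf-bio"):
            cfg = AgentConfig(variant=variant, n=6)
            s = init_agent(cfg, 2, np.random.default_rng(0))
            assert np.array_equal(s.w, np.zeros(6))
            if cfg.activation_kind == "positive":
                assert np.all((s.x >= 0) & (s.x <= 1))
        bio = init_agent(AgentConfig(variant="oVRNNrf-bio", n=50), 2,
                         np.random.default_rng(1))
        assert np.all((bio.c >= 0) & (bio.c <= 1))

    def test_uniform_feedback_direction(self):
        s = init_agent(AgentConfig(variant="oVRNNrf-uniform", n=5), 2,
                       np.random.default_rng(2))
        assert np.allclose(s.c, s.c[0])
        s2 = init_agent(AgentConfig(variant="oVRNNrf-bio-uniform-fixed", n=5),
                        2, np.random.default_rng(2))
        assert np.allclose(s2.c, 0.5)

    def test_shuffled_control_permutes_source_elements(self):
        rng = np.random.default_rng(3)
        src = (rng.standard_normal((5, 5)), rng.standard_normal((5, 2)))
        cfg = AgentConfig(variant="untrained-shuffled-bio", n=5)
        s = init_agent(cfg, 2, np.random.default_rng(4), source=src)
        assert sorted(s.A.ravel()) == pytest.approx(sorted(src[0].ravel()))
        assert sorted(s.B.ravel()) == pytest.approx(sorted(src[1].ravel()))
        with pytest.raises(ValueError):
            init_agent(cfg, 2, np.random.default_rng(4))

    def test_reproducible_given_seed(self):
        cfg = AgentConfig(variant="oVRNNrf", n=4, seed=11)
        a, b = init_agent(cfg, 2), init_agent(cfg, 2)
        for f in ("x", "A", "B", "w", "c"):
            assert np.array_equal(getattr(a, f), getattr(b, f))


class TestAgentStep:
    def test_zero_stream_stays_silent(self):
        cfg = AgentConfig(variant="oVRNNrf", n=4)
        ag = ValueRNNAgent(cfg, 2, rng=np.random.default_rng(0))
        for _ in range(20):
            out = ag.step(np.zeros(2), 0.0)
            assert out.delta == 0.0 and out.v == 0.0
        assert np.array_equal(ag.w, np.zeros(4))

    def test_single_rewarded_step(self):
        cfg = AgentConfig(variant="oVRNNrf", n=3, a_value=0.1)
        ag = ValueRNNAgent(cfg, 2, rng=np.random.default_rng(0))
        x0 = ag.x.copy()
        out = ag.step(np.zeros(2), 1.0)
        assert out.delta == 1.0  # w = 0 so both values vanish
        assert np.allclose(ag.w, 0.1 * x0)

    def test_determinism(self):
        cfg = AgentConfig(variant="oVRNNrf-bio", n=5)
        rng = np.random.default_rng(9)
        obs = rng.random((40, 2))
        rew = (rng.random(40) < 0.2).astype(float)
        outs = []
        for _ in range(2):
            ag = ValueRNNAgent(cfg, 2, rng=np.random.default_rng(33))
            outs.append([ag.step(obs[t], rew[t]) for t in range(40)])
        assert outs[0] == outs[1]

    def test_zero_rnn_rate_trains_readout_only(self):
        obs = np.tile(np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]), (10, 1))
        rew = np.tile(np.array([0.0, 0.0, 1.0]), 10)
        base = AgentConfig(variant="oVRNNrf", n=4, a_RNN=0.0)
        frozen = AgentConfig(variant="untrained-naive", n=4)
        a = ValueRNNAgent(base, 2, rng=np.random.default_rng(5))
        b = ValueRNNAgent(frozen, 2, rng=np.random.default_rng(5))
        A0 = a.A.copy()
        for t in range(len(rew)):
            oa = a.step(obs[t], rew[t])
            ob = b.step(obs[t], rew[t])
            assert oa.v == pytest.approx(ob.v) and \
                oa.delta == pytest.approx(ob.delta)
        assert np.array_equal(a.A, A0)

    def test_range_and_nonnegativity_invariants(self):
        rng = np.random.default_rng(17)
        obs = (rng.random((200, 2)) < 0.15).astype(float)
        rew = obs[:, 1].copy()
        for variant, lo, hi in (("oVRNNrf", -0.5, 0.5),
                                ("oVRNNrf-bio", 0.0, 1.0)):
            ag = ValueRNNAgent(AgentConfig(variant=variant, n=6), 2,
                               rng=np.random.default_rng(2))
            for t in range(200):
                ag.step(obs[t], rew[t])
                assert np.all(ag.x > lo) and np.all(ag.x < hi)
                if ag.config.nonneg_w:
                    assert np.all(ag.w >= 0)


class TestPunctate:
    def test_no_reward_no_change(self):
        ag = PunctateAgent()
        for i in range(9):
            punctate_td_step(ag, i, i + 1, 0.0, 0.8, 0.1)
        assert np.array_equal(ag.values, np.zeros(10))

    def test_episodic_boundary_skips_update(self):
        ag = PunctateAgent(values=np.arange(10.0), episodic=True)
        before = ag.values.copy()
        _, delta = punctate_td_step(ag, 9, None, 0.0, 0.8, 0.1, boundary=True)
        assert delta == 0.0 and np.array_equal(ag.values, before)

    def test_continuous_fixed_point(self):
        # deterministic 4-state ring with reward entering state 0
        gamma, a = 0.8, 0.1
        ag = PunctateAgent(episodic=False)
        for _ in range(4000):
            for s in range(4):
                nxt = (s + 1) % 4
                punctate_td_step(ag, s, nxt, 1.0 if nxt == 0 else 0.0,
                                 gamma, a)
        for s in range(4):
            nxt = (s + 1) % 4
            r = 1.0 if nxt == 0 else 0.0
            delta = r + gamma * ag.values[nxt] - ag.values[s]
            assert abs(delta) < 1e-6

    def test_punctate_table_has_ten_states(self):
        with pytest.raises(ValueError):
            PunctateAgent(values=np.zeros(7))
        with pytest.raises(IndexError):
            punctate_td_step(PunctateAgent(), 10, 0, 0.0, 0.8, 0.1)
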