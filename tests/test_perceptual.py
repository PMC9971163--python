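"""HGF and Rescorla-Wagner belief filters against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srclearn.perceptual import (
    HGFParams,
    RWParams,
    hgf_filter,
    hgf_update,
    learning_rate,
    rw_filter,
)


def _hand_hgf(u_seq, om2, om3, ka=1.0, state=(0.0, 0.1, 1.0, 1.0)):
    """Plain transliteration of the update recursion, kept independent of
    the package implementation."""
    mu2, s2, mu3, s3 = state
    out = []
    for u in u_seq:
        mh2 = mu2
        mh1 = 1.0 / (1.0 + math.exp(-mh2))
        mh3 = mu3
        v2 = math.exp(ka * mh3 + om2)
        sh2 = s2 + v2
        sh3 = s3 + math.exp(om3)
        d1 = u - mh1
        pi2 = 1.0 / sh2 + mh1 * (1.0 - mh1)
        mu2 = mh2 + d1 / pi2
        s2 = 1.0 / pi2
        w2 = v2 / sh2
        d2 = (s2 + (mu2 - mh2) ** 2) / sh2 - 1.0
        pi3 = 1.0 / sh3 + (ka**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        s3 = 1.0 / pi3
        mu3 = mh3 + s3 * (ka / 2.0) * w2 * d2
        out.append((mh1, mu2, s2, mu3, s3))
    return out


class TestHGFUpdate:
    def test_one_step_hand_oracle(self):
        state, rec = hgf_update((0.0, 0.1, 1.0, 1.0), 1, HGFParams())
        assert rec["muhat1"] == pytest.approx(0.5)
        assert rec["delta1"] == pytest.approx(0.5)
        assert rec["mu2"] == pytest.approx(0.07219, abs=1e-4)
        assert rec["mu3"] == pytest.approx(0.99977, abs=1e-4)
        assert rec["sigma3"] == pytest.approx(1.06824, abs=1e-4)

    def test_extreme_belief_limit(self):
        # a confirming input at a saturated belief barely moves level 2
        state, rec = hgf_update((30.0, 0.1, 1.0, 1.0), 1, HGFParams())
        assert abs(rec["delta1"]) < 2e-8  # clipped prediction bound
        assert abs(rec["mu2"] - 30.0) < 1e-6

    def test_two_updates_compose_to_filter(self):
        p = HGFParams()
        s, r1 = hgf_update(p.initial_state(), 1, p)
        _, r2 = hgf_update(s, 0, p)
        traj = hgf_filter([1, 0], p)
        assert traj.mu2[0] == pytest.approx(r1["mu2"], rel=1e-12)
        assert traj.mu2[1] == pytest.approx(r2["mu2"], rel=1e-12)
        assert traj.mu3[1] == pytest.approx(r2["mu3"], rel=1e-12)


class TestHGFFilter:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        u=st.lists(st.integers(0, 1), min_size=1, max_size=10),
        om2=st.floats(-6.0, -2.0),
        om3=st.floats(-4.0, -1.0),
    )
    def test_matches_hand_recursion(self, u, om2, om3):
        traj = hgf_filter(u, HGFParams(omega2=om2, omega3=om3))
        oracle = _hand_hgf(u, om2, om3)
        for t, (mh1, mu2, s2, mu3, s3) in enumerate(oracle):
            assert traj.muhat1[t] == pytest.approx(mh1, rel=1e-10)
            assert traj.mu2[t] == pytest.approx(mu2, rel=1e-10)
            assert traj.mu3[t] == pytest.approx(mu3, rel=1e-10)
            assert traj.sigma3[t] == pytest.approx(s3, rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(u=st.lists(st.integers(0, 1), min_size=2, max_size=50))
    def test_variances_positive_and_predictions_bounded(self, u):
        traj = hgf_filter(u, HGFParams())
        assert len(traj) == len(u)
        for arr in (traj.sigmahat2, traj.sigmahat3, traj.sigma2, traj.sigma3):
            assert (arr > 0).all()
        assert ((traj.muhat1 > 0) & (traj.muhat1 < 1)).all()

    def test_consistent_evidence_monotone_belief(self):
        traj = hgf_filter(np.ones(30, dtype=int), HGFParams())
        assert (np.diff(traj.muhat1) > 0).all()
        assert traj.muhat1[-1] < 1.0

    def test_predictions_causal(self):
        rng = np.random.default_rng(0)
        u = rng.integers(0, 2, 60)
        u2 = u.copy()
        u2[30:] = rng.permutation(u2[30:])
        a = hgf_filter(u, HGFParams())
        b = hgf_filter(u2, HGFParams())
        np.testing.assert_allclose(a.muhat1[:30], b.muhat1[:30])
        np.testing.assert_allclose(a.mu3[:29], b.mu3[:29])

    def test_frozen_level3_reduces_to_fixed_volatility(self):
        p = HGFParams(omega3=-40.0, sigma3_0=1e-12)
        rng = np.random.default_rng(1)
        traj = hgf_filter(rng.integers(0, 2, 200), p)
        assert np.ptp(traj.mu3) < 1e-8

    def test_tracks_block_probability(self, schedule):
        traj = hgf_filter(schedule["u"].to_numpy(), HGFParams())
        p = schedule["p_match"].to_numpy()
        s = 1.0 / (1.0 + np.exp(-traj.mu2))
        assert s[p == 0.9].mean() > s[p == 0.1].mean()
        # volatility lower in confirmed-stable 0.9 blocks than 0.5 blocks
        assert traj.mu3[p == 0.9].mean() < traj.mu3[p == 0.5].mean()

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            hgf_filter([], HGFParams())
        with pytest.raises(ValueError):
            hgf_filter([0, 2], HGFParams())


class TestRW:
    def test_hand_recursion(self):
        traj = rw_filter([1, 1, 0], RWParams(alpha=0.3, v0=0.5))
        np.testing.assert_allclose(traj.v_post, [0.65, 0.755, 0.5285])
        np.testing.assert_allclose(traj.v_pred, [0.5, 0.65, 0.755])
        np.testing.assert_allclose(traj.delta, [0.5, 0.35, -0.755])

    def test_one_step(self):
        traj = rw_filter([1], RWParams(alpha=0.5, v0=0.5))
        assert traj.v_post[0] == pytest.approx(0.75)

    def test_alpha_bounds(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                RWParams(alpha=bad)

    def test_near_zero_alpha_freezes_belief(self):
        traj = rw_filter([1, 0, 1, 1], RWParams(alpha=1e-9, v0=0.4))
        np.testing.assert_allclose(traj.v_post, 0.4, atol=1e-8)

    def test_long_run_mean_tracks_bernoulli_rate(self):
        rng = np.random.default_rng(42)
        p = 0.7
        u = rng.binomial(1, p, 5000)
        traj = rw_filter(u, RWParams(alpha=0.1))
        # stationary mean of v approaches p within Monte-Carlo error
        assert abs(traj.v_post[1000:].mean() - p) < 0.03
        assert ((traj.v_post >= 0) & (traj.v_post <= 1)).all()


class TestLearningRate:
    def test_one_step_value(self):
        traj = hgf_filter([1], HGFParams())
        lr = learning_rate(traj)
        assert lr[0] == pytest.approx(0.0361, abs=1e-3)
        np.testing.assert_allclose(lr, traj.lr1)

    def test_bounded_and_zero_on_null_error(self, prior_mean_trajectory):
        lr = learning_rate(prior_mean_trajectory)
        assert ((lr >= 0) & (lr <= 1)).all()

    def test_peaks_after_block_transitions(self, schedule, prior_mean_trajectory):
        lr = learning_rate(prior_mean_trajectory)
        wins = 0
        for b in range(1, 10):
            i = b * 40
            if lr[i:i + 3].mean() > lr[i - 3:i].mean():
                wins += 1
        assert wins > 4  # majority of the 9 transitions
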