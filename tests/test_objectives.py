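"""Entropy, KL divergence, normalized fidelity, sigmoid diversity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import golgicode as gc
from conftest import random_params


def profile(*vals):
    return gc.GlycanProfile(np.asarray(vals, dtype=float), normalized=True)


@st.composite
def probability_vectors(draw, n=6):
    raw = draw(st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n))
    arr = np.asarray(raw)
    return arr / arr.sum()


class TestEntropy:
    def test_delta_is_zero(self):
        assert gc.entropy(profile(0, 0, 0, 0, 0, 0, 1)) == 0.0

    def test_uniform_is_log_n(self):
        assert gc.entropy(profile(*[0.25] * 4)) == pytest.approx(np.log(4), rel=1e-12)

    def test_dyadic_hand_sum(self):
        assert gc.entropy(profile(0.5, 0.25, 0.125, 0.125)) == pytest.approx(
            1.75 * np.log(2), rel=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            gc.entropy(np.array([0.5, 0.2]))


class TestKL:
    def test_identity_of_indiscernibles(self):
        p = profile(0.5, 0.25, 0.125, 0.125)
        assert gc.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_sum(self):
        p = profile(*[0.25] * 4)
        q = profile(0.5, 0.25, 0.125, 0.125)
        assert gc.kl_divergence(p, q) == pytest.approx(0.25 * np.log(2), rel=1e-12)

    def test_floor_keeps_value_finite(self):
        p = profile(0.5, 0.5, 0.0)
        q = profile(1.0, 0.0, 0.0)
        val = gc.kl_divergence(p, q)
        assert np.isfinite(val) and val > 5.0  # large but no overflow/NaN

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            gc.kl_divergence(np.array([0.5, 0.5]), np.array([1.5, -0.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(probability_vectors(), probability_vectors())
    def test_gibbs_inequality(self, p, q):
        d = gc.kl_divergence(p, q)
        assert d >= -1e-12
        if np.allclose(p, q, atol=1e-15):
            assert d == pytest.approx(0.0, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(probability_vectors())
    def test_self_divergence_vanishes(self, p):
        assert gc.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-10)


class TestFidelity:
    def test_perfect_match(self):
        p = profile(0.5, 0.25, 0.125, 0.125)
        assert gc.fidelity(p, p).F == pytest.approx(0.0, abs=1e-12)

    def test_uniform_vs_dyadic_is_one_eighth(self):
        t = profile(*[0.25] * 4)
        d = profile(0.5, 0.25, 0.125, 0.125)
        assert gc.fidelity(t, d).F == pytest.approx(0.125, abs=1e-12)

    def test_two_point_target_vs_uniform(self):
        t = profile(0.5, 0.5, 0.0, 0.0)
        d = profile(*[0.25] * 4)
        assert gc.fidelity(t, d).F == pytest.approx(1.0, rel=1e-12)

    def test_delta_target_refused(self):
        t = profile(0, 1, 0, 0)
        d = profile(*[0.25] * 4)
        with pytest.raises(ValueError, match="kl_divergence"):
            gc.fidelity(t, d)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        perm = rng.permutation(8)
        f1 = gc.fidelity(gc.GlycanProfile(p, normalized=True),
                         gc.GlycanProfile(q, normalized=True)).F
        f2 = gc.fidelity(gc.GlycanProfile(p[perm], normalized=True),
                         gc.GlycanProfile(q[perm], normalized=True)).F
        assert f1 == pytest.approx(f2, rel=1e-10)


class TestDiversity:
    def test_uniform_at_threshold_is_half_ns(self):
        u = gc.GlycanProfile(np.full(100, 0.01), normalized=True)
        assert gc.diversity(u).value == 50.0  # sigmoid at 0 is exactly 1/2

    def test_single_species_hand_sum(self):
        c = np.zeros(100)
        c[0] = 1.0
        expected = 1.0 / (1.0 + np.exp(-100 * (1 - 0.01))) \
            + 99.0 / (1.0 + np.exp(1.0))
        val = gc.diversity(gc.GlycanProfile(c, normalized=True)).value
        assert val == pytest.approx(expected, rel=1e-10)
        assert val == pytest.approx(27.625, abs=0.01)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(probability_vectors(n=8))
    def test_bounds_and_permutation_invariance(self, p):
        val = gc.diversity(p).value
        assert 0.0 <= val <= 8.0
        perm = np.roll(np.arange(8), 3)
        assert gc.diversity(p[perm]).value == pytest.approx(val, rel=1e-12)

    def test_strictly_increasing_in_each_coordinate(self):
        # finite-difference check on the sigmoid sum itself
        p = np.array([0.4, 0.3, 0.2, 0.1])

        def sigmoid_sum(c):
            return np.sum(1.0 / (1.0 + np.exp(-4 * (c - 0.25))))

        ref = sigmoid_sum(p)
        for i in range(4):
            bumped = p.copy()
            bumped[i] += 1e-6
            assert sigmoid_sum(bumped) > ref

    def test_nonpositive_threshold_rejected(self):
        u = gc.GlycanProfile(np.full(4, 0.25), normalized=True)
        with pytest.raises(ValueError):
            gc.diversity(u, c_th=0.0)


def test_threshold_robust_sigma_ranking():
    """On fixed random parameter draws, the diversity ranking across
    specificities is unchanged for thresholds 0.5/Ns, 1/Ns, 2/Ns."""
    system = gc.GolgiSystem(NC=3, NE=3, Ns=60)
    rankings = []
    for cth_factor in (0.5, 1.0, 2.0):
        vals = []
        for sigma in (0.0, 1.0, 4.0):
            params = random_params(system, sigma=sigma, seed=42)
            disp = gc.steady_state_linear(system, params).displayed
            vals.append(gc.diversity(disp, c_th=cth_factor / 60).value)
        rankings.append(tuple(np.argsort(vals)))
    assert rankings[0] == rankings[1] == rankings[2]
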