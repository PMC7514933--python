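import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_channel
from gazechannel.channel import (
    GazeChannel,
    channel_metrics,
    entropy,
    generic_measures,
    normalized_mi,
    row_conditional_entropy,
    row_mutual_information,
)
from gazechannel.datasets import load_observer_channel
from gazechannel.markov import StateDistribution, TransitionMatrix, stationary_distribution


def make_channel(P, pi, base="e", source="stationary"):
    labels = tuple(f"A{i}" for i in range(P.shape[0]))
    return GazeChannel(
        P=TransitionMatrix(labels, P),
        pi=StateDistribution(labels, pi, source=source),
        log_base=base,
    )


def stationary_channel(P, base="e"):
    labels = tuple(f"A{i}" for i in range(P.shape[0]))
    tm = TransitionMatrix(labels, P)
    return GazeChannel(P=tm, pi=stationary_distribution(tm), log_base=base)


class TestEntropy:
    def test_fair_coin_is_one_bit(self):
        assert entropy([0.5, 0.5], base=2) == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        assert entropy([1.0, 0.0, 0.0], base=2) == 0.0
        assert entropy([1.0, 0.0, 0.0], base="e") == 0.0

    def test_printed_visit_distribution_nats(self):
        _, pi2 = load_observer_channel(2)
        assert entropy(pi2, base="e") == pytest.approx(1.412, abs=0.01)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            entropy([1.1, -0.1])

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            entropy([0.5, 0.4])


class TestRowMeasures:
    def test_row_entropy_printed_value(self):
        tm, _ = load_observer_channel(2)
        assert row_conditional_entropy(tm, 1, base="e") == pytest.approx(0.736, abs=0.01)

    def test_one_hot_row_entropy_zero(self):
        tm, _ = load_observer_channel(5)
        assert row_conditional_entropy(tm, 1, base="e") == 0.0

    def test_uniform_row_is_log_s(self):
        P = np.array([[1 / 3, 1 / 3, 1 / 3], [0, 1, 0], [0, 0, 1]])
        assert row_conditional_entropy(P, 1, base=2) == pytest.approx(math.log2(3))

    def test_row_mi_printed_values(self):
        tm5, pi5 = load_observer_channel(5)
        assert row_mutual_information(tm5, pi5, 1, base="e") == pytest.approx(2.428, abs=0.01)
        tm2, pi2 = load_observer_channel(2)
        assert row_mutual_information(tm2, pi2, 5, base="e") == pytest.approx(0.498, abs=0.01)

    def test_row_equal_to_pi_has_zero_mi(self):
        pi = np.array([0.2, 0.3, 0.5])
        P = np.tile(pi, (3, 1))
        assert row_mutual_information(P, pi, 2) == pytest.approx(0.0, abs=1e-14)

    def test_mass_on_zero_probability_destination_rejected(self):
        P = np.array([[0.5, 0.5], [1.0, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            row_mutual_information(P, np.array([1.0, 0.0]), 1)


class TestChannelMetrics:
    @pytest.mark.parametrize(
        "observer, Hs, Ht, Hxy, MI",
        [(2, 1.412, 0.504, 1.916, 0.908), (5, 1.487, 0.529, 2.016, 0.958)],
    )
    def test_worked_example(self, observer, Hs, Ht, Hxy, MI):
        tm, pi = load_observer_channel(observer)
        m = channel_metrics(GazeChannel(P=tm, pi=pi, log_base="e"))
        assert m.Hs == pytest.approx(Hs, abs=0.01)
        assert m.Ht == pytest.approx(Ht, abs=0.01)
        assert m.Hxy == pytest.approx(Hxy, abs=0.01)
        assert m.MI == pytest.approx(MI, abs=0.01)

    def test_uniform_channel_has_zero_mi(self):
        s = 4
        P = np.full((s, s), 1 / s)
        m = channel_metrics(make_channel(P, np.full(s, 1 / s)))
        assert m.MI == pytest.approx(0.0, abs=1e-12)
        assert m.Ht == pytest.approx(m.Hs) == pytest.approx(math.log(s))

    def test_deterministic_cycle_is_fully_informative(self):
        P = np.roll(np.eye(3), 1, axis=1)
        m = channel_metrics(make_channel(P, np.full(3, 1 / 3)))
        assert m.Ht == 0.0
        assert m.MI == pytest.approx(m.Hs) == pytest.approx(math.log(3))

    def test_chain_rule_identity_with_stationary_pi(self, rng):
        for s in (2, 3, 4, 5, 6):
            ch = stationary_channel(random_channel(rng, s))
            m = channel_metrics(ch)
            assert abs(m.MI - (m.Hs - m.Ht)) < 1e-10
            assert m.Hxy == pytest.approx(m.Hs + m.Ht, abs=1e-14)

    def test_empirical_pi_discrepancy_is_reported_not_hidden(self):
        # printed pi is empirical, so MI != Hs - Ht; both sides stay visible
        tm, pi = load_observer_channel(2)
        m = channel_metrics(GazeChannel(P=tm, pi=pi))
        assert abs(m.MI - (m.Hs - m.Ht)) > 1e-6

    def test_oracle_equivalence_against_generic_measures(self, rng):
        ch = stationary_channel(random_channel(rng, 3))
        m = channel_metrics(ch)
        joint = ch.pi.pi[:, None] * ch.P.P
        g = generic_measures(joint)
        assert abs(g["H_X"] - m.Hs) < 1e-12
        assert abs(g["H_Y_given_X"] - m.Ht) < 1e-12
        assert abs(g["MI"] - m.MI) < 1e-12

    def test_bounds(self, rng):
        for s in (2, 4, 6):
            m = channel_metrics(stationary_channel(random_channel(rng, s)))
            assert 0 <= m.Hs <= math.log(s) + 1e-12
            assert 0 <= m.Ht <= math.log(s) + 1e-12
            assert m.MI >= -1e-12
            assert 0 <= m.rho_Hs <= 1 + 1e-12


class TestGenericMeasures:
    def test_independent_joint_has_zero_mi(self):
        u = np.array([0.3, 0.7])
        v = np.array([0.25, 0.25, 0.5])
        g = generic_measures(np.outer(u, v))
        assert g["MI"] == pytest.approx(0.0, abs=1e-14)

    def test_diagonal_joint_is_one_bit(self):
        g = generic_measures(np.diag([0.5, 0.5]), base=2)
        assert g["MI"] == pytest.approx(1.0)
        assert g["H_Y_given_X"] == pytest.approx(0.0, abs=1e-14)


class TestBaseChange:
    def test_all_metrics_scale_by_ln2(self, rng):
        P = random_channel(rng, 4)
        ch_e = stationary_channel(P, base="e")
        ch_2 = stationary_channel(P, base=2)
        m_e, m_2 = channel_metrics(ch_e), channel_metrics(ch_2)
        ln2 = math.log(2)
        for attr in ("Hs", "Ht", "Hxy", "MI"):
            assert getattr(m_2, attr) * ln2 == pytest.approx(getattr(m_e, attr), rel=1e-14, abs=1e-14)
        np.testing.assert_allclose(m_2.row_H * ln2, m_e.row_H, rtol=1e-13, atol=1e-14)
        np.testing.assert_allclose(m_2.row_I * ln2, m_e.row_I, rtol=1e-13, atol=1e-14)
        # the normalised ratios are base-invariant
        assert m_2.rho_Hs == pytest.approx(m_e.rho_Hs, rel=1e-12)


class TestNormalizedMI:
    def test_printed_correlation_coefficients(self):
        for obs, rho in ((2, 0.643), (5, 0.644)):
            tm, pi = load_observer_channel(obs)
            m = channel_metrics(GazeChannel(P=tm, pi=pi))
            assert normalized_mi(m, "by_Hs") == pytest.approx(rho, abs=0.01)

    def test_zero_mi_gives_zero(self):
        s = 3
        m = channel_metrics(make_channel(np.full((s, s), 1 / s), np.full(s, 1 / s)))
        assert normalized_mi(m, "by_Hs") == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_cycle_gives_one(self):
        P = np.roll(np.eye(3), 1, axis=1)
        m = channel_metrics(make_channel(P, np.full(3, 1 / 3)))
        assert normalized_mi(m, "by_Hs") == pytest.approx(1.0)

    def test_degenerate_channel_rejected(self):
        m = channel_metrics(make_channel(np.array([[1.0]]), np.array([1.0])))
        with pytest.raises(ValueError, match="degenerate"):
            normalized_mi(m)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    s=st.integers(min_value=2, max_value=6),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_channel_and_generic_routes_agree_on_random_channels(s, seed):
    """Channel-form metrics equal the brute-force joint-distribution route,
    and the chain rule MI = Hs - Ht holds, for any stationary channel."""
    rng = np.random.default_rng(seed)
    ch = stationary_channel(random_channel(rng, s))
    m = channel_metrics(ch)
    g = generic_measures(ch.pi.pi[:, None] * ch.P.P)
    assert abs(g["H_X"] - m.Hs) < 1e-10
    assert abs(g["H_Y"] - m.Hs) < 1e-10
    assert abs(g["H_XY"] - m.Hxy) < 1e-10
    assert abs(g["H_Y_given_X"] - m.Ht) < 1e-10
    assert abs(g["MI"] - m.MI) < 1e-10
    assert abs(m.MI - (m.Hs - m.Ht)) < 1e-10


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    lam=st.floats(min_value=0.0, max_value=1.0),
)
def test_mixing_toward_uniform_never_increases_mi(seed, lam):
    """On doubly-stochastic chains (uniform pi preserved), blending the
    transition matrix toward uniform rows cannot increase MI."""
    rng = np.random.default_rng(seed)
    s = 4
    # random doubly-stochastic matrix by symmetrising a permutation mixture
    perms = [np.eye(s)[rng.permutation(s)] for _ in range(6)]
    w = rng.dirichlet(np.ones(6))
    P = sum(wi * Mi for wi, Mi in zip(w, perms))
    U = np.full((s, s), 1 / s)
    pi = np.full(s, 1 / s)
    mi_orig = channel_metrics(make_channel(P, pi)).MI
    mi_mixed = channel_metrics(make_channel((1 - lam) * P + lam * U, pi)).MI
    assert mi_mixed <= mi_orig + 1e-9
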