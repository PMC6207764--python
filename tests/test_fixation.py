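"""Fixation probabilities, cooperation frequency and the stationary chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_scheme
from coopctl import (
    EvolutionParams,
    InterferenceScheme,
    PDGame,
    cooperation_frequency,
    cooperation_ratio_closed_form,
    fixation_probabilities,
    g_statistic,
    stationary_distribution,
)
from coopctl.game import average_payoffs, fermi_probability


def brute_force_absorption(game, params, scheme):
    """Independent oracle: absorption probabilities of the full (N+1)-state
    chain by first-step analysis, built from the Fermi rule from scratch."""
    N = params.N
    tp = np.zeros(N + 1)
    tm = np.zeros(N + 1)
    for k in range(1, N):
        pi_c, pi_d = average_payoffs(k, game, params)
        pi_c += scheme.theta_at(k) / k
        pair = (N - k) / N * k / N
        tp[k] = pair * fermi_probability(pi_d, pi_c, params.beta)
        tm[k] = pair * fermi_probability(pi_c, pi_d, params.beta)
    # solve (I - U) x = b for absorption at S_N
    U = np.zeros((N - 1, N - 1))
    for k in range(1, N):
        U[k - 1, k - 1] = 1 - tp[k] - tm[k]
        if k + 1 <= N - 1:
            U[k - 1, k] = tp[k]
        if k - 1 >= 1:
            U[k - 1, k - 2] = tm[k]
    b_up = np.zeros(N - 1)
    b_up[-1] = tp[N - 1]
    x_up = np.linalg.solve(np.eye(N - 1) - U, b_up)
    b_down = np.zeros(N - 1)
    b_down[0] = tm[1]
    x_down = np.linalg.solve(np.eye(N - 1) - U, b_down)
    return x_up[0], x_down[-1]  # rho_DC, rho_CD


class TestFixationProbabilities:
    @pytest.mark.parametrize("N", [2, 10, 100])
    def test_neutral_is_exactly_one_over_N(self, game, N, rng):
        params = EvolutionParams(N=N, beta=0.0)
        for scheme in (InterferenceScheme.zero(N), random_scheme(rng, N)):
            fp = fixation_probabilities(game, params, scheme)
            assert fp.rho_DC == 1.0 / N
            assert fp.rho_CD == 1.0 / N
            assert fp.log_ratio == 0.0

    def test_probabilities_in_open_interval(self, game):
        fp = fixation_probabilities(game, EvolutionParams(N=50, beta=0.3), InterferenceScheme.zero(50))
        assert 0 < fp.rho_DC < 1 and 0 < fp.rho_CD < 1

    @pytest.mark.parametrize("N,beta,theta", [(2, 0.7, 0.0), (10, 0.1, 0.0), (10, 0.5, 2.0), (12, 1.2, 4.0)])
    def test_matches_first_step_analysis_oracle(self, game, N, beta, theta):
        params = EvolutionParams(N=N, beta=beta)
        scheme = InterferenceScheme.zero(N) if theta == 0 else InterferenceScheme.full_invest(N, theta)
        fp = fixation_probabilities(game, params, scheme)
        rho_dc, rho_cd = brute_force_absorption(game, params, scheme)
        assert fp.rho_DC == pytest.approx(rho_dc, rel=1e-10)
        assert fp.rho_CD == pytest.approx(rho_cd, rel=1e-10)

    def test_scheme_size_mismatch(self, game):
        with pytest.raises(ValueError, match="scheme"):
            fixation_probabilities(game, EvolutionParams(N=10, beta=0.1), InterferenceScheme.zero(12))


class TestClosedForm:
    def test_no_interference_value(self, game):
        # sum of payoff advantages collapses to N(R+S-T-P)/2 + (P-R) = -101
        params = EvolutionParams(N=100, beta=0.1)
        lr = cooperation_ratio_closed_form(game, params, InterferenceScheme.zero(100))
        assert lr == pytest.approx(-10.1, rel=1e-12)
        assert math.exp(lr) == pytest.approx(4.1e-5, rel=0.01)

    def test_neutral_ratio_is_one(self, game, rng):
        lr = cooperation_ratio_closed_form(game, EvolutionParams(N=40, beta=0.0), random_scheme(rng, 40))
        assert lr == 0.0

    def test_depends_on_scheme_only_through_G(self, game):
        # two different allocations with identical G
        N = 30
        params = EvolutionParams(N=N, beta=0.4)
        a = InterferenceScheme.individual_based(N, theta=2.0, t=10)  # G = 20
        theta = np.zeros(N - 1)
        theta[19] = 20 * 20  # all mass at state 20: G = 400/20 = 20
        b = InterferenceScheme.general(theta)
        assert g_statistic(a) == pytest.approx(g_statistic(b))
        assert cooperation_ratio_closed_form(game, params, a) == pytest.approx(
            cooperation_ratio_closed_form(game, params, b), rel=1e-12
        )

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(
        N=st.integers(2, 200),
        beta=st.floats(0.0, 2.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_product_form_agrees_with_closed_form(self, N, beta, seed):
        rng = np.random.default_rng(seed)
        game = PDGame.standard()
        params = EvolutionParams(N=N, beta=beta)
        scheme = InterferenceScheme.general(rng.uniform(0, 10, N - 1))
        fp = fixation_probabilities(game, params, scheme)
        lr = cooperation_ratio_closed_form(game, params, scheme)
        if lr == 0.0:
            assert fp.log_ratio == pytest.approx(0.0, abs=1e-10)
        else:
            assert fp.log_ratio == pytest.approx(lr, rel=1e-8)


class TestGStatistic:
    def test_individual_based_is_t_times_theta(self):
        assert g_statistic(InterferenceScheme.individual_based(100, theta=5.0, t=30)) == pytest.approx(150.0)

    def test_zero_scheme(self):
        assert g_statistic(InterferenceScheme.zero(25)) == 0.0

    def test_linear_scheme(self):
        N = 12
        assert g_statistic(InterferenceScheme.general(np.arange(1, N))) == pytest.approx(N - 1)


class TestCooperationFrequency:
    def test_neutral_is_half_exactly(self, game, rng):
        params = EvolutionParams(N=60, beta=0.0)
        assert cooperation_frequency(game, params, random_scheme(rng, 60)).coop_frequency == 0.5

    def test_balanced_G_gives_half_for_any_beta(self, game):
        # G placed exactly at the 50%-cooperation bound makes the ratio 1
        for beta in (0.05, 0.5, 2.0):
            N = 20
            params = EvolutionParams(N=N, beta=beta)
            G_star = N * (game.T + game.P - game.R - game.S) / 2 + (game.R - game.P)
            theta = np.zeros(N - 1)
            theta[0] = G_star  # all mass at state 1: G = theta_1 / 1
            out = cooperation_frequency(game, params, InterferenceScheme.general(theta))
            assert out.coop_frequency == pytest.approx(0.5, abs=1e-12)

    def test_paper_regime_reaches_99_percent(self, game, params100):
        scheme = InterferenceScheme.individual_based(100, theta=5.0, t=30)
        assert cooperation_frequency(game, params100, scheme).coop_frequency >= 0.99

    def test_frequency_consistent_with_fixation_pair(self, game):
        params = EvolutionParams(N=30, beta=0.3)
        scheme = InterferenceScheme.full_invest(30, 1.5)
        out = cooperation_frequency(game, params, scheme)
        fp = out.fixation
        assert out.coop_frequency == pytest.approx(fp.rho_DC / (fp.rho_DC + fp.rho_CD), rel=1e-10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(k=st.integers(1, 19), bump=st.floats(0.1, 10.0), seed=st.integers(0, 2**31 - 1))
    def test_monotone_in_each_theta(self, k, bump, seed):
        # raising any single theta_k strictly raises the frequency when beta > 0
        game = PDGame.standard()
        N = 20
        params = EvolutionParams(N=N, beta=0.2)
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 3, N - 1)
        lifted = base.copy()
        lifted[k - 1] += bump
        f0 = cooperation_frequency(game, params, InterferenceScheme.general(base)).coop_frequency
        f1 = cooperation_frequency(game, params, InterferenceScheme.general(lifted)).coop_frequency
        assert f1 > f0


class TestStationaryDistribution:
    def test_two_strategies_symmetric(self):
        assert np.allclose(stationary_distribution(np.array([[0, 0.2], [0.2, 0]])), [0.5, 0.5])

    def test_two_strategies_detailed_balance(self):
        # rho_DC = 3 rho_CD -> (0.25, 0.75) ordering (D, C)
        rho = np.array([[0.0, 0.3], [0.1, 0.0]])
        assert np.allclose(stationary_distribution(rho), [0.25, 0.75])

    def test_three_strategies_uniform(self):
        rho = np.full((3, 3), 0.2)
        assert np.allclose(stationary_distribution(rho), [1 / 3] * 3)

    def test_matches_two_state_formula(self, game):
        params = EvolutionParams(N=25, beta=0.4)
        scheme = InterferenceScheme.full_invest(25, 2.0)
        fp = fixation_probabilities(game, params, scheme)
        dist = stationary_distribution(np.array([[0.0, fp.rho_DC], [fp.rho_CD, 0.0]]))
        total = fp.rho_DC + fp.rho_CD
        assert np.allclose(dist, [fp.rho_CD / total, fp.rho_DC / total], atol=1e-12)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.zeros((2, 3)))

    def test_reducible_chain_diagnosed(self):
        # three strategies with no transitions at all between {0,1} and {2}
        rho = np.zeros((3, 3))
        rho[0, 1] = rho[1, 0] = 0.3
        with pytest.raises(np.linalg.LinAlgError, match="reducible|unique"):
            stationary_distribution(rho)
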