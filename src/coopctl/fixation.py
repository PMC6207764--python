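"""Fixation probabilities and the small-mutation-limit cooperation frequency.

In the small-mutation limit the population is monomorphic almost always, and
the long-run dynamics reduce to a two-state Markov chain over the all-D and
all-C states whose transition rates are the fixation probabilities of a
single mutant.  The stationary fraction of time spent in all-C,
rho_DC / (rho_DC + rho_CD), is the cooperation frequency that interference
schemes are designed to raise.

All fixation sums are evaluated in log space.  The Fermi ratio identity
T^-(k)/T^+(k) = exp(-beta Delta_k) collapses the product over states to a
cumulative sum of payoff advantages, so

    rho_DC = 1 / sum_{i=0}^{N-1} exp(-beta sum_{k<=i} Delta_k)

is computed with a log-sum-exp; products of Fermi factors are never formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .game import EvolutionParams, InterferenceScheme, PDGame, delta_vector

__all__ = [
    "FixationPair",
    "CooperationOutcome",
    "fixation_probabilities",
    "cooperation_ratio_closed_form",
    "g_statistic",
    "cooperation_frequency",
    "stationary_distribution",
]


@dataclass(frozen=True)
class FixationPair:
    """Fixation probabilities of a single mutant in each homogeneous state.

    Attributes
    ----------
    rho_DC : float
        Probability a single cooperator fixates in an all-defector population.
    rho_CD : float
        Probability a single defector fixates in an all-cooperator population.
    log_ratio : float
        Natural log of rho_DC / rho_CD.
    """

    rho_DC: float
    rho_CD: float
    log_ratio: float


@dataclass(frozen=True)
class CooperationOutcome:
    """Stationary cooperation frequency with its ingredients."""

    fixation: FixationPair
    coop_frequency: float
    G: float


def fixation_probabilities(
    game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> FixationPair:
    """Fixation probabilities rho_DC and rho_CD under an interference scheme.

    At beta = 0 both equal exactly 1/N (neutral drift); for beta > 0 they are
    evaluated in log space from the cumulative payoff-advantage sums.
    """
    N = params.N
    if scheme.N != N:
        raise ValueError(f"scheme built for N={scheme.N} but params.N={N}")
    if params.beta == 0:
        return FixationPair(rho_DC=1.0 / N, rho_CD=1.0 / N, log_ratio=0.0)
    # S_i = beta * sum_{k=1}^{i} Delta_k for i = 0..N-1 (S_0 = 0)
    s = np.concatenate(([0.0], np.cumsum(params.beta * delta_vector(game, params, scheme))))
    log_rho_dc = -logsumexp(-s[:N])
    # rho_CD is the same construction run from the all-C end: the cumulative
    # sums are re-based at the total advantage S_{N-1}.
    log_rho_cd = -logsumexp(s[N - 1] - s[:N])
    return FixationPair(
        rho_DC=float(np.exp(log_rho_dc)),
        rho_CD=float(np.exp(log_rho_cd)),
        log_ratio=float(log_rho_dc - log_rho_cd),
    )


def g_statistic(scheme: InterferenceScheme) -> float:
    """The scalar G = sum_k theta_k / k through which a scheme sets the
    cooperation frequency; equals t * theta for individual-based schemes."""
    return float(np.sum(scheme.per_capita_bonus()))


def cooperation_ratio_closed_form(
    game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> float:
    """log(rho_DC / rho_CD) in closed form:

        beta * ( N (R + S - T - P) / 2 + (P - R) + G ).

    Depends on the scheme only through G, so any two schemes with equal G
    yield the same cooperation frequency.
    """
    if scheme.N != params.N:
        raise ValueError(f"scheme built for N={scheme.N} but params.N={params.N}")
    base = params.N * (game.R + game.S - game.T - game.P) / 2.0 + (game.P - game.R)
    return params.beta * (base + g_statistic(scheme))


def cooperation_frequency(
    game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> CooperationOutcome:
    """Stationary cooperation frequency rho_DC / (rho_DC + rho_CD).

    Exactly 0.5 at beta = 0 for any scheme; strictly increasing in G for
    beta > 0.  Evaluated from the closed-form log ratio through a stable
    logistic so extreme selection never overflows.
    """
    fix = fixation_probabilities(game, params, scheme)
    if params.beta == 0:
        freq = 0.5
    else:
        # rho_DC/(rho_DC+rho_CD) = sigmoid(log_ratio)
        lr = fix.log_ratio
        freq = float(1.0 / (1.0 + np.exp(-lr))) if lr >= 0 else float(np.exp(lr) / (1.0 + np.exp(lr)))
    return CooperationOutcome(fixation=fix, coop_frequency=freq, G=g_statistic(scheme))


def stationary_distribution(rho: np.ndarray) -> np.ndarray:
    """Stationary distribution of the homogeneous-state chain for s strategies.

    Parameters
    ----------
    rho : (s, s) array
        ``rho[i, j]`` is the probability that a single mutant of strategy j
        fixates in a resident population of strategy i.  The diagonal is
        ignored.

    Returns
    -------
    ndarray of shape (s,)
        The unique stationary distribution of the chain with off-diagonal
        transition probabilities rho[i, j] / (s - 1).  For s = 2 with
        ordering (D, C) this is (rho_CD, rho_DC) normalised.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1] or rho.shape[0] < 2:
        raise ValueError("rho must be a square (s, s) matrix with s >= 2")
    s = rho.shape[0]
    M = rho / (s - 1)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    if np.any(np.diag(M) < -1e-12):
        raise ValueError("invalid fixation matrix: row transition mass exceeds 1")
    # left null space of (M - I): stationary vector of the row-stochastic M
    _, sing, vt = np.linalg.svd(M.T - np.eye(s))
    if s > 2 and sing[-2] < 1e-12:
        raise np.linalg.LinAlgError(
            "stationary distribution is not unique (chain appears reducible); "
            f"second-smallest singular value {sing[-2]:.3e}"
        )
    v = vt[-1]
    v = np.abs(v)
    total = v.sum()
    if total <= 0 or not np.isfinite(total):
        raise np.linalg.LinAlgError("failed to extract a valid stationary vector")
    return v / total
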