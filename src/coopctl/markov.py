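"""Absorbing-Markov-chain accounting of the expected interference cost.

The cooperator count performs a birth-death walk over states S_0..S_N with
S_0 (all-D) and S_N (all-C) absorbing.  The transient block U is
tridiagonal, and the fundamental matrix (I - U)^{-1} gives the expected
number of time steps spent in each transient state.  Under the convention
that a mutant appears at S_1 or S_{N-1} with probability 1/2 each, the
expected visits to S_i are v_i = (n_{1,i} + n_{N-1,i})/2 and the expected
total interference cost is EC = sum_i v_i theta_i.

The needed fundamental-matrix rows are evaluated through the closed-form
Green's function of the birth-death chain, computed entirely in log space:
under strong selection the chain can be quasi-stationary near the
investment threshold and the visit counts then span hundreds of orders of
magnitude, which defeats generic linear solvers but is exact and O(N) in
the log-space recursion.  A dense-inverse path is kept for small-N
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .game import EvolutionParams, InterferenceScheme, PDGame, transition_vectors

__all__ = [
    "ChainAnalysis",
    "CostReport",
    "build_transient_matrix",
    "expected_visits",
    "expected_cost",
    "absorption_probabilities",
    "fundamental_matrix_dense",
]

_DENSE_N_CAP = 50


@dataclass(frozen=True)
class ChainAnalysis:
    """Transient block of the cooperator-count chain.

    ``t_plus[k-1]`` and ``t_minus[k-1]`` are the up/down probabilities from
    state S_k; the tridiagonal U is stored through them.  The start
    convention (equal mass on S_1 and S_{N-1}) is fixed here because every
    downstream quantity assumes it.
    """

    t_plus: np.ndarray
    t_minus: np.ndarray

    @property
    def n_transient(self) -> int:
        return self.t_plus.size

    @property
    def N(self) -> int:
        return self.t_plus.size + 1

    @property
    def U(self) -> np.ndarray:
        """Dense (N-1)x(N-1) transient transition matrix (for inspection)."""
        m = self.n_transient
        U = np.diag(1.0 - self.t_plus - self.t_minus)
        idx = np.arange(m - 1)
        U[idx, idx + 1] = self.t_plus[:-1]
        U[idx + 1, idx] = self.t_minus[1:]
        return U


@dataclass(frozen=True)
class CostReport:
    """Expected interference cost decomposed per state."""

    expected_cost: float
    expected_interference_events: float
    per_state_cost: np.ndarray
    visits: np.ndarray


def build_transient_matrix(
    game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> ChainAnalysis:
    """Assemble the tridiagonal transient block (via its T^+/T^- diagonals)."""
    t_plus, t_minus = transition_vectors(game, params, scheme)
    return ChainAnalysis(t_plus=t_plus, t_minus=t_minus)


def _log_green_rows(chain: ChainAnalysis) -> tuple[np.ndarray, np.ndarray]:
    """log n_{1,j} and log n_{N-1,j} for j = 1..N-1 via the birth-death
    Green's function.

    With gamma_0 = 1, gamma_k = prod_{i<=k} T^-(i)/T^+(i) and the scale sums
    S_j = sum_{k<j} gamma_k, the expected time at S_j (self-loops included)
    starting from S_a is

        n_{a,j} = hit(a, j) * S_j (S_N - S_j) / (T^+(j) gamma_j S_N),

    where hit(a, j) = S_a/S_j for a <= j and (S_N - S_a)/(S_N - S_j) for
    a >= j.  Everything is a sum of positive terms, so evaluating the
    gammas and scale sums in log space is exact up to rounding even when
    the visit counts span hundreds of orders of magnitude.
    """
    if np.any(chain.t_plus <= 0) or np.any(chain.t_minus <= 0):
        raise np.linalg.LinAlgError(
            "a one-step probability T+(k) or T-(k) is exactly zero (selection "
            "too strong for float64); expected visits are not representable"
        )
    m = chain.n_transient
    # log gamma_k for k = 0..N-1
    log_gamma = np.concatenate(
        ([0.0], np.cumsum(np.log(chain.t_minus) - np.log(chain.t_plus)))
    )
    # log S_j = log sum_{k=0}^{j-1} gamma_k for j = 1..N-1, and log S_N
    prefix = np.logaddexp.accumulate(log_gamma)
    log_S = prefix[:-1]          # S_1..S_{N-1}
    log_S_N = prefix[-1]
    # log (S_N - S_j) = log sum_{k=j}^{N-1} gamma_k
    log_tail = np.logaddexp.accumulate(log_gamma[::-1])[::-1][1:]  # j = 1..N-1
    log_denom = np.log(chain.t_plus) + log_gamma[1:] + log_S_N
    log_row_1 = log_gamma[0] + log_tail - log_denom
    log_row_n = log_gamma[m] + log_S - log_denom
    return log_row_1, log_row_n


def expected_visits(chain: ChainAnalysis) -> np.ndarray:
    """Expected number of time steps in each transient state, averaging the
    two single-mutant starts S_1 and S_{N-1} with probability 1/2 each.

    Self-loop steps count: a step that leaves the cooperator count unchanged
    is still a time step spent (and paid for) in that state.
    """
    log_row_1, log_row_n = _log_green_rows(chain)
    v = 0.5 * (np.exp(log_row_1) + np.exp(log_row_n))
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise np.linalg.LinAlgError(
            "expected visit counts are not strictly positive and finite "
            "(likely overflow under extreme selection)"
        )
    return v


def expected_cost(chain: ChainAnalysis, scheme: InterferenceScheme) -> CostReport:
    """Expected total interference cost EC = sum_i v_i theta_i, together
    with the expected number of paying time steps (visits to states with
    theta_i > 0)."""
    if scheme.N != chain.N:
        raise ValueError(
            f"scheme built for N={scheme.N} but chain has {chain.n_transient} transient states"
        )
    v = expected_visits(chain)
    per_state = v * scheme.theta
    paying = scheme.theta > 0
    return CostReport(
        expected_cost=float(per_state.sum()),
        expected_interference_events=float(v[paying].sum()),
        per_state_cost=per_state,
        visits=v,
    )


def absorption_probabilities(chain: ChainAnalysis) -> tuple[float, float]:
    """First-step-analysis cross-check of the fixation probabilities.

    Returns (rho_DC, rho_CD): the probability of absorbing at all-C from
    S_1, and at all-D from S_{N-1}, via the linear system (I - U) x = b.
    """
    m = chain.n_transient
    ab = np.zeros((3, m))
    ab[1] = chain.t_plus + chain.t_minus
    ab[0, 1:] = -chain.t_plus[:-1]
    ab[2, :-1] = -chain.t_minus[1:]
    b_up = np.zeros(m)
    b_up[-1] = chain.t_plus[-1]
    x_up = solve_banded((1, 1), ab, b_up)
    b_down = np.zeros(m)
    b_down[0] = chain.t_minus[0]
    x_down = solve_banded((1, 1), ab, b_down)
    return float(x_up[0]), float(x_down[-1])


def fundamental_matrix_dense(chain: ChainAnalysis) -> np.ndarray:
    """Dense (I - U)^{-1}, restricted to small chains; cross-check path only."""
    if chain.N > _DENSE_N_CAP:
        raise ValueError(
            f"dense fundamental matrix limited to N <= {_DENSE_N_CAP}; use the banded solver"
        )
    return np.linalg.inv(np.eye(chain.n_transient) - chain.U)
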