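"""Sufficient conditions for target cooperation levels and threshold search.

A target fraction omega of cooperation is guaranteed whenever the scheme's
investment statistic G = sum_k theta_k / k meets the closed-form bound

    G >= (1/beta) log(omega / (1 - omega)) + N (T + P - R - S)/2 + (R - P).

For the individual-based family (per-cooperator reward theta paid while the
cooperator count is at most t) G = t * theta, which inverts into minimal
per-individual investments and minimal thresholds.  The cost-optimal
threshold t* is found by exhaustive scan of t = 1..N-1, trading the
cooperation guarantee against the expected interference cost EC(t).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation import cooperation_frequency
from .game import EvolutionParams, InterferenceScheme, PDGame
from .markov import build_transient_matrix, expected_cost

__all__ = [
    "g_bound",
    "min_theta",
    "min_t",
    "MinThresholdResult",
    "OptimizationResult",
    "optimal_threshold",
    "sweep",
]

# slack so analytically exact integer boundaries (e.g. a bound of exactly
# 101) remain admissible despite floating-point round-off
_BOUNDARY_TOL = 1e-9


def _validate_omega(omega: float) -> float:
    omega = float(omega)
    if not (0.0 < omega < 1.0):
        raise ValueError(
            f"target cooperation fraction omega must lie in the open interval (0, 1), got {omega}"
        )
    return omega


def g_bound(omega: float, game: PDGame, params: EvolutionParams) -> float:
    """Smallest investment statistic G guaranteeing cooperation frequency >= omega.

    Requires beta > 0: under neutral selection every scheme yields exactly
    50% cooperation and no finite G can change it.
    """
    omega = _validate_omega(omega)
    if params.beta == 0:
        raise ValueError(
            "g_bound is undefined at beta = 0: neutral selection gives 50% "
            "cooperation regardless of the scheme (invest nothing)"
        )
    base = params.N * (game.T + game.P - game.R - game.S) / 2.0 + (game.R - game.P)
    return math.log(omega / (1.0 - omega)) / params.beta + base


def min_theta(t: int, omega: float, game: PDGame, params: EvolutionParams) -> float:
    """Minimal per-individual investment achieving omega at threshold t.

    Returns 0 when the bound is non-positive (any theta >= 0 suffices).
    """
    if not (1 <= t <= params.N - 1):
        raise ValueError(f"threshold t must be in 1..{params.N - 1}, got {t}")
    bound = g_bound(omega, game, params)
    return max(bound / t, 0.0)


@dataclass(frozen=True)
class MinThresholdResult:
    """Smallest threshold satisfying the sufficient condition.

    ``t_required`` is the smallest integer t with t * theta >= G-bound; it is
    reported even when it exceeds N - 1, in which case ``feasible`` is False
    (no admissible threshold achieves omega at this theta).
    """

    t_required: int
    feasible: bool
    N: int


def min_t(theta: float, omega: float, game: PDGame, params: EvolutionParams) -> MinThresholdResult:
    """Smallest integer threshold t guaranteeing cooperation frequency >= omega
    at per-individual investment theta."""
    if theta <= 0:
        raise ValueError(f"per-individual investment theta must be > 0, got {theta}")
    bound = g_bound(omega, game, params)
    t_req = max(1, math.ceil(bound / theta - _BOUNDARY_TOL))
    return MinThresholdResult(t_required=t_req, feasible=t_req <= params.N - 1, N=params.N)


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the exhaustive threshold scan.

    ``t_star`` is the cost-minimal feasible threshold (smallest such t on
    ties), or None when no threshold reaches omega.  ``better_than_full_set``
    lists feasible thresholds strictly cheaper than FULL-INVEST (t = N-1).
    ``neutral_selection`` marks the beta = 0 degenerate answer, where every
    scheme yields 50% cooperation and the optimum is to invest nothing.
    """

    t_star: int | None
    ec_at_t_star: float | None
    feasible_set: tuple[int, ...]
    better_than_full_set: tuple[int, ...]
    frequencies: np.ndarray
    costs: np.ndarray
    neutral_selection: bool = False

    @property
    def feasible(self) -> bool:
        # Under neutral selection the cheapest feasible action is to invest
        # nothing, which has no threshold: t_star is None yet feasible.
        if self.neutral_selection:
            return self.ec_at_t_star is not None
        return self.t_star is not None


def _scan_thresholds(
    theta: float, game: PDGame, params: EvolutionParams
) -> tuple[np.ndarray, np.ndarray]:
    """coop frequency and EC for every individual-based scheme (theta, t)."""
    n_t = params.N - 1
    freqs = np.empty(n_t)
    costs = np.empty(n_t)
    for t in range(1, n_t + 1):
        scheme = InterferenceScheme.individual_based(params.N, theta, t)
        freqs[t - 1] = cooperation_frequency(game, params, scheme).coop_frequency
        costs[t - 1] = expected_cost(build_transient_matrix(game, params, scheme), scheme).expected_cost
    return freqs, costs


def optimal_threshold(
    theta: float, omega: float, game: PDGame, params: EvolutionParams
) -> OptimizationResult:
    """Cost-optimal threshold t* for the individual-based scheme.

    Scans every t in 1..N-1, computing the stationary cooperation frequency
    and the expected cost; t* minimises EC over the feasible set
    {t : frequency >= omega}, ties broken toward the smallest t.  An empty
    feasible set yields an explicit infeasible result, not an exception.
    """
    omega = _validate_omega(omega)
    if theta <= 0:
        raise ValueError(f"per-individual investment theta must be > 0, got {theta}")
    if params.beta == 0:
        # Neutral drift: frequency is 0.5 for every scheme; if that meets
        # omega the cheapest action is to invest nothing at all.
        if omega <= 0.5:
            return OptimizationResult(
                t_star=None,
                ec_at_t_star=0.0,
                feasible_set=tuple(range(1, params.N)),
                better_than_full_set=(),
                frequencies=np.full(params.N - 1, 0.5),
                costs=np.full(params.N - 1, np.nan),
                neutral_selection=True,
            )
        return OptimizationResult(
            t_star=None,
            ec_at_t_star=None,
            feasible_set=(),
            better_than_full_set=(),
            frequencies=np.full(params.N - 1, 0.5),
            costs=np.full(params.N - 1, np.nan),
            neutral_selection=True,
        )
    freqs, costs = _scan_thresholds(theta, game, params)
    feasible = np.flatnonzero(freqs >= omega - _BOUNDARY_TOL) + 1
    if feasible.size == 0:
        return OptimizationResult(
            t_star=None,
            ec_at_t_star=None,
            feasible_set=(),
            better_than_full_set=(),
            frequencies=freqs,
            costs=costs,
        )
    feas_costs = costs[feasible - 1]
    t_star = int(feasible[np.argmin(feas_costs)])  # argmin takes first minimum: smallest t
    ec_full = costs[-1]
    better = feasible[feas_costs < ec_full]
    return OptimizationResult(
        t_star=t_star,
        ec_at_t_star=float(costs[t_star - 1]),
        feasible_set=tuple(int(t) for t in feasible),
        better_than_full_set=tuple(int(t) for t in better),
        frequencies=freqs,
        costs=costs,
    )


def sweep(
    game: PDGame,
    N: int,
    betas,
    thetas,
    ts,
    omegas=(None,),
) -> pd.DataFrame:
    """Evaluate frequency, cost and feasibility over a parameter grid.

    One row per (beta, theta, t, omega) combination, in deterministic
    lexicographic order.  ``omega = None`` rows skip the feasibility column.
    """
    records = []
    for beta, theta in itertools.product(betas, thetas):
        params = EvolutionParams(N=N, beta=float(beta))
        for t in ts:
            scheme = InterferenceScheme.individual_based(N, float(theta), int(t))
            outcome = cooperation_frequency(game, params, scheme)
            report = expected_cost(build_transient_matrix(game, params, scheme), scheme)
            for omega in omegas:
                rec = {
                    "beta": float(beta),
                    "theta": float(theta),
                    "t": int(t),
                    "coop_frequency": outcome.coop_frequency,
                    "G": outcome.G,
                    "expected_cost": report.expected_cost,
                    "expected_interference_events": report.expected_interference_events,
                }
                if omega is not None:
                    rec["omega"] = float(omega)
                    rec["feasible"] = bool(outcome.coop_frequency >= float(omega) - _BOUNDARY_TOL)
                records.append(rec)
    columns = [
        "beta",
        "theta",
        "t",
        "coop_frequency",
        "G",
        "expected_cost",
        "expected_interference_events",
    ]
    if any(o is not None for o in omegas):
        columns += ["omega", "feasible"]
    return pd.DataFrame.from_records(records, columns=columns)
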