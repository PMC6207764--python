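"""Payoff structure, interference schemes and the birth-death kernel.

The population holds ``N`` players, each a cooperator (C) or defector (D)
in a one-shot Prisoner's Dilemma.  An external decision-maker may inject a
state-conditioned total reward ``theta_i`` whenever the population holds
``i`` cooperators; each cooperator's average payoff is then raised by
``theta_i / i``.  Strategy revision follows the pairwise-comparison (Fermi)
rule with selection intensity ``beta``, which turns the cooperator count
into a tridiagonal birth-death chain with one-step probabilities
``T^+(k)`` and ``T^-(k)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PDGame",
    "EvolutionParams",
    "InterferenceScheme",
    "average_payoffs",
    "fermi_probability",
    "payoff_delta",
    "delta_vector",
    "transition_probabilities",
    "transition_vectors",
]


@dataclass(frozen=True)
class PDGame:
    """2x2 symmetric game with Prisoner's Dilemma preference ordering.

    Parameters
    ----------
    R : float
        Reward for mutual cooperation.
    T : float
        Temptation to defect against a cooperator.
    S : float
        Sucker payoff for cooperating against a defector.
    P : float
        Punishment for mutual defection.
    unchecked : bool
        If True, skip the ``T > R > P > S`` ordering validation so that
        degenerate or non-dilemma matrices can be constructed explicitly.
    """

    R: float
    T: float
    S: float
    P: float
    unchecked: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("R", "T", "S", "P"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"payoff {name} must be finite, got {v!r}")
        if not self.unchecked and not (self.T > self.R > self.P > self.S):
            raise ValueError(
                "Prisoner's Dilemma ordering T > R > P > S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}; "
                "pass unchecked=True to construct anyway"
            )

    @classmethod
    def standard(cls) -> "PDGame":
        """The (R, T, S, P) = (1, 2, -1, 0) parameterisation used throughout."""
        return cls(R=1.0, T=2.0, S=-1.0, P=0.0)


@dataclass(frozen=True)
class EvolutionParams:
    """Population size and selection intensity of the imitation dynamics.

    ``beta = 0`` is neutral drift; larger ``beta`` makes imitation of the
    fitter strategy increasingly deterministic.
    """

    N: int
    beta: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"population size N must be an integer >= 2, got {self.N!r}")
        object.__setattr__(self, "N", int(self.N))
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"selection intensity beta must be finite and >= 0, got {self.beta!r}")


@dataclass(frozen=True)
class InterferenceScheme:
    """Per-state total investment vector Theta = (theta_1, ..., theta_{N-1}).

    ``theta[i - 1]`` is the total reward paid out when the population holds
    ``i`` cooperators (states are labelled by cooperator count; the two
    homogeneous states 0 and N receive no investment).  Use
    :meth:`theta_at` for 1-based access matching the state labels.

    Families
    --------
    ``general``
        Arbitrary non-negative vector.
    ``individual_based``
        Fixed per-cooperator reward ``theta`` paid while the cooperator
        count is at most a threshold ``t``: theta_k = k * theta for k <= t,
        0 above.
    ``full_invest``
        The individual-based scheme with t = N - 1, i.e. the standard
        institutional-reward baseline that always pays cooperators.
    """

    theta: np.ndarray
    family: str = "general"
    per_capita: float | None = None
    t: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.theta, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("theta must be a 1-D vector of length N-1 >= 1")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("all per-state investments theta_i must be finite and >= 0")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "theta", arr)
        if self.family not in ("general", "individual_based", "full_invest"):
            raise ValueError(f"unknown scheme family {self.family!r}")
        if self.family in ("individual_based", "full_invest"):
            if self.per_capita is None or self.t is None:
                raise ValueError("individual-based schemes need per_capita and t")
            k = np.arange(1, self.N)
            expected = np.where(k <= self.t, k * self.per_capita, 0.0)
            if not np.allclose(arr, expected, rtol=1e-12, atol=1e-12):
                raise ValueError("theta vector inconsistent with individual-based (theta, t)")

    # -- constructors -------------------------------------------------

    @classmethod
    def general(cls, theta: np.ndarray) -> "InterferenceScheme":
        return cls(theta=np.asarray(theta, dtype=float))

    @classmethod
    def individual_based(cls, N: int, theta: float, t: int) -> "InterferenceScheme":
        """Each cooperator receives ``theta`` while the count is <= ``t``."""
        if theta < 0:
            raise ValueError("per-individual investment theta must be >= 0")
        if not (1 <= t <= N - 1):
            raise ValueError(f"threshold t must be in 1..N-1, got {t}")
        k = np.arange(1, N)
        vec = np.where(k <= t, k * float(theta), 0.0)
        family = "full_invest" if t == N - 1 else "individual_based"
        return cls(theta=vec, family=family, per_capita=float(theta), t=int(t))

    @classmethod
    def full_invest(cls, N: int, theta: float) -> "InterferenceScheme":
        return cls.individual_based(N, theta, N - 1)

    @classmethod
    def zero(cls, N: int) -> "InterferenceScheme":
        return cls(theta=np.zeros(N - 1))

    # -- accessors ----------------------------------------------------

    @property
    def N(self) -> int:
        return self.theta.size + 1

    def theta_at(self, k: int) -> float:
        """Total investment theta_k at the state with ``k`` cooperators (1-based)."""
        if not (1 <= k <= self.N - 1):
            raise IndexError(f"state index k must be in 1..{self.N - 1}, got {k}")
        return float(self.theta[k - 1])

    def per_capita_bonus(self) -> np.ndarray:
        """theta_k / k for k = 1..N-1: the bonus each cooperator receives."""
        return self.theta / np.arange(1, self.N)

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "N": self.N,
                "family": self.family,
                "theta_per_capita": self.per_capita,
                "t": self.t,
                "theta_vector": self.theta.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "InterferenceScheme":
        obj = json.loads(text)
        return cls(
            theta=np.asarray(obj["theta_vector"], dtype=float),
            family=obj.get("family", "general"),
            per_capita=obj.get("theta_per_capita"),
            t=obj.get("t"),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "InterferenceScheme":
        """Load a general scheme from a 2-column CSV of (state index i, theta_i)."""
        rows: dict[int, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip() or row[0].strip().lstrip("-").startswith(("i", "s")):
                    continue  # header / blank lines
                rows[int(row[0])] = float(row[1])
        if not rows:
            raise ValueError(f"no scheme rows found in {path}")
        n_states = max(rows)
        if set(rows) != set(range(1, n_states + 1)):
            raise ValueError("CSV must list every state index 1..N-1 exactly once")
        return cls.general(np.array([rows[i] for i in range(1, n_states + 1)]))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["state", "theta"])
            for i, th in enumerate(self.theta, start=1):
                writer.writerow([i, th])


def average_payoffs(k: int, game: PDGame, params: EvolutionParams) -> tuple[float, float]:
    """Mean game payoff of a cooperator and of a defector at cooperator count ``k``.

    Every player meets each of the other N-1 players once (no
    self-interaction), so

        Pi_C(k) = ((k-1) R + (N-k) S) / (N-1)
        Pi_D(k) = (k T + (N-k-1) P) / (N-1)

    Interference is *not* included here; the per-cooperator bonus
    theta_k / k is added downstream where the payoff difference enters the
    Fermi rule.

    Raises
    ------
    ValueError
        If ``k`` is not in 1..N-1 (homogeneous states have no mixed payoff).
    """
    N = params.N
    if not (1 <= k <= N - 1):
        raise ValueError(f"cooperator count k must be in 1..{N - 1}, got {k}")
    pi_c = ((k - 1) * game.R + (N - k) * game.S) / (N - 1)
    pi_d = (k * game.T + (N - k - 1) * game.P) / (N - 1)
    return pi_c, pi_d


def fermi_probability(f_A: float, f_B: float, beta: float) -> float:
    """Probability that player A (fitness f_A) imitates player B (fitness f_B).

    The pairwise-comparison rule: 1 / (1 + exp(-beta (f_B - f_A))),
    evaluated through a numerically stable sigmoid so large fitness gaps
    saturate to 0 or 1 without overflow.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return _sigmoid(beta * (np.asarray(f_B, dtype=float) - np.asarray(f_A, dtype=float)))


def _sigmoid(x):
    """Overflow-safe logistic function, vectorised."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def payoff_delta(k: int, game: PDGame, params: EvolutionParams, scheme: InterferenceScheme) -> float:
    """Effective payoff advantage of cooperators at state k:
    Delta_k = Pi_C(k) + theta_k / k - Pi_D(k)."""
    pi_c, pi_d = average_payoffs(k, game, params)
    return pi_c + scheme.theta_at(k) / k - pi_d


def delta_vector(game: PDGame, params: EvolutionParams, scheme: InterferenceScheme) -> np.ndarray:
    """Delta_k for every transient state k = 1..N-1, vectorised."""
    N = params.N
    if scheme.N != N:
        raise ValueError(f"scheme built for N={scheme.N} but params.N={N}")
    k = np.arange(1, N)
    pi_c = ((k - 1) * game.R + (N - k) * game.S) / (N - 1)
    pi_d = (k * game.T + (N - k - 1) * game.P) / (N - 1)
    return pi_c + scheme.per_capita_bonus() - pi_d


def transition_probabilities(
    k: int, game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> tuple[float, float]:
    """One-step probabilities T^+(k), T^-(k) of the cooperator count moving
    up or down by one.

        T^{+/-}(k) = ((N-k)/N) (k/N) [1 + exp(-/+ beta Delta_k)]^{-1}

    Both lie in [0, 1/4] and satisfy T^+(k)/T^-(k) = exp(beta Delta_k).
    """
    N = params.N
    if not (1 <= k <= N - 1):
        raise ValueError(f"cooperator count k must be in 1..{N - 1}, got {k}")
    delta = payoff_delta(k, game, params, scheme)
    pair_prob = (N - k) / N * (k / N)
    t_plus = pair_prob * _sigmoid(params.beta * delta)
    t_minus = pair_prob * _sigmoid(-params.beta * delta)
    return float(t_plus), float(t_minus)


def transition_vectors(
    game: PDGame, params: EvolutionParams, scheme: InterferenceScheme
) -> tuple[np.ndarray, np.ndarray]:
    """T^+(k) and T^-(k) for all k = 1..N-1 as arrays of length N-1."""
    N = params.N
    delta = delta_vector(game, params, scheme)
    k = np.arange(1, N)
    pair_prob = (N - k) / N * (k / N)
    return pair_prob * _sigmoid(params.beta * delta), pair_prob * _sigmoid(-params.beta * delta)
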