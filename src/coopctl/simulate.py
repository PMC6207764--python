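"""Monte-Carlo simulator of the imitation dynamics with interference.

An independent stochastic check on the analytic machinery: it simulates the
pairwise-comparison process directly and estimates fixation probabilities,
per-state visit counts, interference costs and the stationary cooperation
fraction, each with a Monte-Carlo standard error.

Conventions
-----------
One time step is one strategy-revision event: a focal individual and a model
individual are drawn uniformly at random (independently, so the pair may
coincide — a no-op), and the focal adopts the model's strategy with the
Fermi probability evaluated on average payoffs including the per-cooperator
interference bonus.  At cooperator count k this yields exactly the analytic
kernel T^{+/-}(k) = ((N-k)/N)(k/N) sigma(+/- beta Delta_k), with no
rescaling.  The cost theta_i is charged for every time step spent at state
S_i, self-loop steps included, mirroring the fundamental-matrix visit
semantics.

Episodes and long stationary runs are executed on the embedded jump chain
with geometrically distributed dwell times, which is distributionally
identical to stepping one revision event at a time but runs orders of
magnitude faster.  The agent-level event is exposed separately
(:func:`empirical_kernel`) so the kernel itself can be validated against
T^{+/-}(k) by direct sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import EvolutionParams, InterferenceScheme, PDGame, average_payoffs, fermi_probability, transition_vectors

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "run_episode",
    "run_stationary",
    "empirical_kernel",
]

_EPISODE_N_SOFT_CAP = 50


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a Monte-Carlo run.

    ``mode='episode'`` places a single mutant at S_1 or S_{N-1} (probability
    1/2 each) and runs to absorption, repeated ``episodes`` times.
    ``mode='stationary'`` runs one long trajectory of ``generations``
    revision events with mutation probability ``mu`` per event, emulating
    the small-mutation limit (mu <= 1/N^2 recommended).
    """

    game: PDGame
    params: EvolutionParams
    scheme: InterferenceScheme
    mode: str = "episode"
    mu: float = 1e-3
    episodes: int = 10_000
    generations: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("episode", "stationary"):
            raise ValueError(f"mode must be 'episode' or 'stationary', got {self.mode!r}")
        if self.scheme.N != self.params.N:
            raise ValueError("scheme population size does not match params.N")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.mode == "episode":
            if self.episodes < 1:
                raise ValueError("episodes must be >= 1")
            if self.params.N > _EPISODE_N_SOFT_CAP:
                raise ValueError(
                    f"episode mode is intended for small populations (N <= {_EPISODE_N_SOFT_CAP}); "
                    "use the analytic chain for larger N"
                )
        else:
            if not (0 < self.mu < 1):
                raise ValueError("stationary mode needs mutation probability 0 < mu < 1 "
                                 "(mu = 0 would absorb)")
            if self.generations < 1:
                raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class SimulationSummary:
    """Point estimates with standard errors; fields unused by a mode are None."""

    mode: str
    seed: int
    n_samples: int
    est_rho_DC: float | None = None
    se_rho_DC: float | None = None
    est_rho_CD: float | None = None
    se_rho_CD: float | None = None
    est_visits: np.ndarray | None = None
    se_visits: np.ndarray | None = None
    est_total_cost: float | None = None
    se_total_cost: float | None = None
    est_coop_frequency: float | None = None
    se_coop_frequency: float | None = None
    time_fractions: dict | None = field(default=None)


def run_episode(config: SimulationConfig) -> SimulationSummary:
    """Single-mutant absorption episodes, aggregated.

    Each episode starts at S_1 or S_{N-1} with probability 1/2, accumulates
    per-state dwell counts and interference payouts, and ends at fixation of
    either strategy.  All episodes are advanced in parallel on the jump
    chain.
    """
    if config.mode != "episode":
        raise ValueError("run_episode requires mode='episode'")
    rng = np.random.default_rng(config.seed)
    N = config.params.N
    n_ep = config.episodes
    t_plus, t_minus = transition_vectors(config.game, config.params, config.scheme)
    move_prob = t_plus + t_minus
    if np.any(move_prob <= 0):
        raise ValueError("a transient state has zero move probability; episodes cannot terminate")
    up_given_move = t_plus / move_prob
    theta = config.scheme.theta

    start_hi = rng.random(n_ep) < 0.5
    states = np.where(start_hi, N - 1, 1).astype(np.int64)
    started_at_1 = ~start_hi

    visit_mat = np.zeros((n_ep, N - 1))
    costs = np.zeros(n_ep)
    absorbed_at_N = np.zeros(n_ep, dtype=bool)
    active = np.arange(n_ep)

    while active.size:
        s = states[active]
        p_move = move_prob[s - 1]
        dwell = rng.geometric(p_move).astype(float)
        visit_mat[active, s - 1] += dwell
        costs[active] += dwell * theta[s - 1]
        go_up = rng.random(active.size) < up_given_move[s - 1]
        new_s = s + np.where(go_up, 1, -1)
        states[active] = new_s
        hit_top = new_s == N
        hit_bottom = new_s == 0
        absorbed_at_N[active[hit_top]] = True
        active = active[~(hit_top | hit_bottom)]

    # fixation of the mutant: C-mutant episodes start at S_1 and fix at S_N;
    # D-mutant episodes start at S_{N-1} and fix at S_0.
    n_c = int(started_at_1.sum())
    n_d = n_ep - n_c
    est_rho_dc, se_rho_dc = _binomial_estimate(absorbed_at_N[started_at_1])
    est_rho_cd, se_rho_cd = _binomial_estimate(~absorbed_at_N[~started_at_1])

    return SimulationSummary(
        mode="episode",
        seed=config.seed,
        n_samples=n_ep,
        est_rho_DC=est_rho_dc,
        se_rho_DC=se_rho_dc,
        est_rho_CD=est_rho_cd,
        se_rho_CD=se_rho_cd,
        est_visits=visit_mat.mean(axis=0),
        se_visits=visit_mat.std(axis=0, ddof=1) / np.sqrt(n_ep),
        est_total_cost=float(costs.mean()),
        se_total_cost=float(costs.std(ddof=1) / np.sqrt(n_ep)),
        time_fractions={"episodes_started_all_D": n_c, "episodes_started_all_C": n_d},
    )


def _binomial_estimate(successes: np.ndarray) -> tuple[float, float]:
    n = successes.size
    if n == 0:
        return float("nan"), float("nan")
    p = float(successes.mean())
    return p, float(np.sqrt(max(p * (1 - p), 0.0) / n))


def run_stationary(config: SimulationConfig) -> SimulationSummary:
    """Long-run trajectory with explicit rare mutation.

    With probability ``mu`` a revision event mutates: the focal individual
    adopts a uniformly random strategy instead of imitating.  The reported
    cooperation frequency is the fraction of time spent in the all-C state
    among the time spent in the two homogeneous states, which converges to
    the small-mutation-limit value rho_DC / (rho_DC + rho_CD) as mu -> 0.
    Standard errors come from batch means over contiguous blocks of the
    trajectory.
    """
    if config.mode != "stationary":
        raise ValueError("run_stationary requires mode='stationary'")
    rng = np.random.default_rng(config.seed)
    N = config.params.N
    mu = config.mu
    total_steps = config.generations

    # combined per-event up/down probabilities over the full state space
    # 0..N: imitation (only in the interior) plus mutation.
    k = np.arange(0, N + 1)
    t_plus_full = np.zeros(N + 1)
    t_minus_full = np.zeros(N + 1)
    tp, tm = transition_vectors(config.game, config.params, config.scheme)
    t_plus_full[1:N] = tp
    t_minus_full[1:N] = tm
    p_up = (1 - mu) * t_plus_full + mu * ((N - k) / N) * 0.5
    p_down = (1 - mu) * t_minus_full + mu * (k / N) * 0.5
    move = p_up + p_down
    up_given_move = np.divide(p_up, move, out=np.zeros_like(p_up), where=move > 0)

    time_in_state = np.zeros(N + 1)
    n_batches = 32
    batch_len = total_steps / n_batches
    batch_C = np.zeros(n_batches)
    batch_D = np.zeros(n_batches)

    state = 0  # start all-D; the trajectory is long enough to forget this
    elapsed = 0
    # jump-chain loop: geometric dwell at `state`, then move up/down
    while elapsed < total_steps:
        p = move[state]
        dwell = int(rng.geometric(p))
        dwell = min(dwell, total_steps - elapsed)
        time_in_state[state] += dwell
        _accumulate_batches(batch_C, batch_D, state, N, elapsed, dwell, batch_len)
        elapsed += dwell
        if elapsed >= total_steps:
            break
        state += 1 if rng.random() < up_given_move[state] else -1

    homog = time_in_state[0] + time_in_state[N]
    est = float(time_in_state[N] / homog) if homog > 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        batch_tot = batch_C + batch_D
        batch_frac = np.where(batch_tot > 0, batch_C / np.maximum(batch_tot, 1), np.nan)
    good = ~np.isnan(batch_frac)
    if good.sum() >= 2:
        se = float(np.nanstd(batch_frac, ddof=1) / np.sqrt(good.sum()))
    else:
        se = float("nan")
    return SimulationSummary(
        mode="stationary",
        seed=config.seed,
        n_samples=total_steps,
        est_coop_frequency=est,
        se_coop_frequency=se,
        time_fractions={
            "all_D": float(time_in_state[0] / total_steps),
            "all_C": float(time_in_state[N] / total_steps),
            "interior": float(time_in_state[1:N].sum() / total_steps),
        },
    )


def _accumulate_batches(batch_C, batch_D, state, N, start, dwell, batch_len):
    """Spread a homogeneous-state dwell interval over contiguous batches."""
    if state != 0 and state != N:
        return
    target = batch_C if state == N else batch_D
    n_batches = target.size
    lo = start
    hi = start + dwell
    b = min(int(lo / batch_len), n_batches - 1)
    while lo < hi:
        edge = min((b + 1) * batch_len, hi)
        target[b] += edge - lo
        lo = edge
        b = min(b + 1, n_batches - 1)


def empirical_kernel(
    k: int,
    game: PDGame,
    params: EvolutionParams,
    scheme: InterferenceScheme,
    n_events: int,
    seed: int,
) -> tuple[float, float]:
    """Empirical one-step up/down frequencies from state k, by direct
    agent-level sampling of revision events.

    Draws a focal and a model individual uniformly and independently from
    the population (a coincident or same-strategy pair changes nothing) and
    applies the Fermi adoption probability on the average payoffs with the
    interference bonus.  Returns (freq_up, freq_down) over ``n_events``
    events, for comparison with the analytic T^{+/-}(k).
    """
    N = params.N
    if not (1 <= k <= N - 1):
        raise ValueError(f"k must be in 1..{N - 1}, got {k}")
    rng = np.random.default_rng(seed)
    pi_c, pi_d = average_payoffs(k, game, params)
    pi_c += scheme.theta_at(k) / k
    p_adopt_c = fermi_probability(pi_d, pi_c, params.beta)  # focal D meets model C
    p_adopt_d = fermi_probability(pi_c, pi_d, params.beta)  # focal C meets model D

    # population as a strategy array: first k cooperators, rest defectors
    strategies = np.zeros(N, dtype=bool)
    strategies[:k] = True
    focal = rng.integers(0, N, size=n_events)
    model = rng.integers(0, N, size=n_events)
    u = rng.random(n_events)
    f_coop = strategies[focal]
    m_coop = strategies[model]
    ups = (~f_coop) & m_coop & (u < p_adopt_c)
    downs = f_coop & (~m_coop) & (u < p_adopt_d)
    return float(ups.mean()), float(downs.mean())
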