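"""Reproducible parameter-sweep experiments and their tabular outputs.

Three canonical studies (all analytic, hence deterministic and bit-stable
across re-runs):

``threshold_sweep``
    Cooperation level, expected number of paying time steps, and expected
    total cost as functions of the investment threshold t, for several
    per-individual amounts theta.
``optimal_threshold_grid``
    The cost-optimal threshold t* across a theta grid, for several
    selection intensities beta and target cooperation levels omega.
``cost_efficiency_range``
    For each (beta, omega, theta), the set of thresholds t that reach omega
    at strictly lower expected cost than FULL-INVEST (t = N - 1).

Each experiment writes a CSV (fixed column order) plus a JSON manifest of
parameters and package version.  Plotting is optional and applies any log
scaling at plot time only; stored values are never transformed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditions import _scan_thresholds
from .game import EvolutionParams, PDGame

__all__ = [
    "ExperimentSpec",
    "threshold_sweep",
    "optimal_threshold_grid",
    "cost_efficiency_range",
]

_DEFAULT_THETA_GRID = tuple(np.arange(0.5, 50.0 + 0.25, 0.5))


@dataclass(frozen=True)
class ExperimentSpec:
    """Fully determines one experiment run; re-running overwrites outputs."""

    name: str
    out_dir: Path
    game: PDGame = field(default_factory=PDGame.standard)
    N: int = 100
    csv_only: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))


def _write_outputs(spec: ExperimentSpec, df: pd.DataFrame, parameters: dict) -> Path:
    spec.out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = spec.out_dir / f"{spec.name}.csv"
    df.to_csv(csv_path, index=False)
    manifest = {
        "experiment": spec.name,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "game": {"R": spec.game.R, "T": spec.game.T, "S": spec.game.S, "P": spec.game.P},
        "N": spec.N,
        "parameters": parameters,
        "rows": int(len(df)),
    }
    (spec.out_dir / f"{spec.name}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return csv_path


def threshold_sweep(
    spec: ExperimentSpec,
    beta: float = 0.1,
    thetas=(1.0, 5.0, 40.0),
    plot: bool = False,
) -> pd.DataFrame:
    """Frequency, paying-step count and EC over t = 1..N-1 for each theta."""
    params = EvolutionParams(N=spec.N, beta=beta)
    frames = []
    for theta in thetas:
        freqs, costs = _scan_thresholds(float(theta), spec.game, params)
        # expected paying steps: EC / theta for the individual-based family
        # would miscount (cost is theta per cooperator); recompute directly.
        events = _paying_steps(float(theta), spec.game, params)
        frames.append(
            pd.DataFrame(
                {
                    "theta": float(theta),
                    "t": np.arange(1, spec.N),
                    "coop_frequency": freqs,
                    "expected_interference_events": events,
                    "expected_cost": costs,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    _write_outputs(spec, df, {"beta": beta, "thetas": list(map(float, thetas))})
    if plot and not spec.csv_only:
        _plot_threshold_sweep(spec, df)
    return df


def _paying_steps(theta: float, game: PDGame, params: EvolutionParams) -> np.ndarray:
    from .game import InterferenceScheme
    from .markov import build_transient_matrix, expected_cost

    out = np.empty(params.N - 1)
    for t in range(1, params.N):
        scheme = InterferenceScheme.individual_based(params.N, theta, t)
        report = expected_cost(build_transient_matrix(game, params, scheme), scheme)
        out[t - 1] = report.expected_interference_events
    return out


def optimal_threshold_grid(
    spec: ExperimentSpec,
    betas=(0.001, 0.01, 0.1, 1.0),
    omegas=(0.1, 0.5, 0.7, 0.9),
    thetas=_DEFAULT_THETA_GRID,
    plot: bool = False,
) -> pd.DataFrame:
    """t* and its cost over a (beta, omega, theta) grid.

    Infeasible cells (no threshold reaches omega) are recorded with NA
    entries, never dropped.
    """
    records = []
    for beta in betas:
        params = EvolutionParams(N=spec.N, beta=float(beta))
        for theta in thetas:
            freqs, costs = _scan_thresholds(float(theta), spec.game, params)
            for omega in omegas:
                feasible = np.flatnonzero(freqs >= float(omega) - 1e-9) + 1
                if feasible.size:
                    feas_costs = costs[feasible - 1]
                    t_star = int(feasible[np.argmin(feas_costs)])
                    ec = float(costs[t_star - 1])
                else:
                    t_star, ec = None, None
                records.append(
                    {
                        "beta": float(beta),
                        "omega": float(omega),
                        "theta": float(theta),
                        "t_star": t_star,
                        "ec_at_t_star": ec,
                    }
                )
    df = pd.DataFrame.from_records(
        records, columns=["beta", "omega", "theta", "t_star", "ec_at_t_star"]
    )
    _write_outputs(
        spec,
        df,
        {
            "betas": list(map(float, betas)),
            "omegas": list(map(float, omegas)),
            "thetas": list(map(float, thetas)),
        },
    )
    if plot and not spec.csv_only:
        _plot_grid(spec, df, "t_star")
    return df


def cost_efficiency_range(
    spec: ExperimentSpec,
    betas=(0.01, 0.1),
    omegas=(0.1, 0.5, 0.9),
    thetas=_DEFAULT_THETA_GRID,
    plot: bool = False,
) -> pd.DataFrame:
    """Thresholds beating FULL-INVEST: for each (beta, omega, theta), the
    interval(s) of t with EC(t) < EC(N-1) and frequency >= omega."""
    records = []
    for beta in betas:
        params = EvolutionParams(N=spec.N, beta=float(beta))
        for theta in thetas:
            freqs, costs = _scan_thresholds(float(theta), spec.game, params)
            ec_full = costs[-1]
            for omega in omegas:
                better = np.flatnonzero((freqs >= float(omega) - 1e-9) & (costs < ec_full)) + 1
                records.append(
                    {
                        "beta": float(beta),
                        "omega": float(omega),
                        "theta": float(theta),
                        "n_better": int(better.size),
                        "t_min": int(better.min()) if better.size else None,
                        "t_max": int(better.max()) if better.size else None,
                    }
                )
    df = pd.DataFrame.from_records(
        records, columns=["beta", "omega", "theta", "n_better", "t_min", "t_max"]
    )
    _write_outputs(
        spec,
        df,
        {
            "betas": list(map(float, betas)),
            "omegas": list(map(float, omegas)),
            "thetas": list(map(float, thetas)),
        },
    )
    if plot and not spec.csv_only:
        _plot_grid(spec, df, "n_better")
    return df


def _plot_threshold_sweep(spec: ExperimentSpec, df: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for theta, sub in df.groupby("theta"):
        axes[0].plot(sub["t"], sub["coop_frequency"], label=f"theta={theta:g}")
        axes[1].plot(sub["t"], np.log10(sub["expected_interference_events"]))
        axes[2].plot(sub["t"], np.log10(sub["expected_cost"]))
    axes[0].set_ylabel("cooperation frequency")
    axes[1].set_ylabel("log10 expected paying steps")
    axes[2].set_ylabel("log10 expected cost")
    for ax in axes:
        ax.set_xlabel("threshold t")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(spec.out_dir / f"{spec.name}.png", dpi=150)
    plt.close(fig)


def _plot_grid(spec: ExperimentSpec, df: pd.DataFrame, value: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    betas = sorted(df["beta"].unique())
    fig, axes = plt.subplots(1, len(betas), figsize=(4 * len(betas), 4), squeeze=False)
    for ax, beta in zip(axes[0], betas):
        sub_b = df[df["beta"] == beta]
        for omega, sub in sub_b.groupby("omega"):
            ax.plot(sub["theta"], sub[value], label=f"omega={omega:g}")
        ax.set_xlabel("theta")
        ax.set_ylabel(value)
        ax.set_title(f"beta={beta:g}")
        ax.legend()
    fig.tight_layout()
    fig.savefig(spec.out_dir / f"{spec.name}.png", dpi=150)
    plt.close(fig)
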