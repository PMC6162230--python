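"""Population observables and ensemble summaries.

The observables mirror what the spatial-game literature reports: the mean
effective cooperation eps = (1 - s)(1 - alpha), the mean abstention
probability alpha, the cooperator/defector fractions, and the occupancy of
each discrete alpha level.  Ensemble statistics are computed across
independent runs (runs are independent; lattice sites are not, being
correlated by clustering, so per-site errors would be misleading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game_core import effective_cooperation
from .lattice import LatticeWorld

__all__ = [
    "StateMetrics",
    "EnsembleSummary",
    "AggregationError",
    "measure_state",
    "distinct_alpha_levels",
    "ensemble_average",
    "timeseries_frame",
    "write_timeseries_csv",
    "alpha_level_columns",
]


class AggregationError(ValueError):
    """Raised when runs with incompatible configurations are averaged."""


@dataclass(frozen=True)
class StateMetrics:
    """Exact population summaries of one lattice state at one MC step."""

    step: int
    mean_eps: float
    mean_alpha: float
    frac_coop: float
    frac_defect: float
    alpha_histogram: np.ndarray  # occupancy fraction per alpha level; sums to 1


def measure_state(world: LatticeWorld, step: int = 0) -> StateMetrics:
    """Measure a world without perturbing it (pure; consumes no randomness)."""
    s = world.s.ravel()
    alpha = world.alpha.ravel()
    n = s.size
    hist = np.bincount(world.alpha_idx.ravel(), minlength=world.grid.n_levels) / n
    frac_d = float(s.mean())
    return StateMetrics(
        step=step,
        mean_eps=float(effective_cooperation(s, alpha).mean()),
        mean_alpha=float(alpha.mean()),
        frac_coop=1.0 - frac_d,
        frac_defect=frac_d,
        alpha_histogram=hist,
    )


def distinct_alpha_levels(metrics: StateMetrics, min_fraction: float = 0.01) -> int:
    """Number of alpha levels whose occupancy is at least ``min_fraction``.

    With ``min_fraction = 0`` this counts strictly occupied levels.  The 1%
    default filters single-agent relics when asking how many levels the
    population has "converged to"; it is a reporting choice, exposed as a
    parameter.
    """
    if not 0.0 <= min_fraction < 1.0:
        raise ValueError(f"min_fraction must lie in [0, 1), got {min_fraction}")
    h = metrics.alpha_histogram
    if min_fraction == 0.0:
        return int((h > 0.0).sum())
    return int((h >= min_fraction).sum())


def alpha_level_columns(levels: np.ndarray) -> list[str]:
    """CSV column names for alpha-level occupancies: alpha_0, alpha_0.125, ..."""
    return [f"alpha_{lv:g}" for lv in levels]


def timeseries_frame(result) -> pd.DataFrame:
    """One run's recorded metrics as a tidy DataFrame (one row per record)."""
    levels = result.final_world.grid.levels
    cols = alpha_level_columns(levels)
    rows = []
    for m in result.metrics:
        row = {
            "step": m.step,
            "mean_eps": m.mean_eps,
            "mean_alpha": m.mean_alpha,
            "frac_coop": m.frac_coop,
        }
        row.update(dict(zip(cols, m.alpha_histogram)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_timeseries_csv(result, path) -> None:
    """Write a run's time series with header step, mean_eps, mean_alpha,
    frac_coop, then one column per alpha level."""
    timeseries_frame(result).to_csv(path, index=False)


@dataclass
class EnsembleSummary:
    """Ensemble means and standard errors across independent runs.

    ``series`` holds per-recorded-step cross-run means (columns as in
    :func:`timeseries_frame`, plus ``sem_`` columns for the scalar fields).
    ``stationary`` summarises each run's final snapshot: cross-run mean and
    standard error of every scalar metric and of the alpha histogram.
    """

    n_runs: int
    series: pd.DataFrame
    stationary: dict


_SCALAR_FIELDS = ("mean_eps", "mean_alpha", "frac_coop", "frac_defect")


def _config_key(config):
    from dataclasses import asdict

    d = asdict(config)
    d.pop("seed", None)
    return tuple(sorted(d.items(), key=lambda kv: kv[0]))


def ensemble_average(results) -> EnsembleSummary:
    """Average metrics across runs that share a configuration (except seed).

    Standard errors are across runs (sample standard deviation / sqrt(runs);
    zero for a single run).  The stationary summary uses each run's final
    recorded snapshot, i.e. the state after the last MC step.
    """
    results = list(results)
    if not results:
        raise AggregationError("no runs to average")
    key0 = _config_key(results[0].config)
    for r in results[1:]:
        if _config_key(r.config) != key0:
            raise AggregationError("runs differ in configuration beyond the seed")
    steps0 = [m.step for m in results[0].metrics]
    for r in results[1:]:
        if [m.step for m in r.metrics] != steps0:
            raise AggregationError("runs recorded different step grids")

    k = len(results)
    frames = [timeseries_frame(r) for r in results]
    stacked = pd.concat(frames, keys=range(k), names=["run", "row"])
    mean = stacked.groupby(level="row").mean()
    if k > 1:
        sem = stacked.groupby(level="row").std(ddof=1) / np.sqrt(k)
    else:
        sem = mean * 0.0
    series = mean.copy()
    series["step"] = frames[0]["step"].values
    for f in ("mean_eps", "mean_alpha", "frac_coop"):
        series[f"sem_{f}"] = sem[f].values

    finals = [r.metrics[-1] for r in results]
    stationary = {"n_runs": k, "step": finals[0].step}
    for f in _SCALAR_FIELDS:
        vals = np.array([getattr(m, f) for m in finals])
        stationary[f] = float(vals.mean())
        stationary[f"sem_{f}"] = float(vals.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    hists = np.stack([m.alpha_histogram for m in finals])
    stationary["alpha_histogram"] = hists.mean(axis=0)
    stationary["sem_alpha_histogram"] = (
        hists.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(hists.shape[1])
    )
    return EnsembleSummary(n_runs=k, series=series, stationary=stationary)
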