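"""Scenario experiments: climate sweeps and development programs.

Two families of experiments:

* a grid sweep over the trend and amplitude of SST anomalies, recording
  the mean price gap (fishers' price / market price) and mean fishers'
  income of the social-ecological model — the climate-change experiment;
* two fishery development programs with investments starting in a given
  year (default 2005): *demand development* multiplies the demand scale of
  the market from the start year onward, and *cooperation limitation* caps
  trader cooperation from the start year onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelKind, ModelState, Trajectory, simulate
from .errors import ConfigurationError, UndefinedStatisticError
from .forcing import ForcingSeries, SSTModel
from .params import ParameterSet

__all__ = [
    "ScenarioSpec",
    "GridSweepResult",
    "ProgramComparison",
    "apply_scenario",
    "simulate_scenario",
    "run_program_comparison",
    "price_gap",
    "convergence_year",
    "climate_grid_sweep",
]

PROGRAMS = ("baseline", "demand", "cooperation_limit")


@dataclass(frozen=True)
class ScenarioSpec:
    """One development program.

    ``demand``: from ``start_year`` the demand multiplier is scaled by
    ``demand_factor`` (> 1).  ``cooperation_limit``: from ``start_year``
    trader cooperation is capped at ``coop_cap_value`` (< 1).  ``baseline``
    leaves parameters untouched.
    """

    program: str = "baseline"
    start_year: int = 2005
    demand_factor: float = 1.5
    coop_cap_value: float = 0.2

    def __post_init__(self) -> None:
        if self.program not in PROGRAMS:
            raise ConfigurationError(
                f"program must be one of {PROGRAMS}, got {self.program!r}"
            )
        if self.program == "demand" and self.demand_factor <= 1:
            raise ConfigurationError("demand_factor must be > 1")
        if self.program == "cooperation_limit" and not (
            0 <= self.coop_cap_value < 1
        ):
            raise ConfigurationError("coop_cap_value must lie in [0, 1)")


def apply_scenario(
    params: ParameterSet, spec: ScenarioSpec, year: int
) -> ParameterSet:
    """The effective parameter set in ``year`` under the program.

    Identity before ``start_year`` and for the baseline program.
    """
    if spec.program == "baseline" or year < spec.start_year:
        return params
    if spec.program == "demand":
        return params.replace(
            demand_mult=params.demand_mult * spec.demand_factor
        )
    return params.replace(coop_cap=spec.coop_cap_value)


def simulate_scenario(
    model_kind: ModelKind,
    params: ParameterSet,
    spec: ScenarioSpec,
    forcing: ForcingSeries,
    init: ModelState | None = None,
    years: Sequence[int] | None = None,
    **kwargs,
) -> Trajectory:
    """Simulate one model under a program (year-dependent parameters)."""
    yrs = np.asarray(forcing.years if years is None else years, int)
    if spec.program != "baseline" and spec.start_year > int(yrs[-1]):
        raise ConfigurationError(
            f"program start year {spec.start_year} lies beyond the "
            f"simulation horizon ending {int(yrs[-1])}"
        )
    return simulate(
        model_kind,
        params,
        forcing,
        init,
        years=years,
        params_for_year=lambda y: apply_scenario(params, spec, y),
        **kwargs,
    )


@dataclass(frozen=True)
class ProgramComparison:
    """Baseline vs. program incomes for one model."""

    model_kind: str
    spec: ScenarioSpec
    baseline: Trajectory
    program: Trajectory

    def income_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.baseline.years,
                "fishers_baseline": self.baseline.column("income_fishers"),
                "fishers_program": self.program.column("income_fishers"),
                "traders_baseline": self.baseline.column("income_traders"),
                "traders_program": self.program.column("income_traders"),
            }
        )

    def post_start_means(self) -> dict[str, float]:
        """Mean annual incomes (MXN/yr) over the years from the program
        start onward, plus the program-minus-baseline differences."""
        df = self.income_frame()
        post = df[df["year"] >= self.spec.start_year]
        out = {k: float(post[k].mean()) for k in df.columns if k != "year"}
        out["fishers_gain"] = out["fishers_program"] - out["fishers_baseline"]
        out["traders_gain"] = out["traders_program"] - out["traders_baseline"]
        return out


def run_program_comparison(
    model_kinds: Iterable[ModelKind],
    spec: ScenarioSpec,
    params: ParameterSet,
    forcing: ForcingSeries,
    init: ModelState | None = None,
    **kwargs,
) -> dict[str, ProgramComparison]:
    """Run baseline and program for each model over the forcing horizon."""
    if spec.start_year > int(forcing.years[-1]):
        raise ConfigurationError(
            "forcing horizon ends before the program start year"
        )
    out: dict[str, ProgramComparison] = {}
    for kind in model_kinds:
        base = simulate(kind, params, forcing, init, **kwargs)
        prog = simulate_scenario(kind, params, spec, forcing, init, **kwargs)
        out[kind] = ProgramComparison(
            model_kind=kind, spec=spec, baseline=base, program=prog
        )
    return out


def _valid_gap_years(traj: Trajectory, min_catch: float) -> np.ndarray:
    catch = traj.catch
    mkt = traj.market_price
    return (catch > min_catch) & (mkt > 0)


def price_gap(traj: Trajectory, min_catch: float = 1.0) -> float:
    """Mean over years of fishers' price / market (traders') price.

    Values near 1 mean fishers and traders receive converging prices;
    small values mean severe price inequality.  Years with catch at or
    below ``min_catch`` (the isoelastic evaluation floor) are excluded —
    prices are not meaningful there.
    """
    ok = _valid_gap_years(traj, min_catch)
    if not np.any(ok):
        raise UndefinedStatisticError(
            "price gap undefined: no year with positive market price and "
            f"catch above {min_catch}"
        )
    ratio = traj.fisher_price[ok] / traj.market_price[ok]
    return float(ratio.mean())


def convergence_year(
    traj: Trajectory, threshold: float = 0.9, min_catch: float = 1.0
) -> int | None:
    """First year in which the annual price ratio exceeds ``threshold``
    (None if it never does)."""
    ok = _valid_gap_years(traj, min_catch)
    ratio = np.where(ok, traj.fisher_price / np.maximum(traj.market_price, 1e-300), -np.inf)
    hits = np.flatnonzero(ratio > threshold)
    return int(traj.years[hits[0]]) if hits.size else None


@dataclass(frozen=True)
class GridSweepResult:
    """Mean price gap and fishers' income over a trend x amplitude grid."""

    trend_values: np.ndarray       # degC/yr
    amplitude_values: np.ndarray   # degC
    mean_price_gap: np.ndarray     # [i_trend, j_amplitude]
    mean_fisher_income: np.ndarray
    convergence_years: np.ndarray  # year of first ratio > threshold; NaN if never

    def __post_init__(self) -> None:
        shape = (len(self.trend_values), len(self.amplitude_values))
        for name in ("mean_price_gap", "mean_fisher_income", "convergence_years"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ConfigurationError(f"{name} shape must be {shape}")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (trend, amplitude) cell."""
        rows = []
        for i, tr in enumerate(self.trend_values):
            for j, am in enumerate(self.amplitude_values):
                rows.append(
                    {
                        "trend": tr,
                        "amplitude": am,
                        "mean_price_gap": self.mean_price_gap[i, j],
                        "mean_fisher_income": self.mean_fisher_income[i, j],
                        "convergence_year": self.convergence_years[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def climate_grid_sweep(
    trend_grid: Sequence[float],
    amplitude_grid: Sequence[float],
    params: ParameterSet,
    years: Sequence[int],
    init: ModelState | None = None,
    *,
    sst_base: SSTModel | None = None,
    threshold: float = 0.9,
    model_kind: ModelKind = "SEM",
) -> GridSweepResult:
    """Simulate the SEM across a climate grid.

    For every (trend, amplitude) pair an SST series is generated (other
    SST-model fields taken from ``sst_base``; noise-free), mantle length
    and Pacific proportion are derived, and the model is simulated.  Each
    cell records the mean price gap, mean fishers' income, and the first
    price-convergence year (ratio > ``threshold``).  A cell whose
    simulation fails carries NaN.
    """
    trend_grid = np.asarray(trend_grid, float)
    amplitude_grid = np.asarray(amplitude_grid, float)
    if trend_grid.size == 0 or amplitude_grid.size == 0:
        raise ConfigurationError("trend and amplitude grids must be non-empty")
    if sst_base is None:
        sst_base = SSTModel()
    shape = (trend_grid.size, amplitude_grid.size)
    gap = np.full(shape, np.nan)
    income = np.full(shape, np.nan)
    conv = np.full(shape, np.nan)
    for i, tr in enumerate(trend_grid):
        for j, am in enumerate(amplitude_grid):
            model = SSTModel(
                mean_anomaly=sst_base.mean_anomaly,
                trend=float(tr),
                amplitude=float(am),
                period=sst_base.period,
                phase=sst_base.phase,
                noise_sd=0.0,
            )
            try:
                forcing = ForcingSeries.from_sst_model(model, years, params)
                traj = simulate(model_kind, params, forcing, init)
                gap[i, j] = price_gap(traj, min_catch=params.eps_catch)
                income[i, j] = float(traj.column("income_fishers").mean())
                cy = convergence_year(
                    traj, threshold=threshold, min_catch=params.eps_catch
                )
                conv[i, j] = np.nan if cy is None else cy
            except (ValueError, FloatingPointError, UndefinedStatisticError):
                continue
    return GridSweepResult(
        trend_values=trend_grid,
        amplitude_values=amplitude_grid,
        mean_price_gap=gap,
        mean_fisher_income=income,
        convergence_years=conv,
    )
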