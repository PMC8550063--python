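"""Monte-Carlo calibration against observed catch and fishers' prices.

The models are confronted with annual observations of catch (tons/yr) and
fishers' price (MXN/ton).  Calibration draws parameter vectors uniformly
from per-parameter ranges, simulates each draw, and scores it with the
coefficient of determination r² for each observed variable.  The retained
ensemble (top fraction by the combined score) yields a per-year mean
trajectory and 2.5%/97.5% quantile bands.

A separate sensitivity mode replaces the behavioural effort rule with an
exact inversion that chooses, each year, the effort that reproduces the
observed catch — testing whether a model constrained to match catches can
also match prices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .dynamics import (
    ModelKind,
    ModelState,
    Trajectory,
    _catchability_for_year,
    default_initial_state,
    fisher_price_competitive,
    fisher_price_sem,
    incomes,
    market_price,
    simulate,
    step_population,
    trader_cooperation,
)
from .errors import (
    CalibrationFailureError,
    ConfigurationError,
    InvalidInputError,
    UndefinedStatisticError,
)
from .forcing import ForcingSeries
from .params import ParameterSet

__all__ = [
    "ObservationSeries",
    "MonteCarloDesign",
    "CalibrationResult",
    "sample_parameters",
    "r_squared",
    "monte_carlo_calibrate",
    "optimize_effort_to_catch",
    "default_design",
]


@dataclass(frozen=True)
class ObservationSeries:
    """Observed annual catch (tons/yr) and fishers' price (MXN/ton)."""

    years: np.ndarray
    catch_obs: np.ndarray
    fisher_price_obs: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        if years.size == 0:
            raise InvalidInputError("observations must be non-empty")
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise InvalidInputError("observation years must be consecutive")
        object.__setattr__(self, "years", years)
        for name in ("catch_obs", "fisher_price_obs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != years.shape:
                raise InvalidInputError(f"{name} length must match years")
            if np.any(arr < 0):
                raise InvalidInputError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.years.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "catch_tons": self.catch_obs,
                "fisher_price_mxn_per_ton": self.fisher_price_obs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSeries":
        df = pd.read_csv(path)
        required = {"year", "catch_tons", "fisher_price_mxn_per_ton"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"observations CSV {path} must contain columns {sorted(required)}"
            )
        return cls(
            years=df["year"].to_numpy(int),
            catch_obs=df["catch_tons"].to_numpy(float),
            fisher_price_obs=df["fisher_price_mxn_per_ton"].to_numpy(float),
        )


@dataclass(frozen=True)
class MonteCarloDesign:
    """Uniform sampling design: per-parameter (low, high) ranges."""

    ranges: Mapping[str, tuple[float, float]]
    n_draws: int = 1000
    seed: int = 0
    sampling: str = "uniform"   # or "lhs" (Latin hypercube)

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ConfigurationError("design must contain at least one range")
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ConfigurationError(
                    f"range for {name!r} must satisfy low <= high"
                )
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        if self.sampling not in ("uniform", "lhs"):
            raise ConfigurationError(
                f"sampling must be 'uniform' or 'lhs', got {self.sampling!r}"
            )


def default_design(
    params: ParameterSet,
    n_draws: int = 2000,
    seed: int = 0,
    rel_width: float = 0.4,
    names: Sequence[str] | None = None,
    sampling: str = "uniform",
) -> MonteCarloDesign:
    """Ranges of possible parameter values: +/- ``rel_width`` (relative)
    around a reference parameter set, for the parameters calibration can
    plausibly constrain from catch and price observations."""
    if names is None:
        names = ("r", "K", "q_max", "c_E", "p0", "beta", "gamma", "lam")
    ranges = {}
    for name in names:
        centre = getattr(params, name)
        ranges[name] = (centre * (1 - rel_width), centre * (1 + rel_width))
    return MonteCarloDesign(
        ranges=ranges, n_draws=n_draws, seed=seed, sampling=sampling
    )


def sample_parameters(design: MonteCarloDesign) -> pd.DataFrame:
    """Draw ``n_draws`` parameter vectors, one column per parameter.

    Uniform independent sampling by default; Latin-hypercube optionally.
    Reproducible given the design seed.
    """
    names = list(design.ranges)
    lows = np.array([design.ranges[n][0] for n in names])
    highs = np.array([design.ranges[n][1] for n in names])
    if design.sampling == "lhs":
        sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
        u = sampler.random(design.n_draws)
    else:
        rng = np.random.default_rng(design.seed)
        u = rng.uniform(size=(design.n_draws, len(names)))
    return pd.DataFrame(lows + u * (highs - lows), columns=names)


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed
    mean.  Returned as a fraction (may be negative for poor fits);
    multiply by 100 to report percent."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or obs.size < 2:
        raise InvalidInputError(
            "predicted and observed must have equal length >= 2"
        )
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError(
            "r_squared is undefined for a constant observed series"
        )
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a Monte-Carlo calibration run."""

    model_kind: str
    draws: pd.DataFrame           # one row per draw, sampled parameters
    r2_catch: np.ndarray          # fraction, per draw
    r2_price: np.ndarray          # fraction, per draw
    best_index: int               # argmax of the combined score
    best_params: ParameterSet
    ensemble: pd.DataFrame        # year, {catch,price}_{mean,lo,hi}
    retained: np.ndarray          # indices of retained draws

    @property
    def combined(self) -> np.ndarray:
        return 0.5 * (self.r2_catch + self.r2_price)

    @property
    def best_r2_catch(self) -> float:
        return float(self.r2_catch[self.best_index])

    @property
    def best_r2_price(self) -> float:
        return float(self.r2_price[self.best_index])

    def summary(self) -> dict:
        """Headline numbers, r² reported in percent."""
        return {
            "model_kind": self.model_kind,
            "n_draws": int(len(self.draws)),
            "n_retained": int(self.retained.size),
            "best_index": int(self.best_index),
            "best_r2_catch_pct": round(100.0 * self.best_r2_catch, 2),
            "best_r2_price_pct": round(100.0 * self.best_r2_price, 2),
            "best_params": self.best_params.to_dict(),
        }

    def draws_frame(self) -> pd.DataFrame:
        df = self.draws.copy()
        df["r2_catch"] = self.r2_catch
        df["r2_price"] = self.r2_price
        df["combined_score"] = self.combined
        df["retained"] = False
        df.loc[df.index[self.retained], "retained"] = True
        return df

    def write(self, outdir: str | Path) -> None:
        """Write draws+scores CSV, ensemble-band CSV and summary JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.draws_frame().to_csv(outdir / "draws.csv", index=False)
        self.ensemble.to_csv(outdir / "ensemble.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _score_window(
    traj: Trajectory, obs: ObservationSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated catch and price restricted to the observation years."""
    idx = np.searchsorted(traj.years, obs.years)
    if np.any(idx >= len(traj)) or np.any(traj.years[idx] != obs.years):
        raise ConfigurationError(
            "simulation horizon does not cover the observation years"
        )
    return traj.catch[idx], traj.fisher_price[idx]


def monte_carlo_calibrate(
    model_kind: ModelKind,
    design: MonteCarloDesign,
    forcing: ForcingSeries,
    obs: ObservationSeries,
    init: ModelState | None = None,
    base_params: ParameterSet | None = None,
    *,
    retain_fraction: float = 0.1,
    band_over: str = "retained",    # or "all"
    mean_over: str = "retained",    # or "best"
    catch_mode: str = "mantle",
) -> CalibrationResult:
    """Calibrate one model by uniform Monte-Carlo sampling.

    Each draw replaces the sampled fields of ``base_params``, is simulated
    over the forcing years, and is scored by r² of catch and of fishers'
    price over the observation years.  The combined score is the
    unweighted mean of the two r² values; the top ``retain_fraction`` of
    draws forms the ensemble whose per-year mean and 2.5/97.5% quantiles
    are reported (``band_over="all"`` uses every draw; ``mean_over="best"``
    reports the single best run instead of the ensemble mean).
    """
    if base_params is None:
        base_params = ParameterSet()
    if not 0 < retain_fraction <= 1:
        raise ConfigurationError("retain_fraction must lie in (0, 1]")
    if band_over not in ("retained", "all") or mean_over not in ("retained", "best"):
        raise ConfigurationError("band_over/mean_over option not recognised")

    draws = sample_parameters(design)
    n = len(draws)
    r2_c = np.full(n, -np.inf)
    r2_p = np.full(n, -np.inf)
    sim_catch = np.full((n, len(obs)), np.nan)
    sim_price = np.full((n, len(obs)), np.nan)

    n_failed = 0
    for i in range(n):
        try:
            p = base_params.replace(**draws.iloc[i].to_dict())
            traj = simulate(
                model_kind, p, forcing, init, catch_mode=catch_mode
            )
            c, f = _score_window(traj, obs)
        except (ValueError, FloatingPointError, OverflowError):
            n_failed += 1
            continue
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(f))):
            n_failed += 1
            continue
        sim_catch[i] = c
        sim_price[i] = f
        r2_c[i] = r_squared(c, obs.catch_obs)
        r2_p[i] = r_squared(f, obs.fisher_price_obs)

    valid = np.isfinite(r2_c) & np.isfinite(r2_p)
    if not np.any(valid):
        raise CalibrationFailureError(
            f"all {n} draws failed or produced degenerate trajectories "
            f"({n_failed} raised/non-finite); check ranges and base parameters"
        )

    combined = 0.5 * (r2_c + r2_p)
    best = int(np.argmax(combined))
    n_keep = max(1, int(math.ceil(retain_fraction * int(valid.sum()))))
    order = np.argsort(-combined)      # invalid draws carry -inf, sort last
    retained = np.sort(order[:n_keep])

    pool = retained if band_over == "retained" else np.flatnonzero(valid)
    mean_pool = retained if mean_over == "retained" else np.array([best])
    ensemble = pd.DataFrame(
        {
            "year": obs.years,
            "catch_mean": np.nanmean(sim_catch[mean_pool], axis=0),
            "catch_lo": np.nanpercentile(sim_catch[pool], 2.5, axis=0),
            "catch_hi": np.nanpercentile(sim_catch[pool], 97.5, axis=0),
            "price_mean": np.nanmean(sim_price[mean_pool], axis=0),
            "price_lo": np.nanpercentile(sim_price[pool], 2.5, axis=0),
            "price_hi": np.nanpercentile(sim_price[pool], 97.5, axis=0),
        }
    )

    return CalibrationResult(
        model_kind=model_kind,
        draws=draws,
        r2_catch=r2_c,
        r2_price=r2_p,
        best_index=best,
        best_params=base_params.replace(**draws.iloc[best].to_dict()),
        ensemble=ensemble,
        retained=retained,
    )


def optimize_effort_to_catch(
    model_kind: ModelKind,
    params: ParameterSet,
    forcing: ForcingSeries,
    obs: ObservationSeries,
    init: ModelState | None = None,
    *,
    effort_cap: float = np.inf,
    catch_mode: str = "mantle",
) -> tuple[np.ndarray, Trajectory, np.ndarray]:
    """Effort-optimization sensitivity mode.

    Instead of the behavioural effort rule, each year the effort is chosen
    by exact inversion effort = catch_obs / (q * stock) (floored at 0,
    capped at ``effort_cap``), after which stock, prices and incomes
    advance as usual.  Returns ``(effort_series, trajectory, feasible)``
    where ``feasible[t]`` is False when the required effort exceeded the
    cap and the realised catch was truncated below the observed one.
    """
    if init is None:
        init = default_initial_state(params)
    years = obs.years
    if model_kind in ("EDM", "SEM"):
        forcing = forcing.subset(years)

    stock = float(init.stock)
    efforts = np.zeros(len(obs))
    feasible = np.ones(len(obs), dtype=bool)
    states = []
    for i, year in enumerate(years):
        q = _catchability_for_year(model_kind, forcing, i, params, catch_mode)
        target = float(obs.catch_obs[i])
        if target <= 0 or q * stock <= 0:
            effort = 0.0
            feasible[i] = target <= 0
        else:
            effort = target / (q * stock)
            if effort > effort_cap:
                effort = effort_cap
                feasible[i] = False
        next_stock, catch = step_population(stock, effort, q, params)
        if catch < target - 1e-9 * max(target, 1.0):
            feasible[i] = False   # stock too small: catch truncated
        p_m = market_price(catch, params)
        if model_kind == "SEM":
            coop = trader_cooperation(float(forcing.pacific_prop[i]), params)
            p_f = fisher_price_sem(p_m, coop, params)
        else:
            coop = 0.0
            p_f = fisher_price_competitive(p_m, params)
        inc_f, inc_t = incomes(catch, p_m, p_f, effort, params)
        efforts[i] = effort
        states.append(
            ModelState(
                stock=stock, effort=effort, catch=catch,
                market_price=p_m, fisher_price=p_f, cooperation=coop,
                income_fishers=inc_f, income_traders=inc_t,
            )
        )
        stock = next_stock

    traj = Trajectory(years=years, states=tuple(states), model_kind=model_kind)
    return efforts, traj, feasible
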