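"""The three nested annual difference-equation models.

* **BEM** — bioeconomic baseline: discrete Gordon-Schaefer stock dynamics
  (logistic growth, catch = q * effort * stock), effort adjusting to
  realised profit, isoelastic market price, and a competitive market in
  which fishers receive the market price minus processing costs.
* **EDM** — environment-driven model: the BEM with catchability driven by
  SST anomalies through squid body size (warm years select a small
  tropical phenotype that jig fishing catches poorly).
* **SEM** — social-ecological model: the EDM plus trader dynamics.  In warm
  years a rising proportion of landings occurs at Pacific ports, which
  erodes the price-fixing cooperation of the trader oligopsony; fishers'
  prices rise from an empirical minimum toward the competitive level as
  cooperation breaks down.

Each model advances one year at a time in a fixed order: forcing ->
harvest -> market price -> cooperation & fishers' price -> incomes ->
effort response.  Effort responds to realised profit, so increasing
profitability leads to higher effort the following year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .forcing import ForcingSeries, catchability
from .params import ParameterSet, default_parameters

__all__ = [
    "ModelKind",
    "ModelState",
    "Trajectory",
    "step_population",
    "market_price",
    "fisher_price_competitive",
    "trader_cooperation",
    "fisher_price_sem",
    "step_effort",
    "incomes",
    "simulate",
    "default_initial_state",
]

ModelKind = Literal["BEM", "EDM", "SEM"]
MODEL_KINDS: tuple[str, ...] = ("BEM", "EDM", "SEM")

#: Column order of the trajectory CSV schema.
TRAJECTORY_COLUMNS = [
    "year",
    "stock_t",
    "effort",
    "catch_t",
    "market_price_mxn_t",
    "fisher_price_mxn_t",
    "cooperation",
    "income_fishers_mxn",
    "income_traders_mxn",
]


@dataclass(frozen=True)
class ModelState:
    """The per-year state of any of the three models."""

    stock: float            # tons, start of year
    effort: float           # effort units deployed during the year
    catch: float            # tons landed during the year
    market_price: float     # MXN/ton
    fisher_price: float     # MXN/ton, price paid at the beach
    cooperation: float      # trader cooperation in [0, 1] (0 for BEM/EDM)
    income_fishers: float   # MXN/yr, floored at 0 for reporting
    income_traders: float   # MXN/yr, floored at 0

    def __post_init__(self) -> None:
        if self.stock < 0 or self.effort < 0 or self.catch < 0:
            raise InvalidInputError("stock, effort and catch must be >= 0")
        if self.catch > self.stock * (1 + 1e-12):
            raise InvalidInputError("catch cannot exceed the standing stock")
        if not 0 <= self.cooperation <= 1:
            raise InvalidInputError("cooperation must lie in [0, 1]")
        if self.fisher_price > self.market_price + 1e-9:
            raise InvalidInputError(
                "fisher price cannot exceed the market price"
            )


def default_initial_state(params: ParameterSet) -> ModelState:
    """A conventional starting point: a lightly exploited stock."""
    return ModelState(
        stock=0.75 * params.K,
        effort=5_000.0,
        catch=0.0,
        market_price=0.0,
        fisher_price=0.0,
        cooperation=1.0,
        income_fishers=0.0,
        income_traders=0.0,
    )


# ---------------------------------------------------------------------------
# elementary one-year operations
# ---------------------------------------------------------------------------

def step_population(
    stock: float, effort: float, q: float, params: ParameterSet
) -> tuple[float, float]:
    """Advance the stock one year under Gordon-Schaefer dynamics.

    catch = min(q * effort * stock, stock); the next stock adds logistic
    surplus production r * stock * (1 - stock/K) and removes the catch,
    clipped at zero.  Returns ``(next_stock, catch)``.
    """
    if stock < 0 or effort < 0:
        raise InvalidInputError("stock and effort must be >= 0")
    catch = min(q * effort * stock, stock)
    nxt = stock + params.r * stock * (1.0 - stock / params.K) - catch
    return max(nxt, 0.0), catch


def market_price(catch: float, params: ParameterSet) -> float:
    """Isoelastic market price (MXN/ton).

    p_m = demand_mult * p0 * (catch / C_ref) ** (-1/beta): prices respond
    instantly to traded volume, with price flexibility beta.  Catch below
    the floor ``eps_catch`` is evaluated at the floor — price predictions
    are not meaningful at near-zero volumes.
    """
    if catch < 0:
        raise InvalidInputError("catch must be >= 0")
    c = max(catch, params.eps_catch)
    return (
        params.demand_mult
        * params.p0
        * (c / params.C_ref) ** (-1.0 / params.beta)
    )


def fisher_price_competitive(mkt_price: float, params: ParameterSet) -> float:
    """Fishers' price under competitive equilibrium (BEM/EDM):
    the market price minus processing costs, floored at zero."""
    if mkt_price < 0:
        raise InvalidInputError("market price must be >= 0")
    return max(mkt_price - params.c_proc, 0.0)


def trader_cooperation(pacific_prop: float, params: ParameterSet) -> float:
    """Trader cooperation as an inverse-exponential function of the
    Pacific-landings proportion.

    coop = coop_cap * exp(-gamma * pacific_prop): new traders entering at
    Pacific ports enlarge the group and break down the price-fixing
    agreement exponentially.
    """
    if not 0 <= pacific_prop <= 1:
        raise InvalidInputError("pacific_prop must lie in [0, 1]")
    return params.coop_cap * math.exp(-params.gamma * pacific_prop)


def fisher_price_sem(
    mkt_price: float, cooperation: float, params: ParameterSet
) -> float:
    """Fishers' price under the trader oligopsony (SEM).

    A linear blend between the empirical minimum price (full cooperation)
    and the competitive price (no cooperation), clamped into
    [p_f_min, p_f_max] and never exceeding market price minus processing
    costs:

        p_f = clamp(p_f_min + (1 - coop) * (p_m - c_proc - p_f_min),
                    p_f_min, p_f_max)
        p_f = max(min(p_f, p_m - c_proc), 0)
    """
    if not 0 <= cooperation <= 1:
        raise InvalidInputError("cooperation must lie in [0, 1]")
    competitive = mkt_price - params.c_proc
    p_f = params.p_f_min + (1.0 - cooperation) * (competitive - params.p_f_min)
    p_f = min(max(p_f, params.p_f_min), params.p_f_max)
    return max(min(p_f, competitive), 0.0)


def step_effort(
    effort: float, fisher_price: float, catch: float, params: ParameterSet
) -> float:
    """Effort next year responds to this year's realised profit:
    next = max(effort + k_E * (p_f * catch - c_E * effort), 0)."""
    profit = fisher_price * catch - params.c_E * effort
    return max(effort + params.k_E * profit, 0.0)


def incomes(
    catch: float,
    mkt_price: float,
    fisher_price: float,
    effort: float,
    params: ParameterSet,
) -> tuple[float, float]:
    """Annual incomes (MXN/yr) of fishers and traders from the squid
    fishery alone, both floored at zero for reporting.

    fishers: beach revenue minus effort costs; traders: the margin between
    market and beach price net of processing costs, times volume.
    """
    if min(catch, mkt_price, fisher_price, effort) < 0:
        raise InvalidInputError("incomes: all inputs must be >= 0")
    if fisher_price > mkt_price + 1e-9:
        raise InvalidInputError("fisher price cannot exceed market price")
    inc_f = fisher_price * catch - params.c_E * effort
    inc_t = (mkt_price - fisher_price - params.c_proc) * catch
    return max(inc_f, 0.0), max(inc_t, 0.0)


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """One simulated run: consecutive years, one :class:`ModelState` each."""

    years: np.ndarray
    states: tuple[ModelState, ...]
    model_kind: str

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "years", years)
        if len(self.states) != years.size:
            raise InvalidInputError("one state per year required")
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}"
            )

    def __len__(self) -> int:
        return int(self.years.size)

    def column(self, name: str) -> np.ndarray:
        """Extract one state field as an array over years."""
        return np.array([getattr(s, name) for s in self.states], dtype=float)

    @property
    def catch(self) -> np.ndarray:
        return self.column("catch")

    @property
    def fisher_price(self) -> np.ndarray:
        return self.column("fisher_price")

    @property
    def market_price(self) -> np.ndarray:
        return self.column("market_price")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "stock_t": self.column("stock"),
                "effort": self.column("effort"),
                "catch_t": self.column("catch"),
                "market_price_mxn_t": self.column("market_price"),
                "fisher_price_mxn_t": self.column("fisher_price"),
                "cooperation": self.column("cooperation"),
                "income_fishers_mxn": self.column("income_fishers"),
                "income_traders_mxn": self.column("income_traders"),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the annual simulation loop
# ---------------------------------------------------------------------------

def _catchability_for_year(
    model_kind: str,
    forcing: ForcingSeries | None,
    idx: int,
    params: ParameterSet,
    catch_mode: str,
) -> float:
    if model_kind == "BEM":
        return params.q_max
    assert forcing is not None
    if catch_mode == "mantle":
        return float(catchability(forcing.mantle_length[idx], "mantle", params))
    return float(catchability(forcing.sst[idx], "sst", params))


def simulate(
    model_kind: ModelKind,
    params: ParameterSet,
    forcing: ForcingSeries | None,
    init: ModelState | None = None,
    years: Sequence[int] | None = None,
    *,
    catch_mode: str = "mantle",
    coop_lag: bool = False,
    params_for_year: Callable[[int], ParameterSet] | None = None,
) -> Trajectory:
    """Run one of the three models over consecutive years.

    Parameters
    ----------
    model_kind : "BEM", "EDM" or "SEM".
    params : model constants; ignored per-year if ``params_for_year`` is
        given (scenario programs supply a year-dependent parameter set).
    forcing : annual drivers; required for EDM/SEM (catchability) and SEM
        (Pacific proportion).  The BEM ignores it (constant q = q_max).
    init : starting state (defaults to :func:`default_initial_state`).
    years : simulation years; defaults to the forcing years.  For EDM/SEM
        the forcing must cover every simulated year.
    catch_mode : "mantle" (catchability from squid size) or "sst" (directly
        from the SST anomaly) — the two alternative EDM/SEM setups.
    coop_lag : if True, trader cooperation responds to the previous year's
        Pacific proportion instead of the current one.

    The annual update order is: (1) catchability from forcing, (2) harvest
    and stock update, (3) market price, (4) cooperation and fishers' price
    (SEM) or competitive fishers' price (BEM/EDM), (5) incomes, (6) effort
    response to realised profit.  Deterministic given the inputs.
    """
    if model_kind not in MODEL_KINDS:
        raise ConfigurationError(
            f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}"
        )
    if years is None:
        if forcing is None:
            raise ConfigurationError(
                "simulate needs either explicit years or a forcing series"
            )
        years = forcing.years
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise ConfigurationError("simulation horizon is empty")
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise ConfigurationError("simulation years must be consecutive")

    if model_kind in ("EDM", "SEM"):
        if forcing is None:
            raise ConfigurationError(f"{model_kind} requires a forcing series")
        forcing = forcing.subset(years)

    base_params = params
    if init is None:
        init = default_initial_state(base_params)

    stock = float(init.stock)
    effort = float(init.effort)
    states: list[ModelState] = []
    for i, year in enumerate(years):
        p = params_for_year(int(year)) if params_for_year is not None else base_params

        q = _catchability_for_year(model_kind, forcing, i, p, catch_mode)
        next_stock, catch = step_population(stock, effort, q, p)
        p_m = market_price(catch, p)

        if model_kind == "SEM":
            assert forcing is not None
            j = max(i - 1, 0) if coop_lag else i
            coop = trader_cooperation(float(forcing.pacific_prop[j]), p)
            p_f = fisher_price_sem(p_m, coop, p)
        else:
            coop = 0.0
            p_f = fisher_price_competitive(p_m, p)

        inc_f, inc_t = incomes(catch, p_m, p_f, effort, p)
        states.append(
            ModelState(
                stock=stock,
                effort=effort,
                catch=catch,
                market_price=p_m,
                fisher_price=p_f,
                cooperation=coop,
                income_fishers=inc_f,
                income_traders=inc_t,
            )
        )
        effort = step_effort(effort, p_f, catch, p)
        stock = next_stock

    return Trajectory(years=years, states=tuple(states), model_kind=model_kind)
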