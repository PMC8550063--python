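"""Exogenous environmental drivers.

The models are forced by annual sea-surface-temperature (SST) anomalies.
Warming acts through two documented channels:

* squid body size — the large temperate phenotype (mantle length up to
  ~120 cm) is replaced by a small tropical phenotype (~20-40 cm) in warm
  years, and jig-based fishing is less efficient on small squid, so
  catchability declines;
* fishing grounds — in warm years a growing proportion of landings occurs
  at Pacific ports outside the Gulf of California core grounds, which (in
  the social-ecological model) erodes trader cooperation.

This module builds the SST series (linear climate trend plus an El
Niño / La Niña-like sinusoid) and the static maps SST -> mantle length,
mantle length / SST -> catchability, and SST -> Pacific-landings
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .params import ParameterSet

__all__ = [
    "SSTModel",
    "ForcingSeries",
    "generate_sst_series",
    "mantle_length_from_sst",
    "catchability",
    "pacific_proportion",
]


@dataclass(frozen=True)
class SSTModel:
    """Parametric annual SST-anomaly generator.

    value(t) = mean_anomaly + trend * (t - t0)
               + amplitude * sin(2*pi*(t - t0)/period + phase) + noise

    with t0 the first simulated year.  The trend represents climate change;
    the sinusoid represents climatic variability associated with El Niño
    and La Niña cycles.  noise_sd is zero for model runs and positive only
    when generating synthetic data.
    """

    mean_anomaly: float = 0.0  # degC
    trend: float = 0.0         # degC / yr
    amplitude: float = 0.0     # degC
    period: float = 6.0        # yr
    phase: float = 0.0         # radians
    noise_sd: float = 0.0      # degC

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise InvalidParameterError("SSTModel.period must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError("SSTModel.amplitude must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("SSTModel.noise_sd must be >= 0")


def _check_years(years: Sequence[int]) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise InvalidInputError("years must be non-empty")
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise InvalidInputError("years must be consecutive")
    return years


def generate_sst_series(
    model: SSTModel,
    years: Sequence[int],
    seed: int | None = None,
) -> np.ndarray:
    """Annual SST anomaly series (degC) over consecutive ``years``.

    Deterministic given ``seed``; with ``noise_sd == 0`` it equals the
    closed-form trend + sinusoid exactly.
    """
    years = _check_years(years)
    t = years - years[0]
    sst = (
        model.mean_anomaly
        + model.trend * t
        + model.amplitude * np.sin(2.0 * np.pi * t / model.period + model.phase)
    )
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        sst = sst + rng.normal(0.0, model.noise_sd, size=years.size)
    return sst


def mantle_length_from_sst(
    sst: float | np.ndarray, params: ParameterSet
) -> float | np.ndarray:
    """Mean mantle length (cm) implied by an SST anomaly.

    A linearly decreasing map clipped into [ML_min, ML_max]: cold anomalies
    select the large temperate phenotype, warm anomalies the small tropical
    one.
    """
    ml = params.ML_max + params.ml_slope * (np.asarray(sst, float) - params.ml_ref)
    out = np.clip(ml, params.ML_min, params.ML_max)
    return float(out) if np.isscalar(sst) else out


def catchability(
    ml_or_sst: float | np.ndarray,
    mode: str,
    params: ParameterSet,
) -> float | np.ndarray:
    """Catchability per unit effort from mantle length or SST anomaly.

    Two alternative setups:

    * ``mode="mantle"`` — q = q_max * (ML - ML_min) / (ML_max - ML_min),
      clipped to [0, q_max]: large squid are fully catchable by jigs, the
      small tropical phenotype is not.
    * ``mode="sst"`` — q declines linearly from q_max at ``sst_q_ref`` to 0
      over ``sst_q_width`` degC, clipped to [0, q_max].
    """
    x = np.asarray(ml_or_sst, dtype=float)
    if mode == "mantle":
        frac = (x - params.ML_min) / (params.ML_max - params.ML_min)
    elif mode == "sst":
        frac = 1.0 - (x - params.sst_q_ref) / params.sst_q_width
    else:
        raise ConfigurationError(
            f"catchability mode must be 'mantle' or 'sst', got {mode!r}"
        )
    q = params.q_max * np.clip(frac, 0.0, 1.0)
    return float(q) if np.isscalar(ml_or_sst) else q


def pacific_proportion(
    sst: float | np.ndarray, params: ParameterSet
) -> float | np.ndarray:
    """Proportion of annual landings occurring at Pacific ports.

    Inverse-exponential saturation in the SST anomaly above an onset
    threshold:  R = R_max * (1 - exp(-lam * max(sst - T0, 0))).  Zero in
    cold years, approaching R_max in strongly warm (El Niño-like) years.
    """
    excess = np.maximum(np.asarray(sst, dtype=float) - params.T0, 0.0)
    out = params.R_max * (1.0 - np.exp(-params.lam * excess))
    return float(out) if np.isscalar(sst) else out


@dataclass(frozen=True)
class ForcingSeries:
    """Annual exogenous drivers: SST anomaly, mantle length, Pacific
    proportion, over consecutive years."""

    years: np.ndarray        # consecutive integers
    sst: np.ndarray          # degC anomaly
    mantle_length: np.ndarray  # cm
    pacific_prop: np.ndarray   # fraction in [0, 1]

    def __post_init__(self) -> None:
        years = _check_years(self.years)
        object.__setattr__(self, "years", years)
        for name in ("sst", "mantle_length", "pacific_prop"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != years.shape:
                raise InvalidInputError(
                    f"{name} must have the same length as years"
                )
            object.__setattr__(self, name, arr)
        if np.any(self.mantle_length < 0):
            raise InvalidInputError("mantle_length must be >= 0")
        if np.any((self.pacific_prop < 0) | (self.pacific_prop > 1)):
            raise InvalidInputError("pacific_prop must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.years.size)

    @classmethod
    def from_sst_model(
        cls,
        model: SSTModel,
        years: Sequence[int],
        params: ParameterSet,
        seed: int | None = None,
    ) -> "ForcingSeries":
        """Build the full forcing from an SST model: SST series, then the
        derived mantle-length and Pacific-proportion columns."""
        years = _check_years(years)
        sst = generate_sst_series(model, years, seed=seed)
        return cls(
            years=years,
            sst=sst,
            mantle_length=mantle_length_from_sst(sst, params),
            pacific_prop=pacific_proportion(sst, params),
        )

    def subset(self, years: Sequence[int]) -> "ForcingSeries":
        """Restrict to a consecutive sub-range of years."""
        years = _check_years(years)
        idx = np.searchsorted(self.years, years)
        if np.any(idx >= len(self)) or np.any(self.years[idx] != years):
            missing = sorted(set(years.tolist()) - set(self.years.tolist()))
            raise ConfigurationError(f"forcing is missing years {missing}")
        return ForcingSeries(
            years=years,
            sst=self.sst[idx],
            mantle_length=self.mantle_length[idx],
            pacific_prop=self.pacific_prop[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "sst_anomaly_c": self.sst,
                "mantle_length_cm": self.mantle_length,
                "pacific_prop": self.pacific_prop,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        params: ParameterSet | None = None,
        derive_missing: bool = False,
    ) -> "ForcingSeries":
        """Read a forcing CSV (`year,sst_anomaly_c,mantle_length_cm,
        pacific_prop`).  With ``derive_missing``, absent mantle/pacific
        columns are filled from SST via the maps above (requires params)."""
        df = pd.read_csv(path)
        required = {"year", "sst_anomaly_c"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"forcing CSV {path} must contain columns {sorted(required)}"
            )
        sst = df["sst_anomaly_c"].to_numpy(float)
        if "mantle_length_cm" in df.columns:
            ml = df["mantle_length_cm"].to_numpy(float)
        elif derive_missing and params is not None:
            ml = mantle_length_from_sst(sst, params)
        else:
            raise ConfigurationError(
                f"forcing CSV {path} lacks mantle_length_cm "
                "(pass derive_missing=True with parameters to derive it)"
            )
        if "pacific_prop" in df.columns:
            pp = df["pacific_prop"].to_numpy(float)
        elif derive_missing and params is not None:
            pp = pacific_proportion(sst, params)
        else:
            raise ConfigurationError(
                f"forcing CSV {path} lacks pacific_prop "
                "(pass derive_missing=True with parameters to derive it)"
            )
        return cls(
            years=df["year"].to_numpy(int),
            sst=sst,
            mantle_length=ml,
            pacific_prop=pp,
        )
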