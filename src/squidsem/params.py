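"""Model parameters for the Humboldt squid fishery models.

Every constant used by the bioeconomic (BEM), environment-driven (EDM) and
social-ecological (SEM) models lives in a single validated, immutable record
so that a simulation is fully determined by (parameters, forcing, initial
state).  Units are part of each field's documentation; the configuration file
format (see :mod:`squidsem.cli`) repeats them in the key names.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

from .errors import InvalidParameterError

__all__ = ["ParameterSet", "default_parameters"]


@dataclass(frozen=True)
class ParameterSet:
    """All model constants, validated on construction.

    Population and harvest
    ----------------------
    r : intrinsic growth rate of the squid stock (1/yr).
    K : carrying capacity (tons).
    q_max : maximum catchability, realised by the large temperate phenotype
        (fraction of stock caught per effort unit per year).

    Effort and costs
    ----------------
    k_E : effort responsiveness to realised profit (effort units per MXN).
    c_E : cost per unit effort (MXN per effort unit per year).

    Market
    ------
    p0 : demand scale price, the market price at the reference catch
        (MXN/ton).
    C_ref : reference catch volume anchoring the demand curve (tons/yr).
    beta : price flexibility of the isoelastic demand curve (dimensionless,
        > 0); market price is p0 * (catch / C_ref) ** (-1 / beta).
    c_proc : processing cost subtracted between market and beach (MXN/ton).
    p_f_min, p_f_max : empirical bounds on the price fishers receive
        (MXN/ton).
    demand_mult : demand scenario multiplier on the market price (default 1;
        the demand-development program raises it).
    eps_catch : evaluation floor for the isoelastic price at near-zero catch
        (tons); price predictions are not meaningful below it.

    Trader cooperation (SEM)
    ------------------------
    gamma : exponential decay rate of trader cooperation with the proportion
        of Pacific landings (dimensionless).
    coop_cap : cooperation ceiling in [0, 1] (default 1; the
        cooperation-limitation program lowers it).

    Pacific-landings response to SST
    --------------------------------
    lam : saturation rate of the Pacific-landings proportion with SST
        anomaly above onset (1/degC).
    T0 : SST anomaly onset threshold below which no Pacific landings occur
        (degC).
    R_max : saturation level of the Pacific-landings proportion (fraction).

    Squid size and catchability response to SST
    -------------------------------------------
    ML_min, ML_max : mantle lengths of the tropical and temperate phenotypes
        (cm).
    ml_slope : change of mantle length per degC of SST anomaly (cm/degC,
        negative: warmer water, smaller squid).
    ml_ref : SST anomaly at which mantle length equals ML_max (degC).
    sst_q_ref : SST anomaly at which catchability equals q_max in the
        direct-SST setup (degC).
    sst_q_width : SST span over which catchability falls from q_max to 0 in
        the direct-SST setup (degC).
    """

    # population / harvest
    r: float = 0.35
    K: float = 400_000.0
    q_max: float = 2.5e-5
    # effort
    k_E: float = 5.0e-7
    c_E: float = 9_000.0
    # market
    p0: float = 12_000.0
    C_ref: float = 50_000.0
    beta: float = 3.0
    c_proc: float = 1_000.0
    p_f_min: float = 2_000.0
    p_f_max: float = 45_000.0
    demand_mult: float = 1.0
    eps_catch: float = 1.0
    # cooperation
    gamma: float = 5.0
    coop_cap: float = 1.0
    # pacific proportion
    lam: float = 4.0
    T0: float = 0.3
    R_max: float = 1.0
    # mantle length / catchability forcing maps
    ML_min: float = 20.0
    ML_max: float = 120.0
    ml_slope: float = -100.0
    ml_ref: float = 0.3
    sst_q_ref: float = 0.3
    sst_q_width: float = 1.0

    def __post_init__(self) -> None:
        checks = [
            (self.r > 0, "r must be > 0"),
            (self.K > 0, "K must be > 0"),
            (self.q_max > 0, "q_max must be > 0"),
            (self.k_E >= 0, "k_E must be >= 0"),
            (self.c_E >= 0, "c_E must be >= 0"),
            (self.p0 > 0, "p0 must be > 0"),
            (self.C_ref > 0, "C_ref must be > 0"),
            (self.beta > 0, "beta (price flexibility) must be > 0"),
            (self.c_proc >= 0, "c_proc must be >= 0"),
            (0 <= self.p_f_min < self.p_f_max,
             "price bounds require 0 <= p_f_min < p_f_max"),
            (self.demand_mult > 0, "demand_mult must be > 0"),
            (self.eps_catch > 0, "eps_catch must be > 0"),
            (self.gamma >= 0, "gamma must be >= 0"),
            (0 <= self.coop_cap <= 1, "coop_cap must lie in [0, 1]"),
            (self.lam > 0, "lam must be > 0"),
            (0 < self.R_max <= 1, "R_max must lie in (0, 1]"),
            (self.ML_min >= 0, "ML_min must be >= 0"),
            (self.ML_min < self.ML_max, "ML_min must be < ML_max"),
            (self.ml_slope < 0, "ml_slope must be negative"),
            (self.sst_q_width > 0, "sst_q_width must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidParameterError(msg)
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) and not (
                f.name == "p_f_max" and v == math.inf
            ):
                raise InvalidParameterError(f"{f.name} must be finite")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})


def default_parameters(**overrides: float) -> ParameterSet:
    """The package's documented default parameterization.

    The values are placeholders on a realistic scale for the Gulf of
    California Humboldt squid fishery (catches of tens of thousands of
    tons/yr, beach prices of a few thousand MXN/ton) and are meant to be
    replaced with empirically estimated constants when available.
    """
    return ParameterSet(**overrides)
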