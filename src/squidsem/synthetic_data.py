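"""Self-contained synthetic fixtures.

The study's real inputs (official landings and price records, satellite SST
anomalies, mantle-length measurements) are not redistributable, so every
stage of the pipeline is exercised on synthetic stand-ins generated here
from a known parameterization:

* a forcing fixture — trending + periodic SST anomalies, mantle length
  declining with SST, Pacific-landings proportion rising with SST;
* pseudo-observations — catch and fishers' price simulated with the
  social-ecological model under known "true" parameters, perturbed by
  multiplicative lognormal noise with a chosen coefficient of variation.

The default bundle covers 1990-2025 with a 2001-2016 observation window
and is shaped like the study period: catches rise to a peak and collapse
as the warming trend accumulates, while fishers' prices rise late.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import ObservationSeries
from .dynamics import ModelState, Trajectory, default_initial_state, simulate
from .errors import InvalidInputError
from .forcing import ForcingSeries, SSTModel
from .params import ParameterSet, default_parameters

__all__ = [
    "FixtureBundle",
    "make_forcing_fixture",
    "generate_observations",
    "default_fixture",
    "default_sst_model",
    "program_sst_model",
    "program_forcing",
]

#: Fixture horizon and the observation window used for calibration.
FIXTURE_YEARS = np.arange(1990, 2026)
OBS_YEARS = np.arange(2001, 2017)


def default_sst_model(noise_sd: float = 0.0) -> SSTModel:
    """The calibration fixture's climate: a +0.05 degC/yr warming trend on
    top of a 0.4 degC, 6-year El Niño / La Niña-like oscillation starting
    from a cool 1990.  Strong enough that the warm phenotype displaces the
    temperate one within the horizon, collapsing catches late in the
    period."""
    return SSTModel(
        mean_anomaly=-0.4,
        trend=0.05,
        amplitude=0.4,
        period=6.0,
        phase=-0.5 * np.pi,
        noise_sd=noise_sd,
    )


def program_sst_model(noise_sd: float = 0.0) -> SSTModel:
    """The development-program experiment's climate: moderate warming
    (+0.012 degC/yr, amplitude 0.35 degC), under which trader cooperation
    stays high in almost every year, breaking down only episodically when
    an El Niño-like peak pushes landings to Pacific ports."""
    return SSTModel(
        mean_anomaly=-0.4,
        trend=0.012,
        amplitude=0.35,
        period=6.0,
        phase=-0.5 * np.pi,
        noise_sd=noise_sd,
    )


def make_forcing_fixture(
    years: Sequence[int],
    sst_model: SSTModel,
    params: ParameterSet | None = None,
    seed: int | None = None,
) -> ForcingSeries:
    """Forcing series from an SST model: SST, then the derived mantle
    length and Pacific proportion.  Deterministic given the seed."""
    if params is None:
        params = default_parameters()
    return ForcingSeries.from_sst_model(sst_model, years, params, seed=seed)


def program_forcing(
    params: ParameterSet | None = None, noise_sd: float = 0.0,
    seed: int | None = None,
) -> ForcingSeries:
    """The 1990-2025 forcing used by the development-program experiments
    (moderate-warming climate, see :func:`program_sst_model`)."""
    if params is None:
        params = default_parameters()
    return make_forcing_fixture(
        FIXTURE_YEARS, program_sst_model(noise_sd=noise_sd), params, seed=seed
    )


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def generate_observations(
    params: ParameterSet,
    forcing: ForcingSeries,
    init: ModelState | None = None,
    noise_cv: float = 0.05,
    seed: int | None = None,
    obs_years: Sequence[int] | None = None,
) -> tuple[ObservationSeries, Trajectory]:
    """Noisy pseudo-observations of catch and fishers' price.

    The social-ecological model is simulated under ``params``; observed
    catch and price are the simulated values times independent unit-mean
    lognormal factors with coefficient of variation ``noise_cv`` (catch
    and price are positive, heteroskedastic quantities).  Returns the
    observations and the underlying noise-free trajectory.
    """
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be >= 0")
    traj = simulate("SEM", params, forcing, init)
    years = np.asarray(
        forcing.years if obs_years is None else obs_years, dtype=int
    )
    idx = np.searchsorted(traj.years, years)
    catch = traj.catch[idx]
    price = traj.fisher_price[idx]
    if np.all(catch <= params.eps_catch):
        import warnings

        warnings.warn(
            "fixture generation: simulated catch is degenerate (at or below "
            "the evaluation floor in every year)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    obs = ObservationSeries(
        years=years,
        catch_obs=catch * _lognormal_factors(rng, noise_cv, years.size),
        fisher_price_obs=price * _lognormal_factors(rng, noise_cv, years.size),
    )
    return obs, traj


@dataclass(frozen=True)
class FixtureBundle:
    """Everything a calibration or scenario test needs, from one seed."""

    true_params: ParameterSet
    forcing: ForcingSeries
    observations: ObservationSeries
    truth: Trajectory            # the noise-free trajectory behind the obs
    seed: int
    noise_cv: float

    def write(self, outdir: str | Path) -> None:
        """Write the forcing and observation CSVs plus a JSON manifest
        (seed, noise level, true parameters)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.forcing.to_csv(outdir / "forcing.csv")
        self.observations.to_csv(outdir / "observations.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "noise_cv": self.noise_cv,
                    "true_params": self.true_params.to_dict(),
                    "years": [int(self.forcing.years[0]),
                              int(self.forcing.years[-1])],
                    "obs_years": [int(self.observations.years[0]),
                                  int(self.observations.years[-1])],
                },
                fh,
                indent=2,
            )


def default_fixture(
    seed: int = 0,
    noise_cv: float = 0.05,
    params: ParameterSet | None = None,
) -> FixtureBundle:
    """The documented 1990-2025 bundle with a 2001-2016 observation window.

    Under the default parameters the simulated catch rises to a peak and
    collapses as the warming trend accumulates, and fishers' prices rise
    late in the period as trader cooperation erodes — mirroring the
    qualitative shape of the study period.
    """
    if params is None:
        params = default_parameters()
    # derive independent sub-seeds (noise in forcing vs. observations)
    ss = np.random.SeedSequence(seed)
    s_force, s_obs = [int(s) for s in ss.generate_state(2) >> 1]
    forcing = make_forcing_fixture(
        FIXTURE_YEARS, default_sst_model(noise_sd=0.08), params, seed=s_force
    )
    obs, truth = generate_observations(
        params,
        forcing,
        init=default_initial_state(params),
        noise_cv=noise_cv,
        seed=s_obs,
        obs_years=OBS_YEARS,
    )
    return FixtureBundle(
        true_params=params,
        forcing=forcing,
        observations=obs,
        truth=truth,
        seed=seed,
        noise_cv=noise_cv,
    )
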