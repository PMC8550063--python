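# Methods

## Scope and model family

`squidsem` implements three nested annual difference-equation models of
the Mexican Humboldt squid fishery and the analysis pipeline around them:
Monte-Carlo calibration against observed catch/price series, a climate
trend×amplitude sweep, and two development-program experiments.  The
models share a single validated parameter record (`ParameterSet`) so that
a run is fully determined by (parameters, forcing, initial state) and the
nesting relations can be checked exactly.

### Assumptions

* **Population** — a single well-mixed stock with logistic surplus
  production (constant intrinsic growth `r`, constant carrying capacity
  `K`); no age or size structure, no explicit migration.  Catch is
  proportional to catchability × effort × stock and is capped at the
  standing stock so the discrete step can never drive the stock negative.
* **Climate channel** — SST anomalies act only through catchability
  (body-size phenotype), not through biomass.  This follows the acoustic
  evidence that warm-year catch declines reflect a smaller, jig-resistant
  phenotype rather than a smaller stock.
* **Market** — isoelastic demand: price responds instantly to traded
  volume with flexibility `β`.  The BEM/EDM market is in competitive
  equilibrium (fishers receive market price minus processing cost); the
  SEM market is an oligopsony in which cooperating traders pin beach
  prices at an empirical minimum.
* **Behaviour** — effort adjusts to last year's realised profit
  (open-access dynamics); trader cooperation is an instantaneous function
  of the Pacific-landings proportion (see "Design choices").
* **Incomes** — computed from the squid fishery alone: fishers earn beach
  revenue minus effort costs, traders earn the market-minus-beach margin
  net of processing costs, both floored at zero for reporting (the raw,
  possibly negative fisher profit still drives the effort update).

### Annual update order

Within each simulated year: (1) catchability from forcing, (2) harvest
and stock update, (3) market price from realised catch, (4) cooperation
and fishers' price (SEM) or competitive fishers' price (BEM/EDM),
(5) incomes, (6) effort response to realised profit.  Effort reacting to
realised rather than anticipated profit is what makes rising
profitability raise next year's effort.

## Parameters

Defaults are placeholders on a realistic scale for the Gulf of California
fishery (annual catches of tens of thousands of tons, beach prices of a
few thousand MXN/ton); they are meant to be replaced by empirically
estimated constants when available.

| name | default | units | meaning / rationale |
|---|---|---|---|
| `r` | 0.35 | 1/yr | stock growth; sub-MSY harvest at the initial state |
| `K` | 400 000 | tons | carrying capacity |
| `q_max` | 2.5e-5 | 1/(effort·yr) | catchability of the temperate phenotype |
| `k_E` | 5e-7 | effort/MXN | effort responsiveness; slow open-access transient (effort changes by a few hundred units per year at typical profits) |
| `c_E` | 9 000 | MXN/effort/yr | cost per unit effort |
| `p0` | 12 000 | MXN/ton | market price at the reference catch |
| `C_ref` | 50 000 | tons/yr | demand-curve anchor |
| `beta` | 3.0 | – | price flexibility; catch must change substantially before prices do |
| `c_proc` | 1 000 | MXN/ton | processing cost |
| `p_f_min` | 2 000 | MXN/ton | oligopsony beach price (the "everybody knows it will be 5 MXN/kg"-type fixed price, here 2 MXN/kg) |
| `p_f_max` | 45 000 | MXN/ton | empirical ceiling on beach prices |
| `gamma` | 5.0 | – | cooperation decay with Pacific proportion |
| `lam` | 4.0 | 1/degC | Pacific-landings saturation rate above onset |
| `T0` | 0.3 | degC | SST onset of Pacific landings |
| `R_max` | 1.0 | – | Pacific-landings saturation level (exposed, not fixed) |
| `ML_min`, `ML_max` | 20, 120 | cm | tropical / temperate phenotype lengths |
| `ml_slope`, `ml_ref` | −100, 0.3 | cm/degC, degC | size–SST map; catchability reaches zero at +1.3 degC |
| `demand_mult` | 1.0 | – | demand-program lever |
| `coop_cap` | 1.0 | – | cooperation-program lever |
| `eps_catch` | 1.0 | tons | isoelastic evaluation floor (below) |

The onset of cooperation breakdown (`T0`) is aligned with the onset of
the catchability decline (`ml_ref`): in this fishery both are driven by
the same warm-water intrusions, and the alignment is what makes the mean
price gap respond monotonically to a warming trend (the gap would
otherwise dip where warming lowers catch — raising the market price —
before it has begun to erode cooperation).

## Numerical choices

* **Zero-catch price floor** — the isoelastic price diverges as catch →
  0; it is evaluated at `max(catch, eps_catch)` with a 1-ton floor.
  Price predictions at near-zero volumes are not meaningful, and the mean
  price gap excludes years with catch at or below the floor.
* **Clipping** — stock, effort and catchability are floored at zero;
  cooperation lies in [0, 1] by construction; the SEM fishers' price is
  clamped into its empirical bounds and additionally never exceeds the
  competitive level, which keeps the trader margin non-negative.
* **Nesting limits** — "bounds inactive" means `p_f_min = 0`,
  `p_f_max = ∞` (the only non-finite parameter value accepted); with
  `coop_cap = 0` the SEM then reproduces the EDM bit-for-bit.
* **Degenerate inputs** — constant observed series make r² undefined and
  raise; an all-failing Monte-Carlo design raises a calibration-failure
  error with diagnostics rather than returning an empty ensemble.
* **Effort inversion** — the sensitivity mode solves
  `E_t = C_obs,t / (q_t S_t)` exactly each year (0 when the observed
  catch is 0), capped at a configurable maximum; years where the cap or
  the standing stock truncates the realised catch are flagged infeasible.

## Calibration

Uniform independent sampling over per-parameter `(low, high)` ranges
(Latin hypercube available as an option); the default design spans ±40%
around a reference parameter set for the parameters that catch and price
observations can plausibly constrain (`r, K, q_max, c_E, p0, beta,
gamma, lam`).  Each draw is scored by r² of catch and of fishers' price;
the combined score is their unweighted mean, since both variables are
reported symmetrically.  The ensemble mean and 2.5/97.5% bands are
computed over the top decile of draws by combined score (the retention
fraction, and whether bands/means use all draws or the best run, are
options — the choice of retained subset is a convention, not an
inference).

## The synthetic-data generator

The real inputs (official landings and price records for 2001–2016,
satellite SST anomalies, mantle-length measurements) are not bundled.
The generator emulates their statistical structure from known parameters:

* **Calibration fixture** (`default_sst_model`) — a +0.05 degC/yr warming
  trend on a 0.4 degC-amplitude, 6-year oscillation from a cool 1990,
  with 0.08 degC SST noise.  Under the default parameters this yields the
  study-period shape: catches rise to a peak and collapse to under a
  quarter of the peak by the final five years, while fishers' prices are
  pinned at the oligopsony minimum early and rise steeply late as
  cooperation erodes.  Pseudo-observations (2001–2016 window) multiply
  the simulated catch and price by unit-mean lognormal noise with a 5%
  coefficient of variation — catch and price are positive,
  heteroskedastic quantities, and no error model is prescribed by the
  data themselves.
* **Program-experiment climate** (`program_sst_model`) — moderate warming
  (+0.012 degC/yr, amplitude 0.35 degC) under which trader cooperation
  stays high in almost every year and breaks down only episodically at El
  Niño-like peaks.  This is the regime in which the development-program
  comparison is meaningful: fishers' income responds to demand expansion
  only in the episodic high-Pacific-landings years, which is precisely
  the documented contrast with the bioeconomic model.  It also keeps
  catchability positive in every year, making effort inversion well-posed
  over the whole horizon.

What the generator does **not** emulate: reporting artefacts and
underreporting in official landings, intra-annual (seasonal) dynamics,
spatial port structure, serially correlated observation errors, and any
feedback from the fishery onto the climate drivers.  Passing tests
therefore demonstrate that the pipeline recovers known structure from
data *generated by its own model family* — a necessary consistency check
— not that the models describe the real fishery; the published fits to
real records are outside what can be reproduced here.

## Scenario experiments

* **Demand development** — multiplies the demand scale by 1.5 from 2005
  onward (any factor > 1 produces the documented qualitative contrast;
  the magnitude is configurable).
* **Cooperation limitation** — caps trader cooperation at 0.2 from 2005
  onward (configurable).
* **Climate sweep** — a 5×5 grid over trend 0–0.06 degC/yr and amplitude
  0–1.0 degC, other climate fields from the calibration fixture's base;
  each cell records the mean price gap (fishers'/market price over years
  with catch above the floor), mean fishers' income, and the first year
  the annual price ratio exceeds 0.9 ("convergence"; threshold
  configurable).

Problem sizes used throughout the shipped tests and the acceptance
script — 36-year horizons, 2 000–5 000 Monte-Carlo draws, 5×5 sweep
grids — are the package's documented defaults; they are large enough that
the reported ranking and recovery results are stable across seeds.

## Design choices where the design was open

* **Fishers' price form** — "proportional to market price and the level
  of trader cooperation, limited by empirical bounds" admits several
  functional forms; the linear blend between the minimum price (full
  cooperation) and the competitive price (no cooperation) satisfies both
  stated limits and the bounds clause, and is documented as replaceable.
* **Cooperation memory** — cooperation is an instantaneous map of the
  Pacific proportion; a one-year-lag variant is exposed behind the
  `coop_lag` flag.  No relaxation timescale is empirically identified,
  and the instantaneous form keeps the SEM nested exactly inside the
  model family.
* **Trader income accounting** — processing costs are deducted from the
  trader margin (`(p_m − p_f − c_proc)·C`), so the competitive limit
  leaves traders exactly zero margin.
* **Two default climates** — see above; one forcing cannot
  simultaneously exhibit the observed collapse (which requires strong
  accumulated warming) and the program-experiment regime (which requires
  cooperation to remain mostly intact post-2005).
* **Effort responsiveness** — the default `k_E` puts the fishery on a
  slow open-access transient rather than at rent dissipation; with rents
  fully dissipated, income comparisons between programs would degenerate
  (all long-run incomes → 0 regardless of demand).

## Known limitations

* Single stock, single fleet, annual resolution; no spatial or
  size-structured processes.
* The isoelastic market has no demand choke, so simulated market prices
  in near-zero-catch years are orders of magnitude above anything
  observed; all price-based summaries exclude or floor such years.
* The Monte-Carlo filter explores a box prior and reports best-fit and
  ensemble statistics; it is not Bayesian inference and provides no
  identifiability guarantees (the recovery tests show coarse, not
  pointwise, recovery).
* All defaults are scale-realistic placeholders, not estimates; every
  scientific conclusion supported by the package is a statement about
  the model family's structure, not about measured constants.
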