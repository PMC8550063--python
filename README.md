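# squidsem

Nested dynamic models of the Mexican Humboldt squid (*Dosidicus gigas*)
fishery: a bioeconomic baseline, an environment-driven variant, and a
social-ecological model that adds trader-cooperation dynamics — together
with Monte-Carlo calibration, climate and development-program scenario
experiments, and a synthetic-data generator so that the whole pipeline runs
without any external data.

## Who this is for

Fisheries and social-ecological-systems modellers who want a small,
fully-testable reference implementation of how **market power** (an
oligopsony of squid traders fixing beach prices) interacts with
**climate-driven ecology** (warm-water phenotype shifts that reduce
catchability and displace landings to Pacific ports) to shape catches,
prices, and the distribution of income between fishers and traders.

## The models

All three models advance annually.  Stock `S`, effort `E`, catch `C`,
market price `p_m`, fishers' price `p_f`, trader cooperation `c`.

**BEM (bioeconomic baseline)** — discrete Gordon–Schaefer dynamics with
profit-driven effort and isoelastic demand:

    C_t     = min(q E_t S_t, S_t)
    S_{t+1} = S_t + r S_t (1 − S_t/K) − C_t
    p_m,t   = p_0 (C_t / C_ref)^(−1/β)           (β = price flexibility)
    p_f,t   = max(p_m,t − c_proc, 0)             (competitive equilibrium)
    E_{t+1} = max(E_t + k_E (p_f,t C_t − c_E E_t), 0)

**EDM (environment-driven)** — the BEM with catchability forced by SST
anomalies `T_t` through squid body size: mantle length declines linearly
with warming (the large temperate phenotype, 60–120 cm, is replaced by a
small tropical one, 20–40 cm, that jig fishing catches poorly), and

    q_t = q_max (ML_t − ML_min) / (ML_max − ML_min),  clipped to [0, q_max].

**SEM (social-ecological)** — the EDM plus trader dynamics.  Warm
anomalies push a proportion `R_t` of landings to Pacific ports,

    R_t = R_max (1 − exp(−λ max(T_t − T_0, 0))),

new traders entering there break down the price-fixing agreement,

    c_t = coop_cap · exp(−γ R_t),

and fishers' prices interpolate between the empirical minimum (full
cooperation) and the competitive level (no cooperation), clamped into
`[p_f_min, p_f_max]`:

    p_f,t = clamp(p_f_min + (1 − c_t)(p_m,t − c_proc − p_f_min),
                  p_f_min, p_f_max).

The models nest exactly: the SEM with cooperation switched off is the
EDM; the EDM with the temperate phenotype pinned is the BEM.

Calibration is a plain Monte-Carlo filter: parameter vectors drawn
uniformly from per-parameter ranges, each simulated and scored by the
coefficient of determination r² of annual catch and of fishers' price
against observations; the top decile forms an ensemble with per-year
mean and 95% quantile bands.

## Worked example

Calibrate all three models against the default synthetic fixture —
1990–2025 forcing with a warming trend and El Niño-like oscillation, and
noisy 2001–2016 pseudo-observations generated from known
social-ecological parameters:

```python
from squidsem import (default_parameters, default_initial_state,
                      default_fixture, monte_carlo_calibrate)
from squidsem.calibration import default_design

params = default_parameters()
bundle = default_fixture(seed=0, noise_cv=0.05)
design = default_design(params, n_draws=2000, seed=1)
for kind in ("BEM", "EDM", "SEM"):
    res = monte_carlo_calibrate(kind, design, bundle.forcing,
                                bundle.observations,
                                default_initial_state(params), params)
    print(f"{kind}: best r2 catch = {100*res.best_r2_catch:5.1f}%, "
          f"price = {100*res.best_r2_price:5.1f}%")
```

prints

```
BEM: best r2 catch =   8.4%, price =  14.9%
EDM: best r2 catch =  98.8%, price =  53.5%
SEM: best r2 catch =  98.9%, price =  99.6%
```

The ranking is the structural point of the model family: the BEM, blind
to the environment, cannot track the boom and collapse of catches; the
EDM tracks catches but — assuming a competitive market — overestimates
the prices fishers receive; only the SEM, which knows that trader
cooperation suppresses beach prices except in years when landings shift
to Pacific ports, explains both series.

The same pipeline is available from the shell:

```sh
squidsem synth --seed 7 --out fix/
squidsem calibrate --model SEM --forcing fix/forcing.csv \
         --obs fix/observations.csv --n-draws 2000 --out cal/
squidsem scenario --program demand --start 2005 --out scen/
squidsem sweep --trend 0:0.06:5 --amp 0:1:5 --out sweep/
```

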