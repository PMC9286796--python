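# spreadwait

Waiting-time-to-establishment analysis for invasion monitoring data.

When an invasive insect such as the spongy moth (*Lymantria dispar*)
spreads across a landscape, a monitoring quadrat typically passes through
two distinct events: **first detection** (the year the yearly median trap
catch first reaches one moth) and **establishment** (the year the local
population has clearly taken hold).  The years in between — the *waiting
time to establishment* `W = E − D` — measure the local rate of invasion
and, regressed on habitat characteristics, reveal which places are most
vulnerable.  `spreadwait` implements that full analysis chain for
trap-catch monitoring data, plus a synthetic invasion simulator so every
stage can be verified against known ground truth:

1. **Gridding** (`spreadwait.gridding`) — trap-year records to 5 × 5 km
   quadrat series of yearly median catches, after dropping records within
   1.5 km of same-year treatments; inclusion filters remove quadrats that
   never established (< 10 moths total) or were established before
   monitoring began (first record already positive).
2. **Establishment model** (`spreadwait.ffbs`, `spreadwait.establishment`)
   — a Bayesian local-level state-space model per quadrat, fit by a
   forward-filter backward-sample Gibbs sampler on `z = log(1+y)`:

       z_t = mu_t + eps_t,   mu_{t+1} = mu_t + eta_t

   Refit on an expanding window for every target year, it yields the
   posterior predictive probability `p_t` that the year's median catch is
   zero; establishment is the first year at or after detection with
   `p_t < 0.01`.
3. **Design assembly** (`spreadwait.covariates`) — per-quadrat driver
   means (seasonal climate averaged 1995–2015, elevation, host abundance,
   human population, wood use, highways, fragmentation), two background
   variables (year of first detection; mean waiting time of the 3 × 3
   neighborhood) and nested eco-region labels.
4. **Driver regression** (`spreadwait.regression`) — random-intercept
   linear mixed models `W ~ drivers + background + (1 | level-IV
   eco-region)`, maximum likelihood, exhaustive AIC search over all `2^k`
   driver subsets, with VIF and marginal / conditional / driver-only R²
   (Nakagawa & Schielzeth).
5. **Simulator** (`spreadwait.simulate`) — a traveling invasion wave with
   covariate-dependent establishment lags, negative-binomial trapping and
   treatment discs, emitting full ground truth for recovery tests.

## Worked example

The `spreadwait` CLI runs the whole chain on simulated data from a single
seed (stages: `simulate | grid | establish | assemble | regress`):

```sh
spreadwait all --seed 4 --outdir demo
```

```
done: outputs in demo ({'trap_records': 24614, 'treatments': 470,
'quadrats_with_traps': 400, 'included_quadrats': 350,
'analysis_rows': 350, 'models_enumerated': 1024})
```

Of the 400 quadrats in the 20 × 20 grid, 350 turned from uninvaded to
established during 1985–2015 and enter the analysis.
`demo/waiting_time_summary.csv` holds the waiting-time distribution:

```
subregion,n,mean,q25,median,q75
range-wide,350,7.39,5.0,7.0,10.0
central plains,137,6.80,4.0,7.0,9.0
northern mixed wood shield,134,9.17,8.0,9.0,11.0
southeastern forests and plains,79,5.38,4.0,5.0,6.0
```

— a mean wait of 7.4 years range-wide (the simulator's true mean lag is
8).  The exhaustive AIC search over all 1,024 driver subsets
(`demo/r2_summary.csv`, `demo/coefficients.csv`) selects

```
winter_temp+spring_tmax+summer_precip+elevation+wood_use+anthro_frag
r2_marginal = 0.651   r2_conditional = 0.844   r2_marginal_drivers = 0.303
```

with standardized coefficients (yr per sd) `winter_temp −1.84`,
`spring_tmax +0.79`, `summer_precip +0.61`, `elevation +0.68`,
`anthro_frag +0.63` — the generator's true effects are −2, +1, +0.8,
+0.5, +0.6, and the five true-null drivers are all absent except one
small false positive (`wood_use +0.50`).  Colder winters lengthen the
wait; hot springs, wet summers and fragmentation slow establishment.  All
VIFs are below 4 (`demo/vif.csv`), far under the guidance value of 10.

The same pipeline runs on real data by disabling the `simulate` stage and
pointing the config at trap records (`trap_id,x,y,year,count` CSV),
treatment discs (GeoJSON point features with `radius_m`, `year`),
covariate grids (plain-text arrays) and an eco-region label table — see
`spreadwait --help` and `PipelineConfig.from_yaml`.

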