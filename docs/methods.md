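# Methods

## Model structure and assumptions

The simulator tracks sulfur as SO₄-S (mg S per m² ground area) through
five pools — soil solution, foliage, labile organic (ester-sulfate-like),
stable organic (carbon-bonded-like), and adsorbed — plus aboveground
solute stores (canopy, snow) that exist only to route deposition with
water. Assumptions worth keeping in mind:

* **Water controls transport.** All solute movement (canopy throughfall,
  infiltration, bypass, leaching) is slaved to prescribed water fluxes:
  an outflow carries the pool's current concentration. The simulator
  never computes its own hydrology; it consumes a daily forcing table.
* **Steady-state stand.** No tree growth; the only explicit biomass pool
  is seasonal foliage. Uptake not routed to foliage goes straight to the
  soil organic pools, i.e. woody-tissue storage is folded into them.
  There is no retranslocation of S out of leaves before senescence, so
  litterfall S equals foliage S.
* **No canopy exchange.** Dry deposition enters the foliage pool
  directly; wet and fog deposition pass through the canopy water store
  unchanged (no wash-off or foliar leaching).
* **Microbial pools are implicit.** Immobilization moves solution S into
  the labile organic pool at a Michaelis–Menten rate; the microbial
  biomass itself is not tracked.
* **Environmental scaling is multiplicative**: every microbial rate is
  `base rate × resp_Q10(T) × resp_θ(θ)`, with resp_Q10 = 1 at the 8 °C
  base temperature and resp_θ a trapezoid over four moisture thresholds
  (zero when dry or waterlogged, a plateau at intermediate moisture).

## Parameters

The 25-odd site parameters (deposition enrichment factors, moisture
thresholds per process, half-lives, Michaelis constants, uptake demand
thresholds, routing fractions, Langmuir constants) are documented on
`ParameterSet`; the shipped `exelberg.params` and `jubilaeumswarte.params`
files hold the calibration results for the two monitored beech stands.
Fixed constants: base temperature 8 °C; response floor/ceiling 0/1;
rooting depth `z_r = 500 mm` (the depth over which the solution pool is
mixed — not separately calibrated, configurable); half-life years are
converted at 365.25 d/yr.

Two quirks of the shipped reference values matter for interpretation.
First, the plant-uptake maximum rates (0.11 / 0.07 mg m⁻² d⁻¹) are so
small that the annual-demand thresholds (≈1.1–2.2 g m⁻² yr⁻¹) can never
be reached; the demand-throttling Smoothstep is therefore inert at these
values (it is exercised in tests with synthetic parameters). Second, the
documented 1770 pool initializations are far larger than any equilibrium
those rate constants can sustain; the packaged scenario instead
initializes at its own pre-industrial equilibrium (below).

The concentration-dependent labile half-life (sulfatase release under S
starvation, pinned at 0 and 10 mg/L) is implemented behind
`sulfatase_enabled` and off by default: a constant half-life describes
the reference stands adequately.

## Numerical scheme

Classical RK4 with a fixed one-day step. Within a day the forcing is
piecewise-constant, and the water-driven solute fluxes (infiltration
input, leaching) plus litterfall and the uptake V_max are frozen at
their day-start values; only the concentration-dependent rates vary
across RK4 stages. The daily flux ledger is accumulated with the same
RK4 stage weights `(k₁+2k₂+2k₃+k₄)/6` as the state update, which makes
the mass balance close to machine precision by construction (the audit
on the 330-year scenario reports a relative closure error of ~10⁻¹⁶).
A nonnegativity guard clips pools after each step and logs the clipped
mass; with the shipped parameter sets it never triggers beyond rounding
(≲10⁻¹⁵ mg over 330 years) because leaching is bounded by the day-start
store and all other sinks vanish with their driving pool. Leaching uses
`min(percolation/(z_r·θ), 1)` so a single day cannot export more than
the store. The accumulated-uptake counter resets every January 1.

An independent 100-substep Euler integration of the same rate laws
(assembled in the test suite, not shared with the integrator) agrees
with the daily RK4 to better than 0.1% in every pool over a synthetic
year.

## Synthetic forcing

`generate_synthetic_forcing` emulates the study conditions of a Vienna
Woods beech stand: 660 mm annual precipitation (each year scaled
exactly), sinusoidal soil temperature with 8 °C mean and 7.5 °C
amplitude plus daily noise, a bucket water balance (field capacity
0.30 L/L over a 500 mm rooting zone, excess drained at 30%/day, 10%
bypass on >15 mm days) that produces winter-high/summer-low soil
moisture and winter-dominant percolation, a deciduous leaf-area cycle
with Smoothstep leaf-out (DoY 110–140) and autumn decline (DoY 270–300),
Poisson fog episodes in late autumn (≈6/yr, mean 1.5 mm), and SO₂/wet
deposition scaled by a year-indexed emission multiplier (piecewise
linear: near-constant pre-1880 background ≈0.15, peak ≈2.3 around 1980,
decline after 1987, constant ≈0.29 after 2030; normalized to mean 1 over
1988–2012). At multiplier 1 the SO₂-S level is 0.004 mg/m³ and wet
deposition carries 0.9 mg S per mm of rain — magnitudes chosen once to
match reported deposition histories for the region.

Years before 1880 repeat a single climatological weather year (the
stochastic draws start with the emission rise), so the spin-up era is
cyclo-stationary and a true steady state exists. What the generator does
**not** emulate: snow, storm-scale structure, interannual climate
trends, drought years, or any covariance between fog and synoptic
weather. Passing tests on this forcing demonstrate the simulator's
internal consistency (conservation, steady state, trajectory shape,
recoverability of parameters), not fidelity to any real stand.

The packaged reference scenario (`scenario.py`, seed 42, Exelberg
parameters) initializes pools at the pre-industrial equilibrium obtained
by cycling the pre-1880 forcing to convergence (`equilibrium_spin_up`);
the values are frozen in the module so the scenario is cheap to
construct. On this scenario the total soil S stock is steady before 1880
(drift < 0.1%/yr per pool, measured on 4-year block means — year-end
comparisons alias the leap-year calendar), rises through the 20th
century, peaks shortly after 1980 and declines after 2020 without
returning to the pre-industrial level by 2100.

## Calibration

`anneal` maximizes the Nash–Sutcliffe efficiency of simulated vs
observed soil-solution concentrations sampled on the observation dates
(snapshot semantics, no interval averaging). Proposals are Gaussian with
sigma = 5% of each parameter's bound width, reflected into the bounds;
acceptance is Metropolis on the NSE difference with geometric cooling
(defaults: T₀ = 0.02 NSE units, factor 0.90, 25 proposals per
temperature, 24 temperatures). Temperature 0 degenerates to greedy hill
climbing. The best-ever point is returned, so the result can only
improve along the trace. Three target criteria summarize a run
(`evaluate_targets`): steady state before 1880, total soil S at the
survey year within a configurable ±35% of the measured stock, and NSE
above a configurable floor.

The self-consistency experiment (observations generated by the model
itself over a 5-year window) frees six parameters chosen for distinct
dynamical fingerprints — fog enrichment, the three sorption constants,
and the immobilization amplitude and Q10 — with bounds 0.5–2× the
reference values. Organic-pool half-lives are deliberately not freed:
immobilization and re-mineralization of the labile pool compensate each
other almost exactly on this timescale, so those directions of parameter
space are flat at NSE ≈ 0.9999 and no optimizer can pin them down; even
within the chosen set, the Langmuir capacity/affinity pair forms a mild
ridge that occasionally absorbs most of the residual error. Median
behaviour over five annealing seeds is therefore the reported statistic
(~2 700 model runs, well under a minute).

## Known limitations

* Daily resolution: within-day deposition/leaching pulses are smeared.
* The foliage pool ignores retranslocation, so simulated litterfall S
  overestimates what a real stand sheds.
* Bypass flow exports infiltrating solute without contacting the soil
  solution; whether that matches a given site's macropore behaviour is
  an open question (configurable in principle via the forcing split).
* Identifiability: many parameter configurations fit a short
  concentration record equally well; the calibrator finds *a* good set,
  not *the* set.
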