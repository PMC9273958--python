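# Model description and design notes

## Individual model

The energetics of one fish follow the standard abj dynamic energy budget:
a reserve pool E (J) is filled by assimilation and mobilised at rate

    p_C = E ([E_G] v̇_eff / L + [p_M]_T) / ([E_G] + κ E / L³),

of which the fraction κ pays somatic maintenance [p_M]_T·L³ first and
builds structure (dL/dt = max(κ p_C − p_S, 0) / (3 L² [E_G])); the
complement pays maturity maintenance k_J·E_H and accumulates maturity E_H
until puberty, afterwards a reproduction buffer E_R.  Embryos do not feed;
their initial reserve E_0 is fixed by bisection so that the scaled reserve
density e = E v̇ /(L³ {p_Am}) at birth equals the mother's functional
response f.  Metabolic acceleration multiplies both {p_Am} and v̇ by
s_M = L/L_b between birth and metamorphosis (frozen at L_j/L_b after);
this variant was selected because it reproduces the published
length-at-stage and timing predictions of the packaged parameter set to
better than 0.2% (lengths) and 0.3% (time to puberty).  The maximum
assimilation rate is derived from the zoom factor as {p_Am} = z·[p_M]/κ,
so the unaccelerated maximum structural length is L_m = z cm.

Temperature enters through the five-parameter Arrhenius correction with
tolerance boundaries (T_L = 278 K, T_H = 297 K); every rate, including the
Weibull ageing acceleration (corrected by the square of the factor, so a
whole trajectory is the reference trajectory on a rescaled clock), is
specified at T_ref = 293.15 K.  Table rates in this package are all per
day; lengths are structural cm unless labelled preanal (L/δ_M).

**Weight convention.** Dry weight counts structure at d_V = 1 g cm⁻³ and
the reserve pools as fixable biomass at the accelerated reserve capacity:

    W_d = d_V L³ + κ_R · s_M · (E + E_R) / e_j.

The κ_R·s_M factor is the mass basis under which the packaged parameter
set reproduces the published weight-at-stage calibration for this stock
(73.4 g at puberty, ≈5.3 kg asymptotic, gonado-somatic index ≈0.05); the
plain conversion E/e_j would undershoot those values by roughly a third.
Weight at birth is not reproducible under any single convention and is
reported as computed.  A configurable dry:wet factor (default 1) maps
model weight onto survey weight.

**Starvation.** When the κ-share of mobilisation cannot cover somatic
maintenance, the deficit is paid from the reproduction buffer, then from
reserve; structure is never resorbed, and an individual whose reserve is
exhausted dies (the whole cohort, in the population model).  An earlier
all-or-nothing variant (death as soon as the buffer was empty) produced
violent winter boom-bust cycles and stochastic extinctions; drawing down
reserve first is the usual no-shrinking convention and stabilises the
seasonal dynamics.

**Integration.** Population runs use explicit Euler at dt = 1 h, the
scheduler's native step; trait prediction and the test oracles use an
adaptive Runge-Kutta integration with event detection at the maturity
thresholds (rtol 1e-9), against which the Euler path agrees to <1% over a
year.  The ageing ODE pair (q̈, ḣ) is integrated only for the life-span
trait (age at which survival falls to 1/e); population-level ageing
mortality uses the linear hazard below.

## Trait layer

`predict_traits` maps a parameter vector to the eleven zero-variate traits
(ages, preanal lengths and dry weights at birth/puberty, asymptotic size,
life span, maximum reproduction rate, GSI).  Length and weight traits are
temperature-independent; times are reported at T_ref because the
evaluation temperatures behind the published time-based values are not
recoverable.  The estimation loss is the multiplicative symmetric bounded
form (squared deviations normalised by the sum of squared dataset means),
with default weights 1/n_i per dataset; goodness of fit is the weighted
mean relative error (MRE) and the symmetric mean squared error (SMSE,
bounded in [0,1] for non-negative data).  Calibration runs Nelder-Mead on
log-parameters (positivity for free), is deterministic, and recovers two
free parameters from a 10% perturbed start to within 2% on synthetic
truth.  The published overall MRE = 0.128 / SMSE = 0.143 additionally used
univariate datasets (growth, fecundity, length-weight series) that were
never published, so they cannot be recomputed here; the package's report
covers the zero-variate block.

## Population model

Cohorts are deterministic super-individuals (hatching success and
mortalities act as fractions, not draws), stored column-wise and advanced
in lock-step by a compiled kernel that mirrors the per-cohort operations
exposed in the API.  Stage assignment of mortalities: eggs-larvae receive
egg predation and background mortality; juveniles add density-dependent
mortality and (above the length at first capture) fishing; adults add the
ageing hazard.  Spawning occurs once per simulated day inside the
day-of-year window 105–288 when temperature exceeds 14 °C: each female
sheds floor(κ_R E_R / E_0) eggs, all eggs of one day forming one cohort.
Egg provisioning uses E_0 at f = 1 regardless of the mother's current
feeding level (no maternal effect).  Cohorts below 10⁻³ individuals are
pruned.  The calendar has 365-day years; day-of-year is 1-based.

Initial seeding grows individuals to 0.5/1.5/2.5 years at constant
moderate food and abundances totalling a standing stock of order 10³–10⁴
kg km⁻²; after the 5-year spin-up the population state is set by the
forcings, not the seeding.

## Synthetic study conditions

The forcing generator emulates the hairtail's habitat:

* **Temperature** — mean 21 °C, seasonal amplitude 6 °C (August maximum),
  i.e. a 15–27 °C envelope; warming trend 0.02 °C y⁻¹; AR(1) daily
  anomalies (sd 0.4 °C, autocorrelation 0.95).  With this envelope the
  annual-mean Arrhenius factor declines strictly across the +1.4/+2.7/
  +4.4 °C scenario offsets (0.849 → 0.840 → 0.814 → 0.759), because summer
  temperatures are pushed past the upper tolerance boundary — the
  mechanism behind the monotone biomass decline under warming.
* **Food** — a 12-value monthly profile peaking in autumn and lowest in
  winter, lognormal interannual scaling (sd 0.10), mapped to the
  functional response by f = food/(food + K_food).
* **Rivers and rain** — annual Gaussian draws around a Yangtze-scale mean
  flow (9×10¹¹ m³, sd 8×10¹⁰) and 1.1 m rainfall (sd 0.15 m), entering
  the background mortality through the anomaly indices.
* **Fishing** — piecewise-constant annual mortality around 0.0055 d⁻¹
  (≈2 y⁻¹, the heavily exploited regime), lognormal interannual variation
  (sd 0.10), applied to fish above 10 cm preanal length (trawl-like
  selectivity).

**Calibration of the food level.** K_food = 2.4 gives a long-term mean
f ≈ 0.28.  This is deliberately food-limited: with the packaged mortality
coefficients, fecundity at near-satiating food exceeds — by two orders of
magnitude — what the saturating density-dependent terms can remove, so no
stationary population exists there.  Scanning K_food showed a regulated
window (K ≈ 2.2–2.8) between unbounded growth and extinction; K = 2.4
yields a stationary, density-regulated stock of order 10⁴ kg km⁻² across
seeds, with a recruited-stock mean age ≈1.4 y, dominated by one-year-old
fish.  The price is slower-than-observed individual growth (length at age
1 ≈ 11 cm preanal versus ≈19 cm in surveys): the published mortality
coefficients cannot balance realistic growth and a stationary stock
simultaneously, and this package resolves the tension in favour of
regulated population dynamics, which the scenario analysis requires.
Passing tests therefore demonstrate internally consistent, directionally
correct population behaviour under these synthetic conditions — not a
reconstruction of the historical 1965–2007 series, whose forcings were
never published as data.

## Numerical and degenerate-input choices

* Euler steps that would drive reserve negative outside the starvation
  regime raise an error recommending a smaller dt.
* The background mortality is clamped at zero for strongly positive
  flow/rain anomalies (no resurrection).
* Hatching requires both the degree-day threshold and maturity at birth;
  an egg cohort that reaches maturity first simply waits (no feeding)
  while continuing to experience egg predation.
* Maturity never decreases (no rejuvenation); maturation stalls when the
  1−κ flux cannot cover maturity maintenance.
* An extinct population keeps emitting zero-valued records with a logged
  warning rather than aborting the run.
* Annual fishing mortality expands piecewise-constant within calendar
  years by default; midpoint-linear interpolation is available.

## Problem sizes used by the shipped analyses

The scenario battery runs five forcing seeds × six runs of 8 simulated
years (5-year spin-up, 3-year evaluation window) at the native hourly
step; the trait solvers work at adaptive tolerance on a single individual.
The acceptance script recomputes only the deterministic trait block, which
takes seconds.

## Known limitations

* Not spatially explicit; no migration, no size-structured food.
* Food is forced, not dynamic: no feedback from stock to prey, so density
  regulation rests entirely on the published mortality terms.
* The food index → functional response mapping (K_food) and the spawning
  window/temperature defaults are package choices, documented above, not
  published values.
* Ocean acidification and other climate stressors beyond temperature are
  out of scope.
* Weight at birth and the absolute scenario percentages are not
  reproducible from published information; only directions and orderings
  are asserted.
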