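# Methods

## The ecosystem model

The P–Z–F–O system treats the pond as a three-level trophic chain
(phytoplankton → zooplankton → fish) coupled to a single well-mixed
oxygen pool. Its assumptions:

* **Logistic phytoplankton growth** toward carrying capacity K, grazed by
  zooplankton through a Michaelis–Menten (type II) functional response
  with half-saturation hP; zooplankton eaten by fish the same way (hZ).
* **Linear mortality** for all three biomasses; assimilation efficiencies
  eZ, eF convert consumed biomass up the chain.
* **Oxygen balance**: photosynthetic production proportional to P
  (coefficient aP), community respiration proportional to total biomass
  (bR), and surface reaeration relaxing O toward the saturation level at
  rate k2. Saturation is linearised around 20 °C,
  `Osat(T) = Osat_base·(1 − 0.02·(T − 20))`, valid for 0–40 °C (enforced).
* **Temperature forcing** is an externally prescribed sinusoid
  `T(t) = T_mean + A·sin(2πt/period + phase)`. The biological rates are
  *not* temperature-dependent at this modelling stage; temperature enters
  only through Osat. Phase 0 is the only form consistent with a mean of
  18 °C, amplitude 8 °C and stated extremes of 10 and 26 °C; the phase is
  configurable.

Parameter defaults are the typical literature values for temperate ponds
(all rates per day, biomasses g/m³): rP=0.8, K=5.0, gZ=0.6, gF=0.3,
hP=0.5, hZ=0.3, eZ=0.4, eF=0.3, mP=0.1, mZ=0.08, mF=0.05, aP=0.3, bR=0.1,
k2=0.15, Osat_base=9.1 mg/L. A validator rejects values outside the
normal ranges unless explicitly overridden. The worked 50-day "bloom
scenario" (`pondwatch.synth.reference_scenario`) overrides Osat_base to
10 mg/L.

### Integration

Fixed-step classical RK4 with dt = 0.01 day by default. After every step
the state is clipped to the physically valid region (components ≥ 0).
Rationale for a hand-stepped fixed-step scheme rather than an adaptive
library solver: bit-reproducible trajectories for a fixed configuration,
and the EKF prediction needs the same substep positions to compose its
transition matrix. Halving dt changes the 50-day reference trajectory by
less than 1e-5 in sup-norm (tested), so the default step is well inside
the convergent regime.

Note a dynamical property of this parameterisation that matters for
interpretation: the deterministic bloom collapses through a deep
phytoplankton crash (P ~ 2e-4 g/m³ near day 30), so the timing of the
*second* bloom is controlled by the depth of that crash and is extremely
sensitive to any floor effects. With the scenario's process noise the
crash bottoms out near the noise floor instead, and the recovery time
becomes a wide random variable. The bloom onset (≈ day 3) and first
collapse (≈ day 16) are robust; the second onset is not a reliably
predictable quantity under this model.

## Synthetic data generator

`simulate_truth` advances the deterministic dynamics between sample times
(4 RK4 substeps per hourly sample by default) and, when `process_std > 0`,
adds an independent zero-mean Gaussian perturbation with that standard
deviation to *every* state component at *every sampling step*, then
re-projects to the valid region. "Noise 0.02" is thus a per-step standard
deviation, the same convention as the 0.08 mg/L DO measurement noise.

Sensor rendering: hourly DO plus Gaussian noise; temperature copied
noise-free (temperature sensors are an order of magnitude more precise
than the dynamics care about); chlorophyll every 3 days from the
effective-biomass proxy plus its own noise; optional symmetric ±magnitude
outlier spikes with a given per-sample probability. Every stochastic
operation is a pure function of (inputs, seed).

What the generator does **not** emulate: sensor drift and fouling, diel
photosynthesis cycles within the oxygen balance (the model's DO varies on
the forcing timescale, not hour-by-hour with light), transport losses,
and spatial heterogeneity. Tests passing on this generator therefore show
the estimation and decision machinery is correct *given the model class*,
not that the model class captures every feature of a real pond.

## The constrained adaptive EKF

Cycle per DO record: predict → physical check → χ² gate → update →
projection → noise adaptation.

* **Prediction.** The estimate is propagated by RK4 substeps (4 per
  sampling interval). The discrete transition matrix is composed as
  `F1 = Π_j (I + J(x_j)·h)` with the Jacobian evaluated along the
  propagated state; covariance `P ← F1·P·F1ᵀ + Q`, symmetrised.
* **Gate.** `D² = Y²/S` against the χ² quantile at level 0.90 with one
  degree of freedom (2.7055). Rejected measurements are skipped —
  prediction-only step, and the decision layer can fall back to the
  simple trend prognosis. A measured DO outside [Omin, Omax] (e.g.
  > 20 mg/L) is rejected on physical grounds before the gate.
* **Projection.** After each accepted update the state is clipped to
  `P,Z,F ≥ 0`, `Omin ≤ O ≤ Omax` (defaults 0 and 20 mg/L).
* **Noise initialisation.** `R0 = meas_std²`; Q0 diagonal with
  `q_ii = (α_i·Ximax_i·Δt)²`, α_i = 0.1 (validated to 0.05–0.15), uniform
  Ximax = 5 — the carrying-capacity scale for the biomasses and the
  few-mg/L scale of daily DO excursions. With Δt = 1 h this puts q_ii
  within 10% of the generator's true per-step process variance.
* **Adaptation.** Exponentially forgetting innovation variance
  `Ĉ ← (1−λ)Ĉ + λY²` (λ = 0.05), then `R ← max(Ĉ − H·P⁻·Hᵀ, R_floor)`
  using the *prior* covariance (the innovation decomposition
  `S = H·P⁻·Hᵀ + R` holds for the prior; using the posterior
  systematically underestimates R and was observed to destabilise the
  filter). Q is Q0 scaled by a smoothed, clipped ratio of observed to
  model-implied innovation variance, bounded to [0.1×, 10×] — smoothing
  the clipped instantaneous ratio, not the raw one, prevents single large
  innovations from swinging Q.
* **R floor = (0.05 mg/L)².** Optical DO probes do not resolve better
  than ~0.05 mg/L, so adaptation is never allowed to trust the sensor
  beyond that physical bound. Without the floor, R collapses during
  quiescent stretches, the gains on the weakly observed states explode
  through the cross-covariances, and the filter can lock onto a wrong
  branch of the dynamics.
* **Rejection-streak recovery.** After 5 consecutive rejections the
  covariance is inflated by 1.2 per further rejected step. A sustained
  rejection streak signals model mismatch (regime change), not outliers;
  without inflation the innovation variance stays bounded while the
  mismatch does not, and the gate locks the filter out permanently.
* **Covariance ceiling.** Diagonal entries are capped at `(2·Ximax_i)²`
  (rows/columns rescaled jointly, preserving positive semidefiniteness).
  Uncertainty larger than the squared physical range of a state carries
  no information and only produces destabilising gains.

**Initial covariance.** The default P0 is a field-start prior:
`(0.5·Ximax)²` for P and Z, four times that for the weakly observable F,
and the measurement variance for the directly observed O. When the
initial state is actually known (simulation experiments; a freshly
stocked pond with stocking records and a first DO reading) declare
`p0_diag` in the filter config — the benchmark runs use
`[0.01, 0.01, 0.01, meas_std²]`. Known limitation: under the large
field-start prior the filter can take physically implausible excursions
on some noise realisations before settling, because the DO record alone
cannot immediately distinguish biomass configurations with similar oxygen
budgets; the uncertainty it reports during that phase is honest, but the
point estimates are not trustworthy until the covariance contracts.

**Diagnostics.** State RMSE is the root mean squared Euclidean norm of
the per-step state error (per-component variants available). The
stability index `SI = 1 − mean_i(s_i/m_i)` (per-component std over mean
across a window) is exposed with a guard against near-zero means.

## Observability

With only DO measured, local observability is assessed from the gradients
of successive Lie derivatives of h(X) = O along the dynamics: row 0 is
`[0,0,0,1]`, row 1 is the oxygen-balance gradient
`[aP−bR, −bR, −bR, −k2]`, rows 2–3 contain the nonlinear couplings.
Gradients are generated once by exact symbolic differentiation (sympy)
and lambdified; third-order finite differences are too noisy for rank
decisions, so the numeric route exists only as a cross-check. Temperature
is frozen during differentiation (Osat is constant w.r.t. the state).
Rank uses a relative singular-value cutoff of 1e-8. Reports always name
their evaluation state — the rank claim is local and fails at the trivial
equilibrium. The F-column/P-column norm ratio across the stacked
gradients quantifies how much more weakly fish biomass drives the output;
on the standard run the filter's steady-state posterior std of F exceeds
those of P and Z, the practical face of the same structure.

## Indirect observations

`Cchl = kchl·(P − αZ)` and `S = cS·(P − αZ)` link the sparse chlorophyll
and Secchi channels to the effective phytoplankton biomass. The defaults
kchl = 4 µg/L per g/m³ and α = 0.3 are simulation placeholders — both
depend on pond morphometry and must be calibrated per site (the package
warns when the defaults are used). Negative effective biomass is floored
at zero; the proxy is not calibrated in the over-grazed regime. The sign
and units of cS are deliberately left as a signed linear coefficient:
clarity read as disk depth *increases* as biomass falls, so a negative cS
is the natural calibration in those units. Chlorophyll records never
enter the EKF measurement vector during normal operation; they serve
initialization (`init_state`: P0 from the proxy, Z0/F0 from stocking
records, O0 from the first DO reading or Osat) and adequacy checking.

## Trend layer and decisions

* **Outlier elimination**: absolute band plus the isolated-spike rule (a
  point whose difference to *both* neighbours exceeds the threshold;
  endpoints use their single neighbour). Chosen over statistical or
  cluster methods because it needs no training data and runs on a
  microcontroller-class budget.
* **Median-filter cleaning** (for the offline pipeline): points deviating
  from their centred rolling median by more than 3 rolling median
  absolute deviations are replaced by linear interpolation.
* **Segmentation**: day is [06:00, 21:00), inclusive start — DO and pH
  rise through the day and fall at night, so each segment is close to
  monotone and the three curve families fit well.
* **Fitting**: linear and cubic by ordinary polynomial least squares;
  exponential by log-linearisation (deterministic, adequate on monotone
  segments; requires positive data). Fit quality is the Pearson
  correlation between fitted and observed values; below r_min = 0.85
  (accepted band 0.8–0.9) the forecast is discarded. When no family is
  specified all three are fitted and the highest r wins, ties broken by
  simplicity.
* **Time-to-critical**: closed form for linear/exponential; for the cubic,
  dense sampling over the horizon brackets the first sign change and
  Brent's method refines it. Lead time is measured from the last data
  point ("now"), and action is initiated only when lead < preset margin
  (default 4 h, within the recommended 3–5 h).
* **Event resets**: after pond-altering events (chemical treatment,
  aeration, heavy rain, fish transfer) all earlier points are dropped
  from the fitting window.
* **Species thresholds**: built-in winter DO limits per species
  (respiratory-depression range and death level; range endpoints use the
  conservative upper value), pH band 6.5–8.5 (8.0 upper for salmonids),
  surface/bottom pH ratio limit 1.05, bloom threshold P > 2.5 g/m³, fish
  danger F < 0.1 g/m³, and the surface-DO ≥ 10 mg/L unmixed-column
  warning.

## Problem sizes

The benchmark experiments use 30-day hourly runs (721 records) for
filtering and 50-day runs for the bloom scenario; the RMSE-reduction
benchmark averages 20 seeded replicates and the DO-envelope estimate 16
(single-run extremes under the scenario's process noise spread by
±1.5 mg/L seed-to-seed, so the replicate mean is the stable estimator).
These sizes put every property being measured well past its transient
while keeping a full test run in the order of a minute.

## Known limitations

* Biological rates are temperature-independent; only Osat carries T.
* The DO-only filter cannot separate biomass configurations with equal
  oxygen budgets on short windows — F especially is recovered as a trend,
  not an instantaneous value.
* The adaptive Q/R scheme is one standard choice (innovation-based,
  exponential forgetting); it tracks slow seasonal drift, not abrupt
  sensor faults, which are the gate's job.
* Exponential fits are biased for noisy data near zero (log-linearisation
  weights small values heavily); acceptable on the segments used.
* The second bloom onset of the reference scenario is intrinsically
  noise-dominated (see Integration above) and should not be used as a
  validation target.
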