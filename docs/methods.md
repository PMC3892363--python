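# Methods

`mesoflux` estimates the carbon balance of small vegetated mesocosms from
automated closed dynamic chamber CO₂ measurements, and validates the whole
estimation chain against an independent carbon-stock inventory on a
synthetic mesocosm whose bookkeeping is exact by construction. This note
describes the models, the estimation procedures, the simulator, and the
numerical and design choices, in that order.

## 1. Chamber flux estimation

A closed dynamic chamber sealed over a collar accumulates (or draws down)
CO₂ in its headspace; the flux is inferred from the rate of concentration
change. For each closure the package fits an ordinary-least-squares line to
the 1 Hz CO₂ series over the half-open window

    [deadband, deadband + window),   window = 90 s by default,

and converts the slope *m* (µmol mol⁻¹ s⁻¹) to an areal molar flux with the
ideal-gas headspace equation

    F = m · P·V / (R·T·A)   [µmol CO₂ m⁻² s⁻¹],

with P the pressure (Pa), V the system volume (chamber + collar headspace +
tubing, m³), T the air temperature (K), A the collar area (m²) and
R = 8.314 J mol⁻¹ K⁻¹. Signs follow the micrometeorological convention:
positive = release to the atmosphere.

The dead band discards the initial mixing period. Opaque chambers need a
longer one (50 s vs 20 s by default) because photosynthesis continues
briefly after darkening, biasing the early slope low. Both dead bands, the
window, and the per-trace geometry (V, A, T, P) are configuration, not
constants: automated multiplexed systems adjust volumes per collar.

Assumptions: the headspace is well mixed after the dead band; the
concentration rise is linear over 90 s (no saturation or leak curvature);
the analyser reports dry mole fractions (water-vapour dilution is handled
upstream). Fit failures (too-short traces, too few samples) propagate as
explicit missing fluxes, never as silent zeros.

Quality control attaches flags without deleting records: `night` (outside
PAR below 5 µmol m⁻² s⁻¹), `rain` (rainy hour in the environment log), and
`poor_fit` (r² < 0.75, applied only when |slope| exceeds a noise floor of
0.005 ppm s⁻¹ — a genuinely tiny flux produces a legitimately flat, low-r²
trace). Each analysis chooses which flags to honour: light-response fitting
excludes all three; budget integration uses every available flux, because a
budget cannot drop rainy hours.

Hourly cycles pair each transparent closure (NEE) with the opaque closure
(ecosystem respiration, R_eco) that follows it in the same collar-hour;
GPP = R_eco − NEE ≥ 0 under the sign convention.

## 2. PAR-attenuation correction of transparent-chamber NEE

The transparent lid transmits a fraction τ of ambient PAR, so measured
daytime NEE underestimates uptake. The correction has three parts.

**Transmission.** τ is the through-origin least-squares slope of inside on
outside PAR over all daytime pairs: a lid transmits a fraction of incident
light, so an intercept is physically meaningless. With a 0.66 lid the
attenuation is 34%.

**Light response.** NEE uptake (−NEE, stored positive) is regressed on
ln(PAR) over daytime, rain-free, well-fitted transparent records:
uptake = a·ln(PAR) + c. A rectangular hyperbola
uptake = A_max·PAR/(k + PAR) is available but is not the default (it does
not fit these data better). The fit window defaults to the established-plant
period (1 Dec onward): fitting through the autumn growth transient biases
the slope low because uptake amplitude is still rising.

**Offset.** The correction is the offset between the light response
evaluated at ambient and at chamber PAR,

    Δ(PAR) = f(PAR/τ) − f(PAR),

which for the log form is a·ln(1/τ), the same at every PAR. It is added as
uptake (flux − Δ) to every lit transparent record from the net-uptake onset
date (21 Nov by default) onward. Because the log-form offset is
PAR-independent, eligibility defaults to PAR > 0 rather than the night-flag
threshold: dim dawn/dusk records carry the full loss, and excluding them
leaves a systematic under-correction. Both the directly measured inside-PAR
and the reconstructed τ·(outside PAR) can drive the correction.

**Scope.** By default each collar gets its own light-response fit (the
synthetic observing system records inside-PAR at every chamber), so the
correction scales with replicate photosynthetic amplitude; without this, a
single plot-level offset compresses between-collar flux variation by the
chamber-GPP share (~20%) and the ensemble flux-vs-stock slope cannot reach
1. `light_response_scope="plot"` restores the single-model procedure of a
system with one central PAR sensor pair; the plot-level fit is always
computed and reported, and serves as the fallback for collars with too few
usable records.

The PAR compensation point implied by the fitted regression is not reported
as a headline quantity: a log-form uptake model crosses zero at
PAR = exp(−c/a), which conflates respiration (in c) with the light response
and is sensitive to the fit window; consumers who need it can evaluate the
fitted model directly.

## 3. Respiration temperature sensitivity and partitioning

Ecosystem respiration is modelled exponentially, R = a·e^(bT); the fit is
ordinary least squares in log space, ln R = ln a + b·T, and the temperature
sensitivity is reported as Q₁₀ = exp(10·b) with its standard error by
first-order propagation, SE(Q₁₀) = Q₁₀·10·SE(b). Log-space OLS (rather than
nonlinear least squares) is the default because it is closed-form,
reproducible, and testable against independent normal-equation oracles; a
nonlinear fit of the same model changes the weighting of large fluxes, not
the model. Non-positive fluxes cannot enter a log fit; they are excluded
and counted. Fits are made per developmental stage (S1 bare soil, S2
germination, S3 seedling, S4 established plants), with a boundary date
belonging to the stage that starts on it.

The temperature driver is selected by the Pearson correlation between
ln R_eco and each candidate (chamber air, soil surface, 2 cm, 5 cm),
candidates from the records taking precedence over the environment log.
With multiple collars ln R is centred per collar first (a collar fixed
effect); otherwise replicate level differences drown the temperature
signal. Ties break toward the first candidate in the given order. In both
the simulated and the real system the bare-soil stage tracks deep soil
temperature while vegetated stages track chamber air temperature.

Daytime suppression of dark respiration is estimated by adding a day
indicator to the same log-linear model,

    ln R = ln a + b·T + γ·1[day],

so exp(γ) is the day:night respiration ratio at equal temperature; values
below 1 indicate suppression. Day/night labelling uses PAR, not clock time.
Note the estimand: exp(γ) is the suppression of *total* dark respiration.
When heterotrophic respiration (not suppressed) contributes a share w of
R_eco, exp(γ) ≈ s + w·(1−s) for an autotrophic suppression factor s — the
estimator is only a direct estimate of s when the heterotrophic share is
negligible, which is how the parameter-recovery experiment is configured.

## 4. Carbon budget closure

Two independent estimates of each mesocosm's net carbon balance, both in
g C, negative = net gain:

* **Flux balance** — the cumulative sum of hourly corrected NEE fluxes:
  Σ_h F_h × 3600 s × 12.011×10⁻⁶ g µmol⁻¹ × A. A plain hourly sum (not
  trapezoidal): each closure already stands for its hour. Missing hours are
  linearly interpolated up to a 3 h cap; lower coverage is an error, not a
  guess. Before the transparent chambers started (bare soil), the opaque
  flux stands in for NEE — there is no photosynthesis to miss.
* **Stock balance** — the inventory combination
  −(ΔC_soil + C_shoot + C_root + C_DOC − C_seed), where ΔC_soil is
  final − initial soil carbon and the leading minus sign puts the result on
  the flux scale.

DOC bookkeeping deserves care. Leached DOC is carbon the chambers never
see. Under exact conservation, C_seed − ∫NEE − C_DOC = ΔC_soil + C_shoot +
C_root, and substituting into the stock combination shows the +C_DOC term
cancels the leaching loss exactly: the inventory estimates the same
quantity the chambers integrate. That is why C_DOC appears inside the stock
balance but is *not* also added to the flux side — doing both would count
the same grams twice and offset the two estimates by exactly C_DOC. The DOC
term (Σ volume × concentration × 10⁻³ g) is reported as a budget component.

The ensemble comparison reports per-collar differences, the paired mean
difference with its t statistic, the RMSE about the 1:1 line, the OLS slope
and intercept of flux on stock, group means ± SD, and one-way ANOVA F
across treatment groups for each balance type.

## 5. The synthetic mesocosm

The simulator generates everything the observing system would have
recorded, with carbon conservation enforced exactly, so the estimation
chain can be validated against a known truth.

**Environment.** Hourly air temperature = linear winter cooling trend
(8 → 2 °C) + 3 °C diurnal sinusoid peaking at 15:00 + AR(1) weather noise
(σ = 1.2 °C, ρ = 0.8). Soil temperatures at the surface, 2 cm and 5 cm are
exponentially smoothed air temperature (damping and lag increasing with
depth). PAR is a clear-sky half-sine between astronomical sunrise and
sunset at 54° N, scaled by a daily cloudiness factor ~ U(0.25, 1) and
unit-mean lognormal hourly noise (σ = 0.15), so the long-run mean has a
closed form (clear-sky mean × mean cloudiness) used as a test oracle. Rain
is a two-state Markov chain (~20% wet hours). The noise-free limit of every
channel is its deterministic curve exactly.

**Truth.** Per collar and hour:

* R_het = Rh0 · Q10_het^((T_5cm − Tref)/10), with Rh0 = 0.11 µmol m⁻² s⁻¹
  at Tref = 10 °C and Q10_het = 2.45;
* R_auto = r_a · SDW · Q10_auto^((T_air − Tref)/10) · (s if PAR > 0 else 1),
  with r_a = 0.28 µmol m⁻² s⁻¹ per g shoot dry weight, Q10_auto = 2.5 and
  daytime suppression s = 0.8;
* GPP = (SDW/SDW_final) · max(0, a·ln(PAR) + c), with a = 0.44 (per-collar
  nominal), c = −0.24 — amplitudes calibrated once so a default campaign
  lands at the study-scale pools (seed ≈ 1.30 g C, shoot + root ≈ 1.5 g C,
  flux balance ≈ −0.3 g C, small soil change);
* NEE = R_eco − GPP, identically.

Shoot dry weight is zero before germination (14 Nov) and then logistic with
rate 1.2 d⁻¹ and midpoint 7 d after germination: the stand is essentially
established by the net-uptake onset (21 Nov). This deliberately compresses
establishment relative to a slow-growing winter stand (see §7),
consistent with abrupt bulk germination of a densely sown stand.

Replicate variation: per-collar multipliers on growth (CV 5%), on root
allocation (extra CV 5%) and on heterotrophic respiration (CV 35%); the
first two match the between-replicate shoot/root SDs of the reference
campaign, the third reproduces its stock-balance SD (~0.066 g C). Each collar draws
from its own random substream keyed by (seed, collar index), so adding
collars never perturbs existing ones.

**Observation model.** A closure trace is

    C(t) = C₀ + m·t + transient(t) + drawdown(t) + ε,

with m the slope implied by the flux through the inverse ideal-gas
conversion, a mixing transient (5 ppm amplitude, 10 s e-folding) active
only during the first 20 s and frozen at its end value afterwards, an
opaque-daytime photosynthetic drawdown decaying over the first 50 s
(likewise frozen), and white noise (σ = 0.3 ppm). Freezing the transients
at the dead-band edges makes the noise-free slope recovery exact — the
observation-model consistency invariant is testable at 10⁻¹⁰ relative
error. Traces are 145 s at 1 Hz so the opaque rule (50 s dead band
+ 90 s window) fits with margin. The transparent chamber encodes NEE at
τ·PAR (its photosynthesis sees attenuated light) and records inside-PAR as
τ·PAR with 2% sensor noise; the opaque chamber encodes (suppressed) R_eco.

**DOC and inventory.** Rainfall accumulates in each collar's drainage
bottle (capture efficiency 0.55 of rain × collar area); bottles are emptied
after wet spells once they hold > 0.6 L, plus a final collection —
typically a few events and ~3 L per collar per season, at concentrations
around 20 mg C L⁻¹ (σ = 1). The stock inventory takes shoot, root and seed
pools from simulated biomass × carbon fractions (shoot 40.5%, root 34.5%,
seed 41.5% of DW) and sets ΔC_soil to the exact conservation residual, so
before measurement noise the stock balance equals the integrated true-NEE
balance to machine precision; a residual above 10⁻⁹ g is an internal error.
Gaussian measurement noise is then added per pool (soil 0.005, shoot 0.003,
root 0.005, DOC 0.0005, seed 0.0005 g C, 1 SD).

The stock measurement noise is instrument-replicate precision for pooled,
well-mixed subsamples — far below the ~0.15 g soil-carbon detection limit
of a field campaign on 2.5 kg of soil. That is a deliberate design: the
closure experiment is meant to expose flux-side biases, which study-like
inventory noise would mask. With soil noise at 0.05–0.15 g the stock side
dominates the comparison and the flux-on-stock regression slope collapses
toward zero even when the fluxes are perfect — which is exactly why
detecting short-term stock changes in real soils is hard and a flux-based
balance is wanted in the first place.

**Ideal-chamber configuration.** `SimConfig.ideal()` zeroes every
measurement-noise term *and* sets τ = 1. The correction estimated from a
fitted plot-level (or per-collar) light response is a statistical estimate;
it cannot be exact while uptake amplitude varies, so the microgram-level
closure check is defined against an ideal chamber, where measured fluxes
equal true fluxes identically and the check isolates the accounting chain
(slope fit → conversion → pairing → integration → Eq.-style inventory).
With the default (noisy, τ = 0.66) observation model the validation
criteria are statistical: ensemble slope within [0.9, 1.1] and a paired
mean difference indistinguishable from zero.

## 6. Numerical choices

* Trace slopes: vectorised mean-centred OLS in numpy (tens of thousands of
  90-point fits per campaign); identical, value for value, to the
  single-trace path, which the tests assert. Light response, Q₁₀ and
  suppression fits go through statsmodels OLS; ANOVA through
  scipy.stats.f_oneway; all are cross-checked against independently coded
  normal-equation / sum-of-squares oracles at 10⁻¹⁰.
* r² is clamped to [0, 1]; a constant window (zero variance) reports
  r² = 0 with slope 0 rather than NaN.
* The fit window is half-open, [deadband, deadband + window), so sample
  counts at 1 Hz are unambiguous (exactly 90).
* Degenerate inputs fail loudly: short traces, < 10 window samples, < 20
  light-response points after filtering (configurable), < 10 positive
  fluxes for a Q₁₀ fit, an empty day or night class for suppression,
  coverage below the configured minimum for integration.
* CSV artifacts are written with shortest round-trip float reprs and parsed
  with strtod, making write→read bit-exact; runs with identical configs are
  byte-identical, and a manifest records the config hash, seed and row
  counts.
* All randomness flows from one seed through named `SeedSequence` spawn
  keys (environment, collars, DOC, inventory noise, traces), below 2³¹.

## 7. Limitations

* The light-response correction assumes a constant uptake amplitude over
  the correction period. During canopy establishment this is wrong, and a
  constant offset over- or under-corrects the transient; the simulator's
  rapid establishment keeps this residual at the few-mg-C level. For a
  slowly establishing stand a time-varying amplitude model would be needed.
* The simulator has no water or energy balance, no nutrient response (the
  treatment exists only as a label for the ANOVA machinery), no chamber
  leaks or pressure artifacts, no priming or litter dynamics, and its DOC
  is a simple rain-driven accumulator. Passing tests therefore demonstrate
  the correctness of the estimation chain under the stated observation
  model, not robustness to every field artifact.
* The suppression estimator returns the day:night ratio of total dark
  respiration; it is an unbiased estimate of the autotrophic suppression
  factor only when heterotrophic respiration is negligible (§3).
* Apparent stage-wise Q₁₀ values from the full pipeline mix two temperature
  responses (heterotrophic on soil temperature, autotrophic on air) plus
  growth and suppression effects; they are descriptive, and the
  parameter-recovery guarantee applies to the single-component scenarios.
* Collar area defaults to 278 cm² (the effective monitored area), not the
  nominal 314 cm² of a 20 cm circle; both are configurable, and the budget
  scales linearly in the choice.
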