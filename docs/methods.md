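# Methods

This note documents the models, estimators and numerical choices behind
`n2osink`, and what the synthetic-data generators do and do not emulate.

## Batch-vial gas kinetics (`incubation`)

**Rate correction.** Headspace amounts A(t) of each gas are measured at GC
sampling times. Each sampling removes a fraction f = V_sample/V_headspace of
every headspace gas (replaced by inert gas); the removal is applied
multiplicatively immediately after the reading at the event time. Leakage
through the septum is modelled as first-order exchange toward an ambient
amount, dA/dt = r − λ(A − A_amb). With a constant biological rate r per
interval the interval ODE has the closed-form solution

    A(t₁) = A_amb + (A₀′ − A_amb)·e^(−λΔt) + r·(1 − e^(−λΔt))/λ,

which is solved for r; λ → 0 recovers the plain difference quotient. The
defaults are λ = 0 and ambient = 0, appropriate for crimp-sealed vials under
a He atmosphere; both are per-gas configurable.

**Dissolved concentrations.** The liquid concentration is estimated from the
quasi-steady-state transfer balance C_liq = C_eq − r/(kLa·V_liq), where C_eq
is the Henry-law equilibrium with the concurrent headspace partial pressure
and r the liquid-phase consumption rate. This matches the per-interval
spreadsheet-style routine used with robotized incubation systems; the
`bethedge` simulator carries the full dynamic two-compartment state, so the
quasi-steady-state estimate can be validated against it (it agrees within
5% whenever transfer is fast relative to consumption; near complete
depletion the relative error grows as both terms go to zero).

**Dissolved-inventory correction.** N₂O is soluble enough that the liquid of
a half-full vial at equilibrium holds ~30% of the vial's N₂O. Biological
consumption therefore exceeds the headspace decline while the liquid
inventory is drawn down. `liquid_corrected_rates` adds the estimated
inventory change to each interval (r_bio = r_headspace + dI/dt), with the
initial inventory taken at full equilibrium for a freshly prepared vial.
With this correction, cell trajectories reconstructed from cumulated
consumptions match the simulator's biomass within 1%.

**Solubility functions.** N₂O: Weiss & Price (1980) K₀ fit (mol l⁻¹ atm⁻¹,
zero salinity), valid 0–40 °C. O₂: Benson & Krause (1984) freshwater
saturation formula converted to a Henry coefficient. Gas-phase mixing
ratios follow the Weiss & Price convention for a headspace over liquid: the
ppmv refers to the dry gas at total pressure P, i.e. the partial pressure
is referenced to P − p_w(T) with p_w the saturation vapour pressure. Under
this convention 12.9 µM N₂O at 15 °C corresponds to ≈389 ppmv; referencing
the full 1 atm instead would give ≈382 ppmv (−1.8%).

**Biokinetic fits.** All nonlinear fits use trust-region least squares
(tolerances 1e-12). µ_max is the exponential-rate fit r(t) = r₀e^{µt} to
consumption magnitudes during unrestricted growth, started from the
log-linear regression; the fitting window is user-specified or
auto-selected as the longest span with log-linear R² ≥ 0.98 (earliest span
on ties). Michaelis–Menten fits start from V_max = max observed rate and
K_m = concentration at half-max; flat (curvature-free) data return a
flagged K_m → 0 boundary result rather than an exception. Growth yields Y
(cells mol⁻¹) are regression slopes of cell counts on moles consumed;
electron-based yields divide by 4 e⁻/O₂ or 2 e⁻/N₂O after conversion to
cell dry weight.

## Bet-hedging respiration simulator (`bethedge`)

The model has exactly two deterministic subpopulations: a fraction f_NosZ
that expresses N₂O reductase in response to O₂ depletion and the complement
that does not. Both grow aerobically with Michaelis–Menten kinetics in
dissolved O₂; when dissolved O₂ falls below `o2_switch` the expressing
subpopulation additionally grows by N₂O respiration (Michaelis–Menten in
dissolved N₂O, N₂ released mole for mole), while non-expressing cells stop
respiring once O₂ is gone — no late recruitment. This is a deliberate
simplification of stochastic single-cell expression models: with
deterministic subpopulations, f_NosZ is a single identifiable parameter of
the gas curves. Gas exchange is first-order in the departure from Henry-law
equilibrium with coefficient kLa; sampling events instantaneously dilute
the headspace, which reproduces the apparent slow decline of headspace N₂O
before its biological consumption starts.

Default kinetic parameters are the fitted respiratory parameters of the
*Cloacibacterium* inoculant strain: µ_max = 0.29 / 0.11 h⁻¹ and K_m = 0.9 /
12.9 µM for O₂ / N₂O, yields Y = µ_max/V_max with V_max = 0.72 / 0.66 fmol
cell⁻¹ h⁻¹, switch at 2 µM dissolved O₂ (aerobically raised cells; cells
with intact reductase switch at 4–6 µM), f_NosZ = 0.03. Vial geometry
defaults to 50 ml stirred culture in a 120-ml vial at 23 °C with 1-ml
samplings. kLa = 15 h⁻¹ is a configuration placeholder for a stirred vial,
not a measured value. Initial gas doses (9e-5 mol O₂, 1e-4 mol N₂O) are
chosen so O₂ depletion occurs near 18 h and N₂O depletion many hours later,
the regime in which f_NosZ is identifiable.

**Integration.** LSODA with relative tolerance 1e-9 and absolute tolerance
1e-12 mol on gas states (1 cell on population states), integrated piecewise
between sampling events, with exact event location of the O₂-switch
crossing. The output grid carries a bracketing pair of points at the switch
so that quadrature of the electron-flow curve (4·r_O₂ + 2·r_N₂O) sees its
jump; the flow then integrates to 4·cumO₂ + 2·cumN₂O within 1e-6 relative.
Mole balance (N₂ produced vs N₂O consumed, including sampled-out gas)
closes to solver tolerance.

**f_NosZ estimation.** Weighted least squares of simulated vs observed
headspace O₂ and N₂O, each gas normalized by its data range; a fixed
multistart grid {0.01, 0.05, 0.2, 0.8} seeds a bounded scalar refinement
around the best grid point. A flat loss surface (all grid points fitting to
solver-noise level, or negligible spread) yields an "unidentifiable" flag —
this happens when the record does not cover the O₂ → N₂O transition.
Optionally N_ini is fitted jointly (log-scale). On synthetic data with 2%
multiplicative noise, recovery over f ∈ {0.01…1} is accurate to well under
20% relative error.

## Chamber fluxes and reduction inference (`fieldflux`)

Flux from a ~3-min enclosure: q = 10⁻⁶·a·h·p/(R·T) mol m⁻² s⁻¹ with a the
OLS slope (ppm s⁻¹) of the concentration ramp after discarding a 15-s
deadband (robot settling; configurable). Smoothing for display is
Nadaraya–Watson with a Gaussian kernel in time (default bandwidth 4 h,
recorded in output metadata — the bandwidth is presentation, not
inference). Cumulated emissions are trapezoids of the per-chamber flux
records over closed-open periods.

Treatment effects are ratios of cumulated emissions, treated/control:

* **Unpaired designs** (independent chamber sets): ratio of arm means,
  with the Fieller interval for a ratio of independent normal means
  (df = n₁ + n₂ − 2). When g = t²·var(Ȳ)/Ȳ² ≥ 1 the confidence set is
  unbounded and is returned flagged, not raised.
* **Paired designs**: mean of per-pair ratios R_i = X_i/Y_i with a
  Student-t interval (df = n − 1); the paired-means Fieller interval
  (with the sample covariance) and a pair-resampling bootstrap are
  computed alongside, and on simulated paired campaigns the three agree
  in width to within ~35%.
* **Bootstrap intervals** resample chambers within arm (10,000 resamples,
  seed mandatory) and use *expanded percentile* quantiles
  (α′ = Φ(√((df+1)/df)·t_{α/2,df}), Hesterberg 2015) rather than raw
  α/2 percentiles: at the n ≈ 6 chamber counts of field designs the raw
  percentile interval covers only ~87–89% at nominal 95%, while the
  expanded form restores 93–94% — verified by the Monte-Carlo coverage
  tests. This is the package's one deliberate departure from the plain
  percentile recipe.

`calibrate_coverage` measures empirical coverage of any interval method on
a generator with known truth and bisects the nominal level to the target
coverage; on the well-calibrated Fieller interval the calibration leaves
the level essentially unchanged.

Percentage reductions map the ratio interval through r → (1 − r)·100
(monotone, endpoints swap).

## qPCR quantification and survival (`qpcr`)

The quantification model is N = N_T/(2e)^Cq with N_T the amplicons per tube
at signal detection and e the amplification efficiency. Calibration is
linear least squares of log N on Cq (slope −log 2e, intercept log N_T),
requiring ≥4 standards spanning ≥3 decades. Calibrations are carried at
full precision everywhere: with the two-digit reported fit (N_T = 7.68e10, e = 0.85), evaluating at the trusted ceiling Cq = 40 gives ≈46 templates
per tube, whereas the reported threshold of 34 corresponds to an unrounded
efficiency ≈0.8566 — a 2-digit rounding moves the detection threshold by
~35%, which is why rounded parameters are never substituted
internally. Abundances divide templates per tube by the sample mass
represented in the tube (dilution already applied) and by the rRNA-operon
copy number (3). Cq values above the trust ceiling (default 40) are
flagged below-LOD, never zeroed or imputed.

Inhibition screening compares measured vs calibration-predicted Cq along a
spiked dilution series; dilutions with offset ≤ 1 cycle (inclusive) pass,
and the minimum safe dilution is the smallest factor from which all further
dilutions pass.

Survival fits are first-order decay N_t = N₀e^(−d·t) on log abundance, with
T₁/₂ = ln 2/d. Windows for piecewise series (fast decline over days ~3–7,
slow thereafter) are user-specified, not auto-detected, because phase
boundaries in such series are qualitative.

## Inventory scenarios (`upscale`)

A scenario multiplies selected application categories of a long-form
country inventory (kt N₂O-N yr⁻¹) by (1 − factor), default factor 0.6 — the
conservative field estimate of the inoculant's emission reduction — leaving
all other anthropogenic emissions unchanged, and reports absolute and
relative decreases per region. No country inventory values are bundled;
any schema-conformant CSV is accepted.

## Synthetic data (`synth`)

Every generator is a pure function of its seed and serializes its ground
truth. What they emulate, and what they do not:

* **Incubation curves**: simulator trajectories sampled on an hourly
  GC-like schedule with sampling-loss events and multiplicative lognormal
  measurement noise. Not emulated: GC drift, calibration error, per-gas
  detector nonlinearity.
* **Field campaigns**: the control-arm flux path is baseline (200 µg
  N₂O-N m⁻² h⁻¹) + a sinusoidal diurnal cycle (amplitude 100, afternoon
  peak — a stand-in for temperature forcing) + exponential-decay event
  pulses (rain/re-fertilization analogues); the treated arm is the same
  path times the true ratio. Chambers carry independent lognormal level
  multipliers (CV 0.3 — chamber-to-chamber variability of cumulated
  emissions; flux data are positive and right-skewed). Each flux is
  converted to a linear enclosure ppm ramp by inverting the chamber-flux
  formula, so flux processing recovers the generating flux exactly in the
  noiseless case. Not emulated: soil-physical N₂O production (WFPS
  dynamics, source partitioning), non-linear chamber feedback, gap
  structure of real campaigns. Passing coverage tests therefore show the
  interval machinery is calibrated under lognormal chamber noise, not
  that real fields satisfy that noise model.
* **qPCR**: decade-design standards (2.4e1–2.4e6 templates per tube)
  from an exact calibration with additive Gaussian Cq noise; optional
  inhibition offset below a chosen dilution.
* **Survival**: piecewise exponentials with multiplicative lognormal
  noise (always positive).
* **Inventories**: deterministic toy region (n = 1) or random schema-valid
  tables with category sums below totals.

## Problem sizes in the test suite

The shipped suite runs the recovery study at 5 NosZ fractions × 3 seeds
with 2% noise, Monte-Carlo estimator checks at 200–500 replicates, and
coverage checks at 1000 campaigns × 10,000 bootstrap resamples, all with
fixed seeds; these sizes make the Monte-Carlo error small relative to every
asserted bound while keeping a full run around a minute of compute.

## Known limitations

* The quasi-steady-state dissolved-concentration estimate degrades near
  complete gas depletion and immediately after sampling events (the
  liquid re-equilibrates over ~1/kLa); rates on the sampling schedule
  itself are unaffected.
* The two-subpopulation model cannot represent late recruitment of
  non-expressing cells or maintenance respiration; if real cultures
  recruit late, f_NosZ estimates are effective, not census, fractions.
* Fieller intervals assume approximately normal arm means; with n = 6
  lognormal chambers this holds well at CV 0.3 but will degrade for
  heavier-tailed noise.
* O₂-onset detection reports the dissolved O₂ at the first interval with
  net N₂O consumption; its resolution is limited by the sampling
  interval, since dissolved O₂ collapses within minutes of depletion.
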