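# Methods

This note records the models implemented in `pbsdose`, their assumptions, the
numerical choices made where the design was open, and what the synthetic-data
closed loops do and do not demonstrate.

## Dose-per-MU calibration

The calibration factor is modelled as D/MU = D/(χ(E)D + Δ(I_c, E)).
Equivalently MU = χD + Δ: a dose-proportional term and a dose-independent
offset. χ(E) = x₃ − exp(x₁E + x₂) captures the energy dependence of monitor
response relative to dose at the 20 mm water-equivalent reference depth
(LET differences between monitor chamber and reference position); it rises
steeply from ≈166 MU/Gy at 70 MeV and plateaus at x₃ ≈ 205.6 MU/Gy.
Δ = (−exp(d₁E + d₂) + d₃)·I_c·T(E) is proportional to nozzle current
(cyclotron current I_c times transmission T) and is negative throughout the
commissioned domain: the integrate/reset dead time of the monitor
electrometer discards a larger share of charge at higher instantaneous
current, so fewer MU are counted per unit dose, and the effect is dose-
independent because it scales with beam-on time.

**Sign convention for x₁.** The published parameter table lists x₁ positive,
under which χ decreases without bound and is negative over most of the
domain — inconsistent with the described rise to a plateau and with every
printed downstream value. The package's default (`chi_sign_convention =
"adopted"`) uses −|x₁|, which reproduces the plateau (χ(245) = 205.59 MU/Gy)
and all derived quantities; the raw printed convention remains selectable
for auditing and raises a domain error where χ ≤ 0.

**Validity floor.** The denominator χD + Δ must be positive, so for Δ < 0
the model is undefined below D_min = −Δ/χ. `mu_for_dose` refuses requests
within 1% of the floor rather than returning non-physical MU; the error
message reports the floor. At the extreme operating point (245 MeV, 800 nA)
the floor is ≈1.57 Gy, which is why low-dose UHDR deliveries are tuned by
direct measurement rather than by this calibration.

**Staged fit.** `fit_calibration` follows the commissioning procedure:
(1) per-(E, I_c) nonlinear least squares on D/MU residuals with χ and Δ
free; (2) fit of χ(E) to the stage-1 values; (3) per-stratum re-fit of Δ
with χ frozen; (4) fit of the Δ(I_c, E) surface. Three numerical choices:

- Residuals are taken on the calibration factor (Gy/MU), not on MU, because
  that is the quantity the calibration is used for. Under the generator's
  multiplicative dose-noise model the D/MU residual scale is ∝ (D/MU)², so
  the stratum fits weight accordingly (weighted least squares restoring
  homoscedasticity); on noiseless data the fits are exact either way.
- Stage 2 and stage 4 pool stratum estimates weighted by their stage-1/3
  standard errors (plain inverse-variance pooling). With noiseless input the
  standard errors vanish and unweighted pooling is used.
- Transmission t₁–t₄ is measured independently of the dose calibration
  (Faraday-cup current at the focal plane vs machine logs), so stage 4 by
  default treats T(E) as known and estimates only d₁–d₃;
  `fit_transmission=True` frees all seven surface parameters.

Initial guesses are generic (log-linear regression against the running
maximum plus a margin), not the published values, so recovery tests
demonstrate identifiability rather than initialisation.

**Temperature/pressure.** MU are corrected by a single multiplicative factor
(`tp_correction_factor`, default 1). A factor of exactly 1 leaves all
outputs bit-identical.

**Reference-to-surface scaling.** The 20 mm WET → surface dose ratio is the
two-factor rational in E with coefficients a–i. Its numerator is a
difference of ≈0.024-magnitude terms; at the four significant figures the
coefficients are published with, the expression is ill-conditioned and
evaluates to 1.196 at 70 MeV and 1.052 at 245 MeV rather than the
independently quoted measured factors (1.32 and 1.07). The package ships
the expression as printed, pins its actual outputs as regression values,
and accepts a measured-ratio table (`surface_ratio_table`) that overrides
the analytic form by interpolation. The quoted factors are not asserted
anywhere.

**Degrader scaling.** Cell-dose/detector-dose ratios for solid-water-
degraded beams come from Monte Carlo transport, which is out of scope; the
package only interpolates a user-supplied table and refuses extrapolation.

## Beam optics

Focal-plane spot sigmas follow per-axis power laws in energy; the fitted
coefficients are canonical defaults and a measured per-energy table can
override them with linear interpolation. The envelope around the focal
plane is the Courant–Snyder quadratic in σ²; because the model is exactly
quadratic, `fit_courant_snyder` solves a linear least-squares problem in σ²
and derives (σ₀, ρ, ∅), clipping ρ to [−0.99, 0.99] as in the original
fitting. Since |ρ| < 1 implies σ²(z) ≥ σ₀²(1 − ρ²) > 0, validated
parameters can never produce a negative envelope. The per-energy envelope
table was not published: `default_courant_snyder` ships a clearly labelled
synthetic placeholder (ρ = 0, divergence chosen so σ grows 5% over 200 mm).

Scan speed is the measured 245 MeV speed scaled by the inverse momentum
ratio p(245)/p(E) with p = √(T(T + 2m)), m = 938.272 MeV. Two printed
inconsistencies are deliberately left unreconciled: (i) the quoted 2.28 mm
horizontal displacement for 2 A at 70 MeV vs 2.09 mm from the printed
horizontal mm/A fit (the fit parameters are taken as canonical; the
vertical figure agrees with its fit); (ii) the slew-rate settings
(0.45/0.17 A per 10 μs) combined with mm/A would imply ≈23.5/8.9 m/s at
245 MeV, far from the oscilloscope-measured 10.64/2.75 m/s — the measured
speeds are canonical and the slew rates are carried as configuration only.

**Energy-range policy.** Models are fitted over 70–245 MeV. The default
policy warns and extrapolates up to 250 MeV (the transmission fit is
extrapolated to 250 MeV in exactly this way to estimate ≈11.6%) and raises
beyond; `energy_policy: strict` turns the warning into an error.

## Range and depth dose

R80 here is the **proximal** 80%-of-maximum depth (the unusual convention;
most literature uses the distal crossing); the extractor returns both. The
range–energy power law R80 = aE^p is fitted in log–log space, which is
linear and hence exact on noiseless power-law data. Crossings are linearly
interpolated between adjacent samples — at the 0.5 mm near-peak scan
resolution, higher-order interpolation would change results by far less
than the measurement step. Curves are self-normalised to their maximum, the
super-level region at 80% must be contiguous (otherwise "multiple peaks"),
and water-equivalent window offsets are pure additive shifts of the depth
axis.

The analytic Bragg fixture is a slowly rising entrance channel
(∝ (d/d_peak)^0.15) that shoulders off through an erfc at the peak, plus a
Gaussian peak whose width grows with range (w = 0.6 mm + 1.2% of R80,
emulating straggling). The peak position is calibrated by fixed-point
iteration so the analytic proximal 80% crossing lands exactly on the range
model, and the curve is sampled on the measurement protocol's grid (5 mm
steps, 0.5 mm within ±10 mm of the peak). The functional form is a
convenience stand-in for Monte Carlo depth-dose curves, not a transport
claim; real measured curves have nuclear-buildup structure and a skewed
energy spectrum the fixture does not emulate, so closed-loop passes
demonstrate extractor correctness, not agreement with measured IDDs.

## Field synthesis, homogeneity, delivery timing, dose rate

Spot grids are inclusive of both field edges with the field centre at the
origin; x is the horizontal (fast) scan axis. Per-spot MU is the
calibration MU at the 2.5 mm reference spacing scaled by (spacing/2.5)² —
the dose-offset Δ is applied once at the reference geometry and the MU
distributed uniformly, matching the field-level nature of the calibration
measurement. Synthesis exploits the separability of the bivariate Gaussian:
unique spot x/y coordinates generate two kernel matrices and the map is a
sparse-weighted double product, exact to machine precision and fast for
regular grids (a chunked accumulation path handles highly irregular maps).
Absolute (Gy) maps invert the planning relation per spot
(integral = (u·2.5² − Δs²)/χ).

The homogeneity index is computed over the central box spanning 50% of each
linear field dimension (the configurable `central_fraction`), read from the
map's recorded field size. Default pixel pitch is 0.5 mm (the scintillator
camera's pitch is not published).

Delivery timing uses a serpentine row-major path (horizontal fast, matching
the higher horizontal slew rate): per-spot beam-on time is
MU/(MU-rate · nozzle current) with the MU-rate-per-nA constant a
configuration value (not published; it cancels in every ratio-based
result), and inter-spot transit takes max(|Δx|/v_H, |Δy|/v_V) at the
momentum-scaled scan speeds.

Peak spot dose rate scales the measured reference (171.93 Gy/s at 245 MeV,
800 nA) by current, transmission ratio, and the inverse product of the
power-law sigmas; using the fitted rather than per-energy measured sigmas
is what reproduces the printed scaled values (112.65 Gy/s at 240 MeV,
0.05 Gy/s at 70 MeV). Detector averaging integrates the Gaussian over a
centred disc of the detector's active area — closed form for circular
beams, polar quadrature otherwise. The field-average dose rate implements
the 0–100% windowed definition: each evaluation point accumulates dose from
every spot (spread uniformly over that spot's beam-on window) and divides
by the span from the first to the last contributing spot; a relative
contribution cutoff is available but defaults to 0 (all spots contribute).
Published field-average figures depend on unpublished timing constants and
are treated as plausibility envelopes, not regression targets.

## Monitor-chain simulator

The simulator is mechanistic and qualitative: integration windows
accumulate charge on the 100 pF capacitor (instantaneous current limited to
the 5.6 μA collection maximum), the window voltage is scaled by the gain
(5 conventional, 1 UHDR) and clipped at the ±10 V monitor range, reset
windows discard charge, and reported MU is proportional to the integrated
monitor voltage (the counts-per-volt-second constant is arbitrary
configuration and cancels in all ratio-based results). Charge is conserved
exactly: collected + reset + clipped = true. The dead-time fraction is
computed from the timing constants — 49/(111 + 49) = 30.6% — not hard-coded
to the quoted overall 32.7%; the source of the extra overhead is not
documented and both numbers appear in the simulator's report. The simulator
reproduces the sign and current-dependence of the low-dose calibration
distortion, not the fitted Δ values.

## Synthetic measurement generators

All generators are deterministic given (parameters, seed). Noise defaults:
multiplicative Gaussian on doses (1%), additive Gaussian on images (1% of
maximum), 0.03 mm positional jitter for repeatability studies — values
chosen to match the scale of the published repeatability and fit-quality
statistics. The dose–MU generator evaluates MU = χD + Δ exactly and rejects
design points below the validity floor with a warning. Because generators
and fitters share the model family, recovery tests demonstrate correctness
of the fitting pipeline and identifiability of the parameters, not the
adequacy of the model for real chamber data.

Study conditions used by the test suite and the acceptance script:
calibration designs span the full 70–245 MeV grid (10 MeV steps), currents
{50, 200, 800} nA and doses 0.25–16 Gy with five repeats (the
commissioning-scale design); homogeneity fields are 200 × 200 mm at 2.5 mm
spacing and 0.5 Gy with the cyclotron current chosen per energy for a
2 nA nozzle current (capped at 800 nA); dose-rate oracles use a 5 × 5,
20 × 20 mm toy plan at 160 MeV. Synthesized homogeneity maps use a 1 mm
pitch, which resolves the smallest (245 MeV) spots with >4 pixels per
sigma.

## QA checks

`run_qa` evaluates: homogeneity (HI ≤ 3%), dose accuracy against the
calibration prediction (±2%, the routine check tolerance), spot sigma
against the power law (±10%, a package default — the published QA lists the
check but not its tolerance), and centroid repeatability (<0.1 mm). Checks
without inputs are reported as `skipped`, never passed; a report with no
evaluated checks does not pass overall. Reports carry a SHA-256 digest of
the full configuration so a rerun with identical constants and seeds is
identical.

## Known limitations

- No Monte Carlo transport: degrader/LET curves are user-supplied tables.
- The Courant–Snyder defaults are synthetic placeholders (table unpublished).
- The surface-scaling expression is ill-conditioned as printed (see above).
- SOBP weight optimisation, film dosimetry, and hardware interfacing are out
  of scope.
- Absolute times from `delivery_time` depend on the configured MU rate
  constant; only ratios and orderings are meaningful until it is measured.
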