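# Methods

This note documents the models, default parameters and design choices
behind `oscivent`, and what the synthetic cohort does and does not emulate.

## Wave-tube impedance estimation

The forced-oscillation technique superimposes a small oscillatory pressure
on the airway opening and measures the complex input impedance
Zrs(f) = P/Q. In the wave-tube variant, the load impedance terminating a
tube of known acoustic properties is inferred from the pressure transfer
ratio P₁/P₂ across the tube:

    P1/P2 = cosh(γL) + (Z0/Zload)·sinh(γL)
    Zload = Z0·sinh(γL) / (P1/P2 − cosh(γL))

**Tube acoustics.** The tube (default 100 cm × 0.375 cm internal diameter)
is modelled as a lossy transmission line with low-frequency viscothermal
(Poiseuille-regime) wall losses: per unit length, series impedance
R′ + jωL′ with R′ = 8μ/(πa⁴) and L′ = ρ/A, shunt admittance jωC′ with
C′ = A/(ρc²); then γ = √(Z′Y′) and Z0 = √(Z′/Y′). Gas constants default to
body-temperature humidified air (ρ = 1.10·10⁻³ g/cm³, μ = 1.86·10⁻⁴ poise,
c = 3.53·10⁴ cm/s). In the lossless limit |Z0| → ρc/A and γ → jω/c. The
Poiseuille resistance is a low-Womersley approximation; at the top of the
band (20.75 Hz, Womersley number ≈ 5) it underestimates the frequency-
dependent viscous loss. This is immaterial here because simulation and
inversion use the same line model; users feeding real recordings should
treat the acoustics as a documented surrogate, not a calibrated instrument
model.

**Forcing signal.** The original "pseudorandom" component list is not
public. The default grid consists of the prime multiples of 0.25 Hz inside
0.5–20.75 Hz (23 components, 0.5 … 20.75 Hz), chosen greedily so no
component is an integer multiple of another: harmonic and intermodulation
distortion products fall off the component set. Phases are uniform from a
seeded generator; the summed waveform is rescaled to exactly the requested
peak-to-peak amplitude (default 1 cmH₂O). With 8-s records at 256 Hz every
component completes an integer number of cycles, so a single rectangular
window is leakage-free; averaging is done across recordings (3–4 per
timepoint), never within.

**Anti-aliasing.** The acquisition chain's 25 Hz 4th-order low-pass is
applied as its steady-state frequency response, identically on both
channels (recordings are taken in periodic steady state during apnoea).
Identical filtering cancels exactly in the ratio, so the filter choice is
noncritical; it is modelled for completeness, not tuned.

**Pole handling.** Frequencies where P₁/P₂ = cosh(γL) (open-end pole) are
dropped with a warning rather than regularized; for physiological loads on
this grid the pole cannot occur.

## Constant-phase model fitting

The respiratory input impedance is modelled as

    Z(ω) = Raw + jω·Iaw + (G − jH)/ω^α,   α = (2/π)·arctan(H/G)

with ω in rad/s. The angular-frequency convention matters: fitted G and H
change if ω is replaced by 2πf-normalized forms, and all calibration
values in this package assume rad/s. Derived quantities are the tissue
exponent α ∈ (0, 1) (α = 0.5 exactly when G = H) and the hysteresivity
η = G/H.

**Cost function.** The study's optimizer and cost are unnamed; we minimize
the magnitude-normalized complex least squares
Σ |Z_model − Z_data|²/|Z_data|². Unweighted errors would be dominated by
the low-frequency tissue term whenever H ~ 100 × Raw, which is the normal
physiological situation. Equivalence with the original fitter is claimed
only at the level of noise-free parameter recovery.

**Search.** A seeded differential-evolution population stage (Sobol
initialisation, vectorized objective) inside a generous box
(Raw ∈ [0, 100], Iaw ∈ [0, 1], G ∈ [1, 5000], H ∈ [10, 20000]) is followed
by a bounded trust-region least-squares polish (xtol = ftol = 1e-14). The
result is deterministic for a fixed seed; if the polished optimum has an
RMS relative error above 5 % the global stage restarts from a shifted seed
(at most twice, counted in `restarts`). Standard errors are Gauss-Newton
approximations from the polished Jacobian. Spectra with non-positive real
parts at some frequencies are fitted robustly on the remaining points
(≥ 8 required, spanning ≥ 1 decade). Iaw is fitted but never used as a
calibration target, since no reference value for it is tabulated.

Measured behaviour at the defaults: noise-free recovery < 0.1 % per
parameter in ≈ 0.06 s per fit; with 2 % complex noise the median RMS fit
error is ≈ 1.9 % and the median bias of G and H < 1 %.

## Ventilation patterns and delivery

Breaths are pressure-control commands (driving pressure above PEEP,
inspiratory:expiratory ratio fixed at 1:2, baseline rate 40/min). Delivery
through a subject uses a quasi-static single-compartment model

    V_T = ΔP · Crs · (1 − e^(−Ti/τ)),   Crs = 1/H,   τ = (Raw + G/ω_b^α)·Crs

with the tissue resistance evaluated at the breathing frequency ω_b. This
ignores within-breath flow shaping and nonlinear compliance; it is linear
in ΔP, which is what the hourly pressure calibration exploits (an exact
rescale converges on the second pass). Calibration targets the median
delivered V_T of 6 ml/kg within 1 %.

Mode specifics:

* **PCS** — a sigh replaces the first breath at or after every 30-s mark
  (so a 300-s pattern carries exactly 10 sighs). Sighs keep normal breath
  timing; only the peak inspiratory pressure is raised to 35 cmH₂O, and
  they are deliberately *not* rescaled by calibration since their PIP is
  defined absolutely.
* **PVV** — driving pressures and periods follow a looped source series.
  The original pre-recorded diaphragm-derived pattern is unavailable; the
  default is a synthetic stand-in (`PVVSourceSeries.synthetic_default`):
  120 breaths of unit-mean lognormal AR(1) amplitudes (CV 15 %) and
  periods (CV 10 %), lag-1 correlation 0.6, generated once from a fixed
  internal seed so it behaves like a fixed recording. It preserves the
  skew, breath-to-breath autocorrelation and looping of physiological
  breathing; a user CSV can replace it. A `variability["scale"]` of 0
  degenerates PVV to PCV exactly.
* **MVV** — independent breath-wise tidal volumes from a right-skewed
  discrete distribution on [0.6, 2.0] × V_T_ref (0.1 steps): a hump below
  1× carrying 62 % of the mass and a ~1/v² tail of large recruiting
  breaths carrying 28 %. The published recruitment-optimizing distribution
  is not reproduced numerically; the property the study logic relies on —
  frequent delivery of excessively large breaths, hence higher driving
  pressures — is what the surrogate encodes, and the weights are
  configurable. The rate is fixed; only V_T varies.

## Virtual cohort

The generator emulates the study design: 8 groups (PVV/MVV/PCV/PCS ×
PEEP 6/9 cmH₂O), n = 7 per group, block-randomized assignment, weights
drawn from a Beta(2.3, 4.3) rescaled to 2.67–3.99 kg (mean 3.13 kg).

**Anchors.** Group-mean trajectories are pinned to published values:
per-group baseline and post-injury Raw/G/H; pooled post-injury PaO₂/FiO₂
of 63.0 (PEEP 6) and 112 mmHg (PEEP 9) with a severe-ARDS gate at
150 mmHg (re-drawn, mimicking repeated injurious ventilation until the
criterion is met); and five-hour relative changes at moderate PEEP of
G +58.8 %/H +54.5 % (PCS), G +40.8 %/H +50.7 % (MVV), PaCO₂ +43.9/+46.2 %
and pH −4.6 % in both, with flat PVV/PCV trajectories. Values never
printed anywhere are package defaults chosen once as physiologically
plausible: baseline PaO₂/FiO₂ 450 mmHg, PaCO₂ 40 mmHg, lactate
1.5 mmol/l; post-injury PaCO₂ 55/45 mmHg and lactate 2.5/2.0 mmol/l at
PEEP 6/9; modest drifts for the unreported cells (e.g. PF −25 % at T5 for
MVV/PCS at moderate PEEP, G and H −10 % and PF +20 % for all high-PEEP
groups, Raw −15 % for PCS at high PEEP). Only printed numbers serve as
calibration anchors; figure-read intermediate values are not used —
intermediate timepoints are geometric (log-linear) interpolations of the
T0 → T5 ratio.

**Acid–base closure.** pH is never drifted directly: at every timepoint it
is derived from PaCO₂ and bicarbonate via Henderson–Hasselbalch
(pH = 6.1 + log₁₀(HCO₃⁻/(0.03·PaCO₂))), with the bicarbonate pool
decremented one-for-one by the lactate rise above baseline (metabolic
component). Each group's lactate endpoint is solved from its pH anchor
through the same relation, so the −4.6 % pH change is met exactly at zero
noise while lactate stays flat to T2 and rises from T3 — reconciling the
observed temporal profiles of both variables. This is a bookkeeping
closure, not a kinetic acid-base model.

**Noise model.** Between-subject variation is a persistent per-variable
lognormal factor with 10 % CV (the study's sample-size assumption);
within-subject hourly fluctuation is lognormal with 4 % CV, a typical
repeatability figure for low-frequency FOT. Haemodynamics (MAP, HR) are
AR(1) fluctuations around stable group means with the high-PEEP groups
running a higher MAP — an ordering property only, as no numeric anchors
exist. Dropout (pneumothorax emulation) is off by default; when enabled it
censors a subject from a random post-injury timepoint onward. Cytokines
and histology are not simulated.

**Raw recordings.** `emit_raw_recordings` synthesizes 3–4 replicate 8-s
wave-tube recordings per subject and timepoint from the state's true
constant-phase parameters, with additive sensor noise of 0.005 cmH₂O SD —
the noise floor of miniature piezoresistive transducers, and a level at
which the complete chain (recordings → transfer function → inversion →
ensemble average → fit) recovers G and H with ≈ 0.5 % median error. Note
that transfer-ratio noise is amplified at the lowest frequencies, where
|Zload| ≫ |Z0·sinh(γL)|, so chain accuracy is considerably more sensitive
to sensor noise than a naive per-bin SNR argument suggests.

**What passing tests do not show.** The cohort reproduces calibrated group
means, printed interval widths and ordering properties; it does not model
injury biology (surfactant kinetics, inflammation), ventilator–lung
feedback (the trajectory table is conditioned on group, not on the
delivered pattern), inter-variable correlations beyond the acid-base
closure, or non-lognormal outliers. Statistical power computed on this
cohort therefore reflects the calibrated effect sizes and noise structure,
not everything a real study would face.

## Analysis stage

Relative changes are per-subject (value/value_T0 − 1)·100; summaries are
mean ± t-based 95 % CI half-width (t rather than normal because group n is
5–7). Reference-level contrasts follow the protocol's factor structure:
time vs T0, PEEP 9 vs 6 cmH₂O, modes vs PVV. Each variable is screened
with Shapiro–Wilk and log-transformed on failure (applied to the whole
variable, not per cell, and only when all values are positive). With
repeated timepoints a linear mixed model with a subject random intercept
(statsmodels MixedLM) supplies the Wald statistics, adjusted within each
factor family by a single-step max-|Z| multivariate-normal Dunnett-type
correction; in the one-way case (single timepoint, one varying factor) the
exact Dunnett test (scipy) is used — this is the path exercised by the
type-I-error suite, which confirms family-wise control at 0.05 on null
cohorts. The three-way REML machinery itself is deliberately delegated;
this module owns design coding, reference levels, the transformation rule
and the multiplicity family.

The PCA composite standardizes the seven per-subject T5/T0 − 1 values
(correlation-matrix PCA — the variables' units are incommensurable, and
whether the original analysis standardized is unstated; we state it as a
choice) and fixes each component's sign by making its largest-magnitude
loading positive. On the default cohort PC1 is carried by G, H, PaCO₂,
lactate and pH with approximately equal weights.

## Problem sizes and tolerances

Defaults used throughout the test suite and acceptance script: 23-frequency
grid, 8-s records at 256 Hz, 200-draw fit sweeps, 100-replicate power and
calibration checks, 400-replicate type-I suite, 10-replicate averaging for
the cohort calibration summaries. Optimizer tolerances: DE tol 1e-8,
polish xtol/ftol/gtol 1e-14; pole-detection threshold 1e-12 relative;
pressure calibration 1 % with ≤ 20 iterations.
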