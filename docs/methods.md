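# Methods

This note records the models behind `perfusense`, the parameters that
matter, the numerical choices, and what the synthetic data can and
cannot demonstrate.

## Measurement model

A detector frame is a vector of counts on a uniform wavelength grid
(default 300–800 nm at 1 nm). The forward model for a light frame under
LED `L` with integration time `t` is

    counts(λ) = t · [ Σ_f B_f · eff_f(L) · c_f · g_f(λ) + D + drift(t) ] + ε

where `B_f` is the fluorophore's brightness (counts·s⁻¹ per µg/mL at
its emission center), `eff_f(L) ∈ [0,1]` its relative excitation
efficiency under that LED, `g_f` a Gaussian emission profile normalised
to 1 at its center, `D` the dark-current rate and `drift` a slow
sinusoidal ambient term. A dark frame (LED off) drops only the
fluorophore sum. The noise `ε` per pixel is Gaussian with variance
`(σ_read·t)² + s·µ` (read noise plus shot noise proportional to the
expected counts `µ`, shot factor `s` = 1 by default).

Quantification inverts this model in three steps: (1) subtract the most
recent dark frame of the same LED — dark current and ambient terms are
common mode and cancel; (2) average the corrected counts over the
channel's emission band (emission ± 10 nm) and divide by the
integration time; (3) invert the linear calibration and subtract the
run's blank offset. Negative concentrations are clipped to zero and
flagged; estimates below the limit of detection are flagged rather than
suppressed.

Reading out a ±10 nm band instead of the single nominal emission pixel
suppresses pixel noise by ~√21 and reduces to the single-pixel reading
as the halfwidth shrinks to the grid step. Normalising per second of
integration makes calibrations transfer across integration settings.

## Calibration and limit of detection

Standards circulated through the flow cell are averaged over the
trailing 5-minute window once steady (OLS slope of the window
indistinguishable from zero at α = 0.05), and the curve is fitted by
ordinary least squares of intensity on concentration. `σ_blank` is the
sample SD of blank replicates when at least three are present, else the
RMS fit residual; in the simulated workflow it is re-estimated from the
individual blank quantifications of the offset run, because the LOD
characterises a single measurement, not a 5-minute average. The LOD
convention is the standard `3·σ_blank/slope`; the multiplier is a
parameter. The run-specific additive offset is the mean of the first
ten pure-matrix quantifications (signed, unclipped) and is subtracted
from all subsequent estimates.

The default simulator noise is *anchored*: the per-pixel read noise is
solved so that the blank net band intensity has a 3σ concentration
equivalent of exactly 4.4 nM FMN (2.008·10⁻³ µg/mL) on the FMN channel
at 2 s integration, after accounting for the shot noise of the
200 counts/s dark current. This ties every stochastic test to the one
printed instrument-noise figure.

## Timing

With dark interleaving, a cycle visits each channel twice (dark +
light) at integration + overhead per frame. The per-frame overhead
default of 0.75 s is chosen so the two-LED configuration produces one
concentration per analyte every 2 × 2 × (2 + 0.75) = 11 s; it is a
configuration value, not a hardware claim. The concentration stream is
smoothed by a trailing median of 5 (robust to single-frame glitches
from dark pairing); the first k−1 records pass through flagged WARMUP.
A trailing median lags a ramp by ~(k−1)/2 cycles, so exactness checks
of the unsmoothed pipeline use k = 1.

## Perfusion-loop and dialysis models

The HOPE circuit is a closed, well-mixed 3 L loop: the perfusate
concentration is the cumulative released mass over the volume,
`c(t) = (1/V)·∫₀ᵗ r(s) ds`, evaluated in closed form for both release
profiles — saturating `r = r₀·e^(−t/τ)` (good organ: the trajectory
plateaus) and progressive `r = r₀ + a·t` (ongoing damage: the
trajectory accelerates). Pump flow affects mixing only and is carried
as metadata; temperature effects are omitted as the measurement is
temperature-insensitive over the operating range.

The dialysis model is a single blood compartment with creatinine
generation `G` (default 1 mg/min) and dialyzer clearance `CL` (default
100 mL/min, necessarily ≤ the 0.2 L/min bypass flow):
`dc/dt = (G − CL·c)/V_b`, fixed-step RK4 at 1 s (the closed-form
exponential is used as the oracle wherever `G = 0`). Waste dialysate
tracks blood scaled by an equilibration factor, default 1 (complete
equilibration at 200 mL/h dialysate); the factor is exposed because
full equilibration is an assumption, not a measurement.

The creatinine assay train dilutes dialysate by the flow ratio
20/(20+5+5) = 2/3 and delays it by the 30-min tubing transit, modelled
as ideal plug flow (a pure time shift; an axial-dispersion kernel is a
documented extension point). Reaction yield is taken as complete — any
constant shortfall is absorbed into the calibration slope. The
inversion chain divides by the dilution, shifts time back, and divides
by the equilibration factor; composed with the forward model it is the
identity on the overlap window.

## Graft cohorts and classification

Synthetic cohorts default to 19 good and 7 discarded grafts. Good
grafts draw plateau profiles around r₀ = 6 µg/min, τ = 25 min
(plateau ≈ 0.05 µg/mL in 3 L); bad grafts draw progressive profiles
whose nominal 60-min concentration is 3× the good-cohort mean
(r₀ = 2 µg/min, a ≈ 0.16 µg/min²). Both receive multiplicative
lognormal parameter jitter (σ = 0.15) and LOD-anchored measurement
noise on a 1-min sampling grid. No quantitative release rates are
published for human grafts, so these magnitudes are free parameters of
the simulator, chosen once to give physiologically plausible sub-µg/mL
trajectories; they are configuration values.

The reference band is the pointwise mean ± 1.96·SD across the good
cohort on a common grid (lower edge clipped at zero). This is a
tolerance band for an individual trajectory, not a confidence band for
the mean; an SEM mode and the z-multiplier are options. A trajectory is
DEVIATING if (a) more than 20% of grid points lie above the upper
envelope, or (b) its OLS slope over 30–60 min exceeds a minimal
clinically meaningful slope (default 5·10⁻⁴ µg·mL⁻¹·min⁻¹) with
one-sided p < 0.05. The magnitude threshold matters: even a plateauing
trajectory has a small, statistically significant positive slope at the
instrument's noise level, so a pure sign test would flag every graft.
The default sits between the analytic late-phase slopes of the good
(~2·10⁻⁴) and bad (~3·10⁻³) profiles. Both thresholds are tunable and
carry no claim of clinical validity.

The discrete protocol mirrors bedside practice: plate-reader readings
at 5/10/15/30/60 min, with a reading ≥ 3000 A.U. at or after 30 min
marking a discard candidate. Plate-reader A.U. and device µg/mL are
deliberately not converted into each other — no mapping between the
unit systems is defined, so the rule operates in A.U. only.

Transaminase decay is fitted as `y(t) = A·e^(−k·t) + b` with
non-negative parameters by bounded nonlinear least squares, initialised
from a log-linear fit of the baseline-subtracted series with a small
grid of restart rates; constant series return a flagged degenerate fit.
Decay fits are intended to start from the day of peak value.
Correlation reports default to Spearman (robust to skewed FMN
distributions), with Pearson available.

## Problem sizes and determinism

Default test and acceptance workloads are desk scale: 60-minute
perfusion runs (≈330–650 quantification cycles), 24 h of dialysis at
1 s steps, 200-graft bands with 400 held-out draws for coverage, and
100-seed replications for the blank-offset bound and decay-rate
recovery. Every stochastic path derives from an explicit seed; frame
noise is keyed by (seed, timestamp, LED, frame role), so identical
configurations reproduce byte-identical record streams.

## What the synthetic data does not show

The simulator's Gaussian emission profiles, affine fluorescence
response, ideal plug flow and single-compartment clearance are
idealisations: passing tests demonstrate the correctness of the
pipeline's algebra, scheduling, inversion chains and statistics under
the stated models — not instrument linearity, reagent kinetics, matrix
effects or any clinical discrimination performance on real grafts. The
cohort-separation results in particular are properties of the chosen
generator parameters, not of human livers.
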