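"""Synthetic instrument and perfusion-loop simulator.

This module stands in for the hardware and the biology: it synthesises
emission-spectrum detector frames (Gaussian fluorophore profiles, dark
current, shot noise, slow ambient drift), the mass balance of a closed
recirculating hypothermic-perfusion loop accumulating FMN/NADH released
by a graft, a two-compartment dialysis clearance model for creatinine,
and labelled graft cohorts for the assessment analytics.

Physical picture
----------------
* HOPE loop: a liver graft releases analyte into a fixed perfusate
  volume V (default 3 L). With release rate r(t) (µg/min) the perfusate
  concentration is c(t) = (1/V)·∫₀ᵗ r(s) ds — closed forms for both the
  saturating ("plateau", r = r₀·e^{−t/τ}, good organ) and the
  "progressive" (r = r₀ + a·t, ongoing ischemic damage) profiles.
* Detector: counts(λ) = t_int·[Σ_f B_f·eff_f(LED)·c_f·g_f(λ) + dark + drift]
  plus Gaussian read noise and shot noise, where g_f is the fluorophore's
  emission profile normalised to 1 at its center. Dark frames drop the
  fluorophore term only, so dark pairing removes dark current and drift.
* Dialysis: blood compartment dc/dt = (G − CL·c)/V_b with generation G
  and dialyzer clearance CL; waste dialysate tracks blood scaled by an
  equilibration factor.

The default noise level is anchored so that the 3σ concentration
equivalent of a blank net band intensity on the FMN channel equals the
instrument's 4.4 nM limit of detection.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assess import Trajectory
from .calibrate import (
    CalibrationCurve,
    StandardRun,
    blank_offset,
    fit_calibration,
    limit_of_detection,
    steady_state_average,
)
from .errors import ValidationError
from .seriesio import TimeSeries
from .spectra import (
    AnalyteChannel,
    FMN_CHANNEL,
    Spectrum,
    WavelengthGrid,
    band_intensity,
    concentration_from_intensity,
    convert_units,
    dark_subtract,
)
from .streaming import LedSchedule, cycle_period

#: Detector wavelength axis: 300-800 nm at 1 nm.
DEFAULT_GRID = WavelengthGrid(start_nm=300.0, step_nm=1.0, n_points=501)

BILIRUBIN_MOLAR_MASS = 584.66  # g/mol, for the 100 µM negative control


@dataclass(frozen=True)
class FluorophoreModel:
    """Gaussian idealisation of a fluorophore's emission.

    ``brightness`` is in counts·s⁻¹ per (µg/mL) at the emission center
    under an LED with relative excitation efficiency 1.
    """

    analyte: str
    emission_center_nm: float
    emission_sd_nm: float
    brightness: float
    excitation_response: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.emission_sd_nm <= 0:
            raise ValidationError("emission_sd_nm must be > 0")
        if self.brightness < 0:
            raise ValidationError("brightness must be >= 0")
        for led, eff in self.excitation_response.items():
            if not 0.0 <= eff <= 1.0:
                raise ValidationError(
                    f"{self.analyte}: excitation efficiency for {led} must be in [0,1]"
                )

    def profile(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Emission profile normalised to 1 at the center wavelength."""
        d = wavelengths_nm - self.emission_center_nm
        return np.exp(-0.5 * (d / self.emission_sd_nm) ** 2)

    def efficiency(self, led_id: str) -> float:
        return float(self.excitation_response.get(led_id, 0.0))


#: Default fluorophore library. Efficiencies and the bilirubin brightness
#: are set so the instrument's negative controls hold: NADH contributes
#: <1% of the FMN-channel signal at physiologic levels, and 100 µM
#: bilirubin contributes <1% at 530 nm.
DEFAULT_FLUOROPHORES = (
    FluorophoreModel("FMN", 530.0, 25.0, 2.0e4, {"LED405": 1.0, "LED385": 0.8}),
    FluorophoreModel("NADH", 460.0, 30.0, 2.0e4, {"LED385": 1.0, "LED405": 0.002}),
    FluorophoreModel("CREATININE", 475.0, 25.0, 2.0e4, {"LED405": 1.0}),
    FluorophoreModel("BILIRUBIN", 520.0, 25.0, 2.0, {"LED405": 1.0, "LED385": 0.5}),
)


def theoretical_band_slope(
    channel: AnalyteChannel,
    fluor: FluorophoreModel,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> float:
    """Expected net band intensity (counts/s) per µg/mL of the fluorophore.

    This is the noise-free calibration slope implied by the simulator:
    brightness × LED efficiency × band-average of the emission profile.
    """
    wl = grid.wavelengths
    lo = channel.emission_nm - channel.band_halfwidth_nm
    hi = channel.emission_nm + channel.band_halfwidth_nm
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise ValidationError("channel band does not intersect the grid")
    return fluor.brightness * fluor.efficiency(channel.led_id) * float(
        fluor.profile(wl[mask]).mean()
    )


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: dark current, read noise, shot noise, ambient drift.

    Per-pixel frame counts are drawn as N(µ, σ²) with
    µ = t·(signal + dark_mean + drift(t)) and
    σ² = (dark_sd·t)² + shot_factor·µ, then clipped at zero.
    Drift is a slow sinusoid common to paired dark and light frames.
    """

    dark_mean: float = 200.0
    dark_sd: float = 40.0
    shot_factor: float = 1.0
    ambient_drift_amplitude: float = 10.0
    ambient_drift_period_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_sd < 0 or self.shot_factor < 0:
            raise ValidationError("dark_sd and shot_factor must be >= 0")

    def drift(self, t_s: float) -> float:
        if self.ambient_drift_amplitude == 0:
            return 0.0
        return self.ambient_drift_amplitude * math.sin(
            2.0 * math.pi * t_s / self.ambient_drift_period_s
        )

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        """All stochastic and drift terms off (dark current mean kept)."""
        return cls(dark_mean=200.0, dark_sd=0.0, shot_factor=0.0,
                   ambient_drift_amplitude=0.0, seed=seed)


def anchored_noise(
    seed: int = 0,
    *,
    lod_nM: float = 4.4,
    channel: AnalyteChannel = FMN_CHANNEL,
    fluors: Sequence[FluorophoreModel] = DEFAULT_FLUOROPHORES,
    grid: WavelengthGrid = DEFAULT_GRID,
    integration_time_s: float = 2.0,
    dark_mean: float = 200.0,
    shot_factor: float = 1.0,
    ambient_drift_amplitude: float = 10.0,
    ambient_drift_period_s: float = 600.0,
) -> NoiseModel:
    """Noise model whose blank 3σ concentration equivalent equals the LOD.

    Solves for the per-pixel read noise so that the net band intensity of
    a blank (light − dark, both noisy) has standard deviation
    σ_net = slope·LOD/3 on the anchor channel, with the shot-noise
    contribution of the dark current accounted for.
    """
    fluor = next(f for f in fluors if f.analyte == channel.analyte)
    slope = theoretical_band_slope(channel, fluor, grid)
    sigma_conc = convert_units(lod_nM, "nM->ug/mL", channel) / 3.0
    wl = grid.wavelengths
    mask = (np.abs(wl - channel.emission_nm) <= channel.band_halfwidth_nm)
    n_band = int(mask.sum())
    t = integration_time_s
    sigma_net = slope * sigma_conc
    # net band sd = sqrt(2)·σ_pix/(sqrt(n_band)·t)  =>  σ_pix target:
    sigma_pix = sigma_net * t * math.sqrt(n_band) / math.sqrt(2.0)
    shot_var = shot_factor * t * dark_mean
    if sigma_pix ** 2 <= shot_var:
        raise ValidationError(
            "shot noise of the dark current alone exceeds the LOD anchor; "
            "lower dark_mean or shot_factor"
        )
    dark_sd = math.sqrt(sigma_pix ** 2 - shot_var) / t
    return NoiseModel(
        dark_mean=dark_mean, dark_sd=dark_sd, shot_factor=shot_factor,
        ambient_drift_amplitude=ambient_drift_amplitude,
        ambient_drift_period_s=ambient_drift_period_s, seed=seed,
    )


def blank_concentration_sigma(
    lod_nM: float = 4.4, channel: AnalyteChannel = FMN_CHANNEL
) -> float:
    """The anchored single-measurement blank σ in µg/mL (= LOD/3)."""
    return convert_units(lod_nM, "nM->ug/mL", channel) / 3.0


def _frame_rng(noise: NoiseModel, t_s: float, led_id: str, dark: bool) -> np.random.Generator:
    """Deterministic per-frame RNG keyed by (seed, time, LED, role)."""
    key = [
        noise.seed & 0x7FFFFFFF,
        int(round(t_s * 1e6)) & 0x7FFFFFFFFFFF,
        zlib.crc32(led_id.encode()),
        int(dark),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def emit_frame(
    concs: Mapping[str, float],
    channel: AnalyteChannel,
    fluors: Sequence[FluorophoreModel],
    noise: NoiseModel,
    t_s: float,
    dark: bool,
    *,
    grid: WavelengthGrid = DEFAULT_GRID,
    integration_time_s: float = 2.0,
) -> Spectrum:
    """Synthesise one detector frame under the channel's LED.

    Light frames superpose every fluorophore's emission weighted by its
    concentration and LED efficiency; dark frames keep only dark current,
    drift and noise. Deterministic given (noise.seed, t_s, led_id, dark).
    """
    known = {f.analyte for f in fluors}
    unknown = set(concs) - known
    if unknown:
        raise ValidationError(f"no fluorophore model for analytes {sorted(unknown)}")
    wl = grid.wavelengths
    rate = np.full(grid.n_points, noise.dark_mean + noise.drift(t_s))
    if not dark:
        for f in fluors:
            c = float(concs.get(f.analyte, 0.0))
            if c == 0.0:
                continue
            rate = rate + f.brightness * f.efficiency(channel.led_id) * c * f.profile(wl)
    expected = integration_time_s * rate
    var = (noise.dark_sd * integration_time_s) ** 2 + noise.shot_factor * np.clip(
        expected, 0.0, None
    )
    if np.any(var > 0):
        rng = _frame_rng(noise, t_s, channel.led_id, dark)
        counts = expected + rng.normal(0.0, np.sqrt(var))
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected
    return Spectrum(
        grid=grid, counts=counts, led_id=channel.led_id, is_dark=dark,
        integration_time_s=integration_time_s, timestamp_s=t_s,
    )


# ---------------------------------------------------------------------------
# HOPE perfusion loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseProfile:
    """Graft analyte release rate r(t) in µg/min.

    kind="plateau": r(t) = r0·exp(−t/tau)   (release exhausts; good organ)
    kind="progressive": r(t) = r0 + accel·t (damage keeps progressing)
    """

    kind: str
    r0_ug_per_min: float
    tau_min: float = 25.0
    accel_ug_per_min2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("plateau", "progressive"):
            raise ValidationError(f"unknown release profile kind {self.kind!r}")
        if self.r0_ug_per_min < 0:
            raise ValidationError("r0 must be >= 0")
        if self.kind == "plateau" and self.tau_min <= 0:
            raise ValidationError("tau_min must be > 0")

    def rate(self, t_min: float) -> float:
        if self.kind == "plateau":
            return self.r0_ug_per_min * math.exp(-t_min / self.tau_min)
        return self.r0_ug_per_min + self.accel_ug_per_min2 * t_min

    def cumulative(self, t_min: float) -> float:
        """∫₀ᵗ r(s) ds in µg (closed form)."""
        if self.kind == "plateau":
            return self.r0_ug_per_min * self.tau_min * (
                1.0 - math.exp(-t_min / self.tau_min)
            )
        return self.r0_ug_per_min * t_min + 0.5 * self.accel_ug_per_min2 * t_min ** 2


@dataclass(frozen=True)
class HopeScenario:
    """A closed recirculating hypothermic-perfusion run."""

    release_profiles: Mapping[str, ReleaseProfile]
    perfusate_volume_L: float = 3.0
    duration_min: float = 60.0
    flow_rate_mL_min: float = 250.0  # metadata only; does not enter the model

    def __post_init__(self) -> None:
        if self.perfusate_volume_L <= 0:
            raise ValidationError("perfusate_volume_L must be > 0")
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be > 0")
        for analyte, prof in self.release_profiles.items():
            if prof.rate(0.0) < 0 or prof.rate(self.duration_min) < 0:
                raise ValidationError(
                    f"{analyte}: release rate must be >= 0 over the run"
                )

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.release_profiles)


def good_graft_scenario(
    r0_ug_per_min: float = 6.0, tau_min: float = 25.0, **kw
) -> HopeScenario:
    """Saturating FMN release: concentration plateaus (good organ quality)."""
    return HopeScenario(
        release_profiles={"FMN": ReleaseProfile("plateau", r0_ug_per_min, tau_min=tau_min)},
        **kw,
    )


def bad_graft_scenario(
    r0_ug_per_min: float = 2.0, accel_ug_per_min2: float = 0.1607, **kw
) -> HopeScenario:
    """Progressive FMN release: concentration keeps accelerating (ischemic damage)."""
    return HopeScenario(
        release_profiles={
            "FMN": ReleaseProfile("progressive", r0_ug_per_min,
                                  accel_ug_per_min2=accel_ug_per_min2)
        },
        **kw,
    )


def true_hope_concentration(
    scn: HopeScenario, t_min: float, analyte: str | None = None
) -> float:
    """Closed-form perfusate concentration c(t) = (1/V)·∫₀ᵗ r(s) ds, µg/mL."""
    if not 0.0 <= t_min <= scn.duration_min:
        raise ValidationError(
            f"t = {t_min} min outside run [0, {scn.duration_min}] min"
        )
    if analyte is None:
        analyte = scn.analytes[0]
    prof = scn.release_profiles[analyte]
    volume_mL = scn.perfusate_volume_L * 1000.0
    return prof.cumulative(t_min) / volume_mL


def simulate_hope_run(
    scn: HopeScenario,
    schedule: LedSchedule,
    fluors: Sequence[FluorophoreModel] = DEFAULT_FLUOROPHORES,
    noise: NoiseModel | None = None,
    *,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> tuple[list[list[Spectrum]], dict[str, TimeSeries]]:
    """Frame stream plus ground truth for a HOPE run.

    Returns (cycles, truth): each cycle is the ordered frame list the
    acquisition loop would see (dark then light per channel), and truth
    maps each monitored analyte to its true concentration at the light
    frame timestamps. Identical inputs (including the noise seed) give
    identical streams.
    """
    noise = anchored_noise() if noise is None else noise
    period = cycle_period(schedule)
    n_cycles = int(scn.duration_min * 60.0 // period)
    frame_dur = schedule.integration_time_s + schedule.per_frame_overhead_s
    cycles: list[list[Spectrum]] = []
    truth_t: dict[str, list[float]] = {a: [] for a in scn.analytes}
    truth_c: dict[str, list[float]] = {a: [] for a in scn.analytes}
    t = 0.0
    for i in range(n_cycles):
        frames: list[Spectrum] = []
        for channel in schedule.channels:
            if schedule.dark_every_frame or i == 0:
                frames.append(emit_frame(
                    {}, channel, fluors, noise, t, dark=True, grid=grid,
                    integration_time_s=schedule.integration_time_s,
                ))
                t += frame_dur
            t_min = t / 60.0
            concs = {
                a: true_hope_concentration(scn, min(t_min, scn.duration_min), a)
                for a in scn.analytes
            }
            frames.append(emit_frame(
                concs, channel, fluors, noise, t, dark=False, grid=grid,
                integration_time_s=schedule.integration_time_s,
            ))
            if channel.analyte in concs:
                truth_t[channel.analyte].append(t_min)
                truth_c[channel.analyte].append(concs[channel.analyte])
            t += frame_dur
        cycles.append(frames)
    truth = {
        a: TimeSeries(np.array(truth_t[a]), np.array(truth_c[a]),
                      name=f"true_{a}", units="ug/mL", t_unit="min")
        for a in scn.analytes if truth_t[a]
    }
    return cycles, truth


def simulate_standard_run(
    concentration_ug_ml: float,
    channel: AnalyteChannel,
    fluors: Sequence[FluorophoreModel] = DEFAULT_FLUOROPHORES,
    noise: NoiseModel | None = None,
    *,
    duration_min: float = 8.0,
    cadence_s: float = 5.5,
    integration_time_s: float = 2.0,
    grid: WavelengthGrid = DEFAULT_GRID,
    t_start_s: float = 0.0,
    matrix: str = "BELZER_MPS",
) -> StandardRun:
    """Net band-intensity trace while circulating one calibration standard.

    Each measurement is a dark/light pair quantified exactly as the
    streaming pipeline would (dark subtraction then band readout).
    """
    noise = anchored_noise() if noise is None else noise
    times, intensities = [], []
    t = t_start_s
    n = int(duration_min * 60.0 // cadence_s)
    concs = {channel.analyte: concentration_ug_ml}
    for _ in range(n):
        dark = emit_frame({}, channel, fluors, noise, t, dark=True, grid=grid,
                          integration_time_s=integration_time_s)
        light = emit_frame(concs, channel, fluors, noise, t + cadence_s / 2.0,
                           dark=False, grid=grid,
                           integration_time_s=integration_time_s)
        net = dark_subtract(light, dark)
        times.append(light.timestamp_s)
        intensities.append(band_intensity(net, channel))
        t += cadence_s
    return StandardRun(channel.analyte, concentration_ug_ml,
                       np.array(times), np.array(intensities), matrix=matrix)


DEFAULT_STANDARDS_UG_ML = (0.0, 0.0, 0.0, 0.05, 0.1, 0.2, 0.5, 1.0)


def run_simulated_calibration(
    channel: AnalyteChannel,
    standards_ug_ml: Sequence[float] = DEFAULT_STANDARDS_UG_ML,
    fluors: Sequence[FluorophoreModel] = DEFAULT_FLUOROPHORES,
    noise: NoiseModel | None = None,
    *,
    n_blank_offset: int = 10,
    window_min: float = 5.0,
    standard_duration_min: float = 8.0,
) -> CalibrationCurve:
    """Full calibration workflow on simulated standards.

    Circulate each standard, steady-state average over the trailing
    window, fit the linear curve, then quantify ``n_blank_offset`` pure
    blanks (signed estimates) to fix the run's additive offset — the
    procedure performed before connecting a graft.
    """
    noise = anchored_noise() if noise is None else noise
    points = []
    t0 = 0.0
    for conc in standards_ug_ml:
        run = simulate_standard_run(
            conc, channel, fluors, noise,
            duration_min=standard_duration_min, t_start_s=t0,
        )
        ss = steady_state_average(run, window_min=window_min)
        points.append((conc, ss.mean))
        t0 = run.times_s[-1] + 60.0
    curve = fit_calibration(points, analyte=channel.analyte)
    blank_run = simulate_standard_run(
        0.0, channel, fluors, noise,
        duration_min=max(1.0, n_blank_offset * 11.0 / 60.0), cadence_s=11.0,
        t_start_s=t0 + 300.0,
    )
    estimates = [
        concentration_from_intensity(i, curve, clip_negative=False)[0]
        for i in blank_run.intensities[:n_blank_offset]
    ]
    curve.blank_offset = blank_offset(estimates, n_required=n_blank_offset)
    # The LOD characterises a single measurement, so σ_blank is taken from
    # the individual blank quantifications, not the 5-min standard averages.
    if len(blank_run.intensities) >= 3 and blank_run.intensities.std(ddof=1) > 0:
        curve.sigma_blank = float(blank_run.intensities.std(ddof=1))
        curve.lod = limit_of_detection(curve.sigma_blank, curve.slope)
    return curve


# ---------------------------------------------------------------------------
# Dialysis clearance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DialysisScenario:
    """Single blood compartment cleared by a dialyzer on a bypass loop."""

    blood_volume_L: float = 5.0
    initial_creatinine_mg_dL: float = 8.0
    generation_rate_mg_min: float = 1.0
    dialyzer_clearance_mL_min: float = 100.0
    blood_bypass_flow_L_min: float = 0.2
    dialysate_flow_mL_h: float = 200.0
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        for name in ("blood_volume_L", "blood_bypass_flow_L_min",
                     "dialysate_flow_mL_h", "duration_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.initial_creatinine_mg_dL < 0 or self.generation_rate_mg_min < 0:
            raise ValidationError("concentrations and rates must be >= 0")
        if self.dialyzer_clearance_mL_min < 0:
            raise ValidationError("dialyzer_clearance_mL_min must be >= 0")
        if self.dialyzer_clearance_mL_min > self.blood_bypass_flow_L_min * 1000.0:
            raise ValidationError(
                "dialyzer clearance cannot exceed the blood bypass flow"
            )

    @property
    def steady_state_mg_dL(self) -> float:
        """Fixed point G/CL expressed in mg/dL."""
        if self.dialyzer_clearance_mL_min == 0:
            return math.inf
        return 100.0 * self.generation_rate_mg_min / self.dialyzer_clearance_mL_min


def analytic_dialysis_concentration(scn: DialysisScenario, t_min: float) -> float:
    """Closed-form blood creatinine at t (exact for this linear ODE)."""
    k = scn.dialyzer_clearance_mL_min / (1000.0 * scn.blood_volume_L)  # per min
    c0 = scn.initial_creatinine_mg_dL
    if k == 0.0:
        # no clearance: linear accumulation, dc/dt = G/(10·V) mg/dL per min
        return c0 + scn.generation_rate_mg_min * t_min / (10.0 * scn.blood_volume_L)
    c_star = scn.steady_state_mg_dL
    return c_star + (c0 - c_star) * math.exp(-k * t_min)


def simulate_dialysis_run(
    scn: DialysisScenario,
    *,
    dt_s: float = 1.0,
    output_every_s: float = 60.0,
    equilibration_factor: float = 1.0,
) -> tuple[TimeSeries, TimeSeries]:
    """Integrate the blood compartment and derive the waste dialysate.

    Fixed-step RK4 at ``dt_s`` on dc/dt = (G − CL·c)/V_b (units handled
    so c is in mg/dL); waste dialysate = equilibration_factor × blood.
    Returns (blood, dialysate) series with times in minutes.
    """
    if not 0.0 < equilibration_factor <= 1.0:
        raise ValidationError("equilibration_factor must be in (0, 1]")
    # dc/dt in mg/dL per min: mass = c·10·V mg; removal = c·CL/100 mg/min
    g = scn.generation_rate_mg_min
    cl = scn.dialyzer_clearance_mL_min
    v = scn.blood_volume_L

    def f(c: float) -> float:
        return (g - c * cl / 100.0) / (10.0 * v)

    h = dt_s / 60.0  # minutes
    n_steps = int(round(scn.duration_h * 3600.0 / dt_s))
    every = max(1, int(round(output_every_s / dt_s)))
    c = scn.initial_creatinine_mg_dL
    times = [0.0]
    concs = [c]
    for i in range(1, n_steps + 1):
        k1 = f(c)
        k2 = f(c + 0.5 * h * k1)
        k3 = f(c + 0.5 * h * k2)
        k4 = f(c + h * k3)
        c = c + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if i % every == 0 or i == n_steps:
            times.append(i * h)
            concs.append(c)
    blood = TimeSeries(np.array(times), np.array(concs),
                       name="blood_creatinine", units="mg/dL", t_unit="min")
    dialysate = TimeSeries(blood.times, blood.values * equilibration_factor,
                           name="waste_dialysate_creatinine", units="mg/dL",
                           t_unit="min")
    return blood, dialysate


def simulate_assay_train(dialysate: TimeSeries, train) -> TimeSeries:
    """Forward wet-chemistry transform: reagent dilution then transit delay.

    The cuvette sees the dialysate diluted by the NaOH/reagent flows and
    delayed by the tubing transit time (plug flow). ``train`` is a
    :class:`perfusense.flowchem.AssayTrain`.
    """
    from .flowchem import mixing_dilution  # local import: flowchem is the inverse side

    diluted = dialysate.scaled(mixing_dilution(train))
    out = diluted.shifted(train.transit_delay_min)
    return replace(out, name="cuvette_creatinine_product")


# ---------------------------------------------------------------------------
# Graft cohorts
# ---------------------------------------------------------------------------

@dataclass
class GraftCohort:
    good: list[Trajectory]
    bad: list[Trajectory]

    @property
    def all(self) -> list[Trajectory]:
        return self.good + self.bad


def make_graft_cohort(
    n_good: int,
    n_bad: int,
    seed: int,
    *,
    good_r0: float = 6.0,
    good_tau_min: float = 25.0,
    bad_r0: float = 2.0,
    separation_factor: float = 3.0,
    jitter_sigma: float = 0.15,
    volume_L: float = 3.0,
    duration_min: float = 60.0,
    sample_every_min: float = 1.0,
    measurement_sigma: float | None = None,
) -> GraftCohort:
    """Labelled synthetic graft cohort for the assessment analytics.

    Good grafts follow jittered plateau release profiles; bad grafts
    follow progressive profiles whose nominal 60-min concentration is
    ``separation_factor`` × the good-cohort mean at 60 min. Parameter
    jitter is multiplicative lognormal (σ = jitter_sigma) and trajectory
    samples carry LOD-anchored measurement noise.
    """
    if n_good < 2:
        raise ValidationError("n_good must be >= 2 to support a reference band")
    rng = np.random.default_rng(seed)
    sigma = (blank_concentration_sigma() if measurement_sigma is None
             else measurement_sigma)
    times = np.arange(0.0, duration_min + 1e-9, sample_every_min)
    vol_mL = volume_L * 1000.0

    # nominal good 60-min concentration fixes the bad progressive profile
    c_good_60 = good_r0 * good_tau_min * (1 - math.exp(-duration_min / good_tau_min)) / vol_mL
    c_bad_target = separation_factor * c_good_60
    bad_accel = (c_bad_target * vol_mL - bad_r0 * duration_min) / (0.5 * duration_min ** 2)
    if bad_accel < 0:
        raise ValidationError("separation_factor too small for the bad-graft r0")

    def sample(profile: ReleaseProfile, graft_id: str, label: str) -> Trajectory:
        scn = HopeScenario({"FMN": profile}, perfusate_volume_L=volume_L,
                           duration_min=duration_min)
        truth = np.array([true_hope_concentration(scn, t) for t in times])
        noisy = truth + rng.normal(0.0, sigma, size=truth.shape)
        return Trajectory(graft_id, times.copy(), np.clip(noisy, 0.0, None),
                          label=label)

    good = []
    for i in range(n_good):
        r0 = good_r0 * rng.lognormal(0.0, jitter_sigma)
        tau = good_tau_min * rng.lognormal(0.0, jitter_sigma)
        good.append(sample(ReleaseProfile("plateau", r0, tau_min=tau),
                           f"good-{i:02d}", "TRANSPLANTED_OK"))
    bad = []
    for i in range(n_bad):
        jit = rng.lognormal(0.0, jitter_sigma)
        bad.append(sample(
            ReleaseProfile("progressive", bad_r0 * jit,
                           accel_ug_per_min2=bad_accel * jit),
            f"bad-{i:02d}", "DISCARDED"))
    return GraftCohort(good=good, bad=bad)
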