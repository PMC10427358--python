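"""Spectral domain types and elementary detector-frame operations.

The measurement chain of the fluorometric monitor is built from four
small operations on detector frames:

* :func:`dark_subtract` — remove ambient light and dark current using the
  paired LED-off frame acquired for every measurement;
* :func:`band_intensity` — collapse a dark-corrected spectrum to a single
  net intensity by averaging over an emission band, normalised per second
  of integration time so calibrations transfer across integration settings;
* :func:`concentration_from_intensity` — invert a linear calibration
  (intensity = slope·concentration + intercept) with blank-offset
  correction, non-negativity clipping and limit-of-detection flagging;
* :func:`convert_units` — nM ↔ µg/mL conversion via the analyte molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from .errors import (
    EmptyBandError,
    FrameRoleError,
    GridMismatchError,
    InvalidCalibrationError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .calibrate import CalibrationCurve

# Quality flags carried on measurement records
BELOW_LOD = "BELOW_LOD"
SATURATED = "SATURATED"
NEGATIVE_CLIPPED = "NEGATIVE_CLIPPED"
WARMUP = "WARMUP"
MISSING_DARK = "MISSING_DARK"

#: Molar masses (g/mol) used for nM <-> µg/mL conversion. External
#: chemistry constants, not measured by the instrument.
ANALYTE_MOLAR_MASS = {
    "FMN": 456.34,
    "NADH": 709.40,
    "CREATININE": 113.12,
}


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform detector wavelength axis (strictly increasing)."""

    start_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValidationError(f"step_nm must be > 0, got {self.step_nm}")
        if self.n_points < 2:
            raise ValidationError(f"n_points must be >= 2, got {self.n_points}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @property
    def stop_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_points - 1)


@dataclass
class Spectrum:
    """One detector frame: counts on a wavelength grid plus acquisition metadata.

    Raw frames have non-negative counts; dark-corrected frames may go
    negative (noise around the blank level).
    """

    grid: WavelengthGrid
    counts: np.ndarray
    led_id: str
    is_dark: bool
    integration_time_s: float
    timestamp_s: float
    dark_corrected: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_points,):
            raise ValidationError(
                f"counts length {self.counts.shape} != grid n_points {self.grid.n_points}"
            )
        if self.integration_time_s <= 0:
            raise ValidationError("integration_time_s must be > 0")


@dataclass(frozen=True)
class AnalyteChannel:
    """An excitation/emission channel of the instrument.

    ``band_halfwidth_nm`` defines the closed readout band
    [emission_nm − hw, emission_nm + hw] over which counts are averaged;
    the excitation wavelength must be below the emission wavelength
    (Stokes shift).
    """

    analyte: str
    excitation_nm: float
    emission_nm: float
    led_id: str
    band_halfwidth_nm: float = 10.0
    molar_mass_g_per_mol: float = 0.0

    def __post_init__(self) -> None:
        if self.excitation_nm >= self.emission_nm:
            raise ValidationError(
                f"Stokes shift violated for {self.analyte}: "
                f"excitation {self.excitation_nm} nm >= emission {self.emission_nm} nm"
            )
        if self.band_halfwidth_nm <= 0:
            raise ValidationError("band_halfwidth_nm must be > 0")


# Channels as operated in the perfusion / dialysis studies.
FMN_CHANNEL = AnalyteChannel(
    "FMN", excitation_nm=405.0, emission_nm=530.0, led_id="LED405",
    molar_mass_g_per_mol=ANALYTE_MOLAR_MASS["FMN"],
)
NADH_CHANNEL = AnalyteChannel(
    "NADH", excitation_nm=385.0, emission_nm=460.0, led_id="LED385",
    molar_mass_g_per_mol=ANALYTE_MOLAR_MASS["NADH"],
)
CREATININE_CHANNEL = AnalyteChannel(
    "CREATININE", excitation_nm=405.0, emission_nm=475.0, led_id="LED405",
    molar_mass_g_per_mol=ANALYTE_MOLAR_MASS["CREATININE"],
)

DEFAULT_CHANNELS = {
    "FMN": FMN_CHANNEL,
    "NADH": NADH_CHANNEL,
    "CREATININE": CREATININE_CHANNEL,
}


@dataclass
class MeasurementRecord:
    """One timestamped quantification of a single analyte."""

    timestamp_s: float
    analyte: str
    raw_intensity: float
    dark_intensity: float
    net_intensity: float
    concentration: float
    flags: set[str] = field(default_factory=set)


def dark_subtract(raw: Spectrum, dark: Spectrum) -> Spectrum:
    """Subtract the paired LED-off frame from a light frame.

    Removes dark current and ambient light exactly (common-mode
    rejection): adding any constant to both frames leaves the result
    unchanged. Metadata is copied from the light frame.
    """
    if raw.grid != dark.grid:
        raise GridMismatchError(
            f"raw grid {raw.grid} != dark grid {dark.grid}"
        )
    if raw.led_id != dark.led_id:
        raise FrameRoleError(
            f"LED mismatch: raw {raw.led_id!r} vs dark {dark.led_id!r}"
        )
    if raw.is_dark or not dark.is_dark:
        raise FrameRoleError(
            f"expected a light frame and a dark frame, got is_dark="
            f"{raw.is_dark}/{dark.is_dark}"
        )
    return replace(
        raw,
        counts=raw.counts - dark.counts,
        dark_corrected=True,
    )


def band_intensity(spec: Spectrum, channel: AnalyteChannel) -> float:
    """Mean counts over the channel's emission band, per second of integration.

    The readout band is the closed interval emission ± halfwidth; the
    result is linear in the spectrum and blind to counts outside the band.
    Intended for dark-corrected frames.
    """
    wl = spec.grid.wavelengths
    lo = channel.emission_nm - channel.band_halfwidth_nm
    hi = channel.emission_nm + channel.band_halfwidth_nm
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        raise EmptyBandError(
            f"band [{lo}, {hi}] nm contains no grid points "
            f"(grid {spec.grid.start_nm}-{spec.grid.stop_nm} nm)"
        )
    return float(spec.counts[mask].mean() / spec.integration_time_s)


def concentration_from_intensity(
    net: float,
    curve: "CalibrationCurve",
    *,
    clip_negative: bool = True,
) -> tuple[float, set[str]]:
    """Invert the linear calibration to a concentration in µg/mL.

    Applies the curve's blank offset, clips negative results to zero
    (flagged NEGATIVE_CLIPPED) and flags estimates below the limit of
    detection (BELOW_LOD). With ``clip_negative=False`` the signed
    estimate is returned — required when *estimating* a blank offset.
    """
    if curve.slope <= 0:
        raise InvalidCalibrationError(
            f"calibration slope must be > 0, got {curve.slope}"
        )
    conc = (net - curve.intercept) / curve.slope - curve.blank_offset
    flags: set[str] = set()
    if conc < curve.lod:
        flags.add(BELOW_LOD)
    if clip_negative and conc < 0:
        conc = 0.0
        flags.add(NEGATIVE_CLIPPED)
    return conc, flags


def convert_units(
    value: float,
    direction: str,
    channel: AnalyteChannel | None = None,
    *,
    molar_mass_g_per_mol: float | None = None,
) -> float:
    """Convert a concentration between nM and µg/mL.

    nM × M / 10⁶ = µg/mL, with M the molar mass in g/mol. Direction is
    one of ``"nM->ug/mL"`` or ``"ug/mL->nM"``.
    """
    mass = molar_mass_g_per_mol
    if mass is None and channel is not None:
        mass = channel.molar_mass_g_per_mol
    if mass is None or mass <= 0:
        raise ValidationError("a positive molar mass is required for unit conversion")
    if direction == "nM->ug/mL":
        return value * mass / 1e6
    if direction == "ug/mL->nM":
        return value * 1e6 / mass
    raise ValidationError(
        f"unknown direction {direction!r}; use 'nM->ug/mL' or 'ug/mL->nM'"
    )
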