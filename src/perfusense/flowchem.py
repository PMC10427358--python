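"""Creatinine wet-chemistry transform and its inversion.

Waste dialysate is drawn into a bypass (20 mL/h), mixed with NaOH
(5 mL/h) and a colorimetric reagent (5 mL/h), and pushed through a
delay line sized so the mixture reacts completely before reaching the
measurement cuvette (~30 min transit). The cuvette therefore sees the
dialysate concentration scaled by the flow-ratio dilution and shifted in
time. This module inverts that chain — cuvette signal → dialysate
concentration → blood concentration — treating the tubing as an ideal
plug flow (pure delay, no axial dispersion) and the dialysate/blood
equilibration as a constant factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ValidationError
from .seriesio import TimeSeries

import numpy as np


@dataclass(frozen=True)
class AssayTrain:
    """Flows and delays of the reagent mixing train (defaults as operated)."""

    dialysate_flow_mL_h: float = 20.0
    naoh_flow_mL_h: float = 5.0
    reagent_flow_mL_h: float = 5.0
    transit_delay_min: float = 30.0
    equilibration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.dialysate_flow_mL_h <= 0:
            raise ValidationError("dialysate_flow_mL_h must be > 0")
        if self.naoh_flow_mL_h < 0 or self.reagent_flow_mL_h < 0:
            raise ValidationError("reagent flows must be >= 0")
        if self.transit_delay_min < 0:
            raise ValidationError("transit_delay_min must be >= 0")
        if not 0.0 < self.equilibration_factor <= 1.0:
            raise ValidationError("equilibration_factor must be in (0, 1]")


def mixing_dilution(train: AssayTrain) -> float:
    """Fraction of the cuvette stream that is dialysate.

    dialysate / (dialysate + NaOH + reagent); 20:5:5 mL/h gives 2/3.
    """
    total = train.dialysate_flow_mL_h + train.naoh_flow_mL_h + train.reagent_flow_mL_h
    if total <= 0:
        raise ValidationError("total flow must be > 0")
    return train.dialysate_flow_mL_h / total


def delay_line(
    series: TimeSeries, delay_min: float, *, resample: bool = False
) -> TimeSeries:
    """Plug-flow transport: output(t) = input(t − delay).

    By default a pure time shift is returned — every value and every
    inter-sample interval preserved, timestamps advanced by the delay.
    With ``resample=True`` the output is given on the *input* time grid
    instead, with NaN (no signal yet) wherever t − delay precedes the
    first input sample.
    """
    if delay_min < 0:
        raise ValidationError("delay must be >= 0")
    shifted = series.shifted(delay_min)
    if not resample:
        return shifted
    vals = np.interp(series.times, shifted.times, shifted.values,
                     left=np.nan, right=np.nan)
    vals[series.times < shifted.times[0]] = np.nan
    return replace(series, values=vals)


def cuvette_to_dialysate(cuvette: TimeSeries, train: AssayTrain) -> TimeSeries:
    """Invert dilution and transit: index by dialysate-collection time.

    A cuvette reading at time t reflects dialysate drawn at t − delay,
    concentrated back up by the inverse mixing dilution.
    """
    dilution = mixing_dilution(train)
    if dilution == 0:
        raise ValidationError("mixing dilution is zero")
    out = cuvette.scaled(1.0 / dilution).shifted(-train.transit_delay_min)
    return replace(out, name="dialysate_creatinine")


def dialysate_to_blood(dialysate: TimeSeries, train: AssayTrain) -> TimeSeries:
    """Undo dialysate/blood equilibration (factor 1 = full equilibration)."""
    out = dialysate.scaled(1.0 / train.equilibration_factor)
    return replace(out, name="blood_creatinine")
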