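"""Real-time acquisition pipeline: scheduling, per-cycle quantification,
filtering, and timestamped persistence.

One acquisition *cycle* visits every configured channel; with dark
interleaving each visit is a dark frame (LED off) followed by a light
frame. Every light frame is paired with the most recent dark frame of
its LED, so ambient light and dark current cancel exactly even when
conditions drift. The default two-channel schedule with 2 s integration
and 0.75 s per-frame overhead yields one concentration per analyte every
11 s.
"""

from __future__ import annotations

import csv
import json
import statistics
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .calibrate import CalibrationCurve
from .errors import InvalidCalibrationError, ValidationError
from .spectra import (
    MISSING_DARK,
    SATURATED,
    WARMUP,
    AnalyteChannel,
    MeasurementRecord,
    Spectrum,
    band_intensity,
    concentration_from_intensity,
    dark_subtract,
)

RECORD_COLUMNS = [
    "timestamp_s", "analyte", "raw_intensity", "dark_intensity",
    "net_intensity", "concentration_ug_per_ml", "flags",
]


@dataclass(frozen=True)
class LedSchedule:
    """Channel visiting order and per-frame timing of the acquisition loop."""

    channels: tuple[AnalyteChannel, ...]
    integration_time_s: float = 2.0
    per_frame_overhead_s: float = 0.75
    dark_every_frame: bool = True

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("schedule needs at least one channel")
        if self.integration_time_s <= 0:
            raise ValidationError("integration_time_s must be > 0")
        if self.per_frame_overhead_s < 0:
            raise ValidationError("per_frame_overhead_s must be >= 0")


def cycle_period(schedule: LedSchedule) -> float:
    """Seconds per full acquisition cycle.

    n_channels × frames-per-visit × (integration + overhead); dark
    interleaving doubles the frames per visit. The instrument's default
    two-LED configuration gives 2 × 2 × 2.75 s = 11 s.
    """
    frames_per_visit = 2 if schedule.dark_every_frame else 1
    return len(schedule.channels) * frames_per_visit * (
        schedule.integration_time_s + schedule.per_frame_overhead_s
    )


@dataclass
class StreamState:
    """Mutable acquisition-loop state: dark-frame cache, record log, events."""

    schedule: LedSchedule
    last_dark: dict[str, Spectrum] = field(default_factory=dict)
    records: list[MeasurementRecord] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def channel_for_led(self, led_id: str, analyte: str | None = None) -> AnalyteChannel | None:
        for ch in self.schedule.channels:
            if ch.led_id == led_id and (analyte is None or ch.analyte == analyte):
                return ch
        return None


def process_cycle(
    frames: Sequence[Spectrum],
    curves: Mapping[str, CalibrationCurve],
    state: StreamState,
    *,
    saturation_counts: float = 65535.0,
) -> list[MeasurementRecord]:
    """Quantify one cycle of frames.

    Dark frames refresh the per-LED dark cache; each light frame is
    dark-subtracted against the most recent dark of its LED, collapsed
    to a net band intensity and inverted through the channel's
    calibration. A light frame without any dark on record is skipped
    with a logged MISSING_DARK event rather than crashing the run.
    """
    out: list[MeasurementRecord] = []
    for frame in frames:
        if frame.is_dark:
            state.last_dark[frame.led_id] = frame
            continue
        channel = state.channel_for_led(frame.led_id)
        if channel is None:
            state.events.append(
                f"t={frame.timestamp_s:.2f}s UNSCHEDULED_LED {frame.led_id}"
            )
            continue
        dark = state.last_dark.get(frame.led_id)
        if dark is None:
            state.events.append(
                f"t={frame.timestamp_s:.2f}s {MISSING_DARK} {frame.led_id}"
            )
            continue
        curve = curves.get(channel.analyte)
        if curve is None:
            raise InvalidCalibrationError(
                f"no calibration curve for channel {channel.analyte!r}"
            )
        net_spec = dark_subtract(frame, dark)
        raw = band_intensity(
            Spectrum(frame.grid, frame.counts, frame.led_id, False,
                     frame.integration_time_s, frame.timestamp_s), channel)
        dark_i = band_intensity(
            Spectrum(dark.grid, dark.counts, dark.led_id, False,
                     dark.integration_time_s, dark.timestamp_s), channel)
        net = band_intensity(net_spec, channel)
        conc, flags = concentration_from_intensity(net, curve)
        if frame.counts.max() >= saturation_counts:
            flags.add(SATURATED)
        rec = MeasurementRecord(
            timestamp_s=frame.timestamp_s, analyte=channel.analyte,
            raw_intensity=raw, dark_intensity=dark_i, net_intensity=net,
            concentration=conc, flags=flags,
        )
        state.records.append(rec)
        out.append(rec)
    return out


def rolling_filter(
    records: Sequence[MeasurementRecord], k: int = 5
) -> list[MeasurementRecord]:
    """Trailing median-of-k smoother on the concentration stream.

    Robust to the single-frame glitches dark pairing can produce. The
    first k−1 records pass through unfiltered with a WARMUP flag.
    """
    if k < 1 or k % 2 == 0:
        raise ValidationError(f"window k must be odd and >= 1, got {k}")
    out: list[MeasurementRecord] = []
    for i, rec in enumerate(records):
        flags = set(rec.flags)
        if i < k - 1:
            conc = rec.concentration
            flags.add(WARMUP)
        else:
            conc = statistics.median(
                r.concentration for r in records[i - k + 1 : i + 1]
            )
        out.append(MeasurementRecord(
            rec.timestamp_s, rec.analyte, rec.raw_intensity,
            rec.dark_intensity, rec.net_intensity, conc, flags,
        ))
    return out


def _record_row(rec: MeasurementRecord) -> list:
    return [
        repr(float(rec.timestamp_s)), rec.analyte, repr(float(rec.raw_intensity)),
        repr(float(rec.dark_intensity)), repr(float(rec.net_intensity)),
        repr(float(rec.concentration)), ";".join(sorted(rec.flags)),
    ]


def write_records_csv(path: str | Path, records: Iterable[MeasurementRecord]) -> None:
    with Path(path).open("w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for rec in records:
            w.writerow(_record_row(rec))


def read_records_csv(path: str | Path) -> list[MeasurementRecord]:
    records = []
    with Path(path).open("r", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(MeasurementRecord(
                timestamp_s=float(row["timestamp_s"]),
                analyte=row["analyte"],
                raw_intensity=float(row["raw_intensity"]),
                dark_intensity=float(row["dark_intensity"]),
                net_intensity=float(row["net_intensity"]),
                concentration=float(row["concentration_ug_per_ml"]),
                flags=set(f for f in row["flags"].split(";") if f),
            ))
    return records


def run_monitor(
    source: Iterable[Sequence[Spectrum]],
    curves: Mapping[str, CalibrationCurve],
    schedule: LedSchedule,
    out_dir: str | Path,
    *,
    filter_k: int = 5,
    seed: int | None = None,
    run_id: str = "run",
    manifest_extra: Mapping | None = None,
) -> Path:
    """Consume a cycle stream and persist records incrementally.

    Writes ``records.csv`` (flushed per cycle, so a crash loses at most
    one cycle), ``events.log`` and ``manifest.json`` into ``out_dir``.
    The trailing-median filter is applied to the live concentration
    stream per analyte (k=1 disables smoothing).
    """
    if filter_k < 1 or filter_k % 2 == 0:
        raise ValidationError(f"filter_k must be odd and >= 1, got {filter_k}")
    for ch in schedule.channels:
        if ch.analyte not in curves:
            raise InvalidCalibrationError(
                f"refusing to start: no calibration for {ch.analyte!r}"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state = StreamState(schedule)
    raw_by_analyte: dict[str, list[MeasurementRecord]] = {}
    with (out_dir / "records.csv").open("w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for cycle in source:
            recs = process_cycle(cycle, curves, state)
            for rec in recs:
                history = raw_by_analyte.setdefault(rec.analyte, [])
                history.append(rec)
                flags = set(rec.flags)
                if len(history) < filter_k:
                    conc = rec.concentration
                    flags.add(WARMUP)
                else:
                    conc = statistics.median(
                        r.concentration for r in history[-filter_k:]
                    )
                filtered = MeasurementRecord(
                    rec.timestamp_s, rec.analyte, rec.raw_intensity,
                    rec.dark_intensity, rec.net_intensity, conc, flags,
                )
                w.writerow(_record_row(filtered))
            fh.flush()
    (out_dir / "events.log").write_text(
        "".join(f"{line}\n" for line in state.events)
    )
    manifest = {
        "schema": "perfusense.manifest/1",
        "run_id": run_id,
        "created_unix": _time.time(),
        "schedule": {
            "channels": [ch.analyte for ch in schedule.channels],
            "integration_time_s": schedule.integration_time_s,
            "per_frame_overhead_s": schedule.per_frame_overhead_s,
            "dark_every_frame": schedule.dark_every_frame,
            "cycle_period_s": cycle_period(schedule),
        },
        "curves": {a: {"slope": c.slope, "intercept": c.intercept,
                       "lod": c.lod, "blank_offset": c.blank_offset}
                   for a, c in curves.items()},
        "filter_k": filter_k,
        "seed": seed,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir
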