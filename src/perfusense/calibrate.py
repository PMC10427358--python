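"""Calibration of the fluorometric channels.

A calibration run circulates standards of known concentration, waits for
the signal to reach steady state, averages over a trailing window and
fits net band intensity against concentration by ordinary least squares.
The blank noise σ and fitted slope give the limit of detection with the
conventional 3σ_blank/slope definition; the run-specific blank offset is
the mean of ten pure-matrix quantifications and is subtracted from all
subsequent estimates.

The module also provides the cross-talk matrix check (each channel must
respond only to its own analyte), the agreement report against an
independent reference method, and the nominal [M+H]+ adduct mass used to
confirm analyte identity in LC-MS validation runs.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidCalibrationError,
    ValidationError,
)

#: Integer nominal atomic masses for adduct m/z expectation.
NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "P": 31, "S": 32}

#: Molecular formulas of the analytes whose identity is confirmed by LC-MS.
ANALYTE_FORMULA = {"FMN": "C17H21N4O9P", "CREATININE": "C4H7N3O"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class CalibrationCurve:
    """Linear intensity↔concentration map for one analyte.

    slope/intercept are in counts·s⁻¹ (band intensity units) per µg/mL
    and counts·s⁻¹; lod and blank_offset are in µg/mL.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    sigma_blank: float
    lod: float
    n_standards: int
    blank_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidCalibrationError(
                f"{self.analyte}: fitted slope must be > 0, got {self.slope}"
            )
        if self.lod < 0:
            raise InvalidCalibrationError("lod must be >= 0")
        if self.n_standards < 2:
            raise InvalidCalibrationError("a curve needs >= 2 standards")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema"] = "perfusense.curve/1"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationCurve":
        d = {k: v for k, v in d.items() if k != "schema"}
        return cls(**d)


def save_curves(path: str | Path, curves: Mapping[str, CalibrationCurve]) -> None:
    doc = {name: c.to_dict() for name, c in curves.items()}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_curves(path: str | Path) -> dict[str, CalibrationCurve]:
    doc = json.loads(Path(path).read_text())
    return {name: CalibrationCurve.from_dict(d) for name, d in doc.items()}


@dataclass
class StandardRun:
    """Timestamped intensity trace recorded while circulating one standard."""

    analyte: str
    concentration: float
    times_s: np.ndarray
    intensities: np.ndarray
    matrix: str = "BELZER_MPS"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentration < 0:
            raise ValidationError("standard concentration must be >= 0")
        if len(self.times_s) == 0 or self.times_s.shape != self.intensities.shape:
            raise ValidationError("standard run series must be nonempty and aligned")


@dataclass
class SteadyStateResult:
    """Trailing-window average with a slope-based steadiness verdict."""

    mean: float
    is_steady: bool
    slope_per_min: float
    p_value: float
    window_min: float
    n_points: int


def steady_state_average(run: StandardRun, window_min: float = 5.0) -> SteadyStateResult:
    """Average the trailing ``window_min`` minutes of a standard run.

    Steady state is declared when the OLS slope of intensity vs time over
    the window is statistically indistinguishable from zero (two-sided
    t-test, α = 0.05). A non-steady window still returns its mean but
    with ``is_steady=False`` so the caller can reject or extend the run.
    """
    span_min = (run.times_s[-1] - run.times_s[0]) / 60.0
    if span_min < window_min:
        raise InsufficientDataError(
            f"run spans {span_min:.2f} min < window {window_min} min"
        )
    t0 = run.times_s[-1] - window_min * 60.0
    m = run.times_s >= t0
    t = run.times_s[m] / 60.0
    y = run.intensities[m]
    mean = float(y.mean())
    if len(t) < 3 or np.allclose(y, y[0]):
        return SteadyStateResult(mean, True, 0.0, 1.0, window_min, len(t))
    res = stats.linregress(t, y)
    is_steady = bool(res.pvalue >= 0.05)
    return SteadyStateResult(mean, is_steady, float(res.slope), float(res.pvalue),
                             window_min, len(t))


def limit_of_detection(sigma_blank: float, slope: float, multiplier: float = 3.0) -> float:
    """LOD = multiplier·σ_blank/slope in µg/mL (3σ convention by default)."""
    if slope <= 0:
        raise InvalidCalibrationError(f"slope must be > 0, got {slope}")
    if sigma_blank < 0:
        raise InvalidCalibrationError("sigma_blank must be >= 0")
    return multiplier * sigma_blank / slope


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    lod_multiplier: float = 3.0,
) -> CalibrationCurve:
    """Ordinary least squares of net intensity on standard concentration.

    ``points`` are (concentration µg/mL, intensity counts/s) pairs; blank
    replicates are points at concentration 0. σ_blank is the sample SD of
    the blanks when ≥ 3 are present, otherwise the RMS fit residual.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InsufficientDataError("need >= 2 (concentration, intensity) points")
    conc, inten = pts[:, 0], pts[:, 1]
    if np.allclose(conc, conc[0]):
        raise DegenerateDesignError("all standard concentrations identical")
    res = stats.linregress(conc, inten)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise InvalidCalibrationError(
            f"{analyte or 'calibration'}: fitted slope {slope:.4g} is not positive"
        )
    predicted = slope * conc + intercept
    resid = inten - predicted
    ss_tot = float(((inten - inten.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    blanks = inten[conc == 0]
    if len(blanks) >= 3:
        sigma_blank = float(blanks.std(ddof=1))
    else:
        dof = max(len(pts) - 2, 1)
        sigma_blank = float(np.sqrt((resid ** 2).sum() / dof))
    lod = limit_of_detection(sigma_blank, slope, lod_multiplier)
    return CalibrationCurve(
        analyte=analyte, slope=slope, intercept=intercept,
        r_squared=r_squared, sigma_blank=sigma_blank, lod=lod,
        n_standards=len(pts),
    )


def blank_offset(blank_concentrations: Sequence[float], n_required: int = 10) -> float:
    """Run-specific additive offset: mean of the first ``n_required`` blanks.

    The blank estimates must be signed (not clipped at zero), otherwise
    the offset is biased upward.
    """
    vals = np.asarray(blank_concentrations, dtype=float)
    if len(vals) < n_required:
        raise InsufficientDataError(
            f"need >= {n_required} blank quantifications, got {len(vals)}"
        )
    return float(vals[:n_required].mean())


@dataclass
class CrosstalkReport:
    """Relative channel responses, normalised to each channel's own analyte."""

    channels: list[str]
    analytes: list[str]
    matrix: np.ndarray  # entry (i, j): channel i response per unit analyte j
    threshold: float
    verdict: str  # PASS / FAIL / INCOMPLETE
    failures: list[tuple[str, str, float]] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema": "perfusense.crosstalk/1",
            "channels": self.channels,
            "analytes": self.analytes,
            "matrix": [[None if np.isnan(v) else float(v) for v in row]
                       for row in self.matrix],
            "threshold": self.threshold,
            "verdict": self.verdict,
            "failures": [list(f) for f in self.failures],
            "missing": self.missing,
        }


def crosstalk_matrix(
    responses: Mapping[str, Sequence[tuple[float, Mapping[str, float]]]],
    channel_analytes: Sequence[str],
    threshold: float = 0.05,
) -> CrosstalkReport:
    """Cross-talk matrix from single-analyte standard runs.

    ``responses[analyte]`` is a list of (concentration, {channel → net
    intensity}) points measured while only that analyte was present.
    Entry (i, j) is the slope of channel i's intensity vs analyte j's
    concentration, normalised by the channel's own-analyte slope (i, i).
    Off-diagonals above ``threshold`` fail; a column with no concentration
    spread is reported missing rather than failing.
    """
    channels = list(channel_analytes)
    analytes = list(channel_analytes)
    for a in analytes:
        if a not in responses:
            raise DegenerateDesignError(f"no single-analyte runs for {a!r} (diagonal missing)")
    raw = np.full((len(channels), len(analytes)), np.nan)
    missing: list[str] = []
    for j, analyte in enumerate(analytes):
        pts = responses[analyte]
        conc = np.array([p[0] for p in pts], dtype=float)
        if len(conc) < 2 or np.allclose(conc, conc[0]):
            missing.append(analyte)
            continue
        for i, ch in enumerate(channels):
            inten = np.array([p[1][ch] for p in pts], dtype=float)
            raw[i, j] = stats.linregress(conc, inten).slope
    norm = raw.copy()
    for i in range(len(channels)):
        diag = raw[i, i]
        if np.isnan(diag) or diag <= 0:
            if channels[i] not in missing:
                missing.append(channels[i])
            continue
        norm[i, :] = raw[i, :] / diag
    failures = []
    for i, ch in enumerate(channels):
        for j, a in enumerate(analytes):
            if i == j or np.isnan(norm[i, j]):
                continue
            if abs(norm[i, j]) >= threshold:
                failures.append((ch, a, float(norm[i, j])))
    verdict = "INCOMPLETE" if missing else ("FAIL" if failures else "PASS")
    return CrosstalkReport(channels, analytes, norm, threshold, verdict,
                           failures, missing)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula over {C,H,N,O,P,S}."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in NOMINAL_MASS:
            raise ValidationError(f"unknown element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


def expected_adduct_mz(formula: str, adduct: str = "+H") -> int:
    """Nominal m/z of a singly charged adduct from integer atomic masses.

    Only the [M+H]+ adduct is supported; it is the species observed for
    both FMN (457 Da) and creatinine (114 Da) in the validation runs.
    """
    if adduct != "+H":
        raise ValidationError(f"unsupported adduct {adduct!r}; only '+H'")
    counts = parse_formula(formula)
    mass = sum(NOMINAL_MASS[e] * n for e, n in counts.items())
    return mass + NOMINAL_MASS["H"]


@dataclass
class AgreementReport:
    """Sensor-vs-reference method comparison (OLS of sensor on reference)."""

    slope: float
    intercept: float
    r: float
    bias: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema"] = "perfusense.agreement/1"
        return d


def validate_against_reference(
    sensor: Sequence[float], reference: Sequence[float]
) -> AgreementReport:
    """Compare paired sensor and reference concentrations.

    OLS regression of sensor on reference, Pearson r and mean bias
    (sensor − reference)."""
    s = np.asarray(sensor, dtype=float)
    r_ = np.asarray(reference, dtype=float)
    if s.shape != r_.shape or s.ndim != 1 or len(s) < 3:
        raise InsufficientDataError("need >= 3 aligned (sensor, reference) pairs")
    res = stats.linregress(r_, s)
    return AgreementReport(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), bias=float((s - r_).mean()), n=len(s),
    )
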