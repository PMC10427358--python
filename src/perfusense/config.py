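"""Structured run configuration (YAML) with strict validation.

All physical invariants are checked at load time — flows positive,
Stokes shift respected, windows odd — and unknown keys are rejected so
simulated "clinical" runs stay auditable. Defaults mirror the instrument
as operated: 2 s integration, ±10 nm readout band, median-of-5 filter.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ValidationError
from .flowchem import AssayTrain
from .spectra import ANALYTE_MOLAR_MASS, AnalyteChannel
from .streaming import LedSchedule


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelConfig(_Strict):
    analyte: str
    excitation_nm: float = Field(gt=0)
    emission_nm: float = Field(gt=0)
    led_id: str
    band_halfwidth_nm: float = Field(default=10.0, gt=0)
    molar_mass_g_per_mol: Optional[float] = None

    @model_validator(mode="after")
    def _stokes(self) -> "ChannelConfig":
        if self.excitation_nm >= self.emission_nm:
            raise ValueError(
                f"channel {self.analyte}: Stokes shift rule requires "
                f"excitation_nm < emission_nm "
                f"({self.excitation_nm} >= {self.emission_nm})"
            )
        return self

    def to_domain(self) -> AnalyteChannel:
        mass = self.molar_mass_g_per_mol
        if mass is None:
            mass = ANALYTE_MOLAR_MASS.get(self.analyte, 0.0)
        return AnalyteChannel(
            analyte=self.analyte, excitation_nm=self.excitation_nm,
            emission_nm=self.emission_nm, led_id=self.led_id,
            band_halfwidth_nm=self.band_halfwidth_nm,
            molar_mass_g_per_mol=mass,
        )


class NoiseConfig(_Strict):
    mode: Literal["anchored", "none", "explicit"] = "anchored"
    lod_nM: float = Field(default=4.4, gt=0)
    dark_mean: float = Field(default=200.0, ge=0)
    dark_sd: float = Field(default=40.0, ge=0)
    shot_factor: float = Field(default=1.0, ge=0)
    ambient_drift_amplitude: float = Field(default=10.0, ge=0)
    ambient_drift_period_s: float = Field(default=600.0, gt=0)

    def to_domain(self, seed: int = 0):
        from . import simulate

        if self.mode == "none":
            return simulate.NoiseModel.none(seed)
        if self.mode == "anchored":
            return simulate.anchored_noise(
                seed, lod_nM=self.lod_nM, dark_mean=self.dark_mean,
                shot_factor=self.shot_factor,
                ambient_drift_amplitude=self.ambient_drift_amplitude,
                ambient_drift_period_s=self.ambient_drift_period_s,
            )
        return simulate.NoiseModel(
            dark_mean=self.dark_mean, dark_sd=self.dark_sd,
            shot_factor=self.shot_factor,
            ambient_drift_amplitude=self.ambient_drift_amplitude,
            ambient_drift_period_s=self.ambient_drift_period_s, seed=seed,
        )


class ScheduleConfig(_Strict):
    integration_time_s: float = Field(default=2.0, gt=0)
    per_frame_overhead_s: float = Field(default=0.75, ge=0)
    dark_every_frame: bool = True
    filter_k: int = Field(default=5, ge=1)

    @field_validator("filter_k")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("filter_k must be odd")
        return v

    def to_domain(self, channels: tuple[AnalyteChannel, ...]) -> LedSchedule:
        return LedSchedule(
            channels=channels, integration_time_s=self.integration_time_s,
            per_frame_overhead_s=self.per_frame_overhead_s,
            dark_every_frame=self.dark_every_frame,
        )


class ReleaseConfig(_Strict):
    kind: Literal["plateau", "progressive"]
    r0_ug_per_min: float = Field(ge=0)
    tau_min: float = Field(default=25.0, gt=0)
    accel_ug_per_min2: float = 0.0


class HopeConfig(_Strict):
    perfusate_volume_L: float = Field(default=3.0, gt=0)
    duration_min: float = Field(default=60.0, gt=0)
    flow_rate_mL_min: float = Field(default=250.0, gt=0, le=250.0)
    release: dict[str, ReleaseConfig] = Field(
        default_factory=lambda: {"FMN": ReleaseConfig(kind="plateau", r0_ug_per_min=6.0)}
    )

    def to_domain(self):
        from . import simulate

        return simulate.HopeScenario(
            release_profiles={
                a: simulate.ReleaseProfile(
                    r.kind, r.r0_ug_per_min, tau_min=r.tau_min,
                    accel_ug_per_min2=r.accel_ug_per_min2,
                )
                for a, r in self.release.items()
            },
            perfusate_volume_L=self.perfusate_volume_L,
            duration_min=self.duration_min,
            flow_rate_mL_min=self.flow_rate_mL_min,
        )


class DialysisConfig(_Strict):
    blood_volume_L: float = Field(default=5.0, gt=0)
    initial_creatinine_mg_dL: float = Field(default=8.0, ge=0)
    generation_rate_mg_min: float = Field(default=1.0, ge=0)
    dialyzer_clearance_mL_min: float = Field(default=100.0, ge=0)
    blood_bypass_flow_L_min: float = Field(default=0.2, gt=0)
    dialysate_flow_mL_h: float = Field(default=200.0, gt=0)
    duration_h: float = Field(default=24.0, gt=0)

    def to_domain(self):
        from . import simulate

        return simulate.DialysisScenario(**self.model_dump())


class AssayTrainConfig(_Strict):
    dialysate_flow_mL_h: float = Field(default=20.0, gt=0)
    naoh_flow_mL_h: float = Field(default=5.0, ge=0)
    reagent_flow_mL_h: float = Field(default=5.0, ge=0)
    transit_delay_min: float = Field(default=30.0, ge=0)
    equilibration_factor: float = Field(default=1.0, gt=0, le=1)

    def to_domain(self) -> AssayTrain:
        return AssayTrain(**self.model_dump())


class RunConfig(_Strict):
    channels: list[ChannelConfig] = Field(default_factory=list)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    hope: HopeConfig = Field(default_factory=HopeConfig)
    dialysis: DialysisConfig = Field(default_factory=DialysisConfig)
    assay_train: AssayTrainConfig = Field(default_factory=AssayTrainConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (strict: unknown keys fail)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic names the key and constraint
        raise ValidationError(f"{path}: {exc}") from exc


def config_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
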