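"""Run configuration: every tunable threshold of the pipeline in one
serializable object, so operating points can be changed without code edits.

All artifacts written by the CLI embed a schema version, the package
version, the seed and a hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib

import yaml
from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = 1


class DetectorConfig(BaseModel):
    """Slow-potential extraction and detection parameters."""

    sp_corner_hz: float = Field(3.0, gt=0, description="SP band upper corner (Hz)")
    sp_low_hz: float = Field(0.1, ge=0, description="SP band lower corner (Hz)")
    decimate_to_hz: float | None = Field(
        50.0, gt=0, description="working rate for SP-band filtering; None = native"
    )
    threshold_mode: str = Field("k_mad", pattern="^(k_mad|fixed_uV)$")
    k: float = Field(5.0, gt=0, description="threshold in robust noise SDs")
    threshold_uV: float | None = Field(None, gt=0)
    refractory_s: float = Field(1.0, gt=0, description="detector dead time (s)")
    window_s: float = Field(60.0, gt=0, description="frequency profile window (s)")
    discard_initial_s: float = Field(
        60.0, ge=0, description="post-switch transient discarded from segment stats (s)"
    )


class BiphasicConfig(BaseModel):
    """Acceptance window and shape fractions for the biphasic check."""

    peak_min_min: float = Field(2.0, gt=0)
    peak_max_min: float = Field(10.0, gt=0)
    decline_fraction: float = Field(0.7, gt=0, le=1)
    plateau_fraction: float = Field(0.4, gt=0, le=1)
    min_peak_hz: float = Field(0.1, gt=0)
    smooth_windows: int = Field(3, ge=1)
    min_span_min: float = Field(20.0, gt=0)
    decline_search_min: float = Field(8.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.peak_max_min <= self.peak_min_min:
            raise ValueError("peak_max_min must exceed peak_min_min")
        return self


class DecisionConfig(BaseModel):
    """Thresholds of the potency decision tree."""

    g1_threshold_hz: float = Field(0.5, gt=0, description="activity gate at 1 mmol/L glucose")
    alpha: float = Field(0.05, gt=0, lt=1, description="one-sided level for response tests")
    fold_floor: float = Field(2.0, ge=1, description="minimum fold change (OR abs floor)")
    abs_floor_hz: float = Field(0.1, ge=0, description="minimum absolute rise (OR fold floor)")
    fold_min_stim_hz: float = Field(
        0.05, ge=0,
        description="minimum stimulated rate for the fold floor to count as an effect",
    )
    epi_fall_fraction: float = Field(0.5, gt=0, lt=1, description="EPI silencing cutoff")
    epi_rise_factor: float = Field(1.5, gt=1, description="EPI enhancement cutoff")
    dose_alpha: float = Field(0.05, gt=0, lt=1)
    dose_ratio: float = Field(2.0, ge=1, description="top/bottom concentration rate ratio")
    dose_abs_floor_hz: float = Field(0.05, ge=0, description="top-bottom absolute floor")
    min_electrodes: int = Field(5, ge=2)
    biphasic: BiphasicConfig = Field(default_factory=BiphasicConfig)


class BetaScoreConfig(BaseModel):
    """Cut points of the 0-8 graft-function score."""

    glucose_full_mmol: float = Field(5.5, gt=0)
    glucose_zero_mmol: float = Field(7.0, gt=0, description="diabetic-range fasting glucose")
    hba1c_full_pct: float = Field(6.1, gt=0)
    hba1c_zero_pct: float = Field(6.9, gt=0)
    c_peptide_full_nmol: float = Field(0.3, gt=0)
    c_peptide_absent_nmol: float = Field(
        0.1, ge=0, description="treated as absent secretion when no stimulation data"
    )
    insulin_zero_u_per_kg: float = Field(0.24, gt=0)
    optimal_min: int = Field(7, ge=0, le=8)
    suboptimal_min: int = Field(4, ge=0, le=8)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.glucose_full_mmol < self.glucose_zero_mmol):
            raise ValueError("glucose cut points out of order")
        if not (self.hba1c_full_pct < self.hba1c_zero_pct):
            raise ValueError("HbA1c cut points out of order")
        if not (self.c_peptide_absent_nmol < self.c_peptide_full_nmol):
            raise ValueError("C-peptide cut points out of order")
        if not (0 < self.suboptimal_min <= self.optimal_min):
            raise ValueError("category bands out of order")
        return self


class SimulationConfig(BaseModel):
    """Synthetic recording parameters."""

    archetype: str = "biphasic"
    n_electrodes: int = Field(60, ge=2)
    occupied_fraction: float = Field(0.5, gt=0, lt=1)
    sampling_rate_hz: float = Field(1000.0, gt=0)
    segment_s: float = Field(900.0, gt=0)
    biphasic_s: float = Field(1500.0, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration for an end-to-end run."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    decision: DecisionConfig = Field(default_factory=DecisionConfig)
    beta: BetaScoreConfig = Field(default_factory=BetaScoreConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {version} not supported (expected {SCHEMA_VERSION})"
            )
        return cls.model_validate(data)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every report."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
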