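"""Pipeline configuration: every fixed numeric constant of the analysis.

All sequence parameters, calibration constants, quality-control thresholds,
titration constants and statistical significance levels live here (not as
literals inside the computational modules), are validated on construction,
and round-trip losslessly through YAML.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError

__all__ = [
    "AcquisitionConfig",
    "QCConfig",
    "StatsConfig",
    "WaterConfig",
    "PhantomConfig",
    "DerivedConfig",
    "RelaxationConfig",
    "SimulationConfig",
    "PipelineConfig",
    "default_config",
]


class AcquisitionConfig(BaseModel):
    """Per-channel sequence parameters."""

    tr_ms: float = Field(gt=0)
    te_ms: float = Field(ge=0)
    flip_deg: float = Field(gt=0, le=180)
    bandwidth_hz: float = Field(gt=0)
    vector_size: int = Field(ge=64)
    nucleus_freq_mhz: float = Field(gt=0)
    carrier_ppm: float = 0.0

    @model_validator(mode="after")
    def _tr_gt_te(self):
        if not self.tr_ms > self.te_ms:
            raise ValueError("TR must exceed TE")
        return self


class QCConfig(BaseModel):
    """Spectral quality-control thresholds."""

    snr_min: float = Field(default=3.0, gt=0)
    percent_sd_max: float = Field(default=20.0, gt=0)  # %SD limit for Cr and Cho (proton)
    relative_error_max: float = Field(default=1.0, gt=0)  # per-peak CRLB/amplitude limit


class StatsConfig(BaseModel):
    """Significance levels of the cohort statistics."""

    alpha: float = Field(default=0.05, gt=0, lt=1)
    # Bonferroni thresholds: alpha/9 simultaneously analysed phosphorus regions,
    # alpha/4 proton regions and bilateral comparisons, rounded as reported.
    bonferroni_phosphorus: float = Field(default=0.0056, gt=0, lt=1)
    bonferroni_proton: float = Field(default=0.0125, gt=0, lt=1)
    n_phosphorus_regions: int = 9
    n_bilateral_regions: int = 4


class WaterConfig(BaseModel):
    """Internal-water calibration constants (proton channel)."""

    molality_mmol_per_kg: float = Field(default=55510.0, gt=0)
    content_gm: float = Field(default=0.78, gt=0, le=1)
    content_wm: float = Field(default=0.65, gt=0, le=1)
    content_csf: float = Field(default=0.97, gt=0, le=1)
    protons: int = 2


class PhantomConfig(BaseModel):
    """External-reference (phantom replacement) constants, phosphorus channel."""

    concentration_mmol_per_l: float = Field(default=75.0, gt=0)  # KH2PO4 solution
    t1_ms: float = Field(default=5200.0, gt=0)  # Pi resonance of the aqueous phantom
    flip_deg: float = Field(default=60.0, gt=0, le=180)
    tr_ms: float = Field(default=1200.0, gt=0)


class DerivedConfig(BaseModel):
    """Titration constants of the chemical-shift pH and magnesium estimates."""

    ph_pk: float = 6.75
    ph_delta_acid: float = 3.27  # ppm, acid-limit Pi-PCr shift
    ph_delta_base: float = 5.63  # ppm, base-limit Pi-PCr shift
    mg_pk: float = 4.24
    mg_delta_lower: float = -18.58  # ppm, fully Mg-bound beta-ATP-PCr shift bound
    mg_delta_upper: float = -15.74  # ppm, Mg-free bound
    mg_exponent_lower: float = 0.42
    mg_exponent_upper: float = 0.84

    @model_validator(mode="after")
    def _ordered(self):
        if not self.ph_delta_acid < self.ph_delta_base:
            raise ValueError("pH titration bounds out of order")
        if not self.mg_delta_lower < self.mg_delta_upper:
            raise ValueError("pMg titration bounds out of order")
        return self


class RelaxationConfig(BaseModel):
    """Literature relaxation times (ms) per metabolite and channel.

    The proton channel needs T1 and T2 (double-spin-echo correction); the
    phosphorus channel needs T1 only (short-TE FID acquisition).  Water is
    tabulated per tissue compartment.  All values are overridable defaults
    representative of healthy brain at 3 T.
    """

    proton_t1_ms: dict[str, float] = Field(default_factory=lambda: {
        "tNAA": 1400.0, "tCr": 1350.0, "tCho": 1200.0,
    })
    proton_t2_ms: dict[str, float] = Field(default_factory=lambda: {
        "tNAA": 250.0, "tCr": 160.0, "tCho": 220.0,
    })
    water_t1_ms: dict[str, float] = Field(default_factory=lambda: {
        "GM": 1330.0, "WM": 830.0, "CSF": 4000.0,
    })
    water_t2_ms: dict[str, float] = Field(default_factory=lambda: {
        "GM": 110.0, "WM": 80.0, "CSF": 500.0,
    })
    phosphorus_t1_ms: dict[str, float] = Field(default_factory=lambda: {
        "PE": 4500.0, "PC": 4200.0, "Pi": 3800.0, "GPE": 5000.0, "GPC": 4500.0,
        "PCr": 4000.0, "gATP": 1200.0, "aATP": 1100.0, "bATP": 1300.0,
        "NAD": 2000.0, "MM": 500.0,
    })

    @model_validator(mode="after")
    def _positive_and_ordered(self):
        for table in (self.proton_t1_ms, self.proton_t2_ms, self.water_t1_ms,
                      self.water_t2_ms, self.phosphorus_t1_ms):
            for name, value in table.items():
                if value <= 0:
                    raise ValueError(f"relaxation time for {name} must be > 0")
        for name, t2 in self.proton_t2_ms.items():
            t1 = self.proton_t1_ms.get(name)
            if t1 is not None and t2 > t1:
                raise ValueError(f"{name}: T2 must not exceed T1")
        for comp, t2 in self.water_t2_ms.items():
            if t2 > self.water_t1_ms[comp]:
                raise ValueError(f"water {comp}: T2 must not exceed T1")
        return self


class SimulationConfig(BaseModel):
    """Synthetic-data generator settings (cohort structure and noise)."""

    group_sizes: dict[str, int] = Field(default_factory=lambda: {"fN": 21, "mN": 26, "mC": 40})
    cv: float = Field(default=0.15, ge=0, le=0.5)  # inter-subject concentration CV
    cv_ph: float = Field(default=0.005, ge=0, le=0.5)  # pH varies far less than concentrations
    hemispheric_correlation: float = Field(default=0.7, ge=0, lt=1)
    seed: int = 0

    @field_validator("group_sizes")
    @classmethod
    def _sizes(cls, v):
        for g, n in v.items():
            if n < 2:
                raise ValueError(f"group {g}: size must be >= 2")
        return v


class ProtonCountsConfig(BaseModel):
    """Protons contributing to each observed proton resonance (molar scaling)."""

    counts: dict[str, float] = Field(default_factory=lambda: {
        "tNAA": 3.0,   # NAA CH3
        "tCr": 3.0,    # creatine CH3
        "tCho": 9.0,   # choline N(CH3)3
        "water": 2.0,
    })


class PipelineConfig(BaseModel):
    """Root configuration of the reproducible pipeline."""

    proton: AcquisitionConfig = Field(default_factory=lambda: AcquisitionConfig(
        tr_ms=1500.0, te_ms=135.0, flip_deg=90.0, bandwidth_hz=1200.0,
        vector_size=1024, nucleus_freq_mhz=123.2, carrier_ppm=4.70))
    phosphorus: AcquisitionConfig = Field(default_factory=lambda: AcquisitionConfig(
        tr_ms=1200.0, te_ms=2.3, flip_deg=60.0, bandwidth_hz=2000.0,
        vector_size=1024, nucleus_freq_mhz=49.9, carrier_ppm=0.0))
    qc: QCConfig = Field(default_factory=QCConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    water: WaterConfig = Field(default_factory=WaterConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    derived: DerivedConfig = Field(default_factory=DerivedConfig)
    relaxation: RelaxationConfig = Field(default_factory=RelaxationConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    proton_counts: ProtonCountsConfig = Field(default_factory=ProtonCountsConfig)
    # 31P chemical shifts relative to PCr (ppm); Pi default corresponds to pH 6.99
    phosphorus_shifts_ppm: dict[str, float] = Field(default_factory=lambda: {
        "PE": 6.78, "PC": 6.24, "Pi": 4.77, "GPE": 3.50, "GPC": 2.96, "PCr": 0.0,
        "gATP": -2.5, "aATP": -7.5, "NAD": -8.3, "bATP": -16.1, "MM": 2.0,
    })
    proton_shifts_ppm: dict[str, float] = Field(default_factory=lambda: {
        "tNAA": 2.01, "tCr": 3.03, "tCho": 3.20, "water": 4.70,
    })
    atp_j_hz: float = Field(default=16.0, ge=0)
    seed: int = 0
    out_dir: str = "mrsquant_out"

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        try:
            payload = yaml.safe_load(text) or {}
            return cls.model_validate(payload)
        except Exception as exc:  # surfacing as a single config error for the CLI
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def default_config() -> PipelineConfig:
    return PipelineConfig()
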