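"""Synthetic data generators: FIDs, voxel contexts and cohort tables.

The generators emulate the study conditions of the cohort analysis:

* phosphorus spectra as sums of Lorentzian-damped sinusoids for PE, PC,
  Pi, GPE, GPC, PCr, the seven ATP multiplet peaks, NAD and one very
  broad macromolecular hump, plus circular complex Gaussian noise;
* long-TE proton spectra with three singlets (tNAA, tCr, tCho) and a
  separate unsuppressed-water reference FID;
* cohorts of three groups (fN n=21, mN n=26, mC n=40) over nine volumes
  of interest, drawn log-normally around published group means with a
  shared within-subject component that correlates the two hemispheres.

Every generator takes an explicit seed and attaches its ground truth, so
downstream estimation stages can be validated by recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .config import PipelineConfig, default_config
from .errors import SchemaError
from .quantify import VoxelContext
from .spectral import (AcquisitionParams, FidRecord, Multiplet, ResonanceSpec,
                       spectrum, synthesize)

__all__ = [
    "phosphorus_acquisition",
    "proton_acquisition",
    "default_phosphorus_model",
    "default_proton_model",
    "water_reference_model",
    "simulate_fid",
    "noise_sd_for_snr",
    "simulate_voxel_context",
    "CohortDesign",
    "default_cohort_design",
    "simulate_cohort",
]


# --------------------------------------------------------------------------
# acquisitions and spectral models
# --------------------------------------------------------------------------

def phosphorus_acquisition(config: PipelineConfig | None = None) -> AcquisitionParams:
    cfg = (config or default_config()).phosphorus
    return AcquisitionParams(tr_ms=cfg.tr_ms, te_ms=cfg.te_ms, flip_deg=cfg.flip_deg,
                             bandwidth_hz=cfg.bandwidth_hz, vector_size=cfg.vector_size,
                             nucleus_freq_mhz=cfg.nucleus_freq_mhz, channel="phosphorus",
                             carrier_ppm=cfg.carrier_ppm)


def proton_acquisition(config: PipelineConfig | None = None) -> AcquisitionParams:
    cfg = (config or default_config()).proton
    return AcquisitionParams(tr_ms=cfg.tr_ms, te_ms=cfg.te_ms, flip_deg=cfg.flip_deg,
                             bandwidth_hz=cfg.bandwidth_hz, vector_size=cfg.vector_size,
                             nucleus_freq_mhz=cfg.nucleus_freq_mhz, channel="proton",
                             carrier_ppm=cfg.carrier_ppm)


#: default amplitudes (arbitrary signal units, roughly proportional to tissue
#: concentrations) of the standard phosphorus model
_P_AMPLITUDES = {
    "PE": 1.35, "PC": 1.30, "Pi": 0.60, "GPE": 1.45, "GPC": 1.40, "PCr": 3.60,
    "gATP": 2.50, "aATP": 2.50, "bATP": 2.50, "NAD": 0.30, "MM": 3.00,
}


def default_phosphorus_model(config: PipelineConfig | None = None,
                             amplitudes: dict[str, float] | None = None,
                             damping_hz: float = 5.0,
                             mm_damping_hz: float = 200.0) -> list[ResonanceSpec]:
    """The standard in-vivo phosphorus prior-knowledge model.

    Six singlets (PE, PC, Pi, GPE, GPC, PCr), the seven ATP peaks as two
    doublets (gamma, alpha) and one 1:2:1 triplet (beta), NAD, and one
    very broad macromolecular component carrying the baseline.
    """
    cfg = config or default_config()
    shifts = cfg.phosphorus_shifts_ppm
    amps = dict(_P_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)
    j = cfg.atp_j_hz
    model = []
    for name in ("PE", "PC", "Pi", "GPE", "GPC", "PCr"):
        model.append(ResonanceSpec(name, shifts[name], amps[name], damping_hz))
    model.append(ResonanceSpec("gATP", shifts["gATP"], amps["gATP"], damping_hz,
                               multiplet=Multiplet(2, j)))
    model.append(ResonanceSpec("aATP", shifts["aATP"], amps["aATP"], damping_hz,
                               multiplet=Multiplet(2, j)))
    model.append(ResonanceSpec("NAD", shifts["NAD"], amps["NAD"], damping_hz))
    model.append(ResonanceSpec("bATP", shifts["bATP"], amps["bATP"], damping_hz,
                               multiplet=Multiplet(3, j)))
    model.append(ResonanceSpec("MM", shifts["MM"], amps["MM"], mm_damping_hz))
    return model


def default_proton_model(config: PipelineConfig | None = None,
                         amplitudes: dict[str, float] | None = None,
                         damping_hz: float = 4.0) -> list[ResonanceSpec]:
    """Long-TE proton model: three metabolite singlets (water suppressed)."""
    cfg = config or default_config()
    shifts = cfg.proton_shifts_ppm
    amps = {"tNAA": 68.0, "tCr": 48.0, "tCho": 40.0}
    if amplitudes:
        amps.update(amplitudes)
    return [ResonanceSpec(name, shifts[name], amps[name], damping_hz)
            for name in ("tNAA", "tCr", "tCho")]


def water_reference_model(amplitude: float = 1.0e4, damping_hz: float = 8.0,
                          config: PipelineConfig | None = None) -> list[ResonanceSpec]:
    """Unsuppressed tissue-water reference (single line at the carrier)."""
    cfg = config or default_config()
    return [ResonanceSpec("water", cfg.proton_shifts_ppm["water"], amplitude, damping_hz)]


# --------------------------------------------------------------------------
# FID simulation
# --------------------------------------------------------------------------

def simulate_fid(model: list[ResonanceSpec], acquisition: AcquisitionParams,
                 noise_sd: float = 0.0, seed: int | None = None) -> FidRecord:
    """Simulate a complex FID from a resonance list plus circular Gaussian noise.

    ``noise_sd`` is the standard deviation per real and per imaginary
    sample.  The generating model is attached as ground truth.
    """
    if noise_sd < 0:
        raise SchemaError("noise_sd must be >= 0")
    s = synthesize(model, acquisition)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sd, s.size) + 1j * rng.normal(0.0, noise_sd, s.size)
    return FidRecord(samples=s, acquisition=acquisition, ground_truth=tuple(model),
                     noise_sd=float(noise_sd), metadata={"seed": seed})


def noise_sd_for_snr(model: list[ResonanceSpec], acquisition: AcquisitionParams,
                     snr: float) -> float:
    """Time-domain noise SD that yields a given spectral SNR.

    SNR is the package-wide definition (tallest model peak in the
    magnitude spectrum over the RMS of the complex spectral noise); for
    white time-domain noise of SD sigma per component the spectral RMS is
    sigma * sqrt(2 N).
    """
    if snr <= 0:
        raise SchemaError("target SNR must be > 0")
    _, spec = spectrum(synthesize(model, acquisition), acquisition)
    peak = float(np.max(np.abs(spec)))
    return peak / (snr * math.sqrt(2.0 * acquisition.vector_size))


# --------------------------------------------------------------------------
# voxel contexts
# --------------------------------------------------------------------------

#: plausible (GM, WM, CSF) base fractions per region stem
_BASE_FRACTIONS = {
    "FGM": (0.65, 0.25, 0.10), "FWM": (0.25, 0.70, 0.05), "TH": (0.55, 0.40, 0.05),
    "BG": (0.60, 0.35, 0.05), "TL": (0.55, 0.35, 0.10),
}
#: voxel volume ranges (ml) per stem and channel
_VOLUME_RANGES = {
    "phosphorus": {"FGM": (12.0, 18.0), "FWM": (9.0, 14.0), "TH": (7.0, 11.0),
                   "BG": (8.0, 13.0), "TL": (7.0, 12.0)},
    "proton": {"FGM": (13.5, 15.0), "FWM": (11.0, 13.0), "TH": (9.0, 11.0),
               "TL": (8.0, 9.5)},
}


def _region_stem(region: str) -> str:
    return region.split("_", 1)[1] if "_" in region else region


def simulate_voxel_context(region: str, seed: int | None = None,
                           channel: str = "phosphorus") -> VoxelContext:
    """A plausible tissue-composition and calibration record for one voxel."""
    valid = tables.PHOSPHORUS_REGIONS if channel == "phosphorus" else tables.PROTON_REGIONS
    if region not in valid:
        raise SchemaError(f"unknown {channel} region label {region!r}")
    rng = np.random.default_rng(seed)
    stem = _region_stem(region)
    base = np.array(_BASE_FRACTIONS[stem])
    fractions = np.clip(base + rng.uniform(-0.04, 0.04, 3), 0.01, None)
    fractions /= fractions.sum()
    lo, hi = _VOLUME_RANGES[channel][stem]
    volume = float(rng.uniform(lo, hi))
    return VoxelContext(
        region=region,
        hemisphere=tables.hemisphere_of(region),
        f_gm=float(fractions[0]), f_wm=float(fractions[1]), f_csf=float(fractions[2]),
        volume_ml=volume,
        transmitter_amp_subject=float(rng.uniform(380.0, 440.0)),
        transmitter_amp_phantom=400.0,
    )


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Mean structure and noise model of a simulated cohort.

    ``mean_table`` is tidy (group, region, metabolite, mean).  ``cv`` is
    the inter-subject coefficient of variation of the log-normal draw
    (``cv_ph`` applies to pH, which varies far less than concentrations);
    ``hemispheric_correlation`` is the share of the log-variance carried
    by a subject-level component common to both hemispheres of a region.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(tables.GROUP_SIZES))
    mean_table: pd.DataFrame = field(default_factory=lambda: pd.concat(
        [tables.phosphorus_mean_table(), tables.proton_mean_table()], ignore_index=True))
    cv: float = 0.15
    cv_ph: float = 0.005
    hemispheric_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.cv <= 0.5):
            raise SchemaError("cv must lie in [0, 0.5] (0 = deterministic)")
        if not (0.0 <= self.cv_ph <= 0.5):
            raise SchemaError("cv_ph must lie in [0, 0.5]")
        if not (0.0 <= self.hemispheric_correlation < 1.0):
            raise SchemaError("hemispheric correlation must lie in [0, 1)")
        required = {"group", "region", "metabolite", "mean"}
        if not required.issubset(self.mean_table.columns):
            raise SchemaError(f"mean_table must have columns {sorted(required)}")
        known_regions = set(tables.PHOSPHORUS_REGIONS) | set(tables.PROTON_REGIONS)
        bad = set(self.mean_table["region"]) - known_regions
        if bad:
            raise SchemaError(f"unknown region labels: {sorted(bad)}")
        known_metabs = set(tables.PHOSPHORUS_METABOLITES) | set(tables.PROTON_METABOLITES)
        bad = set(self.mean_table["metabolite"]) - known_metabs
        if bad:
            raise SchemaError(f"unknown metabolite labels: {sorted(bad)}")
        if (self.mean_table["mean"] <= 0).any():
            raise SchemaError("all design means must be > 0")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise SchemaError(f"group {g}: size must be >= 2")


def default_cohort_design(config: PipelineConfig | None = None,
                          seed: int | None = None) -> CohortDesign:
    cfg = config or default_config()
    sim = cfg.simulation
    return CohortDesign(group_sizes=dict(sim.group_sizes), cv=sim.cv, cv_ph=sim.cv_ph,
                        hemispheric_correlation=sim.hemispheric_correlation,
                        seed=sim.seed if seed is None else seed)


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw a per-subject cohort concentration table.

    Each value is log-normal around its group x region x metabolite mean
    (mean-preserving parameterisation).  The log-variance splits into a
    subject-level component shared by the left and right voxel of a
    region stem (fraction ``hemispheric_correlation``) and an independent
    residual, which gives paired hemispheric tests their power.
    Deterministic under a fixed seed; cv = 0 returns the means exactly.
    """
    rng = np.random.default_rng(design.seed)
    means = design.mean_table
    rows: list[tuple] = []
    group_order = [g for g in tables.GROUPS if g in design.group_sizes]
    group_order += [g for g in design.group_sizes if g not in group_order]
    region_order = list(dict.fromkeys(means["region"]))
    for group in group_order:
        n = design.group_sizes[group]
        sub = means[means["group"] == group]
        if sub.empty:
            raise SchemaError(f"group {group!r} absent from mean table")
        cell = {(r.region, r.metabolite): r.mean for r in sub.itertuples()}
        subject_ids = [f"{group}{i + 1:03d}" for i in range(n)]
        # shared subject-level component per (region stem, metabolite)
        shared: dict[tuple[str, str], np.ndarray] = {}
        for region in region_order:
            stem = _region_stem(region)
            for metab in dict.fromkeys(sub["metabolite"]):
                if (region, metab) not in cell:
                    continue
                key = (stem, metab)
                if key not in shared:
                    shared[key] = rng.standard_normal(n)
                cv = design.cv_ph if metab == "pH" else design.cv
                sigma2 = math.log1p(cv * cv)
                sigma = math.sqrt(sigma2)
                rho = design.hemispheric_correlation
                z = (math.sqrt(rho) * shared[key]
                     + math.sqrt(1.0 - rho) * rng.standard_normal(n))
                values = cell[(region, metab)] * np.exp(sigma * z - 0.5 * sigma2)
                hemi = tables.hemisphere_of(region)
                rows.extend(
                    (sid, group, region, hemi, metab, float(v))
                    for sid, v in zip(subject_ids, values)
                )
    return pd.DataFrame(rows, columns=["subject_id", "group", "region", "hemisphere",
                                       "metabolite", "concentration_mmol_per_kg"])
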