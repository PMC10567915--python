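"""Absolute quantification: fitted amplitudes -> mmol per kg of brain tissue.

Two calibration routes are implemented, mirroring standard practice for
the two channels:

* **proton**: internal tissue-water reference.  Metabolite and water
  amplitudes are corrected for T1/T2 relaxation under the double-spin-echo
  sequence, the water signal is scaled by the tissue water content of the
  voxel (GM/WM/CSF volume fractions times compartment water contents
  0.78/0.65/0.97) and the molality of pure water, and the proton counts
  of the contributing moieties normalise signal to moles.

* **phosphorus**: phantom replacement.  Amplitudes are corrected for the
  reduced flip angle and T1 saturation of the FID sequence, referenced to
  an external KH2PO4 phantom of known concentration with its own
  relaxation factor, and corrected linearly for coil loading via the
  transmitter amplitudes required for a 90 degree pulse.

Both routes end with a partial-volume correction dividing by (1 - f_CSF),
yielding concentrations per kg of brain tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, default_config
from .errors import CalibrationError, DomainError, SchemaError
from .spectral import AcquisitionParams

__all__ = [
    "VoxelContext",
    "RelaxationTable",
    "ReferenceStandard",
    "QuantificationResult",
    "relaxation_factor_proton",
    "relaxation_factor_phosphorus",
    "csf_correct",
    "water_content_factor",
    "quantify_proton",
    "quantify_phosphorus",
    "amplitude_for_concentration_phosphorus",
    "amplitude_for_concentration_proton",
    "PHOSPHORUS_OUTPUT_MAP",
]

#: reported phosphorus quantities -> contributing fitted resonances.
#: ATP is quantified from the gamma-ATP resonance alone.
PHOSPHORUS_OUTPUT_MAP: dict[str, tuple[str, ...]] = {
    "PME": ("PE", "PC"),
    "Pi": ("Pi",),
    "PDE": ("GPE", "GPC"),
    "PCr": ("PCr",),
    "ATP": ("gATP",),
    "NAD": ("NAD",),
}


@dataclass(frozen=True)
class VoxelContext:
    """Tissue composition and calibration references of one voxel."""

    region: str
    hemisphere: str
    f_gm: float
    f_wm: float
    f_csf: float
    volume_ml: float
    water_content: tuple[float, float, float] = (0.78, 0.65, 0.97)
    transmitter_amp_subject: float | None = None
    transmitter_amp_phantom: float | None = None

    def __post_init__(self):
        fr = (self.f_gm, self.f_wm, self.f_csf)
        if min(fr) < 0:
            raise SchemaError("tissue fractions must be >= 0")
        if abs(sum(fr) - 1.0) > 1e-6:
            raise SchemaError(f"tissue fractions must sum to 1, got {sum(fr)!r}")
        if not (5.0 < self.volume_ml < 25.0):
            raise SchemaError(f"voxel volume {self.volume_ml} ml outside sanity bounds (5, 25)")
        if self.hemisphere not in ("left", "right", "midline"):
            raise SchemaError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class RelaxationTable:
    """Per-metabolite relaxation times (ms); water per tissue compartment."""

    proton_t1_ms: dict[str, float] = field(default_factory=dict)
    proton_t2_ms: dict[str, float] = field(default_factory=dict)
    water_t1_ms: dict[str, float] = field(default_factory=dict)
    water_t2_ms: dict[str, float] = field(default_factory=dict)
    phosphorus_t1_ms: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: PipelineConfig | None = None) -> "RelaxationTable":
        r = (config or default_config()).relaxation
        return cls(proton_t1_ms=dict(r.proton_t1_ms), proton_t2_ms=dict(r.proton_t2_ms),
                   water_t1_ms=dict(r.water_t1_ms), water_t2_ms=dict(r.water_t2_ms),
                   phosphorus_t1_ms=dict(r.phosphorus_t1_ms))

    def _lookup(self, table: dict[str, float], name: str, what: str) -> float:
        try:
            return table[name]
        except KeyError:
            raise SchemaError(f"no {what} tabulated for {name!r}") from None


@dataclass(frozen=True)
class ReferenceStandard:
    """External-phantom calibration for the phosphorus channel."""

    phantom_signal: float
    phantom_concentration_mmol_per_l: float = 75.0
    phantom_relaxation: float | None = None  # precomputed R factor, else from t1
    phantom_t1_ms: float = 5200.0
    water_molality_mmol_per_kg: float = 55510.0

    def __post_init__(self):
        if self.phantom_signal <= 0:
            raise CalibrationError("phantom signal must be > 0")
        if self.phantom_concentration_mmol_per_l <= 0 or self.water_molality_mmol_per_kg <= 0:
            raise CalibrationError("reference concentrations must be > 0")


@dataclass
class QuantificationResult:
    """Concentrations (mmol/kg tissue), their propagated SDs, and every factor applied."""

    concentrations: dict[str, float]
    sd: dict[str, float]
    provenance: dict

    def __getitem__(self, name: str) -> float:
        return self.concentrations[name]


# --------------------------------------------------------------------------
# correction factors
# --------------------------------------------------------------------------

def relaxation_factor_proton(te_ms: float, tr_ms: float, t1_ms: float, t2_ms: float) -> float:
    """Signal attenuation R_H of a double-spin-echo (PRESS) acquisition.

    R_H = exp(-TE/T2) * {1 - exp(-TR/T1) + 2 exp([TE/2 - TR]/T1)
                         - 2 exp([3 TE/2 - TR]/T1)}

    so the fully relaxed signal is S0 = S / R_H.
    """
    if t1_ms <= 0 or t2_ms <= 0:
        raise DomainError("relaxation times must be > 0")
    if not tr_ms > te_ms >= 0:
        raise DomainError("require TR > TE >= 0")
    bracket = (1.0 - math.exp(-tr_ms / t1_ms)
               + 2.0 * math.exp((te_ms / 2.0 - tr_ms) / t1_ms)
               - 2.0 * math.exp((3.0 * te_ms / 2.0 - tr_ms) / t1_ms))
    return math.exp(-te_ms / t2_ms) * bracket


def relaxation_factor_phosphorus(flip_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Steady-state attenuation R_P of a spoiled FID acquisition at flip angle x.

    R_P = sin(x) (1 - E) / (1 - cos(x) E),  E = exp(-TR/T1).
    """
    if t1_ms <= 0:
        raise DomainError("T1 must be > 0")
    if not (0 < flip_deg <= 180):
        raise DomainError("flip angle must lie in (0, 180] degrees")
    if tr_ms <= 0:
        raise DomainError("TR must be > 0")
    x = math.radians(flip_deg)
    e1 = math.exp(-tr_ms / t1_ms)
    return math.sin(x) * (1.0 - e1) / (1.0 - math.cos(x) * e1)


def csf_correct(c_raw: float, f_csf: float) -> float:
    """Partial-volume correction: metabolites reside in tissue, not CSF."""
    if not (0.0 <= f_csf < 1.0):
        raise DomainError(f"CSF fraction {f_csf!r} outside [0, 1)")
    return c_raw / (1.0 - f_csf)


def water_content_factor(voxel: VoxelContext) -> float:
    """Voxel water fraction: f_GM*0.78 + f_WM*0.65 + f_CSF*0.97 (defaults)."""
    c_gm, c_wm, c_csf = voxel.water_content
    return voxel.f_gm * c_gm + voxel.f_wm * c_wm + voxel.f_csf * c_csf


def _load_correction(voxel: VoxelContext) -> tuple[float, bool]:
    if voxel.transmitter_amp_subject is None or voxel.transmitter_amp_phantom is None:
        return 1.0, True
    return voxel.transmitter_amp_subject / voxel.transmitter_amp_phantom, False


# --------------------------------------------------------------------------
# amplitude access (fit results or plain mappings)
# --------------------------------------------------------------------------

def _amplitude_and_sd(fit, name: str) -> tuple[float, float]:
    params = getattr(fit, "params", fit)
    if hasattr(params, "loc"):  # DataFrame from the spectral fitter
        if name not in params.index:
            raise SchemaError(f"resonance {name!r} absent from fit result")
        row = params.loc[name]
        return float(row["amplitude"]), float(row.get("sd_amplitude", 0.0))
    try:
        value = params[name]
    except (KeyError, TypeError):
        raise SchemaError(f"resonance {name!r} absent from fit result") from None
    if np.isscalar(value):
        return float(value), 0.0
    amp, sd = value
    return float(amp), float(sd)


# --------------------------------------------------------------------------
# quantification
# --------------------------------------------------------------------------

def quantify_proton(metab_fit, water_fit, voxel: VoxelContext,
                    relax: RelaxationTable, acq: AcquisitionParams,
                    metabolites: tuple[str, ...] = ("tNAA", "tCr", "tCho"),
                    proton_counts: dict[str, float] | None = None,
                    apply_csf_correction: bool = True) -> QuantificationResult:
    """Internal-water-referenced absolute concentrations (mmol/kg tissue).

    C = (A_met / R_H,met) / (A_water / R_H,water) * water_molality * wcf
        / (n_met / n_water),  then / (1 - f_CSF)

    where wcf is the voxel water-content factor and R_H,water the
    compartment-fraction-weighted water relaxation factor.
    """
    counts = dict(default_config().proton_counts.counts)
    if proton_counts:
        counts.update(proton_counts)
    a_water, sd_water = _amplitude_and_sd(water_fit, "water")
    if a_water <= 0:
        raise CalibrationError("water reference amplitude must be > 0")

    # compartment-weighted water relaxation: each compartment contributes
    # signal proportional to its volume fraction times its water content
    weights = np.array([voxel.f_gm * voxel.water_content[0],
                        voxel.f_wm * voxel.water_content[1],
                        voxel.f_csf * voxel.water_content[2]])
    r_comp = np.array([relaxation_factor_proton(acq.te_ms, acq.tr_ms,
                                                relax._lookup(relax.water_t1_ms, c, "water T1"),
                                                relax._lookup(relax.water_t2_ms, c, "water T2"))
                       for c in ("GM", "WM", "CSF")])
    r_water = float(np.sum(weights * r_comp) / np.sum(weights))
    wcf = water_content_factor(voxel)
    molality = default_config().water.molality_mmol_per_kg
    water_s0 = a_water / r_water

    concentrations: dict[str, float] = {}
    sds: dict[str, float] = {}
    factors: dict[str, dict] = {}
    for name in metabolites:
        a_met, sd_met = _amplitude_and_sd(metab_fit, name)
        r_met = relaxation_factor_proton(acq.te_ms, acq.tr_ms,
                                         relax._lookup(relax.proton_t1_ms, name, "T1"),
                                         relax._lookup(relax.proton_t2_ms, name, "T2"))
        n_ratio = counts[name] / counts["water"]
        c = (a_met / r_met) / water_s0 * molality * wcf / n_ratio
        if apply_csf_correction:
            c = csf_correct(c, voxel.f_csf)
        rel_var = 0.0
        if a_met > 0:
            rel_var += (sd_met / a_met) ** 2
        rel_var += (sd_water / a_water) ** 2
        concentrations[name] = c
        sds[name] = c * math.sqrt(rel_var)
        factors[name] = {"R_H_met": r_met, "proton_count_ratio": n_ratio}

    provenance = {
        "method": "internal water reference",
        "R_H_water": r_water, "water_content_factor": wcf,
        "water_molality_mmol_per_kg": molality,
        "csf_fraction": voxel.f_csf, "csf_corrected": apply_csf_correction,
        "per_metabolite": factors,
    }
    return QuantificationResult(concentrations, sds, provenance)


def quantify_phosphorus(metab_fit, voxel: VoxelContext, ref: ReferenceStandard,
                        relax: RelaxationTable, acq: AcquisitionParams,
                        outputs: dict[str, tuple[str, ...]] | None = None,
                        excluded_peaks: tuple[str, ...] = (),
                        apply_csf_correction: bool = True) -> QuantificationResult:
    """Phantom-replacement absolute concentrations (mmol/kg tissue).

    C = C_phantom * (A_met / R_P,met) / (A_phantom / R_phantom)
        * load_correction,  then / (1 - f_CSF)

    Aggregated outputs sum their corrected components (PME = PE + PC,
    PDE = GPE + GPC); ATP is taken from the gamma-ATP resonance.
    Resonances listed in ``excluded_peaks`` (quality-control rejects)
    yield NaN, recorded in the provenance.
    """
    outputs = outputs or PHOSPHORUS_OUTPUT_MAP
    r_phantom = ref.phantom_relaxation
    if r_phantom is None:
        r_phantom = relaxation_factor_phosphorus(acq.flip_deg, acq.tr_ms, ref.phantom_t1_ms)
    phantom_s0 = ref.phantom_signal / r_phantom
    load, load_skipped = _load_correction(voxel)

    concentrations: dict[str, float] = {}
    sds: dict[str, float] = {}
    factors: dict[str, dict] = {}
    excluded_applied: list[str] = []
    for out_name, components in outputs.items():
        total, var, skipped = 0.0, 0.0, False
        comp_factors = {}
        for comp in components:
            if comp in excluded_peaks:
                skipped = True
                excluded_applied.append(comp)
                continue
            a, sd = _amplitude_and_sd(metab_fit, comp)
            r_p = relaxation_factor_phosphorus(
                acq.flip_deg, acq.tr_ms, relax._lookup(relax.phosphorus_t1_ms, comp, "T1"))
            c = (ref.phantom_concentration_mmol_per_l * (a / r_p) / phantom_s0 * load)
            if apply_csf_correction:
                c = csf_correct(c, voxel.f_csf)
            total += c
            var += (0.0 if a <= 0 else (c * sd / a) ** 2)
            comp_factors[comp] = {"R_P": r_p}
        if skipped and not comp_factors:
            concentrations[out_name] = float("nan")
            sds[out_name] = float("nan")
        else:
            concentrations[out_name] = total
            sds[out_name] = math.sqrt(var)
        factors[out_name] = comp_factors

    provenance = {
        "method": "phantom replacement",
        "phantom_concentration_mmol_per_l": ref.phantom_concentration_mmol_per_l,
        "R_phantom": r_phantom, "load_correction": load,
        "load_correction_skipped": load_skipped,
        "csf_fraction": voxel.f_csf, "csf_corrected": apply_csf_correction,
        "excluded_peaks": sorted(set(excluded_applied)),
        "per_output": factors,
    }
    return QuantificationResult(concentrations, sds, provenance)


# --------------------------------------------------------------------------
# inverse maps (signal amplitude that corresponds to a known concentration);
# used to construct synthetic voxels with known ground-truth concentrations
# --------------------------------------------------------------------------

def amplitude_for_concentration_phosphorus(
        concentration_mmol_per_kg: float, resonance: str, voxel: VoxelContext,
        ref: ReferenceStandard, relax: RelaxationTable,
        acq: AcquisitionParams) -> float:
    """Amplitude a resonance must have for quantify_phosphorus to return C."""
    r_phantom = ref.phantom_relaxation
    if r_phantom is None:
        r_phantom = relaxation_factor_phosphorus(acq.flip_deg, acq.tr_ms, ref.phantom_t1_ms)
    load, _ = _load_correction(voxel)
    r_p = relaxation_factor_phosphorus(
        acq.flip_deg, acq.tr_ms, relax._lookup(relax.phosphorus_t1_ms, resonance, "T1"))
    phantom_s0 = ref.phantom_signal / r_phantom
    return (concentration_mmol_per_kg * (1.0 - voxel.f_csf) * r_p * phantom_s0
            / (ref.phantom_concentration_mmol_per_l * load))


def amplitude_for_concentration_proton(
        concentration_mmol_per_kg: float, metabolite: str, water_amplitude: float,
        voxel: VoxelContext, relax: RelaxationTable, acq: AcquisitionParams,
        proton_counts: dict[str, float] | None = None) -> float:
    """Amplitude a proton resonance must have for quantify_proton to return C."""
    counts = dict(default_config().proton_counts.counts)
    if proton_counts:
        counts.update(proton_counts)
    weights = np.array([voxel.f_gm * voxel.water_content[0],
                        voxel.f_wm * voxel.water_content[1],
                        voxel.f_csf * voxel.water_content[2]])
    r_comp = np.array([relaxation_factor_proton(acq.te_ms, acq.tr_ms,
                                                relax._lookup(relax.water_t1_ms, c, "water T1"),
                                                relax._lookup(relax.water_t2_ms, c, "water T2"))
                       for c in ("GM", "WM", "CSF")])
    r_water = float(np.sum(weights * r_comp) / np.sum(weights))
    r_met = relaxation_factor_proton(acq.te_ms, acq.tr_ms,
                                     relax._lookup(relax.proton_t1_ms, metabolite, "T1"),
                                     relax._lookup(relax.proton_t2_ms, metabolite, "T2"))
    wcf = water_content_factor(voxel)
    molality = default_config().water.molality_mmol_per_kg
    n_ratio = counts[metabolite] / counts["water"]
    return (concentration_mmol_per_kg * (1.0 - voxel.f_csf) * r_met * n_ratio
            * (water_amplitude / r_water) / (molality * wcf))
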