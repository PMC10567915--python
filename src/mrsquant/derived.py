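"""Chemical-shift-derived physiology: intracellular pH, free Mg2+, PCr/Cr.

Intracellular pH follows from the Henderson-Hasselbalch-type titration of
the inorganic-phosphate resonance position delta (ppm, relative to PCr):

    pH = 6.75 + log10[(3.27 - delta) / (delta - 5.63)]

defined on the open interval (3.27, 5.63).  Free cytosolic magnesium
follows from the beta-ATP position delta_beta (ppm, relative to PCr):

    pMg = 4.24 - log10[(delta_beta + 18.58)^0.42 / (-15.74 - delta_beta)^0.84]

defined on (-18.58, -15.74), with [Mg2+] = 10^(-pMg) mol/l reported in
mmol/l.  First-order uncertainty propagation from the CRLB of the fitted
shifts is provided for both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import DerivedConfig
from .errors import NonPhysicalRatioError, UndefinedPHError, UndefinedPMgError

__all__ = [
    "ShiftPair",
    "ph_from_shift",
    "mg_from_shift",
    "pcr_cr_ratio",
    "ph_sd_from_shift_sd",
    "mg_sd_from_shift_sd",
    "shift_pair_from_fit",
]

_DEFAULT = DerivedConfig()


@dataclass(frozen=True)
class ShiftPair:
    """Pi-PCr and beta-ATP-PCr chemical-shift differences (ppm)."""

    delta_pi: float
    delta_beta: float


def shift_pair_from_fit(fit) -> ShiftPair:
    """Build the shift differences from a phosphorus fit (PCr as 0-reference)."""
    pcr = fit.shift("PCr")
    return ShiftPair(delta_pi=fit.shift("Pi") - pcr,
                     delta_beta=fit.shift("bATP") - pcr)


def ph_from_shift(delta_pi: float, constants: DerivedConfig = _DEFAULT) -> float:
    """Intracellular pH from the Pi-PCr shift difference (ppm).

    Strictly increasing on the open titration interval; raises
    UndefinedPHError at or outside the bounds.
    """
    lo, hi = constants.ph_delta_acid, constants.ph_delta_base
    if not (lo < delta_pi < hi):
        raise UndefinedPHError(delta_pi)
    return constants.ph_pk + math.log10((lo - delta_pi) / (delta_pi - hi))


def ph_sd_from_shift_sd(delta_pi: float, shift_sd: float,
                        constants: DerivedConfig = _DEFAULT) -> float:
    """First-order pH uncertainty from the shift-difference SD (ppm)."""
    lo, hi = constants.ph_delta_acid, constants.ph_delta_base
    if not (lo < delta_pi < hi):
        raise UndefinedPHError(delta_pi)
    dd = (-1.0 / (lo - delta_pi) - 1.0 / (delta_pi - hi)) / math.log(10.0)
    return abs(dd) * shift_sd


def mg_from_shift(delta_beta: float,
                  constants: DerivedConfig = _DEFAULT) -> tuple[float, float]:
    """(pMg, [Mg2+] in mmol/l) from the beta-ATP-PCr shift difference (ppm).

    The free-magnesium concentration is the antilog 10^(-pMg) mol/l,
    reported in mmol/l.
    """
    lo, hi = constants.mg_delta_lower, constants.mg_delta_upper
    if not (lo < delta_beta < hi):
        raise UndefinedPMgError(delta_beta)
    pmg = constants.mg_pk - math.log10(
        (delta_beta - lo) ** constants.mg_exponent_lower
        / (hi - delta_beta) ** constants.mg_exponent_upper)
    mg_mmol_per_l = 10.0 ** (-pmg) * 1000.0
    return pmg, mg_mmol_per_l


def mg_sd_from_shift_sd(delta_beta: float, shift_sd: float,
                        constants: DerivedConfig = _DEFAULT) -> tuple[float, float]:
    """First-order (pMg SD, [Mg2+] SD in mmol/l) from the shift SD (ppm)."""
    lo, hi = constants.mg_delta_lower, constants.mg_delta_upper
    if not (lo < delta_beta < hi):
        raise UndefinedPMgError(delta_beta)
    dpmg = -(constants.mg_exponent_lower / (delta_beta - lo)
             + constants.mg_exponent_upper / (hi - delta_beta)) / math.log(10.0)
    pmg, mg = mg_from_shift(delta_beta, constants)
    pmg_sd = abs(dpmg) * shift_sd
    mg_sd = mg * math.log(10.0) * pmg_sd
    return pmg_sd, mg_sd


def pcr_cr_ratio(pcr_mmol_per_kg: float, tcr_mmol_per_kg: float) -> float:
    """PCr over free creatine, with [Cr] = [tCr] - [PCr].

    Defined for voxels where both channels were acquired; requires
    tCr > PCr > 0.
    """
    if not pcr_mmol_per_kg > 0:
        raise NonPhysicalRatioError("PCr concentration must be > 0")
    if not tcr_mmol_per_kg > pcr_mmol_per_kg:
        raise NonPhysicalRatioError(
            f"tCr ({tcr_mmol_per_kg}) must exceed PCr ({pcr_mmol_per_kg})")
    return pcr_mmol_per_kg / (tcr_mmol_per_kg - pcr_mmol_per_kg)
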