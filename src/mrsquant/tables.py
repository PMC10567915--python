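"""Published cohort-level mean tables and region/metabolite vocabularies.

These group x region x metabolite means (mmol/kg wet weight; pH in pH
units; Mg in mmol/l) are the default mean structure of the synthetic
cohort generator and the worked-example inputs of the contrast statistics.
Groups: female non-users (fN, n=21), male non-users (mN, n=26) and male
cannabis users (mC, n=40).
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

__all__ = [
    "GROUPS",
    "GROUP_SIZES",
    "PHOSPHORUS_REGIONS",
    "PROTON_REGIONS",
    "BILATERAL_REGIONS",
    "PHOSPHORUS_METABOLITES",
    "PROTON_METABOLITES",
    "PCR_CR_REGIONS",
    "phosphorus_mean_table",
    "proton_mean_table",
    "hemisphere_of",
]

GROUPS = ("fN", "mN", "mC")
GROUP_SIZES = {"fN": 21, "mN": 26, "mC": 40}

#: The nine phosphorus volumes of interest (FGM is a single midline voxel).
PHOSPHORUS_REGIONS = ("FGM", "r_TH", "r_BG", "r_TL", "r_FWM",
                      "l_TH", "l_BG", "l_TL", "l_FWM")
#: The four proton volumes of interest (right hemisphere plus midline FGM).
PROTON_REGIONS = ("FGM", "r_TL", "r_TH", "r_FWM")
#: Region stems evaluated in both hemispheres.
BILATERAL_REGIONS = ("TH", "BG", "TL", "FWM")
#: Regions where both channels were acquired, hence where PCr/Cr is defined.
PCR_CR_REGIONS = ("FGM", "r_TH", "r_TL", "r_FWM")

PHOSPHORUS_METABOLITES = ("PME", "Pi", "PDE", "PCr", "ATP", "pH", "Mg")
PROTON_METABOLITES = ("tNAA", "tCr", "tCho")

# region -> metabolite -> (fN, mN, mC)
_P_MEANS = {
    "FGM": {
        "PME": (2.70, 2.61, 2.62), "Pi": (0.68, 0.59, 0.54),
        "PDE": (2.89, 3.04, 2.83), "PCr": (3.65, 3.58, 3.60),
        "ATP": (2.83, 2.70, 2.51), "pH": (6.98, 6.99, 6.98),
        "Mg": (0.11, 0.10, 0.10),
    },
    "r_TH": {
        "PME": (2.30, 1.96, 2.05), "Pi": (0.79, 0.75, 0.73),
        "PDE": (2.61, 2.56, 2.63), "PCr": (3.70, 3.23, 3.38),
        "ATP": (2.43, 2.16, 2.03), "pH": (6.99, 6.99, 6.99),
        "Mg": (0.10, 0.11, 0.10),
    },
    "r_BG": {
        "PME": (2.17, 2.16, 2.11), "Pi": (0.61, 0.63, 0.53),
        "PDE": (2.66, 2.70, 2.63), "PCr": (3.48, 3.22, 3.29),
        "ATP": (2.49, 2.36, 2.15), "pH": (6.99, 6.99, 6.99),
        "Mg": (0.11, 0.11, 0.11),
    },
    "r_TL": {
        "PME": (2.03, 2.18, 2.25), "Pi": (0.59, 0.58, 0.53),
        "PDE": (2.03, 2.36, 2.20), "PCr": (3.50, 3.78, 3.79),
        "ATP": (2.30, 2.23, 2.07), "pH": (7.00, 7.00, 6.99),
        "Mg": (0.12, 0.11, 0.11),
    },
    "r_FWM": {
        "PME": (2.27, 2.35, 2.30), "Pi": (0.61, 0.63, 0.54),
        "PDE": (2.56, 2.69, 2.44), "PCr": (3.40, 3.46, 3.42),
        "ATP": (2.60, 2.47, 2.27), "pH": (6.98, 6.99, 6.98),
        "Mg": (0.11, 0.11, 0.11),
    },
    "l_TH": {
        "PME": (2.32, 2.10, 2.09), "Pi": (0.84, 0.80, 0.78),
        "PDE": (2.63, 2.60, 2.70), "PCr": (3.75, 3.50, 3.48),
        "ATP": (2.44, 2.21, 2.12), "pH": (6.99, 6.99, 6.99),
        "Mg": (0.10, 0.11, 0.10),
    },
    "l_BG": {
        "PME": (2.41, 2.30, 2.29), "Pi": (0.72, 0.69, 0.63),
        "PDE": (2.42, 2.54, 2.46), "PCr": (3.68, 3.88, 3.50),
        "ATP": (2.53, 2.32, 2.23), "pH": (7.00, 7.00, 6.99),
        "Mg": (0.11, 0.11, 0.11),
    },
    "l_TL": {
        "PME": (2.13, 2.13, 2.23), "Pi": (0.63, 0.67, 0.59),
        "PDE": (1.90, 1.98, 1.86), "PCr": (3.62, 3.91, 3.78),
        "ATP": (2.27, 2.15, 2.10), "pH": (7.00, 7.00, 7.00),
        "Mg": (0.11, 0.11, 0.11),
    },
    "l_FWM": {
        "PME": (2.22, 2.23, 2.19), "Pi": (0.66, 0.60, 0.56),
        "PDE": (2.14, 2.27, 2.30), "PCr": (3.33, 3.73, 3.47),
        "ATP": (2.35, 2.30, 2.08), "pH": (7.00, 7.00, 7.00),
        "Mg": (0.11, 0.11, 0.11),
    },
}

_H_MEANS = {
    "FGM": {"tNAA": (22.6, 22.8, 22.1), "tCr": (15.5, 16.0, 16.2), "tCho": (4.1, 4.5, 4.6)},
    "r_TL": {"tNAA": (16.1, 15.9, 15.2), "tCr": (10.3, 10.3, 10.2), "tCho": (3.0, 3.3, 3.1)},
    "r_TH": {"tNAA": (14.0, 14.8, 13.4), "tCr": (8.5, 9.2, 7.9), "tCho": (2.4, 2.7, 2.5)},
    "r_FWM": {"tNAA": (14.7, 15.7, 14.7), "tCr": (8.2, 8.8, 8.6), "tCho": (2.7, 2.9, 2.8)},
}


def _tidy(nested: dict, regions: tuple, metabolites: tuple) -> pd.DataFrame:
    rows = []
    for region in regions:
        for metab in metabolites:
            for group, mean in zip(GROUPS, nested[region][metab]):
                rows.append((group, region, metab, mean))
    return pd.DataFrame(rows, columns=["group", "region", "metabolite", "mean"])


def phosphorus_mean_table() -> pd.DataFrame:
    """Tidy group/region/metabolite mean table for the phosphorus channel."""
    return _tidy(_P_MEANS, PHOSPHORUS_REGIONS, PHOSPHORUS_METABOLITES)


def proton_mean_table() -> pd.DataFrame:
    """Tidy group/region/metabolite mean table for the proton channel."""
    return _tidy(_H_MEANS, PROTON_REGIONS, PROTON_METABOLITES)


def hemisphere_of(region: str) -> str:
    """'left' / 'right' / 'midline' from a region label such as 'l_BG'."""
    if region.startswith("l_"):
        return "left"
    if region.startswith("r_"):
        return "right"
    if region == "FGM":
        return "midline"
    raise SchemaError(f"unknown region label {region!r}")
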