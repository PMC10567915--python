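"""Simulation studies validating the pipeline end to end.

Self-contained, seeded studies that exercise the whole chain on synthetic
data: amplitude-recovery calibration of the fitter against the CRLB,
quantification round trips with interval coverage, type-I-error
calibration of the cohort statistics, and the degenerate report round
trip.  They power both the test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import simulate as sim
from . import tables
from .cohort import build_report, group_manova, posthoc_scheffe, relative_diff
from .fitting import PriorConstraint, compute_crlb, fit_time_domain
from .quantify import (ReferenceStandard, RelaxationTable,
                       amplitude_for_concentration_phosphorus,
                       amplitude_for_concentration_proton, quantify_phosphorus,
                       quantify_proton)
from .spectral import ResonanceSpec

__all__ = [
    "standard_prior_knowledge",
    "fit_recovery_study",
    "quantification_roundtrip_study",
    "manova_type1_study",
    "scheffe_familywise_study",
    "paired_t_type1_study",
    "bonferroni_familywise_study",
    "degenerate_report_study",
    "worked_example_contrasts",
]


def standard_prior_knowledge(truth=None):
    """Prior model and constraints used for the standard phosphorus fit.

    Starting values sit at the prior shifts with nominal amplitudes; the
    zero-order phases and the broad macromolecular component's position
    and width are treated as known (fixed), as is usual when the baseline
    component is part of the prior knowledge.
    """
    truth = truth or sim.default_phosphorus_model()
    prior = [ResonanceSpec(r.name, r.shift_ppm, 1.0, r.damping_hz, 0.0, r.multiplet)
             for r in truth]
    constraints = [PriorConstraint(r.name, "phase", "fix", 0.0) for r in truth]
    mm = next(r for r in truth if r.name == "MM")
    constraints += [PriorConstraint("MM", "damping", "fix", mm.damping_hz),
                    PriorConstraint("MM", "shift", "fix", mm.shift_ppm)]
    return truth, prior, constraints


def fit_recovery_study(seed: int, n_replicates: int = 200,
                       snr_range: tuple[float, float] = (10.0, 30.0)) -> dict:
    """Amplitude recovery on standard phosphorus spectra.

    Per replicate the spectral SNR is drawn uniformly from ``snr_range``
    and each amplitude error is standardised by the exact CRLB at the
    true parameters.  The calibration class contains the resonances whose
    worst-case CRLB relative error over the band stays below 0.2 (the
    quality class whose peaks are always retained by QC).
    """
    acq = sim.phosphorus_acquisition()
    truth, prior, constraints = standard_prior_knowledge()
    amps = {r.name: r.amplitude for r in truth}
    crlb_unit = compute_crlb(acq, truth, 1.0, constraints)["sd_amplitude"]
    sigma_worst = sim.noise_sd_for_snr(truth, acq, min(snr_range))
    reliable = [r.name for r in truth
                if sigma_worst * crlb_unit[r.name] / r.amplitude < 0.2]
    rng = np.random.default_rng(seed)
    z: dict[str, list[float]] = {name: [] for name in amps}
    for _ in range(n_replicates):
        snr = rng.uniform(*snr_range)
        sigma = sim.noise_sd_for_snr(truth, acq, snr)
        fid = sim.simulate_fid(truth, acq, sigma, seed=int(rng.integers(2**31)))
        fit = fit_time_domain(fid, prior, constraints)
        for name in amps:
            z[name].append((fit.amplitude(name) - amps[name])
                           / (sigma * crlb_unit[name]))
    per_resonance = {}
    for name, values in z.items():
        v = np.asarray(values)
        per_resonance[name] = {
            "mean_z": float(v.mean()),
            "sd_z": float(v.std(ddof=1)),
            "sem": float(v.std(ddof=1) / math.sqrt(v.size)),
        }
    pooled = np.array([per_resonance[n]["mean_z"] for n in reliable])
    pooled_sem = float(np.array(
        [per_resonance[n]["sem"] for n in reliable]).mean() / math.sqrt(len(reliable)))
    return {
        "per_resonance": per_resonance,
        "reliable": reliable,
        "pooled_mean_z": float(pooled.mean()),
        "pooled_sem": pooled_sem,
        "n_replicates": n_replicates,
    }


_P_TRUE_CONCENTRATIONS = {
    "PE": 1.33, "PC": 1.28, "Pi": 0.59, "GPE": 1.55, "GPC": 1.49,
    "PCr": 3.58, "gATP": 2.70, "aATP": 2.70, "bATP": 2.70, "NAD": 0.30,
}
_H_TRUE_CONCENTRATIONS = {"tNAA": 22.8, "tCr": 16.0, "tCho": 4.5}
_P_EXPECTED_OUTPUTS = {"PME": 2.61, "Pi": 0.59, "PDE": 3.04, "PCr": 3.58,
                       "ATP": 2.70}


def quantification_roundtrip_study(seed: int, n_replicates: int = 200,
                                   snr: float = 15.0) -> dict:
    """simulate -> fit -> quantify round trip, noiseless and noisy.

    Noiseless: largest relative concentration error over both channels.
    Noisy: coverage of the 95% CRLB-propagated interval for the PCr
    concentration over ``n_replicates`` phosphorus voxels.
    """
    relax = RelaxationTable.from_config()
    acq_p = sim.phosphorus_acquisition()
    voxel = sim.simulate_voxel_context("FGM", seed=seed)
    ref = ReferenceStandard(phantom_signal=100.0)
    amps = {n: amplitude_for_concentration_phosphorus(c, n, voxel, ref, relax, acq_p)
            for n, c in _P_TRUE_CONCENTRATIONS.items()}
    amps["MM"] = 1.2 * amps["PCr"]
    truth = sim.default_phosphorus_model(amplitudes=amps)
    _, prior, constraints = standard_prior_knowledge(truth)

    fit0 = fit_time_domain(sim.simulate_fid(truth, acq_p), prior, constraints)
    res0 = quantify_phosphorus(fit0, voxel, ref, relax, acq_p)
    errors = [abs(res0[name] / c_true - 1.0)
              for name, c_true in _P_EXPECTED_OUTPUTS.items()]

    acq_h = sim.proton_acquisition()
    voxel_h = sim.simulate_voxel_context("FGM", seed=seed + 1, channel="proton")
    water_amp = 1.0e4
    amps_h = {n: amplitude_for_concentration_proton(c, n, water_amp, voxel_h,
                                                    relax, acq_h)
              for n, c in _H_TRUE_CONCENTRATIONS.items()}
    fit_h = fit_time_domain(sim.simulate_fid(
        sim.default_proton_model(amplitudes=amps_h), acq_h),
        sim.default_proton_model())
    fit_w = fit_time_domain(sim.simulate_fid(
        sim.water_reference_model(water_amp), acq_h), sim.water_reference_model(1.0))
    res_h = quantify_proton(fit_h, fit_w, voxel_h, relax, acq_h)
    errors += [abs(res_h[n] / c - 1.0) for n, c in _H_TRUE_CONCENTRATIONS.items()]

    sigma = sim.noise_sd_for_snr(truth, acq_p, snr)
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        fid = sim.simulate_fid(truth, acq_p, sigma, seed=int(rng.integers(2**31)))
        fit = fit_time_domain(fid, prior, constraints)
        res = quantify_phosphorus(fit, voxel, ref, relax, acq_p)
        half = 1.96 * res.sd["PCr"]
        covered += abs(res["PCr"] - _P_EXPECTED_OUTPUTS["PCr"]) <= half
    return {
        "noiseless_max_rel_error": float(max(errors)),
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
    }


def _null_mean_table(groups: tuple[str, ...], regions=None,
                     metabolites=None) -> pd.DataFrame:
    """Mean table where every group carries the mN phosphorus means."""
    base = tables.phosphorus_mean_table()
    base = base[base["group"] == "mN"]
    if regions is not None:
        base = base[base["region"].isin(regions)]
    if metabolites is not None:
        base = base[base["metabolite"].isin(metabolites)]
    out = []
    for g in groups:
        block = base.copy()
        block["group"] = g
        out.append(block)
    return pd.concat(out, ignore_index=True)


def manova_type1_study(seed: int, n_replicates: int = 200,
                       n_per_group: int = 500) -> dict:
    """Rejection rate of the Wilks-Lambda MANOVA on null two-group cohorts."""
    mean_table = _null_mean_table(("g1", "g2"), regions=("FGM",))
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        design = sim.CohortDesign(group_sizes={"g1": n_per_group, "g2": n_per_group},
                                  mean_table=mean_table, cv=0.15,
                                  seed=int(rng.integers(2**31)))
        cohort = sim.simulate_cohort(design)
        res = group_manova(cohort, "FGM", groups=("g1", "g2"))
        rejections += res.p_value < 0.05
    return {"rate": rejections / n_replicates, "n_replicates": n_replicates}


def scheffe_familywise_study(seed: int, n_replicates: int = 200) -> dict:
    """Family-wise error of all three pairwise Scheffé tests on null cohorts."""
    mean_table = _null_mean_table(tables.GROUPS, regions=("FGM",),
                                  metabolites=("ATP",))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        design = sim.CohortDesign(mean_table=mean_table, cv=0.15,
                                  seed=int(rng.integers(2**31)))
        cohort = sim.simulate_cohort(design)
        ps = [posthoc_scheffe(cohort, "FGM", "ATP", pair)
              for pair in (("mN", "fN"), ("mC", "mN"), ("mC", "fN"))]
        hits += min(ps) < 0.05
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def paired_t_type1_study(seed: int, n_replicates: int = 200,
                         n_pairs: int = 26) -> dict:
    """Rejection rate of the hemispheric paired t test under symmetry."""
    from scipy import stats as sps
    base = _null_mean_table(("mN",), regions=("l_BG", "r_BG"), metabolites=("PCr",))
    # hemispheric symmetry under the null: both sides share the left mean
    left_mean = float(base.loc[base["region"] == "l_BG", "mean"].iloc[0])
    base.loc[:, "mean"] = left_mean
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        design = sim.CohortDesign(group_sizes={"mN": n_pairs}, mean_table=base,
                                  cv=0.15, seed=int(rng.integers(2**31)))
        cohort = sim.simulate_cohort(design)
        left = cohort[cohort["region"] == "l_BG"].sort_values("subject_id")
        right = cohort[cohort["region"] == "r_BG"].sort_values("subject_id")
        p = sps.ttest_rel(right["concentration_mmol_per_kg"].to_numpy(),
                          left["concentration_mmol_per_kg"].to_numpy()).pvalue
        rejections += p < 0.05
    return {"rate": rejections / n_replicates, "n_replicates": n_replicates}


def bonferroni_familywise_study(seed: int, n_cohorts: int = 200,
                                threshold: float = 0.0056) -> dict:
    """Family-wise error of the nine-region MANOVA screen on null cohorts."""
    mean_table = _null_mean_table(tables.GROUPS)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        design = sim.CohortDesign(mean_table=mean_table, cv=0.15,
                                  seed=int(rng.integers(2**31)))
        cohort = sim.simulate_cohort(design)
        any_significant = False
        for region in tables.PHOSPHORUS_REGIONS:
            if group_manova(cohort, region).p_value < threshold:
                any_significant = True
                break
        hits += any_significant
    return {"rate": hits / n_cohorts, "n_cohorts": n_cohorts,
            "threshold": threshold}


def degenerate_report_study() -> dict:
    """CV -> 0 cohort: largest absolute deviation of reported means from
    the published tables (2-decimal scale)."""
    cohort = sim.simulate_cohort(sim.CohortDesign(cv=0.0, cv_ph=0.0))
    report = build_report(cohort)
    worst = 0.0
    for table_fn, blocks in ((tables.phosphorus_mean_table, report.phosphorus_groups),
                             (tables.proton_mean_table, report.proton_groups)):
        for row in table_fn().itertuples():
            got = round(float(blocks[row.region].loc[row.metabolite, row.group]), 2)
            worst = max(worst, abs(got - row.mean))
    return {"max_abs_error": worst}


def worked_example_contrasts() -> dict:
    """The quoted relative-difference percentages, from the published means."""
    p = tables.phosphorus_mean_table().set_index(["group", "region", "metabolite"])["mean"]
    h = tables.proton_mean_table().set_index(["group", "region", "metabolite"])["mean"]
    return {
        "dCN_FGM_ATP": relative_diff(p["mC", "FGM", "ATP"], p["mN", "FGM", "ATP"]).percent,
        "dmf_rTH_ATP": relative_diff(p["mN", "r_TH", "ATP"], p["fN", "r_TH", "ATP"]).percent,
        "dCN_lBG_PCr": relative_diff(p["mC", "l_BG", "PCr"], p["mN", "l_BG", "PCr"]).percent,
        "drl_BG_PCr_mN": relative_diff(p["mN", "r_BG", "PCr"], p["mN", "l_BG", "PCr"]).percent,
        "dmf_lFWM_PCr": relative_diff(p["mN", "l_FWM", "PCr"], p["fN", "l_FWM", "PCr"]).percent,
        "dCN_FGM_tNAA": relative_diff(h["mC", "FGM", "tNAA"], h["mN", "FGM", "tNAA"]).percent,
    }
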