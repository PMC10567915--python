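"""The staged pipeline: simulate -> fit -> quantify -> derive -> stats.

Stages exchange flat CSV/JSON artifacts in the output directory, every
correction factor and quality-control decision is logged, and identical
configuration plus seeds give byte-identical outputs.  The demo subject
simulated by the ``simulate`` stage carries the male-non-user group-mean
concentrations as ground truth, so the quantification stages can be
inspected end to end against known values.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from . import io as mio
from . import simulate as sim
from .cohort import build_report
from .config import PipelineConfig
from .derived import (mg_from_shift, mg_sd_from_shift_sd, ph_from_shift,
                      ph_sd_from_shift_sd, shift_pair_from_fit)
from .errors import MrsQuantError, SchemaError
from .fitting import fit_time_domain, qc_filter
from .quantify import (ReferenceStandard, RelaxationTable,
                       amplitude_for_concentration_phosphorus,
                       amplitude_for_concentration_proton, quantify_phosphorus,
                       quantify_proton)
from .spectral import ResonanceSpec
from .tables import phosphorus_mean_table, proton_mean_table

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "quantify", "derive", "stats", "all")

_DEMO_REGION = "FGM"
_DEMO_GROUP = "mN"
_DEMO_SNR_NOISE = {"phosphorus": 0.02, "proton": 0.02}  # relative to peak amplitude
_PHANTOM_AMPLITUDE = 100.0
#: demo beta-ATP position (ppm): corresponds to a physiological free [Mg2+]
_DEMO_BETA_ATP_PPM = -16.4


class _Log:
    def __init__(self):
        self.records: list[dict] = []

    def add(self, stage: str, event: str, **payload):
        self.records.append({"stage": stage, "event": event, **payload})

    def write(self, path: Path):
        path.write_text(json.dumps(self.records, indent=1, sort_keys=True))


def _demo_concentrations(channel: str) -> dict[str, float]:
    table = phosphorus_mean_table() if channel == "phosphorus" else proton_mean_table()
    sub = table[(table["group"] == _DEMO_GROUP) & (table["region"] == _DEMO_REGION)]
    return dict(zip(sub["metabolite"], sub["mean"]))


def _simulate_stage(config: PipelineConfig, out: Path, seed: int, log: _Log) -> None:
    relax = RelaxationTable.from_config(config)
    # -- phosphorus demo voxel -------------------------------------------
    acq_p = sim.phosphorus_acquisition(config)
    voxel_p = sim.simulate_voxel_context(_DEMO_REGION, seed=seed, channel="phosphorus")
    ref = ReferenceStandard(phantom_signal=_PHANTOM_AMPLITUDE,
                            phantom_concentration_mmol_per_l=config.phantom.concentration_mmol_per_l,
                            phantom_t1_ms=config.phantom.t1_ms)
    targets = _demo_concentrations("phosphorus")
    # split aggregate targets over their components at the default proportions
    component_targets = {
        "PE": 0.51 * targets["PME"], "PC": 0.49 * targets["PME"],
        "Pi": targets["Pi"],
        "GPE": 0.51 * targets["PDE"], "GPC": 0.49 * targets["PDE"],
        "PCr": targets["PCr"], "gATP": targets["ATP"], "aATP": targets["ATP"],
        "bATP": targets["ATP"], "NAD": 0.3,
    }
    amplitudes = {
        name: amplitude_for_concentration_phosphorus(c, name, voxel_p, ref, relax, acq_p)
        for name, c in component_targets.items()
    }
    amplitudes["MM"] = 1.2 * amplitudes["PCr"]
    model_p = sim.default_phosphorus_model(config, amplitudes=amplitudes)
    model_p = [r if r.name != "bATP"
               else ResonanceSpec(r.name, _DEMO_BETA_ATP_PPM, r.amplitude,
                                  r.damping_hz, r.phase_deg, r.multiplet)
               for r in model_p]
    noise_p = _DEMO_SNR_NOISE["phosphorus"] * amplitudes["PCr"]
    fid_p = sim.simulate_fid(model_p, acq_p, noise_sd=noise_p, seed=seed)
    mio.write_fid(fid_p, out / "demo_31p.fid.json", "json")
    mio.write_fid(fid_p, out / "demo_31p.jmrui.txt", "jmrui-text")
    (out / "demo_31p.voxel.json").write_text(json.dumps(asdict(voxel_p), sort_keys=True))
    phantom_fid = sim.simulate_fid(
        [ResonanceSpec("Pi", config.phosphorus_shifts_ppm["Pi"],
                       _PHANTOM_AMPLITUDE, 3.0)], acq_p, noise_sd=0.0)
    mio.write_fid(phantom_fid, out / "demo_phantom.fid.json", "json")
    log.add("simulate", "phosphorus_voxel", seed=seed, region=_DEMO_REGION,
            noise_sd=noise_p, true_concentrations=targets)

    # -- proton demo voxel -----------------------------------------------
    acq_h = sim.proton_acquisition(config)
    voxel_h = sim.simulate_voxel_context(_DEMO_REGION, seed=seed + 1, channel="proton")
    water_amp = 1.0e4
    targets_h = _demo_concentrations("proton")
    amps_h = {name: amplitude_for_concentration_proton(c, name, water_amp, voxel_h,
                                                       relax, acq_h)
              for name, c in targets_h.items()}
    model_h = sim.default_proton_model(config, amplitudes=amps_h)
    noise_h = _DEMO_SNR_NOISE["proton"] * max(amps_h.values())
    fid_h = sim.simulate_fid(model_h, acq_h, noise_sd=noise_h, seed=seed + 2)
    water_fid = sim.simulate_fid(sim.water_reference_model(water_amp, config=config),
                                 acq_h, noise_sd=noise_h, seed=seed + 3)
    mio.write_fid(fid_h, out / "demo_1h.fid.json", "json")
    mio.write_fid(water_fid, out / "demo_1h_water.fid.json", "json")
    (out / "demo_1h.voxel.json").write_text(json.dumps(asdict(voxel_h), sort_keys=True))
    log.add("simulate", "proton_voxel", seed=seed + 1, region=_DEMO_REGION,
            noise_sd=noise_h, true_concentrations=targets_h)

    # -- cohort -----------------------------------------------------------
    design = sim.default_cohort_design(config, seed=seed)
    cohort = sim.simulate_cohort(design)
    mio.write_cohort_csv(cohort, out / "cohort.csv")
    log.add("simulate", "cohort", seed=design.seed, cv=design.cv,
            groups=design.group_sizes)


def _fit_stage(config: PipelineConfig, out: Path, seed: int, log: _Log) -> None:
    for stem, channel in (("demo_31p", "phosphorus"), ("demo_phantom", "phosphorus"),
                          ("demo_1h", "proton"), ("demo_1h_water", "proton")):
        path = out / f"{stem}.fid.json"
        if not path.exists():
            raise SchemaError(f"fit stage: missing artifact {path.name} (run simulate first)")
        fid = mio.read_fid(path)
        if fid.ground_truth is not None:
            # prior knowledge: the model structure with nominal starting values
            model = [ResonanceSpec(r.name, r.shift_ppm, 1.0, r.damping_hz, 0.0,
                                   r.multiplet) for r in fid.ground_truth]
        else:
            model = (sim.default_phosphorus_model(config) if channel == "phosphorus"
                     else sim.default_proton_model(config))
        fit = fit_time_domain(fid, model)
        (out / f"{stem}.fit.json").write_text(mio.fit_result_to_json(fit))
        mio.fit_result_to_csv(fit, out / f"{stem}.fit.csv")
        verdict = qc_filter(fit, channel, config.qc)
        log.add("fit", "fitted", artifact=stem, converged=fit.converged,
                snr=fit.spectrum_snr, qc_pass=verdict.spectrum_ok,
                qc_reasons=verdict.reasons, qc_excluded_peaks=verdict.excluded_peaks)


def _load_fit_params(path: Path) -> dict[str, tuple[float, float]]:
    payload = json.loads(path.read_text())
    return {name: (row["amplitude"], row["sd_amplitude"] or 0.0)
            for name, row in payload["resonances"].items()}


def _load_voxel(path: Path):
    from .quantify import VoxelContext
    return VoxelContext(**json.loads(path.read_text()))


def _quantify_stage(config: PipelineConfig, out: Path, seed: int, log: _Log) -> None:
    relax = RelaxationTable.from_config(config)
    for needed in ("demo_31p.fit.json", "demo_phantom.fit.json",
                   "demo_1h.fit.json", "demo_1h_water.fit.json"):
        if not (out / needed).exists():
            raise SchemaError(f"quantify stage: missing artifact {needed} (run fit first)")
    voxel_p = _load_voxel(out / "demo_31p.voxel.json")
    fit_p = _load_fit_params(out / "demo_31p.fit.json")
    phantom_amp = _load_fit_params(out / "demo_phantom.fit.json")["Pi"][0]
    ref = ReferenceStandard(phantom_signal=phantom_amp,
                            phantom_concentration_mmol_per_l=config.phantom.concentration_mmol_per_l,
                            phantom_t1_ms=config.phantom.t1_ms)
    excluded = tuple(
        rec["qc_excluded_peaks"] for rec in log.records
        if rec.get("event") == "fitted" and rec.get("artifact") == "demo_31p"
    )
    excluded_peaks = tuple(excluded[0]) if excluded else ()
    result_p = quantify_phosphorus(fit_p, voxel_p, ref, relax,
                                   sim.phosphorus_acquisition(config),
                                   excluded_peaks=excluded_peaks)
    voxel_h = _load_voxel(out / "demo_1h.voxel.json")
    result_h = quantify_proton(_load_fit_params(out / "demo_1h.fit.json"),
                               _load_fit_params(out / "demo_1h_water.fit.json"),
                               voxel_h, relax, sim.proton_acquisition(config),
                               proton_counts=config.proton_counts.counts)
    payload = {
        "phosphorus": {"concentrations_mmol_per_kg": result_p.concentrations,
                       "sd": result_p.sd, "provenance": result_p.provenance},
        "proton": {"concentrations_mmol_per_kg": result_h.concentrations,
                   "sd": result_h.sd, "provenance": result_h.provenance},
    }
    (out / "concentrations.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    log.add("quantify", "phosphorus", **{k: v for k, v in result_p.provenance.items()
                                         if k != "per_output"})
    log.add("quantify", "proton", **{k: v for k, v in result_h.provenance.items()
                                     if k != "per_metabolite"})


def _derive_stage(config: PipelineConfig, out: Path, seed: int, log: _Log) -> None:
    path = out / "demo_31p.fit.json"
    if not path.exists():
        raise SchemaError("derive stage: missing phosphorus fit (run fit first)")
    payload = json.loads(path.read_text())
    res = payload["resonances"]

    class _Shifts:
        def shift(self, name):
            return res[name]["shift_ppm"]

    pair = shift_pair_from_fit(_Shifts())
    shift_sd = max(res["Pi"]["sd_shift_ppm"] or 0.0, 1e-6)
    beta_sd = max(res["bATP"]["sd_shift_ppm"] or 0.0, 1e-6)
    ph = ph_from_shift(pair.delta_pi, config.derived)
    pmg, mg = mg_from_shift(pair.delta_beta, config.derived)
    derived = {
        "delta_pi_ppm": pair.delta_pi, "pH": ph,
        "pH_sd": ph_sd_from_shift_sd(pair.delta_pi, shift_sd, config.derived),
        "delta_beta_ppm": pair.delta_beta, "pMg": pmg, "Mg_mmol_per_l": mg,
        "Mg_sd_mmol_per_l": mg_sd_from_shift_sd(pair.delta_beta, beta_sd,
                                                config.derived)[1],
    }
    (out / "derived.json").write_text(json.dumps(derived, indent=1, sort_keys=True))
    log.add("derive", "derived_parameters", **derived)


def _stats_stage(config: PipelineConfig, out: Path, seed: int, log: _Log) -> None:
    path = out / "cohort.csv"
    if not path.exists():
        raise SchemaError("stats stage: missing cohort.csv (run simulate first)")
    cohort = mio.read_cohort_csv(path)
    report = build_report(cohort, config.stats)
    (out / "report.tsv").write_text(report.to_tsv())
    report.contrast_rows().to_csv(out / "contrasts.csv", index=False,
                                  float_format="%.10g")
    manova = {"phosphorus": report.phosphorus_manova_p,
              "proton": report.proton_manova_p,
              "bonferroni": {"phosphorus": config.stats.bonferroni_phosphorus,
                             "proton": config.stats.bonferroni_proton}}
    (out / "report.json").write_text(json.dumps(manova, indent=1, sort_keys=True))
    for w in report.warnings:
        log.add("stats", "warning", message=w)
    log.add("stats", "report_written", regions=len(report.phosphorus_groups))


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "fit": _fit_stage,
    "quantify": _quantify_stage,
    "derive": _derive_stage,
    "stats": _stats_stage,
}


def run_pipeline(config: PipelineConfig, stage: str = "all",
                 out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute one stage (or all, in order); returns artifact paths and the log."""
    if stage not in STAGES:
        raise SchemaError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    log = _Log()
    log.add("pipeline", "start", requested_stage=stage, seed=seed)
    stages = list(STAGES[:-1]) if stage == "all" else [stage]
    for name in stages:
        try:
            _STAGE_FUNCS[name](config, out, seed, log)
        except MrsQuantError:
            log.add(name, "failed")
            log.write(out / "pipeline_log.json")
            raise
    log.write(out / "pipeline_log.json")
    return {"out_dir": out, "stages": stages, "log": log.records}
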