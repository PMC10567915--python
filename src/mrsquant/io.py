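"""File formats: FID dialects, cohort CSV, fit-result JSON/CSV.

Two FID dialects are supported:

* a plain-text layout compatible with the jMRUI text format (header with
  sampling interval, transmitter frequency and point count, then one
  real/imaginary pair per line), lossy only to text precision;
* a JSON dialect carrying the full acquisition metadata and, when
  present, the simulation ground truth, bit-exact for the samples.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .fitting import SpectralFitResults
from .spectral import AcquisitionParams, FidRecord, Multiplet, ResonanceSpec

__all__ = [
    "write_fid", "read_fid",
    "write_cohort_csv", "read_cohort_csv",
    "fit_result_to_json", "fit_result_to_csv",
]

_COHORT_COLUMNS = ["subject_id", "group", "region", "hemisphere",
                   "metabolite", "concentration_mmol_per_kg"]


# --------------------------------------------------------------------------
# FID dialects
# --------------------------------------------------------------------------

def _resonance_to_dict(res: ResonanceSpec) -> dict:
    d = asdict(res)
    d["multiplet"] = {"n_peaks": res.multiplet.n_peaks, "j_hz": res.multiplet.j_hz,
                      "ratios": list(res.multiplet.ratios)}
    return d


def _resonance_from_dict(d: dict) -> ResonanceSpec:
    m = d.get("multiplet") or {}
    return ResonanceSpec(
        name=d["name"], shift_ppm=d["shift_ppm"], amplitude=d["amplitude"],
        damping_hz=d["damping_hz"], phase_deg=d["phase_deg"],
        multiplet=Multiplet(m.get("n_peaks", 1), m.get("j_hz", 0.0),
                            tuple(m.get("ratios", ())) or ()))


def write_fid(fid: FidRecord, path: str | Path, dialect: str = "json") -> Path:
    """Write a FID in the 'json' or 'jmrui-text' dialect."""
    path = Path(path)
    if dialect == "json":
        acq = asdict(fid.acquisition)
        payload = {
            "format": "mrsquant-fid", "version": 1,
            "acquisition": acq,
            "noise_sd": fid.noise_sd,
            "metadata": {k: v for k, v in fid.metadata.items()
                         if isinstance(v, (str, int, float, bool, type(None)))},
            "real": fid.samples.real.tolist(),
            "imag": fid.samples.imag.tolist(),
        }
        if fid.ground_truth is not None:
            payload["ground_truth"] = [_resonance_to_dict(r) for r in fid.ground_truth]
        path.write_text(json.dumps(payload))
    elif dialect == "jmrui-text":
        acq = fid.acquisition
        lines = [
            "jMRUI Data Textfile", "",
            f"Filename: {path.name}", "",
            f"PointsInDataset: {acq.vector_size}",
            "DatasetsInFile: 1",
            f"SamplingInterval: {acq.dwell_s * 1e3:.10g}",
            "ZeroOrderPhase: 0",
            "BeginTime: 0",
            f"TransmitterFrequency: {acq.nucleus_freq_mhz * 1e6:.10g}",
            "MagneticField: 3",
            f"TypeOfNucleus: {acq.nucleus}",
            "NameOfPatient: ", "DateOfExperiment: ", "Spectrometer: ", "AdditionalInfo: ",
            "", "Signal and FFT", "sig(real)\tsig(imag)",
            "Signal 1 out of 1 in file",
        ]
        lines += [f"{z.real:.12E}\t{z.imag:.12E}" for z in fid.samples]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise SchemaError(f"unknown FID dialect {dialect!r}")
    return path


def read_fid(path: str | Path, dialect: str | None = None,
             acquisition: AcquisitionParams | None = None) -> FidRecord:
    """Read a FID; the dialect is inferred from the content when omitted.

    The jMRUI text header does not carry sequence timing or the channel,
    so an ``acquisition`` template may be supplied; its bandwidth, size
    and frequency are overridden by (and checked against) the header.
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        dialect = "json" if text.lstrip().startswith("{") else "jmrui-text"
    if dialect == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON FID: {exc.msg}", exc.lineno) from None
        try:
            acq = AcquisitionParams(**payload["acquisition"])
            samples = (np.asarray(payload["real"], dtype=float)
                       + 1j * np.asarray(payload["imag"], dtype=float))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"JSON FID missing field: {exc}") from None
        if samples.size != acq.vector_size:
            raise ParseError(
                f"JSON FID declares {acq.vector_size} points but carries {samples.size}")
        truth = payload.get("ground_truth")
        return FidRecord(samples=samples, acquisition=acq,
                         ground_truth=tuple(_resonance_from_dict(d) for d in truth)
                         if truth else None,
                         noise_sd=payload.get("noise_sd"),
                         metadata=payload.get("metadata", {}))
    if dialect != "jmrui-text":
        raise SchemaError(f"unknown FID dialect {dialect!r}")
    return _read_jmrui_text(text, acquisition)


def _read_jmrui_text(text: str, template: AcquisitionParams | None) -> FidRecord:
    header: dict[str, str] = {}
    lines = text.splitlines()
    data_start = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if ":" in line:
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        if line.startswith("Signal 1 out of"):
            data_start = i + 1
            break
    if data_start is None:
        raise ParseError("jMRUI text: no 'Signal 1 out of' marker found",
                         len(lines) or 1)
    try:
        n_points = int(header["PointsInDataset"])
        dwell_ms = float(header["SamplingInterval"])
        freq_hz = float(header["TransmitterFrequency"])
    except KeyError as exc:
        raise ParseError(f"jMRUI text: missing header field {exc}") from None
    except ValueError as exc:
        raise ParseError(f"jMRUI text: malformed header value ({exc})") from None
    if dwell_ms <= 0:
        raise ParseError("jMRUI text: non-positive sampling interval")
    values = []
    for offset, raw in enumerate(lines[data_start:]):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError("jMRUI text: expected real/imaginary pair",
                             data_start + offset + 1)
        try:
            values.append(complex(float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError("jMRUI text: non-numeric sample",
                             data_start + offset + 1) from None
        if len(values) == n_points:
            break
    if len(values) != n_points:
        raise ParseError(
            f"jMRUI text: header declares {n_points} points, file has {len(values)}",
            len(lines))
    nucleus = header.get("TypeOfNucleus", "")
    channel = "phosphorus" if "31" in nucleus else "proton"
    bandwidth = 1.0 / (dwell_ms * 1e-3)
    if template is not None:
        acq = AcquisitionParams(
            tr_ms=template.tr_ms, te_ms=template.te_ms, flip_deg=template.flip_deg,
            bandwidth_hz=bandwidth, vector_size=n_points,
            nucleus_freq_mhz=freq_hz / 1e6,
            channel=template.channel, carrier_ppm=template.carrier_ppm)
    else:
        acq = AcquisitionParams(
            tr_ms=1200.0 if channel == "phosphorus" else 1500.0,
            te_ms=2.3 if channel == "phosphorus" else 135.0,
            flip_deg=60.0 if channel == "phosphorus" else 90.0,
            bandwidth_hz=bandwidth, vector_size=n_points,
            nucleus_freq_mhz=freq_hz / 1e6, channel=channel,
            carrier_ppm=0.0 if channel == "phosphorus" else 4.70)
    return FidRecord(samples=np.asarray(values), acquisition=acq,
                     metadata={"header": header})


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = set(_COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise SchemaError(f"cohort table lacks columns: {sorted(missing)}")
    cohort[_COHORT_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"cohort CSV lacks columns: {sorted(missing)}", 1)
    return frame


# --------------------------------------------------------------------------
# fit results
# --------------------------------------------------------------------------

def fit_result_to_json(fit: SpectralFitResults) -> str:
    payload = {
        "converged": fit.converged,
        "residual_norm": fit.residual_norm,
        "noise_sd": fit.noise_sd,
        "spectrum_snr": fit.spectrum_snr,
        "snr_definition": fit.meta.get("snr", {}),
        "resonances": json.loads(
            fit.params.replace([np.inf, -np.inf], None).to_json(orient="index")),
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def fit_result_to_csv(fit: SpectralFitResults, path: str | Path) -> Path:
    path = Path(path)
    frame = fit.params.copy()
    frame.insert(0, "resonance", frame.index)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path
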