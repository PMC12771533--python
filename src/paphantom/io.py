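"""Readers/writers for the on-disk formats and run configuration.

CSV dialect everywhere: comma-separated, '.' decimal, UTF-8, '#' comments.
Structured data (law parameters, fit results, manifests, run configs) is
JSON with unit-bearing key names. Fit outputs carry provenance: SHA-256 of
the input file and the seed used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .laws import (
    AbsorptionLawParams,
    AttenuationLawParams,
    ScatteringLawParams,
)
from .measurement import CalorimetryRecord, WaveformPair
from .pa_signal import PAAline

logger = logging.getLogger("paphantom")

__all__ = [
    "SchemaError",
    "RunConfig",
    "RUN_CONFIG_SCHEMA",
    "validate_config",
    "load_run_config",
    "load_default_laws",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_calorimetry_csv",
    "read_calorimetry_csv",
    "write_waveform_pair",
    "read_waveform_pair",
    "write_aline_set",
    "read_aline_set",
    "write_fit_json",
    "file_sha256",
]

SPECTRUM_COLUMNS = ("c_agarose_pct", "c_tio2_mg_ml", "lambda_nm", "mu_a_cm1")
SPECTRUM_OPTIONAL = ("mu_s_prime_cm1",)
CALORIMETRY_COLUMNS = ("m_water_kg", "m_phantom_kg", "T_water_C",
                       "T_phantom_C", "T_eq_C", "C_calo_JK")


class SchemaError(ValueError):
    """A file or config violates its declared schema; names the offender."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

RUN_CONFIG_SCHEMA = {
    "seed": (int, False),
    "input_paths": (list, False),
    "law_parameter_file": (str, False),
    "output_dir": (str, False),
    "verbosity": (str, False),
    "units": (dict, False),
    "allow_extrapolation": (bool, False),
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    input_paths: list = field(default_factory=list)
    law_parameter_file: str | None = None
    output_dir: str = "."
    verbosity: str = "info"
    units: dict = field(default_factory=dict)
    allow_extrapolation: bool = False


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping against the published schema."""
    if not isinstance(raw, dict):
        raise SchemaError("run config must be a JSON object")
    for key in raw:
        if key not in RUN_CONFIG_SCHEMA:
            raise SchemaError(f"unknown config key: {key!r}")
    for key, (typ, required) in RUN_CONFIG_SCHEMA.items():
        if key in raw and not isinstance(raw[key], typ):
            raise SchemaError(
                f"config key {key!r} must be {typ.__name__}, "
                f"got {type(raw[key]).__name__}")
        if required and key not in raw:
            raise SchemaError(f"missing required config key: {key!r}")
    return RunConfig(**raw)


def load_run_config(path) -> RunConfig:
    return validate_config(json.loads(Path(path).read_text()))


def load_default_laws() -> dict:
    """Bundled law coefficients with standard errors, units and domains."""
    text = resources.files("paphantom.data").joinpath(
        "default_laws.json").read_text()
    raw = json.loads(text)
    return {
        "absorption": AbsorptionLawParams(
            **{k: raw["absorption"][k]
               for k in ("a", "b", "c", "a_se", "b_se", "c_se")}),
        "scattering": ScatteringLawParams(
            **{k: raw["scattering"][k]
               for k in ("x", "y", "a_rm", "x_se", "y_se")}),
        "attenuation": AttenuationLawParams(
            **{k: raw["attenuation"][k]
               for k in ("a1", "a2", "a3", "b1", "b2",
                         "a1_se", "a2_se", "a3_se", "b1_se", "b2_se")}),
        "raw": raw,
    }


# ---------------------------------------------------------------------------
# Spectrum (optical dataset) CSV
# ---------------------------------------------------------------------------

def write_spectrum_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing column(s): {missing}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectrum_csv(path) -> pd.DataFrame:
    """Read an optical dataset; header-validated, per-row parse errors name
    their line number. A file without the mu_s_prime column is read in
    absorption-only mode (logged)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {missing}")
    if "mu_s_prime_cm1" not in df.columns:
        logger.info("%s: no mu_s_prime_cm1 column, absorption-only mode",
                    path.name)
    check_cols = list(SPECTRUM_COLUMNS) + [
        c for c in SPECTRUM_OPTIONAL if c in df.columns]
    for col in check_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise SchemaError(
                f"{path.name}: malformed value in column {col!r} "
                f"at line {bad[0] + 2}")
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# Calorimetry CSV
# ---------------------------------------------------------------------------

def write_calorimetry_csv(records, path) -> None:
    rows = [{"m_water_kg": r.m_water, "m_phantom_kg": r.m_phantom,
             "T_water_C": r.T_water, "T_phantom_C": r.T_phantom,
             "T_eq_C": r.T_eq, "C_calo_JK": r.C_calo} for r in records]
    pd.DataFrame(rows, columns=CALORIMETRY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_calorimetry_csv(path) -> list[CalorimetryRecord]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CALORIMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {missing}")
    return [CalorimetryRecord(m_water=row.m_water_kg,
                              m_phantom=row.m_phantom_kg,
                              T_water=row.T_water_C, T_phantom=row.T_phantom_C,
                              T_eq=row.T_eq_C, C_calo=row.C_calo_JK)
            for row in df.itertuples()]


# ---------------------------------------------------------------------------
# Waveform pairs (two two-column CSVs + JSON sidecar)
# ---------------------------------------------------------------------------

def write_waveform_pair(pair: WaveformPair, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(pair.reference_trace)) / pair.sampling_rate
    for name, trace in (("reference", pair.reference_trace),
                        ("sample", pair.sample_trace)):
        np.savetxt(directory / f"{name}.csv",
                   np.column_stack([t, trace]), delimiter=",",
                   header="time_s,voltage", comments="# ")
    meta = {"sampling_rate_hz": pair.sampling_rate, "h_m": pair.h,
            "u_h_m": pair.u_h, "T_water_C": pair.T_water}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_waveform_pair(directory) -> WaveformPair:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    ref = np.loadtxt(directory / "reference.csv", delimiter=",", comments="#")
    sam = np.loadtxt(directory / "sample.csv", delimiter=",", comments="#")
    return WaveformPair(reference_trace=ref[:, 1], sample_trace=sam[:, 1],
                        sampling_rate=meta["sampling_rate_hz"],
                        h=meta["h_m"], u_h=meta.get("u_h_m", 20e-6),
                        T_water=meta["T_water_C"])


# ---------------------------------------------------------------------------
# PA A-line sets (per-wavelength traces + JSON manifest)
# ---------------------------------------------------------------------------

def write_aline_set(alines, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for aline in alines:
        fname = f"aline_{aline.wavelength_nm:.0f}nm.csv"
        t = np.arange(len(aline.trace)) / aline.sampling_rate
        np.savetxt(directory / fname, np.column_stack([t, aline.trace]),
                   delimiter=",", header="time_s,voltage", comments="# ")
        manifest.append({"file": fname, "wavelength_nm": aline.wavelength_nm,
                         "photodiode_value": aline.photodiode_value,
                         "sampling_rate_hz": aline.sampling_rate,
                         "n_averages": aline.n_averages})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_aline_set(directory) -> list[PAAline]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    alines = []
    for entry in manifest:
        data = np.loadtxt(directory / entry["file"], delimiter=",", comments="#")
        alines.append(PAAline(trace=data[:, 1],
                              sampling_rate=entry["sampling_rate_hz"],
                              wavelength_nm=entry["wavelength_nm"],
                              photodiode_value=entry["photodiode_value"],
                              n_averages=entry.get("n_averages", 512)))
    return alines


# ---------------------------------------------------------------------------
# Fit outputs with provenance
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fit_json(params, path, input_files=(), seed=None, extra=None) -> None:
    """Serialise a fitted parameter set with provenance metadata."""
    if dataclasses.is_dataclass(params):
        payload = dataclasses.asdict(params)
    else:
        payload = dict(params)
    payload = {k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
               for k, v in payload.items()}
    doc = {
        "parameters": payload,
        "provenance": {
            "input_sha256": {str(p): file_sha256(p) for p in input_files},
            "seed": seed,
        },
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=str))
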