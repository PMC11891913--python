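"""Delimited-text readers and writers for all assay schemas.

One on-disk dialect is used everywhere: comma-separated values with "."
decimal, optional ``# key=value`` header lines before the column header.
Readers validate against the documented schemas and raise
:class:`~memassay.meta.SchemaError` / :class:`~memassay.meta.ValidationError`
naming the offending field; they never silently coerce.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (DecayHistogram, EmissionSpectrum, InjectionSeries,
                         MonolayerTrace)
from .meta import ResultRecord, SampleMeta, SchemaError, ValidationError

CAL_TO_J = 4.184


def _split_header(path) -> tuple[dict[str, str], str]:
    """Split leading ``# key=value`` lines from the CSV body."""
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    header[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    return header, "".join(body_lines)


def _read_table(path, required: tuple[str, ...]) -> tuple[dict[str, str], pd.DataFrame]:
    header, body = _split_header(path)
    if not body.strip():
        raise SchemaError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO(body))
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return header, df


def _require_header(header: dict, path, *keys: str) -> None:
    for key in keys:
        if key not in header:
            raise SchemaError(f"{path}: missing header key {key!r}")


def _write(path, header: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------- spectra

def read_spectra(path) -> list[EmissionSpectrum]:
    """Read a long-format spectra file into one spectrum per (sample, time).

    Schema: columns ``sample_id, time_min, wavelength_nm, intensity`` with
    optional ``# excitation_nm=...`` header.
    """
    header, df = _read_table(
        path, ("sample_id", "time_min", "wavelength_nm", "intensity"))
    excitation = float(header["excitation_nm"]) if "excitation_nm" in header else None
    spectra = []
    for (sid, t), grp in df.groupby(["sample_id", "time_min"], sort=True):
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(wl) <= 0):
            i = int(np.argmax(np.diff(wl) <= 0))
            raise ValidationError(
                f"{path}: wavelengths not strictly increasing for sample "
                f"{sid!r} at t={t} (row with {wl[i + 1]} nm)")
        spectra.append(EmissionSpectrum(
            wavelengths=wl,
            intensities=grp["intensity"].to_numpy(dtype=float),
            excitation_nm=excitation,
            time_min=float(t),
            meta=SampleMeta(sample_id=str(sid)),
        ))
    return spectra


def write_spectra(spectra: list[EmissionSpectrum], path) -> None:
    frames = []
    for sp in spectra:
        frames.append(pd.DataFrame({
            "sample_id": sp.sample_id or "sample",
            "time_min": sp.time_min,
            "wavelength_nm": sp.wavelengths,
            "intensity": sp.intensities,
        }))
    header = {}
    excitations = {sp.excitation_nm for sp in spectra if sp.excitation_nm is not None}
    if len(excitations) == 1:
        header["excitation_nm"] = repr(excitations.pop())
    _write(path, header, pd.concat(frames, ignore_index=True))


# ------------------------------------------------------------------ decay

def read_decay(path) -> DecayHistogram:
    """Read a TCSPC decay histogram (columns ``time_ns, counts``)."""
    header, df = _read_table(path, ("time_ns", "counts"))
    counts = df["counts"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative counts")
    if np.any(counts != np.round(counts)):
        raise ValidationError(f"{path}: fractional counts (photon counts must be integers)")
    return DecayHistogram(
        time=df["time_ns"].to_numpy(dtype=float),
        counts=counts,
        acquisition_s=float(header.get("acquisition_s", 1.0)),
        excitation_nm=float(header.get("excitation_nm", 467.0)),
        emission_nm=float(header.get("emission_nm", 515.0)),
        meta=SampleMeta(sample_id=header.get("sample_id", "")),
    )


def write_decay(decay: DecayHistogram, path) -> None:
    header = {
        "sample_id": decay.meta.sample_id if decay.meta else "",
        "acquisition_s": repr(decay.acquisition_s),
        "excitation_nm": repr(decay.excitation_nm),
        "emission_nm": repr(decay.emission_nm),
    }
    df = pd.DataFrame({"time_ns": decay.time,
                       "counts": decay.counts.astype(np.int64)})
    _write(path, header, df)


# ------------------------------------------------------------- injections

def read_injections(path) -> InjectionSeries:
    """Read an ITC injection series.

    Header keys ``cell_volume_mL, syringe_lipid_mM, cell_peptide_mM,
    temperature_C``; columns ``injection_index, volume_uL`` and either
    ``heat_uJ`` or ``heat_ucal`` (converted with 1 cal = 4.184 J).
    """
    header, df = _read_table(path, ("injection_index", "volume_uL"))
    _require_header(header, path, "cell_volume_mL", "syringe_lipid_mM",
                    "cell_peptide_mM")
    if "heat_uJ" in df.columns:
        heats = df["heat_uJ"].to_numpy(dtype=float)
    elif "heat_ucal" in df.columns:
        heats = df["heat_ucal"].to_numpy(dtype=float) * CAL_TO_J
    else:
        raise SchemaError(f"{path}: missing required column 'heat_uJ' (or 'heat_ucal')")
    cell_volume = float(header["cell_volume_mL"])
    if cell_volume <= 0:
        raise ValidationError(f"{path}: cell_volume_mL must be positive")
    return InjectionSeries(
        cell_volume=cell_volume,
        cell_peptide_conc=float(header["cell_peptide_mM"]),
        syringe_lipid_conc=float(header["syringe_lipid_mM"]),
        injection_volumes=df["volume_uL"].to_numpy(dtype=float),
        heats=heats,
        temperature=float(header.get("temperature_C", 25.0)),
        meta=SampleMeta(sample_id=header.get("sample_id", "")),
    )


def write_injections(series: InjectionSeries, path) -> None:
    header = {
        "sample_id": series.meta.sample_id if series.meta else "",
        "cell_volume_mL": repr(series.cell_volume),
        "syringe_lipid_mM": repr(series.syringe_lipid_conc),
        "cell_peptide_mM": repr(series.cell_peptide_conc),
        "temperature_C": repr(series.temperature),
    }
    df = pd.DataFrame({
        "injection_index": np.arange(1, series.n_injections + 1),
        "volume_uL": series.injection_volumes,
        "heat_uJ": series.heats,
    })
    _write(path, header, df)


# -------------------------------------------------------------- monolayer

def read_monolayer(path) -> MonolayerTrace:
    """Read a surface-pressure trace (columns ``time_s, pressure_mN_m``)."""
    header, df = _read_table(path, ("time_s", "pressure_mN_m"))
    _require_header(header, path, "injection_time_s")
    return MonolayerTrace(
        time=df["time_s"].to_numpy(dtype=float),
        pressure=df["pressure_mN_m"].to_numpy(dtype=float),
        injection_time=float(header["injection_time_s"]),
        meta=SampleMeta(sample_id=header.get("sample_id", "")),
    )


def write_monolayer(trace: MonolayerTrace, path) -> None:
    header = {
        "sample_id": trace.meta.sample_id if trace.meta else "",
        "injection_time_s": repr(trace.injection_time),
    }
    df = pd.DataFrame({"time_s": trace.time, "pressure_mN_m": trace.pressure})
    _write(path, header, df)


# -------------------------------------------------------------------- dls

def read_dls(path) -> pd.DataFrame:
    """Read a DLS summary table (instrument-computed Z-average and PDI)."""
    _, df = _read_table(path, ("sample_id", "peptide_conc_uM",
                               "z_average_nm", "pdi"))
    if (df["z_average_nm"] < 0).any():
        raise ValidationError(f"{path}: negative z_average_nm")
    if (df["pdi"] < 0).any():
        raise ValidationError(f"{path}: negative pdi")
    return df


def write_dls(df: pd.DataFrame, path) -> None:
    _write(path, {}, df[["sample_id", "peptide_conc_uM", "z_average_nm", "pdi"]])


# ---------------------------------------------------------------- results

RESULT_COLUMNS = ("sample_id", "assay", "metric_name", "metric_value",
                  "incubation_time", "qc_flags", "truth_value")


def write_results(records: list[ResultRecord], path) -> None:
    """Write tidy result rows; duplicate metric keys are an error."""
    if not records:
        raise ValidationError("records must be non-empty")
    keys = [(r.sample_id, r.assay, r.metric_name, r.incubation_time)
            for r in records]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValidationError(f"duplicate result row for {dup}")
    df = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "assay": [r.assay for r in records],
        "metric_name": [r.metric_name for r in records],
        "metric_value": [r.metric_value for r in records],
        "incubation_time": [r.incubation_time for r in records],
        "qc_flags": [";".join(sorted(r.qc_flags)) for r in records],
        "truth_value": [r.truth_value for r in records],
    })
    _write(path, {}, df)


def read_results(path) -> list[ResultRecord]:
    _, df = _read_table(path, RESULT_COLUMNS[:5])
    records = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "qc_flags", "")
        flags = frozenset() if pd.isna(flags) or flags == "" else frozenset(str(flags).split(";"))
        truth = getattr(row, "truth_value", None)
        truth = None if truth is None or pd.isna(truth) else float(truth)
        records.append(ResultRecord(
            sample_id=str(row.sample_id),
            assay=str(row.assay),
            metric_name=str(row.metric_name),
            metric_value=float(row.metric_value),
            incubation_time=float(row.incubation_time),
            qc_flags=flags,
            truth_value=truth,
        ))
    return records
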