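"""Charge-neutralization stoichiometry, DLS flagging, and onset alignment.

A cationic peptide of charge ``z_P`` neutralizes the anionic surface charge
of a vesicle suspension when the charge ratio

    R_c = z_P * c_P / (f_anionic * c_L * leaflet_fraction)

reaches 1 -- for the whole vesicle (``leaflet_fraction = 1``) or for the
outer leaflet only (0.5, peptide excluded from the lumen).  Aggregation,
lipid mixing, packing changes and leakage set in around this point, so
effect onsets across assays are annotated with their ``R_c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import SampleMeta, ValidationError

LEAFLET_FRACTIONS = {"both": 1.0, "outer": 0.5}
DLS_SIZE_LIMIT_NM = 1000.0
DLS_PREP_SIZE_NM = (100.0, 120.0)  # acceptable initial Z-average
DLS_PREP_PDI = 0.1


@dataclass
class ChargeStoichiometry:
    R_c: float
    z_P: int
    f_anionic: float
    leaflet_fraction: float
    neutralization_conc: float  # uM peptide at R_c = 1
    neutralization_molar_ratio: float  # lipid/peptide at R_c = 1


def _leaflet_fraction(leaflet: str) -> float:
    try:
        return LEAFLET_FRACTIONS[leaflet]
    except KeyError:
        raise ValidationError(
            f"leaflet must be one of {sorted(LEAFLET_FRACTIONS)}, "
            f"got {leaflet!r}") from None


def charge_ratio(meta: SampleMeta, leaflet: str = "both") -> ChargeStoichiometry:
    """Peptide/lipid charge ratio for a sample (added concentrations)."""
    f_anionic = meta.anionic_fraction
    if f_anionic <= 0:
        raise ValidationError(
            "R_c undefined for purely zwitterionic membranes (no anionic lipid)")
    if meta.lipid_conc <= 0:
        raise ValidationError("lipid_conc must be positive")
    lf = _leaflet_fraction(leaflet)
    r_c = (meta.peptide_charge * meta.peptide_conc) / (
        f_anionic * meta.lipid_conc * lf)
    c_star, ratio = neutralization_concentration(
        meta.lipid_conc, f_anionic, meta.peptide_charge, leaflet)
    return ChargeStoichiometry(
        R_c=r_c, z_P=meta.peptide_charge, f_anionic=f_anionic,
        leaflet_fraction=lf, neutralization_conc=c_star,
        neutralization_molar_ratio=ratio)


def neutralization_concentration(c_lipid: float, f_anionic: float, z_p: int,
                                 leaflet: str = "both") -> tuple[float, float]:
    """Peptide concentration and lipid/peptide molar ratio at R_c = 1.

    ``c_P* = f_anionic * c_L * leaflet_fraction / z_P``; the molar ratio is
    ``c_L / c_P*``.  Units follow ``c_lipid`` (uM in, uM out).
    """
    if f_anionic <= 0:
        raise ValidationError("f_anionic must be positive")
    if c_lipid <= 0 or z_p <= 0:
        raise ValidationError("c_lipid and z_p must be positive")
    lf = _leaflet_fraction(leaflet)
    c_star = f_anionic * c_lipid * lf / z_p
    return c_star, c_lipid / c_star


def flag_dls(dls_table: pd.DataFrame, size_limit: float = DLS_SIZE_LIMIT_NM,
             pdi_limit: float = DLS_PREP_PDI) -> pd.DataFrame:
    """Attach QC flags to an instrument DLS table.

    Rows with Z-average above ``size_limit`` are flagged ``aggregated``; the
    peptide-free preparation row is checked against the extrusion spec
    (110 +/- 10 nm, PDI < 0.1) and flagged ``prep_out_of_spec`` otherwise.
    """
    if (dls_table["z_average_nm"] < 0).any():
        raise ValidationError("negative z_average_nm")
    out = dls_table.copy()
    flags: list[str] = []
    prep = out.loc[out["peptide_conc_uM"] == out["peptide_conc_uM"].min()]
    prep_bad = bool(
        ((prep["z_average_nm"] < DLS_PREP_SIZE_NM[0]) |
         (prep["z_average_nm"] > DLS_PREP_SIZE_NM[1]) |
         (prep["pdi"] >= pdi_limit)).any())
    for row in out.itertuples(index=False):
        row_flags = []
        if row.z_average_nm > size_limit:
            row_flags.append("aggregated")
        if prep_bad and row.peptide_conc_uM == prep["peptide_conc_uM"].iloc[0]:
            row_flags.append("prep_out_of_spec")
        flags.append(";".join(sorted(row_flags)))
    out["qc_flags"] = flags
    return out


@dataclass
class OnsetRow:
    assay: str
    onset_conc: float | None  # uM; None means "> max tested"
    onset_R_c: float | None
    onset_R_c_outer: float | None


def detect_onset(conc: np.ndarray, value: np.ndarray, uncertainty,
                 flagged: np.ndarray | None = None) -> float | None:
    """Lowest concentration whose metric exceeds the reference by 3 sigma.

    The reference is the value at the lowest (zero/no-peptide)
    concentration.  A point may also count as exceeding if its QC rule
    flagged it (``flagged`` boolean array).  Returns ``None`` when nothing
    exceeds ("> max tested").
    """
    conc = np.asarray(conc, dtype=float)
    value = np.asarray(value, dtype=float)
    if conc.size < 3:
        raise ValidationError("need >= 3 concentrations incl. a reference")
    order = np.argsort(conc)
    conc, value = conc[order], value[order]
    unc = np.broadcast_to(np.asarray(uncertainty, dtype=float), conc.shape)[order]
    if flagged is None:
        flagged = np.zeros(conc.shape, dtype=bool)
    else:
        flagged = np.asarray(flagged, dtype=bool)[order]
    ref = value[0]
    for c, v, s, fl in zip(conc[1:], value[1:], unc[1:], flagged[1:]):
        if fl or abs(v - ref) > 3.0 * s:
            return float(c)
    return None


def onset_alignment(series: dict[str, dict], meta: SampleMeta) -> pd.DataFrame:
    """Align effect onsets across assays against the charge ratio R_c.

    ``series`` maps assay name to a dict with keys ``conc`` (uM, including
    the zero/reference point), ``value``, ``uncertainty`` and optionally
    ``flagged``.  Returns a table of per-assay onset concentration with its
    R_c (both leaflets) and R_c,outer annotation.
    """
    rows = []
    f_anionic = meta.anionic_fraction
    for assay, data in series.items():
        onset = detect_onset(data["conc"], data["value"], data["uncertainty"],
                             data.get("flagged"))
        if onset is None:
            rows.append(OnsetRow(assay, None, None, None))
        else:
            rc = meta.peptide_charge * onset / (f_anionic * meta.lipid_conc)
            rows.append(OnsetRow(assay, onset, rc, rc / 0.5))
    return pd.DataFrame({
        "assay": [r.assay for r in rows],
        "onset_conc_uM": [np.nan if r.onset_conc is None else r.onset_conc
                          for r in rows],
        "onset_R_c": [np.nan if r.onset_R_c is None else r.onset_R_c
                      for r in rows],
        "onset_R_c_outer": [np.nan if r.onset_R_c_outer is None
                            else r.onset_R_c_outer for r in rows],
        "note": ["> max tested" if r.onset_conc is None else ""
                 for r in rows],
    })
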