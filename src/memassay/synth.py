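"""Synthetic raw data with known ground truth for every assay.

Each generator emulates the statistical structure the corresponding
analysis assumes -- biexponential calcein decays with Poisson counting
noise and a dark (statically quenched) entrapped fraction; two-band laurdan
spectra whose band ratio encodes GP; NBD/rhodamine spectra whose
donor/acceptor ratio follows the linear probe-dilution model; exothermic
one-set-of-sites injection heats with cell-displacement dilution; monolayer
pressure traces relaxing exponentially to a plateau -- and returns a
ground-truth dict alongside the data so analyzers can be tested for
recovery.  ``simulate_study`` writes a coherent multi-assay directory
emulating a full concentration series, with presets mirroring a fast-leaking
("cR3W3-like") and a slow/non-leaking ("c(RW)3-like") peptide.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .containers import (DecayHistogram, EmissionSpectrum, InjectionSeries,
                         MonolayerTrace)
from .itc import predicted_injection_heats
from .meta import SampleMeta, ValidationError

# FRET ratio anchors of the generator's linear-dilution model:
# donor/acceptor ratio before peptide (intact FRET) and after Triton
# (FRET abolished by infinite probe dilution).
FRET_R0 = 0.5
FRET_RINF = 3.0
LAURDAN_BAND_SD = 25.0  # nm
FRET_BAND_SD = 12.0  # nm


# ------------------------------------------------------------------ decay

def simulate_decay(true_leak: float, dark_fraction: float,
                   tau_e: float = 0.4, tau_f: float = 4.0,
                   total_counts: float = 1e6, channels: int = 1024,
                   t_max: float = 25.0, seed: int | None = None,
                   acquisition_s: float = 60.0, scale: float = 1.0,
                   poisson: bool = True,
                   meta: SampleMeta | None = None
                   ) -> tuple[DecayHistogram, dict]:
    """Simulate a calcein TCSPC decay.

    ``total_counts`` is the expected count of the *fully released*
    equivalent sample, so intact/release pairs generated with the same value
    share a brightness scale (required for Q_stat calibration).  The
    entrapped amplitude is scaled by ``(1 - dark_fraction)``: static
    quenching makes molecules dark without shifting the lifetime, implying
    ``Q_stat = 1/(1 - dark_fraction)``.  ``scale`` applies an overall
    attenuation (e.g. pipetting loss).  With ``poisson=False`` the
    expectation values are returned (noiseless).
    """
    if not 0.0 <= true_leak <= 1.0:
        raise ValidationError("true_leak must be in [0, 1]")
    if not 0.0 <= dark_fraction < 1.0:
        raise ValidationError("dark_fraction must be in [0, 1)")
    if total_counts <= 0:
        raise ValidationError("total_counts must be positive")
    t = np.arange(channels) * (t_max / channels)
    sum_f = float(np.sum(np.exp(-t / tau_f)))
    b_full = total_counts / sum_f  # counts at t0 of a fully released sample
    b_e = b_full * (1.0 - true_leak) * (1.0 - dark_fraction) * scale
    b_f = b_full * true_leak * scale
    expected = b_e * np.exp(-t / tau_e) + b_f * np.exp(-t / tau_f)
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    truth = {
        "true_leak": true_leak, "dark_fraction": dark_fraction,
        "tau_E": tau_e, "tau_F": tau_f, "B_E": b_e, "B_F": b_f,
        "Q_stat": 1.0 / (1.0 - dark_fraction), "scale": scale, "seed": seed,
    }
    decay = DecayHistogram(time=t, counts=counts, acquisition_s=acquisition_s,
                           meta=meta or SampleMeta(sample_id="synthetic"))
    return decay, truth


# ---------------------------------------------------------------- spectra

def _gaussian(wl: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sd) ** 2)


def _laurdan_amplitudes(gp_target: float) -> tuple[float, float]:
    """Band amplitudes (440, 490) whose measured GP equals ``gp_target``.

    The 440/490 read-outs each contain cross-talk c from the other Gaussian
    band; the 2x2 linear system is solved so the analyzer recovers the
    target exactly.
    """
    if not -1.0 < gp_target < 1.0:
        raise ValidationError("target GP must be inside (-1, 1)")
    c = float(np.exp(-0.5 * (50.0 / LAURDAN_BAND_SD) ** 2))
    det = 1.0 - c * c
    a440 = ((1.0 + gp_target) - c * (1.0 - gp_target)) / det
    a490 = ((1.0 - gp_target) - c * (1.0 + gp_target)) / det
    if a440 < 0 or a490 < 0:
        raise ValidationError(
            f"target GP {gp_target} not representable with two "
            f"{LAURDAN_BAND_SD} nm bands")
    return a440, a490


def simulate_spectra(kind: str, states, times=None, noise_sd: float = 0.0,
                     seed: int | None = None, labeled_fraction: float = 0.2,
                     amplitude: float = 1000.0, attenuation: dict | None = None,
                     include_triton: bool = True,
                     meta: SampleMeta | None = None
                     ) -> tuple[list[EmissionSpectrum], dict]:
    """Simulate a laurdan or FRET emission-spectra time series.

    For ``kind="laurdan"`` the states are target GP values; for
    ``kind="fret"`` they are fused fractions (the donor/acceptor ratio
    follows ``R = R0 + phi*(1-f)/2*(R_inf - R0)``), and a final Triton
    reference spectrum is appended unless ``include_triton=False``.  The
    first state is the pre-addition reference at ``time_min = 0``.
    ``noise_sd`` is Gaussian noise relative to the peak amplitude;
    ``attenuation = {"factor": a, "from_time": t}`` multiplies spectra at
    ``time >= t`` to emulate aggregation artifacts.
    """
    states = list(states)
    if times is None:
        times = [0.0] + [10.0 * i for i in range(1, len(states))]
    if len(times) != len(states):
        raise ValidationError("times and states differ in length")
    rng = np.random.default_rng(seed)
    meta = meta or SampleMeta(sample_id="synthetic")
    spectra: list[EmissionSpectrum] = []
    truth: dict = {"kind": kind, "states": states, "times": list(times),
                   "seed": seed, "attenuation": attenuation}

    if kind == "laurdan":
        wl = np.arange(390.0, 601.0)
        for t, gp_t in zip(times, states):
            a440, a490 = _laurdan_amplitudes(gp_t)
            inten = amplitude * (a440 * _gaussian(wl, 440.0, LAURDAN_BAND_SD)
                                 + a490 * _gaussian(wl, 490.0, LAURDAN_BAND_SD))
            inten = _attenuate(inten, t, attenuation)
            if noise_sd > 0:
                inten = inten + rng.normal(0.0, noise_sd * amplitude, wl.size)
            spectra.append(EmissionSpectrum(wl, inten, excitation_nm=360.0,
                                            time_min=float(t), meta=meta))
        truth["GP"] = states
        return spectra, truth

    if kind == "fret":
        wl = np.arange(480.0, 651.0)
        ratios = [FRET_R0 + phi * (1.0 - labeled_fraction) / 2.0
                  * (FRET_RINF - FRET_R0) for phi in states]
        for t, r in zip(times, ratios):
            inten = amplitude * (r * _gaussian(wl, 520.0, FRET_BAND_SD)
                                 + _gaussian(wl, 580.0, FRET_BAND_SD))
            inten = _attenuate(inten, t, attenuation)
            if noise_sd > 0:
                inten = inten + rng.normal(0.0, noise_sd * amplitude, wl.size)
            spectra.append(EmissionSpectrum(wl, inten, excitation_nm=463.0,
                                            time_min=float(t), meta=meta))
        truth.update({"R": ratios, "R0": FRET_R0, "R_inf": FRET_RINF,
                      "labeled_fraction": labeled_fraction,
                      "LME": [phi * (1.0 - labeled_fraction) / 2.0
                              for phi in states]})
        if include_triton:
            t_tri = float(max(times)) + 5.0
            inten = amplitude * (FRET_RINF * _gaussian(wl, 520.0, FRET_BAND_SD)
                                 + _gaussian(wl, 580.0, FRET_BAND_SD))
            if noise_sd > 0:
                inten = inten + rng.normal(0.0, noise_sd * amplitude, wl.size)
            spectra.append(EmissionSpectrum(wl, inten, excitation_nm=463.0,
                                            time_min=t_tri, meta=meta))
            truth["triton_index"] = len(spectra) - 1
        return spectra, truth

    raise ValidationError(f"kind must be 'laurdan' or 'fret', got {kind!r}")


def _attenuate(inten: np.ndarray, t: float, attenuation: dict | None
               ) -> np.ndarray:
    if attenuation and t >= attenuation["from_time"]:
        return inten * attenuation["factor"]
    return inten


# -------------------------------------------------------------------- itc

def simulate_itc(n: float, k: float, dh: float, cell_volume_ml: float = 1.4,
                 cell_mm: float = 0.1, syringe_mm: float = 5.0,
                 n_injections: int = 28, vol_ul: float = 10.0,
                 noise_sd: float = 0.0, seed: int | None = None,
                 meta: SampleMeta | None = None
                 ) -> tuple[InjectionSeries, dict]:
    """Simulate an injection-heat series from the one-set-of-sites model.

    ``k`` in 1/M, ``dh`` in kJ/mol, ``noise_sd`` is Gaussian noise on the
    heats in uJ.
    """
    if n <= 0 or k <= 0:
        raise ValidationError("n and K must be positive")
    series = InjectionSeries(
        cell_volume=cell_volume_ml, cell_peptide_conc=cell_mm,
        syringe_lipid_conc=syringe_mm,
        injection_volumes=np.full(n_injections, vol_ul),
        heats=np.zeros(n_injections),
        meta=meta or SampleMeta(sample_id="synthetic"))
    heats = predicted_injection_heats(series, n, k, dh)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, heats.size)
    series.heats = heats
    truth = {"n": n, "K": k, "dH": dh, "noise_sd": noise_sd, "seed": seed,
             "c_value": n * k * cell_mm * 1e-3}
    return series, truth


# -------------------------------------------------------------- monolayer

def simulate_monolayer(pi0: float, delta_pi_plateau: float,
                       rate_min: float = 5.0, noise_sd: float = 0.05,
                       seed: int | None = None, pre_min: float = 30.0,
                       post_min: float = 45.0, dt_s: float = 1.0,
                       meta: SampleMeta | None = None
                       ) -> tuple[MonolayerTrace, dict]:
    """Simulate a surface-pressure trace: flat baseline, then an exponential
    rise of amplitude ``delta_pi_plateau`` with time constant ``rate_min``."""
    if rate_min <= 0:
        raise ValidationError("rate_min must be positive")
    t_inj = pre_min * 60.0
    t = np.arange(0.0, t_inj + post_min * 60.0 + dt_s, dt_s)
    pressure = np.full(t.size, float(pi0))
    post = t > t_inj
    pressure[post] += delta_pi_plateau * (
        1.0 - np.exp(-(t[post] - t_inj) / (rate_min * 60.0)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sd, t.size)
    trace = MonolayerTrace(time=t, pressure=pressure, injection_time=t_inj,
                           meta=meta or SampleMeta(sample_id="synthetic"))
    truth = {"pi0": pi0, "delta_pi_plateau": delta_pi_plateau,
             "rate_min": rate_min, "noise_sd": noise_sd, "seed": seed}
    return trace, truth


# ------------------------------------------------------------------ study

PRESETS: dict[str, dict] = {
    # fast-leaking, aggregating peptide on PG/PE: leakage onset 3 uM,
    # all-or-none release, L_total ~ 0.5 at 30 uM after 10 min
    "cR3W3-like": {
        "peptide_id": "cR3W3",
        "lipid_fractions": {"POPG": 0.5, "POPE": 0.5},
        "lipid_conc_uM": 30.0,
        "peptide_concs_uM": [0.0, 1.0, 2.5, 3.0, 5.0, 10.0, 30.0, 100.0],
        "leakage": {"onset_uM": 3.0, "mode": "all_or_none",
                    "dark_fraction": 0.5,
                    "leak_by_conc": {3.0: 0.05, 5.0: 0.15, 10.0: 0.35,
                                     30.0: 0.5, 100.0: 0.6}},
        "aggregation_onset_uM": 3.0,
        "gp": {"gp0": 0.30, "max_delta": 0.08, "onset_uM": 3.0},
        "fret": {"onset_uM": 3.0, "max_fused": 1.0},
        "itc": {"n": 4.7, "K": 84e3, "dH": -4.7,
                "cell_mM": 0.1, "syringe_mM": 5.0},
        "monolayer": {"pi0_grid": [10.0, 15.0, 20.0, 25.0, 30.0, 35.0],
                      "delta_pi_at_35": 4.0, "slope": -0.15},
    },
    # selective, slow/non-leaking peptide: no leakage onset at <= 10 uM,
    # graded lifetime shift at high concentration, aggregation from 10 uM
    "c(RW)3-like": {
        "peptide_id": "c(RW)3",
        "lipid_fractions": {"POPG": 0.5, "POPE": 0.5},
        "lipid_conc_uM": 30.0,
        "peptide_concs_uM": [0.0, 1.0, 2.5, 3.0, 5.0, 10.0, 30.0, 100.0],
        "leakage": {"onset_uM": 30.0, "mode": "graded",
                    "dark_fraction": 0.5,
                    "leak_by_conc": {30.0: 0.1, 100.0: 0.25},
                    "tau_e_by_conc": {30.0: 1.0, 100.0: 2.0}},
        "aggregation_onset_uM": 10.0,
        "gp": {"gp0": 0.30, "max_delta": 0.04, "onset_uM": 5.0},
        "fret": {"onset_uM": 10.0, "max_fused": 0.8},
        "itc": {"n": 11.0, "K": 4.9e3, "dH": -1.9,
                "cell_mM": 0.1, "syringe_mM": 10.0},
        "monolayer": {"pi0_grid": [10.0, 15.0, 20.0, 25.0, 30.0, 35.0],
                      "delta_pi_at_35": 2.0, "slope": -0.12},
    },
}


def _scale(conc: float, onset: float, full: float) -> float:
    """Linear ramp from 0 at the onset concentration to 1 at ``full``."""
    if conc < onset:
        return 0.0
    if full <= onset:
        return 1.0
    return min((conc - onset) / (full - onset), 1.0)


def simulate_study(config: dict | str, seed: int = 0,
                   out_dir: str | Path | None = None
                   ) -> tuple[dict, dict]:
    """Generate a coherent whole-study dataset for one peptide preset.

    ``config`` is a preset name (``"cR3W3-like"`` / ``"c(RW)3-like"``) or a
    dict of the same shape.  Returns ``(datasets, truth)``; when ``out_dir``
    is given all raw files plus a ``truth.json`` sidecar are written so the
    CLI pipeline can run end-to-end on them.  Identical (config, seed) give
    identical data.
    """
    cfg = PRESETS[config] if isinstance(config, str) else config
    concs = list(cfg["peptide_concs_uM"])
    max_conc = max(concs)
    for key in ("aggregation_onset_uM",):
        if cfg[key] > max_conc:
            raise ValidationError(
                f"{key} {cfg[key]} exceeds the maximum tested concentration")
    if cfg["leakage"]["onset_uM"] > max_conc:
        raise ValidationError("leakage onset exceeds the maximum tested concentration")
    ss = np.random.SeedSequence(seed)
    child = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ("decay", "laurdan", "fret", "itc", "monolayer"),
                 ss.spawn(5))}
    pid = cfg["peptide_id"]

    def meta_for(conc: float, t: float = 10.0) -> SampleMeta:
        return SampleMeta(
            sample_id=f"{pid}_c{conc:g}", lipid_fractions=cfg["lipid_fractions"],
            lipid_conc=cfg["lipid_conc_uM"], peptide_id=pid,
            peptide_conc=conc, incubation_time=t)

    truth: dict = {"preset": pid, "seed": seed, "config": cfg}
    data: dict = {"meta": {f"{pid}_c{c:g}": meta_for(c) for c in concs}}

    # --- leakage decays: per-concentration sample + reference + release
    lk = cfg["leakage"]
    decays = {}
    for i, conc in enumerate(concs):
        leak = lk["leak_by_conc"].get(conc, 0.0)
        tau_e = lk.get("tau_e_by_conc", {}).get(conc, 0.4)
        decay, d_truth = simulate_decay(
            true_leak=leak, dark_fraction=lk["dark_fraction"], tau_e=tau_e,
            seed=child["decay"] + i, meta=meta_for(conc))
        decays[conc] = decay
        truth.setdefault("leakage", {})[conc] = d_truth
    release, rel_truth = simulate_decay(
        true_leak=1.0, dark_fraction=lk["dark_fraction"],
        seed=child["decay"] + 1000,
        meta=SampleMeta(sample_id=f"{pid}_release"))
    data["decays"] = decays
    data["decay_reference"] = decays[0.0]
    data["decay_release"] = release
    truth["leakage_release"] = rel_truth

    # --- laurdan: per-concentration GP step at 10 min incubation
    gp_cfg = cfg["gp"]
    laurdan = {}
    for i, conc in enumerate(concs):
        d_gp = gp_cfg["max_delta"] * _scale(conc, gp_cfg["onset_uM"], 30.0)
        spectra, s_truth = simulate_spectra(
            "laurdan", [gp_cfg["gp0"], gp_cfg["gp0"] + d_gp],
            noise_sd=0.002, seed=child["laurdan"] + i, meta=meta_for(conc))
        laurdan[conc] = spectra
        truth.setdefault("laurdan", {})[conc] = s_truth
    data["laurdan"] = laurdan

    # --- fret: fused fraction ramps from its onset; attenuation above the
    # aggregation onset emulates intensity loss
    fr = cfg["fret"]
    fret = {}
    for i, conc in enumerate(concs):
        phi = fr["max_fused"] * _scale(conc, fr["onset_uM"], 30.0)
        att = ({"factor": 0.3, "from_time": 20.0}
               if conc > cfg["aggregation_onset_uM"] else None)
        spectra, s_truth = simulate_spectra(
            "fret", [0.0, phi, phi], times=[0.0, 10.0, 30.0],
            noise_sd=0.002, seed=child["fret"] + i, attenuation=att,
            meta=meta_for(conc))
        fret[conc] = spectra
        truth.setdefault("fret", {})[conc] = s_truth
    data["fret"] = fret

    # --- itc
    itc_cfg = cfg["itc"]
    series, itc_truth = simulate_itc(
        n=itc_cfg["n"], k=itc_cfg["K"], dh=itc_cfg["dH"],
        cell_mm=itc_cfg["cell_mM"], syringe_mm=itc_cfg["syringe_mM"],
        noise_sd=0.5, seed=child["itc"],
        meta=SampleMeta(sample_id=f"{pid}_itc"))
    data["itc"] = series
    truth["itc"] = itc_truth

    # --- monolayer series over pi0
    mono_cfg = cfg["monolayer"]
    slope = mono_cfg["slope"]
    intercept = mono_cfg["delta_pi_at_35"] - slope * 35.0
    mono = {}
    for i, pi0 in enumerate(mono_cfg["pi0_grid"]):
        dp = intercept + slope * pi0
        trace, m_truth = simulate_monolayer(
            pi0, dp, seed=child["monolayer"] + i,
            meta=SampleMeta(sample_id=f"{pid}_pi0_{pi0:g}"))
        mono[pi0] = trace
        truth.setdefault("monolayer", {})[pi0] = m_truth
    data["monolayer"] = mono
    truth["monolayer_regression"] = {"slope": slope, "intercept": intercept}

    # --- dls table
    agg = cfg["aggregation_onset_uM"]
    dls = pd.DataFrame({
        "sample_id": [f"{pid}_c{c:g}" for c in concs],
        "peptide_conc_uM": concs,
        "z_average_nm": [110.0 if c < agg else 1500.0 + 20.0 * c
                         for c in concs],
        "pdi": [0.05 if c < agg else 0.35 for c in concs],
    })
    data["dls"] = dls
    truth["aggregation_onset_uM"] = agg

    if out_dir is not None:
        _write_study(Path(out_dir), data, truth, concs)
    return data, truth


def _write_study(out: Path, data: dict, truth: dict, concs: list[float]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for conc, decay in data["decays"].items():
        aio.write_decay(decay, out / f"decay_c{conc:g}.csv")
    aio.write_decay(data["decay_release"], out / "decay_release.csv")
    laurdan_all = [sp for c in concs for sp in data["laurdan"][c]]
    aio.write_spectra(laurdan_all, out / "laurdan.csv")
    fret_all = [sp for c in concs for sp in data["fret"][c]]
    aio.write_spectra(fret_all, out / "fret.csv")
    aio.write_injections(data["itc"], out / "itc.csv")
    for pi0, trace in data["monolayer"].items():
        aio.write_monolayer(trace, out / f"monolayer_pi0_{pi0:g}.csv")
    aio.write_dls(data["dls"], out / "dls.csv")

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, SampleMeta):
            return obj.__dict__
        return str(obj)

    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=default, sort_keys=True)
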