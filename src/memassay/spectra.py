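"""Laurdan generalized polarization and FRET lipid-mixing efficiency.

Laurdan's emission maximum shifts from 440 nm (ordered, dehydrated
headgroups) toward 490 nm (hydrated, fluid) so the generalized polarization

    GP = (I440 - I490) / (I440 + I490)

reports lipid headgroup packing; ``delta_GP = GP - GP0`` quantifies the
change induced by peptide relative to the membrane before addition.

Lipid mixing is followed by FRET between NBD (donor, 520 nm) and rhodamine
(acceptor, 580 nm) labelled lipids in double-labelled vesicles mixed with
unlabelled ones.  Fusion dilutes the probes, relieving FRET, so the
donor/acceptor ratio ``R = I520/I580`` increases; the lipid mixing
efficiency normalizes against the pre-addition ratio ``R0`` and the
detergent (Triton) ratio ``R_inf``:

    LME = (R - R0) / (R_inf - R0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EmissionSpectrum
from .meta import ValidationError

LAURDAN_BLUE_NM = 440.0
LAURDAN_RED_NM = 490.0
NBD_NM = 520.0
RHO_NM = 580.0
#: Half-width of the band window used for peak/interp intensity, nm.
BAND_HALFWIDTH_NM = 5.0
#: NBD intensity below this fraction of the pre-addition maximum flags the
#: spectrum as unreliable (aggregation/light-scattering artifacts).
NBD_LOSS_FRACTION = 0.5


@dataclass
class GPResult:
    GP: float
    I440: float
    I490: float
    time_min: float = 0.0
    GP0: float | None = None
    delta_GP: float | None = None


@dataclass
class FretResult:
    R: float
    I_nbd_520: float
    I_rho_580: float
    time_min: float = 0.0
    R0: float | None = None
    R_inf: float | None = None
    LME: float | None = None
    qc_flags: frozenset[str] = frozenset()


def background_subtract(spectrum: EmissionSpectrum,
                        buffer_spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Subtract a buffer spectrum pointwise (interpolated if grids differ).

    Small negative residuals are preserved, not clipped.
    """
    if (buffer_spectrum.wavelengths[0] > spectrum.wavelengths[0] + 1e-9 or
            buffer_spectrum.wavelengths[-1] < spectrum.wavelengths[-1] - 1e-9):
        raise ValidationError(
            "buffer spectrum does not cover the sample wavelength range")
    bg = np.interp(spectrum.wavelengths, buffer_spectrum.wavelengths,
                   buffer_spectrum.intensities)
    return EmissionSpectrum(
        wavelengths=spectrum.wavelengths.copy(),
        intensities=spectrum.intensities - bg,
        excitation_nm=spectrum.excitation_nm,
        time_min=spectrum.time_min,
        meta=spectrum.meta)


def band_intensity(spectrum: EmissionSpectrum, center_nm: float,
                   mode: str = "interp") -> float:
    """Band intensity at ``center_nm``.

    ``mode="peak"`` returns the maximum within +/- 5 nm (used for the
    NBD/rhodamine maxima); ``mode="interp"`` linearly interpolates at the
    center (used for laurdan 440/490).
    """
    lo, hi = center_nm - BAND_HALFWIDTH_NM, center_nm + BAND_HALFWIDTH_NM
    if lo < spectrum.wavelengths[0] or hi > spectrum.wavelengths[-1]:
        raise ValidationError(
            f"band window [{lo}, {hi}] nm outside the "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm grid")
    if mode == "interp":
        return float(np.interp(center_nm, spectrum.wavelengths,
                               spectrum.intensities))
    if mode == "peak":
        mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        return float(np.max(spectrum.intensities[mask]))
    raise ValidationError(f"unknown mode {mode!r}")


def gp(spectrum: EmissionSpectrum) -> GPResult:
    """Generalized polarization of a background-subtracted laurdan spectrum."""
    i440 = band_intensity(spectrum, LAURDAN_BLUE_NM, "interp")
    i490 = band_intensity(spectrum, LAURDAN_RED_NM, "interp")
    if i440 + i490 <= 0:
        raise ValidationError(
            f"GP undefined: I440 + I490 = {i440 + i490!r} <= 0")
    return GPResult(GP=(i440 - i490) / (i440 + i490), I440=i440, I490=i490,
                    time_min=spectrum.time_min)


def delta_gp(results: list[GPResult],
             reference: str | int = "pre") -> list[GPResult]:
    """Attach ``GP0`` and ``delta_GP`` to a GP time series.

    ``reference="pre"`` uses the time point at ``time_min <= 0`` (the
    membrane before peptide addition); an integer selects by index.  A
    positive ``delta_GP`` means decreased headgroup hydration/polarity.
    """
    if not results:
        raise ValidationError("empty GP series")
    if reference == "pre":
        pre = [r for r in results if r.time_min <= 0]
        if not pre:
            raise ValidationError(
                "no pre-addition (time_min <= 0) reference in the GP series")
        gp0 = pre[np.argmax([r.time_min for r in pre])].GP
    else:
        gp0 = results[int(reference)].GP
    return [GPResult(GP=r.GP, I440=r.I440, I490=r.I490, time_min=r.time_min,
                     GP0=gp0, delta_GP=r.GP - gp0) for r in results]


def fret_ratio(spectrum: EmissionSpectrum) -> FretResult:
    """Donor/acceptor intensity ratio R = I_NBD(520)/I_Rho(580) (peak mode)."""
    i_nbd = band_intensity(spectrum, NBD_NM, "peak")
    i_rho = band_intensity(spectrum, RHO_NM, "peak")
    if i_rho <= 0:
        raise ValidationError("acceptor (rhodamine, 580 nm) intensity is zero")
    return FretResult(R=i_nbd / i_rho, I_nbd_520=i_nbd, I_rho_580=i_rho,
                      time_min=spectrum.time_min)


def lme(r: float, r0: float, r_inf: float) -> tuple[float, frozenset[str]]:
    """Lipid mixing efficiency ``(R - R0)/(R_inf - R0)``.

    Not clamped; values above the single-round theoretical maximum are
    flagged ``above_theoretical_max``.
    """
    if r_inf == r0:
        raise ValidationError("R_inf equals R0: degenerate normalization")
    value = (r - r0) / (r_inf - r0)
    flags: set[str] = set()
    if value > theoretical_lme_max(0.2):
        flags.add("above_theoretical_max")
    return value, frozenset(flags)


def theoretical_lme_max(labeled_fraction: float, rounds: int = 1) -> float:
    """Theoretical maximum LME for random pairwise vesicle fusion.

    A labelled vesicle meets an unlabelled partner with probability
    ``1 - labeled_fraction``; each fusion halves the probe density, and the
    normalized signal is linear in acceptor dilution, giving
    ``(1 - f) * (1 - 2**-rounds)`` -- 0.4 for the 1:4 labelled/unlabelled
    mixture (f = 0.2) after one round.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValidationError("labeled_fraction must be in (0, 1]")
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    return (1.0 - labeled_fraction) * (1.0 - 2.0 ** -rounds)


def flag_intensity_loss(spectra: list[EmissionSpectrum]) -> list[frozenset[str]]:
    """Flag spectra whose NBD intensity fell below 50% of the pre-addition max.

    The pre-addition reference is every spectrum with ``time_min <= 0``.
    """
    pre = [sp for sp in spectra if sp.time_min <= 0]
    if not pre:
        raise ValidationError("no pre-addition spectrum (time_min <= 0)")
    ref = max(band_intensity(sp, NBD_NM, "peak") for sp in pre)
    flags = []
    for sp in spectra:
        i_nbd = band_intensity(sp, NBD_NM, "peak")
        if i_nbd < NBD_LOSS_FRACTION * ref:
            flags.append(frozenset({"nbd_loss_gt_50pct"}))
        else:
            flags.append(frozenset())
    return flags


def lme_series(spectra: list[EmissionSpectrum],
               triton: EmissionSpectrum) -> list[FretResult]:
    """Full LME trajectory from a FRET spectra series plus Triton reference.

    ``R0`` is taken from the pre-addition (``time_min <= 0``) spectra,
    ``R_inf`` from the Triton spectrum; intensity-loss QC flags are attached.
    """
    pre = [sp for sp in spectra if sp.time_min <= 0]
    if not pre:
        raise ValidationError("no pre-addition spectrum (time_min <= 0)")
    r0 = float(np.mean([fret_ratio(sp).R for sp in pre]))
    r_inf = fret_ratio(triton).R
    loss_flags = flag_intensity_loss(spectra)
    out = []
    for sp, lf in zip(spectra, loss_flags):
        frag = fret_ratio(sp)
        value, flags = lme(frag.R, r0, r_inf)
        out.append(FretResult(R=frag.R, I_nbd_520=frag.I_nbd_520,
                              I_rho_580=frag.I_rho_580, time_min=sp.time_min,
                              R0=r0, R_inf=r_inf, LME=value,
                              qc_flags=flags | lf))
    return out
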