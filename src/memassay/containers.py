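"""Raw-measurement containers for the four instrument data types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meta import SampleMeta, ValidationError


@dataclass
class EmissionSpectrum:
    """A fluorescence emission spectrum at one (sample, time) point."""

    wavelengths: np.ndarray  # nm, strictly ascending
    intensities: np.ndarray  # arbitrary units
    excitation_nm: float | None = None
    time_min: float = 0.0
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValidationError("wavelengths and intensities differ in length")
        if self.wavelengths.size < 2:
            raise ValidationError("spectrum needs at least 2 points")
        dw = np.diff(self.wavelengths)
        if np.any(dw <= 0):
            i = int(np.argmax(dw <= 0))
            raise ValidationError(
                f"wavelengths not strictly increasing at row {i + 1} "
                f"({self.wavelengths[i + 1]} nm after {self.wavelengths[i]} nm)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id if self.meta is not None else ""


@dataclass
class DecayHistogram:
    """A TCSPC fluorescence decay histogram.

    File readers enforce integer counts (photon counting); the in-memory
    container also accepts expectation-valued (float) counts so that
    noiseless synthetic decays can be fitted through the same path.
    """

    time: np.ndarray  # ns per channel, uniform spacing
    counts: np.ndarray  # photons per channel, >= 0
    acquisition_s: float = 1.0
    excitation_nm: float = 467.0
    emission_nm: float = 515.0
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time.shape != self.counts.shape:
            raise ValidationError("time and counts differ in length")
        if self.time.size < 4:
            raise ValidationError("decay needs at least 4 channels")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("channel times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-30):
            raise ValidationError("channel spacing is not uniform within 1e-9 relative")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.acquisition_s <= 0:
            raise ValidationError("acquisition_s must be positive")

    @property
    def channel_width(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class InjectionSeries:
    """An ITC injection-heat series (lipid titrated into peptide)."""

    cell_volume: float  # mL
    cell_peptide_conc: float  # mM, initial concentration in the cell
    syringe_lipid_conc: float  # mM
    injection_volumes: np.ndarray  # uL per injection
    heats: np.ndarray  # uJ per injection (exothermic negative)
    temperature: float = 25.0
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_volume <= 0:
            raise ValidationError("cell_volume must be positive")
        if self.cell_peptide_conc <= 0 or self.syringe_lipid_conc <= 0:
            raise ValidationError("concentrations must be positive")
        if self.injection_volumes.size != self.heats.size:
            raise ValidationError("volumes and heats differ in length")
        if self.injection_volumes.size < 2:
            raise ValidationError("need at least 2 injections")
        if np.any(self.injection_volumes <= 0):
            raise ValidationError("injection volumes must be positive")
        if not np.all(np.isfinite(self.heats)):
            raise ValidationError("heats must be finite")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)


@dataclass
class MonolayerTrace:
    """A Langmuir-monolayer surface-pressure time trace."""

    time: np.ndarray  # s
    pressure: np.ndarray  # mN/m
    injection_time: float  # s, peptide added to the subphase
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape:
            raise ValidationError("time and pressure differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not (self.time[0] <= self.injection_time <= self.time[-1]):
            raise ValidationError("injection_time outside trace span")
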