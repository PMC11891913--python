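"""Shared domain types for the assay pipeline.

Every assay in the package is keyed by a :class:`SampleMeta` describing the
vesicle/monolayer preparation and the peptide challenge, and produces tidy
:class:`ResultRecord` rows that downstream cross-assay analysis joins on
``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class SchemaError(ValueError):
    """A delimited-text file does not match the declared assay schema."""


class ValidationError(ValueError):
    """Input values violate a documented precondition."""


class FitError(RuntimeError):
    """A model fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


#: Anionic lipid species carrying one negative elementary charge at pH 7.4.
ANIONIC_LIPIDS = frozenset({"POPG", "DMPG", "DPPG", "PG", "POPS", "PS", "CL"})

#: Registry of metric names a ResultRecord may carry.
METRIC_REGISTRY = frozenset({
    "delta_pi", "pi0", "pi_end", "baseline_sd",
    "slope", "intercept", "x_intercept",
    "GP", "GP0", "delta_GP",
    "R", "R0", "R_inf", "LME",
    "L_total", "L_total_raw", "sum_of_B", "sum_of_B_ref", "Q_stat",
    "B_E", "tau_E", "B_F", "tau_F", "free_fraction",
    "n", "K", "dH", "c_value",
    "R_c", "R_c_outer", "neutralization_conc", "neutralization_ratio",
    "z_average", "pdi",
    "onset_conc", "onset_R_c",
})


@dataclass
class SampleMeta:
    """Sample description shared by all assays.

    Parameters
    ----------
    sample_id : str
        Join key across assays.
    lipid_fractions : dict
        Mole fraction per lipid species; must sum to 1.
    lipid_conc : float
        Total lipid concentration, uM.
    peptide_id : str
        Peptide identifier (e.g. ``"cR3W3"``).
    peptide_conc : float
        Added peptide concentration, uM.
    peptide_charge : int
        Net positive charge in elementary charges; +3 for the cyclic
        R3W3-family hexapeptides (three arginines).
    incubation_time : float
        Minutes since peptide addition.
    temperature : float
        deg C.
    buffer_label : str
        Free-text buffer description.
    """

    sample_id: str
    lipid_fractions: dict[str, float] = field(default_factory=dict)
    lipid_conc: float = 0.0
    peptide_id: str = ""
    peptide_conc: float = 0.0
    peptide_charge: int = 3
    incubation_time: float = 0.0
    temperature: float = 25.0
    buffer_label: str = "10 mM TRIS, 110 mM NaCl, 0.5 mM EDTA, pH 7.4"

    def __post_init__(self) -> None:
        if self.lipid_fractions:
            for name, x in self.lipid_fractions.items():
                if not 0.0 <= x <= 1.0:
                    raise ValidationError(
                        f"lipid fraction for {name!r} is {x}, outside [0, 1]")
            total = sum(self.lipid_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"lipid fractions sum to {total!r}, not 1 within 1e-9")
        if self.lipid_conc < 0:
            raise ValidationError("lipid_conc must be >= 0")
        if self.peptide_conc < 0:
            raise ValidationError("peptide_conc must be >= 0")
        if self.incubation_time < 0:
            raise ValidationError("incubation_time must be >= 0")

    @property
    def anionic_fraction(self) -> float:
        """Mole fraction of lipids carrying one negative charge."""
        return sum(x for name, x in self.lipid_fractions.items()
                   if name.upper() in ANIONIC_LIPIDS)


@dataclass
class ResultRecord:
    """One tidy output row: a named metric for one sample and assay."""

    sample_id: str
    assay: str
    metric_name: str
    metric_value: float
    incubation_time: float = 0.0
    qc_flags: frozenset[str] = frozenset()
    truth_value: float | None = None

    _ASSAYS = frozenset({"monolayer", "itc", "laurdan", "lipid_mixing",
                         "leakage", "dls", "crossassay"})

    def __post_init__(self) -> None:
        if self.assay not in self._ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.metric_name not in METRIC_REGISTRY:
            raise ValidationError(f"unknown metric_name {self.metric_name!r}")
        self.qc_flags = frozenset(self.qc_flags)
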