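"""One-set-of-sites analysis of lipid-into-peptide ITC titrations.

The titration injects a lipid (vesicle) suspension into a peptide solution.
With the peptide as the "macromolecule" carrying ``n`` equivalent lipid sites
of site binding constant ``K`` and molar enthalpy ``dH``, the cumulative heat
after reaching total concentrations ``X_t`` (lipid) and ``M_t`` (peptide) in
the cell of volume ``V0`` is

    Q = (n*M_t*dH*V0/2) * [b - sqrt(b^2 - 4*X_t/(n*M_t))],
    b = 1 + X_t/(n*M_t) + 1/(n*K*M_t)

and the heat of injection ``i`` is the difference of consecutive ``Q`` with a
displaced-volume correction.  The perfusion-cell bookkeeping uses the
standard instrument convention for concentrations after a cumulative
injected volume ``dV``:

    M_t = M0*(1 - dV/(2*V0))/(1 + dV/(2*V0)),
    X_t = X_syr*(dV/V0)/(1 + dV/(2*V0)).

Exothermic heats are negative.  Heat of dilution is not modelled.

The fit is exposed statsmodels-style: build a :class:`OneSiteBindingModel`
from an :class:`~memassay.containers.InjectionSeries`, call :meth:`fit`, and
inspect the returned :class:`OneSiteBindingResults` (parameters, standard
errors, ``c_value`` diagnostic, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import InjectionSeries
from .meta import FitError, ValidationError

#: Restart grid for the binding constant (1/M) used when a start fails.
K_RESTART_GRID = (1e2, 1e3, 1e4, 1e5, 1e6, 1e7)


def running_concentrations(series: InjectionSeries
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Total lipid and peptide concentrations in the cell after each injection.

    Returns ``(X_t, M_t)`` in mol/L, each of length ``n_injections``.
    """
    v0 = series.cell_volume * 1e-3  # L
    dv = np.cumsum(series.injection_volumes) * 1e-6  # L
    if np.any(dv >= 2.0 * v0):
        raise ValidationError(
            "cumulative injected volume reaches twice the cell volume; "
            "the displacement model is invalid there")
    m0 = series.cell_peptide_conc * 1e-3  # mol/L
    xs = series.syringe_lipid_conc * 1e-3
    ratio = dv / (2.0 * v0)
    m_t = m0 * (1.0 - ratio) / (1.0 + ratio)
    x_t = xs * (dv / v0) / (1.0 + ratio)
    return x_t, m_t


def one_site_cumulative_heat(x_t, m_t, n: float, k: float, dh: float,
                             v0: float):
    """Cumulative heat Q (J) of the one-set-of-sites isotherm.

    Parameters are in SI solution units: ``x_t``/``m_t`` mol/L, ``k`` 1/M,
    ``dh`` J/mol, ``v0`` L.  The radicand is clamped to zero when within
    -1e-12 (floating-point guard); a more negative radicand raises.
    """
    if n <= 0 or k <= 0:
        raise ValidationError("n and K must be positive")
    x_t = np.asarray(x_t, dtype=float)
    m_t = np.asarray(m_t, dtype=float)
    ratio = x_t / (n * m_t)
    b = 1.0 + ratio + 1.0 / (n * k * m_t)
    radicand = b * b - 4.0 * ratio
    if np.any(radicand < -1e-12):
        bad = float(np.min(radicand))
        raise FitError(
            f"negative radicand {bad:.3e} in one-site heat for n={n}, K={k}, "
            f"dH={dh}")
    radicand = np.maximum(radicand, 0.0)
    return (n * m_t * dh * v0 / 2.0) * (b - np.sqrt(radicand))


def predicted_injection_heats(series: InjectionSeries, n: float, k: float,
                              dh: float) -> np.ndarray:
    """Per-injection heats dQ (uJ) for parameters ``n``, ``K`` (1/M), ``dH`` (kJ/mol).

    ``dQ(i) = Q(i) - Q(i-1) + (dV_i/V0) * (Q(i) + Q(i-1)) / 2`` accounts for
    the heat carried out by the displaced volume.
    """
    v0 = series.cell_volume * 1e-3
    x_t, m_t = running_concentrations(series)
    q = one_site_cumulative_heat(x_t, m_t, n, k, dh * 1e3, v0)  # J
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = series.injection_volumes * 1e-6
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    return dq * 1e6  # uJ


@dataclass
class OneSiteBindingResults:
    """Fitted one-set-of-sites parameters with uncertainties.

    Attributes
    ----------
    n, K, dH : float
        Stoichiometry (lipid/peptide), binding constant (1/M), molar binding
        enthalpy (kJ/mol).
    n_se, K_se, dH_se : float
        Asymptotic standard errors from the Jacobian at the optimum.
    c_value : float
        Wiseman diagnostic ``n*K*M0``; below ~1 the isotherm has no
        sigmoidal inflection and n/K are weakly identified (``low_c`` flag).
    residual_rms : float
        RMS of the heat residuals, uJ.
    """

    model: "OneSiteBindingModel"
    n: float
    K: float
    dH: float
    n_se: float
    K_se: float
    dH_se: float
    c_value: float
    residual_rms: float
    fitted_heats: np.ndarray
    residuals: np.ndarray
    outlier_mask: np.ndarray | None = None
    qc_flags: frozenset[str] = frozenset()
    nfev: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {"n": self.n, "K": self.K, "dH": self.dH}

    @property
    def bse(self) -> dict[str, float]:
        return {"n": self.n_se, "K": self.K_se, "dH": self.dH_se}

    def summary(self) -> str:
        lines = [
            "One-set-of-sites binding fit",
            "============================",
            f"injections used : {self.residuals.size}",
            f"n  (lipid/pept) : {self.n:12.4g} +/- {self.n_se:.2g}",
            f"K  (1/M)        : {self.K:12.4g} +/- {self.K_se:.2g}",
            f"dH (kJ/mol)     : {self.dH:12.4g} +/- {self.dH_se:.2g}",
            f"c value (nKM0)  : {self.c_value:12.4g}",
            f"residual RMS    : {self.residual_rms:12.4g} uJ",
        ]
        if self.qc_flags:
            lines.append("flags           : " + ", ".join(sorted(self.qc_flags)))
        return "\n".join(lines)


@dataclass
class OneSiteBindingModel:
    """One-set-of-sites model bound to an injection series.

    Parameters
    ----------
    series : InjectionSeries
    discard_first : bool
        Drop the first injection before fitting (instrument practice for a
        leaky syringe tip); off by default.
    robust : bool
        Use a soft-L1 loss so heats deviating near the inflection do not
        dominate; an outlier mask (>3 RMS) is then reported.
    weights : array, optional
        Per-injection weights (1/sigma) for weighted least squares.
    """

    series: InjectionSeries
    discard_first: bool = False
    robust: bool = False
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n_used = self.series.n_injections - int(self.discard_first)
        if n_used < 6:
            raise ValidationError(
                f"need >= 6 informative injections, have {n_used}")

    def _observed(self) -> np.ndarray:
        heats = self.series.heats
        return heats[1:] if self.discard_first else heats

    def _predict(self, n: float, k: float, dh: float) -> np.ndarray:
        dq = predicted_injection_heats(self.series, n, k, dh)
        return dq[1:] if self.discard_first else dq

    def _auto_init(self) -> tuple[float, float]:
        """Heuristic (n, dH) start from the raw heats."""
        x_t, m_t = running_concentrations(self.series)
        heats = self.series.heats
        steps = np.abs(np.diff(heats))
        i = int(np.argmax(steps)) + 1 if steps.size else 0
        n_init = max(float(x_t[i] / m_t[i]), 0.1)
        # early injections: nearly all injected lipid binds
        v0 = self.series.cell_volume * 1e-3
        mol_per_inj = (self.series.syringe_lipid_conc * 1e-3
                       * self.series.injection_volumes[:2] * 1e-6)
        dh_init = float(np.mean(heats[:2]) * 1e-6 / np.mean(mol_per_inj)) / 1e3
        if dh_init == 0.0:
            dh_init = -1.0
        del v0
        return n_init, dh_init

    def fit(self, init: tuple[float, float, float] | None = None,
            k_grid: tuple[float, ...] = K_RESTART_GRID) -> OneSiteBindingResults:
        """Least-squares fit of predicted versus observed injection heats.

        ``init`` is an optional ``(n, K, dH)`` start; by default a heuristic
        start is tried with every K in ``k_grid`` and the best optimum kept.
        """
        observed = self._observed()
        weights = None
        if self.weights is not None:
            weights = np.asarray(self.weights, dtype=float)
            if self.discard_first:
                weights = weights[1:]

        def residual(theta: np.ndarray) -> np.ndarray:
            n, logk, dh = theta
            try:
                res = self._predict(n, 10.0 ** logk, dh) - observed
            except (FitError, ValidationError):
                return np.full_like(observed, 1e12)
            return res * weights if weights is not None else res

        starts: list[tuple[float, float, float]] = []
        if init is not None:
            starts.append((init[0], np.log10(init[1]), init[2]))
        n0, dh0 = self._auto_init()
        starts.append((n0, 4.0, dh0))  # default K = 1e4 1/M
        starts.extend((n0, np.log10(k), dh0) for k in k_grid)

        scale_dq = float(np.max(np.abs(observed))) or 1.0
        loss = "soft_l1" if self.robust else "linear"
        best = None
        for n_s, lk_s, dh_s in starts:
            try:
                sol = least_squares(
                    residual, x0=[n_s, lk_s, dh_s],
                    bounds=([1e-6, 0.0, -np.inf], [np.inf, 12.0, np.inf]),
                    x_scale=[max(n_s, 0.1), 1.0, max(abs(dh_s), 0.1)],
                    loss=loss, f_scale=0.05 * scale_dq if self.robust else 1.0,
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError("one-site fit failed to converge over the restart "
                           "grid", best_residual=None)
        return self._package(best, observed, weights)

    def _package(self, sol, observed, weights) -> OneSiteBindingResults:
        n, logk, dh = sol.x
        k = 10.0 ** logk
        fitted = self._predict(n, k, dh)
        resid = fitted - observed
        dof = max(observed.size - 3, 1)
        s2 = float(np.sum((resid * weights) ** 2 if weights is not None
                          else resid ** 2)) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * s2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        k_se = k * np.log(10.0) * se[1]
        m0 = self.series.cell_peptide_conc * 1e-3
        c_value = n * k * m0
        flags: set[str] = set()
        if c_value < 1.0:
            flags.add("low_c")
        rms = float(np.sqrt(np.mean(resid ** 2)))
        mask = None
        if self.robust:
            mask = np.abs(resid) > 3.0 * rms
        return OneSiteBindingResults(
            model=self, n=float(n), K=float(k), dH=float(dh),
            n_se=float(se[0]), K_se=float(k_se), dH_se=float(se[2]),
            c_value=float(c_value), residual_rms=rms,
            fitted_heats=fitted, residuals=resid, outlier_mask=mask,
            qc_flags=frozenset(flags), nfev=int(sol.nfev))


def fit_one_site(series: InjectionSeries, init=None, *, discard_first=False,
                 robust=False, weights=None) -> OneSiteBindingResults:
    """Convenience wrapper: build the model and fit it."""
    model = OneSiteBindingModel(series, discard_first=discard_first,
                                robust=robust, weights=weights)
    return model.fit(init=init)
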