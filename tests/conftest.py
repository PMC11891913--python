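import numpy as np
import pytest

from memassay import SampleMeta, simulate_decay, simulate_itc


@pytest.fixture
def pg_pe_meta():
    """30 uM PG/PE (1:1) vesicles with 5 uM of a +3 peptide."""
    return SampleMeta(
        sample_id="s1", lipid_fractions={"POPG": 0.5, "POPE": 0.5},
        lipid_conc=30.0, peptide_id="cR3W3", peptide_conc=5.0,
        peptide_charge=3, incubation_time=10.0)


@pytest.fixture
def row_d_series():
    """Noiseless injection series from the strong-binding PG/PE regime."""
    series, truth = simulate_itc(4.7, 84e3, -4.7, cell_mm=0.1, syringe_mm=5.0,
                                 noise_sd=0.0)
    return series, truth


@pytest.fixture
def row_a_series():
    """Noiseless series from the weak-binding (low-c) PC regime."""
    series, truth = simulate_itc(47.0, 0.79e3, -0.9, cell_mm=0.02,
                                 syringe_mm=20.0, noise_sd=0.0)
    return series, truth


@pytest.fixture
def noiseless_decay():
    decay, truth = simulate_decay(0.3, 0.5, poisson=False)
    return decay, truth


def biexp_grid_oracle(decay, tau_e_range=(0.05, 2.0), tau_f_range=(2.0, 10.0),
                      n_grid=40, zooms=7):
    """Independent lifetime grid search with linear amplitude solves.

    Zooming grid over (tau_E, tau_F); at each node the amplitudes and
    background solve an ordinary least-squares system.  Returns the
    best-fit (B_E, tau_E, B_F, tau_F).
    """
    start = int(np.argmax(decay.counts))
    t = decay.time[start:] - decay.time[start]
    y = decay.counts[start:]
    lo_e, hi_e = tau_e_range
    lo_f, hi_f = tau_f_range
    best = None
    for _ in range(zooms):
        te_grid = np.linspace(lo_e, hi_e, n_grid)
        tf_grid = np.linspace(lo_f, hi_f, n_grid)
        for te in te_grid:
            for tf in tf_grid:
                design = np.column_stack([
                    np.exp(-t / te), np.exp(-t / tf), np.ones_like(t)])
                coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
                rss = float(np.sum((design @ coef - y) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, float(te), float(tf), coef)
        _, te_b, tf_b, _ = best
        span_e = (hi_e - lo_e) / n_grid * 4
        span_f = (hi_f - lo_f) / n_grid * 4
        lo_e, hi_e = max(te_b - span_e, 1e-3), te_b + span_e
        lo_f, hi_f = max(tf_b - span_f, 1e-3), tf_b + span_f
    _, te_b, tf_b, coef = best
    return coef[0], te_b, coef[1], tf_b


def one_site_bisection_oracle(x_t, m_t, n, k, dh, v0, tol=1e-16):
    """Brute-force equilibrium solve of the one-set-of-sites isotherm.

    Bisection on the bound-lipid concentration X_b in [0, min(X, nM)] for
    the mass-action condition K = theta / ((1 - theta) * X_free) with
    theta = X_b/(n*M); returns Q = X_b * dH * V0.
    """
    lo, hi = 0.0, min(x_t, n * m_t)

    def g(xb):
        theta = xb / (n * m_t)
        return k * (1.0 - theta) * (x_t - xb) - theta

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-30):
            break
    return 0.5 * (lo + hi) * dh * v0
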