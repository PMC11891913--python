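# Methods

This note documents the models implemented in `memassay`, their
assumptions, the conventions chosen where the field leaves room, and what
the synthetic-data generator does and does not emulate.

## Monolayer insertion (Δπ)

A peptide injected into the subphase beneath a lipid monolayer at initial
pressure π₀ raises the surface pressure as it adsorbs and inserts. We
report Δπ = π_end − π₀ with:

- π₀: mean pressure over a pre-injection baseline window (default 600 s).
  The baseline is considered stable when its standard deviation stays
  below **0.2 mN/m**; above that the record carries `unstable_baseline`.
- π_end: mean pressure over a **120-s window ending exactly 35 min** after
  injection. The evaluation time follows standard practice for these slow
  adsorption kinetics; the window mean is our convention to suppress
  tensiometer noise (a single-sample read-out would inherit its full sd).
- Δπ may be negative (film destabilization) and is invariant under adding
  a constant to the whole trace.

Across a series of monolayers the Δπ(π₀) trend is summarized by ordinary
least squares (statsmodels); for a negative slope the x-intercept
−intercept/slope is the maximal insertion pressure, the π₀ beyond which
the peptide can no longer insert. No peptide-only surface-activity
correction is applied: the working subphase concentration is chosen below
the peptide's own surface activity.

## ITC one-set-of-sites isotherm

Titrating lipid vesicles into a peptide solution and treating the peptide
as a macromolecule carrying *n* equivalent, independent lipid sites with
site constant *K* and molar enthalpy ΔH gives the cumulative heat

Q = (n·M_t·ΔH·V₀/2)·[b − √(b² − 4X_t/(n·M_t))],
b = 1 + X_t/(n·M_t) + 1/(n·K·M_t),

with X_t, M_t the total lipid and peptide concentrations in the cell. A
perfusion cell displaces liquid on each injection; concentrations follow
the standard instrument bookkeeping
M_t = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀), X_t = X_syr(ΔV/V₀)/(1 + ΔV/2V₀),
and the per-injection heat is dQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2.

Conventions and numerical choices:

- **Sign**: exothermic heats are negative throughout.
- **Units**: concentrations enter in mM, volumes in mL/µL, heats in µJ
  (µcal accepted on input, 1 cal = 4.184 J); K is reported in M⁻¹ and ΔH
  in kJ/mol.
- **Dilution heat** is fixed at zero — no per-injection offset parameter.
- The radicand is clamped at 0 when within −1e-12 (floating-point guard);
  anything more negative is reported as an error with its inputs.
- The fit is absolute-heat least squares over (n, log₁₀K, ΔH) with
  multi-start over K ∈ {10²…10⁷} M⁻¹; the heuristic start takes n from
  the lipid/peptide ratio at the steepest heat change and ΔH from the
  first two injections (where essentially all injected lipid binds).
  Fitting log₁₀K keeps the problem well-scaled across six decades.
  Standard errors come from the Jacobian at the optimum.
- The Wiseman diagnostic c = n·K·M₀ is always reported; **c < 1** flags
  `low_c`: the isotherm has no inflection and n, K are only weakly
  identified (they remain exactly recoverable on noiseless data, which is
  what the recovery tests check — real low-c titrations will carry large
  standard errors).
- `robust=True` switches to a soft-L1 loss and reports an outlier mask
  (>3 RMS), for titrations where heats near the inflection deviate from
  the one-site shape (e.g. sudden access to the inner leaflet upon
  permeabilization). The deviation itself is not modelled.
- First-injection discard is available (`discard_first`) but off by
  default.

The forward model is verified in the tests against an independent
bisection solve of the mass-action equilibrium (1e-10) and against the
strong-binding closed form Q = ΔH·V₀·min(X_t, n·M_t) at K = 10¹² M⁻¹.

## Laurdan GP and FRET lipid mixing

GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) on background-subtracted spectra,
with intensities interpolated at exactly 440/490 nm; ΔGP is taken against
the pre-addition spectrum (time ≤ 0). Positive ΔGP corresponds to
decreased headgroup hydration/polarity (tighter packing). GP is bounded
in [−1, 1] for non-negative spectra and invariant under detector gain.

For lipid mixing, R = I_NBD(520)/I_Rho(580) using window maxima (±5 nm),
and LME = (R − R₀)/(R∞ − R₀) with R₀ from the pre-addition spectra and
R∞ from the Triton-solubilized reference. Two conventions are fixed here
because the ratio direction is not universal in the literature: R is
donor/acceptor, so probe dilution (fusion) *increases* R and LME lies in
[0, 1]; and LME is **not clamped** — values above the theoretical maximum
are flagged `above_theoretical_max` instead, since they indicate
intensity artifacts rather than extra fusion. Both choices are symmetric
to invert.

The theoretical maximum assumes one round of random pairwise fusion: a
labelled vesicle meets an unlabelled partner with probability 1 − f
(f = labelled fraction), fusion doubles the membrane area and halves the
probe density, and the Triton-normalized signal is linear in acceptor
dilution. This gives max LME = (1 − f)/2 — 0.4 for the common 1:4
labelled/unlabelled mixture — generalized to r rounds as
(1 − f)(1 − 2⁻ʳ). This is a deliberately minimal model: it ignores
multiple fusion partners, labelled–labelled fusion products beyond the
first round, and any nonlinearity of FRET in acceptor density.

QC: spectra whose NBD intensity falls below **50 %** of the pre-addition
maximum are flagged `nbd_loss_gt_50pct` (scattering/sedimentation of
aggregates invalidates intensity-based metrics).

## TCSPC calcein leakage

Entrapped calcein at self-quenching concentration decays fast
(τ_E ≈ 0.4 ns); released, diluted calcein decays slowly (τ_F ≈ 4 ns). The
decay model c(t) = B_E·e^(−t/τ_E) + B_F·e^(−t/τ_F) + bg is fitted by
**Poisson maximum likelihood** (not χ² least squares — the tail channels
hold few photons), from the peak channel onward. No instrument-response
deconvolution is attempted: with a 1 MHz pulse period the excitation is
effectively a delta function on the nanosecond lifetimes of interest.
Numerics: L-BFGS-B on peak-normalized parameters with analytic gradients,
then a projected-Newton polish with the analytic Hessian so that
noiseless data are recovered to optimizer precision (the tests require
1e-6 against an independent lifetime grid search); lifetimes are
constrained to 0.05 ≤ τ_E < τ_F ≤ 10 ns (components reordered after the
fit; a lifetime ending on a bound flags `bound_hit`), a 3×3 lifetime
restart grid guards against non-convergence, amplitudes are reported per
second of acquisition, and decays with fewer than 10⁴ total counts are
flagged `low_counts`. τ_F may be pinned to a free-calcein calibration
value (`fix_tauf`).

Static quenching renders part of the entrapped dye completely dark
without shifting the lifetime of the remainder, so B_E undercounts
entrapped molecules. The correction factor is calibrated per preparation
from an intact reference and a detergent (full-release) sample measured
at equal settings:

Q_stat = (B_F,release − B_F,intact)/B_E,intact,

i.e. the factor that makes the *Sum of B* = B_F + Q_stat·B_E conserved
upon complete release. Q_stat < 1 is physically inconsistent (sample
loss) and flagged. When no calibration pair is available the CLI falls
back to Q_stat = 1 with a loud warning. Total leakage is

f = B_F/(B_F + Q_stat·B_E), L_total = (f − f₀)/(1 − f₀),

with f₀ from the no-peptide reference; this form is fixed by its
constraints — it equals 0 at the reference, 1 at full release, uses B_F₀,
and makes the Sum of B its constant denominator. L_total is clamped to
[0, 1] with the pre-clamp value retained. Records whose Sum of B drops
more than **20 %** below the reference are flagged and excluded from
headline tables.

Leakage **mode** is classified over a concentration series: *all-or-none*
(vesicles empty completely; τ_E stays within 15 % of its median while the
free fraction rises), *graded* (partial release dilutes the entrapped dye;
τ_E trends upward toward τ_F, Spearman trend with a two-sided permutation
test at α = 0.05), else *indeterminate*. The 15 % band and the
permutation test are this package's conventions; with fewer than five
concentrations the permutation test cannot reach significance, so short
series return indeterminate rather than a false classification.

## Charge-ratio cross-assay

R_c = z_P·c_P/(f⁻·c_L·leaflet_fraction) with added (not bound)
concentrations; PG and other singly-anionic species contribute one
negative charge, PC/PE none. The outer-leaflet fraction is fixed at 0.5
(real extruded-vesicle asymmetry is ignored). Neutralization quantities
satisfy R_c = 1 exactly: c_P* = f⁻·c_L·leaflet_fraction/z_P. Effect
onsets are detected as the lowest concentration whose metric exceeds the
zero-peptide reference by 3× its stated uncertainty (or whose QC rule
fired); this is a convention — practitioners usually identify onsets by
inspection — and it is monotone in the noise floor. DLS tables are only
ingested and flagged (Z-average > 1000 nm ⇒ `aggregated`; preparation
outside 110 ± 10 nm or PDI ≥ 0.1 ⇒ `prep_out_of_spec`); cumulant
analysis itself is instrument territory.

## Synthetic data

The generators produce data with exactly the structure the analyzers
assume, plus a truth sidecar:

- **Decays**: biexponential expectation with the entrapped amplitude
  scaled by (1 − dark_fraction) and per-channel Poisson sampling.
  `total_counts` refers to the fully-released equivalent sample so that
  intact/release pairs share a brightness scale (implied
  Q_stat = 1/(1 − dark_fraction)). Defaults: τ_E = 0.4 ns, τ_F = 4.0 ns,
  10⁶ counts, 1024 channels over 25 ns.
- **Spectra**: Gaussian bands (laurdan 440/490 nm, σ = 25 nm; NBD/Rho
  520/580 nm, σ = 12 nm). Laurdan amplitudes solve a 2×2 system including
  band cross-talk so the analyzer recovers the target GP exactly; FRET
  amplitude ratios follow the linear-dilution model with anchors
  R₀ = 0.5 and R∞ = 3.0. Band widths are conventions — all derived
  metrics are ratio-based and gain-invariant (tested). A multiplicative
  attenuation segment emulates aggregation artifacts.
- **ITC**: heats from the forward model plus Gaussian noise.
- **Monolayer**: π₀ baseline, then an exponential rise to the plateau
  (default time constant 5 min) plus Gaussian noise (default 0.05 mN/m).
- **Study presets**: a 30 µM lipid suspension challenged with a
  0–100 µM peptide grid. `cR3W3-like` places leakage/aggregation onsets
  at 3 µM with all-or-none release reaching L_total = 0.5 at 30 µM within
  10 min; `c(RW)3-like` has no leakage at ≤ 10 µM, a graded lifetime
  shift at high concentration, and aggregation from 10 µM. Identical
  (config, seed) yield byte-identical directories.

What the generators do **not** emulate — and hence what passing recovery
tests do not show about real data: instrument response functions,
afterpulsing and dead-time in photon counting, wavelength-dependent
detector sensitivity, real spectral lineshapes and Raman/scatter peaks,
baseline drift in calorimetry, heats of dilution, mechanistic
fusion/leakage kinetics, and vesicle polydispersity. Recovery tests
demonstrate the correctness of the estimators under their stated model,
not robustness to unmodelled instrument physics.

## Problem sizes used in the test suite

Recovery suites run at the study conditions above: 28-injection
titrations, 10⁶-count/1024-channel decays (20 replicate seeds per
condition in the bias tests), 50-seed noise studies for ITC. The full
suite completes in well under a minute of CPU apart from the replicate
loops.
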