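# memassay

Quantification of peptide–membrane interaction assays for membrane
biophysics: given the delimited-text exports of five standard experiments on
lipid model membranes, `memassay` turns them into the comparable, QC-flagged
metrics used to characterize membrane-active peptides (antimicrobials,
cell-penetrating peptides) — and ships a synthetic-data generator with known
ground truth so every analyzer can be validated by recovery tests.

## What it computes

| Assay | Input | Metric |
|---|---|---|
| Langmuir monolayer insertion | surface-pressure trace π(t) | Δπ = π_end − π₀ (π_end: 120-s window mean 35 min after injection), plus the Δπ-vs-π₀ regression and its x-intercept (maximal insertion pressure) |
| Isothermal titration calorimetry | injection-heat series | one-set-of-sites fit: stoichiometry *n* (lipid/peptide), binding constant *K* (M⁻¹), enthalpy ΔH (kJ/mol), with standard errors and the Wiseman *c* = nKM₀ diagnostic |
| Laurdan fluorescence | emission spectra | generalized polarization GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) and ΔGP vs the pre-addition membrane |
| FRET lipid mixing | NBD/rhodamine spectra | ratio R = I₅₂₀/I₅₈₀ and lipid-mixing efficiency LME = (R − R₀)/(R∞ − R₀), with the single-round theoretical maximum (1 − f)/2 |
| TCSPC calcein leakage | decay histograms | Poisson-MLE biexponential fit (B_E, τ_E, B_F, τ_F), static-quenching correction Q_stat, total leakage L_total, Sum-of-B quality metric, all-or-none vs graded classification |
| Cross-assay | all of the above + DLS tables | charge ratio R_c = z_P·c_P/(f⁻·c_L·leaflet), neutralization concentrations/ratios, effect-onset alignment, aggregation flags |

The two genuine model fits follow the statsmodels convention: a model
object built from data whose `fit()` returns a results object with
parameters, standard errors and `summary()`:

```python
from memassay import OneSiteBindingModel, BiexponentialDecayModel
results = OneSiteBindingModel(series).fit()
print(results.summary())
```

## Worked example

Generate a synthetic study of a fast-leaking cationic peptide on charged
PG/PE vesicles and fit its ITC titration:

```python
import memassay as ma

series, truth = ma.simulate_itc(n=4.7, k=84e3, dh=-4.7,
                                cell_mm=0.1, syringe_mm=5.0, noise_sd=0.5,
                                seed=1)
print(ma.fit_one_site(series).summary())
```

```
One-set-of-sites binding fit
============================
injections used : 28
n  (lipid/pept) :        4.703 +/- 0.0031
K  (1/M)        :     8.39e+04 +/- 6.3e+02
dH (kJ/mol)     :       -4.705 +/- 0.0041
c value (nKM0)  :        39.46
residual RMS    :       0.3971 uJ
```

With 0.5 µJ of heat noise the fit recovers the generating parameters
(n = 4.7 lipids per peptide, K = 84·10³ M⁻¹, ΔH = −4.7 kJ/mol) to a few
parts per thousand; c ≈ 39 means the isotherm is well within the sigmoidal,
identifiable regime.

The same works from the shell on a full synthetic study:

```
memassay simulate --preset cR3W3-like --seed 1 --out data/
memassay itc-fit data/itc.csv
memassay leakage data/decay_c*.csv --reference data/decay_c0.csv \
         --triton data/decay_release.csv
memassay crossassay --dls data/dls.csv
```

The leakage command calibrates Q_stat ≈ 2 from the intact/Triton pair
(half of the entrapped calcein is dark in this preset), then reports
L_total per concentration — e.g. `L_total=0.510` at 30 µM against a
generating truth of 0.5 — flagging any record whose Sum of B dropped more
than 20 %. `crossassay` prints the charge-neutralization points for the
30 µM PG/PE suspension: 5 µM peptide for both leaflets (lipid/peptide
6:1) and 2.5 µM for the outer leaflet (12:1).

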