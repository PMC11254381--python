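# alphalat

Analysis pipeline linking **hemispheric volumetric asymmetry of subcortical
structures** to **hemispheric lateralized modulation of posterior alpha
oscillations** during covert spatial attention, together with a synthetic
cohort generator that makes every stage testable without raw MEG/MRI
recordings.

## Who this is for

Researchers combining structural MRI (subcortical segmentations) with MEG/EEG
sensor-level oscillatory measures who want a tested, reproducible
implementation of the laterality-index + model-selection workflow: given a
cohort's subcortical volume table, sensor-level epochs with attention-cue
labels, and trial-level behavior, the pipeline produces per-subject laterality
indices, an exhaustively searched linear model of structure–function coupling,
multivariate condition-wise tests, and behavioral control analyses.

## The indices and models

For each subcortical structure *s* (thalamus Th, caudate nucleus CN, putamen
Put, globus pallidus GP, hippocampus Hipp, amygdala Amyg, nucleus accumbens
Acc), the **lateralization volume** is

    LV_s = (V_s^right − V_s^left) / (V_s^right + V_s^left),

positive for rightward asymmetry.  At each sensor *k*, alpha power (8–13 Hz,
−850–0 ms pre-target, sliding 3-cycle Hanning-taper spectral estimate, planar
gradiometer pairs summed) yields the **modulation index**

    MI(α)_k = (P_k^att-right − P_k^att-left) / (P_k^att-right + P_k^att-left).

The 5 mirror-symmetric sensor pairs with the largest group-level
right-minus-left MI difference form the ROI (10 sensors), and the
**hemispheric lateralized modulation** per subject is

    HLM(α) = mean_k∈ROI-right MI(α)_k + mean_k∈ROI-left MI(α)_k ∈ (−2, 2),

negative when the left hemisphere modulates more strongly.  **Behavioral
asymmetry** applies the same normalized difference to per-side accuracy and
response time.

Structure–function coupling is modelled as

    HLM(α) ~ β0 + Σ_s β_s LV_s + ε,

with the regressor subset chosen by exhaustive search over all 2⁷−1 = 127
subsets ranked by AIC (BIC reported alongside), collinearity checked by VIF,
and normality by Shapiro–Wilk.  Condition-wise effects (four attentional
load/salience conditions) use a multivariate multiple regression of the four
per-condition HLM(α) outcomes on the key LVs, with Hotelling T² per-regressor
tests across outcomes and Wilks' Λ (Rao's F) nested-model comparisons.

The synthetic generator inverts this chain: it draws LVs from configurable
per-structure distributions, sets target HLM(α) through the linear coupling
with configurable coefficients and noise, and emits amplitude-modulated alpha
sinusoids (plus 1/f background noise) on paired planar channels so that the
full spectral pipeline recovers the targets.

## Worked example

```python
import numpy as np
from alphalat import GeneratorConfig, draw_truth, fit_ols, model_search

cfg = GeneratorConfig(seed=42)                      # 33 subjects, default coupling
_, truth = draw_truth(cfg, np.random.default_rng(cfg.seed))

search = model_search(truth.lv, truth.hlm, criterion="aic")
print("winning subset:", "+".join(search.winning))

fit = fit_ols(truth.lv[["Th", "CN", "GP"]], truth.hlm)
for name, b, se, t, p in zip(fit.names, fit.params, fit.bse,
                             fit.tvalues, fit.pvalues):
    print(f"{name:>9}  beta={b: .3f}  se={se:.3f}  t({fit.df_resid})={t: .2f}  p={p:.4f}")
print(f"F({fit.df_model},{fit.df_resid}) = {fit.fvalue:.3f}, "
      f"p = {fit.f_pvalue:.4f}, adj R^2 = {fit.rsquared_adj:.3f}")
```

prints

```
winning subset: Th+CN+GP
intercept  beta=-0.020  se=0.018  t(29)=-1.14  p=0.2632
       Th  beta=-2.466  se=1.016  t(29)=-2.43  p=0.0216
       CN  beta= 1.570  se=0.480  t(29)= 3.27  p=0.0028
       GP  beta= 0.858  se=0.393  t(29)= 2.19  p=0.0371
F(3,29) = 6.084, p = 0.0024, adj R^2 = 0.323
```

This cohort was generated with coupling β = (−2.19, 0.92, 0.51) for
(Th, CN, GP) and noise calibrated so the model explains roughly 40% of the
HLM(α) variance at n = 33: the exhaustive search recovers the true subset,
the estimated coefficients carry the true signs (thalamus opposite to caudate
and pallidus), and the residual degrees of freedom are n − 4 = 29.  Estimates
differ from the generating values by single-cohort sampling error (the
standard errors shown).

The same analysis runs from the shell, through the spectral stage, on a
cohort written to disk:

```sh
alphalat simulate --out cohort --seed 42
alphalat run-all cohort --out cohort/report
```

which writes `laterality.csv` (per-subject HLM(α), condition-wise HLM(α),
LVs, behavioral asymmetries), `model_search.csv` (all 127 subsets with
AIC/BIC/R²) and `report.json` (winning model, VIF, LV one-sample tests,
multivariate tests, behavior regressions, provenance).

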