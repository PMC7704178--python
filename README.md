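# dpdce

Tracer-kinetic analysis of dynamic contrast-enhanced (DCE) MRI with the
**distributed-parameter (DP)** model and the conventional **Tofts** model,
built around the question of whether perfusion/permeability parameters can
separate IDH-mutant from IDH-wildtype gliomas.

The package covers the whole chain:

1. **Signal → concentration.** Variable-flip-angle (DESPOT1) estimation of
   baseline T1 and M0 from multi-flip-angle SPGR data, and point-by-point
   inversion of the dynamic SPGR series to tracer concentration via
   `R1(t) = R1(0) + r1·C(t)`.
2. **Forward models.** Closed-form tissue curves `C_tiss = C_A ⊗ F·R(t)` for
   Tofts (`R ∝ exp(−Kep t)`) and DP, whose residue function is 1 during the
   capillary transit time `tc = Vp/F` and afterwards decays through a
   Bessel-function interstitial washout governed by PS and Ve. A brute-force
   finite-difference solver of the underlying axially distributed transport
   equations validates the closed form.
3. **Voxel-wise fitting.** Deterministic multi-start, bound-constrained
   least squares producing parameter maps: `F`, `PS`, `Ve`, `Vp`, `E` (DP)
   and `Ktrans`, `Ve`, `Kep` (Tofts).
4. **Monte Carlo precision.** Coefficient-of-variation study of the fitted
   parameters versus concentration SNR (peak clean curve / noise sd).
5. **Cohort statistics.** Per-patient median pooling, Shapiro–Wilk,
   Wilcoxon rank-sum, Spearman correlations, and ROC analysis with the
   Youden-index cutoff.
6. **Synthetic cohorts.** Because no patient data is distributable, a
   generator produces two-group glioma cohorts whose voxel-level kinetic
   parameters reproduce published group medians and interquartile ranges,
   end-to-end down to the SPGR signal.

## Worked example

```python
import numpy as np
from dpdce import (AcquisitionProtocol, DpParams, population_aif,
                   dp_concentration, fit_voxel, run_cv_study, add_noise)

protocol = AcquisitionProtocol()          # 180 dynamics at 2 s, TR 5.318 ms
aif = population_aif(protocol.dynamic_grid())

truth = DpParams(f=12.48, ps=3.38, ve=9.30, vp=1.59)   # wildtype-like tumor
curve = dp_concentration(truth, aif)

noisy = add_noise(curve, snr=20.0, seed=0)
fit = fit_voxel(noisy, aif, model="dp")
print(fit.params)
# DpParams(f=11.895..., ps=3.649..., ve=9.170..., vp=1.466...)

report = run_cv_study(truth, aif, snr=20.0, n_reps=500, seed=20)
print(report.table[["cv", "bias"]].round(2))
#          cv  bias
# param
# f      4.57  0.46
# ps     2.86  0.08
# ve     1.66 -0.06
# vp     3.36 -0.09
```

The single noisy fit recovers the generating parameters to a few percent at
SNR 20; the Monte Carlo table shows the estimator's precision — every
fitted DP parameter has a coefficient of variation under 5% at this noise
level, comfortably inside the ≲13% regime in which the parameters are
considered reliable.

A full synthetic cohort study from the shell:

```bash
dpdce simulate --config run.yaml --seed 1   # write cohort NIfTI bundles
dpdce fit      --config run.yaml            # voxel-wise maps, both models
dpdce analyze  --config run.yaml            # median/diagnostic/correlation tables
dpdce mc-cv    --config run.yaml --out cv.tsv
```

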