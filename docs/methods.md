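# Methods

## Tracer-kinetic models

Both models express the tissue concentration as a convolution of the
arterial input function (AIF) with an impulse response,
`C_tiss(t) = C_A(t) ⊗ F·R(t)`, with all times in minutes and volume
parameters converted from their conventional per-100 mL units to unit
fractions before any arithmetic.

**Tofts.** One extravascular compartment: `F·R(t) = Ktrans·exp(−(Ktrans/Ve)·t)`.
The intravascular contribution is not modelled, so `Ktrans` mixes flow and
permeability.

**Distributed parameter (DP).** A plug-flow capillary of fractional volume
`Vp` and transit time `tc = Vp/F` exchanges with a locally well-mixed
interstitium of volume `Ve` at rate `PS`. The residue function is

```
R(τ) = 1                                             0 ≤ τ < tc
R(τ) = 1 − e^{−b}·[1 + ∫₀^{τ−tc} e^{−a s} √(ab/s) · I₁(2√(ab·s)) ds]
```

with `a = PS/Ve`, `b = PS/F` and `I₁` the modified Bessel function of order
one. At `τ = tc` the residue drops from 1 to the first-pass extraction
`E = 1 − e^{−PS/F}`; it is non-increasing, bounded in [0, 1] and integrates
the injected mass exactly (R → 0). The bracketed grouping matters: the
alternative reading `(1 − e^{−b})(1 + ∫…)` diverges to `e^{b} − 1` and
violates mass conservation, so it cannot be the intended form; the
implementation was additionally validated against an independent numerical
solution of the transport equations (below).

### Numerical evaluation of the DP washout

Expanding `I₁` termwise turns the washout integral into an exact series:

```
1 − R(tc + s) = e^{−b} + Σ_{m≥1} Poisson(m; b) · P(m, a·s)
```

where `P` is the regularized lower incomplete gamma function. Every term is
positive, so the sum is numerically stable for any parameter values, and it
evaluates vectorised over a whole time grid. An adaptive Gauss–Kronrod
quadrature of the raw Bessel integrand (whose `1/√s` singularity at `s = 0`
is removable with limit `a·b`) is retained as an independent cross-check;
the two agree to machine precision in the tests.

### Discrete convolution

The AIF is treated as piecewise linear on its uniform sampling grid. The
Tofts curve uses plain trapezoidal discrete convolution (second-order
accurate for its smooth kernel). For DP the vascular plateau is a boxcar of
width `tc`, which for mutant-like parameters (`tc ≈ 1.4 s`) is *narrower
than the 2 s sampling interval*; sampling it at grid points would misweight
it by tens of percent. The implementation therefore integrates the boxcar
exactly through the (piecewise-quadratic) cumulative integral of the AIF
and convolves only the smooth post-extraction tail by the trapezoidal rule.
Against refined references the residual discretization error of the full
curve is ≲0.2% of the peak.

### PDE oracle

`pde_oracle` solves the axially distributed two-region model directly:
first-order upwind advection of the capillary concentration over `n_axial`
segments plus explicit exchange with the interstitium, with substeps
respecting the advection CFL limit (violations raise an error reporting the
required step). The discrete update is written in flux form, so mass is
conserved to round-off (the audit reports the worst relative imbalance).
With `n_axial = 200` and 4× time refinement it agrees with the closed form
to well under 1% of the curve peak for both tumor-like parameter regimes,
and the deviation shrinks monotonically under grid refinement.

## Signal model

SPGR steady state, `S = M0·sinα·(1 − E1)/(1 − E1·cosα)`, `E1 = exp(−TR/T1)`;
TE/T2* decay is constant across the series and absorbed into `M0` (it
cancels in the conversion). Baseline `T1`/`M0` come from the linearised
DESPOT1 regression of `S/sinα` on `S/tanα` over the precontrast flip angles
(4°/8°/15°, the ten precontrast dynamics averaged first); slopes outside
(0, 1) — or signals carrying no flip-angle information — flag the voxel as
unfittable. Dynamic frames are inverted for `E1`, giving
`C(t) = (R1(t) − R1(0))/r1`. Signals at or above the SPGR ceiling
`M0·sinα`, or implying concentrations below a floor of −0.05 mM, mark the
sample invalid; smaller negative noise excursions are zeroed.

The longitudinal relaxivity is a required protocol constant, default
`r1 = 3.7 L·mmol⁻¹·s⁻¹` (gadopentetate-class agent at 3 T); it linearly
rescales all concentrations, which is why it is explicit configuration
rather than a buried constant. No B1-inhomogeneity correction and no
bolus-arrival delay between AIF and tissue are modelled.

## Voxel fitting

Bound-constrained trust-region-reflective least squares on the whole
180-sample curve. Bounds: `Ktrans ∈ [0, 5] min⁻¹`, Tofts `Ve ∈ (0, 1]`;
`F ∈ (0, 200]`, `PS ∈ [0, 100]` (mL/min/100 mL), `Ve, Vp ∈ [0, 100]`
(mL/100 mL). The DP objective is multimodal, so fitting is multi-start over
a fixed coarse lattice (Tofts 3×3; DP 3×2×2×2 over F/PS/Ve/Vp). The
residual sum of squares is evaluated at *every* lattice point — the
returned optimum provably dominates the lattice — and full refinement runs
from the best four starts, which profiling showed preserves the global
basin (refining fewer degrades low-SNR recovery) at a quarter of the cost
of refining all. Tolerances 1e-8 on cost and step, 200 evaluations per
start. All-zero curves short-circuit to the zero-transfer solution; failed
voxels propagate as missing values and are excluded from patient medians
rather than zero-filled, which would bias group statistics.

## Monte Carlo precision study

SNR is defined in concentration space: peak of the clean curve divided by
the Gaussian noise sd. The default study uses the wildtype-median DP
parameters as truth (the tumor regime the reliability claim refers to), the
population AIF, 500 replicates, and reports per-parameter CV = 100·sd/mean
and relative bias over converged fits; runs with under 50% convergence are
flagged unreliable. A signal-space noise mode exists in the generator for
end-to-end experiments. At SNR 20 the measured CVs of F, PS, Ve, Vp are all
below 5%.

## Cohort statistics

Patients enter the statistics as the median of their valid tumor voxels per
parameter. Group differences use the two-sided Wilcoxon rank-sum test
(exact enumeration for tie-free samples with both n ≤ 20, tie-corrected
normal approximation otherwise); normality reporting uses Shapiro–Wilk;
cross-model relationships use Spearman rank correlation. ROC analysis
computes AUC as the tie-corrected Mann–Whitney probability, oriented so
AUC ≥ 0.5 (the orientation — whether values *below* the cutoff call a
mutant — is recorded; mutant gliomas run lower on most parameters). The
Youden cutoff scans the midpoints between adjacent distinct observed
values plus the two degenerate extremes; ties in sensitivity + specificity
break toward higher specificity. Accuracy is always derived from the
confusion matrix, `(sens·n_mut + spec·n_wt)/n`; when checking printed
sensitivity/specificity pairs, the rates are first converted back to the
nearest integer counts, since printed rates are themselves rounded. No
multiple-testing correction is applied (raw p at α = 0.05).

## Synthetic cohort generator

The generator emulates a 24 IDH-mutant / 31 IDH-wildtype glioma cohort
under the study protocol (3 precontrast flip angles × 10 dynamics, 180
postcontrast dynamics at 2 s, TR 5.318 ms). All kinetic parameters are
positive and right-skewed, so each group's (median, q25, q75) triple is
fitted by a lognormal: `mu = ln(median)`, `sigma` the average of the two
log-tail widths divided by z₀.₇₅ (asymmetric tails are compromised
symmetrically; zero quartiles are floored at 0.01 before log-fitting).
Within a patient, PS/Ve/Vp are rank-correlated at Spearman 0.7 and the
Tofts Ve tracks the DP Ve at 0.95 through a Gaussian copula (positive
definite by construction); physical constraints (`Vp + Ve ≤ 100`,
`PS ≤ 3F`) are enforced by resampling.

Patient-level medians are drawn as a **quantile-balanced sample** by
default: correlated normal scores are rank-remapped onto the (i − ½)/n
quantiles, so a small cohort represents the group distribution — and in
particular reproduces its median — without the ±16% sampling scatter an
iid draw of n ≈ 30 lognormal medians would impose; rank correlations are
preserved and plain iid sampling remains available (`stratified=False`).
Voxel values scatter lognormally (sigma 0.3) around their patient median,
fully at random.

Each patient is a small image block (spatial realism is out of scope) with
mild per-voxel baseline variation (T1 1400 ms ± 3%, M0 ± 5% lognormal);
voxel DP curves map through R1(t) to SPGR signals, plus the three-angle
precontrast blocks. The AIF is a population bolus model (two Gaussian
passes plus sigmoid-gated washout, Parker-type coefficients, arrival 10 s
after the series start) used directly as plasma concentration — no
hematocrit correction. What the generator does *not* emulate: real
inter-patient correlation structure, anatomy (edema, necrosis, vessels),
motion, B1 fields, arterial partial volume, and temporally correlated
noise; pipeline recovery on this cohort therefore demonstrates estimator
correctness under the stated noise model, not clinical performance.

## Problem sizes and determinism

The default study sizes are 500 Monte Carlo replicates per SNR and a
31-patient × 100-voxel wildtype cohort for pipeline-recovery experiments;
the tests use the same sizes for the headline checks and smaller ones for
invariance checks. Every stochastic entry point takes a seed; cohorts
derive one independent substream per patient from the master seed, so
per-patient data are reproducible independently of generation order.

## Known limitations

* The DP fit assumes the AIF is known exactly and time-aligned with the
  tissue curve; bolus-arrival mismatch is not estimated.
* Sub-grid capillary transit times (mutant-like `tc < dt`) make `Vp` and
  `F` weakly identified at low SNR; the Monte Carlo module quantifies this
  but the fitter does not regularize it.
* The Wilcoxon/ROC tie conventions match the midrank definitions; exotic
  tie-handling variants of other software may differ in the last digit.
* Adiabatic tissue-homogeneity and two-compartment exchange models, water
  exchange, and T2* effects are out of scope.
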