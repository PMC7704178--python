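"""Synthetic two-group glioma DCE cohort generator.

No patient data accompanies the study this package models, so every
downstream stage is exercised on a fully synthetic cohort whose
voxel-level kinetic parameters reproduce published group summaries
(median and interquartile range per parameter, for IDH-mutant and
IDH-wildtype gliomas).

Distributional choices
----------------------
All kinetic parameters are positive and right-skewed, so patient-level
medians are drawn from lognormal distributions fitted to the (median,
q25, q75) triples; voxel values scatter lognormally around their patient
median.  Within a patient, the permeability/volume parameters (PS, Ve,
Vp) are rank-correlated through a Gaussian copula (Spearman 0.7 by
default), and the Tofts interstitial volume tracks the DP one (Spearman
0.95), mirroring the strong cross-model Ve correlation seen clinically.

The arterial input is a population bolus model: two Gaussian passes plus
a sigmoid-gated exponential washout, time-shifted by the injection
offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import Aif, DpParams, TimeGrid, dp_concentration
from .signal import AcquisitionProtocol, signal_from_concentration, spgr_signal

__all__ = [
    "PopulationAifSpec",
    "GroupSpec",
    "MUTANT_GROUP",
    "WILDTYPE_GROUP",
    "lognormal_from_quartiles",
    "population_aif",
    "sample_patient_params",
    "sample_voxel_params",
    "generate_patient_dataset",
    "generate_cohort",
    "PatientDataset",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


# ---------------------------------------------------------------------------
# population AIF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationAifSpec:
    """Parameters of the population bolus AIF (Parker-type mixed model).

    Two Gaussian peaks (amplitudes in mM·min, centres/widths in minutes)
    plus an exponential washout gated by a sigmoid; ``t0_s`` is the bolus
    arrival delay after the start of the dynamic series, in seconds.
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483
    t0_s: float = 10.0

    def curve(self, grid: TimeGrid) -> Aif:
        t = grid.t_min - self.t0_s / 60.0
        cp = np.zeros_like(t)
        m = t > 0
        tm = t[m]
        for a, mu, sig in ((self.a1, self.t1, self.sigma1),
                           (self.a2, self.t2, self.sigma2)):
            cp[m] += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((tm - mu) ** 2) / (2 * sig**2))
        cp[m] += self.alpha * np.exp(-self.beta * tm) / (1 + np.exp(-self.s * (tm - self.tau)))
        cp[0] = 0.0
        return Aif(grid, np.clip(cp, 0.0, None))


def population_aif(grid: TimeGrid, spec: PopulationAifSpec | None = None) -> Aif:
    """Population AIF evaluated on ``grid`` (default spec)."""
    return (spec or PopulationAifSpec()).curve(grid)


# ---------------------------------------------------------------------------
# group specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Cohort group: patient count and per-parameter (median, q25, q75).

    Parameter keys: DP ``f, ps, ve, vp`` (mL/min/100 mL and mL/100 mL) and
    Tofts ``ktrans`` (min⁻¹), ``tofts_ve`` (mL/100 mL).  ``voxel_sigma`` is
    the lognormal scatter of voxel values around the patient median;
    ``n_voxels_range`` the inclusive range of tumor voxels per patient.
    """

    name: str
    n_patients: int
    params: dict
    voxel_sigma: float = 0.3
    n_voxels_range: tuple = (80, 120)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for key, (med, q25, q75) in self.params.items():
            if not (q25 <= med <= q75) or q25 == q75:
                raise ValueError(f"invalid quartiles for {key}")


# Group summaries the generator reproduces (per-patient medians of the two
# IDH groups; DP and Tofts parameters, conventional units).
MUTANT_GROUP = GroupSpec(
    name="mutant",
    n_patients=24,
    params={
        "f": (9.21, 4.70, 12.82),
        "ps": (0.21, 0.03, 1.52),
        "ve": (0.25, 0.12, 9.91),
        "vp": (0.21, 0.06, 0.44),
        "ktrans": (0.02, 0.01, 0.10),
        "tofts_ve": (0.24, 0.00, 8.65),
    },
)
WILDTYPE_GROUP = GroupSpec(
    name="wildtype",
    n_patients=31,
    params={
        "f": (12.48, 10.04, 14.56),
        "ps": (3.38, 2.41, 5.74),
        "ve": (9.30, 5.69, 15.11),
        "vp": (1.59, 0.93, 2.43),
        "ktrans": (0.07, 0.04, 0.09),
        "tofts_ve": (10.01, 7.86, 16.10),
    },
)

# Gaussian-copula correlation of the normal scores, order
# (f, ps, ve, vp, ktrans, tofts_ve).  Spearman 0.7 among PS/Ve/Vp and 0.95
# between the two Ve's (0.6 residual tofts_ve links), converted to Pearson
# via 2·sin(π·ρs/6); verified positive definite.
_PARAM_ORDER = ("f", "ps", "ve", "vp", "ktrans", "tofts_ve")


def _copula_matrix(rho_s: float = 0.7) -> np.ndarray:
    def pearson(rs):
        return 2.0 * np.sin(np.pi * rs / 6.0)

    r = np.eye(6)
    main = pearson(rho_s)
    strong = pearson(0.95)
    weak = pearson(0.6)
    for i, j, v in [(1, 2, main), (1, 3, main), (2, 3, main),
                    (5, 2, strong), (5, 1, weak), (5, 3, weak)]:
        r[i, j] = r[j, i] = v
    return r


def lognormal_from_quartiles(median: float, q25: float, q75: float,
                             floor_eps: float = 0.01):
    """Fit (mu, sigma) of a lognormal to a (median, q25, q75) triple.

    ``mu = ln(median)``; sigma averages the two (possibly asymmetric)
    log-tail widths divided by the normal 75th-percentile z-score.  Zero
    quantiles are floored at ``floor_eps`` before log-fitting.
    """
    q25 = max(q25, floor_eps)
    median = max(median, floor_eps)
    q75 = max(q75, floor_eps)
    if not (0 < q25 < median < q75):
        raise ValueError("need 0 < q25 < median < q75 after flooring")
    mu = np.log(median)
    sigma = 0.5 * (np.log(median / q25) + np.log(q75 / median)) / _Z75
    return float(mu), float(sigma)


def _sample_correlated(mus, sigmas, n, rng, rho_s=0.7):
    chol = np.linalg.cholesky(_copula_matrix(rho_s))
    z = rng.standard_normal((n, len(mus))) @ chol.T
    return np.exp(np.asarray(mus) + z * np.asarray(sigmas))


def _enforce_constraints(draws: np.ndarray, rng, mus, sigmas, rho_s,
                         max_attempts: int = 100) -> np.ndarray:
    """Resample rows violating physical constraints (vp+ve <= 100, ps <= 3f)."""
    def bad(rows):
        return (rows[:, 2] + rows[:, 3] > 100.0) | (rows[:, 1] > 3.0 * rows[:, 0])

    for _ in range(max_attempts):
        mask = bad(draws)
        if not mask.any():
            return draws
        draws[mask] = _sample_correlated(mus, sigmas, int(mask.sum()), rng, rho_s)
    raise RuntimeError("could not satisfy parameter constraints after resampling")


def sample_patient_params(spec: GroupSpec, seed, rho_s: float = 0.7,
                          stratified: bool = True) -> pd.DataFrame:
    """Draw per-patient median parameters for one group.

    With ``stratified`` (default) each parameter's marginal is a balanced
    quantile sample of its fitted lognormal — the correlated normal scores
    are rank-remapped onto the quantiles (i − ½)/n — so a small cohort
    represents the group distribution (and in particular its median)
    without the large sampling scatter of an iid draw; rank correlations
    are preserved.  ``stratified=False`` gives plain iid sampling.

    Returns a DataFrame with one row per patient (columns f, ps, ve, vp,
    ktrans, tofts_ve in conventional units) reproducible under ``seed``.
    """
    from scipy import stats as sps

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mus, sigmas = zip(*(lognormal_from_quartiles(*spec.params[k]) for k in _PARAM_ORDER))
    if stratified:
        chol = np.linalg.cholesky(_copula_matrix(rho_s))
        z = rng.standard_normal((spec.n_patients, len(mus))) @ chol.T
        q = sps.norm.ppf((np.arange(1, spec.n_patients + 1) - 0.5) / spec.n_patients)
        ranks = np.argsort(np.argsort(z, axis=0), axis=0)
        z = q[ranks]
        draws = np.exp(np.asarray(mus) + z * np.asarray(sigmas))
        # constraint violations are repaired by iid redraws
        draws = _enforce_constraints(draws, rng, mus, sigmas, rho_s)
    else:
        draws = _sample_correlated(mus, sigmas, spec.n_patients, rng, rho_s)
        draws = _enforce_constraints(draws, rng, mus, sigmas, rho_s)
    df = pd.DataFrame(draws, columns=_PARAM_ORDER)
    df.insert(0, "patient_id", [f"{spec.name}{i + 1:03d}" for i in range(spec.n_patients)])
    df.insert(1, "group", spec.name)
    return df


def sample_voxel_params(patient_row, n_voxels: int, voxel_sigma: float,
                        rng, rho_s: float = 0.7) -> pd.DataFrame:
    """Voxel-level parameters scattered lognormally around a patient median."""
    mus = [np.log(patient_row[k]) for k in _PARAM_ORDER]
    sigmas = [voxel_sigma] * len(_PARAM_ORDER)
    draws = _sample_correlated(mus, sigmas, n_voxels, rng, rho_s)
    draws = _enforce_constraints(draws, rng, mus, sigmas, rho_s)
    return pd.DataFrame(draws, columns=_PARAM_ORDER)


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------


@dataclass
class PatientDataset:
    """One synthetic patient: truth, curves and SPGR image blocks."""

    patient_id: str
    group: str
    voxel_truth: pd.DataFrame          # per-voxel kinetic parameters
    curves: np.ndarray                 # (n_voxels, n_dynamics) clean concentration
    dyn: np.ndarray                    # (x, y, z, n_dynamics) dynamic signal
    precontrast: dict                  # flip angle -> (x, y, z, n_reps) signal
    mask: np.ndarray                   # (x, y, z) bool
    t1_0: np.ndarray                   # (x, y, z) baseline T1 (ms)
    m0: np.ndarray                     # (x, y, z) equilibrium signal

    def write(self, out_dir) -> None:
        """Write the NIfTI bundle + truth table of one patient."""
        import os

        import nibabel as nib

        os.makedirs(out_dir, exist_ok=True)
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(self.dyn.astype(np.float32), aff),
                 os.path.join(out_dir, "dyn.nii.gz"))
        for fa, block in self.precontrast.items():
            nib.save(nib.Nifti1Image(block.astype(np.float32), aff),
                     os.path.join(out_dir, f"precontrast_fa{int(fa)}.nii.gz"))
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff),
                 os.path.join(out_dir, "mask.nii.gz"))
        self.voxel_truth.to_csv(os.path.join(out_dir, "truth.tsv"),
                                sep="\t", index=False)


def _block_shape(n_voxels: int) -> tuple:
    nz = 3 if n_voxels >= 9 else 1
    nx = int(np.ceil(np.sqrt(n_voxels / nz)))
    ny = int(np.ceil(n_voxels / (nx * nz)))
    return nx, ny, nz


def generate_patient_dataset(
    patient_row,
    n_voxels: int,
    aif: Aif,
    protocol: AcquisitionProtocol,
    seed,
    voxel_sigma: float = 0.3,
    signal_snr: float | None = None,
    t1_0_ms: float = 1400.0,
    m0_mean: float = 1000.0,
    rho_s: float = 0.7,
) -> PatientDataset:
    """Synthesize one patient's DCE dataset from DP ground truth.

    Voxel parameters are drawn around the patient medians, DP forward
    curves computed on the AIF grid, mapped through R1(t) to SPGR signal at
    the dynamic flip angle, and the precontrast multi-flip-angle blocks
    synthesized from the baseline T1.  With ``signal_snr`` set, Gaussian
    noise of sd = mean baseline dynamic-angle signal / signal_snr is added
    to every signal sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    voxels = sample_voxel_params(patient_row, n_voxels, voxel_sigma, rng, rho_s)
    n_t = protocol.n_dynamics
    if aif.grid.n != n_t or abs(aif.grid.dt - protocol.dt) > 1e-9:
        raise ValueError("AIF grid must match the dynamic protocol")

    curves = np.empty((n_voxels, n_t))
    for i, row in enumerate(voxels.itertuples(index=False)):
        p = DpParams(f=row.f, ps=row.ps, ve=row.ve, vp=row.vp)
        curves[i] = dp_concentration(p, aif).c

    shape = _block_shape(n_voxels)
    mask = np.zeros(shape, dtype=bool)
    flat = np.unravel_index(np.arange(n_voxels), shape)
    mask[flat] = True

    # mild per-voxel variation of the baseline tissue properties
    t1_vox = t1_0_ms * np.exp(rng.normal(0.0, 0.03, n_voxels))
    m0_vox = m0_mean * np.exp(rng.normal(0.0, 0.05, n_voxels))

    t1_map = np.full(shape, np.nan)
    m0_map = np.full(shape, np.nan)
    t1_map[flat] = t1_vox
    m0_map[flat] = m0_vox

    dyn = np.zeros(shape + (n_t,), dtype=float)
    for i in range(n_voxels):
        dyn[flat[0][i], flat[1][i], flat[2][i]] = signal_from_concentration(
            curves[i], t1_vox[i], m0_vox[i], protocol
        )

    n_pre = protocol.n_precontrast_per_fa
    precontrast = {}
    for fa in protocol.flip_angles_precontrast:
        block = np.zeros(shape + (n_pre,), dtype=float)
        base = spgr_signal(m0_vox, t1_vox, fa, protocol.tr)
        block[flat] = base[:, None]
        precontrast[fa] = block

    if signal_snr is not None:
        base_dyn = spgr_signal(m0_mean, t1_0_ms, protocol.flip_angle_dynamic, protocol.tr)
        sd = base_dyn / signal_snr
        dyn[mask] += rng.normal(0.0, sd, dyn[mask].shape)
        for fa in precontrast:
            precontrast[fa][mask] += rng.normal(0.0, sd, precontrast[fa][mask].shape)

    voxel_truth = voxels.copy()
    voxel_truth.insert(0, "voxel", np.arange(n_voxels))
    return PatientDataset(
        patient_id=patient_row["patient_id"],
        group=patient_row["group"],
        voxel_truth=voxel_truth,
        curves=curves,
        dyn=dyn,
        precontrast=precontrast,
        mask=mask,
        t1_0=t1_map,
        m0=m0_map,
    )


def generate_cohort(
    groups=(MUTANT_GROUP, WILDTYPE_GROUP),
    protocol: AcquisitionProtocol | None = None,
    aif_spec: PopulationAifSpec | None = None,
    seed: int = 0,
    n_voxels: int | None = None,
    signal_snr: float | None = None,
    rho_s: float = 0.7,
):
    """Generate a full synthetic cohort.

    Returns ``(patients, aif, manifest)`` where ``patients`` is a list of
    `PatientDataset`, and ``manifest`` a DataFrame of patient ids, groups,
    voxel counts and true patient-median parameters.  One master seed fixes
    the whole cohort; every patient draws from an independent substream, so
    per-patient data are independent of generation order.
    """
    protocol = protocol or AcquisitionProtocol()
    aif = population_aif(protocol.dynamic_grid(), aif_spec)
    master = np.random.SeedSequence(seed)
    group_seeds = master.spawn(len(groups))
    patients = []
    rows = []
    for spec, gseed in zip(groups, group_seeds):
        pseed, *vox_seeds = gseed.spawn(spec.n_patients + 1)
        table = sample_patient_params(spec, np.random.default_rng(pseed), rho_s)
        for (_, prow), vseed in zip(table.iterrows(), vox_seeds):
            rng = np.random.default_rng(vseed)
            if n_voxels is None:
                nv = int(rng.integers(spec.n_voxels_range[0],
                                      spec.n_voxels_range[1] + 1))
            else:
                nv = n_voxels
            ds = generate_patient_dataset(
                prow, nv, aif, protocol, rng,
                voxel_sigma=spec.voxel_sigma, signal_snr=signal_snr, rho_s=rho_s,
            )
            patients.append(ds)
            rec = {"patient_id": prow["patient_id"], "group": spec.name,
                   "n_voxels": nv}
            rec.update({k: prow[k] for k in _PARAM_ORDER})
            rows.append(rec)
    manifest = pd.DataFrame(rows)
    return patients, aif, manifest
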