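"""Voxel-wise nonlinear least-squares estimation of tracer-kinetic parameters.

Each voxel's concentration-time curve is fitted with the Tofts or the
distributed-parameter (DP) forward model by bound-constrained trust-region
least squares.  The DP objective is multimodal, so fitting is multi-start
over a fixed coarse lattice of physiologically spread starting points: the
residual sum of squares is evaluated at every lattice point and full
refinement runs from the best few, which keeps runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    Aif,
    ConcentrationCurve,
    DerivedParams,
    DpParams,
    ToftsParams,
    dp_concentration,
    extraction_ratio,
    tofts_concentration,
)
from .signal import AcquisitionProtocol, concentration_from_signal, fit_vfa_t1_map

__all__ = [
    "FitOptions",
    "FitResult",
    "ParameterMaps",
    "fit_voxel",
    "fit_curves",
    "fit_roi",
    "DP_PARAM_NAMES",
    "TOFTS_PARAM_NAMES",
]

DP_PARAM_NAMES = ("f", "ps", "ve", "vp", "e")
TOFTS_PARAM_NAMES = ("ktrans", "ve", "kep")

# Multi-start lattices.  Tofts in (min^-1, fraction); DP in conventional
# per-100 mL units (fractions 0.05/0.2 -> 5/20 mL/100 mL etc.).
_TOFTS_STARTS = [
    (kt, ve) for kt in (0.01, 0.1, 0.5) for ve in (0.05, 0.2, 0.5)
]
_DP_STARTS = [
    (f, ps, ve, vp)
    for f in (5.0, 15.0, 50.0)
    for ps in (0.5, 5.0)
    for ve in (5.0, 20.0)
    for vp in (1.0, 5.0)
]

# Bounds: Ktrans in [0, 5] min^-1, Ve (Tofts) in [~0, 1];
# F in (0, 200] mL/min/100 mL, PS in [0, 100], Ve/Vp in [~0, 100] mL/100 mL.
_TOFTS_LO = np.array([0.0, 1e-4])
_TOFTS_HI = np.array([5.0, 1.0])
_DP_LO = np.array([1e-2, 0.0, 1e-3, 1e-4])
_DP_HI = np.array([200.0, 100.0, 100.0, 100.0])


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for `fit_voxel`.

    ``n_refine`` is the number of best lattice starts refined by full least
    squares (RSS is still evaluated at every start, so the returned optimum
    dominates the whole lattice).
    """

    ftol: float = 1e-8
    xtol: float = 1e-8
    max_nfev: int = 200
    n_refine_dp: int = 4
    n_refine_tofts: int = 4
    zero_curve_eps: float = 1e-12


DEFAULT_FIT_OPTIONS = FitOptions()


@dataclass(frozen=True)
class FitResult:
    params: object                # ToftsParams | DpParams (fields NaN on failure)
    derived: DerivedParams
    rss: float
    n_iter: int
    converged: bool
    start_index: int              # lattice start that won (-1 for shortcuts)


def _derived_for(params, model: str) -> DerivedParams:
    if model == "tofts":
        kep = params.ktrans / params.ve if params.ve > 0 else np.nan
        return DerivedParams(kep=kep)
    e = extraction_ratio(params.ps, params.f) if params.f > 0 else np.nan
    return DerivedParams(e=e)


def _forward(model: str, x: np.ndarray, aif: Aif) -> np.ndarray:
    if model == "tofts":
        return tofts_concentration(ToftsParams(*x), aif).c
    return dp_concentration(DpParams(*x), aif).c


def fit_voxel(
    curve: ConcentrationCurve,
    aif: Aif,
    model: str = "dp",
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> FitResult:
    """Fit one concentration-time curve, returning the best multi-start solution."""
    if model not in ("tofts", "dp"):
        raise ValueError("model must be 'tofts' or 'dp'")
    if curve.grid.n != aif.grid.n or abs(curve.grid.dt - aif.grid.dt) > 1e-9:
        raise ValueError("curve and AIF must share a time grid")
    c_obs = curve.c

    if np.all(np.abs(c_obs) <= options.zero_curve_eps):
        # no enhancement: zero-transfer solution, exactly optimal
        if model == "tofts":
            params = ToftsParams(ktrans=0.0, ve=0.0)
        else:
            params = DpParams(f=np.nan, ps=0.0, ve=0.0, vp=0.0)
        return FitResult(params, DerivedParams(), 0.0, 0, True, -1)

    starts = _TOFTS_STARTS if model == "tofts" else _DP_STARTS
    lo = _TOFTS_LO if model == "tofts" else _DP_LO
    hi = _TOFTS_HI if model == "tofts" else _DP_HI
    n_refine = options.n_refine_tofts if model == "tofts" else options.n_refine_dp

    def resid(x):
        return _forward(model, x, aif) - c_obs

    start_rss = np.array([float(np.sum(resid(np.asarray(s)) ** 2)) for s in starts])
    order = np.argsort(start_rss, kind="stable")[: max(1, n_refine)]

    best = None
    for idx in order:
        x0 = np.clip(np.asarray(starts[idx], dtype=float), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                ftol=options.ftol, xtol=options.xtol, max_nfev=options.max_nfev,
                x_scale="jac",
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol, int(idx))

    if best is None:
        params = (
            ToftsParams(np.nan, np.nan) if model == "tofts"
            else DpParams(np.nan, np.nan, np.nan, np.nan)
        )
        return FitResult(params, DerivedParams(), np.nan, 0, False, -1)

    rss, sol, start_index = best
    x = sol.x
    params = ToftsParams(*x) if model == "tofts" else DpParams(*x)
    converged = bool(sol.status > 0)
    return FitResult(
        params,
        _derived_for(params, model),
        rss,
        int(sol.nfev),
        converged,
        start_index,
    )


def _result_values(res: FitResult, model: str) -> dict:
    if model == "tofts":
        return {
            "ktrans": res.params.ktrans,
            "ve": res.params.ve,
            "kep": res.derived.kep,
        }
    return {
        "f": res.params.f,
        "ps": res.params.ps,
        "ve": res.params.ve,
        "vp": res.params.vp,
        "e": res.derived.e,
    }


def fit_curves(
    curves: np.ndarray,
    aif: Aif,
    model: str = "dp",
    options: FitOptions = DEFAULT_FIT_OPTIONS,
):
    """Fit a batch of curves (rows of ``curves``); returns a dict of arrays.

    NaN rows (failed conversions) and failed fits yield NaN parameters; the
    ``converged`` entry reports per-curve success.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    names = TOFTS_PARAM_NAMES if model == "tofts" else DP_PARAM_NAMES
    out = {name: np.full(curves.shape[0], np.nan) for name in names}
    out["rss"] = np.full(curves.shape[0], np.nan)
    out["converged"] = np.zeros(curves.shape[0], dtype=bool)
    for i, c in enumerate(curves):
        if not np.all(np.isfinite(c)):
            continue
        res = fit_voxel(ConcentrationCurve(aif.grid, c), aif, model, options)
        if res.converged:
            for k, v in _result_values(res, model).items():
                out[k][i] = v
            out["rss"][i] = res.rss
            out["converged"][i] = True
    return out


@dataclass
class ParameterMaps:
    """Per-parameter 3-D maps (NaN outside the ROI or where the fit failed)."""

    model: str
    maps: dict                    # name -> float32 ndarray (x, y, z)
    converged: np.ndarray         # bool ndarray (x, y, z)

    @property
    def param_names(self):
        return tuple(self.maps)

    def save_nifti(self, out_dir, subject: str, affine=None) -> list:
        """Write one float32 NIfTI file per parameter; returns the paths."""
        import os

        import nibabel as nib

        if affine is None:
            affine = np.eye(4)
        paths = []
        os.makedirs(out_dir, exist_ok=True)
        for name, vol in self.maps.items():
            path = os.path.join(out_dir, f"{subject}_{self.model}_{name}.nii.gz")
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
            paths.append(path)
        return paths


def fit_roi(
    series_4d: np.ndarray,
    mask: np.ndarray,
    t1map,
    aif: Aif,
    protocol: AcquisitionProtocol,
    model: str = "dp",
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> ParameterMaps:
    """Convert and fit every in-mask voxel of a 4-D dynamic series.

    Parameters
    ----------
    series_4d : ndarray (x, y, z, t)
        Dynamic SPGR signal.
    mask : bool ndarray (x, y, z)
        Tumor ROI; voxels outside are left NaN.
    t1map : tuple (t1, m0) of ndarrays, or (t1, m0, fit_ok)
        Baseline T1 (ms) and M0 per voxel from the variable-flip-angle fit.

    Deterministic: voxels are processed independently with a fixed start
    lattice, so the result does not depend on traversal order.
    """
    series_4d = np.asarray(series_4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if series_4d.shape[:3] != mask.shape:
        raise ValueError("series and mask shapes disagree")
    if not mask.any():
        raise ValueError("empty ROI mask")
    t1_vol, m0_vol = t1map[0], t1map[1]
    fit_ok = t1map[2] if len(t1map) > 2 else np.isfinite(t1_vol)

    idx = np.argwhere(mask)
    curves = np.full((idx.shape[0], series_4d.shape[3]), np.nan)
    for row, (i, j, k) in enumerate(idx):
        if not fit_ok[i, j, k]:
            continue
        c, valid = concentration_from_signal(
            series_4d[i, j, k], t1_vol[i, j, k], m0_vol[i, j, k], protocol
        )
        if valid.all():
            curves[row] = c
    fitted = fit_curves(curves, aif, model, options)

    names = TOFTS_PARAM_NAMES if model == "tofts" else DP_PARAM_NAMES
    maps = {
        name: np.full(mask.shape, np.nan, dtype=np.float32) for name in names
    }
    conv = np.zeros(mask.shape, dtype=bool)
    for row, (i, j, k) in enumerate(idx):
        conv[i, j, k] = fitted["converged"][row]
        for name in names:
            maps[name][i, j, k] = fitted[name][row]
    return ParameterMaps(model=model, maps=maps, converged=conv)
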