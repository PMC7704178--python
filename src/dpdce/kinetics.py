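"""Tracer-kinetic forward models for dynamic contrast-enhanced MRI.

Two closed-form models of the tissue concentration-time curve
``C_tiss(t) = C_A(t) ⊗ F·R(t)`` are provided:

* **Tofts** — single extravascular compartment, impulse response
  ``Ktrans · exp(-(Ktrans/Ve) · t)``.
* **Distributed-parameter (DP)** — plug-flow capillary of transit time
  ``tc = Vp/F`` exchanging with a radially well-mixed interstitium.  Its
  residue function is 1 during the vascular transit and afterwards decays
  through a Bessel-function washout term governed by the permeability-surface
  area product PS and the interstitial volume Ve.

A brute-force finite-difference solver of the underlying axially distributed
transport equations (`pde_oracle`) is included so the DP closed form can be
validated against an independent numerical solution.

Units
-----
Public parameters use the conventional perfusion units: F and PS in
mL/min/100 mL, Ve and Vp in mL/100 mL, Ktrans and Kep in min⁻¹, time grids
in seconds, concentrations in mM.  Internally everything is converted to
unit-volume fractions and minutes before any convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.integrate import cumulative_trapezoid, quad

__all__ = [
    "TimeGrid",
    "Aif",
    "ToftsParams",
    "DpParams",
    "DerivedParams",
    "ConcentrationCurve",
    "DegenerateKernelError",
    "CflError",
    "tofts_concentration",
    "dp_residue",
    "dp_concentration",
    "pde_oracle",
    "extraction_ratio",
    "kep",
    "bessel_washout_integrand",
]

SEC_PER_MIN = 60.0

# relative tolerance for "uniform spacing" of time grids
_GRID_RTOL = 1e-9


class DegenerateKernelError(ValueError):
    """Model impulse response undefined (e.g. Ve = 0 with nonzero transfer)."""


class CflError(RuntimeError):
    """Explicit time step violates the advection stability limit."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling times starting at zero.

    Parameters
    ----------
    t : array-like
        Sample times.  Must be uniformly spaced, strictly increasing and
        start at 0.
    units : {"s", "min"}
        Unit of ``t``; stored internally in seconds.
    """

    t: np.ndarray
    units: str = "s"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if self.units == "min":
            t = t * SEC_PER_MIN
        elif self.units != "s":
            raise ValueError(f"unknown time unit {self.units!r}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least two samples")
        if t[0] != 0.0:
            raise ValueError("time grid must start at 0")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > _GRID_RTOL * max(steps[0], 1.0):
            raise ValueError("time grid must be uniformly spaced")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "units", "s")

    @classmethod
    def uniform(cls, n: int, dt_s: float) -> "TimeGrid":
        return cls(np.arange(n) * float(dt_s))

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Step in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def t_min(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.t / SEC_PER_MIN

    @property
    def dt_min(self) -> float:
        return self.dt / SEC_PER_MIN


@dataclass(frozen=True)
class Aif:
    """Arterial input function: plasma tracer concentration C_A(t) in mM."""

    grid: TimeGrid
    cp: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.cp, dtype=float)
        if cp.shape != self.grid.t.shape:
            raise ValueError("AIF and grid length mismatch")
        if not np.all(np.isfinite(cp)):
            raise ValueError("AIF contains non-finite values")
        if np.any(cp < 0):
            raise ValueError("AIF must be nonnegative")
        if cp[0] != 0.0:
            raise ValueError("AIF must start at zero (pre-bolus baseline)")
        object.__setattr__(self, "cp", cp)

    @classmethod
    def from_tsv(cls, path) -> "Aif":
        """Read a two-column TSV with header ``time_s\tcp_mM``."""
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(TimeGrid(data[:, 0]), data[:, 1])

    def to_tsv(self, path) -> None:
        header = "time_s\tcp_mM"
        np.savetxt(path, np.column_stack([self.grid.t, self.cp]),
                   delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tissue tracer concentration C_tiss(t) in mM on a uniform grid."""

    grid: TimeGrid
    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.shape != self.grid.t.shape:
            raise ValueError("curve and grid length mismatch")
        if not np.all(np.isfinite(c)):
            raise ValueError("curve contains non-finite values")
        object.__setattr__(self, "c", c)


@dataclass(frozen=True)
class ToftsParams:
    """Tofts model parameters: Ktrans (min⁻¹) and Ve (fraction in [0, 1])."""

    ktrans: float
    ve: float

    def validate(self) -> None:
        if not (self.ktrans >= 0):
            raise ValueError("ktrans must be >= 0")
        if not (0 <= self.ve <= 1):
            raise ValueError("ve must be a fraction in [0, 1]")


@dataclass(frozen=True)
class DpParams:
    """DP model parameters in conventional units.

    f, ps : mL/min/100 mL;  ve, vp : mL/100 mL.
    """

    f: float
    ps: float
    ve: float
    vp: float

    def validate(self) -> None:
        if not (self.f > 0):
            raise ValueError("f must be > 0")
        if not (self.ps >= 0):
            raise ValueError("ps must be >= 0")
        if not (self.ve >= 0 and self.vp >= 0):
            raise ValueError("ve and vp must be >= 0")
        if self.ve + self.vp > 100.0:
            raise ValueError("ve + vp must not exceed 100 mL/100 mL")


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from fitted parameters: Kep (min⁻¹) and E (%)."""

    kep: float = np.nan
    e: float = np.nan


# ---------------------------------------------------------------------------
# discrete convolution
# ---------------------------------------------------------------------------


def _trap_convolve(x: np.ndarray, k: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal discrete convolution ``(x ⊗ k)(t_i)`` on a uniform grid."""
    n = x.size
    full = np.convolve(x, k)[:n] * dt
    # trapezoid end-point correction: half weight at j = 0 and j = i
    return full - 0.5 * dt * (x * k[0] + k * x[0])


def _cumint_interp(t_query: np.ndarray, t: np.ndarray, x: np.ndarray,
                   ix: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-linear signal at arbitrary times.

    ``ix`` is the trapezoidal cumulative integral of ``x`` at the nodes ``t``;
    between nodes the integral is quadratic, which matters at sharp features
    such as bolus arrival.  Queries before t[0] return 0.
    """
    dt = t[1] - t[0]
    out = np.zeros_like(t_query)
    inside = t_query > 0
    tq = np.clip(t_query[inside], 0.0, t[-1])
    j = np.minimum((tq / dt).astype(int), t.size - 2)
    theta = tq - t[j]
    out[inside] = ix[j] + x[j] * theta + 0.5 * (x[j + 1] - x[j]) * theta**2 / dt
    return out


# ---------------------------------------------------------------------------
# Tofts model
# ---------------------------------------------------------------------------


def tofts_concentration(p: ToftsParams, aif: Aif) -> ConcentrationCurve:
    """Tissue curve of the Tofts model: C_A ⊗ Ktrans·exp(−(Ktrans/Ve)·t)."""
    p.validate()
    if p.ktrans == 0:
        return ConcentrationCurve(aif.grid, np.zeros(aif.grid.n))
    if p.ve == 0:
        raise DegenerateKernelError("Tofts kernel undefined for ve = 0 with ktrans > 0")
    t = aif.grid.t_min
    kern = p.ktrans * np.exp(-(p.ktrans / p.ve) * t)
    c = _trap_convolve(aif.cp, kern, aif.grid.dt_min)
    c[0] = 0.0
    return ConcentrationCurve(aif.grid, c)


# ---------------------------------------------------------------------------
# DP model
# ---------------------------------------------------------------------------


def bessel_washout_integrand(s, a: float, b: float):
    """Integrand ``exp(−a·s)·sqrt(ab/s)·I₁(2·sqrt(ab·s))`` of the DP washout.

    The apparent 1/sqrt(s) singularity at s = 0 is removable with limit
    ``a·b``; below s = 1e-10 the limit value is substituted.  Evaluated with
    the exponentially scaled Bessel function to avoid overflow.
    """
    s = np.asarray(s, dtype=float)
    out = np.full(s.shape, a * b, dtype=float)
    m = s > 1e-10
    sm = s[m]
    z = 2.0 * np.sqrt(a * b * sm)
    out[m] = np.sqrt(a * b / sm) * special.i1e(z) * np.exp(z - a * sm)
    return out if out.ndim else float(out)


def _leakage_cdf(s: np.ndarray, a: float, b: float) -> np.ndarray:
    """Fraction of tracer that has washed out through the interstitium.

    Equals ``exp(−b)·∫₀^s exp(−a·u)·sqrt(ab/u)·I₁(2√(ab·u)) du``, evaluated
    by the exact series Σ_{m≥1} Poisson(m; b) · P(m, a·s) with P the
    regularized lower incomplete gamma function.  All terms are positive, so
    the sum is numerically stable for any b.
    """
    if b == 0:
        return np.zeros_like(s)
    n_terms = int(np.ceil(b + 10.0 * np.sqrt(b) + 20.0))
    m = np.arange(1, n_terms + 1, dtype=float)
    log_pois = m * np.log(b) - b - special.gammaln(m + 1.0)
    weights = np.exp(log_pois)
    gam = special.gammainc(m[:, None], a * np.clip(s, 0.0, None)[None, :])
    return weights @ gam


def dp_residue(tau, p: DpParams):
    """DP residue function R(τ), τ in minutes.

    R(τ) = 1 for 0 ≤ τ < tc = Vp/F; at τ = tc it drops to the extracted
    fraction 1 − exp(−PS/F) and thereafter decays through the interstitial
    washout term.  Causal: R = 0 for τ < 0.  Values lie in [0, 1].
    """
    p.validate()
    tau = np.asarray(tau, dtype=float)
    scalar = tau.ndim == 0
    tau = np.atleast_1d(tau)
    tc = p.vp / p.f  # minutes
    if p.ps == 0:
        r = np.where((tau >= 0) & (tau < tc), 1.0, 0.0)
        r[tau == 0.0] = 1.0
    else:
        if p.ve == 0:
            raise DegenerateKernelError("DP residue undefined for ve = 0 with ps > 0")
        a = p.ps / p.ve  # per minute
        b = p.ps / p.f
        e1 = -np.expm1(-b)  # 1 − exp(−PS/F)
        s = np.clip(tau - tc, 0.0, None)
        tail = e1 - _leakage_cdf(s, a, b)
        r = np.where(tau < tc, 1.0, tail)
        r[tau == 0.0] = 1.0
        r[tau < 0.0] = 0.0
    r = np.clip(r, 0.0, 1.0)
    return float(r[0]) if scalar else r


def _dp_residue_quad(tau: float, p: DpParams) -> float:
    """Reference DP residue via adaptive Gauss–Kronrod quadrature.

    Slow scalar implementation used to cross-check the series form.
    """
    p.validate()
    if tau < 0:
        return 0.0
    tc = p.vp / p.f
    if tau == 0.0 or tau < tc:
        return 1.0
    if p.ps == 0:
        return 0.0
    if p.ve == 0:
        raise DegenerateKernelError("DP residue undefined for ve = 0 with ps > 0")
    a = p.ps / p.ve
    b = p.ps / p.f
    integral, _ = quad(bessel_washout_integrand, 0.0, tau - tc, args=(a, b),
                       limit=200)
    return float(np.clip(1.0 - np.exp(-b) * (1.0 + integral), 0.0, 1.0))


def dp_concentration(p: DpParams, aif: Aif) -> ConcentrationCurve:
    """Tissue curve of the DP model: C_tiss = C_A ⊗ F·R.

    The vascular plateau of R (a boxcar of width tc = Vp/F, often narrower
    than the sampling interval) is integrated exactly through the cumulative
    integral of the AIF; the smooth washout tail is convolved by the
    trapezoidal rule on the native grid.
    """
    p.validate()
    t = aif.grid.t_min
    dt = aif.grid.dt_min
    cp = aif.cp
    f = p.f / 100.0  # per minute, per unit tissue volume
    tc = p.vp / p.f  # minutes

    ia = cumulative_trapezoid(cp, t, initial=0.0)
    ia_shift = _cumint_interp(t - tc, t, cp, ia)
    c = f * (ia - ia_shift)

    if p.ps > 0:
        if p.ve == 0:
            raise DegenerateKernelError("DP kernel undefined for ve = 0 with ps > 0")
        a = p.ps / p.ve
        b = p.ps / p.f
        e1 = -np.expm1(-b)
        tail = e1 - _leakage_cdf(t, a, b)  # R(tc + s) on s = t
        cp_shift = np.interp(t - tc, t, cp, left=0.0)
        c = c + f * _trap_convolve(cp_shift, tail, dt)
    c[0] = 0.0
    return ConcentrationCurve(aif.grid, c)


# ---------------------------------------------------------------------------
# PDE oracle for the DP model
# ---------------------------------------------------------------------------


def pde_oracle(
    p: DpParams,
    aif: Aif,
    n_axial: int = 100,
    time_refine: int = 4,
    dt_sub_s: float | None = None,
    return_audit: bool = False,
):
    """Numerical solution of the axially distributed two-region exchange model.

    A plug-flow capillary (concentration c_v(x, t), transit time tc = Vp/F)
    exchanges with a locally well-mixed interstitium (c_e(x, t)) at rate
    PS·(c_v − c_e).  First-order upwind finite differences on ``n_axial``
    axial segments with forward-Euler substeps; the output grid of `aif` is
    internally refined ``time_refine``-fold and the AIF linearly interpolated
    onto it.

    Parameters
    ----------
    dt_sub_s : float, optional
        Explicit substep in seconds.  If it violates the advection CFL limit
        (substep ≤ segment transit time) a `CflError` reports the required
        step.  By default a stable step is chosen automatically.
    return_audit : bool
        Also return a dict with the discrete mass balance (tracer in, out,
        stored, and the maximal relative imbalance over time).

    Independent of `dp_concentration`; used to validate it.
    """
    p.validate()
    if n_axial < 50:
        raise ValueError("n_axial must be >= 50")
    if p.vp <= 0:
        raise ValueError("pde_oracle requires vp > 0 (finite capillary volume)")
    if p.ps > 0 and p.ve == 0:
        raise DegenerateKernelError("ve = 0 with ps > 0 is degenerate")

    f = p.f / 100.0 / SEC_PER_MIN  # per second
    vpf = p.vp / 100.0
    vef = p.ve / 100.0
    ps = p.ps / 100.0 / SEC_PER_MIN  # per second
    tc = vpf / f  # seconds
    tau_seg = tc / n_axial

    dt_out = aif.grid.dt
    dt_fine = dt_out / time_refine
    # stability: advection Courant <= 1 and explicit exchange rates resolved
    limits = [tau_seg, dt_fine]
    if p.ps > 0:
        limits += [0.2 * vpf / ps, 0.2 * vef / ps]
    dt_max = min(limits)
    if dt_sub_s is not None:
        if dt_sub_s > tau_seg * (1 + 1e-12):
            raise CflError(
                f"dt_sub_s={dt_sub_s:g} s violates the CFL limit; "
                f"required dt <= {tau_seg:g} s for n_axial={n_axial}"
            )
        dt = dt_sub_s
    else:
        dt = dt_max
    n_sub = int(np.ceil(dt_fine / dt - 1e-12))
    dt = dt_fine / n_sub

    t_out = aif.grid.t
    t_end = t_out[-1]
    n_steps = int(round(t_end / dt))

    cv = np.zeros(n_axial)
    ce = np.zeros(n_axial)
    c_out = np.zeros(t_out.size)
    mass_in = 0.0
    mass_out = 0.0
    max_imbalance = 0.0

    adv = dt / tau_seg
    k_ex = dt * ps  # exchange flux coefficient per unit tissue volume

    out_idx = 1
    next_out = t_out[1] if t_out.size > 1 else np.inf
    for step in range(1, n_steps + 1):
        t_now = step * dt
        c_in = np.interp(t_now, t_out, aif.cp)
        # upwind advection (conservative)
        cv_new = cv - adv * cv
        cv_new[1:] += adv * cv[:-1]
        cv_new[0] += adv * c_in
        mass_in += dt * f * c_in
        mass_out += dt * f * cv[-1]
        cv = cv_new
        # exchange (exactly conservative by construction)
        if p.ps > 0:
            flux = k_ex * (cv - ce)  # per segment, per unit tissue volume/n
            cv = cv - flux / vpf
            ce = ce + flux / vef
        stored = (vpf * cv.mean() + vef * ce.mean())
        if mass_in > 0:
            imbalance = abs(mass_in - mass_out - stored) / mass_in
            max_imbalance = max(max_imbalance, imbalance)
        while out_idx < t_out.size and t_now >= t_out[out_idx] - 0.5 * dt:
            c_out[out_idx] = stored
            out_idx += 1
    curve = ConcentrationCurve(aif.grid, c_out)
    if return_audit:
        audit = {
            "mass_in": mass_in,
            "mass_out": mass_out,
            "stored": (vpf * cv.mean() + vef * ce.mean()),
            "max_rel_imbalance": max_imbalance,
            "dt_sub_s": dt,
        }
        return curve, audit
    return curve


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def extraction_ratio(ps: float, f: float) -> float:
    """First-pass extraction ratio E = 100·(1 − exp(−PS/F)), in percent."""
    if not (f > 0):
        raise ValueError("f must be > 0")
    if ps < 0:
        raise ValueError("ps must be >= 0")
    return float(100.0 * -np.expm1(-ps / f))


def kep(ktrans: float, ve: float) -> float:
    """Efflux rate constant Kep = Ktrans/Ve (min⁻¹)."""
    if ve <= 0:
        raise ZeroDivisionError("kep undefined for ve <= 0")
    return ktrans / ve
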