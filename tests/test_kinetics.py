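"""Forward-model tests: Tofts and DP closed forms against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from dpdce import (
    Aif,
    CflError,
    DegenerateKernelError,
    DpParams,
    TimeGrid,
    ToftsParams,
    bessel_washout_integrand,
    dp_concentration,
    dp_residue,
    extraction_ratio,
    kep,
    pde_oracle,
    tofts_concentration,
)
from dpdce.kinetics import _dp_residue_quad, _trap_convolve


def rel_linf(a, b):
    return np.max(np.abs(a - b)) / np.max(np.abs(b))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class TestTimeGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([1.0, 2.0]))          # not starting at 0
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 2.0, 3.0]))     # non-uniform
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0]))               # too short

    def test_unit_round_trip(self):
        """Declaring the grid in minutes or seconds gives identical models."""
        g_s = TimeGrid.uniform(120, 2.0)
        g_min = TimeGrid(g_s.t / 60.0, units="min")
        assert np.allclose(g_s.t, g_min.t)
        cp = np.zeros(120)
        cp[5:] = np.exp(-0.3 * g_s.t_min[5:])
        p = ToftsParams(0.1, 0.2)
        c1 = tofts_concentration(p, Aif(g_s, cp)).c
        c2 = tofts_concentration(p, Aif(g_min, cp)).c
        assert np.allclose(c1, c2)

    def test_aif_invariants(self, grid):
        with pytest.raises(ValueError):
            Aif(grid, np.full(grid.n, -1.0))
        with pytest.raises(ValueError):
            Aif(grid, np.ones(grid.n))  # nonzero baseline


# ---------------------------------------------------------------------------
# Tofts model
# ---------------------------------------------------------------------------


class TestTofts:
    def test_zero_transfer(self, aif):
        c = tofts_concentration(ToftsParams(0.0, 0.3), aif).c
        assert np.all(c == 0)

    def test_degenerate_ve(self, aif):
        with pytest.raises(DegenerateKernelError):
            tofts_concentration(ToftsParams(0.1, 0.0), aif)

    def test_biexponential_analytic(self):
        """Against the closed-form convolution of two exponentials.

        For C_A = A·exp(−m t) the model is
        Ktrans·A·(exp(−m t) − exp(−kep t))/(kep − m).
        """
        ktrans, ve = 0.07, 0.1001
        kep_v = ktrans / ve
        A, m = 5.0, 2.0
        g = TimeGrid.uniform(3600, 0.1)  # refined grid
        t = g.t_min
        cp = A * np.exp(-m * t)
        cp[0] = 0.0  # pre-bolus baseline convention
        c = tofts_concentration(ToftsParams(ktrans, ve), Aif(g, cp)).c
        expected = ktrans * A * (np.exp(-m * t) - np.exp(-kep_v * t)) / (kep_v - m)
        i = t > 0.2  # past the single-sample baseline transient
        assert np.max(np.abs(c[i] - expected[i])) / expected.max() < 0.005

    def test_impulse_response_is_kernel(self):
        """A unit-area AIF impulse reproduces Ktrans·exp(−kep τ)."""
        ktrans, ve = 0.1, 0.15
        g = TimeGrid.uniform(1200, 0.5)
        dt_min = g.dt_min
        cp = np.zeros(g.n)
        cp[1] = 1.0 / dt_min  # area 1 mM·min (trapezoid sees a 2·dt triangle)
        c = tofts_concentration(ToftsParams(ktrans, ve), Aif(g, cp)).c
        tau = g.t_min - g.t_min[1]
        expected = np.where(tau >= 0, ktrans * np.exp(-(ktrans / ve) * tau), 0.0)
        i = slice(3, None)
        assert np.max(np.abs(c[i] - expected[i])) / expected.max() < 0.02


# ---------------------------------------------------------------------------
# DP residue function
# ---------------------------------------------------------------------------


class TestDpResidue:
    def test_initial_value(self, wildtype_dp):
        assert dp_residue(0.0, wildtype_dp) == 1.0

    def test_causality(self, wildtype_dp):
        assert dp_residue(-0.5, wildtype_dp) == 0.0

    def test_ps_zero_boxcar(self):
        p = DpParams(f=10.0, ps=0.0, ve=5.0, vp=2.0)
        tc = p.vp / p.f
        tau = np.linspace(0, 1.0, 2001)
        r = dp_residue(tau, p)
        assert np.all(r[tau < tc] == 1.0)
        assert np.all(r[tau >= tc] == 0.0)

    def test_jump_value_at_transit_time(self, wildtype_dp):
        """R just past tc equals the extraction fraction 1 − exp(−PS/F)."""
        tc = wildtype_dp.vp / wildtype_dp.f
        e = 1.0 - np.exp(-wildtype_dp.ps / wildtype_dp.f)
        assert dp_residue(tc * (1 + 1e-9), wildtype_dp) == pytest.approx(e, rel=1e-6)
        assert e == pytest.approx(0.237, abs=5e-4)

    @pytest.mark.parametrize("p", [
        DpParams(12.48, 3.38, 9.30, 1.59),
        DpParams(9.21, 0.21, 0.25, 0.21),
        DpParams(50.0, 30.0, 40.0, 5.0),
    ], ids=["wildtype", "mutant", "high-extraction"])
    def test_series_matches_quadrature(self, p):
        """The Poisson-series residue equals Gauss–Kronrod quadrature."""
        for tau in [0.05, 0.2, 0.5, 1.0, 2.0, 5.0]:
            assert dp_residue(tau, p) == pytest.approx(
                _dp_residue_quad(tau, p), abs=1e-10)

    def test_monotone_and_bounded(self, wildtype_dp, mutant_dp):
        tau = np.linspace(0, 6, 4001)
        for p in (wildtype_dp, mutant_dp):
            r = dp_residue(tau, p)
            assert np.all((0 <= r) & (r <= 1))
            assert np.all(np.diff(r) <= 1e-12)

    def test_degenerate_ve(self):
        with pytest.raises(DegenerateKernelError):
            dp_residue(0.5, DpParams(f=10.0, ps=1.0, ve=0.0, vp=1.0))

    def test_bessel_integrand_removable_singularity(self):
        a, b = 0.3634, 0.2708
        assert bessel_washout_integrand(1e-12, a, b) == pytest.approx(a * b, abs=1e-6)
        # finite on an interval including 0
        vals = bessel_washout_integrand(np.linspace(0, 2, 101), a, b)
        assert np.all(np.isfinite(vals))


# ---------------------------------------------------------------------------
# DP concentration and the PDE oracle
# ---------------------------------------------------------------------------


class TestDpConcentration:
    def test_vascular_only_limit(self, aif):
        """ps = 0: curve equals F·(C_A ⊗ boxcar[0, Vp/F]) computed brute-force."""
        p = DpParams(f=12.0, ps=0.0, ve=5.0, vp=2.0)
        c = dp_concentration(p, aif).c
        refine = 64
        gf = TimeGrid.uniform(aif.grid.n * refine, aif.grid.dt / refine)
        cpf = np.interp(gf.t, aif.grid.t, aif.cp)
        box = (gf.t_min < p.vp / p.f).astype(float)
        ref = _trap_convolve(cpf, (p.f / 100.0) * box, gf.dt_min)[::refine]
        assert rel_linf(c, ref) < 0.005

    @pytest.mark.parametrize("params", [
        DpParams(9.21, 0.21, 0.25, 0.21),
        DpParams(12.48, 3.38, 9.30, 1.59),
    ], ids=["mutant", "wildtype"])
    def test_against_pde_oracle(self, aif, params):
        """Closed form vs the independent finite-difference transport solution."""
        c = dp_concentration(params, aif).c
        ref = pde_oracle(params, aif, n_axial=200, time_refine=4).c
        assert rel_linf(c, ref) < 0.01

    def test_causal_start(self, aif, wildtype_dp):
        c = dp_concentration(wildtype_dp, aif).c
        assert c[0] == 0.0
        assert np.all(c >= -1e-12)


class TestPdeOracle:
    def test_ps_zero_matches_boxcar_solution(self, aif):
        p = DpParams(f=12.0, ps=0.0, ve=5.0, vp=2.0)
        ref = dp_concentration(p, aif).c
        c = pde_oracle(p, aif, n_axial=200, time_refine=4).c
        assert rel_linf(c, ref) < 0.01

    def test_mass_conservation(self, aif, wildtype_dp):
        _, audit = pde_oracle(wildtype_dp, aif, n_axial=100, time_refine=2,
                              return_audit=True)
        assert audit["max_rel_imbalance"] < 1e-3

    def test_grid_refinement_converges(self, aif, wildtype_dp):
        """Halving dt and doubling n_axial shrinks the deviation monotonically."""
        ref = dp_concentration(wildtype_dp, aif).c
        errs = [
            rel_linf(pde_oracle(wildtype_dp, aif, n_axial=na, time_refine=tr).c, ref)
            for na, tr in [(50, 1), (100, 2), (200, 4)]
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_cfl_violation_raises(self, aif, wildtype_dp):
        with pytest.raises(CflError):
            pde_oracle(wildtype_dp, aif, n_axial=100, dt_sub_s=10.0)

    def test_first_pass_extraction(self, grid):
        """Tracer left in tissue after one transit of a finite bolus ≈ E.

        Interstitial backflux is made negligible (large Ve) so that the
        retained fraction after the vascular phase has emptied equals the
        first-pass extraction 1 − exp(−PS/F).
        """
        p = DpParams(f=12.0, ps=3.0, ve=90.0, vp=2.0)
        t = grid.t_min
        cp = np.clip(1.0 - np.abs(t - 0.25) / 0.15, 0.0, None)  # triangular bolus
        cp[0] = 0.0
        a = Aif(grid, cp)
        c = pde_oracle(p, a, n_axial=200, time_refine=4).c
        mass_in = (p.f / 100.0) * np.trapezoid(cp, t)
        tc = p.vp / p.f
        i_star = np.searchsorted(t, 0.4 + tc + 0.1)  # bolus over + transit + margin
        retained = c[i_star] / mass_in
        e = 1.0 - np.exp(-p.ps / p.f)
        assert retained == pytest.approx(e, rel=0.03)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


class TestDerived:
    def test_extraction_ratio_values(self):
        assert extraction_ratio(0.0, 10.0) == 0.0
        assert extraction_ratio(1e6, 10.0) == pytest.approx(100.0, abs=1e-6)
        assert extraction_ratio(3.38, 12.48) == pytest.approx(23.7, abs=0.05)
        with pytest.raises(ValueError):
            extraction_ratio(1.0, 0.0)

    def test_extraction_ratio_monotone(self):
        ps_vals = np.linspace(0.5, 20, 8)
        f_vals = np.linspace(5, 50, 8)
        for f in f_vals:
            e = [extraction_ratio(ps, f) for ps in ps_vals]
            assert np.all(np.diff(e) > 0)
        for ps in ps_vals:
            e = [extraction_ratio(ps, f) for f in f_vals]
            assert np.all(np.diff(e) < 0)

    def test_kep(self):
        assert kep(0.0, 0.5) == 0.0
        assert kep(0.07, 0.1001) == pytest.approx(0.699, abs=5e-4)
        k, v = 0.3, 0.21
        assert kep(k, v) * v == pytest.approx(k, rel=1e-12)
        with pytest.raises(ZeroDivisionError):
            kep(0.1, 0.0)
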