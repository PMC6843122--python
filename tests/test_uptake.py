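"""Radial convection-diffusion uptake solver and its kinetics."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from pspacsys.pools import LayerEnvironment, PoolState
from pspacsys.uptake import (
    ParameterError,
    UptakeParams,
    hair_uptake,
    make_grid,
    mm_influx,
    solve_radial,
    solve_radial_reference,
    uptake_per_layer,
)

REF = UptakeParams()  # De=1e-7, b=20, r0=0.015, v0=1e-7, Imax=3e-6, Km=6e-3, Cmin=2e-4


class TestMichaelisMenten:
    def test_zero_at_cmin(self):
        assert mm_influx(REF.Cmin, REF.Imax, REF.Km, REF.Cmin) == 0.0

    def test_zero_below_cmin(self):
        assert mm_influx(REF.Cmin / 2, REF.Imax, REF.Km, REF.Cmin) == 0.0

    def test_half_saturation(self):
        cl = REF.Cmin + REF.Km
        assert mm_influx(cl, REF.Imax, REF.Km, REF.Cmin) == pytest.approx(REF.Imax / 2)

    def test_saturation_limit(self):
        cl = REF.Cmin + 1e6 * REF.Km
        assert mm_influx(cl, REF.Imax, REF.Km, REF.Cmin) == pytest.approx(
            REF.Imax, rel=1e-4
        )

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ParameterError):
            mm_influx(1e-3, 1e-6, 0.0, 0.0)

    def test_monotone_in_cl(self):
        cls = np.linspace(0, 0.1, 200)
        vals = mm_influx(cls, REF.Imax, REF.Km, REF.Cmin)
        assert np.all(np.diff(vals) >= 0)


class TestRootHairs:
    def test_zero_imaxh_reduces_to_classic(self):
        params = UptakeParams(Imaxh=0.0, hair_surface_density=5.0)
        ih0, ih = hair_uptake(0.01, params)
        assert ih0 == 0.0 and float(ih) == 0.0

    def test_hair_half_saturation(self):
        params = UptakeParams(Imaxh=2e-6, Kmh=4e-3, hair_surface_density=5.0)
        ih0, ih = hair_uptake(params.Cmin + params.Kmh, params)
        assert ih0 == pytest.approx(params.Imaxh / 2)
        assert float(ih) == pytest.approx(5.0 * params.Imaxh / 2)

    def test_below_cmin_ceases(self):
        params = UptakeParams(Imaxh=2e-6, hair_surface_density=5.0)
        ih0, _ = hair_uptake(params.Cmin * 0.5, params)
        assert ih0 == 0.0


class TestSolveRadial:
    def test_uniform_cmin_no_driving_force(self):
        # with v0 = 0 there is no mechanism to raise Cl above Cmin anywhere
        params = UptakeParams(v0=0.0)
        grid = make_grid(params.r0, 0.5, params.Cmin, 40)
        out, uptake = solve_radial(grid, params, 86400.0)
        assert uptake == 0.0
        assert np.allclose(out.cl, params.Cmin)

    def test_closed_system_mass_conserved(self):
        params = UptakeParams(Imax=0.0, Imaxh=0.0, v0=0.0)
        grid = make_grid(params.r0, 0.5, 5e-3, 48)
        m0 = grid.solute_mass(params.b)
        out, uptake = solve_radial(grid, params, 1e5)
        assert uptake == 0.0
        assert out.solute_mass(params.b) == pytest.approx(m0, rel=1e-8)

    def test_mass_balance_every_call(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            params = UptakeParams(
                De=10 ** rng.uniform(-8, -6),
                b=rng.uniform(5, 100),
                Imax=10 ** rng.uniform(-7, -5),
                Km=10 ** rng.uniform(-3, -1.7),
                v0=rng.uniform(0, 2e-7),
                Imaxh=2e-7,
                hair_surface_density=rng.uniform(0, 5),
            )
            cl0 = params.Cmin + 10 ** rng.uniform(-3.5, -1.7)
            grid = make_grid(params.r0, rng.uniform(0.2, 0.6), cl0, 40)
            m0 = grid.solute_mass(params.b)
            out, uptake = solve_radial(grid, params, 86400.0)
            assert m0 - out.solute_mass(params.b) == pytest.approx(uptake, rel=1e-6)

    def test_reference_parameter_set_matches_oracle(self):
        grid = make_grid(REF.r0, 0.5, 5e-3, 48)
        _, up = solve_radial(grid, REF, 86400.0)
        _, up_ref = solve_radial_reference(grid, REF, 86400.0)
        assert up == pytest.approx(up_ref, rel=0.01)

    def test_linear_limit_against_matrix_exponential(self):
        """At Cl - Cmin << Km (v0 = 0, hairs off) uptake kinetics are linear
        with surface conductance Imax/Km; the whole problem is then a linear
        ODE system solved exactly by a matrix exponential."""
        params = UptakeParams(v0=0.0, Imaxh=0.0, hair_surface_density=0.0)
        eps = 1e-4 * params.Km
        cl0 = params.Cmin + eps
        n = 40
        grid = make_grid(params.r0, 0.4, cl0, n)
        duration = 86400.0

        _, up_nl = solve_radial(grid, params, duration, dt=duration / 400)

        # independent linear solution on the same finite-volume geometry
        r, faces = grid.r, grid.faces
        vol = grid.cell_volumes
        bvol = params.b * vol
        kappa = params.Imax / params.Km
        a = params.De * params.b / (r[0] - faces[0])
        # surface balance a*(C0-Cs) = kappa*(Cs-Cmin) -> U linear in C0-Cmin
        u_coef = 2 * math.pi * params.r0 * kappa * a / (a + kappa)
        A = np.zeros((n, n))
        rf = faces[1:-1]
        dcoef = 2 * math.pi * rf * params.De * params.b / np.diff(r)
        for j in range(n - 1):
            A[j, j] -= dcoef[j]
            A[j, j + 1] += dcoef[j]
            A[j + 1, j + 1] -= dcoef[j]
            A[j + 1, j] += dcoef[j]
        A[0, 0] -= u_coef
        A = A / bvol[:, None]
        # work in x = C - Cmin so the system is homogeneous
        x0 = np.full(n, eps)
        x_end = expm(A * duration) @ x0
        up_lin = float(np.sum(bvol * (x0 - x_end)))
        assert up_nl == pytest.approx(up_lin, rel=0.02)

    def test_monotone_in_initial_concentration_and_imax(self):
        base = None
        for cl0 in (1e-3, 2e-3, 4e-3):
            grid = make_grid(REF.r0, 0.4, cl0, 40)
            _, up = solve_radial(grid, REF, 86400.0)
            if base is not None:
                assert up > base
            base = up
        prev = None
        for imax in (1e-6, 3e-6, 9e-6):
            params = UptakeParams(Imax=imax)
            grid = make_grid(params.r0, 0.4, 3e-3, 40)
            _, up = solve_radial(grid, params, 86400.0)
            if prev is not None:
                assert up >= prev
            prev = up

    def test_concentration_never_negative(self):
        params = UptakeParams(Imax=1e-5)  # aggressive uptake
        grid = make_grid(params.r0, 0.2, 5e-4, 40)
        out, _ = solve_radial(grid, params, 86400.0)
        assert np.all(out.cl >= 0.0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            make_grid(0.05, 0.05, 1e-3)


class TestUptakePerLayer:
    LAYER = LayerEnvironment()

    def test_zero_root_length(self):
        pools = PoolState(soluble=10.0)
        assert uptake_per_layer(0.0, self.LAYER, pools, REF) == 0.0

    def test_zero_soluble_pool(self):
        assert uptake_per_layer(5.0, self.LAYER, PoolState(), REF) == 0.0

    def test_below_cmin_returns_zero(self):
        # a labile pool mapping below Cmin yields no net influx
        tiny = PoolState(soluble=1e-4)
        assert uptake_per_layer(5.0, self.LAYER, tiny, REF) == 0.0

    def test_withdrawal_capped_by_pool(self):
        pools = PoolState(soluble=0.05)
        got = uptake_per_layer(10.0, self.LAYER, pools, REF)
        assert 0.0 <= got <= pools.soluble

    def test_doubling_rld_gain_bounded(self):
        """More roots take up more P, but at most twice as much; once the
        depletion zones overlap, the gain is clearly sub-linear."""
        pools = PoolState(soluble=10.0)
        u1 = uptake_per_layer(2.0, self.LAYER, pools, REF)
        u2 = uptake_per_layer(4.0, self.LAYER, pools, REF)
        assert 1.0 < u2 / u1 <= 2.0 + 1e-3  # non-overlapping: ~exactly 2
        fast = UptakeParams(De=1e-6)  # mobile solute -> interacting roots
        c1 = uptake_per_layer(20.0, self.LAYER, pools, fast)
        c2 = uptake_per_layer(40.0, self.LAYER, pools, fast)
        assert 1.0 < c2 / c1 < 2.0

    def test_negative_rld_rejected(self):
        with pytest.raises(ValueError):
            uptake_per_layer(-1.0, self.LAYER, PoolState(soluble=1.0), REF)
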