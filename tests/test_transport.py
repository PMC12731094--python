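"""Oxygen transport: MM kinetics, analytic oracles, maximum principle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bioaxsim import (
    FluidProps,
    Label,
    OxygenParams,
    ReactionMode,
    ReactionSpec,
    analytic_fixture,
    mm_rate,
    solve_steady_flow,
    solve_transport,
)
from bioaxsim.geometry import VoxelDomain
from bioaxsim.scenarios import _box_labels

PARAMS = OxygenParams()


class TestMMRate:
    def test_zero_concentration_gives_zero(self):
        assert mm_rate(0.0, 1e-6, PARAMS.Km_c) == 0.0

    def test_half_saturation_identity(self):
        km = PARAMS.Km_c
        assert mm_rate(km, 2e-6, km) == pytest.approx(1e-6, rel=1e-12)

    def test_paper_parameters_near_saturation(self):
        # at C0 the rate sits at C0/(C0+Km) ≈ 96.4 % of Vmax
        r = mm_rate(0.214, 3.33e-6, 7.90e-3)
        assert r == pytest.approx(3.21e-6, rel=5e-3)

    @given(c=st.floats(0.0, 10.0), vmax=st.floats(1e-9, 1e-3))
    def test_bounded_below_vmax(self, c, vmax):
        r = mm_rate(c, vmax, PARAMS.Km_c)
        assert 0.0 <= r < vmax or (c == 0.0 and r == 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(-1e-6, 1e-6, PARAMS.Km_c)


class TestSlabOracles:
    def test_zeroth_order_slab_matches_closed_form(self):
        fx = analytic_fixture("slab_consumption")
        sol = solve_transport(fx.domain, None, fx.oxygen, fx.reactions)
        n = fx.domain.shape[0] - 2
        x = (np.arange(n) + 0.5) * (1e-3 / n)
        c = sol.c[1:-1, 1, 1]
        ref = fx.reference(x)
        assert np.max(np.abs(c - ref) / np.abs(ref)) <= 0.02

    def test_first_order_slab_grid_convergence(self):
        # halving the spacing must reduce the error at least 2× (the
        # diffusion discretization is second order away from boundaries)
        def solve_at(n):
            L = 1e-3
            h = L / n
            lab = _box_labels((n, 1, 1))
            lab[0, 1, 1] = int(Label.INTERFACE)
            dom = VoxelDomain(lab, h, origin=np.array([-h, -h, -h]))
            km, kr = 1e6, 5e-3
            rx = [ReactionSpec(ReactionMode.volumetric, kr * km, km)]
            sol = solve_transport(dom, None, PARAMS, rx)
            kappa = math.sqrt(kr / PARAMS.D)
            x = (np.arange(n) + 0.5) * h
            ref = PARAMS.C0 * np.cosh(kappa * (L - x)) / math.cosh(kappa * L)
            return np.max(np.abs(sol.c[1:-1, 1, 1] - ref))

        assert solve_at(25) / solve_at(50) >= 2.0


class TestWellMixed:
    def test_trajectory_matches_ode_oracle(self):
        fx = analytic_fixture("well_mixed_mm")
        sol = solve_transport(
            fx.domain, None, fx.oxygen, fx.reactions, schedule=fx.schedule
        )
        times = np.array([h[0] for h in sol.history])
        means = np.array([h[1] for h in sol.history])
        ref = fx.reference(times)
        assert np.max(np.abs(means - ref)) / fx.oxygen.C0 <= 0.005

    def test_transient_budget_closes(self):
        fx = analytic_fixture("well_mixed_mm")
        sol = solve_transport(
            fx.domain, None, fx.oxygen, fx.reactions, schedule=fx.schedule
        )
        h = fx.domain.spacing
        consumed = sol.history[-1][2]
        storage_drop = (fx.oxygen.C0 - sol.history[-1][1]) * h**3
        assert consumed == pytest.approx(storage_drop, rel=0.02)


class TestClosedBox:
    def test_equilibrium_preserved_steady(self):
        fx = analytic_fixture("closed_box")
        sol = solve_transport(fx.domain, None, fx.oxygen, fx.reactions)
        c = sol.c[fx.domain.fluid_mask]
        assert np.all(c == fx.oxygen.C0)

    def test_equilibrium_preserved_transient(self):
        fx = analytic_fixture("closed_box")
        sol = solve_transport(
            fx.domain, None, fx.oxygen, fx.reactions,
            schedule={"dt": 50.0, "t_end": 500.0},
        )
        c = sol.c[fx.domain.fluid_mask]
        assert np.allclose(c, fx.oxygen.C0, rtol=1e-12)


def random_sinked_domain(rng):
    """Small closed domain with an interface patch and random MM sinks."""
    shape = tuple(rng.integers(4, 7, size=3))
    lab = _box_labels(shape)
    lab[1:-1, 1:-1, -1][rng.random((shape[0], shape[1])) < 0.7] = int(
        Label.INTERFACE
    )
    # sprinkle scaffold voxels
    interior = lab[1:-1, 1:-1, 1:-1]
    scaf = rng.random(interior.shape) < 0.15
    interior[scaf] = int(Label.SCAFFOLD)
    lab[1:-1, 1:-1, 1:-1] = interior
    dom = VoxelDomain(lab, 1e-3)
    if not dom.fluid_mask.any():
        return None, None
    rx = [
        ReactionSpec(ReactionMode.volumetric, float(rng.uniform(0, 5e-6)),
                     PARAMS.Km_c),
        ReactionSpec(ReactionMode.surface, float(rng.uniform(0, 2e-8)),
                     PARAMS.Km_c),
    ]
    return dom, rx


class TestMaximumPrincipleAndMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_on_randomized_domains(self, seed):
        rng = np.random.default_rng(seed)
        dom, rx = random_sinked_domain(rng)
        if dom is None:
            pytest.skip("degenerate random domain")
        sol = solve_transport(dom, None, PARAMS, rx)
        c = sol.c[dom.fluid_mask]
        assert np.all(c >= -1e-15)
        assert np.all(c <= PARAMS.C0 * (1 + 1e-12))

    @pytest.mark.parametrize("seed", range(3))
    def test_steady_field_monotone_in_vmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        dom, rx = random_sinked_domain(rng)
        if dom is None:
            pytest.skip("degenerate random domain")
        sol1 = solve_transport(dom, None, PARAMS, rx)
        rx2 = [
            ReactionSpec(r.mode, 2.0 * r.vmax, r.km_c) for r in rx
        ]
        sol2 = solve_transport(dom, None, PARAMS, rx2)
        m = dom.fluid_mask
        assert np.all(sol2.c[m] <= sol1.c[m] + 1e-12)


class TestTransientGuards:
    def test_cfl_violation_reports_suggested_dt(self):
        from bioaxsim.scenarios import _box_labels as bl
        from bioaxsim import solve_steady_flow, FluidProps

        lab = bl((6, 3, 3))
        lab[0, 1, 1] = int(Label.INLET)
        lab[-1, 1, 1] = int(Label.OUTLET)
        dom = VoxelDomain(lab, 1e-3)
        flow = solve_steady_flow(dom, FluidProps(), 1e-7)
        with pytest.raises(ValueError, match="CFL"):
            solve_transport(
                dom, flow, PARAMS, [], schedule={"dt": 1e6, "t_end": 2e6}
            )


class TestSurfaceVolumetricConsistency:
    def test_thin_slab_homogenization(self):
        # scaffold slab of thickness t with areal σ on both faces vs a
        # fluid slab with volumetric 2σ/t; both ends held at C0
        n, h = 41, 0.25e-3
        t_cells = 2
        sigma = 1e-10
        mid = n // 2

        lab = _box_labels((n, 1, 1))
        lab[0, 1, 1] = int(Label.INTERFACE)
        lab[-1, 1, 1] = int(Label.INTERFACE)
        lab_surface = lab.copy()
        lab_surface[mid:mid + t_cells, 1, 1] = int(Label.SCAFFOLD)
        dom_s = VoxelDomain(lab_surface, h)
        rx_s = [ReactionSpec(ReactionMode.surface, sigma, PARAMS.Km_c)]
        sol_s = solve_transport(dom_s, None, PARAMS, rx_s)

        dom_v = VoxelDomain(lab.copy(), h)
        vmax_hom = 2 * sigma / (t_cells * h)
        slab_region = np.zeros(dom_v.shape, bool)
        slab_region[mid:mid + t_cells, 1, 1] = True
        rx_v = [ReactionSpec(ReactionMode.volumetric, vmax_hom, PARAMS.Km_c,
                             region=slab_region)]
        sol_v = solve_transport(dom_v, None, PARAMS, rx_v)
        outside = np.zeros(dom_s.shape, bool)
        outside[1:mid, 1, 1] = True
        ratio = sol_s.c[outside] / sol_v.c[outside]
        assert np.all(np.abs(ratio - 1.0) <= 0.10)
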