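"""Scaffold generation, porosity measurement, and chamber assembly."""

import math

import numpy as np
import pytest

from bioaxsim import (
    ChamberSpec,
    Label,
    ScaffoldSpec,
    ScaffoldVariant,
    build_chamber_domain,
    coarsen_block,
    generate_sphere_subtracted_scaffold,
    generate_strut_scaffold,
    measure_porosity,
)
from bioaxsim.geometry import VoxelDomain, subtract_spheres


def strut_spec(porosity=0.50, **kw):
    kw.setdefault("pore_spacing", 2.5e-3)
    return ScaffoldSpec(
        target_porosity=porosity, variant=ScaffoldVariant.strut_lattice, **kw
    )


class TestMeasurePorosity:
    def test_uniform_blocks(self):
        solid = VoxelDomain(
            np.full((4, 4, 4), int(Label.SCAFFOLD), np.uint8), 1e-3
        )
        fluid = VoxelDomain(np.full((4, 4, 4), int(Label.FLUID), np.uint8), 1e-3)
        assert measure_porosity(solid) == 0.0
        assert measure_porosity(fluid) == 1.0

    def test_checkerboard_is_half(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        lab = np.where(idx % 2 == 0, int(Label.SCAFFOLD), int(Label.FLUID))
        assert measure_porosity(VoxelDomain(lab.astype(np.uint8), 1e-3)) == 0.5

    def test_empty_envelope_rejected(self):
        block = VoxelDomain(np.full((2, 2, 2), int(Label.FLUID), np.uint8), 1e-3)
        with pytest.raises(ValueError):
            measure_porosity(block, envelope=np.zeros((2, 2, 2), bool))


class TestSphereSubtraction:
    def test_single_sphere_volume_matches_analytic(self):
        # one 1 mm-radius sphere in a 10 mm cube: porosity = (4/3)πr³/V
        block = subtract_spheres(
            (10e-3, 10e-3, 10e-3), np.array([[5e-3, 5e-3, 5e-3]]),
            1e-3, 0.05e-3,
        )
        expected = (4.0 / 3.0) * math.pi * 1e-3**3 / (1e-2**3)
        assert measure_porosity(block) == pytest.approx(expected, rel=0.02)

    def test_zero_target_gives_solid_block(self):
        spec = ScaffoldSpec(target_porosity=0.0)
        assert measure_porosity(generate_sphere_subtracted_scaffold(spec)) == 0.0

    @pytest.mark.parametrize("target", [0.3, 0.525, 0.7])
    def test_porosity_tuning_hits_target(self, target):
        for seed in (0, 1):
            block = generate_sphere_subtracted_scaffold(
                ScaffoldSpec(target_porosity=target, seed=seed)
            )
            assert measure_porosity(block) == pytest.approx(target, abs=0.005)

    def test_seeded_reproducibility(self):
        a = generate_sphere_subtracted_scaffold(ScaffoldSpec(seed=7))
        b = generate_sphere_subtracted_scaffold(ScaffoldSpec(seed=7))
        c = generate_sphere_subtracted_scaffold(ScaffoldSpec(seed=8))
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)

    def test_spacing_above_quarter_pore_rejected(self):
        with pytest.raises(ValueError):
            generate_sphere_subtracted_scaffold(ScaffoldSpec(), spacing=0.3e-3)


class TestStrutLattice:
    def test_default_target_hits_half_porosity(self):
        block = generate_strut_scaffold(strut_spec())
        assert measure_porosity(block) == pytest.approx(0.50, abs=0.005)

    def test_width_over_pitch_matches_closed_form(self):
        # solid fraction of the orthogonal grid: ax + ay − ax·ay with
        # per-direction fraction a ≈ 1 − sqrt(porosity)
        block = generate_strut_scaffold(strut_spec(0.50))
        solid2d = block.solid_mask[:, :, 0]
        ax = solid2d.all(axis=1).mean()  # full solid columns along x
        a_star = 1 - math.sqrt(0.5)
        assert ax == pytest.approx(a_star, abs=0.05)

    @pytest.mark.parametrize("target", [0.35, 0.525, 0.65])
    def test_other_targets(self, target):
        block = generate_strut_scaffold(strut_spec(target))
        assert measure_porosity(block) == pytest.approx(target, abs=0.005)

    def test_empty_lattice_when_target_is_unity(self):
        block = generate_strut_scaffold(strut_spec(1.0))
        assert measure_porosity(block) == 1.0

    def test_excessive_width_rejected(self):
        # a tight pitch at moderate porosity forces strut widths that
        # reach the pitch (struts would merge into a solid wall)
        with pytest.raises((ValueError, RuntimeError)):
            generate_strut_scaffold(strut_spec(0.2, pore_spacing=0.25e-3))

    def test_deterministic(self):
        a = generate_strut_scaffold(strut_spec())
        b = generate_strut_scaffold(strut_spec())
        assert np.array_equal(a.labels, b.labels)


class TestCoarsening:
    def test_solid_fraction_threshold(self):
        lab = np.full((8, 8, 8), int(Label.SCAFFOLD), np.uint8)
        lab[:, :, 4:] = int(Label.FLUID)  # lower half solid
        block = VoxelDomain(lab, 0.5e-3)
        coarse = coarsen_block(block, 2e-3)
        assert coarse.shape == (2, 2, 2)
        assert coarse.solid_mask[:, :, 0].all()
        assert not coarse.solid_mask[:, :, 1].any()


class TestChamberAssembly:
    def test_quarter_fluid_volume_tracks_fill_volume(self):
        dom = build_chamber_domain(ChamberSpec(n_scaffolds=0), [], 2e-3)
        assert dom.fluid_volume == pytest.approx(110e-6 / 4, rel=0.03)

    def test_full_cylinder_volume_identity(self):
        # V = πr²h reproduced by voxel count × spacing³
        ch = ChamberSpec(n_scaffolds=0, quarter_symmetry=False)
        dom = build_chamber_domain(ch, [], 2e-3)
        assert dom.fluid_volume == pytest.approx(110e-6, rel=0.03)

    def test_quarter_matches_full_quadrant(self):
        q = build_chamber_domain(ChamberSpec(n_scaffolds=0), [], 2e-3)
        f = build_chamber_domain(
            ChamberSpec(n_scaffolds=0, quarter_symmetry=False), [], 2e-3
        )
        assert q.fluid_volume == pytest.approx(f.fluid_volume / 4, rel=0.02)

    def test_boundary_labels_present_and_partition(self):
        dom = build_chamber_domain(ChamberSpec(), [generate_strut_scaffold(strut_spec())], 2e-3)
        for lbl in (Label.FLUID, Label.WALL, Label.SCAFFOLD, Label.INTERFACE,
                    Label.INLET, Label.OUTLET, Label.SYMMETRY):
            assert dom.mask(lbl).any(), f"missing {lbl.name}"
        # ports sit on the domain base (array boundary side)
        ports = dom.mask(Label.INLET) | dom.mask(Label.OUTLET)
        assert ports.any()
        assert np.argwhere(ports)[:, 2].max() == 0

    def test_fluid_never_touches_array_boundary(self):
        dom = build_chamber_domain(ChamberSpec(n_scaffolds=0), [], 2e-3)
        fm = dom.fluid_mask
        assert not fm[0].any() and not fm[-1].any()
        assert not fm[:, 0].any() and not fm[:, -1].any()
        assert not fm[:, :, 0].any() and not fm[:, :, -1].any()

    def test_protruding_scaffold_rejected(self):
        blk = generate_strut_scaffold(strut_spec())
        with pytest.raises(ValueError):
            build_chamber_domain(
                ChamberSpec(), [blk], 2e-3, ring_radius_frac=0.99
            )

    def test_scaffold_embedding_preserves_count(self):
        blk = generate_strut_scaffold(strut_spec())
        dom = build_chamber_domain(ChamberSpec(), [blk], 2e-3)

        # 12 scaffolds → 3 placement sites in the quarter domain; every
        # scaffold voxel must fall in one of the three ring positions
        scaf = dom.mask(Label.SCAFFOLD)
        assert scaf.any()
        centers = np.argwhere(scaf) + 0.5
        xy = centers[:, :2] * dom.spacing + dom.origin[:2]
        r_ring = 0.6 * 0.04
        sites = np.array([
            [r_ring * math.cos(math.radians(a)),
             r_ring * math.sin(math.radians(a))]
            for a in (15.0, 45.0, 75.0)
        ])
        d = np.linalg.norm(xy[:, None, :] - sites[None], axis=2)
        nearest = d.argmin(axis=1)
        assert set(nearest) == {0, 1, 2}
        assert d.min(axis=1).max() <= 7.5e-3  # inside a block half-diagonal
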