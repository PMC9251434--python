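"""Rasterization, pore detection, constriction and gate measurement."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.transform import Rotation

import corelandscape as cl
from corelandscape.assembly import CP_GROUPS, BeadModel
from corelandscape.pores import ResolutionError

from conftest import mini_config


def _single_bead():
    return BeadModel(
        bead_ids=np.array([0]),
        groups=np.array(["lid"], dtype=object),
        positions=np.zeros((1, 3)),
        radii=np.array([2.5]),
        pseudo_residues=np.array(["A"], dtype=object),
    )


@pytest.fixture(scope="module")
def mini_closed():
    core = cl.build_reference_assembly(mini_config()).select(CP_GROUPS)
    return cl.rasterize(core, spacing=1.0)


@pytest.fixture(scope="module")
def mini_drilled():
    cfg = mini_config(pores=(cl.PoreSpec.circular(16.0, 0.0, 10.0),))
    return cl.build_reference_assembly(cfg).select(CP_GROUPS)


class TestRasterize:
    def test_single_bead_occupied_ball(self):
        grid = cl.rasterize(_single_bead(), spacing=0.5, probe_radius=1.4)
        centers = np.argwhere(grid.occupied)
        pts = grid.origin + (centers + 0.5) * grid.spacing
        r = np.linalg.norm(pts, axis=1)
        assert r.max() <= 3.9 + 0.5 * np.sqrt(3)  # radius + one voxel
        assert r.max() >= 3.9 - 0.5 * np.sqrt(3)
        # analytic volume of a 3.9 A ball, within a voxel-skin tolerance
        vol = grid.occupied.sum() * grid.spacing**3
        assert vol == pytest.approx(4 / 3 * np.pi * 3.9**3, rel=0.1)

    def test_empty_structure_all_solvent(self):
        empty = BeadModel(
            np.array([], dtype=int),
            np.array([], dtype=object),
            np.zeros((0, 3)),
            np.array([]),
            np.array([], dtype=object),
        )
        grid = cl.rasterize(empty, spacing=1.0)
        assert not grid.occupied.any()

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ResolutionError):
            cl.rasterize(_single_bead(), spacing=6.0)

    def test_grid_padded_with_solvent(self, mini_closed):
        occ = mini_closed.occupied
        assert not occ[:2].any() and not occ[-2:].any()
        assert not occ[:, :2].any() and not occ[:, -2:].any()
        assert not occ[:, :, :2].any() and not occ[:, :, -2:].any()


class TestDetectAndMeasure:
    def test_closed_shell_zero_pores(self, mini_closed):
        assert cl.detect_pores(mini_closed) == []
        assert cl.measure_gate(mini_closed) == 0.0

    def test_drilled_circular_channel(self, mini_drilled):
        grid = cl.rasterize(mini_drilled, spacing=0.5)
        pores = cl.detect_pores(grid)
        assert len(pores) == 1
        assert pores[0].d_min == pytest.approx(10.0, abs=0.5)
        assert pores[0].d_max == pytest.approx(10.0, abs=0.75)

    def test_grid_refinement_convergence(self, mini_drilled):
        """Halving the spacing moves the measured diameters < one spacing."""
        coarse = cl.detect_pores(cl.rasterize(mini_drilled, spacing=0.5))[0]
        fine = cl.detect_pores(cl.rasterize(mini_drilled, spacing=0.25))[0]
        assert abs(coarse.d_min - fine.d_min) < 0.5
        assert abs(coarse.d_max - fine.d_max) < 0.75

    def test_rotation_invariance(self, mini_drilled):
        """Measurements agree within a voxel after a global rigid rotation."""
        base = cl.detect_pores(cl.rasterize(mini_drilled, spacing=1.0))
        rot = Rotation.from_euler("xz", [33, 12], degrees=True).as_matrix()
        moved = mini_drilled.transformed(rotation=rot, translation=[3.0, -7.0, 11.0])
        turned = cl.detect_pores(cl.rasterize(moved, spacing=1.0))
        assert len(turned) == len(base) == 1
        assert turned[0].d_min == pytest.approx(base[0].d_min, abs=1.0)
        assert turned[0].d_max == pytest.approx(base[0].d_max, abs=1.5)

    @pytest.mark.parametrize("k,seed", [(3, 1), (5, 2), (7, 3)])
    def test_pore_count_matches_drilled_count(self, k, seed):
        """k non-intersecting drilled channels are detected as exactly k pores."""
        rng = np.random.default_rng(seed)
        azimuths = np.linspace(0, 360, k, endpoint=False) + rng.uniform(0, 10)
        pores = tuple(
            cl.PoreSpec.circular(
                float(rng.uniform(20, 40)), float(az), float(rng.uniform(4, 8))
            )
            for az in azimuths
        )
        core = cl.build_reference_assembly(
            cl.AssemblyConfig(pores=pores)
        ).select(CP_GROUPS)
        found = cl.detect_pores(cl.rasterize(core, spacing=1.0))
        assert len(found) == k

    def test_no_interior_cavity_rejected(self):
        grid = cl.rasterize(_single_bead(), spacing=1.0)
        grid.structure.meta.update(
            barrel_axis=np.array([0.0, 0.0, 1.0]),
            axis_origin=np.zeros(3),
            barrel_height=0.0,
            inner_radius=1.0,
            outer_radius=2.0,
            bead_radius=2.5,
            cap_thickness=1.0,
            cap_centers_z=(0.0, 0.0),
        )
        with pytest.raises(ValueError, match="interior cavity"):
            cl.detect_pores(grid)


class TestGate:
    @pytest.mark.parametrize("diameter", [4.0, 14.0, 17.0])
    def test_gate_measured_within_one_spacing(self, diameter):
        cfg = mini_config(gate_diameter=diameter)
        core = cl.build_reference_assembly(cfg).select(CP_GROUPS)
        grid = cl.rasterize(core, spacing=0.5)
        assert cl.measure_gate(grid) == pytest.approx(diameter, abs=0.5)


class TestChemistry:
    def _drilled_with_residues(self, residue):
        cfg = mini_config(pores=(cl.PoreSpec.circular(16.0, 0.0, 10.0),))
        core = cl.build_reference_assembly(cfg).select(CP_GROUPS)
        if callable(residue):
            core.pseudo_residues = np.array(
                [residue(i) for i in range(len(core))], dtype=object
            )
        else:
            core.pseudo_residues = np.full(len(core), residue, dtype=object)
        return core

    def test_isoleucine_lining_hydrophobic(self):
        core = self._drilled_with_residues("I")
        grid = cl.rasterize(core, spacing=1.0)
        pore = cl.detect_pores(grid)[0]
        charge, hyd, klass = cl.characterize_pore(pore, core, grid)
        assert hyd == pytest.approx(4.5)  # published Kyte-Doolittle value
        assert klass == "hydrophobic"
        assert charge == 0

    def test_serine_lining_hydrophilic(self):
        core = self._drilled_with_residues("S")
        grid = cl.rasterize(core, spacing=1.0)
        pore = cl.detect_pores(grid)[0]
        _charge, hyd, klass = cl.characterize_pore(pore, core, grid)
        assert hyd == pytest.approx(-0.8)
        assert klass == "hydrophilic"

    def test_balanced_charges_cancel(self):
        """Equal numbers of D and K within the 4 A lining shell cancel."""
        from corelandscape.pores import Pore

        model = BeadModel(
            bead_ids=np.arange(4),
            groups=np.full(4, "cp_beta_1", dtype=object),
            positions=np.array(
                [[2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0.5]]
            ),
            radii=np.full(4, 1.0),
            pseudo_residues=np.array(list("DKDK"), dtype=object),
        )
        grid = cl.rasterize(model, spacing=1.0)
        pore = Pore(pore_id=0, voxels=np.array([grid.index_of([0.0, 0.0, 0.0])]))
        charge, hyd, _klass = cl.characterize_pore(pore, model, grid)
        assert charge == 0
        assert sorted(pore.lining_residues) == ["D", "D", "K", "K"]


class TestReleaseFilter:
    def test_strict_seven_angstrom_boundary(self):
        from corelandscape.pores import Pore

        mk = lambda d: Pore(pore_id=0, voxels=np.zeros((1, 3), int), d_min=d, d_max=d)
        subset, count = cl.filter_releasing([mk(7.0), mk(4.0), mk(7.9), mk(10.0)])
        assert count == 2
        assert sorted(p.d_min for p in subset) == [7.9, 10.0]
        assert not mk(7.0).releasing  # exactly 7 A is excluded
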