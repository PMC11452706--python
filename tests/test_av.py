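"""Accessible-volume engine against analytic and exhaustive oracles."""

import math
import textwrap

import numpy as np
import pytest

import fretcycle as fc
from fretcycle.av import AVParams, BuriedSiteError, Structure, read_structure
from fretcycle.simulate import generate_toy_structure

SPHERE_PARAMS = AVParams(
    linker_length=8.0, linker_width=1.0, dye_radii=(1.0, 1.0, 1.0), grid_spacing=0.5
)


@pytest.fixture(scope="module")
def lone_atom():
    return generate_toy_structure("lone-attachment-atom")


@pytest.fixture(scope="module")
def lone_av(lone_atom):
    return fc.compute_av(lone_atom, SPHERE_PARAMS, dye_radius=1.0)


THREE_ATOM_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
    ATOM      3  SG  CYS A   2       1.500   2.000   0.000  1.00  0.00           S
    END
    """
)

TWO_MODEL_PDB = textwrap.dedent(
    """\
    MODEL        1
    ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.000   0.000   0.000  1.00  0.00           C
    ENDMDL
    MODEL        2
    ATOM      1  CA  ALA A   1       0.000   0.000   9.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.000   0.000   9.000  1.00  0.00           C
    ATOM      3  CA  ALA A   3       6.000   0.000   9.000  1.00  0.00           C
    ENDMDL
    END
    """
)

ALTLOC_PDB = textwrap.dedent(
    """\
    ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
    ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.50  0.00           C
    ATOM      3  CA  ALA A   2       3.000   0.000   0.000  1.00  0.00           C
    END
    """
)


class TestReadStructure:
    def test_hand_written_atoms(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(THREE_ATOM_PDB)
        s = read_structure(path)
        assert len(s) == 3
        np.testing.assert_allclose(s.coords[2], [1.5, 2.0, 0.0])
        assert s.element[2] == "S"
        assert s.radii[2] == pytest.approx(1.80)
        assert s.select_atom("A:2:SG") == 2

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "two_models.pdb"
        path.write_text(TWO_MODEL_PDB)
        assert len(read_structure(path)) == 2

    def test_altloc_pairs_collapse_to_one_atom(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        s = read_structure(path)
        assert len(s) == 2
        np.testing.assert_allclose(s.coords[0], [0.0, 0.0, 0.0])


class TestComputeAV:
    def test_lone_atom_volume_matches_sphere(self, lone_av):
        analytic = 4.0 / 3.0 * math.pi * SPHERE_PARAMS.linker_length**3
        assert abs(lone_av.volume - analytic) / analytic < 0.05

    def test_lone_atom_mean_position_at_attachment(self, lone_av):
        assert np.linalg.norm(lone_av.mean_position) < SPHERE_PARAMS.grid_spacing

    def test_wall_centroid_is_hemisphere_centroid(self):
        wall = generate_toy_structure(
            "planar-wall", extent=60.0, spacing=0.6, radius=0.45, layers=2
        )
        params = AVParams(
            linker_length=21.0, linker_width=0.2, dye_radii=(0.1,) * 3, grid_spacing=0.6
        )
        av = fc.compute_av(wall, params, dye_radius=0.1)
        # all points on the attachment side of the wall
        assert av.points[:, 2].min() >= 0.0
        assert av.mean_position[2] == pytest.approx(3 * 21.0 / 8.0, abs=0.5)

    def test_buried_site_raises(self):
        cavity = generate_toy_structure("spherical-cavity", radius=3.0, point_spacing=0.8)
        params = AVParams(
            linker_length=8.0, linker_width=4.5, dye_radii=(5.5, 4.5, 1.5), grid_spacing=0.5
        )
        with pytest.raises(BuriedSiteError):
            fc.compute_av(cavity, params, dye_radius=5.5)

    def test_steric_monotonicity(self, lone_atom):
        av_free = fc.compute_av(lone_atom, SPHERE_PARAMS, dye_radius=1.0)
        blocked = generate_toy_structure(
            "planar-wall", z=2.0, extent=30.0, spacing=0.5, radius=1.0, layers=1
        )
        more = Structure(
            coords=np.vstack([lone_atom.coords, blocked.coords]),
            radii=np.concatenate([lone_atom.radii, blocked.radii]),
            element=np.concatenate([lone_atom.element, blocked.element]),
            chain_id=np.concatenate([lone_atom.chain_id, blocked.chain_id]),
            res_id=np.concatenate([lone_atom.res_id, blocked.res_id + 10]),
            atom_name=np.concatenate([lone_atom.atom_name, blocked.atom_name]),
            attachment_index=0,
        )
        av_blocked = fc.compute_av(more, SPHERE_PARAMS, dye_radius=1.0)
        assert av_blocked.volume < av_free.volume

    def test_grid_refinement_converges(self, lone_atom):
        coarse = fc.compute_av(
            lone_atom,
            AVParams(linker_length=8.0, linker_width=1.0, dye_radii=(1.0,) * 3, grid_spacing=1.0),
            dye_radius=1.0,
        )
        fine = fc.compute_av(lone_atom, SPHERE_PARAMS, dye_radius=1.0)
        assert abs(fine.volume - coarse.volume) / coarse.volume < 0.03

    def test_atom_order_invariance(self):
        wall = generate_toy_structure("planar-wall", extent=20.0, spacing=1.0, radius=1.0)
        params = AVParams(
            linker_length=6.0, linker_width=2.0, dye_radii=(1.5,) * 3, grid_spacing=0.5
        )
        av1 = fc.compute_av(wall, params, dye_radius=1.5)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(wall))
        shuffled = Structure(
            coords=wall.coords[perm],
            radii=wall.radii[perm],
            element=wall.element[perm],
            chain_id=wall.chain_id[perm],
            res_id=wall.res_id[perm],
            atom_name=wall.atom_name[perm],
            attachment_index=int(np.argwhere(perm == wall.attachment_index)[0, 0]),
        )
        av2 = fc.compute_av(shuffled, params, dye_radius=1.5)
        assert av1.n_points == av2.n_points
        np.testing.assert_allclose(
            np.sort(av1.points, axis=0), np.sort(av2.points, axis=0), atol=1e-9
        )


class TestComputeAV3:
    def test_identical_radii_degenerate_to_single_av(self, lone_atom):
        av3 = fc.compute_av3(lone_atom, SPHERE_PARAMS)
        av1 = fc.compute_av(lone_atom, SPHERE_PARAMS, dye_radius=1.0)
        assert av3.n_points == av1.n_points
        np.testing.assert_allclose(av3.mean_position, av1.mean_position, atol=1e-9)

    def test_smaller_clearance_gives_larger_volume(self):
        wall = generate_toy_structure("planar-wall", extent=40.0, spacing=1.0, radius=1.5)
        base = dict(linker_length=10.0, linker_width=4.5, grid_spacing=0.5)
        small = fc.compute_av(
            wall, AVParams(dye_radii=(1.5, 1.5, 1.5), **base), dye_radius=1.5
        )
        large = fc.compute_av(
            wall, AVParams(dye_radii=(5.5, 5.5, 5.5), **base), dye_radius=5.5
        )
        assert small.volume >= large.volume

    def test_mean_position_is_weighted_average_of_components(self):
        wall = generate_toy_structure("planar-wall", extent=40.0, spacing=1.0, radius=1.5)
        params = AVParams(
            linker_length=10.0, linker_width=4.5, dye_radii=(5.5, 4.5, 1.5), grid_spacing=0.5
        )
        av3 = fc.compute_av3(wall, params)
        points = {}
        for r in params.dye_radii:
            av = fc.compute_av(wall, params, dye_radius=r)
            for p in map(tuple, np.round(av.points, 6)):
                points[p] = points.get(p, 0) + 1
        coords = np.array(list(points))
        w = np.array(list(points.values()), dtype=float)
        w /= w.sum()
        np.testing.assert_allclose(av3.mean_position, w @ coords, atol=1e-6)


class TestPairStats:
    def _point_av(self, center):
        return fc.AccessibleVolume(
            points=np.array([center], dtype=float),
            weights=np.array([1.0]),
            attachment_point=np.asarray(center, dtype=float),
            grid_spacing=0.5,
            params=SPHERE_PARAMS,
        )

    def test_point_like_avs_at_forster_radius(self):
        stats = fc.av_pair_stats(self._point_av([0, 0, 0]), self._point_av([59, 0, 0]),
                                 R0=59.0, n_samples=100, seed=0)
        assert stats["mean_RDA"] == pytest.approx(59.0)
        assert stats["Rmp"] == pytest.approx(59.0)
        assert stats["R_meanE"] == pytest.approx(59.0)
        assert stats["mean_E"] == pytest.approx(0.5)

    def test_coincident_avs_have_zero_rmp(self, lone_av):
        stats = fc.av_pair_stats(lone_av, lone_av, n_samples=1000, seed=1)
        assert stats["Rmp"] == pytest.approx(0.0, abs=1e-9)

    def test_mean_distance_matches_exhaustive_double_sum(self, lone_atom):
        params = AVParams(
            linker_length=5.0, linker_width=1.0, dye_radii=(1.0,) * 3, grid_spacing=0.5
        )
        av_a = fc.compute_av(lone_atom, params, dye_radius=1.0)
        av_b = fc.AccessibleVolume(
            points=av_a.points + np.array([80.0, 0.0, 0.0]),
            weights=av_a.weights,
            attachment_point=av_a.attachment_point + np.array([80.0, 0.0, 0.0]),
            grid_spacing=av_a.grid_spacing,
            params=params,
        )
        stats = fc.av_pair_stats(av_a, av_b, n_samples=400_000, seed=2)
        # exhaustive weighted double sum on decimated clouds
        pa, wa = av_a.points[::3], av_a.weights[::3]
        pb, wb = av_b.points[::3], av_b.weights[::3]
        wa, wb = wa / wa.sum(), wb / wb.sum()
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        exact = float(wa @ d @ wb)
        assert abs(stats["mean_RDA"] - exact) < 0.2

    def test_mean_distance_never_below_mean_position_distance(self, lone_av):
        shifted = fc.AccessibleVolume(
            points=lone_av.points + np.array([20.0, 5.0, 1.0]),
            weights=lone_av.weights,
            attachment_point=lone_av.attachment_point,
            grid_spacing=lone_av.grid_spacing,
            params=lone_av.params,
        )
        stats = fc.av_pair_stats(lone_av, shifted, n_samples=50_000, seed=3)
        assert stats["mean_RDA"] >= stats["Rmp"] - 1e-9

    def test_deterministic_given_seed(self, lone_av):
        a = fc.av_pair_stats(lone_av, lone_av, n_samples=1000, seed=5)
        b = fc.av_pair_stats(lone_av, lone_av, n_samples=1000, seed=5)
        assert a == b
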