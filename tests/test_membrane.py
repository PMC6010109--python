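import numpy as np
import pytest

from memborient.membrane import (
    GeometryError,
    anchor_insertion_depth,
    depth_summary,
    phosphate_plane,
    residue_centres,
    residue_distance_profile,
)
from memborient.structio import MolecularSystem, Trajectory


def _system(names, resids, masses, chains=None):
    n = len(names)
    return MolecularSystem(
        names=np.array(names),
        elements=np.array(["C"] * n),
        resids=np.array(resids),
        resnames=np.array(["ALA"] * n),
        chains=np.array(chains if chains else ["A"] * n),
        masses=np.array(masses, dtype=float),
        radii=np.full(n, 1.7),
    )


def _flat_phosphates(n_per_leaflet=8, z=2.0, spacing=1.0):
    """Two square grids of phosphate positions at +/- z."""
    side = int(np.ceil(np.sqrt(n_per_leaflet)))
    xy = np.array([(i * spacing, j * spacing) for i in range(side)
                   for j in range(side)])[:n_per_leaflet]
    upper = np.column_stack([xy, np.full(n_per_leaflet, z)])
    lower = np.column_stack([xy, np.full(n_per_leaflet, -z)])
    return np.vstack([upper, lower])


class TestPhosphatePlane:
    def test_flat_leaflets_at_half_thickness(self):
        coords = _flat_phosphates(z=2.0)
        upper, lower = phosphate_plane(coords, np.arange(len(coords)))
        assert upper.mean_z == pytest.approx(2.0)
        assert lower.mean_z == pytest.approx(-2.0)
        assert upper.mean_z > lower.mean_z

    def test_jittered_mean_equals_member_average(self):
        rng = np.random.default_rng(0)
        coords = _flat_phosphates(z=2.0)
        coords[:, 2] += rng.normal(scale=0.1, size=len(coords))
        idx = np.arange(len(coords))
        upper, _ = phosphate_plane(coords, idx)
        by_hand = coords[upper.members][:, 2].mean()
        assert upper.mean_z == pytest.approx(by_hand, abs=1e-12)

    def test_plane_fit_recovers_tilted_normal(self):
        coords = _flat_phosphates(n_per_leaflet=16, z=2.0)
        tilt = np.radians(5.0)
        rot = np.array([[np.cos(tilt), 0, np.sin(tilt)], [0, 1, 0],
                        [-np.sin(tilt), 0, np.cos(tilt)]])
        tilted = coords @ rot.T
        upper, _ = phosphate_plane(tilted, np.arange(len(coords)),
                                   mode="plane-fit")
        expected = rot @ np.array([0.0, 0.0, 1.0])
        angle = np.degrees(np.arccos(np.clip(upper.normal @ expected, -1, 1)))
        assert angle < 0.1

    def test_too_few_phosphates_raise(self):
        with pytest.raises(GeometryError):
            phosphate_plane(np.zeros((4, 3)), np.arange(4))


class TestDistanceProfile:
    def test_signed_distance_above_plane(self):
        phos = _flat_phosphates(z=1.0)
        protein = np.array([[0.0, 0.0, 3.0]])
        coords = np.vstack([protein, phos])
        system = _system(["CA"] + ["P"] * len(phos), [1] + [2] * len(phos),
                         [12.0] + [31.0] * len(phos),
                         chains=["A"] + ["M"] * len(phos))
        traj = Trajectory(coords=coords[None], box=np.array([[10.0, 10, 10]]))
        prof = residue_distance_profile(traj, system, np.array([0]),
                                        np.arange(1, len(phos) + 1))
        assert prof.distances[0, 0] == pytest.approx(2.0)

    def test_mass_weighted_centre_by_hand(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.3]])
        system = _system(["C", "H"], [1, 1], [12.0, 1.0])
        resids, centres = residue_centres(coords, system, np.array([0, 1]))
        assert centres[0, 2] == pytest.approx(1.3 * 1.0 / 13.0)

    def test_anchor_residues_have_negative_distances(self, zero_noise_run):
        run = zero_noise_run
        prof = residue_distance_profile(
            run.trajectory, run.system, run.regions["anchor_cys"],
            run.regions.membrane_phosphates)
        # the anchor chains reach ~1.7 nm below the plane: centres dip under
        assert (prof.distances < 0).all()

    def test_xy_translation_invariance_and_z_equivariance(self):
        phos = _flat_phosphates(z=1.0)
        protein = np.array([[0.5, 0.5, 2.5]])
        coords = np.vstack([protein, phos])
        system = _system(["CA"] + ["P"] * len(phos), [1] + [2] * len(phos),
                         [12.0] + [31.0] * len(phos),
                         chains=["A"] + ["M"] * len(phos))
        def dist(c):
            traj = Trajectory(coords=c[None], box=np.array([[10.0, 10, 10]]))
            return residue_distance_profile(
                traj, system, np.array([0]),
                np.arange(1, len(phos) + 1)).distances[0, 0]
        base = dist(coords)
        assert dist(coords + [3.0, -2.0, 0.0]) == pytest.approx(base, abs=1e-12)
        assert dist(coords + [0.0, 0.0, 5.0]) == pytest.approx(base, abs=1e-12)


class TestInsertionDepth:
    def _scene(self, carbon_z, local_raise=0.0):
        phos = _flat_phosphates(n_per_leaflet=25, z=2.0, spacing=1.0)
        centre = phos[:25, :2].mean(axis=0)
        near = np.linalg.norm(phos[:25, :2] - centre, axis=1) <= 1.0
        phos[:25][near, 2] += local_raise
        carbons = np.array([[centre[0], centre[1], carbon_z],
                            [centre[0], centre[1], carbon_z + 0.3]])
        coords = np.vstack([carbons, phos])
        return coords, np.array([0, 1]), np.arange(2, 2 + len(phos))

    def test_depth_below_local_plane(self):
        coords, anchor, phos = self._scene(carbon_z=2.0 - 1.74)
        assert anchor_insertion_depth(coords, anchor, phos) == pytest.approx(1.74)

    def test_carbon_at_plane_gives_zero(self):
        coords, anchor, phos = self._scene(carbon_z=2.0)
        assert anchor_insertion_depth(coords, anchor, phos) == pytest.approx(0.0)

    def test_local_vs_global_plane_difference(self):
        coords, anchor, phos = self._scene(carbon_z=0.5, local_raise=0.2)
        local = anchor_insertion_depth(coords, anchor, phos, lateral_cutoff=1.0)
        # global reference: average over the whole upper leaflet
        glob = anchor_insertion_depth(coords, anchor, phos, lateral_cutoff=1e9)
        n_up = 25
        n_near = int((np.linalg.norm(
            coords[2:2 + n_up, :2] - coords[:2, :2].mean(axis=0), axis=1)
            <= 1.0).sum())
        expected_gap = 0.2 - 0.2 * n_near / n_up
        assert local - glob == pytest.approx(expected_gap, abs=1e-9)

    def test_coplanar_local_equals_global(self):
        coords, anchor, phos = self._scene(carbon_z=0.8)
        local = anchor_insertion_depth(coords, anchor, phos, lateral_cutoff=1.0)
        glob = anchor_insertion_depth(coords, anchor, phos, lateral_cutoff=1e9)
        assert local == pytest.approx(glob, abs=1e-12)

    def test_empty_anchor_raises(self):
        from memborient.structio import SelectionError
        coords, _, phos = self._scene(carbon_z=1.0)
        with pytest.raises(SelectionError):
            anchor_insertion_depth(coords, np.array([], dtype=int), phos)


class TestDepthSummary:
    def test_constant_series_flagged_degenerate(self):
        s = depth_summary(np.full(20, 1.74))
        assert s["sd"] == 0.0
        assert s["degenerate"] is True
        assert s["shapiro_p"] is None

    def test_gaussian_sample_mean_within_bound(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(1.71, 0.1, size=10_000)
        s = depth_summary(vals)
        assert s["mean"] == pytest.approx(1.71, abs=0.003)  # 3 x SE
        assert s["shapiro_p"] > 0.01
        assert sum(s["histogram"]["counts"]) == 10_000

    def test_small_sample_keeps_moments(self):
        s = depth_summary(np.array([1.0, 1.2, 1.4]))
        assert s["shapiro_w"] is None
        assert s["mean"] == pytest.approx(1.2)
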