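import numpy as np
import pandas as pd
import pytest

from memborient.orientation import (
    DegeneracyError,
    UndefinedTorsionError,
    classify,
    g_vector,
    orientation_records,
    pivot_angle,
    population_summary,
    s_vector,
    torsion_phi,
)

from .helpers import four_point_dihedral_deg

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


def _ellipsoid_cloud(rng=None, n=60, axes=(2.0, 1.0, 1.0)):
    """Evenly distributed surface points (random clouds estimate the axis
    poorly at small n, which would test sampling, not the implementation)."""
    if rng is None:
        from memborient.synthetic import _fibonacci_sphere
        pts = _fibonacci_sphere(n)
    else:
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts * np.array(axes)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestGVector:
    def test_long_axis_of_ellipsoid(self):
        pts = _ellipsoid_cloud(axes=(2.0, 1.0, 1.0))
        g = g_vector(pts, np.arange(len(pts)), previous=X)
        angle = np.degrees(np.arccos(abs(np.clip(g @ X, -1, 1))))
        assert angle < 1.0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = _ellipsoid_cloud(rng)
        g = g_vector(pts, np.arange(len(pts)), previous=X)
        rot = _random_rotation(np.random.default_rng(2))
        g_rot = g_vector(pts @ rot.T, np.arange(len(pts)), previous=rot @ g)
        np.testing.assert_allclose(g_rot, rot @ g, atol=1e-9)

    def test_spherical_cloud_degenerate(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(500, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]  # isotropic sphere
        with pytest.raises(DegeneracyError):
            g_vector(pts, np.arange(len(pts)))


class TestSVector:
    def test_unit_offset_recovered(self):
        g_pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        s_pts = g_pts + np.array([0, 0, -1.0])
        coords = np.vstack([g_pts, s_pts])
        s = s_vector(coords, np.arange(4, 8), np.arange(4))
        np.testing.assert_allclose(s, [0, 0, -1.0], atol=1e-12)

    def test_translation_invariant(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(10, 3))
        s = s_vector(coords, np.arange(6, 10), np.arange(6))
        s2 = s_vector(coords + [5.0, -3.0, 7.0], np.arange(6, 10), np.arange(6))
        np.testing.assert_allclose(s, s2, atol=1e-12)

    def test_switch_face_direction_on_fixture(self):
        from memborient.synthetic import build_protein_fixture
        for seed in range(5):
            system, coords = build_protein_fixture(seed=seed)
            g = np.flatnonzero((system.resids >= 15) & (system.resids <= 184)
                               & (system.names == "CA"))
            sw = np.flatnonzero(
                (((system.resids >= 44) & (system.resids <= 66))
                 | ((system.resids >= 75) & (system.resids <= 91)))
                & (system.names == "CA"))
            s = s_vector(coords, sw, g)
            assert s @ X > 0  # switch face is the +x face by construction

    def test_empty_switch_raises(self):
        from memborient.structio import SelectionError
        with pytest.raises(SelectionError):
            s_vector(np.zeros((4, 3)), np.array([], dtype=int), np.arange(4))


class TestAngles:
    def test_parallel_to_surface_is_ninety(self):
        assert pivot_angle(Z, X) == pytest.approx(90.0)

    def test_aligned_and_antialigned(self):
        assert pivot_angle(Z, Z) == pytest.approx(0.0)
        assert pivot_angle(Z, -Z) == pytest.approx(180.0)

    def test_syn_and_anti_reference_torsions(self):
        assert torsion_phi(Z, X, -Z) == pytest.approx(180.0)
        assert torsion_phi(Z, X, Z) == pytest.approx(0.0)

    def test_matches_four_point_dihedral_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 1000:
            n, G, S = rng.normal(size=(3, 3))
            try:
                mine = torsion_phi(n, G, S)
            except UndefinedTorsionError:
                continue
            n_u, G_u, S_u = (v / np.linalg.norm(v) for v in (n, G, S))
            oracle = four_point_dihedral_deg(n_u, G_u, S_u)
            diff = abs((mine - oracle + 180.0) % 360.0 - 180.0)
            assert diff < 1e-6
            checked += 1

    def test_mirror_symmetry(self):
        """Mirroring S through the n-G plane negates the torsion (mod 360)."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = Z
            G = X
            S = rng.normal(size=3)
            S /= np.linalg.norm(S)
            S_mirror = S * np.array([1.0, -1.0, 1.0])  # n-G plane is y = 0
            try:
                a = torsion_phi(n, G, S)
                b = torsion_phi(n, G, S_mirror)
            except UndefinedTorsionError:
                continue
            assert (a + b) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
                   (a + b) % 360.0 == pytest.approx(360.0, abs=1e-6)

    def test_undefined_when_parallel(self):
        with pytest.raises(UndefinedTorsionError):
            torsion_phi(Z, Z, X)
        with pytest.raises(UndefinedTorsionError):
            torsion_phi(Z, X, X)

    def test_invariance_under_rotation_about_normal(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            G, S = rng.normal(size=(2, 3))
            t = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(t), -np.sin(t), 0],
                            [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
            try:
                base_phi = torsion_phi(Z, G, S)
            except UndefinedTorsionError:
                continue
            assert pivot_angle(Z, rot @ G) == pytest.approx(
                pivot_angle(Z, G), abs=1e-9)
            assert torsion_phi(Z, rot @ G, rot @ S) == pytest.approx(
                base_phi, abs=1e-6)


class TestAngleProperties:
    """Range and consistency invariants over arbitrary vector triples."""

    from hypothesis import given, settings, strategies as st

    vec = st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)).map(
        np.array).filter(lambda v: np.linalg.norm(v) > 1e-3)

    @given(n=vec, G=vec, S=vec)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_ranges_and_label_consistency(self, n, G, S):
        theta = pivot_angle(n, G)
        assert 0.0 <= theta <= 180.0
        try:
            phi = torsion_phi(n, G, S)
        except UndefinedTorsionError:
            return
        assert 0.0 <= phi < 360.0
        label = classify(theta, phi)
        if label == "syn":
            assert 120.0 <= phi <= 240.0
        elif label == "anti":
            assert phi < 60.0 or phi > 300.0
        else:
            assert 60.0 <= phi < 120.0 or 240.0 < phi <= 300.0


class TestClassify:
    @pytest.mark.parametrize("phi,label", [
        (190.0, "syn"),      # the inactive-state population location
        (0.0, "anti"),
        (120.0, "syn"),      # closed syn boundary
        (240.0, "syn"),
        (60.0, "intermediate"),   # anti window is open
        (300.0, "intermediate"),
        (59.9, "anti"),
        (300.1, "anti"),
    ])
    def test_thresholds(self, phi, label):
        assert classify(90.0, phi) == label


class TestPopulationSummary:
    def test_all_syn_fraction_one(self):
        rec = pd.DataFrame({
            "frame": range(5), "theta": [90.0] * 5, "phi": [180.0] * 5,
            "label": ["syn"] * 5, "flagged": [False] * 5,
        })
        assert population_summary(rec)["fractions"]["syn"] == 1.0

    def test_equal_weight_mixture_splits_labels(self, protein_fixture,
                                                membrane_fixture):
        from memborient.synthetic import (AngleMixture, TrajectoryParams,
                                          generate_trajectory)
        protein, pc = protein_fixture
        membrane, mc, _ = membrane_fixture
        params = TrajectoryParams(
            n_frames=1000, seed=17,
            theta=AngleMixture([(95.0, 7.5, 1.0)]),
            phi=AngleMixture([(80.0, 10.0, 0.5), (190.0, 10.0, 0.5)]))
        run = generate_trajectory(protein, pc, membrane, mc, params)
        rec = orientation_records(run.trajectory, run.system, run.regions)
        s = population_summary(rec)
        # the 190-degree component is syn, the 80-degree one is not
        assert s["fractions"]["syn"] == pytest.approx(0.5, abs=0.05)

    def test_circular_mean_recovery(self, protein_fixture, membrane_fixture):
        from memborient.synthetic import (AngleMixture, TrajectoryParams,
                                          generate_trajectory)
        protein, pc = protein_fixture
        membrane, mc, _ = membrane_fixture
        params = TrajectoryParams(
            n_frames=1000, seed=23,
            theta=AngleMixture([(95.0, 5.0, 1.0)]),
            phi=AngleMixture([(190.0, 10.0, 1.0)]))
        run = generate_trajectory(protein, pc, membrane, mc, params)
        rec = orientation_records(run.trajectory, run.system, run.regions)
        s = population_summary(rec)
        assert abs((s["phi_circmean"] - 190.0 + 180.0) % 360.0 - 180.0) < 1.5

    def test_flagged_frames_counted_separately(self):
        rec = pd.DataFrame({
            "frame": [0, 1, 2],
            "theta": [0.0, 90.0, 90.0],
            "phi": [np.nan, 180.0, 10.0],
            "label": ["undefined", "syn", "anti"],
            "flagged": [True, False, False],
        })
        s = population_summary(rec)
        assert s["n_flagged"] == 1
        assert s["fractions"]["syn"] == pytest.approx(0.5)

    def test_no_valid_frames_raises(self):
        rec = pd.DataFrame({"frame": [0], "theta": [0.0], "phi": [np.nan],
                            "label": ["undefined"], "flagged": [True]})
        with pytest.raises(ValueError):
            population_summary(rec)
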