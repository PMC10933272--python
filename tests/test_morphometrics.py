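"""Dataset builders, GPA, shape PCA, PC reconstructions and allometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from osteomap.morphometrics import (
    LandmarkConfiguration,
    PCAResult,
    allometry_test,
    build_diaphysis_dataset,
    build_distal_dataset,
    build_proximal_dataset,
    covariance_pca,
    gpa,
    mirror_distal_landmarks,
    pca,
    procrustes_distance,
    shape_at_pc_extreme,
)
from osteomap.orientation import orient_bone
from osteomap.phantom import (
    anatomical_points,
    distal_landmarks,
    proximal_facet_vertices,
)
from osteomap.volume import LabeledVolume


def _random_config(rng, n=30, sid="s"):
    return LandmarkConfiguration(sid, "distal", rng.normal(size=(21, 3)))


def _rigid_copy(config, rng, sid):
    R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
    scale = rng.uniform(0.5, 2.0)
    t = rng.normal(size=3) * 10
    return LandmarkConfiguration(sid, config.dataset, scale * config.points @ R.T + t)


class TestDatasetBuilders:
    def test_diaphysis_has_882_points(self, curved_phantom):
        _, volume, _, frame = curved_phantom
        cfg = build_diaphysis_dataset(volume, frame)
        assert cfg.points.shape == (882, 3)
        assert cfg.dataset == "diaphysis"

    def test_straight_cylinder_sections_congruent_under_z_shift(self, fine_cylinder):
        _, volume, _, frame = fine_cylinder
        cfg = build_diaphysis_dataset(volume, frame, 0.50, 0.54, 0.02)
        pts = cfg.points.reshape(3, 42, 3)  # 3 sections × (21 ext + 21 int)
        for sec in pts[1:]:
            assert np.allclose(sec[:, :2], pts[0][:, :2], atol=0.2)
            assert np.ptp(sec[:, 2]) < 1e-9

    def test_rigid_motion_equivariance_by_quarter_turn(self, curved_phantom):
        """Rotating the volume 90° about z (exact on the voxel grid) must
        rotate the landmark dataset by the same motion within a voxel."""
        spec, volume, _, frame = curved_phantom
        cfg = build_diaphysis_dataset(volume, frame, 0.50, 0.54, 0.02)

        rot_labels = np.rot90(volume.labels, k=1, axes=(0, 1)).copy()
        # np.rot90(axes=(0,1)): (x, y) -> (-y, x); each grid axis is
        # symmetric about 0, but x/y extents differ, so swap the origin
        rot_origin = volume.origin_mm[[1, 0, 2]]
        rot_vol = LabeledVolume(rot_labels, volume.spacing_mm, rot_origin)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        pts_rot = anatomical_points(spec).transformed(R)
        frame_rot = orient_bone(rot_vol, pts_rot)
        cfg_rot = build_diaphysis_dataset(rot_vol, frame_rot, 0.50, 0.54, 0.02)
        # frame coordinates are intrinsic: the datasets must agree directly
        assert np.max(np.abs(cfg_rot.points - cfg.points)) <= spec.voxel_spacing_mm

    def test_proximal_has_24_ordered_points(self, curved_phantom):
        spec, volume, _, frame = curved_phantom
        cfg = build_proximal_dataset(volume, frame, proximal_facet_vertices(spec))
        assert cfg.points.shape == (24, 3)
        assert cfg.point_roles[:3] == ["landmark"] * 3
        ring = cfg.points[3:]
        assert np.ptp(ring[:, 2]) <= spec.voxel_spacing_mm  # coplanar at 80%

    def test_proximal_rejects_permuted_vertices(self, curved_phantom):
        spec, volume, _, frame = curved_phantom
        verts = proximal_facet_vertices(spec)[[1, 0, 2]]
        with pytest.raises(ValueError, match="order"):
            build_proximal_dataset(volume, frame, verts)

    def test_distal_dataset_and_guards(self, curved_phantom):
        spec, _, _, _ = curved_phantom
        named, ring = distal_landmarks(spec)
        cfg = build_distal_dataset(named, ring)
        assert cfg.points.shape == (21, 3)
        missing = dict(named)
        missing.pop("medial_epicondyle")
        with pytest.raises(ValueError, match="medial_epicondyle"):
            build_distal_dataset(missing, ring)
        dup = dict(named)
        dup["medial_epicondyle"] = dup["lateral_epicondyle"]
        with pytest.raises(ValueError, match="duplicate"):
            build_distal_dataset(dup, ring)

    def test_mirrored_distal_landmarks_swap_roles(self, curved_phantom):
        spec, _, _, _ = curved_phantom
        named, _ = distal_landmarks(spec)
        mirrored = mirror_distal_landmarks(named)
        assert np.allclose(
            mirrored["medial_epicondyle"] * [-1, 1, 1], named["lateral_epicondyle"]
        )
        assert set(mirrored) == set(named)


class TestGPA:
    def test_rigid_copies_align_to_zero_distance(self):
        rng = np.random.default_rng(0)
        base = _random_config(rng)
        configs = [base] + [_rigid_copy(base, rng, f"s{i}") for i in range(7)]
        res = gpa(configs)
        for a in res.aligned:
            for b in res.aligned:
                assert procrustes_distance(a, b) < 1e-8

    def test_two_configurations_match_analytic_ordinary_procrustes(self):
        """GPA of two shapes equals the closed-form two-shape superimposition."""
        from scipy.linalg import orthogonal_procrustes

        rng = np.random.default_rng(1)
        a = _random_config(rng, sid="a")
        b = LandmarkConfiguration("b", "distal", a.points + 0.05 * rng.normal(size=(21, 3)))
        res = gpa([a, b])
        d_ours = procrustes_distance(res.aligned[0], res.aligned[1])

        def standardize(p):
            q = p - p.mean(axis=0)
            return q / np.linalg.norm(q)

        sa, sb = standardize(a.points), standardize(b.points)
        R, _ = orthogonal_procrustes(sb, sa)  # SVD closed form
        d_oracle = np.linalg.norm(sa - sb @ R)
        assert d_ours == pytest.approx(d_oracle, rel=1e-8)

    def test_permutation_invariance_of_mean_shape(self):
        rng = np.random.default_rng(2)
        configs = [
            LandmarkConfiguration(f"s{i}", "distal", rng.normal(size=(21, 3)))
            for i in range(6)
        ]
        m1 = gpa(configs).mean_shape
        m2 = gpa(configs[::-1]).mean_shape
        assert np.allclose(m1, m2, atol=1e-8)

    def test_unit_centroid_size_and_centering(self):
        rng = np.random.default_rng(3)
        res = gpa([_random_config(rng, sid=f"s{i}") for i in range(4)])
        for x in res.aligned:
            assert np.allclose(x.mean(axis=0), 0, atol=1e-12)
            assert np.linalg.norm(x) == pytest.approx(1.0)

    def test_no_reflection_allowed(self):
        rng = np.random.default_rng(4)
        base = _random_config(rng)
        reflected = LandmarkConfiguration("r", "distal", base.points * [-1, 1, 1])
        res = gpa([base, reflected])
        # a reflected shape cannot be brought onto the original by rotation
        assert procrustes_distance(res.aligned[0], res.aligned[1]) > 1e-3

    def test_degenerate_config_rejected(self):
        flat = LandmarkConfiguration("z", "distal", np.zeros((21, 3)))
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="centroid size"):
            gpa([flat, _random_config(rng)])


class TestShapePCA:
    def test_identical_shapes_have_zero_variance(self):
        rng = np.random.default_rng(0)
        base = _random_config(rng)
        configs = [_rigid_copy(base, rng, f"s{i}") for i in range(5)]
        res = pca(gpa(configs))
        assert res.eigenvalues.size == 0 or np.all(res.eigenvalues < 1e-16)

    def test_percent_variance_sums_to_100_and_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        configs = [
            LandmarkConfiguration(f"s{i}", "distal", rng.normal(size=(21, 3)))
            for i in range(8)
        ]
        res = pca(gpa(configs))
        assert res.percent_variance.sum() == pytest.approx(100.0)
        G = res.loadings @ res.loadings.T
        assert np.allclose(G, np.eye(len(res.loadings)), atol=1e-10)

    def test_scores_reproduce_by_projection(self):
        rng = np.random.default_rng(2)
        aligned = gpa(
            [LandmarkConfiguration(f"s{i}", "distal", rng.normal(size=(21, 3))) for i in range(7)]
        )
        res = pca(aligned)
        data = aligned.aligned.reshape(7, -1)
        proj = (data - res.mean_vector) @ res.loadings.T
        assert np.max(np.abs(proj - res.scores)) < 1e-10

    def test_exclusion_by_id(self):
        rng = np.random.default_rng(3)
        aligned = gpa(
            [LandmarkConfiguration(f"s{i}", "distal", rng.normal(size=(21, 3))) for i in range(6)]
        )
        res = pca(aligned, exclude=["s0"])
        assert res.specimen_ids == [f"s{i}" for i in range(1, 6)]
        with pytest.raises(ValueError, match="unknown"):
            pca(aligned, exclude=["nope"])
        with pytest.raises(ValueError, match="at least 3"):
            pca(aligned, exclude=[f"s{i}" for i in range(4)])

    def test_duplicate_specimen_keeps_loading_direction(self):
        """Eigenvector stability: duplicating a specimen of a one-component
        family reweights variance but cannot rotate the loading direction."""
        rng = np.random.default_rng(4)
        mean = rng.normal(size=63)
        direction = rng.normal(size=63)
        direction /= np.linalg.norm(direction)
        ts = [-2.0, -1.0, 0.5, 2.5]
        data = np.stack([mean + t * direction for t in ts])
        ids = [f"s{i}" for i in range(4)]
        res_a = covariance_pca(data, ids)
        res_b = covariance_pca(np.vstack([data, data[:1]]), ids + ["dup"])
        assert abs(res_a.loadings[0] @ res_b.loadings[0]) > 1 - 1e-6


class TestPCExtremes:
    def test_score_zero_is_mean_and_symmetry(self):
        rng = np.random.default_rng(0)
        aligned = gpa(
            [LandmarkConfiguration(f"s{i}", "distal", rng.normal(size=(21, 3))) for i in range(6)]
        )
        res = pca(aligned)
        mean = shape_at_pc_extreme(res, 0, 0.0)
        assert np.allclose(mean.reshape(-1), res.mean_vector)
        plus = shape_at_pc_extreme(res, 0, 0.2)
        minus = shape_at_pc_extreme(res, 0, -0.2)
        assert np.allclose(0.5 * (plus + minus), mean, atol=1e-12)
        with pytest.raises(IndexError):
            shape_at_pc_extreme(res, 99, 0.0)

    def test_reconstruction_identity_on_one_component_family(self):
        """Shapes = mean + t_i · direction: PC1 reconstructs each exactly."""
        rng = np.random.default_rng(1)
        mean = rng.normal(size=(21, 3))
        direction = rng.normal(size=(21, 3))
        direction /= np.linalg.norm(direction)
        ts = np.linspace(-0.01, 0.01, 5)
        data = np.stack([(mean + t * direction).reshape(-1) for t in ts])
        res = covariance_pca(data, [f"s{i}" for i in range(5)])
        for i in range(5):
            rec = res.mean_vector + res.scores[i, 0] * res.loadings[0]
            assert np.allclose(rec, data[i], atol=1e-10)


class TestAllometry:
    @staticmethod
    def _result_with_scores(scores):
        n = len(scores)
        return PCAResult(
            scores=np.asarray(scores, float).reshape(n, 1),
            loadings=np.ones((1, 4)) / 2.0,
            eigenvalues=np.array([1.0]),
            percent_variance=np.array([100.0]),
            mean_vector=np.zeros(4),
            specimen_ids=[f"s{i}" for i in range(n)],
        )

    def test_perfect_linear_signal(self):
        sizes = np.linspace(10, 20, 30)
        res = self._result_with_scores(3.0 * np.log(sizes) - 1.0)
        slope, r2, p = allometry_test(res, sizes, n_permutations=999, seed=0)
        assert slope == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_permuting_scores_destroys_signal(self):
        rng = np.random.default_rng(0)
        sizes = np.linspace(10, 20, 40)
        strong = 2.0 * np.log(sizes)
        rejected = 0
        for rep in range(20):
            shuffled = rng.permutation(strong)
            _, _, p = allometry_test(
                self._result_with_scores(shuffled), sizes, n_permutations=500, seed=rep
            )
            rejected += p <= 0.05
        assert rejected <= 2  # signal destroyed in >= 90% of repeats

    def test_constant_sizes_rejected(self):
        res = self._result_with_scores(np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            allometry_test(res, np.full(5, 3.0))


class TestParameterRecovery:
    def test_diaphyseal_shape_pc1_separates_thickness_groups(self, population_analysis):
        configs = population_analysis["configs"]
        groups = np.array(population_analysis["groups"])
        res = pca(gpa(configs))
        signs = np.sign(res.scores[:, 0])
        acc = max(
            np.mean(signs[groups == "thick"] > 0) / 2 + np.mean(signs[groups == "thin"] < 0) / 2,
            np.mean(signs[groups == "thick"] < 0) / 2 + np.mean(signs[groups == "thin"] > 0) / 2,
        )
        assert acc >= 0.9
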