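"""Atlas construction: rigid alignment, GPA, PCA modes, scores."""

import numpy as np
import pytest

from cardioatlas import (
    SimulationConfig,
    SurfaceMesh,
    build_atlas,
    generalized_procrustes,
    make_template,
    reconstruct_shape,
    rigid_align_pair,
    score_shapes,
    select_modes,
    subgroup_variance_explained,
)
from cardioatlas.atlas import align_atlas_frame, principal_angles_deg, scores_matrix
from cardioatlas.synthdata import sample_shape_population
from cardioatlas.types import ShapeAtlas, meshes_to_matrix


def _rotation(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


class TestRigidAlignPair:
    def test_identity(self):
        t = make_template(60)
        out = rigid_align_pair(t, t)
        assert np.max(np.abs(out.points - t.points)) < 1e-10

    def test_recovers_rigid_transform(self, rng):
        t = make_template(60)
        rot = _rotation(rng.standard_normal(3), 54.0)
        moved = SurfaceMesh("m", t.points @ rot.T + np.array([5.0, -3.0, 11.0]))
        back = rigid_align_pair(moved, t)
        rmsd = np.sqrt(np.mean(np.sum((back.points - t.points) ** 2, axis=1)))
        assert rmsd < 1e-8

    def test_scale_never_removed(self):
        t = make_template(60)
        scaled = SurfaceMesh("s", t.points * 2.0)
        out = rigid_align_pair(scaled, t)
        size_in = np.linalg.norm(scaled.points - scaled.centroid())
        size_out = np.linalg.norm(out.points - out.centroid())
        assert size_out == pytest.approx(size_in, rel=1e-12)
        assert size_out == pytest.approx(2 * np.linalg.norm(t.points - t.centroid()), rel=1e-10)

    def test_rotation_matches_grid_search_oracle(self):
        # 4 asymmetric points rotated 37 degrees about a fixed axis; the
        # best angle on a 0.1-degree grid must be 37, and Kabsch must do at
        # least as well as the best grid rotation.
        pts = np.array([[1.0, 0, 0], [0, 2.0, 0], [0, 0, 3.5], [1.0, 1.0, 0.5]])
        ref = SurfaceMesh("ref", pts)
        axis = np.array([0.3, -0.5, 0.81])
        moved = SurfaceMesh("m", pts @ _rotation(axis, 37.0).T)

        def rmsd_at(angle):
            cand = moved.points @ _rotation(axis, -angle).T
            cand = cand - cand.mean(axis=0) + ref.points.mean(axis=0)
            return np.sqrt(np.mean(np.sum((cand - ref.points) ** 2, axis=1)))

        grid = np.arange(0.0, 360.0, 0.1)
        vals = np.array([rmsd_at(a) for a in grid])
        best = grid[vals.argmin()]
        assert best == pytest.approx(37.0, abs=0.1)
        aligned = rigid_align_pair(moved, ref)
        rmsd_kabsch = np.sqrt(np.mean(np.sum((aligned.points - ref.points) ** 2, axis=1)))
        assert rmsd_kabsch <= vals.min() + 1e-12

    def test_degenerate_rejected(self):
        pts = np.ones((10, 3))
        with pytest.raises(ValueError):
            rigid_align_pair(SurfaceMesh("d", pts), SurfaceMesh("d2", pts + 1))


class TestGeneralizedProcrustes:
    def test_already_aligned_converges_immediately(self, rng):
        t = make_template(60)
        meshes = [
            SurfaceMesh(f"m{i}", t.points - t.points.mean(axis=0)
                        + rng.normal(0, 0.5, size=t.points.shape) * 0)
            for i in range(4)
        ]
        aligned, consensus, n_iter = generalized_procrustes(meshes)
        assert n_iter <= 2
        mean = np.mean([m.points for m in meshes], axis=0)
        mean -= mean.mean(axis=0)
        assert np.max(np.abs(consensus.points - mean)) < 1e-9

    def test_rigid_copies_collapse(self, rng):
        t = make_template(80)
        meshes = []
        for i in range(6):
            rot = _rotation(rng.standard_normal(3), rng.uniform(0, 180))
            meshes.append(SurfaceMesh(f"m{i}", t.points @ rot.T + rng.uniform(-30, 30, 3)))
        aligned, _, _ = generalized_procrustes(meshes)
        stack = meshes_to_matrix(aligned)
        assert np.max(np.abs(stack - stack[0])) < 1e-6

    def test_consensus_is_long_run_fixed_point(self, rng):
        t = make_template(40)
        meshes = [SurfaceMesh(f"m{i}", t.points + rng.normal(0, 2.0, t.points.shape))
                  for i in range(3)]
        _, consensus, _ = generalized_procrustes(meshes, tol_mm=1e-10)
        # independent oracle: run the raw iteration 100 times
        ref = meshes[0].points - meshes[0].points.mean(axis=0)
        cur = list(meshes)
        for _ in range(100):
            cur = [rigid_align_pair(m, SurfaceMesh("r", ref)) for m in cur]
            ref = np.mean([m.points for m in cur], axis=0)
            ref -= ref.mean(axis=0)
        assert np.max(np.abs(consensus.points - ref)) < 1e-7


class TestBuildAtlas:
    def test_two_subjects_single_mode(self, rng):
        t = make_template(40)
        a = SurfaceMesh("a", t.points)
        b = SurfaceMesh("b", t.points + rng.normal(0, 1.0, t.points.shape))
        atlas = build_atlas([a, b])
        assert atlas.eigenvalues[0] > 0
        assert np.all(atlas.eigenvalues[1:] < 1e-10 * atlas.eigenvalues[0])
        assert atlas.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_trace_conservation(self, small_atlas):
        atlas, aligned = small_atlas
        x = meshes_to_matrix(aligned)
        total = np.sum((x - x.mean(axis=0)) ** 2) / (x.shape[0] - 1)
        assert np.sum(atlas.eigenvalues) == pytest.approx(total, rel=1e-8)

    def test_variance_fractions_match_generator(self):
        cfg = SimulationConfig(
            n_subjects=500, n_points=300, n_latent_modes=3, mode_sds=(8.0, 4.0, 2.0),
            noise_sd=0.2, per_mode_h2=(0.0,) * 3, seed=41,
        )
        template = make_template(300)
        meshes, _ = sample_shape_population(cfg, template)
        aligned, _, _ = generalized_procrustes(meshes)
        atlas = build_atlas(aligned)
        # mode k contributes P*sd_k^2 variance (per-point RMS convention),
        # noise contributes noise_sd^2 in each of 3P coordinates
        p = cfg.n_points
        sds = np.array(cfg.mode_sds)
        total = p * np.sum(sds**2) + 3 * p * cfg.noise_sd**2
        theory = (p * sds**2 + cfg.noise_sd**2) / total
        assert np.all(np.abs(atlas.variance_fractions[:3] / theory - 1) < 0.10)

    def test_sign_convention_deterministic(self, small_atlas):
        atlas, aligned = small_atlas
        atlas2 = build_atlas(aligned)
        assert np.array_equal(atlas.modes, atlas2.modes)
        idx = np.argmax(np.abs(atlas.modes), axis=0)
        assert np.all(atlas.modes[idx, np.arange(atlas.n_modes)] > 0)


class TestScores:
    def test_mean_shape_scores_zero(self, small_atlas):
        atlas, _ = small_atlas
        [s] = score_shapes(atlas, [atlas.mean_mesh()], align=False, n_modes=3)
        assert np.max(np.abs(s.z)) < 1e-10

    def test_constructed_two_sd_shape(self, small_atlas):
        atlas, _ = small_atlas
        mesh = reconstruct_shape(atlas, np.array([2.0, 0.0, 0.0]), modes=[0, 1, 2])
        [s] = score_shapes(atlas, [mesh], align=False, n_modes=3)
        assert np.allclose(s.z, [2.0, 0.0, 0.0], atol=1e-8)

    def test_training_scores_unit_variance_uncorrelated(self, small_atlas):
        atlas, aligned = small_atlas
        k = 10
        z = scores_matrix(score_shapes(atlas, aligned, align=False, n_modes=k))
        v = z.var(axis=0, ddof=1)
        assert np.all(np.abs(v - 1.0) < 1e-6)
        c = np.corrcoef(z.T) - np.eye(k)
        assert np.max(np.abs(c)) < 1e-10

    def test_zero_eigenvalue_rejected(self, rng):
        t = make_template(40)
        a = SurfaceMesh("a", t.points)
        b = SurfaceMesh("b", t.points + rng.normal(0, 1.0, t.points.shape))
        atlas = build_atlas([a, b])
        with pytest.raises(ValueError):
            score_shapes(atlas, [a], n_modes=2)


class TestModeSelection:
    @pytest.mark.parametrize(
        "fracs,threshold,expected",
        [
            ((0.5, 0.3, 0.15, 0.04, 0.009), 0.01, [0, 1, 2, 3]),
            ((0.01, 0.005), 0.01, []),  # strict inequality at the boundary
            ((0.6, 0.4), 0.5, [0]),
        ],
    )
    def test_threshold_rule(self, fracs, threshold, expected):
        fracs = np.asarray(fracs, dtype=float)
        lam = np.sort(fracs)[::-1]
        atlas = ShapeAtlas(
            mean_shape=np.zeros(3 * max(4, len(fracs))),
            modes=np.eye(3 * max(4, len(fracs)))[:, : len(fracs)],
            eigenvalues=lam,
            variance_fractions=fracs,
            n_train=10,
        )
        assert select_modes(atlas, threshold) == expected


class TestReconstruction:
    def test_zero_scores_give_mean(self, small_atlas):
        atlas, _ = small_atlas
        m = reconstruct_shape(atlas, np.zeros(3), modes=[0, 1, 2])
        assert np.allclose(m.as_vector(), atlas.mean_shape)

    def test_full_rank_round_trip(self, small_atlas):
        atlas, aligned = small_atlas
        k = int(np.sum(atlas.eigenvalues > 1e-10))
        scores = score_shapes(atlas, aligned[:10], align=False, n_modes=k)
        for mesh, s in zip(aligned[:10], scores):
            recon = reconstruct_shape(atlas, s.z, modes=list(range(k)))
            assert np.max(np.abs(recon.points - mesh.points)) < 1e-6

    def test_out_of_range_mode(self, small_atlas):
        atlas, _ = small_atlas
        with pytest.raises(ValueError):
            reconstruct_shape(atlas, np.zeros(1), modes=[atlas.n_modes])


class TestSubgroupVariance:
    def test_training_set_full_span(self, small_atlas):
        atlas, aligned = small_atlas
        k = int(np.sum(atlas.eigenvalues > 1e-10))
        pct = subgroup_variance_explained(atlas, aligned, list(range(k)), align=False)
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_same_generative_model_high_capture(self):
        # low measurement noise: nearly all subgroup variance lies in the
        # span of the true latent modes
        base = dict(
            n_points=120, n_latent_modes=3, mode_sds=(8.0, 4.0, 2.0),
            noise_sd=0.05, per_mode_h2=(0.0,) * 3,
        )
        template = make_template(120)
        train, _ = sample_shape_population(
            SimulationConfig(n_subjects=300, seed=97, **base), template
        )
        atlas = build_atlas(generalized_procrustes(train)[0])
        meshes, _ = sample_shape_population(
            SimulationConfig(n_subjects=100, seed=99, **base), template, field_seed=97
        )
        pct = subgroup_variance_explained(atlas, meshes, list(range(3)))
        assert pct >= 95.0

    def test_extra_orthogonal_mode_reduces_capture(self, small_atlas, rng):
        atlas, aligned = small_atlas
        # add a new orthogonal mode with power equal to mode 1's
        d = atlas.mean_shape.size
        u = rng.standard_normal(d)
        u -= atlas.modes @ (atlas.modes.T @ u)
        u /= np.linalg.norm(u)
        lam1 = atlas.eigenvalues[0]
        extra = rng.standard_normal(len(aligned)) * np.sqrt(lam1)
        meshes = [
            SurfaceMesh(m.subject_id, (m.as_vector() + e * u).reshape(-1, 3))
            for m, e in zip(aligned, extra)
        ]
        k = int(np.sum(atlas.eigenvalues > 1e-10))
        pct = subgroup_variance_explained(atlas, meshes, list(range(k)), align=False)
        share = extra.var(ddof=1) / (np.sum(atlas.eigenvalues) + extra.var(ddof=1))
        assert pct == pytest.approx(100.0 * (1 - share), abs=1.5)


class TestInvariants:
    def test_rigid_invariance_of_atlas(self, small_population, rng):
        meshes, _ = small_population
        meshes = meshes[:60]
        rot = _rotation(rng.standard_normal(3), 63.0)
        shift = np.array([12.0, -4.0, 7.0])
        moved = [SurfaceMesh(m.subject_id, m.points @ rot.T + shift) for m in meshes]
        a1 = build_atlas(generalized_procrustes(meshes)[0])
        a2 = build_atlas(generalized_procrustes(moved)[0])
        k = 5
        rel = np.abs(a1.eigenvalues[:k] - a2.eigenvalues[:k]) / a1.eigenvalues[:k]
        assert np.max(rel) < 1e-6
        z1 = np.abs(scores_matrix(score_shapes(a1, meshes, n_modes=k)))
        z2 = np.abs(scores_matrix(score_shapes(a2, moved, n_modes=k)))
        assert np.max(np.abs(z1 - z2)) < 1e-6

    def test_mode_subspace_recovery(self):
        cfg = SimulationConfig(
            n_subjects=500, n_points=300, n_latent_modes=5,
            mode_sds=(10.0, 6.0, 4.0, 2.0, 1.0), noise_sd=0.5,
            per_mode_h2=(0.0,) * 5, seed=43,
        )
        template = make_template(300)
        meshes, truth = sample_shape_population(cfg, template)
        aligned, _, _ = generalized_procrustes(meshes)
        atlas = align_atlas_frame(build_atlas(aligned), template)
        angles = principal_angles_deg(truth.displacement_fields, atlas.modes[:, :5])
        assert np.max(angles) < 5.0

    def test_projection_residual_monotone(self, small_atlas):
        from cardioatlas.shape_qc import projection_residual

        atlas, aligned = small_atlas
        mesh = aligned[0]
        res = [projection_residual(atlas, mesh, n_modes=k, align=False)
               for k in range(1, 12)]
        assert np.all(np.diff(res) <= 1e-12)
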