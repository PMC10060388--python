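"""Bending energy, relative warps (shape PCA), shapes, and deformation grids."""

import numpy as np
import pytest
import scipy.linalg

from facemorph.procrustes import generalized_procrustes, tangent_project
from facemorph.relwarps import (
    SingularSystemError,
    _tps_system,
    bending_energy,
    deformation_grid,
    mean_shape,
    relative_warps,
    shape_at_score,
    variance_table,
)


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


class TestBendingEnergy:
    def test_three_points_have_zero_energy(self):
        bem = bending_energy(np.array([[0.0, 0], [1, 0], [0, 1]]))
        assert np.abs(bem.energy_matrix).max() < 1e-9

    def test_affine_displacements_annihilated(self, rng):
        ref = rng.normal(size=(10, 2))
        bem = bending_energy(ref)
        disp = ref @ rng.normal(size=(2, 2)).T + rng.normal(size=2)
        assert abs(bem.energy(disp)) < 1e-9

    def test_symmetric_positive_semidefinite(self, rng):
        bem = bending_energy(rng.normal(size=(12, 2)))
        b = bem.energy_matrix
        assert np.abs(b - b.T).max() < 1e-9
        assert np.linalg.eigvalsh(b).min() > -1e-9

    def test_collinear_reference_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(SingularSystemError):
            bending_energy(pts)

    def test_rigid_invariance_and_size_scaling(self, rng):
        ref = rng.normal(size=(8, 2))
        disp = rng.normal(size=(8, 2))
        e0 = bending_energy(ref).energy(disp)
        moved = ref @ _rot(0.8) + np.array([3.0, -1.0])
        assert bending_energy(moved).energy(disp @ _rot(0.8)) == pytest.approx(e0, rel=1e-9)
        assert bending_energy(ref * 2.0).energy(disp) == pytest.approx(e0 / 4.0, rel=1e-9)

    def test_quadratic_form_matches_integrated_bending(self, rng):
        """Quadrature oracle: v' B v equals the integral of
        f_xx^2 + 2 f_xy^2 + f_yy^2 of the fitted spline, divided by 16*pi
        (the constant for the r^2 log r^2 kernel), to 1% on a 5-point toy."""
        ref = np.array([[0.0, 0], [1, 0.1], [0.2, 1], [1.1, 0.9], [0.5, 0.4]])
        bem = bending_energy(ref)
        v = rng.normal(size=(5, 2)) * 0.1
        l = _tps_system(ref)

        def second_derivs(w, qx, qy):
            dx = qx[..., None] - ref[:, 0]
            dy = qy[..., None] - ref[:, 1]
            r2 = dx * dx + dy * dy
            with np.errstate(divide="ignore", invalid="ignore"):
                lg = np.where(r2 > 0, np.log(r2), 0.0)
                inv = np.where(r2 > 0, 1.0 / np.where(r2 > 0, r2, 1.0), 0.0)
            return (
                (2 * lg + 2 + 4 * dx * dx * inv) @ w,
                (4 * dx * dy * inv) @ w,
                (2 * lg + 2 + 4 * dy * dy * inv) @ w,
            )

        integral = 0.0
        for ax in range(2):
            sol = scipy.linalg.solve(l, np.concatenate([v[:, ax], np.zeros(3)]))
            w = sol[:5]
            xs = np.linspace(-4, 5, 1500)
            h = xs[1] - xs[0]
            gx, gy = np.meshgrid(xs, xs)
            fxx, fxy, fyy = second_derivs(w, gx, gy)
            integral += np.sum(fxx**2 + 2 * fxy**2 + fyy**2) * h * h
            xs2 = np.linspace(-100, 101, 1000)
            h2 = xs2[1] - xs2[0]
            gx, gy = np.meshgrid(xs2, xs2)
            mask = (gx < -4) | (gx > 5) | (gy < -4) | (gy > 5)
            fxx, fxy, fyy = second_derivs(w, gx, gy)
            integral += np.sum((fxx**2 + 2 * fxy**2 + fyy**2)[mask]) * h2 * h2
        assert integral / (16 * np.pi) == pytest.approx(bem.energy(v), rel=0.01)


class TestRelativeWarps:
    def test_eighty_generic_specimens_give_79_pcs(self, study_scale_analysis):
        assert study_scale_analysis["model"].n_components == 79

    def test_rank_one_rows(self, rng):
        direction = rng.normal(size=6)
        rows = np.outer(rng.normal(size=9), direction)
        model = relative_warps(rows)
        assert model.n_components == 1
        assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_from_scores(self, rng):
        rows = rng.normal(size=(12, 8)) * 0.01
        rows -= rows.mean(axis=0)  # consensus-centered rows
        model = relative_warps(rows)
        recon = model.scores @ model.eigenvectors
        np.testing.assert_allclose(recon, rows, atol=1e-8)

    def test_matches_singular_value_oracle(self, study_scale_analysis):
        rows = study_scale_analysis["rows"]
        model = study_scale_analysis["model"]
        centered = rows - rows.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        oracle = sv**2 / (rows.shape[0] - 1)
        np.testing.assert_allclose(model.eigenvalues, oracle[:79], atol=1e-9)

    def test_orthonormal_eigenvectors_and_score_moments(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        gram = model.eigenvectors @ model.eigenvectors.T
        assert np.abs(gram - np.eye(model.n_components)).max() < 1e-8
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(
            model.scores.var(axis=0, ddof=1), model.eigenvalues, rtol=1e-9
        )

    def test_sign_convention_infant_scores_higher(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        ages = study_scale_analysis["dataset"].age_labels()
        diffs = model.scores[ages == "infant"].mean(axis=0) - model.scores[ages == "adult"].mean(axis=0)
        assert np.all(diffs >= -1e-12)

    def test_rigid_motion_of_dataset_leaves_scores_unchanged(self, rng):
        data = rng.normal(size=(10, 7, 2)) * 0.05 + rng.normal(size=(7, 2))
        moved = data @ _rot(1.1) + np.array([5.0, -2.0])
        m1 = relative_warps(tangent_project(generalized_procrustes(data)))
        m2 = relative_warps(tangent_project(generalized_procrustes(moved)))
        np.testing.assert_allclose(np.abs(m1.scores), np.abs(m2.scores), atol=1e-6)

    def test_alpha_requires_bending_energy_model(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            relative_warps(rng.normal(size=(5, 8)), alpha=1.0)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            relative_warps(np.zeros((1, 8)))


class TestVarianceTable:
    def test_single_pc_toy(self, rng):
        rows = np.outer(rng.normal(size=5), rng.normal(size=4))
        vt = variance_table(relative_warps(rows))
        assert len(vt) == 1
        assert vt["cumulative_fraction"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_are_normalized_eigenvalues(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        vt = variance_table(model)
        np.testing.assert_allclose(
            vt["fraction"], model.eigenvalues / model.eigenvalues.sum(), atol=1e-12
        )
        assert np.all(np.diff(vt["cumulative_fraction"]) >= -1e-12)
        assert vt["cumulative_fraction"].iloc[-1] == pytest.approx(1.0, abs=1e-9)


class TestShapeAtScore:
    def test_zero_score_is_consensus(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        np.testing.assert_allclose(shape_at_score(model, 0, 0.0).points, model.consensus)

    def test_symmetry_about_consensus(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        hi = shape_at_score(model, 1, 0.02).points
        lo = shape_at_score(model, 1, -0.02).points
        np.testing.assert_allclose((hi + lo) / 2, model.consensus, atol=1e-12)

    def test_projection_round_trip(self, study_scale_analysis):
        model = study_scale_analysis["model"]
        s = 1.5 * np.sqrt(model.eigenvalues[2])
        shape = shape_at_score(model, 2, s)
        recovered = (shape.points.reshape(-1) - model.consensus.reshape(-1)) @ model.eigenvectors[2]
        assert recovered == pytest.approx(s, abs=1e-9)

    def test_out_of_range_pc(self, study_scale_analysis):
        with pytest.raises(IndexError):
            shape_at_score(study_scale_analysis["model"], 500, 1.0)


class TestMeanShape:
    def test_single_specimen_subset(self, study_scale_analysis):
        fit = study_scale_analysis["fit"]
        m = mean_shape(fit, np.array([3]))
        aligned = fit.aligned[3]
        expect = aligned - aligned.mean(axis=0)
        expect /= np.sqrt(np.sum(expect**2))
        np.testing.assert_allclose(m.points, expect, atol=1e-12)

    def test_full_mean_is_consensus(self, study_scale_analysis):
        fit = study_scale_analysis["fit"]
        np.testing.assert_allclose(mean_shape(fit).points, fit.consensus, atol=1e-6)

    def test_symmetric_pair_mean(self, rng):
        base = rng.normal(size=(9, 2))
        base -= base.mean(axis=0)
        base /= np.sqrt(np.sum(base**2))
        d = rng.normal(size=(9, 2)) * 1e-5  # ensures O(|d|^2) terms below tolerance
        d -= d.mean(axis=0)
        fit = generalized_procrustes(np.stack([base + d, base - d]), tol=1e-12)
        m = mean_shape(fit)
        from facemorph.procrustes import procrustes_distance

        assert procrustes_distance(m.points, base) < 1e-9

    def test_empty_subset_names_predicate(self, study_scale_analysis):
        with pytest.raises(ValueError, match="nobody"):
            mean_shape(study_scale_analysis["fit"], np.zeros(80, bool), name="nobody")


class TestDeformationGrid:
    def test_identity_warp(self, rng):
        ref = rng.normal(size=(6, 2))
        grid = deformation_grid(ref, ref, density=8)
        lo, hi = ref.min(axis=0), ref.max(axis=0)
        pad = 0.05 * (hi - lo)
        xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], 8)
        ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], 8)
        gx, gy = np.meshgrid(xs, ys)
        np.testing.assert_allclose(grid[..., 0], gx, atol=1e-9)
        np.testing.assert_allclose(grid[..., 1], gy, atol=1e-9)

    def test_affine_target_gives_affine_grid(self, rng):
        ref = rng.normal(size=(7, 2))
        a = np.array([[1.2, 0.3], [-0.1, 0.9]])
        b = np.array([0.5, -1.0])
        grid = deformation_grid(ref, ref @ a.T + b, density=5)
        ident = deformation_grid(ref, ref, density=5)
        np.testing.assert_allclose(grid, ident @ a.T + b, atol=1e-8)

    def test_exact_at_landmarks_and_heldout_midpoints(self, rng):
        """Held-out oracle: on a smooth synthetic warp, interpolation error at
        midpoints is far below the warp magnitude."""
        from facemorph.relwarps import tps_warp

        ref = rng.uniform(-1, 1, size=(20, 2))

        def smooth(p):
            return p + 0.05 * np.column_stack([np.sin(p[:, 1]), np.cos(p[:, 0])])

        warp = tps_warp(ref, smooth(ref))
        assert np.abs(warp(ref) - smooth(ref)).max() < 1e-9
        held = (ref[:10] + ref[10:]) / 2
        err = np.abs(warp(held) - smooth(held)).max()
        assert err < 0.01  # warp amplitude is 0.05
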