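"""Ordinary and generalized Procrustes superimposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

import scanmorph as sm
from scanmorph.procrustes import _center_scale, optimal_rotation, tangent_project


def random_config(rng, p=10):
    return rng.normal(size=(p, 3))


def similarity_copy(config, rng, reflect=False):
    r = Rotation.random(random_state=int(rng.integers(2**16))).as_matrix()
    if reflect:
        r = r @ np.diag([1.0, 1.0, -1.0])
    return config @ r * rng.uniform(0.3, 3.0) + rng.normal(size=3)


class TestCentroidSize:
    def test_square_corners(self):
        square = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0],
                           [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
        assert sm.centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_homogeneity(self, rng):
        config = random_config(rng)
        assert sm.centroid_size(2 * config) == pytest.approx(
            2 * sm.centroid_size(config))

    def test_matches_direct_formula(self, rng):
        config = random_config(rng, p=289)
        # coordinate-wise recomputation of the definition
        expected = 0.0
        centroid = config.sum(axis=0) / len(config)
        for point in config:
            for k in range(3):
                expected += (point[k] - centroid[k]) ** 2
        assert sm.centroid_size(config) == pytest.approx(np.sqrt(expected))

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError, match="zero centroid size"):
            sm.centroid_size(np.ones((5, 3)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**16),
           scale=st.floats(0.01, 100.0),
           shift=st.floats(-1e3, 1e3))
    def test_similarity_equivariance(self, seed, scale, shift):
        """Centroid size scales with the configuration and ignores
        rotation and translation."""
        config = np.random.default_rng(seed).normal(size=(7, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        moved = scale * config @ rot + shift
        assert sm.centroid_size(moved) == pytest.approx(
            scale * sm.centroid_size(config), rel=1e-9)


class TestOpa:
    def test_similarity_copy_has_zero_residual(self, rng):
        ref = random_config(rng)
        moved = similarity_copy(ref, rng)
        _, d = sm.opa(moved, ref)
        assert d < 1e-10

    def test_planar_rotation_matches_closed_form(self, rng):
        """For z=0 configs the optimal angle is atan2 of coordinate sums."""
        ref = np.zeros((3, 3))
        ref[:, :2] = rng.normal(size=(3, 2))
        mov = np.zeros((3, 3))
        mov[:, :2] = rng.normal(size=(3, 2))
        x, _ = _center_scale(mov)
        y, _ = _center_scale(ref)
        num = np.sum(x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0])
        den = np.sum(x[:, 0] * y[:, 0] + x[:, 1] * y[:, 1])
        theta = np.arctan2(num, den)
        c, s = np.cos(theta), np.sin(theta)
        expected = x @ np.array([[c, s, 0], [-s, c, 0], [0, 0, 1.0]])
        fitted, _ = sm.opa(mov, ref)
        np.testing.assert_allclose(fitted, expected, atol=1e-12)

    def test_reflection_handling(self, rng):
        ref = random_config(rng)
        mirrored = similarity_copy(ref, rng, reflect=True)
        _, d_proper = sm.opa(mirrored, ref, allow_reflection=False)
        _, d_reflect = sm.opa(mirrored, ref, allow_reflection=True)
        assert d_proper > 1e-3
        assert d_reflect < 1e-10

    def test_matches_scipy_oracle(self, rng):
        ref, _ = _center_scale(random_config(rng))
        mov, _ = _center_scale(random_config(rng))
        fitted, _ = sm.opa(mov, ref, allow_reflection=True)
        r, _ = orthogonal_procrustes(mov, ref)
        np.testing.assert_allclose(fitted, mov @ r, atol=1e-12)

    def test_residual_symmetric(self, rng):
        a = random_config(rng)
        b = random_config(rng)
        _, d_ab = sm.opa(a, b)
        _, d_ba = sm.opa(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            sm.opa(random_config(rng, 5), random_config(rng, 6))


def _brute_force_gpa(coords, rng, tol=1e-12, n_starts=5):
    """Alternating minimization restarted from random reference rotations."""
    best = None
    for _ in range(n_starts):
        aligned = np.stack([_center_scale(c)[0] for c in coords])
        start_rot = Rotation.random(
            random_state=int(rng.integers(2**16))).as_matrix()
        consensus = aligned[0] @ start_rot
        for _ in range(2000):
            for i in range(len(aligned)):
                r, _ = orthogonal_procrustes(aligned[i], consensus)
                if np.linalg.det(r) < 0:
                    u, _, vt = np.linalg.svd(aligned[i].T @ consensus)
                    u[:, -1] *= -1
                    r = u @ vt
                aligned[i] = aligned[i] @ r
            new, _ = _center_scale(aligned.mean(axis=0))
            if np.linalg.norm(new - consensus) < tol:
                break
            consensus = new
        obj = ((aligned - consensus) ** 2).sum()
        if best is None or obj < best[0]:
            best = (obj, aligned, consensus)
    return best


class TestGpa:
    def test_similarity_copies_collapse(self, rng):
        base = random_config(rng, p=8)
        stack = np.stack([similarity_copy(base, rng) for _ in range(6)])
        res = sm.gpa(stack, tol=1e-12)
        assert sm.total_procrustes_variance(res) < 1e-12

    def test_rotation_invariance_of_tangent_coords(self, rng):
        stack = np.stack([random_config(rng, p=8) for _ in range(5)])
        res1 = sm.gpa(stack)
        rot = Rotation.random(random_state=4).as_matrix()
        res2 = sm.gpa(stack @ rot)
        np.testing.assert_allclose(res1.tangent_coords, res2.tangent_coords,
                                   atol=1e-8)

    def test_matches_brute_force_oracle(self, rng):
        base = random_config(rng, p=6)
        stack = np.stack(
            [similarity_copy(base + rng.normal(0, 0.05, base.shape), rng)
             for _ in range(3)])
        res = sm.gpa(stack, tol=1e-12)
        obj_oracle, aligned_oracle, consensus_oracle = \
            _brute_force_gpa(stack, rng)
        obj = ((res.aligned - res.consensus) ** 2).sum()
        assert obj == pytest.approx(obj_oracle, rel=1e-8)
        # consensus agrees up to a rotation of the whole solution
        _, d = sm.opa(res.consensus, consensus_oracle)
        assert d < 1e-6
        fit_rot = optimal_rotation(res.consensus, consensus_oracle)
        np.testing.assert_allclose(
            np.stack([a @ fit_rot for a in res.aligned]),
            aligned_oracle, atol=1e-5)

    def test_objective_monotone_and_aligned_normalized(self, small_study):
        dataset, _ = small_study
        res = sm.gpa(dataset)
        diffs = np.diff(res.objective_history)
        assert np.all(diffs <= 1e-12 * max(res.objective_history))
        centroids = res.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-12
        sizes = np.sqrt((res.aligned**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-12)

    def test_requires_two_specimens(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            sm.gpa(random_config(rng)[None])


class TestTangentProjection:
    def test_consensus_maps_to_zero(self, small_study):
        dataset, _ = small_study
        res = sm.gpa(dataset)
        res2 = sm.ProcrustesResult(
            aligned=res.consensus[None].repeat(2, axis=0),
            consensus=res.consensus,
            centroid_sizes=np.ones(2),
            tangent_coords=np.empty((2, 0)),
            iterations=0, converged=True,
        )
        np.testing.assert_allclose(tangent_project(res2), 0.0, atol=1e-14)

    def test_projection_contracts(self, small_study):
        dataset, _ = small_study
        res = sm.gpa(dataset)
        raw = res.aligned.reshape(len(res.aligned), -1) \
            - res.consensus.reshape(-1)
        proj = res.tangent_coords
        assert np.all(np.linalg.norm(proj, axis=1)
                      <= np.linalg.norm(raw, axis=1) + 1e-15)

    def test_matches_rank_one_projector_oracle(self, rng):
        stack = np.stack([random_config(rng, p=5) for _ in range(4)])
        res = sm.gpa(stack)
        c = res.consensus.reshape(-1)
        c_hat = c / np.linalg.norm(c)
        projector = np.eye(len(c)) - np.outer(c_hat, c_hat)
        flat = res.aligned.reshape(4, -1)
        expected = (flat - c) @ projector
        np.testing.assert_allclose(res.tangent_coords, expected, atol=1e-12)
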