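"""PCA, between-group PCA, LOOCV classification, confusion summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import scanmorph as sm


class TestPca:
    def test_variance_explained_sums_to_100(self, rng):
        res = sm.pca(rng.normal(size=(10, 6)))
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert np.all(res.variance_explained >= 0)

    def test_eigenvalues_match_characteristic_polynomial(self):
        """3 specimens in 2 variables: eigenvalues are the roots of the
        quadratic characteristic polynomial of the 2x2 covariance."""
        y = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 3.0]])
        cov = np.cov(y.T)
        tr, det = cov[0, 0] + cov[1, 1], np.linalg.det(cov)
        disc = np.sqrt(tr**2 - 4 * det)
        roots = sorted([(tr + disc) / 2, (tr - disc) / 2], reverse=True)
        res = sm.pca(y)
        # scores are centered, so singular values give (n-1) * eigenvalue
        eigvals = (res.scores**2).sum(axis=0) / (len(y) - 1)
        np.testing.assert_allclose(eigvals, roots, rtol=1e-10)
        np.testing.assert_allclose(
            res.variance_explained, 100 * np.array(roots) / sum(roots))

    def test_loadings_orthonormal(self, rng):
        res = sm.pca(rng.normal(size=(8, 5)))
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-12)

    def test_pipeline_rotation_invariance(self, small_study):
        """Rotating raw configurations before GPA leaves PCA scores
        unchanged."""
        dataset, _ = small_study
        res1 = sm.pca(sm.gpa(dataset).tangent_coords)
        rot = Rotation.random(random_state=9).as_matrix()
        res2 = sm.pca(sm.gpa(dataset.coords @ rot).tangent_coords)
        np.testing.assert_allclose(np.abs(res1.scores), np.abs(res2.scores),
                                   atol=1e-8)


class TestBgpca:
    def test_two_groups_give_one_axis(self, rng):
        y = rng.normal(size=(12, 7))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = sm.bgpca(y, groups)
        assert res.loadings.shape[1] == 1
        assert res.scores.shape == (12, 1)

    def test_axis_recovers_separating_coordinate(self, rng):
        y = rng.normal(size=(20, 5), scale=0.01)
        y[10:, 0] += 5.0
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = sm.bgpca(y, groups)
        cos = abs(res.loadings[0, 0])
        assert cos > 1 - 1e-5

    def test_three_group_axes_match_hand_eigendecomposition(self):
        means = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 1.0], [0.0, 3.0, -1.0]])
        y = np.repeat(means, 2, axis=0)
        groups = np.repeat(["a", "b", "c"], 2)
        res = sm.bgpca(y, groups)
        grand = means.mean(axis=0)
        centered = means - grand
        vals, vecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(vals)[::-1][:2]
        expected_axes = vecs[:, order]
        for k in range(2):
            cos = abs(res.loadings[:, k] @ expected_axes[:, k])
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_scores_isometric_on_group_means(self, rng):
        """Projected group means preserve the means' pairwise distances
        (the axes span the between-means subspace)."""
        y = rng.normal(size=(18, 9))
        groups = np.repeat(["a", "b", "c"], 6)
        res = sm.bgpca(y, groups)
        means = np.stack([y[groups == g].mean(axis=0) for g in "abc"])
        mean_scores = (means - res.mean) @ res.loadings
        for i in range(3):
            for j in range(i + 1, 3):
                d_full = np.linalg.norm(means[i] - means[j])
                d_proj = np.linalg.norm(mean_scores[i] - mean_scores[j])
                assert d_proj == pytest.approx(d_full, abs=1e-9)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            sm.bgpca(rng.normal(size=(4, 3)), np.array(["a"] * 4))


class TestLoocv:
    def test_separable_groups_classified_perfectly(self, rng):
        y = rng.normal(size=(20, 6))
        y[10:, 0] += 30.0  # between-mean distance 10x within-group spread
        groups = np.array(["a"] * 10 + ["b"] * 10)
        report = sm.loocv_classify(y, groups)
        assert report.accuracy_pct == 100.0
        assert report.kappa == 1.0

    def test_single_member_group_rejected(self, rng):
        y = rng.normal(size=(5, 3))
        groups = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            sm.loocv_classify(y, groups)

    def test_held_out_specimen_not_used_for_its_own_fold(self, rng):
        """The prediction for specimen i matches a direct refit that never
        saw specimen i."""
        y = rng.normal(size=(12, 5))
        y[6:, 1] += 2.0
        groups = np.array(["a"] * 6 + ["b"] * 6)
        report = sm.loocv_classify(y, groups)
        i = 3
        mask = np.arange(12) != i
        fold = sm.bgpca(y[mask], groups[mask])
        means = np.stack([
            y[mask][groups[mask] == g].mean(axis=0) for g in ("a", "b")])
        d = np.linalg.norm(
            (means - fold.mean) @ fold.loadings
            - (y[i] - fold.mean) @ fold.loadings, axis=1)
        expected = ("a", "b")[int(np.argmin(d))]
        # rebuild the per-specimen assignments to compare
        preds = []
        for j in range(12):
            m = np.arange(12) != j
            f = sm.bgpca(y[m], groups[m])
            mm = np.stack([
                y[m][groups[m] == g].mean(axis=0) for g in ("a", "b")])
            dd = np.linalg.norm((mm - f.mean) @ f.loadings
                                - (y[j] - f.mean) @ f.loadings, axis=1)
            preds.append(("a", "b")[int(np.argmin(dd))])
        confusion = pd.crosstab(pd.Series(groups), pd.Series(preds))
        assert report.confusion.to_numpy().sum() == 12
        np.testing.assert_array_equal(
            report.confusion.to_numpy(),
            confusion.reindex(index=["a", "b"],
                              columns=["a", "b"]).fillna(0).to_numpy())
        assert preds[i] == expected


class TestClassificationReport:
    def test_two_class_frequency_table(self):
        confusion = pd.DataFrame([[5, 2], [2, 2]], index=["f", "m"],
                                 columns=["f", "m"])
        report = sm.classification_report(confusion)
        assert report.accuracy_pct == pytest.approx(63.6, abs=0.05)
        np.testing.assert_allclose(
            report.per_class_pct.loc["f"], [71.4, 28.6], atol=0.05)
        np.testing.assert_allclose(
            report.per_class_pct.loc["m"], [50.0, 50.0], atol=1e-12)
        assert report.kappa == pytest.approx(0.214, abs=0.0005)

    def test_kappa_anchors(self):
        perfect = np.diag([4, 6, 2])
        rep = sm.classification_report(perfect)
        assert rep.accuracy_pct == 100.0
        assert rep.kappa == 1.0
        # independence: counts proportional to row x column marginals
        marginal = np.outer([10, 20], [12, 18]) / 30
        rep0 = sm.classification_report(marginal * 30 / 30)
        assert rep0.kappa == pytest.approx(0.0, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(0, 10, size=(3, 3))
        counts[np.diag_indices(3)] += 5
        labels = ["x", "y", "z"]
        base = sm.classification_report(
            pd.DataFrame(counts, index=labels, columns=labels))
        perm = [2, 0, 1]
        permuted = sm.classification_report(pd.DataFrame(
            counts[np.ix_(perm, perm)],
            index=[labels[i] for i in perm],
            columns=[labels[i] for i in perm]))
        assert permuted.accuracy_pct == pytest.approx(base.accuracy_pct)
        assert permuted.kappa == pytest.approx(base.kappa)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            sm.classification_report(np.zeros((2, 2), dtype=int))


class TestAverageReplicates:
    def test_triad_means(self, small_study):
        dataset, _ = small_study
        fit = sm.gpa(dataset)
        avg, fac = sm.classify.average_replicates(
            fit.tangent_coords, dataset.factors)
        n_cells = dataset.factors.groupby(["individual", "device"]).ngroups
        assert avg.shape == (n_cells, fit.tangent_coords.shape[1])
        first = dataset.factors.iloc[0]
        mask = ((dataset.factors["individual"] == first["individual"])
                & (dataset.factors["device"] == first["device"])).to_numpy()
        np.testing.assert_allclose(
            avg[0], fit.tangent_coords[mask].mean(axis=0))
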