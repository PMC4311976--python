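"""Penalized discriminant analysis: penalty, fitting, df, CV selection."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.linalg import splu

from diamorph import pda
from diamorph.pda import (
    CylinderPenalty,
    classify,
    effective_df,
    fit_pda,
    flatten_maps,
    loading_map,
    make_folds,
    penalty_matrix,
    project,
    select_lambda,
    split_train_test,
)

TOY = (3, 4)  # small cylinder grid for dense oracles


def toy_design(seed=0, n_per=10, sep=2.0):
    rng = np.random.default_rng(seed)
    p = TOY[0] * TOY[1]
    mus = rng.normal(scale=sep, size=(3, p))
    x = np.vstack([rng.normal(size=(n_per, p)) + mus[i] for i in range(3)])
    labels = np.repeat(["a", "b", "c"], n_per)
    return x, labels


class TestPenaltyMatrix:
    def test_constant_vector_in_null_space(self):
        omega = penalty_matrix(*TOY)
        assert np.abs(omega @ np.ones(omega.shape[0])).max() == 0.0
        omega_big = penalty_matrix()
        assert np.abs(omega_big @ np.ones(6120)).max() < 1e-9

    def test_symmetric_positive_semidefinite(self):
        omega = penalty_matrix(*TOY).toarray()
        np.testing.assert_allclose(omega, omega.T)
        evals = np.linalg.eigvalsh(omega)
        assert evals.min() > -1e-10

    def test_spike_rougher_than_ramp(self):
        omega = penalty_matrix(*TOY)
        spike = np.zeros(12)
        spike[5] = 1.0
        ramp = np.tile(np.linspace(-1, 1, TOY[0]), (TOY[1], 1)).T.ravel()
        ramp /= np.linalg.norm(ramp)
        assert spike @ (omega @ spike) > ramp @ (omega @ ramp)

    def test_matches_brute_force_neighbor_sums(self):
        """Omega's quadratic form equals the summed squared graph-Laplacian
        output (wrap in degrees, free ends in sections) on a 3x4 grid."""
        omega = penalty_matrix(*TOY).toarray()
        rng = np.random.default_rng(0)
        v = rng.normal(size=TOY)

        lap = np.roll(v, 1, 1) + np.roll(v, -1, 1) - 2 * v
        lap[1:] += v[:-1] - v[1:]
        lap[:-1] += v[1:] - v[:-1]
        assert v.ravel() @ omega @ v.ravel() == pytest.approx(np.sum(lap**2), rel=1e-12)

    def test_spectral_solve_matches_sparse_lu(self):
        pen = CylinderPenalty((5, 12))
        omega = pen.matrix()
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 60))
        lam, eps = 0.7, 1e-3
        a = (lam * omega + eps * sp.identity(60)).tocsc()
        ref = splu(a).solve(x.T).T
        np.testing.assert_allclose(pen.solve(lam, eps, x), ref, atol=1e-9)


class TestSplitAndFolds:
    def test_default_split_sizes_and_composition(self):
        labels = np.repeat(["A", "B", "C"], [14, 14, 15])
        train, test = split_train_test(labels, per_group_train=12, seed=0)
        assert len(train) == 36 and len(test) == 7
        comp = dict(zip(*np.unique(labels[test], return_counts=True)))
        assert comp == {"A": 2, "B": 2, "C": 3}
        assert set(train) | set(test) == set(range(43))

    def test_split_deterministic_given_seed(self):
        labels = np.repeat(["A", "B", "C"], [14, 14, 15])
        t1, s1 = split_train_test(labels, seed=5)
        t2, s2 = split_train_test(labels, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(s1, s2)
        t3, _ = split_train_test(labels, seed=6)
        assert not np.array_equal(t1, t3)

    def test_small_group_rejected(self):
        labels = np.repeat(["A", "B", "C"], [11, 14, 15])
        with pytest.raises(ValueError, match="11"):
            split_train_test(labels, per_group_train=12, seed=0)

    def test_folds_partition_one_per_group(self):
        codes = np.repeat([0, 1, 2], 12)
        rng = np.random.default_rng(0)
        folds = make_folds(codes, 12, rng)
        assert len(folds) == 12
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(36))
        for f in folds:
            assert len(f) == 3
            assert sorted(codes[f]) == [0, 1, 2]

    def test_unbalanced_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.repeat([0, 1], [12, 11]), 12, np.random.default_rng(0))


class TestFitPDA:
    def test_separable_groups_zero_training_errors(self):
        x, labels = toy_design(seed=0, sep=3.0)
        model = fit_pda(x, labels, lam=1e-4, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        assert model.training_errors_ == 0
        assert model.n_discriminants == 2

    def test_unpenalized_underdetermined_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 12))
        labels = ["a", "a", "b", "b", "c", "c"]
        with pytest.raises(ValueError, match="lambda"):
            fit_pda(x, labels, lam=0.0, penalty=CylinderPenalty(TOY), eps=0.0,
                    grid_shape=TOY)

    def test_duplicated_rows_same_directions(self):
        x, labels = toy_design(seed=1)
        m1 = fit_pda(x, labels, lam=0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        m2 = fit_pda(
            np.vstack([x, x]), np.concatenate([labels, labels]), lam=0.5,
            penalty=CylinderPenalty(TOY), grid_shape=TOY,
        )
        for k in range(2):
            a = m1.coef_[:, k] / np.linalg.norm(m1.coef_[:, k])
            b = m2.coef_[:, k] / np.linalg.norm(m2.coef_[:, k])
            assert abs(a @ b) == pytest.approx(1.0, abs=1e-6)

    def test_ridge_penalty_matches_regularized_lda_oracle(self):
        """With an identity penalty, optimal-scoring loadings span the same
        directions as the generalized eigenvectors of (S_B, S_W + lam I)."""
        x, labels = toy_design(seed=2, n_per=12)
        lam, eps = 3.0, 1e-9
        model = fit_pda(x, labels, lam, penalty=sp.identity(x.shape[1], format="csr"),
                        eps=eps)
        xc = x - x.mean(axis=0)
        p = x.shape[1]
        sb = np.zeros((p, p))
        sw = np.zeros((p, p))
        for g in np.unique(labels):
            xi = xc[np.asarray(labels) == g]
            mu = xi.mean(axis=0)
            sb += len(xi) * np.outer(mu, mu)
            sw += (xi - mu).T @ (xi - mu)
        # per-sample-averaged loss: the effective penalty weight is n*lam
        w, v = eigh(sb, sw + x.shape[0] * (lam + eps) * np.eye(p))
        v = v[:, np.argsort(w)[::-1][:2]]
        for k in range(2):
            a = model.coef_[:, k] / np.linalg.norm(model.coef_[:, k])
            b = v[:, k] / np.linalg.norm(v[:, k])
            assert abs(a @ b) == pytest.approx(1.0, abs=1e-6)

    def test_large_lambda_smooth_loadings(self):
        x, labels = toy_design(seed=3)
        pen = CylinderPenalty(TOY)
        omega = pen.matrix()
        lams = [1e-2, 1e2, 1e6]
        rough = []
        for lam in lams:
            m = fit_pda(x, labels, lam, penalty=pen, grid_shape=TOY)
            b = m.coef_[:, 0] / np.linalg.norm(m.coef_[:, 0])
            rough.append(b @ (omega @ b))
        assert rough[0] > rough[1] > rough[2]

    def test_discriminants_penalized_orthogonal(self):
        x, labels = toy_design(seed=4)
        lam = 0.8
        pen = CylinderPenalty(TOY)
        model = fit_pda(x, labels, lam, penalty=pen, grid_shape=TOY)
        xc = x - x.mean(axis=0)
        a = (lam * pen.matrix() + model.eps * sp.identity(x.shape[1])).toarray()
        metric = xc.T @ xc + x.shape[0] * a
        b1, b2 = model.coef_[:, 0], model.coef_[:, 1]
        cross = b1 @ metric @ b2
        norm = np.sqrt((b1 @ metric @ b1) * (b2 @ metric @ b2))
        assert abs(cross) / norm < 1e-8


class TestEffectiveDF:
    def test_monotone_and_bounded(self):
        x, _ = toy_design(seed=5)
        pen = CylinderPenalty(TOY)
        lams = np.logspace(-4, 8, 15)
        dfs = [effective_df(l, pen, x) for l in lams]
        assert all(np.diff(dfs) <= 1e-9)
        assert dfs[0] <= min(x.shape[0] - 1, x.shape[1]) + 1e-6

    def test_large_lambda_df_approaches_null_space_dim(self):
        x, _ = toy_design(seed=6)
        pen = CylinderPenalty(TOY)
        assert effective_df(1e12, pen, x) == pytest.approx(1.0, abs=0.05)

    def test_matches_dense_eigendecomposition_oracle(self):
        x, _ = toy_design(seed=7)
        pen = CylinderPenalty(TOY)
        lam = 2.5
        eps = pda._default_eps(x)
        xc = x - x.mean(axis=0)
        a = x.shape[0] * (lam * pen.matrix().toarray() + eps * np.eye(x.shape[1]))
        hat = xc @ np.linalg.solve(xc.T @ xc + a, xc.T)
        assert effective_df(lam, pen, x) == pytest.approx(np.trace(hat), rel=1e-6)


class TestProjectClassify:
    def test_training_centroids_reproduced(self):
        x, labels = toy_design(seed=8)
        model = fit_pda(x, labels, 0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        scores = project(model, x)
        for i, g in enumerate(model.classes_):
            np.testing.assert_allclose(
                scores[np.asarray(labels) == g].mean(axis=0),
                model.centroids_[i],
                atol=1e-8,
            )

    def test_adding_constant_map_shifts_scores_rigidly(self):
        # projection is affine in x: adding one constant map to every row
        # shifts all scores equally, so relative positions are invariant
        x, labels = toy_design(seed=9)
        model = fit_pda(x, labels, 0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        s1 = project(model, x)
        s2 = project(model, x + 3.7)
        np.testing.assert_allclose(s1 - s1[0], s2 - s2[0], atol=1e-9)

    def test_centroid_classifies_as_own_label(self):
        x, labels = toy_design(seed=10, sep=3.0)
        model = fit_pda(x, labels, 0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        for i, g in enumerate(model.classes_):
            xi = x[np.asarray(labels) == g].mean(axis=0, keepdims=True)
            assert classify(model, xi)[0] == g

    def test_tie_breaks_to_first_class(self):
        x, labels = toy_design(seed=11)
        model = fit_pda(x, labels, 0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        # a point equidistant from two centroids in discriminant space:
        # solve for x-scores at the midpoint of centroids a and b
        model.centroids_[1] = model.centroids_[0]  # force exact tie
        mid = x[:1]
        assert classify(model, mid)[0] in (model.classes_[0],)

    def test_loading_map_round_trip(self):
        x, labels = toy_design(seed=12)
        model = fit_pda(x, labels, 0.5, penalty=CylinderPenalty(TOY), grid_shape=TOY)
        lm = loading_map(model, 1)
        assert lm.values.shape == TOY
        np.testing.assert_array_equal(lm.values.ravel(), model.coef_[:, 0])
        assert set(np.unique(lm.sign)) <= {-1, 1}
        with pytest.raises(ValueError):
            loading_map(model, 3)


class TestSelectLambda:
    def test_single_lambda_grid_returns_it(self):
        x, labels = toy_design(seed=13, n_per=4)
        sel = select_lambda(
            x, labels, penalty=CylinderPenalty(TOY), lambda_grid=np.array([0.7]),
            n_folds=4, repeats=3, seed=0, grid_shape=TOY,
        )
        assert sel.lambda_ == 0.7

    def test_single_repeat_warns(self):
        x, labels = toy_design(seed=14, n_per=4)
        with pytest.warns(UserWarning, match="repeat"):
            select_lambda(
                x, labels, penalty=CylinderPenalty(TOY),
                lambda_grid=np.array([0.1, 1.0]), n_folds=4, repeats=1, seed=0,
                grid_shape=TOY,
            )

    def test_separable_cohort_selects_lowest_df(self):
        x, labels = toy_design(seed=15, n_per=6, sep=6.0)
        sel = select_lambda(
            x, labels, penalty=CylinderPenalty(TOY),
            lambda_grid=np.logspace(-4, 6, 8), n_folds=6, repeats=10, seed=0,
            grid_shape=TOY,
        )
        assert sel.admissible.sum() >= 2  # many lambdas admissible
        assert sel.df_ == pytest.approx(sel.df_grid[sel.admissible].min())

    def test_deterministic_given_seed(self):
        x, labels = toy_design(seed=16, n_per=4)
        kw = dict(penalty=CylinderPenalty(TOY), lambda_grid=np.logspace(-2, 2, 4),
                  n_folds=4, repeats=5, grid_shape=TOY)
        s1 = select_lambda(x, labels, seed=3, **kw)
        s2 = select_lambda(x, labels, seed=3, **kw)
        assert s1.lambda_ == s2.lambda_
        np.testing.assert_array_equal(s1.errors, s2.errors)


class TestFlattenMaps:
    def test_raster_order_and_shape(self):
        m = np.arange(12.0).reshape(TOY)
        x = flatten_maps([m, 2 * m])
        assert x.shape == (2, 12)
        np.testing.assert_array_equal(x[0], m.ravel())
        with pytest.raises(ValueError):
            flatten_maps([m, np.zeros((4, 4))])
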