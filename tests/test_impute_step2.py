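import numpy as np
import pytest

import mbimpute as mb
from mbimpute._lasso import lambda_max, objective, solve_weighted_lasso
from mbimpute.impute_step2 import build_design, predict_matrix
from mbimpute.io_preprocess import ABUNDANCE_FLOOR


def fista_oracle(X, y, w, lam, n_iter=200000, tol=1e-12):
    """Independent proximal-gradient (FISTA) solver for
    ||y - Xb||^2 + lam * sum w_j |b_j|; dense, deliberately naive."""
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    L = 2.0 * np.linalg.norm(X, 2) ** 2
    b = np.zeros(X.shape[1])
    z = b.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = 2.0 * X.T @ (X @ z - y)
        step = z - grad / L
        thr = lam * np.asarray(w) / L
        b_new = np.sign(step) * np.maximum(np.abs(step) - thr, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = b_new + ((t - 1) / t_new) * (b_new - b)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b, t = b_new, t_new
    return b


class TestNeighborSets:
    def test_full_neighbor_set(self):
        D = mb.PhyloDistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        nb = mb.select_neighbor_taxa(D, 3)
        for j in range(4):
            assert set(nb.indices[j]) == set(range(4)) - {j}

    def test_index_tie_break(self):
        D = mb.PhyloDistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        nb = mb.select_neighbor_taxa(D, 2)
        np.testing.assert_array_equal(nb.indices[1], [0, 2])

    def test_self_excluded(self):
        rng = np.random.default_rng(0)
        Dv = rng.uniform(1, 5, (6, 6))
        Dv = (Dv + Dv.T) / 2
        np.fill_diagonal(Dv, 0)
        D = mb.PhyloDistanceMatrix(Dv, [f"t{j}" for j in range(6)])
        nb = mb.select_neighbor_taxa(D, 5)
        for j in range(6):
            assert j not in nb.indices[j]

    def test_k_out_of_range(self):
        D = mb.PhyloDistanceMatrix(np.ones((3, 3)) - np.eye(3), list("abc"))
        with pytest.raises(ValueError):
            mb.select_neighbor_taxa(D, 3)


class TestBuildDesign:
    def _inputs(self, n=5, m=10, k=3, q=2, seed=0):
        rng = np.random.default_rng(seed)
        Y = mb.AbundanceMatrix(
            rng.uniform(1, 5, (n, m)),
            [f"s{i}" for i in range(n)], [f"t{j}" for j in range(m)],
        )
        cols = [np.ones(n)] + [rng.standard_normal(n) for _ in range(q - 1)]
        X = mb.CovariateMatrix(
            np.column_stack(cols), ["intercept"] + [f"c{l}" for l in range(q - 1)]
        )
        Dv = rng.uniform(1, 5, (m, m))
        Dv = (Dv + Dv.T) / 2
        np.fill_diagonal(Dv, 0)
        D = mb.PhyloDistanceMatrix(Dv, Y.taxon_ids)
        mask = mb.MissingMask(rng.random((n, m)) < 0.2, 0.5)
        nb = mb.select_neighbor_taxa(D, k)
        return Y, X, D, mask, nb

    def test_parameter_count(self):
        Y, X, D, mask, nb = self._inputs()
        prob = build_design(Y, X, mask, nb, D, psi=1.0)
        assert prob.matrix.shape[1] == 10 * 3 + 5 * 4 + 10 * 2  # 70
        assert prob.n_params == 70

    def test_structural_nonzeros_per_row(self):
        Y, X, D, mask, nb = self._inputs()
        prob = build_design(Y, X, mask, nb, D, psi=1.0)
        csr = prob.matrix.tocsr()
        nnz = np.diff(csr.indptr)
        assert np.all(nnz == 3 + 4 + 2)  # k + (n-1) + q

    def test_psi_zero_unit_weights(self):
        Y, X, D, mask, nb = self._inputs()
        prob = build_design(Y, X, mask, nb, D, psi=0.0)
        m, k, n = 10, 3, 5
        np.testing.assert_array_equal(prob.penalty_weights[: m * k], 1.0)
        np.testing.assert_array_equal(
            prob.penalty_weights[m * k : m * k + n * (n - 1)], 1.0
        )
        np.testing.assert_array_equal(prob.penalty_weights[m * k + n * 4 :], 0.0)

    def test_no_covariate_column_count(self):
        Y, X, D, mask, nb = self._inputs()
        prob = build_design(Y, None, mask, nb, D, psi=1.0)
        assert prob.matrix.shape[1] == 10 * 3 + 5 * 4

    def test_empty_omega_rejected(self):
        Y, X, D, mask, nb = self._inputs()
        full = mb.MissingMask(np.ones_like(mask.flags), 0.5)
        with pytest.raises(ValueError, match="train"):
            build_design(Y, X, full, nb, D, psi=1.0)


class TestSolverAgainstOracle:
    def test_matches_proximal_gradient(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        prob = build_design(Y, X, mask, nb, D, psi=1.0)
        y = prob.response
        for lam in [0.5, 1.0, 5.0]:
            beta, _, _, conv = solve_weighted_lasso(
                prob.matrix, y, prob.penalty_weights, lam, tol=1e-10,
                max_sweeps=50000,
            )
            assert conv
            oracle = fista_oracle(prob.matrix, y, prob.penalty_weights, lam)
            assert np.max(np.abs(beta - oracle)) < 1e-4

    def test_objective_nonincreasing_along_path(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        prob = build_design(Y, X, mask, nb, D, psi=1.0)
        y = prob.response
        w = prob.penalty_weights
        lam_hi = lambda_max(prob.matrix, y, w)
        lams = np.geomspace(lam_hi, lam_hi * 1e-3, 12)
        beta = None
        prev_sse = np.inf
        for lam in lams:
            beta, resid, _, _ = solve_weighted_lasso(
                prob.matrix, y, w, lam, beta0=beta, tol=1e-10,
                max_sweeps=50000,
            )
            sse = float(resid @ resid)
            assert sse <= prev_sse + 1e-8
            prev_sse = sse

    def test_monotone_penalty_in_distance(self, tiny_problem):
        """Raising one taxon pair's distance never grows |kappa| there."""
        Y, X, D, mask, nb = tiny_problem
        lam = 0.5
        j, rank = 0, 0
        jp = nb.indices[j, rank]
        col = j * nb.k + rank
        kappas = []
        for scale in [1.0, 2.0, 4.0]:
            Dv = D.values.copy()
            Dv[j, jp] = Dv[jp, j] = D.values[j, jp] * scale
            D2 = mb.PhyloDistanceMatrix(Dv, D.taxon_ids)
            prob = build_design(Y, X, mask, nb, D2, psi=1.0)
            beta, _, _, _ = solve_weighted_lasso(
                prob.matrix, prob.response, prob.penalty_weights, lam,
                tol=1e-10, max_sweeps=50000,
            )
            kappas.append(abs(beta[col]))
        assert kappas[0] >= kappas[1] >= kappas[2] - 1e-12


class TestFitAndImpute:
    def test_full_shrinkage_limit(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        prob = build_design(Y, X, mask, nb, D, psi=1.0)
        lam_hi = lambda_max(prob.matrix, prob.response, prob.penalty_weights)
        model = mb.fit_penalized(
            Y, X, mask, nb, D, psi_grid=[1.0],
            lambda_grid=[2 * lam_hi], cv_folds=2, seed=0,
        )
        assert np.all(model.kappa == 0)
        assert np.all(model.tau == 0)
        # predictions reduce to the per-taxon covariate regression
        pred = predict_matrix(Y, model, X)
        keep = ~mask.flags
        for j in range(Y.values.shape[1]):
            rows = keep[:, j]
            coef, *_ = np.linalg.lstsq(
                X.values[rows], Y.values[rows, j], rcond=None
            )
            np.testing.assert_allclose(
                pred[rows, j], X.values[rows] @ coef, atol=1e-5
            )

    def test_omega_entries_bit_exact(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        model = mb.fit_penalized(
            Y, X, mask, nb, D, psi_grid=[0.0, 1.0], n_lambda=8,
            cv_folds=3, seed=0,
        )
        result = mb.impute(Y, model, mask, X)
        keep = ~mask.flags
        assert np.array_equal(
            result.Y_imputed.values[keep], Y.values[keep]
        )
        assert np.all(result.Y_imputed.values >= ABUNDANCE_FLOOR)

    def test_empty_mask_is_noop(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        model = mb.fit_penalized(
            Y, X, mask, nb, D, psi_grid=[1.0], n_lambda=5, cv_folds=2, seed=0
        )
        empty = mb.MissingMask(np.zeros_like(mask.flags), 0.5)
        result = mb.impute(Y, model, empty, X)
        np.testing.assert_array_equal(result.Y_imputed.values, Y.values)

    def test_no_covariate_variant_matches_intercept_fit(self, tiny_problem):
        """With per-column-centered Y and intercept-only X, the two
        variants coincide exactly in the strong-shrinkage limit, and at
        moderate shrinkage they differ only through the (small, unpenalized)
        per-taxon intercepts."""
        Y, X, D, mask, nb = tiny_problem
        vals = Y.values.copy()
        for j in range(vals.shape[1]):
            rows = ~mask.flags[:, j]
            vals[:, j] -= vals[rows, j].mean()
        Yc = mb.AbundanceMatrix(vals, Y.sample_ids, Y.taxon_ids)

        prob = build_design(Yc, X, mask, nb, D, psi=1.0)
        lam_hi = lambda_max(prob.matrix, prob.response, prob.penalty_weights)
        with_x = mb.fit_penalized(
            Yc, X, mask, nb, D, psi_grid=[1.0], lambda_grid=[2 * lam_hi],
            cv_folds=2, seed=0,
        )
        without = mb.fit_no_covariates(
            Yc, mask, nb, D, psi_grid=[1.0], lambda_grid=[2 * lam_hi],
            cv_folds=2, seed=0,
        )
        pa = predict_matrix(Yc, with_x, X)
        pb = predict_matrix(Yc, without, None)
        # intercepts equal the (zero) column means: exact agreement
        np.testing.assert_allclose(pa, pb, atol=1e-9)

        lam = 0.5
        with_x = mb.fit_penalized(
            Yc, X, mask, nb, D, psi_grid=[1.0], lambda_grid=[lam],
            cv_folds=2, seed=0,
        )
        without = mb.fit_no_covariates(
            Yc, mask, nb, D, psi_grid=[1.0], lambda_grid=[lam],
            cv_folds=2, seed=0,
        )
        pa = predict_matrix(Yc, with_x, X)
        pb = predict_matrix(Yc, without, None)
        gap = np.max(np.abs(pa - pb))
        assert gap <= 2 * np.max(np.abs(with_x.zeta)) + 1e-9

    def test_no_covariate_full_shrinkage_predicts_zero(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        prob = build_design(Y, None, mask, nb, D, psi=1.0)
        lam_hi = lambda_max(prob.matrix, prob.response, prob.penalty_weights)
        model = mb.fit_no_covariates(
            Y, mask, nb, D, psi_grid=[1.0], lambda_grid=[2 * lam_hi],
            cv_folds=2, seed=0,
        )
        np.testing.assert_array_equal(predict_matrix(Y, model, None), 0.0)

    def test_kappa_support_inside_neighbor_sets(self, tiny_problem):
        Y, X, D, mask, nb = tiny_problem
        model = mb.fit_penalized(
            Y, X, mask, nb, D, psi_grid=[0.0], n_lambda=8, cv_folds=2, seed=0
        )
        assert np.all(np.diag(model.kappa) == 0)
        assert np.all(np.diag(model.tau) == 0)
        m = Y.values.shape[1]
        allowed = np.zeros((m, m), dtype=bool)
        for j in range(m):
            allowed[j, nb.indices[j]] = True
        assert np.all(model.kappa[~allowed] == 0)


class TestBackTransform:
    def test_floor_maps_to_zero_count(self):
        Y = mb.AbundanceMatrix(
            np.full((2, 2), ABUNDANCE_FLOOR), ["a", "b"], ["x", "y"]
        )
        res = mb.ImputedResult(Y, mb.MissingMask(np.zeros((2, 2), bool), 0.5))
        norm, orig = mb.back_transform(res, np.array([1e6, 1e6]))
        np.testing.assert_allclose(norm, 0.0, atol=1e-12)

    def test_round_trip_and_library_scaling(self):
        rng = np.random.default_rng(4)
        counts = mb.CountMatrix(
            rng.integers(0, 100, (3, 4)).astype(float) + 1,
            ["a", "b", "c"], list("wxyz"),
        )
        Mn = mb.normalize_counts(counts)
        Y = mb.log_transform(Mn)
        res = mb.ImputedResult(Y, mb.MissingMask(np.zeros((3, 4), bool), 0.5))
        norm, orig = mb.back_transform(res, Mn.library_sizes)
        np.testing.assert_allclose(norm, Mn.values, rtol=1e-9)
        np.testing.assert_allclose(orig, counts.values, rtol=1e-9)
        norm2, orig2 = mb.back_transform(res, 2 * Mn.library_sizes)
        np.testing.assert_allclose(orig2, 2 * orig, rtol=1e-12)


class TestPermutationEquivariance:
    def test_sample_permutation(self):
        """Permuting sample order permutes the imputed matrix identically."""
        cfg = mb.SimulationConfig(n=14, m=12, scheme="all", seed=3,
                                  taxon_block_size=4)
        ds = mb.simulate(cfg)
        perm = np.random.default_rng(0).permutation(cfg.n)

        def run(Y, X):
            return mb.impute_abundance(
                Y, X, ds.D, psi_grid=[0.0, 1.0], n_lambda=8, cv_folds=3,
                seed=5,
            ).Y_imputed.values

        base = run(ds.Y_observed, ds.X)
        Yp = mb.AbundanceMatrix(
            ds.Y_observed.values[perm],
            [ds.Y_observed.sample_ids[i] for i in perm],
            ds.Y_observed.taxon_ids,
        )
        Xp = mb.CovariateMatrix(ds.X.values[perm], ds.X.column_names)
        permuted = run(Yp, Xp)
        # tolerance covers coordinate-descent path noise from the permuted
        # column ordering; the fit itself is order-free
        np.testing.assert_allclose(permuted, base[perm], atol=5e-4)
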