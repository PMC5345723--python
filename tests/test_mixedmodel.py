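"""REML/BLUP solver: MME structure, likelihood, oracles, convergence."""

import numpy as np
import pytest

from singlestep import (
    CovarianceStructures, RelationshipMatrix, RemlOptions, TraitDataset,
    aic, blup_solve, build_A, build_A_inverse, build_mme, reml_fit,
    read_phenotypes, standardize, PedigreeTable,
)
from singlestep.mixedmodel import _ModelFrame


def halfsib_pedigree(s, k):
    recs = [(f"M{f}", None, None) for f in range(s)]
    recs += [(f"M{f}_O{j}", f"M{f}", None) for f in range(s) for j in range(k)]
    return PedigreeTable.from_records(recs)


def simulate_halfsib(s, k, sa2, se2, rng):
    ped = halfsib_pedigree(s, k)
    off = [i for i in ped.ids if "_O" in i]
    fam_eff = rng.standard_normal(s) * np.sqrt(sa2 / 4)
    resid = rng.standard_normal(s * k) * np.sqrt(0.75 * sa2 + se2)
    y = np.repeat(fam_eff, k) + resid
    ds = TraitDataset(tuple(off), tuple(i.split("_")[0] for i in off), None,
                      y.reshape(-1, 1), ("t",), np.zeros(len(off), bool))
    return ped, ds


class TestStandardize:
    def test_z_scores_and_idempotence(self):
        ds = TraitDataset(("a", "b", "c"), ("f",) * 3, None,
                          np.array([[1.0], [2.0], [3.0]]), ("t",),
                          np.zeros(3, bool))
        out = standardize(ds)
        assert np.allclose(out.traits.ravel(), [-1, 0, 1])  # sample SD = 1
        assert out.scaling["t"] == (2.0, 1.0)
        again = standardize(out)
        assert np.abs(again.traits - out.traits).max() < 1e-12

    def test_population_sd_option(self):
        ds = TraitDataset(("a", "b", "c"), ("f",) * 3, None,
                          np.array([[1.0], [2.0], [3.0]]), ("t",),
                          np.zeros(3, bool))
        out = standardize(ds, ddof=0)
        assert np.var(out.traits, ddof=0) == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        ds = TraitDataset(("a", "b"), ("f", "f"), None,
                          np.array([[1.0], [1.0]]), ("t",), np.zeros(2, bool))
        with pytest.raises(ValueError, match="zero variance"):
            standardize(ds)


class TestBuildMme:
    def test_ridge_reduction_single_trait(self):
        """With K=I and no blocks, the MME are ridge regression with
        lambda = s2_e / s2_a."""
        rng = np.random.default_rng(0)
        n = 8
        ids = tuple(f"i{j}" for j in range(n))
        y = rng.standard_normal(n)
        ds = TraitDataset(ids, ("f",) * n, None, y.reshape(-1, 1), ("t",),
                          np.zeros(n, bool))
        K_inv = RelationshipMatrix(ids, np.eye(n), "A_inv")
        sa2, se2 = 0.4, 0.6
        cs = CovarianceStructures([[sa2]], None, [[se2]])
        C, rhs, maps = build_mme(ds, K_inv, cs)
        lam = se2 / sa2
        X = np.ones((n, 1))
        expected = np.block([
            [X.T @ X, X.T],
            [X, np.eye(n) + lam * np.eye(n)],
        ]) / se2
        assert np.allclose(C, expected)
        assert np.allclose(rhs, np.concatenate([[y.sum()], y]) / se2)
        assert maps["additive_offset"] == 1

    def test_hand_assembled_two_block_instance(self):
        """4 trees, 2 blocks, single trait, K=I: coefficient matrix equals
        the hand-built Henderson blocks."""
        ids = ("a", "b", "c", "d")
        y = np.array([1.0, 2.0, 0.5, -1.0])
        ds = TraitDataset(ids, ("f",) * 4, ("B1", "B1", "B2", "B2"),
                          y.reshape(-1, 1), ("t",), np.zeros(4, bool))
        K_inv = RelationshipMatrix(ids, np.eye(4), "A_inv")
        sa2, su2, se2 = 0.5, 0.2, 1.0
        cs = CovarianceStructures([[sa2]], [su2], [[se2]])
        C, rhs, _ = build_mme(ds, K_inv, cs)
        X = np.ones((4, 1))
        Z1 = np.eye(4)
        Z2 = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        W = np.hstack([X, Z1, Z2])
        expected = W.T @ W / se2
        expected[1:5, 1:5] += np.eye(4) / sa2
        expected[5:, 5:] += np.eye(2) / su2
        assert np.allclose(C, expected)
        assert np.allclose(rhs, W.T @ y / se2)

    def test_complete_bivariate_residual_blocks(self):
        """With both traits present everywhere, R^-1 is block diagonal with
        identical 2x2 blocks, so the cross-trait MME coupling equals the
        off-diagonal of inv(Sigma_e) everywhere."""
        rng = np.random.default_rng(1)
        n = 5
        ids = tuple(f"i{j}" for j in range(n))
        ds = TraitDataset(ids, ("f",) * n, None, rng.standard_normal((n, 2)),
                          ("t1", "t2"), np.zeros(n, bool))
        K_inv = RelationshipMatrix(ids, np.eye(n), "A_inv")
        Se = np.array([[1.0, 0.3], [0.3, 0.8]])
        cs = CovarianceStructures(np.eye(2) * 0.5, None, Se)
        frame = _ModelFrame(ds, K_inv)
        blocks, _ = frame._residual_blocks(Se)
        Rinv = frame._pattern_sparse(blocks).toarray()
        Se_inv = np.linalg.inv(Se)
        for i in range(n):
            rows = [frame.obs_index[i, 0], frame.obs_index[i, 1]]
            assert np.allclose(Rinv[np.ix_(rows, rows)], Se_inv)


class TestRemlFit:
    def test_balanced_halfsib_equals_anova(self):
        """On balanced one-way half-sib data REML reproduces the closed-form
        ANOVA variance components."""
        rng = np.random.default_rng(3)
        s, k = 60, 6
        ped, ds = simulate_halfsib(s, k, 0.3, 0.7, rng)
        est = reml_fit(ds, build_A_inverse(ped),
                       opts=RemlOptions(tol_loglik=1e-12, tol_params=1e-9))
        y = ds.traits.ravel().reshape(s, k)
        fmeans = y.mean(axis=1)
        msb = k * np.sum((fmeans - y.mean()) ** 2) / (s - 1)
        msw = np.sum((y - fmeans[:, None]) ** 2) / (s * (k - 1))
        sb = (msb - msw) / k
        assert est.converged
        assert est.structures.additive[0, 0] == pytest.approx(4 * sb, abs=1e-6)
        assert est.structures.residual[0, 0] == pytest.approx(msw - 3 * sb, abs=1e-6)

    def test_zero_additive_variance_pinned_at_boundary(self):
        rng = np.random.default_rng(4)
        ped, ds = simulate_halfsib(40, 6, 0.0, 1.0, rng)
        est = reml_fit(ds, build_A_inverse(ped))
        assert est.structures.additive[0, 0] >= 0.0
        # truth is zero; allow one-sided sampling noise of the design
        assert est.structures.additive[0, 0] < 0.25
        assert est.converged

    def test_loglik_invariant_to_intercept_shift(self):
        rng = np.random.default_rng(5)
        ped, ds = simulate_halfsib(25, 5, 0.3, 0.7, rng)
        Ainv = build_A_inverse(ped)
        est1 = reml_fit(ds, Ainv)
        shifted = TraitDataset(ds.tree_id, ds.family_id, None,
                               ds.traits + 7.5, ds.trait_names, ds.genotyped)
        est2 = reml_fit(shifted, Ainv)
        assert est1.loglik == pytest.approx(est2.loglik, abs=1e-5)

    def test_bivariate_recovery_with_missing_records(self):
        """Moderate-size bivariate fit with scattered single-trait records
        lands near the simulated components."""
        rng = np.random.default_rng(6)
        s, k = 80, 7
        ped = halfsib_pedigree(s, k)
        off = [i for i in ped.ids if "_O" in i]
        A = build_A(ped)
        L = np.linalg.cholesky(A.values)
        Sa = np.array([[0.35, 0.0], [0.0, 0.6]])
        Se = np.array([[0.65, 0.0], [0.0, 0.4]])
        a = L @ rng.standard_normal((ped.n, 2)) @ np.linalg.cholesky(Sa).T
        idx = A.indices_of(off)
        y = a[idx] + rng.standard_normal((len(off), 2)) @ np.linalg.cholesky(Se).T
        y[::34, 0] = np.nan
        y[1::23, 1] = np.nan
        ds = TraitDataset(tuple(off), tuple(i.split("_")[0] for i in off), None,
                          y, ("t1", "t2"), np.zeros(len(off), bool))
        est = reml_fit(ds, build_A_inverse(ped))
        assert est.converged
        assert est.structures.additive[0, 0] == pytest.approx(0.35, abs=0.25)
        assert est.structures.additive[1, 1] == pytest.approx(0.6, abs=0.25)
        assert est.structures.residual[1, 1] == pytest.approx(0.4, abs=0.2)

    def test_nonconvergence_is_flagged_not_raised(self):
        rng = np.random.default_rng(7)
        ped, ds = simulate_halfsib(20, 5, 0.3, 0.7, rng)
        est = reml_fit(ds, build_A_inverse(ped), opts=RemlOptions(max_iter=1))
        assert not est.converged
        assert est.n_iter == 1


class TestBlupSolve:
    def test_gls_oracle_small(self):
        """BLUPs, intercept and prediction SEs match the dense GLS/PEV
        formulas on a 10-tree instance."""
        rng = np.random.default_rng(8)
        n = 10
        ids = tuple(f"i{j}" for j in range(n))
        K = np.eye(n)
        K[0, 1] = K[1, 0] = 0.5
        K[2, 3] = K[3, 2] = 0.25
        y = rng.standard_normal(n)
        ds = TraitDataset(ids, ("f",) * n, None, y.reshape(-1, 1), ("t",),
                          np.zeros(n, bool))
        K_inv = RelationshipMatrix(ids, np.linalg.inv(K), "A_inv")
        sa2, se2 = 0.4, 0.6
        sol = blup_solve(ds, K_inv, CovarianceStructures([[sa2]], None, [[se2]]))
        V = sa2 * K + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a_hat = sa2 * K @ Vi @ (y - X @ beta)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        pev = sa2 * K - (sa2 * K) @ P @ (sa2 * K)
        assert sol.fixed_effects["t"] == pytest.approx(beta[0])
        assert np.allclose(sol.breeding_values["t"].to_numpy(), a_hat)
        assert np.allclose(sol.se_bv["t"].to_numpy(), np.sqrt(np.diag(pev)))

    def test_strong_shrinkage_limit(self):
        rng = np.random.default_rng(9)
        n = 12
        ids = tuple(f"i{j}" for j in range(n))
        ds = TraitDataset(ids, ("f",) * n, None,
                          rng.standard_normal((n, 1)), ("t",), np.zeros(n, bool))
        K_inv = RelationshipMatrix(ids, np.eye(n), "A_inv")
        sol = blup_solve(ds, K_inv,
                         CovarianceStructures([[1e-6]], None, [[1.0]]))
        assert np.abs(sol.breeding_values["t"]).max() < 1e-4

    def test_unphenotyped_parents_get_nonzero_blups(self):
        rng = np.random.default_rng(10)
        ped, ds = simulate_halfsib(15, 6, 0.4, 0.6, rng)
        sol = blup_solve(ds, build_A_inverse(ped),
                         CovarianceStructures([[0.4]], None, [[0.6]]))
        mothers = [i for i in ped.ids if "_O" not in i]
        assert np.abs(sol.breeding_values.loc[mothers, "t"]).max() > 0.01


class TestAic:
    @pytest.mark.parametrize("loglik,t,expected", [(-10.0, 3, 26.0), (0.0, 0, 0.0)])
    def test_arithmetic(self, loglik, t, expected):
        assert aic(loglik, t) == expected

    def test_bivariate_free_parameter_count(self):
        cs = CovarianceStructures(np.eye(2), np.ones(2), np.eye(2))
        assert cs.n_free == 8  # 3 additive + 2 block + 3 residual
        est_aic = aic(-100.0, cs.n_free)
        assert est_aic == 216.0


class TestReadPhenotypes:
    def test_round_trip(self, tmp_path):
        ds = TraitDataset(("a", "b"), ("f1", "f2"), ("B1", "B2"),
                          np.array([[1.0, np.nan], [2.0, 3.0]]), ("HT", "WD"),
                          np.array([True, False]))
        p = tmp_path / "pheno.tsv"
        ds.to_tsv(p)
        back = read_phenotypes(p)
        assert back.tree_id == ds.tree_id
        assert back.block_id == ds.block_id
        assert np.allclose(back.traits, ds.traits, equal_nan=True)
        assert list(back.genotyped) == [True, False]


class TestLikelihoodOracles:
    """The MME-based restricted likelihood and its analytic score against
    direct dense-matrix evaluation."""

    @staticmethod
    def _toy_frame():
        rng = np.random.default_rng(42)
        recs = [(f"M{f}", None, None) for f in range(8)]
        recs += [(f"M{f}_O{j}", f"M{f}", None) for f in range(8) for j in range(6)]
        ped = PedigreeTable.from_records(recs)
        A = build_A(ped)
        off = [i for i in ped.ids if "_O" in i]
        n = len(off)
        Sa = np.array([[0.3, -0.02], [-0.02, 0.6]])
        Se = np.array([[0.7, 0.05], [0.05, 0.4]])
        su = np.array([0.05, 0.02])
        L = np.linalg.cholesky(A.values)
        a = L @ rng.standard_normal((ped.n, 2)) @ np.linalg.cholesky(Sa).T
        bidx = np.arange(n) % 3
        ub = rng.standard_normal((3, 2)) * np.sqrt(su)
        y = a[A.indices_of(off)] + ub[bidx] + \
            rng.standard_normal((n, 2)) @ np.linalg.cholesky(Se).T
        y[0, 1] = np.nan
        y[5, 0] = np.nan
        ds = TraitDataset(tuple(off), tuple(i.split("_")[0] for i in off),
                          tuple(f"B{b}" for b in bidx), y, ("t1", "t2"),
                          np.zeros(n, bool))
        from singlestep import build_A_inverse
        cs = CovarianceStructures(Sa, su, Se)
        return ped, A, ds, build_A_inverse(ped), cs, bidx

    def test_restricted_loglik_matches_dense_formula(self):
        from singlestep.mixedmodel import _evaluate
        ped, A, ds, Ainv, cs, bidx = self._toy_frame()
        frame = _ModelFrame(ds, Ainv)
        state = _evaluate(frame, cs)
        # direct dense evaluation of the restricted likelihood
        obs = ~np.isnan(ds.traits)
        rows = np.flatnonzero(obs.ravel())
        tree_of, trait_of = rows // 2, rows % 2
        yv = ds.traits.ravel()[rows]
        nobs = len(yv)
        aidx = A.indices_of(list(ds.tree_id))
        X = np.zeros((nobs, 2))
        Z1 = np.zeros((nobs, 2 * ped.n))
        Z2 = np.zeros((nobs, 6))
        for r, (tr, k) in enumerate(zip(tree_of, trait_of)):
            X[r, k] = 1
            Z1[r, k * ped.n + aidx[tr]] = 1
            Z2[r, k * 3 + bidx[tr]] = 1
        V = Z1 @ np.kron(cs.additive, A.values) @ Z1.T \
            + Z2 @ np.kron(np.diag(cs.block), np.eye(3)) @ Z2.T
        for t in range(ds.n):
            rr = np.flatnonzero(tree_of == t)
            kk = trait_of[rr]
            V[np.ix_(rr, rr)] += cs.residual[np.ix_(kk, kk)]
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XVX)
        ll = -0.5 * ((nobs - 2) * np.log(2 * np.pi) + ldV + ldX + yv @ P @ yv)
        assert state.loglik == pytest.approx(ll, abs=1e-8)

    def test_score_matches_numerical_gradient(self):
        from singlestep.mixedmodel import _derivatives, _evaluate
        ped, A, ds, Ainv, cs, bidx = self._toy_frame()
        frame = _ModelFrame(ds, Ainv)
        state = _evaluate(frame, cs)
        score, AI = _derivatives(frame, state)
        theta = cs.to_vector()
        h = 1e-5
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            lp = _evaluate(frame, CovarianceStructures.from_vector(tp, 2, True)).loglik
            lm = _evaluate(frame, CovarianceStructures.from_vector(tm, 2, True)).loglik
            assert score[i] == pytest.approx((lp - lm) / (2 * h), abs=1e-5)
        # the average-information matrix is symmetric positive definite
        assert np.linalg.eigvalsh(AI).min() > 0
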