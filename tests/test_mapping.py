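"""Mapping fits, benchmarks, and performance metrics."""

import numpy as np
import pytest

import scfcmap as sm
from scfcmap.matrices import upper_triangle

from oracles import loop_pearson, normal_equations, power_iteration_eig


def rank1_fc(u, lam=2.0):
    return sm.ConnectomeMatrix(lam * np.outer(u, u), role="functional", strict=False)


class TestFitProposed:
    def test_rank1_exact(self, seeded_pair):
        _, _, smodes, _, _ = seeded_pair
        u = smodes.eigenvectors[:, 3]
        fc = rank1_fc(u)
        res = sm.fit_proposed(smodes, sm.decompose_fc(fc), k=1, evaluate_against=fc)
        np.testing.assert_allclose(res.predicted.values, fc.values, atol=1e-8)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-8)

    def test_complete_basis_reproduces_clipped_fc(self, seeded_pair):
        _, fc, smodes, fmodes, _ = seeded_pair
        res = sm.fit_proposed(smodes, fmodes, k=fmodes.n_positive)
        np.testing.assert_allclose(res.predicted.values, fmodes.reconstruct(), atol=1e-8)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-8)

    def test_k1_matches_power_iteration_oracle(self):
        sc, _, _ = sm.gen_sc(8, density=0.7, seed=5)
        smodes = sm.decompose_sc(sc)
        rng = np.random.default_rng(9)
        w = rng.standard_normal(8)
        w /= np.linalg.norm(w)
        truth = sm.SyntheticTruth(seed=9, planted_weights=w,
                                  planted_spectrum=sm.default_spectrum(8, n_active=5))
        fc = sm.gen_fc_planted(smodes, truth)
        fmodes = sm.decompose_fc(fc)
        res = sm.fit_proposed(smodes, fmodes, k=1)
        vals, vecs = power_iteration_eig(fc.values)
        expected = vals[0] * np.outer(vecs[:, 0], vecs[:, 0])
        np.testing.assert_allclose(res.predicted.values, expected, atol=1e-6)

    def test_monotone_coverage_and_residual(self, seeded_pair):
        _, fc, smodes, fmodes, _ = seeded_pair
        total = fmodes.eigenvalues.sum()
        clipped = fmodes.reconstruct()
        prev_cov, prev_res = -1.0, np.inf
        for k in range(1, 11):
            cov = fmodes.eigenvalues[:k].sum() / total
            res = sm.fit_proposed(smodes, fmodes, k=k)
            resid = np.linalg.norm(res.predicted.values - clipped)
            assert cov >= prev_cov - 1e-12
            assert resid <= prev_res + 1e-12
            prev_cov, prev_res = cov, resid

    def test_k_out_of_range(self, seeded_pair):
        _, _, smodes, fmodes, _ = seeded_pair
        with pytest.raises(sm.InvalidInputError):
            sm.fit_proposed(smodes, fmodes, k=0)
        with pytest.raises(sm.InvalidInputError):
            sm.fit_proposed(smodes, fmodes, k=11)


class TestSuperiorityOverDiagonalFit:
    def test_nondiagonal_mode_combination(self, seeded_pair):
        """FC planted as rank-1 in a non-diagonal structural-mode combination:
        the K=1 projection mapping is exact while the diagonal-only eigenmode
        fit cannot reach the cross-term V1 V2^T."""
        _, _, smodes, _, _ = seeded_pair
        u = (smodes.eigenvectors[:, 0] + smodes.eigenvectors[:, 1]) / np.sqrt(2)
        fc = rank1_fc(u, lam=3.0)
        fmodes = sm.decompose_fc(fc)
        proposed = sm.fit_proposed(smodes, fmodes, k=1, evaluate_against=fc)
        tewarie = sm.fit_tewarie(smodes, fc)
        assert proposed.whole_brain_r == pytest.approx(1.0, abs=1e-8)
        assert tewarie.whole_brain_r < 1.0 - 1e-6


class TestFitTewarie:
    def test_shared_eigenvectors_exact(self, seeded_pair):
        _, _, smodes, _, _ = seeded_pair
        d = np.linspace(2.0, 0.1, 10)
        fc = sm.ConnectomeMatrix((smodes.eigenvectors * d) @ smodes.eigenvectors.T,
                                 role="functional", strict=False)
        res = sm.fit_tewarie(smodes, fc)
        np.testing.assert_allclose(np.sort(res.params["a"]), np.sort(d), atol=1e-10)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-8)

    def test_identity_fc(self, seeded_pair):
        _, _, smodes, _, _ = seeded_pair
        fc = sm.ConnectomeMatrix(np.eye(10), role="functional")
        res = sm.fit_tewarie(smodes, fc)
        np.testing.assert_allclose(res.params["a"], np.ones(10), atol=1e-10)

    def test_closed_form_equals_least_squares_oracle(self, seeded_pair):
        _, fc, smodes, _, _ = seeded_pair
        res = sm.fit_tewarie(smodes, fc)
        # generic least squares over vectorized outer-product regressors
        regressors = np.column_stack([
            np.outer(smodes.eigenvectors[:, j], smodes.eigenvectors[:, j]).ravel()
            for j in range(10)
        ])
        coefs = normal_equations(regressors, fc.values.ravel())
        np.testing.assert_allclose(res.params["a"], coefs, atol=1e-6)


class TestFitBecker:
    def test_polynomial_spectrum_exact(self, seeded_pair):
        _, _, smodes, _, _ = seeded_pair
        poly = np.polynomial.Polynomial([0.5, 0.2, 0.05])
        lam_f = poly(smodes.eigenvalues)
        assert (lam_f > 0).all()
        # functional modes share SC's eigenvectors, eigenvalues p(lambda^s)
        order = np.argsort(-lam_f, kind="stable")
        fmodes = sm.ModeSet(lam_f[order], smodes.eigenvectors[:, order], role="functional")
        res = sm.fit_becker(smodes, fmodes, l_max=2)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            res.predicted.values, fmodes.reconstruct(), atol=1e-8)

    def test_lmax_zero_constant_diagonal(self, seeded_pair):
        _, _, smodes, fmodes, _ = seeded_pair
        res = sm.fit_becker(smodes, fmodes, l_max=0)
        off = res.predicted.values[~np.eye(10, dtype=bool)]
        # prediction is a0 * I rotated into the functional basis: a0 * I exactly
        np.testing.assert_allclose(res.predicted.values,
                                   np.eye(10) * res.params["a"][0], atol=1e-10)
        assert np.abs(off).max() < 1e-10

    def test_duality_with_contribution_matrix(self, seeded_pair):
        _, _, smodes, fmodes, _ = seeded_pair
        res = sm.fit_becker(smodes, fmodes, l_max=3)
        contrib = sm.contribution_weights(fmodes, smodes)
        vtrv = smodes.eigenvectors.T @ res.params["rotation"] @ smodes.eigenvectors
        np.testing.assert_allclose(vtrv, contrib.weights.T, atol=1e-10)

    def test_matrix_domain_equivalence(self, seeded_pair):
        """The eigen-domain polynomial fit reproduces R (sum a_l SC^l) R^T."""
        sc, _, smodes, fmodes, _ = seeded_pair
        res = sm.fit_becker(smodes, fmodes, l_max=3)
        a = res.params["a"]
        poly_sc = sum(a[l] * np.linalg.matrix_power(sc.values, l) for l in range(4))
        r = res.params["rotation"]
        np.testing.assert_allclose(res.predicted.values, r @ poly_sc @ r.T, atol=1e-7)


class TestFitCommunication:
    def test_self_predictor_perfect(self, seeded_pair):
        _, fc, _, _, _ = seeded_pair
        stack = sm.PredictorStack(names=("self",), matrices=(fc.values.copy(),))
        res = sm.fit_communication(fc, stack)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-10)

    def test_intercept_only_flagged(self, seeded_pair):
        _, fc, _, _, _ = seeded_pair
        with pytest.raises(sm.UndefinedResultError):
            sm.fit_communication(fc, sm.PredictorStack(names=(), matrices=()))

    def test_coefficients_match_normal_equations(self, seeded_pair):
        sc, fc, _, _, _ = seeded_pair
        rng = np.random.default_rng(4)
        mats = []
        for _ in range(3):
            m = rng.standard_normal((10, 10))
            mats.append((m + m.T) / 2)
        stack = sm.PredictorStack(names=("p1", "p2", "p3"), matrices=tuple(mats))
        res = sm.fit_communication(fc, stack)
        cols = []
        for m in mats:
            x = upper_triangle(m)
            cols.append((x - x.mean()) / x.std())
        design = np.column_stack([np.ones(45)] + cols)
        expected = normal_equations(design, fc.upper_triangle())
        np.testing.assert_allclose(res.params["a"], expected, atol=1e-8)

    def test_collinear_predictors_warn(self, seeded_pair):
        _, fc, _, _, _ = seeded_pair
        m = fc.values.copy()
        stack = sm.PredictorStack(names=("a", "b"), matrices=(m, 2 * m))
        with pytest.warns(UserWarning, match="collinear"):
            sm.fit_communication(fc, stack)


class TestReferenceMapping:
    def test_identical_cohort(self, correlation_fc):
        group = sm.group_reference([correlation_fc] * 3)
        res = sm.reference_predict(group, correlation_fc)
        assert res.whole_brain_r == pytest.approx(1.0, abs=1e-12)

    def test_cancellation_flagged(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        a = sm.ConnectomeMatrix(m, role="functional", strict=False)
        neg = -m.copy()
        np.fill_diagonal(neg, 1.0)
        b = sm.ConnectomeMatrix(neg, role="functional", strict=False)
        group = sm.group_reference([a, b])
        with pytest.warns(UserWarning, match="undefined"):
            res = sm.reference_predict(group, a)
        assert np.isnan(res.whole_brain_r)

    def test_heterogeneous_cohort_oracle(self):
        rng = np.random.default_rng(8)
        fcs = []
        for _ in range(10):
            signals = rng.standard_normal((60, 8))
            fcs.append(sm.ConnectomeMatrix(np.corrcoef(signals, rowvar=False), role="functional"))
        group = sm.group_reference(fcs)
        for fc in fcs:
            res = sm.reference_predict(group, fc)
            expected = loop_pearson(group.mean_fc.upper_triangle(), fc.upper_triangle())
            assert res.whole_brain_r == pytest.approx(expected, abs=1e-10)


class TestPerformanceMetrics:
    def test_whole_brain_r_extremes(self, correlation_fc):
        assert sm.whole_brain_r(correlation_fc, correlation_fc) == pytest.approx(1.0)
        negated = -correlation_fc.values
        np.fill_diagonal(negated, 1.0)
        assert sm.whole_brain_r(negated, correlation_fc) == pytest.approx(-1.0)

    def test_whole_brain_r_loop_oracle(self, seeded_pair):
        _, fc, smodes, fmodes, _ = seeded_pair
        pred = sm.fit_proposed(smodes, fmodes, k=2).predicted
        expected = loop_pearson(pred.upper_triangle(), fc.upper_triangle())
        assert sm.whole_brain_r(pred, fc) == pytest.approx(expected, abs=1e-10)

    def test_whole_brain_r_zero_variance_flagged(self):
        const = np.full((4, 4), 0.5)
        np.fill_diagonal(const, 1.0)
        other = np.eye(4)
        with pytest.raises(sm.UndefinedResultError):
            sm.whole_brain_r(const, other)

    def test_regional_r_identity_and_oracle(self, seeded_pair):
        _, fc, smodes, fmodes, _ = seeded_pair
        np.testing.assert_allclose(sm.regional_r(fc, fc), np.ones(10), atol=1e-12)
        pred = sm.fit_proposed(smodes, fmodes, k=2).predicted
        regional = sm.regional_r(pred, fc)
        mask = ~np.eye(10, dtype=bool)
        for i in range(10):
            expected = loop_pearson(pred.values[i, mask[i]], fc.values[i, mask[i]])
            assert regional[i] == pytest.approx(expected, abs=1e-10)

    def test_regional_zero_variance_flagged_entry(self):
        pred = np.zeros((5, 5))
        rng = np.random.default_rng(1)
        emp = rng.standard_normal((5, 5))
        emp = (emp + emp.T) / 2
        with pytest.warns(UserWarning, match="zero-variance"):
            out = sm.regional_r(pred, emp)
        assert np.isnan(out).all()

    def test_fraction_better(self):
        a = np.array([0.5, 0.6, 0.7])
        assert sm.fraction_better(a, a) == 0.0
        assert sm.fraction_better(a + 0.1, a) == 1.0
        b = np.array([0.6, 0.5, 0.7])
        # counting oracle: strictly greater only
        assert sm.fraction_better(a, b) == pytest.approx(
            sum(x > y for x, y in zip(a, b)) / 3)

    def test_mean_delta_sign_matches_fraction(self, seeded_pair):
        _, fc, smodes, fmodes, _ = seeded_pair
        ra = sm.fit_proposed(smodes, fmodes, k=3, evaluate_against=fc).regional_r
        rb = sm.fit_tewarie(smodes, fc).regional_r
        frac = sm.fraction_better(ra, rb)
        if frac > 0.5:
            assert np.mean(ra - rb) > 0
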