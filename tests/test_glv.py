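import numpy as np
import pandas as pd
import pytest

from sedshift import glv, synthetic, tables_io
from sedshift.glv import (build_design, classify_interactions, fit_glv, glv_rhs,
                          jacobian, stability_analysis, stability_spectrum,
                          stage_analysis, stage_windows, steady_state)
from sedshift.tables_io import CommunityMatrix


def _matrix(N, times):
    N = np.asarray(N, dtype=float)
    rel = pd.DataFrame(N, index=[f"s{i}" for i in range(N.shape[0])],
                       columns=[f"t{j}" for j in range(N.shape[1])])
    ages = pd.Series(np.asarray(times, dtype=float), index=rel.index)
    return CommunityMatrix(rel=rel, ages=ages, closed=False)


class TestStageWindows:
    def test_study_shape_gives_seven_stages(self):
        wins = stage_windows(35, w=10, s=5)
        assert len(wins) == 7
        assert (wins[6].start, wins[6].stop) == (30, 35)
        assert len(wins[6]) == 5

    def test_minimal_two_windows(self):
        wins = stage_windows(10, w=10, s=5)
        assert [(w.start, w.stop) for w in wins] == [(0, 10), (5, 10)]

    def test_single_full_window_at_boundary(self):
        wins = stage_windows(12, w=10, s=5)
        assert wins[0].stop - wins[0].start == 10

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            stage_windows(35, w=5, s=5)
        with pytest.raises(ValueError):
            stage_windows(6, w=10, s=5)


class TestBuildDesign:
    def test_logistic_recovery_within_one_percent(self):
        r_true, a_true, n0 = 0.9, 3.0, 0.02
        t = np.linspace(0, 8, 200)
        k = r_true / a_true
        N = k / (1 + (k / n0 - 1) * np.exp(-r_true * t))
        mat = _matrix(N[:, None], t)
        design = build_design(mat, glv.StageWindow(1, 0, len(t)))
        fit = fit_glv(design, lambda_grid=[0.0], k_folds=2)
        assert fit.r[0] == pytest.approx(r_true, rel=0.01)
        assert fit.A[0, 0] == pytest.approx(a_true, rel=0.01)

    def test_constant_window_has_zero_responses(self):
        mat = _matrix([[0.3, 0.2]] * 6, np.arange(6))
        design = build_design(mat, glv.StageWindow(1, 0, 6))
        np.testing.assert_allclose(design.Y, 0.0)

    def test_doubling_dt_halves_responses(self):
        rng = np.random.default_rng(0)
        N = rng.uniform(0.05, 0.3, size=(6, 3))
        d1 = build_design(_matrix(N, np.arange(6)), glv.StageWindow(1, 0, 6))
        d2 = build_design(_matrix(N, 2.0 * np.arange(6)), glv.StageWindow(1, 0, 6))
        np.testing.assert_allclose(d2.Y, d1.Y / 2)

    def test_nonmonotone_ages_rejected(self):
        mat = _matrix([[0.1]] * 4, [0.0, 1.0, 1.0, 2.0])
        mat.ages.iloc[2] = 0.5  # force a decrease
        with pytest.raises(ValueError, match="increasing"):
            build_design(mat, glv.StageWindow(1, 0, 4))

    def test_all_zero_taxon_flagged(self):
        N = np.array([[0.3, 0.0], [0.2, 0.0], [0.25, 0.0], [0.3, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            design = build_design(_matrix(N, np.arange(4)), glv.StageWindow(1, 0, 4))
        assert design.dropped == ["t1"]


class TestFitGLV:
    def test_ols_limit_matches_linear_solve(self):
        rng = np.random.default_rng(1)
        S, n = 2, 8
        X = np.hstack([np.ones((n, 1)), -rng.uniform(0.1, 0.5, size=(n, S))])
        beta_true = rng.normal(size=(S + 1, S))
        Y = X @ beta_true
        design = glv.GLVDesign(taxa=["a", "b"], X=X, Y=Y, dt=np.ones(n),
                               pseudocount=1e-6)
        fit = fit_glv(design, lambda_grid=[0.0], k_folds=2)
        np.testing.assert_allclose(fit.r, beta_true[0], atol=1e-8)
        np.testing.assert_allclose(fit.A, beta_true[1:].T, atol=1e-8)

    def test_huge_penalty_shrinks_interactions_not_growth(self):
        rng = np.random.default_rng(2)
        S, n = 3, 12
        X = np.hstack([np.ones((n, 1)), -rng.uniform(0.1, 0.5, size=(n, S))])
        Y = rng.normal(0.2, 0.05, size=(n, S))
        design = glv.GLVDesign(taxa=list("abc"), X=X, Y=Y, dt=np.ones(n),
                               pseudocount=1e-6)
        fit = fit_glv(design, lambda_grid=[1e6], k_folds=3)
        assert np.abs(fit.A).max() < 1e-3
        assert np.abs(fit.r).max() > 0.05

    @staticmethod
    def _pooled_recovery_fit(seed):
        r, A, episodes = synthetic.recovery_dataset(seed=seed)
        designs = [build_design(_matrix(ep.to_numpy(), 0.3 * np.arange(len(ep))),
                                glv.StageWindow(1, 0, len(ep)))
                   for ep in episodes]
        return r, A, fit_glv(glv.pool_designs(designs))

    def test_chosen_lambda_attains_cv_minimum_and_is_finite(self):
        _r, _A, fit = self._pooled_recovery_fit(3)
        assert np.isfinite(fit.cv_error)
        assert fit.lambdas[0] in glv.DEFAULT_LAMBDA_GRID

    def test_parameter_recovery_on_simulated_community(self):
        _r, A, fit = self._pooled_recovery_fit(0)
        corr = np.corrcoef(fit.A.ravel(), A.ravel())[0, 1]
        assert corr > 0.9
        nz = A != 0
        assert (np.sign(fit.A[nz]) == np.sign(A[nz])).mean() >= 0.9

    def test_too_few_equations_rejected(self):
        X = np.hstack([np.ones((3, 1)), -np.random.rand(3, 2)])
        design = glv.GLVDesign(taxa=["a", "b"], X=X, Y=np.zeros((3, 2)),
                               dt=np.ones(3), pseudocount=1e-6)
        with pytest.raises(ValueError, match="folds"):
            fit_glv(design, k_folds=5)


class TestDynamics:
    def test_rhs_zero_at_extinction_and_equilibrium(self):
        r = np.array([1.0, 0.5])
        A = np.array([[1.0, 0.0], [0.0, 2.0]])
        np.testing.assert_allclose(glv_rhs((r, A), np.zeros(2)), 0.0)
        np.testing.assert_allclose(glv_rhs((r, A), np.array([1.0, 0.25])), 0.0,
                                   atol=1e-12)

    def test_rhs_matches_hand_evaluation(self):
        rng = np.random.default_rng(3)
        r, A = rng.normal(size=4), rng.normal(size=(4, 4))
        N = rng.uniform(0.1, 1.0, size=4)
        expected = [N[i] * (r[i] - sum(A[i, j] * N[j] for j in range(4)))
                    for i in range(4)]
        np.testing.assert_allclose(glv_rhs((r, A), N), expected, rtol=1e-12)

    @pytest.mark.parametrize("r, A, expected", [
        ([1.0], [[2.0]], [0.5]),
        ([1.0, 1.0], [[1.0, 0.0], [0.0, 2.0]], [1.0, 0.5]),
        ([1.0, 1.0, 1.0], np.eye(3).tolist(), [1.0, 1.0, 1.0]),
    ])
    def test_steady_state_known_solutions(self, r, A, expected):
        n_star, feasible = steady_state((np.array(r), np.array(A)))
        np.testing.assert_allclose(n_star, expected, rtol=1e-12)
        assert feasible

    def test_singular_matrix_rejected_with_condition(self):
        r = np.array([1.0, 1.0])
        A = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-14]])
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            steady_state((r, A))

    def test_jacobian_single_species_logistic(self):
        r, A = np.array([0.7]), np.array([[2.0]])
        J = jacobian((r, A), np.array([0.35]))
        assert J[0, 0] == pytest.approx(-0.7)

    def test_jacobian_equals_diag_form_at_equilibrium(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            S = int(rng.integers(2, 6))
            A = rng.normal(size=(S, S)) + S * np.eye(S)
            r = rng.uniform(0.5, 1.5, size=S)
            n_star = np.linalg.solve(A, r)
            J = jacobian((r, A), n_star)
            np.testing.assert_allclose(J, -np.diag(n_star) @ A, atol=1e-10)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        r, A = rng.normal(size=3), rng.normal(size=(3, 3))
        N = rng.uniform(0.2, 0.8, size=3)
        J = jacobian((r, A), N)
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            num = (glv_rhs((r, A), N + e) - glv_rhs((r, A), N - e)) / (2 * h)
            np.testing.assert_allclose(J[:, k], num, atol=1e-6)


class TestStability:
    def test_diagonal_spectrum(self):
        eig, centroid, stable = stability_spectrum(np.diag([-1.0, -2.0]))
        assert sorted(eig.real) == [-2.0, -1.0]
        assert centroid == pytest.approx(-1.5)
        assert stable

    def test_pure_rotation_is_not_stable(self):
        eig, centroid, stable = stability_spectrum([[0.0, 1.0], [-1.0, 0.0]])
        np.testing.assert_allclose(sorted(eig.imag), [-1.0, 1.0])
        assert centroid == pytest.approx(0.0, abs=1e-12)
        assert not stable

    def test_verdict_agrees_with_linear_ode_integration(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(6)
        checked = 0
        while checked < 25:
            J = rng.normal(scale=0.5, size=(6, 6))
            _eig, _c, stable = stability_spectrum(J)
            rate = np.linalg.eigvals(J).real.max()
            if abs(rate) < 0.05:
                continue
            T = 8.0 / abs(rate)
            x0 = rng.normal(size=6)
            x0 /= np.linalg.norm(x0)
            grew = np.linalg.norm(expm(J * T) @ x0) > 1.0
            assert grew == (not stable)
            checked += 1

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stability_spectrum(np.array([[np.nan, 0.0], [0.0, -1.0]]))


class TestClassification:
    def test_sign_convention_cases(self):
        r = np.zeros(2)
        inter = classify_interactions((r, np.array([[1.0, -1.0], [-1.0, 1.0]])))
        assert inter.pairs["type"].iloc[0] == "mutualism"
        inter = classify_interactions((r, np.array([[1.0, 1.0], [-1.0, 1.0]])))
        assert inter.pairs["type"].iloc[0] == "exploitation"
        inter = classify_interactions((r, np.array([[1.0, 1.0], [1.0, 1.0]])))
        assert inter.pairs["type"].iloc[0] == "antagonism"

    def test_raw_mode_flips_mutualism_and_antagonism(self):
        r = np.zeros(2)
        A = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert classify_interactions((r, A), on="raw").pairs["type"].iloc[0] \
            == "antagonism"

    def test_proportions_match_brute_force(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(5, 5))
        inter = classify_interactions((np.zeros(5), A))
        counts = {"mutualism": 0, "antagonism": 0, "exploitation": 0}
        for i in range(5):
            for j in range(i + 1, 5):
                eij, eji = -A[i, j], -A[j, i]
                if eij > 0 and eji > 0:
                    counts["mutualism"] += 1
                elif eij < 0 and eji < 0:
                    counts["antagonism"] += 1
                else:
                    counts["exploitation"] += 1
        total = sum(counts.values())
        for kind, c in counts.items():
            assert inter.proportions[kind] == pytest.approx(c / total)
        assert sum(inter.proportions.values()) == pytest.approx(1.0)

    def test_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(4, 4))
        perm = np.array([2, 0, 3, 1])
        a = classify_interactions((np.zeros(4), A))
        b = classify_interactions((np.zeros(4), A[np.ix_(perm, perm)]))
        assert a.proportions == pytest.approx(b.proportions)
        for kind in a.strength:
            assert a.strength[kind] == pytest.approx(b.strength[kind], nan_ok=True)

    def test_zero_effect_pairs_flagged_null(self):
        A = np.array([[1.0, 0.0], [1.0, 1.0]])
        inter = classify_interactions((np.zeros(2), A))
        assert inter.n_null == 1


class TestStageAnalysis:
    @pytest.fixture(scope="class")
    def stages(self, scenario):
        _, table = scenario
        cm = tables_io.to_relative(table)
        mat = tables_io.select_modeled_taxa(cm, max_taxa=4, renormalize=False)
        return stage_analysis(mat)

    def test_seven_stages_analyzed(self, stages):
        assert len(stages) == 7
        assert [s.window.index for s in stages] == list(range(1, 8))

    def test_stage_summary_has_stability_columns(self, stages, scenario):
        sc, _ = scenario
        tab = glv.stage_summary(stages, ages=sc.sample_times)
        assert {"centroid_re", "stable", "feasible"} <= set(tab.columns)
        assert tab["centroid_re"].notna().sum() >= 5

    def test_transition_stage_attains_max_centroid(self, stages, scenario):
        sc, _ = scenario
        cent = {s.window.index: s.stability.centroid_re
                for s in stages if s.stability is not None}
        best = max(cent, key=cent.get)
        win = [s.window for s in stages if s.window.index == best][0]
        ages = sc.sample_times
        assert ages[win.start] <= sc.transition_time
        assert ages[win.stop - 1] >= sc.threshold_time

    def test_fitted_dynamics_reproduce_noiseless_window(self):
        # forward-difference consistency: refitting a noiseless dense
        # trajectory and re-simulating reproduces it
        r = np.array([1.0, 0.8])
        A = np.array([[4.0, 0.6], [-0.4, 5.0]])
        t = np.linspace(0, 6, 120)
        traj = synthetic.simulate_glv(r, A, np.array([0.1, 0.05]), t)
        mat = _matrix(traj, t)
        design = build_design(mat, glv.StageWindow(1, 0, len(t)))
        fit = fit_glv(design, lambda_grid=[1e-8], k_folds=2)
        resim = synthetic.simulate_glv(fit.r, fit.A, traj[0], t)
        np.testing.assert_allclose(resim, traj, atol=5e-3)
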