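"""Tests for the linear-ODE network inference: latent dynamics, the ridge
regression step, network reconstruction, the greedy optimizer, and the
ensemble averaging."""

import numpy as np
import pytest

from grnode.scode import (
    GRNModel,
    assemble_A,
    ensemble_average,
    fit_W,
    infer_ensemble,
    latent_dynamics,
    optimize_scode,
    scan_D,
)


class TestLatentDynamics:
    @pytest.mark.parametrize("b,t,expected", [
        ([0.0, 0.0], [0.2, 0.9], np.ones((2, 2))),
        ([1.0], [0.0, 1.0], [[1.0, np.e]]),
        ([-2.0], [0.5], [[np.exp(-1.0)]]),
    ])
    def test_values(self, b, t, expected):
        np.testing.assert_allclose(latent_dynamics(np.array(b), np.array(t)),
                                   expected, rtol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            latent_dynamics(np.array([np.nan]), np.array([0.5]))


class TestFitW:
    def test_exact_interpolation_square_Z(self, rng):
        Z = rng.normal(size=(4, 4))
        W0 = rng.normal(size=(7, 4))
        W, rss = fit_W(W0 @ Z, Z, ridge=0)
        np.testing.assert_allclose(W, W0, atol=1e-9)
        assert rss < 1e-16 * ((W0 @ Z) ** 2).sum() + 1e-18

    def test_orthogonal_signal_gives_zero_W(self):
        Z = np.array([[1.0, 1.0, 1.0, 1.0]])
        X = np.array([[1.0, -1.0, 1.0, -1.0]])   # orthogonal to rows of Z
        W, rss = fit_W(X, Z, ridge=0)
        np.testing.assert_allclose(W, 0.0, atol=1e-12)
        assert rss == pytest.approx(4.0)

    def test_matches_normal_equations_oracle(self, rng):
        """Closed-form (ZZ' + ridge I)^-1 Z X' oracle on a random case."""
        X = rng.normal(size=(6, 12))
        Z = rng.normal(size=(3, 12))
        ridge = 1e-3
        W, rss = fit_W(X, Z, ridge=ridge)
        W_oracle = np.linalg.solve(Z @ Z.T + ridge * np.eye(3), Z @ X.T).T
        np.testing.assert_allclose(W, W_oracle, atol=1e-10)
        assert rss == pytest.approx(((X - W_oracle @ Z) ** 2).sum())

    def test_rank_deficient_Z_without_ridge_raises(self):
        Z = np.vstack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_W(np.ones((2, 5)), Z, ridge=0)
        W, _ = fit_W(np.ones((2, 5)), Z, ridge=1e-6)   # solvable with ridge
        assert np.isfinite(W).all()


class TestAssembleA:
    def test_identity_and_orthonormal_cases(self, rng):
        b = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(assemble_A(np.eye(3), b), np.diag(b))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 3)))
        np.testing.assert_allclose(assemble_A(Q, b), Q @ np.diag(b) @ Q.T,
                                   atol=1e-10)

    def test_matches_svd_pinv_oracle(self, rng):
        W = rng.normal(size=(6, 3))
        b = rng.normal(size=3)
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        pinv = Vt.T @ np.diag(1 / s) @ U.T
        np.testing.assert_allclose(assemble_A(W, b), W @ np.diag(b) @ pinv,
                                   atol=1e-10)


class TestOptimizeScode:
    def test_rss_trace_non_increasing_and_deterministic(self, small_grn,
                                                        noiseless_cohort):
        m1 = optimize_scode(noiseless_cohort.latent, noiseless_cohort.true_time,
                            seed=42)
        m2 = optimize_scode(noiseless_cohort.latent, noiseless_cohort.true_time,
                            seed=42)
        assert (np.diff(m1.rss_trace) <= 1e-12).all()
        assert m1.rss <= m1.rss_trace[0]
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.b, m2.b)

    def test_model_invariant_A_equals_WBWpinv(self, noiseless_cohort):
        m = optimize_scode(noiseless_cohort.latent, noiseless_cohort.true_time,
                           seed=3)
        np.testing.assert_allclose(
            m.A, m.W @ np.diag(m.b) @ np.linalg.pinv(m.W), rtol=1e-8, atol=1e-10)

    def test_invalid_inputs(self, noiseless_cohort):
        X = noiseless_cohort.latent
        with pytest.raises(ValueError):
            optimize_scode(X, noiseless_cohort.true_time, iterations=0)
        with pytest.raises(ValueError):
            optimize_scode(X, np.full(X.shape[1], 0.5))


class TestScanD:
    def test_single_value_reproduces_one_run(self, noiseless_cohort):
        X, t = noiseless_cohort.latent, noiseless_cohort.true_time
        table = scan_D(X, t, [4], iterations=50, seed=5)
        model = optimize_scode(X, t, D=4, iterations=50, seed=5)
        assert table == [(4, model.rss)]

    def test_underparameterized_model_fits_much_worse(self):
        """Noiseless rank-2 dynamics: D >= 2 fits far better than D = 1."""
        from grnode.synthetic import generate_true_grn, simulate_timecourse

        worse = 0
        for s in range(5):
            g = generate_true_grn(30, 2, seed=60 + s)
            c = simulate_timecourse(g, noise_model="none", jitter_sd=0.05,
                                    seed=70 + s)
            table = dict(scan_D(c.latent, c.true_time, [1, 2],
                                iterations=100, seed=80 + s))
            norm = (c.latent ** 2).sum()
            if table[2] < 0.1 * table[1] or table[2] < 1e-6 * norm:
                worse += 1
        assert worse >= 4

    def test_all_D_below_sample_count_required(self, noiseless_cohort):
        with pytest.raises(ValueError):
            scan_D(noiseless_cohort.latent, noiseless_cohort.true_time, [100],
                   iterations=5, seed=0)


def _model_from_A(A, seed=0):
    G = A.shape[0]
    return GRNModel(W=np.eye(G), b=np.ones(G), A=A, rss=0.0, D=G, seed=seed,
                    iterations=0)


class TestEnsembleAverage:
    def test_identical_runs(self, rng):
        A = rng.normal(size=(5, 5))
        ens = ensemble_average([_model_from_A(A) for _ in range(4)], top_k=2)
        np.testing.assert_allclose(ens.A_avg, A)
        np.testing.assert_allclose(ens.run_pccs, 1.0)

    def test_outlier_run_excluded(self, rng):
        """Two identical runs + one noise run, top 2 kept -> the noise run is
        dropped and the average equals the repeated A (direct PCC check)."""
        A = rng.normal(size=(6, 6))
        noise = rng.normal(size=(6, 6))
        runs = [_model_from_A(A, 0), _model_from_A(noise, 1),
                _model_from_A(A, 2)]
        meanA = (2 * A + noise) / 3           # direct PCC check
        assert (np.corrcoef(A.ravel(), meanA.ravel())[0, 1]
                > np.corrcoef(noise.ravel(), meanA.ravel())[0, 1])
        ens = ensemble_average(runs, top_k=2)
        assert ens.selected_runs == [0, 2]
        np.testing.assert_allclose(ens.A_avg, A)

    def test_scale_invariance_of_pccs(self, rng):
        As = [rng.normal(size=(4, 4)) for _ in range(5)]
        e1 = ensemble_average([_model_from_A(a) for a in As], top_k=3)
        e2 = ensemble_average([_model_from_A(2 * a) for a in As], top_k=3)
        np.testing.assert_allclose(e2.run_pccs, e1.run_pccs, atol=1e-12)
        np.testing.assert_allclose(e2.A_avg, 2 * e1.A_avg, atol=1e-12)

    def test_constant_run_never_selected(self, rng):
        As = [rng.normal(size=(4, 4)) for _ in range(3)]
        runs = [_model_from_A(a) for a in As] + [_model_from_A(np.ones((4, 4)))]
        ens = ensemble_average(runs, top_k=3)
        assert 3 not in ens.selected_runs
        assert ens.run_pccs[3] == -np.inf

    def test_too_few_runs(self, rng):
        with pytest.raises(ValueError):
            ensemble_average([_model_from_A(rng.normal(size=(3, 3)))], top_k=2)


class TestRecovery:
    def test_noiseless_identifiability(self, small_grn, noiseless_cohort):
        """With the true b, the regression recovers W and A exactly."""
        from grnode.scode import latent_dynamics

        Z = latent_dynamics(small_grn.b_true, noiseless_cohort.true_time)
        W, rss = fit_W(noiseless_cohort.latent, Z, ridge=0)
        rel = np.linalg.norm(W - small_grn.W_true) / np.linalg.norm(
            small_grn.W_true)
        assert rel < 1e-8
        A = assemble_A(W, small_grn.b_true)
        scale = np.abs(small_grn.A_true).max()
        np.testing.assert_allclose(A, small_grn.A_true, atol=1e-8 * scale)

    def test_ensemble_is_deterministic(self, noiseless_cohort):
        e1, _ = infer_ensemble(noiseless_cohort.latent,
                               noiseless_cohort.true_time, runs=6, top_k=3,
                               iterations=30, seed=99)
        e2, _ = infer_ensemble(noiseless_cohort.latent,
                               noiseless_cohort.true_time, runs=6, top_k=3,
                               iterations=30, seed=99)
        np.testing.assert_allclose(e1.A_avg, e2.A_avg, atol=1e-10)
        assert e1.selected_runs == e2.selected_runs
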