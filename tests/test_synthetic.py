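"""Tests for the ground-truth generators: realizability, determinism,
conservation, and the planted structures every downstream stage relies on."""

import numpy as np
import pytest

from grnode import scode
from grnode.synthetic import (
    generate_celltype_profiles,
    generate_signaling_annotation,
    generate_tf_database,
    generate_true_grn,
    simulate_timecourse,
)


class TestGenerateTrueGRN:
    def test_factorization_invariant(self, small_grn):
        """A_true = W·diag(b)·pinv(W) to numerical tolerance."""
        A = small_grn.W_true @ np.diag(small_grn.b_true) @ np.linalg.pinv(
            small_grn.W_true)
        np.testing.assert_allclose(small_grn.A_true, A, rtol=1e-10, atol=1e-10)

    def test_identity_loadings_give_diagonal_network(self):
        """With W = I the network reduces to the latent rates on the diagonal."""
        b = np.array([0.5, -2.0, 1.5])
        A = scode.assemble_A(np.eye(3), b)
        np.testing.assert_allclose(A, np.diag(b), atol=1e-12)

    def test_rank_equals_latent_dimension(self, small_grn):
        # forced by the construction A = W B W+, verified numerically
        assert np.linalg.matrix_rank(small_grn.A_true, tol=1e-8) == 4

    def test_determinism(self):
        g1 = generate_true_grn(30, 3, seed=5)
        g2 = generate_true_grn(30, 3, seed=5)
        np.testing.assert_array_equal(g1.W_true, g2.W_true)
        np.testing.assert_array_equal(g1.b_true, g2.b_true)
        np.testing.assert_array_equal(g1.abundance, g2.abundance)
        assert g1.edge_set == g2.edge_set

    def test_edge_signs_match_A(self, small_grn):
        for i, j, s in small_grn.edge_set:
            assert np.sign(small_grn.A_true[i, j]) == s

    @pytest.mark.parametrize("G,D,quant", [(3, 5, 0.5), (10, 2, 0.0), (10, 2, 1.0)])
    def test_invalid_arguments(self, G, D, quant):
        with pytest.raises(ValueError):
            generate_true_grn(G, D, seed=0, edge_quantile=quant)


class TestSimulateTimecourse:
    def test_sample_counts(self, small_grn):
        c77 = simulate_timecourse(small_grn, stages=7, per_stage=11, seed=0)
        assert len(c77.sample_ids) == 77
        c76 = simulate_timecourse(small_grn, stages=7,
                                  per_stage=[10, 11, 11, 11, 11, 11, 11], seed=0)
        assert len(c76.sample_ids) == 76

    def test_counts_are_nonnegative_integers(self, poisson_cohort):
        assert poisson_cohort.counts.dtype.kind == "i"
        assert (poisson_cohort.counts >= 0).all()

    def test_true_time_tracks_stage_rank(self, small_grn):
        c = simulate_timecourse(small_grn, jitter_sd=0.0, seed=3)
        stage_rank = np.repeat(np.arange(7), 11)
        order = np.argsort(stage_rank, kind="stable")
        assert (np.diff(c.true_time[order]) >= 0).all()
        assert c.true_time.min() >= 0 and c.true_time.max() <= 1

    def test_determinism(self, small_grn):
        a = simulate_timecourse(small_grn, noise_model="poisson", seed=9)
        b = simulate_timecourse(small_grn, noise_model="poisson", seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.true_time, b.true_time)

    def test_latent_satisfies_ode(self, small_grn):
        """dX/dt = A_true·X on a dense grid (finite-difference check)."""
        t = np.linspace(0.05, 0.95, 41)
        h = 1e-6
        Xm = small_grn.W_true @ np.exp(np.outer(small_grn.b_true, t - h))
        Xp = small_grn.W_true @ np.exp(np.outer(small_grn.b_true, t + h))
        X = small_grn.W_true @ np.exp(np.outer(small_grn.b_true, t))
        deriv = (Xp - Xm) / (2 * h)
        np.testing.assert_allclose(deriv, small_grn.A_true @ X,
                                   rtol=1e-5, atol=1e-6 * np.abs(X).max())

    def test_realizability_rss_at_truth(self, small_grn, noiseless_cohort):
        """The inference model fits the noiseless latent cohort exactly."""
        Z = scode.latent_dynamics(small_grn.b_true, noiseless_cohort.true_time)
        resid = noiseless_cohort.latent - small_grn.W_true @ Z
        assert (resid ** 2).sum() < 1e-8 * (noiseless_cohort.latent ** 2).sum()

    def test_poisson_total_conservation(self, small_grn):
        lib, S = 100_000, 77
        c = simulate_timecourse(small_grn, library_size=lib,
                                noise_model="poisson", seed=21)
        assert abs(c.counts.sum() - lib * S) < 3 * np.sqrt(lib * S)

    def test_invalid_arguments(self, small_grn):
        with pytest.raises(ValueError):
            simulate_timecourse(small_grn, library_size=-1)
        with pytest.raises(ValueError):
            simulate_timecourse(small_grn, stages=1)
        with pytest.raises(ValueError):
            simulate_timecourse(small_grn, noise_model="gauss")


class TestTFDatabase:
    def test_clean_database_lists_true_top_targets(self, small_grn):
        db = generate_tf_database(small_grn, small_grn.gene_ids[:5],
                                  per_tf_targets=8, fp_rate=0.0, seed=1)
        idx = {g: i for i, g in enumerate(small_grn.gene_ids)}
        for tf, targets in db.items():
            score = np.abs(small_grn.A_true[:, idx[tf]]).copy()
            score[idx[tf]] = -np.inf
            top = {small_grn.gene_ids[i] for i in np.argsort(-score)[:8]}
            assert set(targets) <= top and len(targets) == 8

    def test_full_false_positive_rate_gives_no_true_targets(self, small_grn):
        """fp_rate=1 replaces every target with a non-target."""
        idx = {g: i for i, g in enumerate(small_grn.gene_ids)}
        for seed in range(5):
            db = generate_tf_database(small_grn, small_grn.gene_ids[:3],
                                      per_tf_targets=5, fp_rate=1.0, seed=seed)
            for tf, targets in db.items():
                score = np.abs(small_grn.A_true[:, idx[tf]]).copy()
                score[idx[tf]] = -np.inf
                top = {small_grn.gene_ids[i] for i in np.argsort(-score)[:5]}
                assert not set(targets) & top

    def test_zero_targets_and_errors(self, small_grn):
        db = generate_tf_database(small_grn, small_grn.gene_ids[:2],
                                  per_tf_targets=0, seed=0)
        assert all(v == [] for v in db.values())
        with pytest.raises(ValueError):
            generate_tf_database(small_grn, small_grn.gene_ids[:1],
                                 per_tf_targets=51, seed=0)
        with pytest.raises(KeyError):
            generate_tf_database(small_grn, ["nope"], per_tf_targets=1, seed=0)


class TestSignalingAnnotation:
    def test_nine_pathways_emitted(self, small_grn):
        _, anns = generate_signaling_annotation(small_grn, n_pathways=9, seed=2)
        assert len(anns) == 9
        assert len({a.name for a in anns}) == 9

    @pytest.mark.parametrize("sign,cmp", [("same", 1), ("opposite", -1)])
    def test_sign_relation_on_shared_downstream(self, small_grn, sign, cmp):
        g2, anns = generate_signaling_annotation(small_grn, n_pathways=4,
                                                 seed=3, sign=sign)
        idx = {g: i for i, g in enumerate(g2.gene_ids)}
        for ann in anns:
            L, R = idx[ann.ligand_genes[0]], idx[ann.receptor_genes[0]]
            assert ann.shared_downstream
            for gname in ann.shared_downstream:
                i = idx[gname]
                assert np.sign(g2.A_true[i, L]) * np.sign(g2.A_true[i, R]) == cmp

    def test_shared_fraction_at_least_90pct(self, small_grn):
        from grnode.synthetic import _column_top

        g2, anns = generate_signaling_annotation(small_grn, n_pathways=4, seed=4)
        idx = {g: i for i, g in enumerate(g2.gene_ids)}
        for ann in anns:
            L, R = idx[ann.ligand_genes[0]], idx[ann.receptor_genes[0]]
            dL = _column_top(g2.A_true, L, 0.9, exclude=(L, R))
            dR = _column_top(g2.A_true, R, 0.9, exclude=(L, R))
            assert len(dL & dR) >= 0.9 * min(len(dL), len(dR))
            assert {idx[g] for g in ann.shared_downstream} == dL & dR

    def test_factorization_preserved_after_rewrite(self, small_grn):
        g2, _ = generate_signaling_annotation(small_grn, n_pathways=3, seed=5)
        A = g2.W_true @ np.diag(g2.b_true) @ np.linalg.pinv(g2.W_true)
        np.testing.assert_allclose(g2.A_true, A, rtol=1e-9, atol=1e-9)


class TestCelltypeProfiles:
    def test_planted_pairs_are_coexpressed(self, small_grn):
        pairs = [("g0001", "g0002"), ("g0010", "g0020")]
        prof = generate_celltype_profiles(small_grn, n_celltypes=98,
                                          coexpressed_pairs=pairs, seed=6)
        assert prof.shape == (98, 50)
        for u, d in pairs:
            assert np.corrcoef(prof[u], prof[d])[0, 1] > 0.4

    def test_null_exceedance_rate_is_small(self, small_grn):
        """Without planted pairs, PCC > 0.4 at n=98 is a far-tail event
        (null sd ~ 1/sqrt(97) ~ 0.10), so almost no pair crosses it."""
        from itertools import combinations

        prof = generate_celltype_profiles(small_grn, n_celltypes=98, seed=7)
        vals = prof.to_numpy()
        corr = np.corrcoef(vals.T)
        pairs = list(combinations(range(20), 2))
        rate = np.mean([corr[i, j] > 0.4 for i, j in pairs])
        assert rate <= 0.01

    def test_requires_three_celltypes(self, small_grn):
        with pytest.raises(ValueError):
            generate_celltype_profiles(small_grn, n_celltypes=2, seed=0)
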