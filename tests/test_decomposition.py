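"""NMF synergy extraction: factorization, VAF, rank rule, similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.decomposition import NMF as SkNMF

from spinalsynergy.cohort import _trapezoid
from spinalsynergy.decomposition import (
    RankSelection,
    SynergyNMF,
    cosine_similarity,
    nmf,
    nndsvd,
    normalize_synergies,
    pair_components,
    pairwise_similarity,
    select_rank,
    vaf,
)


def _random_nonneg(rng, m=5, n=60):
    return np.abs(rng.standard_normal((m, n)))


class TestNNDSVD:
    def test_nonnegative_and_deterministic(self, rng):
        A = _random_nonneg(rng)
        W1, H1 = nndsvd(A, 3)
        W2, H2 = nndsvd(A, 3)
        assert np.all(W1 >= 0) and np.all(H1 >= 0)
        np.testing.assert_array_equal(W1, W2)

    def test_rank_bounds(self, rng):
        A = _random_nonneg(rng)
        with pytest.raises(ValueError):
            nndsvd(A, 0)
        with pytest.raises(ValueError):
            nndsvd(A, 6)


class TestSynergyNMF:
    def test_exact_low_rank_matrix_fully_explained(self, rng):
        # Multiplicative updates converge only linearly, so an exactly
        # factorable matrix is recovered to a VAF deficit of ~1e-5.
        W0 = np.abs(rng.standard_normal((5, 2)))
        C0 = np.abs(rng.standard_normal((2, 80)))
        dec = nmf(W0 @ C0, 2, tol=1e-12, max_iter=50_000)
        assert dec.vaf_global == pytest.approx(1.0, abs=1e-4)

    def test_zero_muscle_row_gets_zero_weights(self, rng):
        D = _random_nonneg(rng)
        D[2] = 0.0
        dec = nmf(D, 2)
        assert np.all(dec.W[2] < 1e-6 * dec.W.max())

    def test_vaf_nondecreasing_in_rank(self, rng):
        D = _random_nonneg(rng, n=200)
        vafs = [nmf(D, r).vaf_global for r in range(1, 6)]
        assert np.all(np.diff(vafs) >= -1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_deterministic(self, rng):
        D = _random_nonneg(rng)
        d1, d2 = nmf(D, 2), nmf(D, 2)
        np.testing.assert_array_equal(d1.W, d2.W)
        np.testing.assert_array_equal(d1.C, d2.C)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=4))
    def test_multiplicative_updates_never_increase_objective(self, seed, rank):
        A = _random_nonneg(np.random.default_rng(seed), m=5, n=30)
        est = SynergyNMF(n_components=rank, max_iter=300)
        est.fit(A.T)
        hist = est.objective_history_
        assert np.all(np.diff(hist) <= 1e-8 * hist[0])
        assert np.all(est.components_ >= 0)

    def test_components_ordered_by_energy(self, rng):
        W0 = np.abs(rng.standard_normal((5, 2)))
        C0 = np.vstack([10 * np.abs(rng.standard_normal(80)),
                        np.abs(rng.standard_normal(80))])
        dec = nmf(W0 @ C0, 2)
        e = dec.component_energy()
        assert e[0] >= e[1]

    def test_matches_sklearn_reconstruction_quality(self, rng):
        """Independent route: sklearn's NMF with the same objective and a
        comparable deterministic init should reach a similar reconstruction."""
        D = _random_nonneg(rng, n=120)
        ours = nmf(D, 2)
        sk = SkNMF(n_components=2, init="nndsvda", solver="mu",
                   beta_loss="frobenius", max_iter=2000, tol=1e-6)
        Wsk = sk.fit_transform(D)
        sk_vaf = 1 - np.sum((D - Wsk @ sk.components_) ** 2) / np.sum(D**2)
        assert ours.vaf_global == pytest.approx(sk_vaf, abs=0.02)

    def test_sklearn_estimator_contract(self, rng):
        X = _random_nonneg(rng, m=5, n=40).T  # samples x features
        est = SynergyNMF(n_components=2)
        act = est.fit_transform(X)
        assert act.shape == (40, 2)
        assert est.components_.shape == (2, 5)
        assert est.get_params()["n_components"] == 2
        est2 = clone(est).set_params(n_components=3)
        assert est2.n_components == 3
        proj = est.transform(X)
        err_refit = np.linalg.norm(X - act @ est.components_)
        err_proj = np.linalg.norm(X - proj @ est.components_)
        assert err_proj <= err_refit * 1.5
        assert est.inverse_transform(act).shape == X.shape


class TestVaf:
    def test_perfect_reconstruction(self):
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        g, per = vaf(D, np.eye(2), D)
        assert g == pytest.approx(1.0)
        np.testing.assert_allclose(per, 1.0)

    def test_zero_reconstruction(self):
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        g, _ = vaf(D, np.zeros((2, 1)), np.zeros((1, 2)))
        assert g == pytest.approx(0.0)

    def test_hand_computed_example(self):
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        WC = np.array([[1.0, 2.0], [3.0, 0.0]])
        g, per = vaf(D, WC, np.eye(2))
        assert g == pytest.approx(1 - 16 / 30)
        assert per[0] == pytest.approx(1.0)
        assert per[1] == pytest.approx(1 - 16 / 25)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))


class TestSelectRank:
    def test_exact_rank_one_selects_one(self, rng):
        w = np.abs(rng.standard_normal(5))[:, None]
        c = np.abs(rng.standard_normal(50))[None, :]
        sel = select_rank(w @ c)
        assert isinstance(sel, RankSelection)
        assert sel.rank == 1 and not sel.discarded

    def test_unattainable_threshold_flags_discard(self, rng):
        D = _random_nonneg(rng, n=40)
        sel = select_rank(D, threshold=1.0)
        assert sel.discarded

    def test_scans_ascending(self, rng):
        D = _random_nonneg(rng, n=40)
        sel = select_rank(D, threshold=0.5)
        assert list(sel.vaf_by_rank) == list(range(1, sel.rank + 1))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_rank(np.ones((2, 2)), threshold=0.0)


class TestNormalization:
    def test_columns_and_rows_unit_max(self, rng):
        dec = nmf(_random_nonneg(rng), 2)
        out = normalize_synergies(dec)
        np.testing.assert_allclose(out.W.max(axis=0), 1.0)
        np.testing.assert_allclose(out.C.max(axis=1), 1.0)
        assert out.normalized

    def test_already_normalized_unchanged(self, rng):
        dec = normalize_synergies(nmf(_random_nonneg(rng), 2))
        out = normalize_synergies(dec)
        np.testing.assert_allclose(out.W, dec.W)

    def test_zero_column_stays_zero(self):
        from spinalsynergy.decomposition import SynergyDecomposition
        dec = SynergyDecomposition(
            W=np.array([[1.0, 0.0], [2.0, 0.0]]),
            C=np.ones((2, 4)), channels=["a", "b"],
            vaf_global=0.5, vaf_per_muscle=np.array([0.5, 0.5]), converged=True,
        )
        out = normalize_synergies(dec)
        np.testing.assert_array_equal(out.W[:, 1], 0.0)


class TestSimilarity:
    def test_identical_vectors(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1.0], [1.0, 2.0])

    def test_pairwise_identical(self):
        mean, M = pairwise_similarity([np.ones(3)] * 3)
        assert mean == pytest.approx(1.0)
        np.testing.assert_allclose(M, 1.0)

    def test_pairwise_orthogonal(self):
        mean, _ = pairwise_similarity([np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        assert mean == pytest.approx(0.0)

    def test_pairwise_needs_two(self):
        with pytest.raises(ValueError):
            pairwise_similarity([np.ones(3)])

    def test_greedy_pairing_recovers_permutation(self, rng):
        A = np.abs(rng.standard_normal((6, 3)))
        B = A[:, [2, 0, 1]]
        pairs = dict(pair_components(A, B))
        assert pairs == {0: 1, 1: 2, 2: 0}


class TestRecovery:
    def test_two_known_patterns_recovered_under_light_noise(self, rng):
        """Bursts built from a burst-shaped and a baseline-complement
        activation with spread mixing weights; <=10% multiplicative noise.
        (The burst/complement pair are the extreme rays of the data cone, so
        they are the identifiable form of the two latent sources.)"""
        n = 800
        trap = _trapezoid(n, 100.0, 500.0, 5000.0)
        C0 = np.vstack([trap, 1.0 - trap])
        W0 = np.array([[1.0, 0.05], [0.9, 0.1], [0.8, 0.2], [0.4, 0.35], [0.5, 0.45]])
        D = (W0 @ C0) * (1 + 0.1 * rng.uniform(-1, 1, size=(5, n)))
        dec = nmf(D, 2)
        pairs = pair_components(C0.T, dec.C.T)
        assert len(pairs) == 2
        for i, j in pairs:
            assert cosine_similarity(C0[i], dec.C[j]) >= 0.90
        wpairs = pair_components(W0, dec.W)
        for i, j in wpairs:
            assert cosine_similarity(W0[:, i], dec.W[:, j]) >= 0.90

    def test_latent_templates_recovered_in_span_sense_on_cohort(self):
        """Round trip through the full pipeline at default noise: the burst
        and baseline templates must be reconstructible from the recovered
        components (NMF is identifiable only up to the data cone's rays)."""
        from spinalsynergy.cohort import Cohort, CohortConfig
        from spinalsynergy.preprocessing import burst_matrices
        from spinalsynergy.decomposition import nonneg_projection_similarity

        cohort = Cohort(CohortConfig(seed=5))
        bms = burst_matrices(cohort.recording(0, 1, 0), expected=6)
        templates = cohort.latent_templates(bms[0].D.shape[1], bms[0].sample_rate)
        for bm in bms:
            dec = nmf(bm, 2)
            for name, tpl in templates.items():
                assert nonneg_projection_similarity(tpl, dec.C) >= 0.90, name
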