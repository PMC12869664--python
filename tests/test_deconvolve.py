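"""Cluster merging, signature construction and simplex-constrained
deconvolution, with brute-force and grid-search oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from clonerisk.containers import MergeConfig, PseudobulkProfile
from clonerisk.deconvolve import (build_signature_matrix,
                                  centroid_correlations, deconvolve_bulk,
                                  merge_clusters, weighted_similarity)


def make_profiles(centroids, n_cells=100):
    genes = np.array([f"g{i}" for i in range(len(centroids[0]))], dtype=object)
    n_cells = [n_cells] * len(centroids) if np.isscalar(n_cells) else n_cells
    return [PseudobulkProfile(cluster_id=i, centroid=np.asarray(c, float),
                              n_cells=n_cells[i], gene_ids=genes)
            for i, c in enumerate(centroids)]


class TestCorrelations:
    def test_identity_and_negation(self, rng):
        c = rng.random(30)
        corr = centroid_correlations(make_profiles([c, c, 1.0 - c]))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_matches_brute_force_covariance(self, rng):
        X = rng.random((4, 50))
        corr = centroid_correlations(make_profiles(list(X)))
        for i, j in itertools.combinations(range(4), 2):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            manual = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert corr[i, j] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_centroid_is_na(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = centroid_correlations(make_profiles([np.ones(25),
                                                        rng.random(25)]))
        assert np.isnan(corr[0, 1])


class TestMerge:
    def test_single_linkage_chain_merges_transitively(self, rng):
        base = rng.random(100)
        # A~B and B~C above threshold, A~C below: one chained component
        a = base + rng.normal(0, 0.01, 100)
        b = base + rng.normal(0, 0.01, 100)
        c = b + rng.normal(0, 0.015, 100)
        profs = make_profiles([a, b, c])
        corr = centroid_correlations(profs)
        thr = sorted([corr[0, 1], corr[1, 2], corr[0, 2]])[1] - 1e-6
        cfg = MergeConfig(r_threshold=max(min(thr, 0.999), 0.5), min_cells=1)
        if corr[0, 2] < cfg.r_threshold < min(corr[0, 1], corr[1, 2]):
            merged = merge_clusters(profs, corr, cfg)
            assert len(merged) == 1
            assert len(merged[0].members) == 3

    def test_no_edges_no_merging(self, rng):
        profs = make_profiles(list(rng.random((4, 60))))
        merged = merge_clusters(profs, config=MergeConfig(min_cells=1))
        assert len(merged) == 4

    def test_small_clusters_disqualified_before_merging(self, rng):
        c = rng.random(40)
        profs = make_profiles([c, c + 1e-9, rng.random(40)],
                              n_cells=[30, 100, 100])
        merged = merge_clusters(profs, config=MergeConfig(min_cells=50))
        members = [m for s in merged for m in s.members]
        assert ("", 0) not in members  # the 30-cell cluster is gone
        assert len(merged) == 2

    def test_merged_centroid_is_weighted_convex_combination(self, rng):
        c = rng.random(50)
        profs = make_profiles([c, c + rng.normal(0, 1e-4, 50)],
                              n_cells=[100, 300])
        merged = merge_clusters(profs, config=MergeConfig(min_cells=1))
        assert len(merged) == 1
        expect = (100 * profs[0].centroid + 300 * profs[1].centroid) / 400
        np.testing.assert_allclose(merged[0].centroid, expect, atol=1e-12)
        assert merged[0].n_cells == 400

    def test_partition_property(self, rng):
        profs = make_profiles(list(rng.random((6, 80))), n_cells=60)
        merged = merge_clusters(profs, config=MergeConfig(min_cells=50))
        members = sorted(m for s in merged for m in s.members)
        assert members == [("", i) for i in range(6)]
        assert len(merged) <= 6


class TestSignature:
    def _merged(self, rng, k=3, g=200):
        profs = make_profiles(list(rng.random((k, g)) * 2), n_cells=100)
        return merge_clusters(profs, config=MergeConfig(min_cells=1))

    def test_all_genes_mode_preserves_genes(self, rng):
        sig = build_signature_matrix(self._merged(rng))
        assert sig.matrix.shape == (200, 3)

    def test_top_k_bound_and_marker_ranking(self, rng):
        merged = self._merged(rng, k=4)
        sig = build_signature_matrix(merged, "top_k_markers", top_k=20)
        assert len(sig.matrix) <= 80
        # each subclone's top markers by brute-force effect ranking are kept
        cent = np.column_stack([m.centroid for m in merged])
        for j in range(4):
            effect = cent[:, j] - np.delete(cent, j, axis=1).mean(axis=1)
            top = np.argsort(effect)[-20:]
            genes = np.asarray(merged[0].gene_ids)[top]
            assert set(genes) <= set(sig.matrix.index)

    def test_fewer_than_two_subclones_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            build_signature_matrix(self._merged(rng)[:1])


def _signature_from_linear(profiles, names=None):
    """Helper: wrap linear-scale relative profiles into a SignatureMatrix."""
    merged = merge_clusters(
        make_profiles([np.log1p(p * 1e4) for p in profiles.T]),
        config=MergeConfig(min_cells=1),
    )
    # undo merging side effects: profiles are random, never merged
    sig = build_signature_matrix(merged)
    if names:
        sig.matrix.columns = names
    return sig


class TestDeconvolution:
    def _profiles(self, rng, g=2000, k=8):
        p = rng.lognormal(0, 1, (g, k))
        return p / p.sum(axis=0)

    def test_noiseless_mixture_recovered_exactly(self, rng):
        prof = self._profiles(rng, g=500, k=4)
        sig = _signature_from_linear(prof)
        pi = np.array([0.6, 0.4, 0.0, 0.0])
        bulk = pd.Series((prof @ pi) * 1e4, index=sig.matrix.index)
        est = deconvolve_bulk(bulk, sig)
        np.testing.assert_allclose(est.proportions.to_numpy(), pi, atol=1e-8)
        assert est.kkt_residual < 1e-6

    def test_pure_column_gives_indicator(self, rng):
        prof = self._profiles(rng, g=300, k=3)
        sig = _signature_from_linear(prof)
        bulk = pd.Series(prof[:, 1] * 1e4, index=sig.matrix.index)
        est = deconvolve_bulk(bulk, sig)
        np.testing.assert_allclose(est.proportions.to_numpy(), [0, 1, 0],
                                   atol=1e-8)

    def test_invariant_to_bulk_rescaling(self, rng):
        prof = self._profiles(rng, g=300, k=3)
        sig = _signature_from_linear(prof)
        bulk = pd.Series(prof @ np.array([0.2, 0.5, 0.3]),
                         index=sig.matrix.index)
        a = deconvolve_bulk(bulk, sig).proportions
        b = deconvolve_bulk(bulk * 731.0, sig).proportions
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_matches_grid_search_oracle_on_noisy_three_subclones(self, rng):
        prof = self._profiles(rng, g=400, k=3)
        sig = _signature_from_linear(prof)
        truth = np.array([0.5, 0.3, 0.2])
        noisy = (prof @ truth) * rng.lognormal(0, 0.2, 400)
        bulk = pd.Series(noisy, index=sig.matrix.index)
        est = deconvolve_bulk(bulk, sig).proportions.to_numpy()
        # brute-force grid search over the 2-simplex at step 0.01
        A = sig.matrix.to_numpy()
        A = A / A.sum(axis=0) * 1e4
        b = noisy / noisy.sum() * 1e4
        best, best_pi = np.inf, None
        for p1 in np.arange(0, 1.0001, 0.01):
            for p2 in np.arange(0, 1.0001 - p1, 0.01):
                pi = np.array([p1, p2, 1 - p1 - p2])
                r = np.linalg.norm(A @ pi - b)
                if r < best:
                    best, best_pi = r, pi
        assert np.abs(est - best_pi).max() < 0.011  # within one grid step
        assert np.abs(est - truth).max() < 0.05

    def test_weighting_modes_run_and_stay_on_simplex(self, rng):
        prof = self._profiles(rng, g=300, k=4)
        sig = _signature_from_linear(prof)
        bulk = pd.Series((prof @ np.array([0.4, 0.3, 0.2, 0.1])) *
                         rng.lognormal(0, 0.3, 300), index=sig.matrix.index)
        for mode in ("none", "variance", "dampened"):
            est = deconvolve_bulk(bulk, sig, weighting=mode)
            assert est.proportions.sum() == pytest.approx(1.0, abs=1e-9)
            assert (est.proportions >= 0).all()
        with pytest.raises(ValueError, match="weighting"):
            deconvolve_bulk(bulk, sig, weighting="bogus")

    def test_duplicate_columns_warn_but_solve(self, rng):
        from clonerisk.containers import SignatureMatrix
        prof = self._profiles(rng, g=300, k=2)
        prof = np.column_stack([prof, prof[:, 0]])  # exact duplicate column
        genes = [f"g{i}" for i in range(300)]
        sig = SignatureMatrix(
            matrix=pd.DataFrame(prof, index=genes, columns=list("abc")),
            provenance={c: {"members": [("", i)]} for i, c in enumerate("abc")},
        )
        bulk = pd.Series(prof[:, 1] * 1e4, index=sig.matrix.index)
        with pytest.warns(UserWarning, match="rank-deficient"):
            est = deconvolve_bulk(bulk, sig)
        assert est.proportions.iloc[1] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_shared_genes_rejected(self, rng):
        prof = self._profiles(rng, g=100, k=2)
        sig = _signature_from_linear(prof)
        bulk = pd.Series(np.ones(5), index=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="shared"):
            deconvolve_bulk(bulk, sig)


class TestWeightedSimilarity:
    def test_query_equal_to_reference_wins(self, rng):
        R = pd.DataFrame(rng.lognormal(0, 1, (200, 3)),
                         index=[f"g{i}" for i in range(200)],
                         columns=list("abc"))
        w = weighted_similarity(R["b"], R)
        assert w["b"] == pytest.approx(1.0, abs=1e-9)

    def test_unexplained_query_flags_residual(self, rng):
        R = pd.DataFrame(np.eye(30)[:, :2] * 10 + 1e-12,
                         index=[f"g{i}" for i in range(30)], columns=list("ab"))
        q = pd.Series(np.r_[np.zeros(25), np.ones(5) * 10], index=R.index)
        w = weighted_similarity(q, R)
        assert w.attrs["residual_norm"] > 1.0

    def test_reduces_to_plain_nnls_under_equal_weights(self, rng):
        import scipy.optimize
        R = pd.DataFrame(np.full((50, 2), 3.0) + rng.random((50, 2)),
                         index=[f"g{i}" for i in range(50)], columns=list("ab"))
        # make the diagonal weights exactly equal by equalizing row means
        R.iloc[:, 1] = 2 * R.iloc[:, 0].mean() - R.iloc[:, 0]
        q = pd.Series(0.7 * R["a"] + 0.3 * R["b"], index=R.index)
        w = weighted_similarity(q, R)
        coef, _ = scipy.optimize.nnls(R.to_numpy(), q.to_numpy())
        np.testing.assert_allclose(w.attrs["raw_coef"], coef, atol=1e-8)
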