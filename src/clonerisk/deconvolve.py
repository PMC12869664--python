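"""Cluster merging, signature-matrix construction and bulk deconvolution.

Patient-specific clusters whose mean log-normalized profiles correlate at
r > 0.986 are combined (single-linkage connected components; clusters under
50 cells are disqualified first).  Merged centroids — mapped back to linear
scale so mixing is linear — form a gene x subclone signature matrix, and a
bulk profile is expressed as a non-negative, sum-to-one mixture of its
columns by (optionally weighted) least squares on library-size-normalized
vectors.  The solver is an exact active-set method on the simplex, so
noiseless mixtures are recovered to machine precision.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .containers import (AbundanceEstimate, MergeConfig, MergedSubclone,
                         PseudobulkProfile, SignatureMatrix)

log = logging.getLogger(__name__)

_SCALE = 1e4  # both bulk and signature normalized to counts-per-1e4


def centroid_correlations(profiles: list[PseudobulkProfile]) -> np.ndarray:
    """Pairwise Pearson correlation of cluster centroids (diagonal 1)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X = np.vstack([p.centroid for p in profiles])
    if X.shape[1] < 20:
        raise ValueError("need at least 20 shared genes")
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance centroid(s); their correlations are NA")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def merge_clusters(
    profiles: list[PseudobulkProfile],
    corr: np.ndarray | None = None,
    config: MergeConfig = MergeConfig(),
    provenance: list | None = None,
    labels: list | None = None,
) -> list[MergedSubclone]:
    """Merge high-similarity clusters into aggregate subclones.

    Clusters with fewer than ``config.min_cells`` cells are dropped first;
    the survivors are partitioned into single-linkage connected components
    over edges with r > ``config.r_threshold``; each component's centroid is
    the cell-count-weighted mean of its members.  ``provenance`` (e.g.
    ``(patient, cluster_id)`` tuples) and longitudinal ``labels`` ride along.
    """
    if provenance is None:
        provenance = [("", p.cluster_id) for p in profiles]
    if labels is None:
        labels = [None] * len(profiles)
    keep = [i for i, p in enumerate(profiles) if p.n_cells >= config.min_cells]
    dropped = len(profiles) - len(keep)
    if dropped:
        log.info("disqualified %d clusters with < %d cells", dropped,
                 config.min_cells)
    if not keep:
        warnings.warn("no clusters survive the minimum-cell filter")
        return []
    kept = [profiles[i] for i in keep]
    if corr is None:
        corr = centroid_correlations(kept) if len(kept) > 1 else np.ones((1, 1))
    else:
        if corr.shape != (len(profiles),) * 2:
            raise ValueError("correlation matrix inconsistent with profiles")
        corr = corr[np.ix_(keep, keep)]
    adj = sp.csr_matrix(np.nan_to_num(corr, nan=-1.0) > config.r_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    merged = []
    for c in range(n_comp):
        members = [kept[i] for i in np.where(comp == c)[0]]
        w = np.array([m.n_cells for m in members], dtype=float)
        centroid = np.average([m.centroid for m in members], axis=0, weights=w)
        idx = [keep[i] for i in np.where(comp == c)[0]]
        diam = min(
            (corr[i, j] for a, i in enumerate(np.where(comp == c)[0])
             for j in np.where(comp == c)[0][a + 1:]),
            default=1.0,
        )
        if len(members) > 1:
            log.info("merged %d clusters (minimum within-group r=%.4f)",
                     len(members), diam)
        merged.append(MergedSubclone(
            subclone_id=f"M{c:03d}",
            centroid=centroid,
            n_cells=int(w.sum()),
            members=[provenance[i] for i in idx],
            labels=[labels[i] for i in idx],
            gene_ids=members[0].gene_ids,
        ))
    return merged


def build_signature_matrix(
    merged: list[MergedSubclone],
    gene_selection: str = "all",
    top_k: int = 50,
) -> SignatureMatrix:
    """Gene x subclone signature on the linear scale (expm1 of centroids).

    ``top_k_markers`` restricts rows to the union of each subclone's top-k
    genes by effect size (centroid minus mean of the other centroids).
    """
    if len(merged) < 2:
        raise ValueError("need at least 2 subclones for a signature")
    genes = np.asarray(merged[0].gene_ids)
    values = np.column_stack([np.expm1(m.centroid) for m in merged])
    if (values.sum(axis=0) == 0).any():
        raise ValueError("signature contains an all-zero column")
    cols = [m.subclone_id for m in merged]
    if gene_selection == "top_k_markers":
        keep = np.zeros(len(genes), dtype=bool)
        cent = np.column_stack([m.centroid for m in merged])
        for j in range(cent.shape[1]):
            others = np.delete(cent, j, axis=1).mean(axis=1)
            effect = cent[:, j] - others
            keep[np.argsort(effect)[-top_k:]] = True
        values, genes = values[keep], genes[keep]
    elif gene_selection != "all":
        raise ValueError(f"unknown gene_selection {gene_selection!r}")
    matrix = pd.DataFrame(values, index=genes, columns=cols)
    provenance = {m.subclone_id: {"members": m.members, "labels": m.labels,
                                  "n_cells": m.n_cells} for m in merged}
    return SignatureMatrix(matrix=matrix, provenance=provenance)


def _simplex_lsq(A: np.ndarray, b: np.ndarray, w: np.ndarray | None = None):
    """Exact active-set solver for min ||W^1/2 (A pi - b)|| on the simplex.

    Solves the KKT system on the current support, drops the most negative
    coordinate while infeasible, then re-adds zero coordinates whose
    gradient violates stationarity.  Returns (pi, kkt_residual).
    """
    n = A.shape[1]
    scale = np.linalg.norm(b)
    A = A / scale  # tolerance-friendly scaling; solution is unchanged
    b = b / scale
    if w is None:
        G = A.T @ A
        c = A.T @ b
    else:
        Aw = A * w[:, None]
        G = A.T @ Aw
        c = Aw.T @ b
    support = np.ones(n, dtype=bool)
    for _ in range(6 * n + 30):
        idx = np.where(support)[0]
        k = len(idx)
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = G[np.ix_(idx, idx)]
        K[:k, k] = 1.0
        K[k, :k] = 1.0
        rhs = np.r_[c[idx], 1.0]
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        pi_s, mu = sol[:k], sol[k]
        if (pi_s < -1e-12).any():
            support[idx[np.argmin(pi_s)]] = False
            if not support.any():  # pathological; restart from best single
                support[np.argmax(c)] = True
            continue
        pi = np.zeros(n)
        pi[idx] = np.clip(pi_s, 0.0, None)
        grad = G @ pi - c
        off = np.where(~support)[0]
        gtol = 1e-9 * (1.0 + abs(mu))
        viol = off[grad[off] < mu - gtol] if len(off) else np.array([], int)
        if len(viol):
            support[viol[np.argmin(grad[viol])]] = True
            continue
        kkt = max(
            float(np.max(np.abs(grad[idx] - mu))) if k else 0.0,
            float(abs(pi.sum() - 1.0)),
        )
        return pi / pi.sum(), kkt
    return _simplex_lsq_slsqp(G, c, n)


def _simplex_lsq_slsqp(G, c, n):
    """SLSQP fallback for the rare case the active set cycles."""
    res = scipy.optimize.minimize(
        lambda p: 0.5 * p @ G @ p - c @ p,
        np.full(n, 1.0 / n),
        jac=lambda p: G @ p - c,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones(n)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    pi = np.clip(res.x, 0.0, None)
    pi /= pi.sum()
    grad = G @ pi - c
    active = pi > 1e-9
    mu = grad[active].mean() if active.any() else 0.0
    kkt = float(np.max(np.abs(grad[active] - mu))) if active.any() else 0.0
    return pi, kkt


def deconvolve_bulk(
    bulk,
    sig: SignatureMatrix,
    weighting: str = "none",
    min_shared_genes: int = 20,
    damp_iters: int = 4,
    damp_quantile: float = 0.98,
) -> AbundanceEstimate:
    """Estimate subclone proportions in one bulk sample.

    ``bulk`` is a pandas Series (gene-indexed) or array aligned with the
    signature rows.  Both sides are normalized to counts-per-1e4, so the
    solution is invariant to positive rescaling of the bulk vector.
    ``weighting``: ``none`` (W=I), ``variance`` (W_g = 1/(1+b_g)) or
    ``dampened`` (iteratively reweighted by the model fit, weights capped at
    a high quantile).
    """
    S = sig.matrix
    if isinstance(bulk, pd.Series):
        shared = S.index.intersection(bulk.index)
        if len(shared) < min_shared_genes:
            raise ValueError(
                f"only {len(shared)} genes shared between bulk and signature"
            )
        b = bulk.loc[shared].to_numpy(dtype=float)
        A = S.loc[shared].to_numpy(dtype=float)
    else:
        b = np.asarray(bulk, dtype=float)
        if len(b) != len(S):
            raise ValueError("unlabeled bulk vector must align with signature rows")
        A = S.to_numpy(dtype=float)
    if (b < 0).any():
        raise ValueError("bulk expression must be non-negative")
    if b.sum() == 0:
        raise ValueError("bulk vector is all zeros")
    b = b / b.sum() * _SCALE
    A = A / A.sum(axis=0, keepdims=True) * _SCALE
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient signature (near-duplicate columns); "
                      "solution returned but may be non-unique")
    if weighting == "none":
        pi, kkt = _simplex_lsq(A, b)
    elif weighting == "variance":
        pi, kkt = _simplex_lsq(A, b, w=1.0 / (1.0 + b))
    elif weighting == "dampened":
        pi, kkt = _simplex_lsq(A, b)
        for _ in range(damp_iters):
            fitted = A @ pi
            w = 1.0 / np.maximum(fitted, 1e-6)
            w = np.minimum(w, np.quantile(w, damp_quantile))
            pi, kkt = _simplex_lsq(A, b, w=w)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    resid = float(np.linalg.norm(A @ pi - b))
    return AbundanceEstimate(
        proportions=pd.Series(pi, index=S.columns),
        residual_norm=resid, kkt_residual=kkt,
        method=f"simplex-lsq/{weighting}",
    )


def deconvolve_cohort(bulk: pd.DataFrame, sig: SignatureMatrix,
                      weighting: str = "none", **kwargs) -> pd.DataFrame:
    """Deconvolve every column of a genes x samples bulk table."""
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        rows = {
            s: deconvolve_bulk(bulk[s], sig, weighting, **kwargs).proportions
            for s in bulk.columns
        }
    return pd.DataFrame(rows).T


def weighted_similarity(
    query: np.ndarray,
    reference: pd.DataFrame,
    min_shared_genes: int = 20,
) -> pd.Series:
    """Diagonally weighted NNLS association of a query centroid with references.

    Weights W_g = 1/(1 + mean reference expression of g) de-emphasize
    high-abundance genes; the returned weights are normalized to sum 1 and
    carry the residual norm in ``.attrs``.
    """
    if isinstance(query, pd.Series):
        shared = reference.index.intersection(query.index)
        if len(shared) < min_shared_genes:
            raise ValueError("too few shared genes")
        q = query.loc[shared].to_numpy(dtype=float)
        R = reference.loc[shared].to_numpy(dtype=float)
    else:
        q = np.asarray(query, dtype=float)
        R = reference.to_numpy(dtype=float)
        if len(q) != len(R):
            raise ValueError("query must align with reference rows")
    w = 1.0 / (1.0 + R.mean(axis=1))
    sw = np.sqrt(w)
    coef, resid = scipy.optimize.nnls(R * sw[:, None], q * sw)
    total = coef.sum()
    if total <= 0:
        warnings.warn("query is unexplained by the references (all-zero fit)")
        out = pd.Series(np.zeros(R.shape[1]), index=reference.columns)
    else:
        out = pd.Series(coef / total, index=reference.columns)
    out.attrs["residual_norm"] = float(resid)
    out.attrs["raw_coef"] = coef
    return out
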