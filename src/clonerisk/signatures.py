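"""Recurrent-upregulation gene signatures.

Each expanded / relapsed / stable cluster is compared to the pooled cells
of all diminished clusters of the same patient by two-sided Wilcoxon
rank-sum tests on log-normalized expression, with a 25%-expressed filter
and Benjamini-Hochberg adjustment within the comparison.  A gene's
*recurrence tally* counts the comparisons in which it was significantly
upregulated (adjusted p < 0.05 and positive effect); genes above an
Otsu-style cutoff — chosen to split the bimodal tally distribution —
constitute the recurrence ("Expanded Genes") signature.  Enrichment of the
signature in named gene sets uses a one-sided hypergeometric test; a
simple rank-z score summarizes a gene set in bulk samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, otsu_threshold

log = logging.getLogger(__name__)


def rank_sum_de(
    test_values: np.ndarray,
    ref_values: np.ndarray,
    gene_ids,
    min_frac_expressed: float = 0.25,
    alpha: float = 0.05,
    comparison_id: str = "cmp",
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum comparison of two cell groups.

    Inputs are genes x cells matrices of log-normalized expression.  Genes
    expressed (value > 0) in fewer than ``min_frac_expressed`` of the cells
    of both groups are filtered out and carry p = NA.  Effect is the
    difference of group means; BH adjustment spans the tested genes of this
    comparison; ``significant_up`` requires adjusted p < alpha and a
    positive effect.
    """
    test = np.asarray(
        test_values.todense() if hasattr(test_values, "todense") else test_values,
        dtype=float,
    )
    ref = np.asarray(
        ref_values.todense() if hasattr(ref_values, "todense") else ref_values,
        dtype=float,
    )
    if test.shape[1] < 3 or ref.shape[1] < 3:
        raise ValueError("need at least 3 cells per group")
    if test.shape[0] != ref.shape[0] or test.shape[0] != len(gene_ids):
        raise ValueError("gene dimension mismatch")
    frac_test = (test > 0).mean(axis=1)
    frac_ref = (ref > 0).mean(axis=1)
    tested = (frac_test >= min_frac_expressed) | (frac_ref >= min_frac_expressed)
    p = np.full(len(gene_ids), np.nan)
    if tested.any():
        res = stats.mannwhitneyu(test[tested], ref[tested], axis=1,
                                 alternative="two-sided")
        p[tested] = res.pvalue
    p_adj = bh_adjust(p)
    effect = test.mean(axis=1) - ref.mean(axis=1)
    out = pd.DataFrame({
        "gene": np.asarray(gene_ids, dtype=object),
        "effect": effect,
        "frac_expressed_test": frac_test,
        "frac_expressed_ref": frac_ref,
        "p": p,
        "p_adj": p_adj,
    }).set_index("gene")
    out["significant_up"] = (out["p_adj"] < alpha) & (out["effect"] > 0)
    out.attrs["comparison_id"] = comparison_id
    out.attrs["alpha"] = alpha
    return out


def tally_recurrence(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Count, per gene, the comparisons with significant upregulation.

    ``n_comparisons_total`` is the number of comparisons supplied, not the
    per-gene tested count.  Duplicate comparison ids are rejected.
    """
    if len(results) == 0:
        raise ValueError("need at least one comparison")
    ids = [r.attrs.get("comparison_id") for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated comparison ids: {ids}")
    tally = None
    for r in results:
        s = r["significant_up"].astype(int)
        tally = s if tally is None else tally.add(s, fill_value=0)
    out = pd.DataFrame({"n_significant": tally.astype(int)})
    out["n_comparisons_total"] = len(results)
    return out


def select_bimodal_cutoff(tally: pd.DataFrame | np.ndarray,
                          manual: int | None = None) -> int:
    """Cutoff splitting the bimodal tally distribution (Otsu criterion).

    Returns the smallest tally in the upper class.  A ``manual`` override
    is accepted and logged.
    """
    values = (tally["n_significant"].to_numpy()
              if isinstance(tally, pd.DataFrame) else np.asarray(tally))
    if manual is not None:
        log.info("using manual recurrence cutoff %d", manual)
        return int(manual)
    return otsu_threshold(values)


def select_genes(tally: pd.DataFrame, cutoff: int) -> pd.DataFrame:
    out = tally.copy()
    out["selected"] = out["n_significant"] >= cutoff
    return out


def enrichment_test(
    gene_list,
    gene_sets: dict,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_list`` in each set.

    Sets are intersected with the universe; p is the upper-tail probability
    of the observed overlap; BH adjustment spans the sets.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe or not genes:
        raise ValueError("gene list and universe must be non-empty")
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe)
        k = len(set(members) & genes)
        # P(overlap >= k) drawing n from N with K successes
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["p_adj"] < alpha
    return out


def gene_set_score(expression: pd.DataFrame, gene_set,
                   min_genes: int = 5) -> pd.Series:
    """Per-sample activity score of a gene set in bulk expression.

    Each gene's values are ranked across samples and z-scored; the score is
    the mean over set genes, so it is invariant to any monotone per-gene
    transform of the input.
    """
    present = expression.index.intersection(pd.Index(list(gene_set)))
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} set genes present (need >= {min_genes})"
        )
    ranks = expression.rank(axis=1)
    z = ranks.sub(ranks.mean(axis=1), axis=0).div(
        ranks.std(axis=1, ddof=0).replace(0, np.nan), axis=0)
    return z.loc[present].mean(axis=0).rename("gene_set_score")


def patient_comparisons(
    norm_values,
    gene_ids,
    cluster_labels: np.ndarray,
    class_table: pd.DataFrame,
    patient: str,
    min_cells: int = 3,
    **de_kwargs,
) -> list[pd.DataFrame]:
    """All test-cluster vs pooled-diminished comparisons for one patient.

    Test clusters are those labeled expanded, relapsed or stable; the
    reference pool is the union of cells of all diminished clusters.
    Returns an empty list when the patient lacks a diminished pool.
    """
    labels = class_table["label"]
    dim_ids = labels.index[labels == "diminished"]
    pool_mask = np.isin(cluster_labels, dim_ids)
    if pool_mask.sum() < min_cells:
        log.warning("patient %s: no usable diminished pool", patient)
        return []
    dense = np.asarray(
        norm_values.todense() if hasattr(norm_values, "todense") else norm_values
    )
    ref = dense[:, pool_mask]
    results = []
    for cid in labels.index[labels.isin(["expanded", "relapsed", "stable"])]:
        mask = cluster_labels == cid
        if mask.sum() < min_cells:
            continue
        results.append(rank_sum_de(
            dense[:, mask], ref, gene_ids,
            comparison_id=f"{patient}:c{cid}_vs_diminished", **de_kwargs,
        ))
    return results
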