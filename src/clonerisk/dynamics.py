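"""Longitudinal subclone classification.

A cluster's diagnosis/relapse composition fractions are computed relative
to each timepoint's total QC-passing cells (normal-donor cells excluded
from both denominators).  With threshold theta (default 10%), clusters are
labeled:

* ``expanded``   — present at diagnosis (n_dx > 0), f_rel > theta, f_dx <= theta
* ``diminished`` — f_dx > theta, f_rel <= theta
* ``stable``     — f_dx > theta and f_rel > theta
* ``relapsed``   — absent at diagnosis (n_dx = 0), f_rel > theta
* ``other``      — everything else (small clusters, majority-normal clusters)

Inequalities at the threshold are strict, and this is the only reading
under which the four named categories are mutually exclusive and exhaustive
over clusters holding >theta of either timepoint.  A diminished cluster is
flagged *transforming* when its centroid correlates strongly with some
relapse-emergent cluster's centroid — a lightweight surrogate for trajectory
inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("expanded", "stable", "diminished", "relapsed", "other")


def composition_fractions(labels: np.ndarray, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster diagnosis/relapse counts and fractions.

    ``labels`` assigns a cluster to every cell of ``cell_meta`` (QC-passing
    cells only).  Cells with timepoints other than diagnosis/relapse (e.g.
    normal donors) are excluded from the denominators but counted in
    ``n_normal`` / ``frac_normal`` for majority-normal detection.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cell_meta):
        raise ValueError("labels must cover cell_meta")
    tp = cell_meta["timepoint"].to_numpy()
    is_dx, is_rel = tp == "diagnosis", tp == "relapse"
    N_dx, N_rel = int(is_dx.sum()), int(is_rel.sum())
    if N_dx == 0 or N_rel == 0:
        raise ValueError("a timepoint has zero QC-passing cells")
    rows = []
    for cid in np.unique(labels):
        in_c = labels == cid
        n_dx = int((in_c & is_dx).sum())
        n_rel = int((in_c & is_rel).sum())
        n_other = int((in_c & ~is_dx & ~is_rel).sum())
        rows.append({
            "cluster_id": int(cid), "n_dx": n_dx, "n_rel": n_rel,
            "f_dx": n_dx / N_dx, "f_rel": n_rel / N_rel,
            "n_normal": n_other,
            "frac_normal": n_other / max(in_c.sum(), 1),
        })
    return pd.DataFrame(rows).set_index("cluster_id")


def classify_subclone(
    n_dx: int, n_rel: int, f_dx: float, f_rel: float, threshold: float = 0.10
) -> str:
    """Label one cluster from its longitudinal composition (total function)."""
    if f_rel > threshold:
        if n_dx == 0:
            return "relapsed"
        if f_dx > threshold:
            return "stable"
        return "expanded"
    if f_dx > threshold:
        return "diminished"
    return "other"


def classify_table(
    fractions: pd.DataFrame,
    threshold: float = 0.10,
    normal_majority: float = 0.5,
) -> pd.DataFrame:
    """Vectorized classification of a composition table.

    Clusters whose cells are mostly normal-donor derived are pre-labeled
    ``other`` regardless of their tumor-timepoint fractions.
    """
    out = fractions.copy()
    out["label"] = [
        classify_subclone(r.n_dx, r.n_rel, r.f_dx, r.f_rel, threshold)
        for r in fractions.itertuples()
    ]
    if "frac_normal" in out.columns:
        out.loc[out["frac_normal"] > normal_majority, "label"] = "other"
    return out


def classify_patient_group(labels) -> str:
    """Group A iff the patient has any expanded subclone, else Group B."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("patient has no clusters")
    return "A" if "expanded" in labels else "B"


def flag_transforming(
    diminished_centroids: np.ndarray,
    relapsed_centroids: np.ndarray,
    r_min: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag diminished clusters whose centroid tracks a relapse-emergent one.

    Returns (flags, best_r) per diminished centroid; a cluster transforms
    iff its maximum Pearson correlation with any relapsed centroid is
    >= ``r_min``.  With no relapsed (or no diminished) centroids all flags
    are False.
    """
    dim = np.atleast_2d(np.asarray(diminished_centroids, dtype=float))
    rel = np.atleast_2d(np.asarray(relapsed_centroids, dtype=float))
    if dim.size == 0 or rel.size == 0:
        n = dim.shape[0] if dim.size else 0
        return np.zeros(n, dtype=bool), np.full(n, np.nan)
    dc = dim - dim.mean(axis=1, keepdims=True)
    rc = rel - rel.mean(axis=1, keepdims=True)
    denom = np.outer(np.linalg.norm(dc, axis=1), np.linalg.norm(rc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (dc @ rc.T) / denom
    best = np.nanmax(corr, axis=1)
    return best >= r_min, best


def compare_condition_composition(
    labels: np.ndarray,
    condition: np.ndarray,
    replicate: np.ndarray,
    min_fold: float = 3.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treated-vs-control composition shift per cluster.

    Cluster fractions are computed within each replicate animal/sample; a
    Welch t-test compares the per-replicate fractions between conditions.
    A cluster is ``expanded_under_treatment`` when its mean treated fraction
    is at least ``min_fold`` times the control fraction at p < alpha
    (``diminished_under_treatment`` symmetric).  With a single replicate per
    arm the p-value is NA and the verdict rests on fold change alone.
    """
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    replicate = np.asarray(replicate)
    bad = set(condition) - {"treated", "control"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    df = pd.DataFrame({"cluster": labels, "condition": condition,
                       "replicate": replicate})
    # per-replicate cluster fractions (replicates nested in condition)
    frac = (df.groupby(["condition", "replicate"])["cluster"]
              .value_counts(normalize=True).rename("frac").reset_index())
    rows = []
    eps = 1e-12
    for cid in np.unique(labels):
        ft = _rep_fracs(frac, "treated", cid)
        fc = _rep_fracs(frac, "control", cid)
        mt, mc = ft.mean(), fc.mean()
        fold = (mt + eps) / (mc + eps)
        if len(ft) >= 2 and len(fc) >= 2:
            p = stats.ttest_ind(ft, fc, equal_var=False).pvalue
        else:
            p = np.nan
        signif = (p < alpha) if np.isfinite(p) else True  # fold-only fallback
        if fold >= min_fold and signif:
            verdict = "expanded_under_treatment"
        elif fold <= 1.0 / min_fold and signif:
            verdict = "diminished_under_treatment"
        else:
            verdict = "unchanged"
        rows.append({"cluster_id": int(cid), "frac_treated": mt,
                     "frac_control": mc, "fold": fold, "p": p,
                     "verdict": verdict})
    return pd.DataFrame(rows).set_index("cluster_id")


def _rep_fracs(frac: pd.DataFrame, condition: str, cid) -> np.ndarray:
    reps = frac.loc[frac["condition"] == condition, "replicate"].unique()
    sel = frac[(frac["condition"] == condition) & (frac["cluster"] == cid)]
    by_rep = sel.set_index("replicate")["frac"]
    return np.array([by_rep.get(r, 0.0) for r in reps])
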