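"""Small statistical kernels used across modules.

Contains a Benjamini-Hochberg step-up adjustment, an Otsu-style threshold
for integer tallies, and a fast Newton fit of the univariate Cox partial
likelihood with Breslow tie handling.  The univariate Cox fit exists so that
screening dozens of subclones over many simulation replicates stays cheap;
it is validated against lifelines in the test suite, and multivariate fits
always go through lifelines.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.sum(~np.isnan(p)))
    return np.minimum(p * m, 1.0)


def otsu_threshold(values: np.ndarray) -> int:
    """Threshold an integer tally distribution by minimum intra-class variance.

    Returns the smallest value of the upper class.  Raises ``ValueError`` on
    a degenerate (single-valued) distribution.
    """
    values = np.asarray(values)
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) < 2:
        raise ValueError(
            "tally distribution is degenerate (single value); supply a manual cutoff"
        )
    best = None
    best_cut = None
    for i in range(1, len(uniq)):
        lo = values[values < uniq[i]]
        hi = values[values >= uniq[i]]
        w = len(lo) * np.var(lo) + len(hi) * np.var(hi)
        if best is None or w < best - 1e-12:
            best = w
            best_cut = int(uniq[i])
    return best_cut


def cox_univariate(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict:
    """Newton fit of a one-covariate Cox proportional-hazards model.

    Breslow handling of tied event times.  Returns coefficient, standard
    error, hazard ratio and two-sided Wald p-value.  Raises ``ValueError``
    for a constant covariate or a cohort without events.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if not (len(time) == len(event) == len(x)):
        raise ValueError("time, event and x must have equal length")
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    # sort by decreasing time so the risk set of any subject is a prefix
    order = np.argsort(-time, kind="mergesort")
    t = time[order]
    d = event[order].astype(bool)
    xs = x[order]
    xbar = xs.mean()
    xc = xs - xbar  # centering stabilizes exp()

    # risk-set boundary per subject: last index sharing its time value
    last_tied = np.searchsorted(-t, -t, side="right") - 1

    ev_idx = np.where(d)[0]
    ev_bound = last_tied[ev_idx]
    x_ev = xc[ev_idx]

    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        eta = beta * xc
        eta -= eta.max()
        w = np.exp(eta)
        s0 = np.cumsum(w)[ev_bound]
        s1 = np.cumsum(w * xc)[ev_bound]
        s2 = np.cumsum(w * xc * xc)[ev_bound]
        mean = s1 / s0
        score = np.sum(x_ev - mean)
        info = np.sum(s2 / s0 - mean**2)
        if info <= 0:
            raise ValueError("non-positive information; covariate degenerate")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {"coef": beta, "se": se, "hr": float(np.exp(beta)), "z": z, "p": p}


def cox_loglik(time: np.ndarray, event: np.ndarray, eta: np.ndarray) -> float:
    """Breslow log partial likelihood at linear predictor ``eta``."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(-time, kind="mergesort")
    t = time[order]
    d = event[order].astype(bool)
    e = eta[order]
    shift = e.max()
    last_tied = np.searchsorted(-t, -t, side="right") - 1
    log_s0 = np.log(np.cumsum(np.exp(e - shift))) + shift
    ev = np.where(d)[0]
    return float(np.sum(e[ev] - log_s0[last_tied[ev]]))
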