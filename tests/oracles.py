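"""Independent oracles: slow, transparent reimplementations used only to
cross-check the package.  Nothing here imports the implementation paths it
verifies."""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf, sqrt

import numpy as np
from scipy import stats


# --- logistic regression: hand-coded Newton/IRLS ---------------------------

def irls_logistic(x, y, tol=1e-12, max_iter=200):
    """(intercept, slope), (se_intercept, se_slope) by Newton-Raphson with
    the observed information matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    H = np.eye(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


# --- Hardy-Weinberg: exact enumeration in rational arithmetic ---------------

def hwe_enumeration_p(n_AA, n_Aa, n_aa):
    """Two-sided conditional exact p by full enumeration with Fractions."""
    n = n_AA + n_Aa + n_aa
    na = 2 * min(n_AA, n_aa) + n_Aa
    if na == 0:
        return 1.0
    denom = comb(2 * n, na)
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        n_rare_hom = (na - h) // 2
        n_common_hom = n - h - n_rare_hom
        multinom = (
            comb(n, h) * comb(n - h, n_rare_hom)
        )  # n! / (h! n_rare_hom! n_common_hom!)
        probs[h] = Fraction(multinom * 2**h, denom)
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# --- AUC: brute-force pair counting ----------------------------------------

def auc_pair_counting(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases = scores[labels]
    controls = scores[~labels]
    total = 0.0
    for xc in cases:
        for yc in controls:
            if xc > yc:
                total += 1.0
            elif xc == yc:
                total += 0.5
    return total / (cases.size * controls.size)


# --- DeLong: naive double-loop structural components ------------------------

def _psi(x, y):
    return 1.0 if x > y else (0.5 if x == y else 0.0)


def delong_naive(scores_list, labels):
    """AUCs and the full covariance matrix for several paired score vectors."""
    labels = np.asarray(labels, dtype=bool)
    k = len(scores_list)
    cases = [np.asarray(s)[labels] for s in scores_list]
    controls = [np.asarray(s)[~labels] for s in scores_list]
    m, n = cases[0].size, controls[0].size
    aucs = np.zeros(k)
    V10 = np.zeros((k, m))
    V01 = np.zeros((k, n))
    for r in range(k):
        for i in range(m):
            V10[r, i] = sum(_psi(cases[r][i], controls[r][j]) for j in range(n)) / n
        for j in range(n):
            V01[r, j] = sum(_psi(cases[r][i], controls[r][j]) for i in range(m)) / m
        aucs[r] = V10[r].mean()
    S10 = np.cov(V10) if k > 1 else np.atleast_2d(np.var(V10, ddof=1))
    S01 = np.cov(V01) if k > 1 else np.atleast_2d(np.var(V01, ddof=1))
    cov = S10 / m + S01 / n
    return aucs, np.atleast_2d(cov)


def delong_paired_z(scores_a, scores_b, labels):
    aucs, cov = delong_naive([scores_a, scores_b], labels)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-16:
        return 0.0, 1.0
    z = (aucs[0] - aucs[1]) / sqrt(var)
    return z, 2 * stats.norm.sf(abs(z))


# --- decision tree: exhaustive split search and recursion -------------------

def oracle_candidate_cuts(kind, values):
    distinct = sorted(set(v for v in values if not np.isnan(v)))
    if len(distinct) < 2:
        return []
    if kind == "binary":
        raw = [1.0]
    elif kind == "dose":
        raw = [1.0, 2.0]
    else:
        raw = distinct
    return [
        c
        for c in raw
        if any(v >= c for v in distinct) and any(v < c for v in distinct)
    ]


def oracle_best_split(labels, predictors, kappa_weight=0.5, min_subgroup=10,
                      alpha=0.01, correction="bonferroni_predictors",
                      criterion="weighted_sesp", idx=None):
    """Plain-loop exhaustive search mirroring the documented conventions.

    predictors: list of (name, kind, full values array).
    Returns (rule tuple or None, p_raw, p_corrected, status) where rule is
    (name, cut, positive_side).
    """
    labels = np.asarray(labels, dtype=bool)
    if idx is None:
        idx = np.arange(labels.size)
    best = None
    n_pred_eval = 0
    n_cuts = 0
    for name, kind, values in predictors:
        vals = np.asarray(values, dtype=float)[idx]
        keep = ~np.isnan(vals)
        v, yy = vals[keep], labels[idx][keep]
        if yy.size == 0 or yy.all() or not yy.any():
            continue
        n_missing = int((~keep).sum())
        admissible_here = False
        for cut in oracle_candidate_cuts(kind, v):
            ge = v >= cut
            n_ge, n_lt = int(ge.sum()), int((~ge).sum())
            if n_ge >= n_lt:
                n_ge += n_missing
            else:
                n_lt += n_missing
            if min(n_ge, n_lt) < min_subgroup:
                continue
            admissible_here = True
            n_cuts += 1
            frac_ge = yy[ge].mean()
            frac_lt = yy[~ge].mean()
            side = "ge" if frac_ge >= frac_lt else "lt"
            pos = ge if side == "ge" else ~ge
            tp = float((pos & yy).sum())
            fn = float((~pos & yy).sum())
            fp = float((pos & ~yy).sum())
            tn = float((~pos & ~yy).sum())
            if criterion == "weighted_sesp":
                q = kappa_weight * tp / (tp + fn) + (1 - kappa_weight) * tn / (tn + fp)
            else:
                denom = kappa_weight * (tp + fn) * (fn + tn) + (1 - kappa_weight) * (
                    tp + fp
                ) * (fp + tn)
                q = (tp * tn - fn * fp) / denom if denom else 0.0
            if best is None or q > best[0] + 1e-12:
                table = [[(ge & yy).sum(), (ge & ~yy).sum()],
                         [((~ge) & yy).sum(), ((~ge) & ~yy).sum()]]
                chi2, p_raw, _, _ = stats.chi2_contingency(np.array(table, float), correction=False)
                best = (q, (name, cut, side), float(p_raw))
        if admissible_here:
            n_pred_eval += 1
    if best is None:
        return None, np.nan, np.nan, "no_admissible"
    factor = n_pred_eval if correction == "bonferroni_predictors" else n_cuts
    p_corr = min(1.0, best[2] * max(factor, 1))
    status = "found" if p_corr <= alpha else "not_significant"
    return best[1], best[2], p_corr, status


def oracle_grow(labels, predictors, kappa_weight=0.5, min_subgroup=10,
                alpha=0.01, max_path_splits=4, correction="bonferroni_predictors",
                criterion="weighted_sesp"):
    """Recursive oracle tree: nested (rule, counts, children-or-leaf_reason)."""
    labels = np.asarray(labels, dtype=bool)

    def rec(idx, depth):
        y = labels[idx]
        counts = (int(y.sum()), int((~y).sum()))
        if y.all() or not y.any():
            return {"counts": counts, "leaf": "pure"}
        if depth >= max_path_splits:
            return {"counts": counts, "leaf": "max_depth"}
        rule, p_raw, p_corr, status = oracle_best_split(
            labels, predictors, kappa_weight, min_subgroup, alpha, correction,
            criterion, idx,
        )
        if status == "no_admissible":
            return {"counts": counts, "leaf": "min_subgroup"}
        if status == "not_significant":
            return {"counts": counts, "leaf": "not_significant"}
        name, cut, side = rule
        vals = np.asarray(next(v for n2, k2, v in predictors if n2 == name), float)[idx]
        ge = vals >= cut
        lt = vals < cut
        missing = np.isnan(vals)
        if ge.sum() >= lt.sum():
            ge = ge | missing
        else:
            lt = lt | missing
        return {
            "counts": counts,
            "rule": rule,
            "children": [rec(idx[ge], depth + 1), rec(idx[lt], depth + 1)],
        }

    return rec(np.arange(labels.size), 0)
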