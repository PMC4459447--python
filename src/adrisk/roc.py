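"""ROC curves, Mann-Whitney AUC with DeLong standard errors, paired AUC
comparison, nested score-set evaluation, and the optimal-set stopping rule.

The AUC is computed by pair counting (ties count one half), identical to the
Mann-Whitney U statistic scaled by the number of case-control pairs.
Standard errors and the paired comparison use DeLong's structural
components: for case i, V10_i is the mean of the win indicator against all
controls, and symmetrically V01_j for controls; var(AUC) = S10/m + S01/n
with sample variances S10, S01.

The optimal nested score set is the first whose two successors show
consecutively lower AUCs (AUC_{i+1} < AUC_i and AUC_{i+2} < AUC_{i+1});
when the rule never fires, the maximum-AUC set is selected.  A literal
variant (AUC_i > AUC_{i+1} and AUC_i > AUC_{i+2}) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortValidationError, GenotypeMatrix
from .scoring import ScoreSet, compute_sample_scores


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise CohortValidationError("need at least one case and one control")
    return labels


@dataclass
class ROCCurve:
    """Operating points (threshold, sensitivity, specificity).

    Predicted-positive means score >= threshold; thresholds run from +inf
    (Se 0, Sp 1) down to the minimum score (Se 1, Sp 0).
    """

    points: np.ndarray  # (k, 3): threshold, sensitivity, specificity


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    m = labels.sum()
    n = (~labels).sum()
    pts = []
    for t in thresholds:
        pos = scores >= t
        se = (pos & labels).sum() / m
        sp = (~pos & ~labels).sum() / n
        pts.append((t, se, sp))
    return ROCCurve(np.array(pts))


@dataclass
class AUCResult:
    auc: float
    se: float
    n_case: int
    n_control: int


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus per-case (V10) and per-control (V01) structural components."""
    x = scores[labels]   # cases
    y = scores[~labels]  # controls
    # midrank formulation (O((m+n) log(m+n)))
    m, n = x.size, y.size
    allv = np.concatenate([x, y])
    t_all = stats.rankdata(allv)
    t_x = stats.rankdata(x)
    t_y = stats.rankdata(y)
    v10 = (t_all[:m] - t_x) / n
    v01 = 1.0 - (t_all[m:] - t_y) / m
    auc = (t_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> AUCResult:
    """Pair-counting AUC with a DeLong standard error."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return AUCResult(auc, se, m, n)


def compare_paired_auc(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test of AUC(a) vs AUC(b) on the same samples.

    Returns (z, two-sided p).  A degenerate variance (e.g. identical score
    vectors) yields z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise CohortValidationError("paired scores must align on samples")
    labels = _check_two_classes(labels)
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (d10.var(ddof=1) / m if m > 1 else 0.0) + (
        d01.var(ddof=1) / n if n > 1 else 0.0
    )
    if var <= 1e-16:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ScoreSetEvaluation:
    label: str
    auc_result: AUCResult
    p_vs_first: float | None   # None for the first set
    p_vs_prev: float | None    # None for the first set
    delta_auc: float           # 0.0 by convention for the first set
    is_first: bool = False


def evaluate_score_sets(
    sets: list[ScoreSet], g: GenotypeMatrix, labels: np.ndarray
) -> list[ScoreSetEvaluation]:
    """AUC (with SE), paired p vs the first set and vs the previous set, and
    the AUC increment, for each nested score set."""
    if not sets:
        raise CohortValidationError("need at least one score set")
    labels = _check_two_classes(labels)
    score_vecs = [
        compute_sample_scores(s, g)["score"].to_numpy() for s in sets
    ]
    evaluations = []
    first = score_vecs[0]
    prev_auc = None
    for k, (s, vec) in enumerate(zip(sets, score_vecs)):
        res = auc_mann_whitney(vec, labels)
        if k == 0:
            ev = ScoreSetEvaluation(s.label, res, None, None, 0.0, is_first=True)
        else:
            _, p_first = compare_paired_auc(vec, first, labels)
            _, p_prev = compare_paired_auc(vec, score_vecs[k - 1], labels)
            ev = ScoreSetEvaluation(
                s.label, res, p_first, p_prev, res.auc - prev_auc
            )
        evaluations.append(ev)
        prev_auc = res.auc
    return evaluations


def select_optimal_set(aucs, rule: str = "two_decreases") -> int:
    """Index (1-based) of the optimal set in a nested-AUC sequence.

    ``two_decreases`` (default): the first i with AUC_{i+1} < AUC_i and
    AUC_{i+2} < AUC_{i+1}.  ``literal``: the first i with AUC_i > AUC_{i+1}
    and AUC_i > AUC_{i+2}.  Fallback when the rule never fires: the (first)
    maximum.
    """
    aucs = [
        ev.auc_result.auc if isinstance(ev, ScoreSetEvaluation) else float(ev)
        for ev in aucs
    ]
    if not aucs:
        raise CohortValidationError("need at least one AUC value")
    if rule not in ("two_decreases", "literal"):
        raise CohortValidationError(f"unknown stopping rule {rule!r}")
    for i in range(len(aucs) - 2):
        if rule == "two_decreases":
            fired = aucs[i + 1] < aucs[i] and aucs[i + 2] < aucs[i + 1]
        else:
            fired = aucs[i] > aucs[i + 1] and aucs[i] > aucs[i + 2]
        if fired:
            return i + 1
    return int(np.argmax(aucs)) + 1


@dataclass
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    pvp: float  # predictive value positive; NaN when no predicted positives
    pvn: float  # predictive value negative; NaN when no predicted negatives
    percent_correct: float


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ClassificationMetrics:
    """Confusion-matrix metrics at predicted-positive = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    pos = scores >= threshold
    tp = float((pos & labels).sum())
    fp = float((pos & ~labels).sum())
    tn = float((~pos & ~labels).sum())
    fn = float((~pos & labels).sum())
    def ratio(a, b):
        return a / b if b > 0 else np.nan
    return ClassificationMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        pvp=ratio(tp, tp + fp),
        pvn=ratio(tn, tn + fn),
        percent_correct=(tp + tn) / labels.size,
    )


def evaluation_table(evaluations: list[ScoreSetEvaluation]) -> pd.DataFrame:
    """Score-set evaluations as a Score / AUC / SE / p / delta table."""
    return pd.DataFrame(
        {
            "Score": [ev.label for ev in evaluations],
            "AUC": [ev.auc_result.auc for ev in evaluations],
            "SE": [ev.auc_result.se for ev in evaluations],
            "P_vs_first": [ev.p_vs_first for ev in evaluations],
            "P_vs_prev": [ev.p_vs_prev for ev in evaluations],
            "dAUC": [ev.delta_auc for ev in evaluations],
        }
    )
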