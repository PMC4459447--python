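"""Per-marker additive logistic association scan.

Each marker is tested with an intercept + dose logistic regression (dose =
minor-allele count 0/1/2), complete-case per marker.  The reported statistic
is the Wald z (slope over its observed-information standard error) with a
two-sided normal-tail p-value, matching the convention of standard
genetics association tooling.  No covariates are included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortValidationError, GenotypeMatrix, SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    marker_id: str
    or_: float        # odds ratio per minor allele
    stat: float       # Wald z
    p: float          # two-sided; NaN when flagged
    maf: float        # among samples used
    n_used: int
    flags: tuple = ()

    @property
    def slope(self) -> float:
        return float(np.log(self.or_))


#: Results sorted ascending by p, ties by |stat| descending then marker_id.
RankedAssociationList = list


def wald_pvalue(stat: float) -> float:
    """Two-sided normal-tail p for a Wald z statistic."""
    if not np.isfinite(stat):
        raise CohortValidationError("Wald statistic must be finite")
    return float(2.0 * stats.norm.sf(abs(stat)))


def fit_additive_logistic(
    dose: np.ndarray, status: np.ndarray, marker_id: str = ""
) -> AssociationResult:
    """ML logistic fit of case status on minor-allele dose.

    Samples with missing dose are dropped.  Complete separation yields a
    flagged result (p = NaN) rather than an error; a constant dose is an
    error because the slope is undefined.
    """
    import statsmodels.api as sm

    dose = np.asarray(dose, dtype=float)
    status = np.asarray(status, dtype=float)
    mask = ~np.isnan(dose)
    x, y = dose[mask], status[mask]
    if y.size == 0 or y.min() == y.max():
        raise CohortValidationError("need at least one case and one control")
    if x.min() == x.max():
        raise CohortValidationError(f"constant dose for marker {marker_id!r}")
    f = x.mean() / 2.0
    maf = float(min(f, 1.0 - f))
    X = sm.add_constant(x)
    flags: tuple = ()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or se > 50 or abs(slope) > 15:
            raise RuntimeError("quasi-separation")
        z = slope / se
        return AssociationResult(
            marker_id, float(np.exp(slope)), z, wald_pvalue(z), maf, int(y.size)
        )
    except Exception as exc:  # separation / non-convergence
        logger.warning("marker %s: flagged logistic fit (%s)", marker_id, exc)
        return AssociationResult(
            marker_id, np.nan, np.nan, np.nan, maf, int(y.size), flags=("separation",)
        )


def rank_results(results: list[AssociationResult]) -> RankedAssociationList:
    """Ascending p; ties by |stat| descending then marker_id; NaN p last."""
    def key(r: AssociationResult):
        p = r.p if np.isfinite(r.p) else np.inf
        s = abs(r.stat) if np.isfinite(r.stat) else -np.inf
        return (p, -s, r.marker_id)

    return sorted(results, key=key)


def run_association_scan(
    g: GenotypeMatrix,
    samples: list[SampleRecord],
    case_groups: set[str] = frozenset({"AmnAD", "AtAD"}),
) -> RankedAssociationList:
    """Scan every marker; samples outside case_groups + controls are excluded."""
    by_id = {s.sample_id: s for s in samples}
    status, keep = [], []
    for i, sid in enumerate(g.sample_ids):
        s = by_id.get(sid)
        if s is None:
            continue
        if s.group in case_groups:
            status.append(1.0)
            keep.append(i)
        elif s.group == "control":
            status.append(0.0)
            keep.append(i)
    status = np.asarray(status)
    if status.size == 0 or status.max() == 0:
        raise CohortValidationError("no cases among the selected samples")
    if status.min() == 1:
        raise CohortValidationError("no controls among the selected samples")
    results = []
    for j, var in enumerate(g.variants):
        dose = g.dose[keep, j]
        try:
            results.append(fit_additive_logistic(dose, status, var.marker_id))
        except CohortValidationError as exc:
            logger.warning("marker %s skipped in scan: %s", var.marker_id, exc)
    return rank_results(results)


def bonferroni_significant(
    ranked: RankedAssociationList, alpha: float, k: int
) -> RankedAssociationList:
    """Markers with p < alpha / k (k = number of tests, supplied explicitly)."""
    if k < 1:
        raise CohortValidationError("k must be >= 1")
    thr = alpha / k
    return [r for r in ranked if np.isfinite(r.p) and r.p < thr]


def carrier_enrichment_test(
    carrier: np.ndarray, group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on carrier x group.

    ``carrier`` is a per-sample boolean; ``group_a``/``group_b`` are index
    arrays (or boolean masks) selecting the two groups.
    """
    carrier = np.asarray(carrier, dtype=bool)
    a = carrier[group_a]
    b = carrier[group_b]
    if a.size == 0 or b.size == 0:
        raise CohortValidationError("both groups must be non-empty")
    table = np.array(
        [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CohortValidationError("zero margin in carrier x group table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def association_table(ranked: RankedAssociationList, g: GenotypeMatrix) -> pd.DataFrame:
    """Scan results as a Gene/SNP/OR/STAT/P/MAF table."""
    gene = {v.marker_id: v.gene_label for v in g.variants}
    return pd.DataFrame(
        {
            "Gene": [gene.get(r.marker_id, "") for r in ranked],
            "SNP": [r.marker_id for r in ranked],
            "OR": [r.or_ for r in ranked],
            "STAT": [r.stat for r in ranked],
            "P": [r.p for r in ranked],
            "MAF": [r.maf for r in ranked],
        }
    )
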