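"""Risk-allele scoring: LD pruning of ranked findings, risk-allele
orientation, nested score sets, and per-sample allele-count scores.

LD is measured as the squared Pearson correlation of allele doses over
pairwise-complete samples (composite LD; phase-free).  Pruning is a greedy
scan in rank order: a marker is kept iff its r^2 with every already-kept
marker is at or below the cutoff, so the most strongly associated marker of
each linked group survives.

Scores follow the classic SNP-scoring convention: each marker contributes
its risk-allele dose (the minor-allele dose, flipped to the major allele
when the estimated OR is below 1 so every marker counts toward risk), a
missing genotype contributes twice the in-sample risk-allele frequency, and
the total is divided by twice the number of markers — so with unit weights
the score is the mean risk-allele fraction, in [0, 1].
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationResult, RankedAssociationList
from .cohort import CohortValidationError, GenotypeMatrix


class UndefinedLDError(ValueError):
    """r^2 is undefined (constant dose on the pairwise-complete samples)."""


def genotype_r2(dose_a: np.ndarray, dose_b: np.ndarray) -> float:
    """Squared Pearson correlation of doses over pairwise-complete samples."""
    a = np.asarray(dose_a, dtype=float)
    b = np.asarray(dose_b, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise UndefinedLDError("fewer than 2 pairwise-complete samples")
    if a.min() == a.max() or b.min() == b.max():
        raise UndefinedLDError("constant dose vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune_ranked(
    ranked: RankedAssociationList, g: GenotypeMatrix, threshold: float = 0.8
) -> RankedAssociationList:
    """Greedy rank-order pruning at the r^2 cutoff (rank order preserved)."""
    kept: list[AssociationResult] = []
    kept_dose: list[np.ndarray] = []
    for r in ranked:
        dose = g.column(r.marker_id)
        linked = False
        for other in kept_dose:
            try:
                if genotype_r2(dose, other) > threshold:
                    linked = True
                    break
            except UndefinedLDError:
                continue  # undefined LD never counts as linked
        if not linked:
            kept.append(r)
            kept_dose.append(dose)
    return kept


@dataclass(frozen=True)
class ScoredMarker:
    marker_id: str
    risk_allele: str  # "minor" or "major"
    weight: float = 1.0
    source_or: float = np.nan

    def __post_init__(self):
        if self.risk_allele not in ("minor", "major"):
            raise CohortValidationError("risk_allele must be 'minor' or 'major'")
        if self.weight < 0:
            raise CohortValidationError("weight must be non-negative")


@dataclass(frozen=True)
class ScoreSet:
    label: str
    markers: tuple  # ordered ScoredMarker tuple

    @property
    def size(self) -> int:
        return len(self.markers)


def orient_risk_allele(a: AssociationResult, weighting: str = "unit") -> ScoredMarker:
    """Point the scored allele in the risk direction.

    OR >= 1 keeps the minor allele (boundary OR = 1 keeps minor); OR < 1
    flips to the major allele.  ``weighting='log_or'`` uses |log OR| as the
    weight instead of allele counting.
    """
    if not np.isfinite(a.or_) or a.or_ <= 0:
        raise CohortValidationError(f"marker {a.marker_id}: OR unavailable")
    risk = "minor" if a.or_ >= 1 else "major"
    weight = 1.0 if weighting == "unit" else float(abs(np.log(a.or_)))
    return ScoredMarker(a.marker_id, risk, weight, a.or_)


def set_label(k: int) -> str:
    """1 -> 'A', 26 -> 'Z', 27 -> 'AA', ..."""
    label = ""
    while k > 0:
        k, rem = divmod(k - 1, 26)
        label = string.ascii_uppercase[rem] + label
    return label


def build_nested_score_sets(
    pruned: RankedAssociationList, max_sets: int = 26, weighting: str = "unit"
) -> list[ScoreSet]:
    """Nested sets: set k = top k pruned markers, labelled A, B, C, ..."""
    if not pruned:
        raise CohortValidationError("cannot build score sets from zero markers")
    n = min(len(pruned), max_sets)
    oriented = [orient_risk_allele(r, weighting) for r in pruned[:n]]
    return [ScoreSet(set_label(k), tuple(oriented[:k])) for k in range(1, n + 1)]


def risk_allele_frequency(sm: ScoredMarker, g: GenotypeMatrix) -> float:
    """In-sample frequency of the risk allele among non-missing genotypes."""
    dose = g.column(sm.marker_id)
    nonmiss = dose[~np.isnan(dose)]
    if nonmiss.size == 0:
        return np.nan
    f_minor = nonmiss.mean() / 2.0
    return float(f_minor if sm.risk_allele == "minor" else 1.0 - f_minor)


def compute_sample_scores(
    s: ScoreSet, g: GenotypeMatrix, impute_missing: bool = True
) -> pd.DataFrame:
    """Per-sample risk score for one score set.

    Returns a DataFrame (sample_id, score, n_markers_used).  With imputation
    (default), a missing genotype contributes ``2 x in-sample risk-allele
    frequency`` and the denominator is ``2 x set size``; without it, only
    observed markers enter and the denominator shrinks accordingly (a sample
    missing every marker gets a missing score).
    """
    m = s.size
    contrib = np.zeros((g.n_samples, m))
    observed = np.zeros((g.n_samples, m), dtype=bool)
    weights = np.array([sm.weight for sm in s.markers])
    for k, sm in enumerate(s.markers):
        dose = g.column(sm.marker_id)
        risk_dose = dose if sm.risk_allele == "minor" else 2.0 - dose
        miss = np.isnan(risk_dose)
        observed[:, k] = ~miss
        if impute_missing:
            fill = 2.0 * risk_allele_frequency(sm, g)
            risk_dose = np.where(miss, fill, risk_dose)
        else:
            risk_dose = np.where(miss, 0.0, risk_dose)
        contrib[:, k] = risk_dose * weights[k]
    if impute_missing:
        score = contrib.sum(axis=1) / (2.0 * m)
    else:
        denom = 2.0 * observed.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 0, contrib.sum(axis=1) / denom, np.nan)
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "score": score,
            "n_markers_used": observed.sum(axis=1) if not impute_missing else m,
        }
    )


# ---------------------------------------------------------------------------
# Score-file dialect: marker_id <tab> risk allele token <tab> weight

def write_score_file(s: ScoreSet, g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for sm in s.markers:
            var = g.variants[g.marker_index(sm.marker_id)]
            token = var.minor_allele if sm.risk_allele == "minor" else var.major_allele
            fh.write(f"{sm.marker_id}\t{token}\t{sm.weight:g}\n")


def read_score_file(path, g: GenotypeMatrix, label: str = "imported") -> ScoreSet:
    markers = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            marker_id, token, weight = line.rstrip("\n").split("\t")
            var = g.variants[g.marker_index(marker_id)]
            if token == var.minor_allele:
                risk = "minor"
            elif token == var.major_allele:
                risk = "major"
            else:
                raise CohortValidationError(
                    f"{marker_id}: allele token {token!r} matches neither allele"
                )
            markers.append(ScoredMarker(marker_id, risk, float(weight)))
    if not markers:
        raise CohortValidationError("empty score file")
    return ScoreSet(label, tuple(markers))
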