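"""Cohort data model, genotype/phenotype IO, APOE epsilon-4 derivation, and
marker quality control.

Genotypes are held as an additive dose matrix: ``dose[i, j]`` is the number
of copies (0/1/2, NaN when missing) of the *minor* allele of marker ``j``
carried by sample ``i``.  The minor allele is determined per marker from the
in-sample allele frequency among non-missing genotypes; frequency ties are
broken by designating the alphabetically first allele as minor.

QC follows the usual candidate-panel inclusion criteria: per-marker call
rate > 0.80 (strict), minor allele frequency >= 0.01, and a Hardy-Weinberg
exact-test p-value > 0.001 (strict).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

GROUPS = ("control", "AmnAD", "AtAD")
SEXES = ("male", "female")
SPLITS = ("discovery", "validation", "unassigned")


class CohortFormatError(ValueError):
    """A file does not conform to the expected dialect."""


class CohortValidationError(ValueError):
    """Content violates a data-model invariant."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    age: int
    sex: str
    split: str = "unassigned"

    def __post_init__(self):
        if self.group not in GROUPS:
            raise CohortValidationError(f"unknown group token {self.group!r}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"unknown sex token {self.sex!r}")
        if self.split not in SPLITS:
            raise CohortValidationError(f"unknown split token {self.split!r}")
        if not (0 <= self.age):
            raise CohortValidationError(f"negative age {self.age}")

    @property
    def is_case(self) -> bool:
        return self.group != "control"


@dataclass(frozen=True)
class VariantRecord:
    marker_id: str
    gene_label: str = ""
    minor_allele: str = "A"
    major_allele: str = "B"

    def __post_init__(self):
        if self.minor_allele == self.major_allele:
            raise CohortValidationError(
                f"{self.marker_id}: minor and major allele identical"
            )


@dataclass
class GenotypeMatrix:
    """Samples x markers additive minor-allele dose matrix (NaN = missing)."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dose: np.ndarray  # float64, shape (n_samples, n_markers)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.sample_ids), len(self.variants)):
            raise CohortValidationError("dose matrix shape inconsistent with ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortValidationError("duplicate sample ids")
        ids = [v.marker_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate marker ids")
        valid = np.isnan(self.dose) | np.isin(self.dose, (0.0, 1.0, 2.0))
        if not valid.all():
            raise CohortValidationError("doses must be 0/1/2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.variants)

    @property
    def marker_ids(self) -> list[str]:
        return [v.marker_id for v in self.variants]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.dose[:, self.marker_index(marker_id)]

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.variants[j] for j in idx],
            self.dose[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), list(self.variants), self.dose[idx, :].copy()
        )


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.80  # strict: call rate must exceed this
    min_maf: float = 0.01        # inclusive
    min_hwe_p: float = 0.001     # strict

    def __post_init__(self):
        for v in (self.min_call_rate, self.min_maf, self.min_hwe_p):
            if not (0 < v <= 1):
                raise CohortValidationError("QC thresholds must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Phenotype table IO

def read_cohort_table(path) -> list[SampleRecord]:
    """Read a tab-delimited phenotype table (columns id, group, age, sex[, split])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing required column(s): {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise CohortValidationError(f"duplicate sample id(s): {dups}")
    records = []
    for row in df.itertuples(index=False):
        split = getattr(row, "split", "unassigned")
        if split is None or (isinstance(split, float) and np.isnan(split)):
            split = "unassigned"
        try:
            age = int(row.age)
        except (TypeError, ValueError):
            raise CohortFormatError(f"non-integer age {row.age!r} for {row.id}")
        records.append(SampleRecord(row.id, row.group, age, row.sex, split))
    return records


def write_cohort_table(samples: list[SampleRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "split": [s.split for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype IO

def _orient_to_minor(dose: np.ndarray, allele_lo: str, allele_hi: str):
    """Given doses of ``allele_hi``, return (dose of minor allele, minor, major).

    Frequency ties designate the alphabetically first allele as minor.
    """
    nonmiss = dose[~np.isnan(dose)]
    freq_hi = nonmiss.mean() / 2.0 if nonmiss.size else 0.0
    if freq_hi > 0.5 or (freq_hi == 0.5 and allele_lo < allele_hi):
        return 2.0 - dose, allele_lo, allele_hi
    return dose, allele_hi, allele_lo


def read_genotype_matrix(path, format: str = "dose_tsv") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field, biallelic sites) or a dose TSV.

    Doses are re-oriented so that they count the in-sample minor allele.
    Multi-allelic VCF records are skipped with a warning; a TSV cell that is
    not 0/1/2/NA is a format error.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dose_tsv":
        return _read_dose_tsv(path)
    raise CohortFormatError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping non-biallelic record %s", v.ID or v.POS)
            continue
        alt_dose = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        alt_dose[alt_dose == 3] = np.nan
        dose, minor, major = _orient_to_minor(alt_dose, v.REF, v.ALT[0])
        marker_id = v.ID or f"{v.CHROM}:{v.POS}"
        variants.append(VariantRecord(marker_id, v.CHROM, minor, major))
        cols.append(dose)
    dose = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, dose)


def _read_dose_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    arr = df.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = arr[~ok][0]
        raise CohortFormatError(f"non-integer dose value {bad!r}")
    variants, cols = [], []
    for j, marker in enumerate(df.columns):
        dose, minor, major = _orient_to_minor(arr[:, j], "A", "B")
        variants.append(VariantRecord(str(marker), "", minor, major))
        cols.append(dose)
    dose = np.column_stack(cols) if cols else np.empty((len(df.index), 0))
    return GenotypeMatrix([str(s) for s in df.index], variants, dose)


def write_dose_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dose, index=g.sample_ids, columns=g.marker_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


_BASES = set("ACGT")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes.

    Markers get synthetic coordinates (chr1, 1 kb apart).  Allele tokens that
    are not single bases (e.g. a haplotype marker) are written as A/C.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, var in enumerate(g.variants):
            major, minor = var.major_allele, var.minor_allele
            if major not in _BASES or minor not in _BASES:
                major, minor = "A", "C"
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in g.dose[:, j]
            ]
            fh.write(
                f"chr1\t{1000 * (j + 1)}\t{var.marker_id}\t{major}\t{minor}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# APOE epsilon-4 derivation

def derive_apoe_e4_dose(
    rs429358_dose: np.ndarray,
    rs7412_dose: np.ndarray,
    double_het_as_e2e4: bool = True,
) -> np.ndarray:
    """Per-sample epsilon-4 haplotype dose from the two APOE coding SNPs.

    Inputs are minor-allele doses: copies of C at rs429358 and copies of T at
    rs7412.  The epsilon-4 haplotype carries rs429358-C together with
    rs7412-C, so a chromosome bearing a rs7412-T cannot be epsilon-4; the dose
    is ``min(nC, 2 - nT)``.  The ambiguous double heterozygote (nC = nT = 1)
    is assigned epsilon-2/epsilon-4 (dose 1) by convention; set
    ``double_het_as_e2e4=False`` for the alternative epsilon-1/epsilon-3
    phasing (dose 0).  Missing either input yields missing.
    """
    c = np.asarray(rs429358_dose, dtype=float)
    t = np.asarray(rs7412_dose, dtype=float)
    if c.shape != t.shape:
        raise CohortValidationError("APOE SNP dose vectors differ in length")
    e4 = np.minimum(c, 2.0 - t)
    e4 = np.maximum(e4, 0.0)
    if not double_het_as_e2e4:
        e4 = np.where((c == 1) & (t == 1), 0.0, e4)
    e4 = np.where(np.isnan(c) | np.isnan(t), np.nan, e4)
    return e4


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (Levene-Haldane distribution).  Monomorphic markers return
    1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise CohortValidationError("genotype counts must be non-negative integers")
    n = int(n_AA + n_Aa + n_aa)
    if n < 1:
        raise CohortValidationError("at least one genotype required")
    na = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if na == 0:
        return 1.0
    hets = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    # log P(h) up to a constant: conditional on n and na
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (na + hets) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(n_Aa)
    p_obs = probs[np.searchsorted(hets, obs)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Marker QC

def marker_qc_metrics(
    g: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-marker call rate, MAF, HWE exact p, and pass/fail with reasons.

    Returns a DataFrame (one row per marker, in matrix order) with columns
    marker_id, call_rate, maf, hwe_p, passed, fail_reasons.  Degenerate
    markers (all missing) are flagged, never raised.

    ``hwe_sample_ids`` restricts the Hardy-Weinberg test to a subset
    (typically the controls: pooling cases and controls mixes two HWE
    populations with different allele frequencies at true risk loci, and
    the resulting homozygote excess can reject exactly the markers that
    matter).  Call rate and MAF always use all samples.
    """
    if g.n_samples < 1:
        raise CohortValidationError("QC requires at least one sample")
    t = thresholds or QCThresholds()
    if hwe_sample_ids is not None:
        pos = {s: i for i, s in enumerate(g.sample_ids)}
        hwe_rows = np.array([pos[s] for s in hwe_sample_ids], dtype=int)
        if hwe_rows.size == 0:
            raise CohortValidationError("hwe_sample_ids selects no samples")
    else:
        hwe_rows = None
    rows = []
    for j, var in enumerate(g.variants):
        col = g.dose[:, j]
        nonmiss = col[~np.isnan(col)]
        call_rate = nonmiss.size / g.n_samples
        if nonmiss.size == 0:
            maf, hwe_p = np.nan, np.nan
        else:
            f = nonmiss.mean() / 2.0
            maf = min(f, 1.0 - f)
            hwe_col = col if hwe_rows is None else col[hwe_rows]
            hwe_col = hwe_col[~np.isnan(hwe_col)]
            if hwe_col.size == 0:
                hwe_p = np.nan
            else:
                hwe_p = hwe_exact_test(
                    int((hwe_col == 0).sum()),
                    int((hwe_col == 1).sum()),
                    int((hwe_col == 2).sum()),
                )
        reasons = []
        if not call_rate > t.min_call_rate:
            reasons.append("call_rate")
        if not (not np.isnan(maf) and maf >= t.min_maf):
            reasons.append("maf")
        if not (not np.isnan(hwe_p) and hwe_p > t.min_hwe_p):
            reasons.append("hwe")
        rows.append(
            {
                "marker_id": var.marker_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "passed": not reasons,
                "fail_reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_sample_ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop failing markers (original order preserved) and return the report."""
    report = marker_qc_metrics(g, thresholds, hwe_sample_ids)
    keep = report.loc[report["passed"], "marker_id"].tolist()
    if not keep:
        warnings.warn("no markers pass QC; returning empty matrix")
    return g.subset_markers(keep), report


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
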