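"""Phenotype/genotype IO, APOE epsilon-4 derivation, HWE exact test, marker QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrisk.cohort import (
    CohortFormatError,
    CohortValidationError,
    QCThresholds,
    apply_qc,
    derive_apoe_e4_dose,
    hwe_exact_test,
    marker_qc_metrics,
    read_cohort_table,
    read_genotype_matrix,
    write_dose_tsv,
    write_vcf,
)
from conftest import make_matrix
from oracles import hwe_enumeration_p


# --- phenotype table -------------------------------------------------------

def test_read_cohort_table_roundtrip(tmp_path):
    p = tmp_path / "pheno.tsv"
    p.write_text(
        "id\tgroup\tage\tsex\tsplit\n"
        "s1\tcontrol\t70\tfemale\tdiscovery\n"
        "s2\tAmnAD\t81\tmale\tvalidation\n"
        "s3\tAtAD\t77\tfemale\tdiscovery\n"
    )
    recs = read_cohort_table(p)
    assert [r.sample_id for r in recs] == ["s1", "s2", "s3"]
    assert recs[1].group == "AmnAD" and recs[1].age == 81 and recs[1].is_case
    assert not recs[0].is_case


def test_read_cohort_table_rejects_unknown_group(tmp_path):
    p = tmp_path / "pheno.tsv"
    p.write_text("id\tgroup\tage\tsex\ns1\tAD\t70\tfemale\n")
    with pytest.raises(CohortValidationError):
        read_cohort_table(p)


def test_read_cohort_table_requires_columns_and_unique_ids(tmp_path):
    p = tmp_path / "pheno.tsv"
    p.write_text("id\tgroup\tage\ns1\tcontrol\t70\n")
    with pytest.raises(CohortFormatError):
        read_cohort_table(p)
    p.write_text("id\tgroup\tage\tsex\ns1\tcontrol\t70\tmale\ns1\tcontrol\t71\tmale\n")
    with pytest.raises(CohortValidationError):
        read_cohort_table(p)


def test_read_cohort_table_empty_with_header(tmp_path):
    p = tmp_path / "pheno.tsv"
    p.write_text("id\tgroup\tage\tsex\n")
    assert read_cohort_table(p) == []


# --- genotype matrices -----------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5\n"
)


def test_vcf_minor_allele_orientation(tmp_path):
    # site 1: ALT minor (freq 0.2) -> het = dose 1 of ALT
    # site 2: ALT freq 0.7 -> REF is minor; doses count REF by brute recount
    p = tmp_path / "g.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/1\n"
        + "chr1\t200\trsB\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\t0/1\t1/1\n"
    )
    g = read_genotype_matrix(p, "vcf")
    assert g.marker_ids == ["rsA", "rsB"]
    np.testing.assert_array_equal(g.column("rsA"), [1, 0, 0, 0, 1])
    # brute-force recount: ALT 'G' appears 7/10 times, so minor is REF 'A'
    np.testing.assert_array_equal(g.column("rsB"), [0, 0, 1, 1, 0])
    var = g.variants[1]
    assert var.minor_allele == "A" and var.major_allele == "G"


def test_vcf_missing_and_multiallelic(tmp_path):
    p = tmp_path / "g.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0\t0/0\n"
        + "chr1\t200\trsM\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0\n"
    )
    g = read_genotype_matrix(p, "vcf")
    assert g.marker_ids == ["rsA"]  # multi-allelic skipped
    assert np.isnan(g.column("rsA")[0])


def test_dose_tsv_roundtrip_and_na(tmp_path):
    g = make_matrix({"m1": [0, 1, 1, None], "m2": [1, 1, 0, 0]})
    p = tmp_path / "dose.tsv"
    write_dose_tsv(g, p)
    g2 = read_genotype_matrix(p, "dose_tsv")
    assert g2.sample_ids == g.sample_ids
    np.testing.assert_array_equal(np.isnan(g2.dose), np.isnan(g.dose))
    np.testing.assert_array_equal(g2.dose[~np.isnan(g.dose)], g.dose[~np.isnan(g.dose)])


def test_dose_tsv_rejects_non_integer(tmp_path):
    p = tmp_path / "dose.tsv"
    p.write_text("sample\tm1\ns1\t0\ns2\t1.5\n")
    with pytest.raises(CohortFormatError):
        read_genotype_matrix(p, "dose_tsv")


def test_vcf_write_read_roundtrip(tmp_path, rng):
    dose = {f"m{j}": rng.integers(0, 3, size=30).tolist() for j in range(4)}
    g = make_matrix(dose)
    p = tmp_path / "g.vcf"
    write_vcf(g, p)
    g2 = read_genotype_matrix(p, "vcf")
    assert g2.marker_ids == g.marker_ids
    # minor-allele doses agree up to the reader's own re-orientation
    for m in g.marker_ids:
        a, b = g.column(m), g2.column(m)
        assert np.array_equal(a, b) or np.array_equal(a, 2 - b)


# --- APOE epsilon-4 --------------------------------------------------------

@pytest.mark.parametrize(
    "c_dose,t_dose,expected",
    [
        (2, 0, 2),   # epsilon-4/epsilon-4
        (0, 0, 0),   # rs429358 TT -> no epsilon-4
        (0, 2, 0),
        (1, 0, 1),   # epsilon-3/epsilon-4
        (1, 1, 1),   # double het -> epsilon-2/epsilon-4 convention
        (2, 1, 1),
        (2, 2, 0),   # rs7412 TT: no chromosome can be epsilon-4
    ],
)
def test_apoe_e4_haplotype_table(c_dose, t_dose, expected):
    out = derive_apoe_e4_dose(np.array([c_dose], float), np.array([t_dose], float))
    assert out[0] == expected


def test_apoe_e4_double_het_alternative_convention():
    out = derive_apoe_e4_dose(np.array([1.0]), np.array([1.0]), double_het_as_e2e4=False)
    assert out[0] == 0


def test_apoe_e4_missing_propagates_and_length_checked():
    c = np.array([1.0, np.nan, 2.0])
    t = np.array([0.0, 0.0, np.nan])
    out = derive_apoe_e4_dose(c, t)
    assert out[0] == 1 and np.isnan(out[1]) and np.isnan(out[2])
    with pytest.raises(CohortValidationError):
        derive_apoe_e4_dose(np.zeros(2), np.zeros(3))


# --- HWE exact test --------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ((100, 0, 0), 1.0),       # monomorphic
        ((1, 0, 1), 1 / 3),       # full enumeration for n=2, minor count 2
        ((25, 50, 25), 1.0),      # observed het count is modal
    ],
)
def test_hwe_exact_known_values(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_exact_rejects_empty():
    with pytest.raises(CohortValidationError):
        hwe_exact_test(0, 0, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_AA=st.integers(0, 80),
    n_Aa=st.integers(0, 80),
    n_aa=st.integers(0, 40),
)
def test_hwe_matches_rational_enumeration(n_AA, n_Aa, n_aa):
    """The log-space implementation agrees with exact rational enumeration."""
    if n_AA + n_Aa + n_aa == 0:
        return
    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
        hwe_enumeration_p(n_AA, n_Aa, n_aa), abs=1e-12
    )


# --- marker QC -------------------------------------------------------------

def test_qc_metrics_basic():
    g = make_matrix(
        {
            "allhet": [1] * 8,
            "partmiss": [0, 1, None, None, 0, 1, 0, 1],
        }
    )
    rep = marker_qc_metrics(g)
    allhet = rep[rep.marker_id == "allhet"].iloc[0]
    assert allhet.maf == 0.5 and allhet.call_rate == 1.0
    partmiss = rep[rep.marker_id == "partmiss"].iloc[0]
    assert partmiss.call_rate == pytest.approx(0.75)
    assert "call_rate" in partmiss.fail_reasons


def test_qc_hwe_boundary_is_strict():
    # inclusion requires HWE p strictly above 0.001
    g = make_matrix({"m": [1] * 20})  # all-het: grossly non-HWE
    rep = marker_qc_metrics(g)
    assert rep.iloc[0].hwe_p < 0.001
    assert "hwe" in rep.iloc[0].fail_reasons and not rep.iloc[0].passed


def test_apply_qc_removes_planted_failures(rng):
    n = 60
    # clean markers drawn at Hardy-Weinberg proportions so they pass QC
    good = {f"g{k}": rng.binomial(2, 0.3, size=n).tolist() for k in range(3)}
    low_maf = [0] * (n - 1) + [1]                       # MAF 1/120 < 0.01
    low_call = rng.integers(0, 3, size=n).astype(object)
    low_call[: n // 2] = None                           # call rate 0.5
    bad_hwe = [1] * n                                   # all-het
    g = make_matrix(
        {**good, "low_maf": low_maf, "low_call": list(low_call), "bad_hwe": bad_hwe}
    )
    g_qc, report = apply_qc(g)
    assert g_qc.marker_ids == list(good)
    failed = report[~report.passed]
    reasons = dict(zip(failed.marker_id, failed.fail_reasons))
    assert "maf" in reasons["low_maf"]
    assert "call_rate" in reasons["low_call"]
    assert "hwe" in reasons["bad_hwe"]
    # verify by direct metric computation
    assert report.set_index("marker_id").loc["low_call", "call_rate"] == pytest.approx(0.5)


def test_qc_hwe_controls_only_option(rng):
    """Pooling two HWE populations with different allele frequencies inflates
    homozygotes (Wahlund effect); restricting the HWE test to the control
    subset rescues such a marker."""
    controls = rng.binomial(2, 0.10, size=200)
    cases = rng.binomial(2, 0.55, size=200)
    g = make_matrix({"risk": np.concatenate([controls, cases]).tolist()})
    ids = g.sample_ids
    pooled = marker_qc_metrics(g)
    ctl_only = marker_qc_metrics(g, hwe_sample_ids=ids[:200])
    assert pooled.iloc[0].hwe_p < 0.001          # mixture rejected
    assert ctl_only.iloc[0].hwe_p > 0.001        # controls alone are HWE
    assert ctl_only.iloc[0].passed and not pooled.iloc[0].passed


def test_apply_qc_idempotent(rng):
    dose = {f"m{k}": rng.integers(0, 3, size=40).tolist() for k in range(6)}
    dose["bad"] = [0] * 39 + [1]
    g = make_matrix(dose)
    g1, _ = apply_qc(g)
    g2, rep2 = apply_qc(g1)
    assert g2.marker_ids == g1.marker_ids
    np.testing.assert_array_equal(g1.dose, g2.dose)
    assert rep2.passed.all()


def test_qc_report_pass_iff_all_thresholds(rng):
    dose = {f"m{k}": rng.integers(0, 3, size=50).tolist() for k in range(10)}
    g = make_matrix(dose)
    t = QCThresholds()
    rep = marker_qc_metrics(g, t)
    for _, row in rep.iterrows():
        expected = (
            row.call_rate > t.min_call_rate
            and row.maf >= t.min_maf
            and row.hwe_p > t.min_hwe_p
        )
        assert row.passed == expected
        assert 0 <= row.call_rate <= 1 and row.maf <= 0.5
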