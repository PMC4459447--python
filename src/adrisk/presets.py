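"""Study presets: the published marker panel, cohort demographics, and the
reference score-set evaluation series.

These constants calibrate the synthetic cohorts to the study conditions this
package models: a candidate-gene panel of 75 variants genotyped in unrelated
older adults (65-101 y) split into a Discovery stage (59 AD cases, 133
controls) and a Validation stage, with AD cases subtyped as amnestic (AmnAD)
or atypical (AtAD).  Only the top 20 association results of the panel are
published with per-marker statistics; the remaining 55 markers are filled in
with deterministic, realistically spread minor-allele frequencies and no
planted effect.
"""

from __future__ import annotations

import numpy as np

#: Published top-20 association rows: (gene, marker_id, OR, Wald z, p, cohort MAF).
#: ORs are per minor allele from the additive logistic scan of the Discovery
#: cohort (all AD vs control).
STUDY_ASSOCIATION_TABLE: list[tuple[str, str, float, float, float, float]] = [
    ("APOE", "rs429358/rs7412", 4.28, 4.83, 1.36e-6, 0.20),
    ("HFE", "rs1799945", 2.83, 3.15, 1.64e-3, 0.15),
    ("PICALM", "rs3851179", 0.47, -3.04, 2.37e-3, 0.42),
    ("CR1", "rs6701713", 0.42, -2.65, 0.01, 0.19),
    ("SLC6A4", "rs2020942", 1.81, 2.63, 0.01, 0.40),
    ("TPH1", "rs1799913", 0.64, -2.02, 0.04, 0.44),
    ("KIAA0319", "rs4504469", 0.60, -2.02, 0.04, 0.35),
    ("CDC42BPA", "rs1320490", 1.63, 1.93, 0.05, 0.20),
    ("TMEM175", "rs6599389", 0.41, -1.81, 0.07, 0.08),
    ("SORL1", "rs2070045", 1.63, 1.74, 0.08, 0.22),
    ("CNTNAP2", "rs17236239", 0.66, -1.61, 0.11, 0.16),
    ("ATP2C2", "rs8053211", 1.45, 1.56, 0.12, 0.43),
    ("CD2AP", "rs9349407", 1.48, 1.55, 0.12, 0.29),
    ("TPD52", "rs7814569", 1.79, 1.53, 0.13, 0.09),
    ("COMT", "rs4680", 0.72, -1.41, 0.16, 0.50),
    ("C9ORF72", "rs3849942", 1.42, 1.38, 0.17, 0.24),
    ("CPE", "rs11186856", 0.33, -1.37, 0.17, 0.33),
    ("SORL1", "rs12285364", 0.42, -1.34, 0.18, 0.04),
    ("RIT2", "rs4130047", 0.70, -1.33, 0.18, 0.31),
    ("MOBP", "rs1768208", 0.72, -1.30, 0.19, 0.29),
]

#: A few further panel members named in the decision-tree results, with
#: population-typical MAFs (no per-marker statistics were published for them).
EXTRA_NAMED_MARKERS: list[tuple[str, str, float]] = [
    ("ACE", "rs4343", 0.47),
    ("GRN", "rs5848", 0.30),
    ("GSK3B", "rs13312998", 0.12),
    ("DCDC2", "rs1091047", 0.19),
]

N_PANEL_MARKERS = 75

# --- Cohort demographics (per stage x group) -------------------------------
# group keys: "AmnAD", "AtAD", "control"

DEMOGRAPHICS = {
    "discovery": {
        "n": {"AmnAD": 42, "AtAD": 17, "control": 133},
        "age_mean_sd": {"AmnAD": (76.2, 7.9), "AtAD": (73.3, 6.5), "control": (73.9, 6.2)},
        "frac_female": {"AmnAD": 0.429, "AtAD": 0.412, "control": 0.571},
        "apoe4_carrier": {"AmnAD": 0.643, "AtAD": 0.412, "control": 0.203},
    },
    "validation": {
        "n": {"AmnAD": 84, "AtAD": 22, "control": 150},
        "age_mean_sd": {"AmnAD": (80.7, 8.4), "AtAD": (80.9, 9.3), "control": (76.8, 7.4)},
        "frac_female": {"AmnAD": 0.536, "AtAD": 0.273, "control": 0.533},
        "apoe4_carrier": {"AmnAD": 0.494, "AtAD": 0.364, "control": 0.240},
    },
    "global": {
        "n": {"AmnAD": 126, "AtAD": 39, "control": 283},
        "age_mean_sd": {"AmnAD": (79.2, 8.5), "AtAD": (77.6, 9.0), "control": (75.4, 7.0)},
        "frac_female": {"AmnAD": 0.500, "AtAD": 0.333, "control": 0.551},
        "apoe4_carrier": {"AmnAD": 0.552, "AtAD": 0.385, "control": 0.223},
    },
}

#: Reported stage totals.  The per-subtype Validation counts above sum to 256
#: while the study text reports 276 participants (126 cases, 150 controls);
#: both totals are exposed and neither is asserted to be the correct one.
DISCOVERY_N_REPORTED = 192
VALIDATION_N_REPORTED = 276
VALIDATION_N_TABLE = 256

AGE_RANGE = (65, 101)

# --- Reference score-set evaluation series ---------------------------------

#: First (single-marker, APOE-only) score set's AUC in the Discovery stage.
REFERENCE_BASE_AUC = 0.69

#: Published per-set AUC increments for score sets B..Z (sets are nested:
#: set k = top k ranked, LD-pruned, risk-oriented markers).
REFERENCE_DELTA_AUC = [
    0.056, 0.038, 0.021, 0.023, 0.005, 0.011, 0.003, 0.008, 0.006, 0.010,
    -0.011, 0.005, -0.004, 0.004, -0.001, 0.007, -0.001, -0.001, 0.002,
    -0.001, 0.005, 0.005, 0.001, 0.001, 0.007,
]

#: Size of the score set the study selected (set "Q").
REFERENCE_SELECTED_SET_SIZE = 17

# --- Simulator calibration -------------------------------------------------

#: Per-allele odds ratios planted by default.  The APOE epsilon-4 effect acts
#: in the amnestic subtype and the HFE rs1799945 effect in the atypical
#: subtype; all other panel markers are null by default.
APOE_MARKER_ID = "rs429358/rs7412"
HFE_MARKER_ID = "rs1799945"
APOE_PLANTED_OR = 4.3
HFE_PLANTED_OR = 2.83

#: Control-population minor allele frequencies for the two effect markers.
#: The published panel MAFs (0.20 APOE, 0.15 HFE) are pooled case+control
#: frequencies; under the planted ORs the control-population values below
#: reproduce them, and the APOE value implies a Hardy-Weinberg control
#: epsilon-4 carrier rate of 1 - 0.88^2 = 22.6%, matching the observed 22.3%.
APOE_CONTROL_MAF = 0.12
HFE_CONTROL_MAF = 0.145


def panel_marker_table() -> list[tuple[str, str, float]]:
    """(gene, marker_id, control MAF) for the full 75-marker synthetic panel.

    The 20 published markers keep their panel MAFs (except the two effect
    markers, which use the control-population values above); the named
    decision-tree markers follow; the remainder are filler null markers with
    MAFs evenly spread over [0.05, 0.45].
    """
    rows: list[tuple[str, str, float]] = []
    for gene, rsid, _or, _z, _p, maf in STUDY_ASSOCIATION_TABLE:
        if rsid == APOE_MARKER_ID:
            maf = APOE_CONTROL_MAF
        elif rsid == HFE_MARKER_ID:
            maf = HFE_CONTROL_MAF
        rows.append((gene, rsid, maf))
    rows.extend(EXTRA_NAMED_MARKERS)
    n_fill = N_PANEL_MARKERS - len(rows)
    fill_mafs = np.round(np.linspace(0.05, 0.45, n_fill), 3)
    for i, maf in enumerate(fill_mafs):
        rows.append(("panel", f"snp{len(rows) + 1:02d}", float(maf)))
    assert len(rows) == N_PANEL_MARKERS
    return rows
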