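"""Two-stage study orchestration and the three stratified decision trees.

``run_two_stage_study`` performs the full discovery/validation risk-score
analysis on a simulated or loaded cohort: marker QC, additive logistic
association scan in the discovery stage, LD pruning of the ranked findings,
risk-allele orientation, nested score-set construction, AUC/DeLong
evaluation, selection of the optimal set by the two-consecutive-decrease
rule, and application of the frozen scoring file to the validation stage.

``run_subtype_trees`` fits the kappa-weighted recursive-partitioning tree
three times: all AD vs controls, amnestic AD vs controls, and atypical AD
vs controls, with sex, age, the APOE epsilon-4 dose, and every QC-passing
marker as predictors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .association import association_table, run_association_scan
from .cohort import (
    CohortValidationError,
    GenotypeMatrix,
    QCThresholds,
    SampleRecord,
    apply_qc,
    read_cohort_table,
    read_genotype_matrix,
    write_cohort_table,
    write_dose_tsv,
    write_qc_report,
)
from .roc import (
    auc_mann_whitney,
    classification_metrics,
    compare_paired_auc,
    evaluate_score_sets,
    evaluation_table,
    select_optimal_set,
)
from .scoring import build_nested_score_sets, compute_sample_scores, ld_prune_ranked
from .simulate import SimulationConfig, default_config, simulate_cohort, split_cohort
from .tree import DecisionTree, Predictor, TreeConfig, export_tree, grow_tree

logger = logging.getLogger(__name__)

DEFAULT_DISCOVERY_FRACTION = presets.DISCOVERY_N_REPORTED / (
    presets.DISCOVERY_N_REPORTED + presets.VALIDATION_N_REPORTED
)


@dataclass
class StudyConfig:
    simulation: SimulationConfig | None = None
    genotype_path: str | None = None
    genotype_format: str = "dose_tsv"
    phenotype_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    bonferroni_k: int = presets.N_PANEL_MARKERS
    ld_threshold: float = 0.8
    max_sets: int = 26
    stopping_rule: str = "two_decreases"
    discovery_fraction: float = DEFAULT_DISCOVERY_FRACTION
    tree: TreeConfig = field(default_factory=TreeConfig)
    seed: int = 0

    def __post_init__(self):
        has_paths = self.genotype_path is not None
        if has_paths == (self.simulation is not None):
            raise CohortValidationError(
                "exactly one of simulation config or input paths must be supplied"
            )


def load_cohort(config: StudyConfig):
    """Materialize (genotypes, samples) from the simulator or from files."""
    if config.simulation is not None:
        sim = simulate_cohort(config.simulation)
        samples = sim.samples
        if all(s.split == "unassigned" for s in samples):
            samples = split_cohort(samples, config.discovery_fraction, config.seed)
        return sim.genotypes, samples
    g = read_genotype_matrix(config.genotype_path, config.genotype_format)
    samples = read_cohort_table(config.phenotype_path)
    return g, samples


@dataclass
class TwoStageResult:
    qc_report: pd.DataFrame
    association: pd.DataFrame
    discovery_evaluations: list
    selected_index: int          # 1-based = marker count of selected set
    selected_label: str
    score_sets: list
    score_file_sha256: str
    validation_table: pd.DataFrame
    classification_sweep: pd.DataFrame
    n_discovery: int
    n_validation: int
    log: dict


def _score_file_text(score_set, g: GenotypeMatrix) -> str:
    lines = []
    for sm in score_set.markers:
        var = g.variants[g.marker_index(sm.marker_id)]
        token = var.minor_allele if sm.risk_allele == "minor" else var.major_allele
        lines.append(f"{sm.marker_id}\t{token}\t{sm.weight:g}")
    return "\n".join(lines) + "\n"


def run_two_stage_study(config: StudyConfig) -> TwoStageResult:
    g, samples = load_cohort(config)
    by_id = {s.sample_id: s for s in samples}

    # QC on the full cohort (inclusion criteria are dataset-level); HWE is
    # assessed in controls only so that planted/true risk loci are not
    # rejected for the case/control mixture's homozygote excess
    controls = [s.sample_id for s in samples if s.group == "control"]
    g_qc, qc_report = apply_qc(g, config.qc, hwe_sample_ids=controls or None)

    disc_ids = [s.sample_id for s in samples if s.split == "discovery"]
    valid_ids = [s.sample_id for s in samples if s.split == "validation"]
    if not disc_ids or not valid_ids:
        raise CohortValidationError("cohort must carry discovery/validation splits")
    g_disc = g_qc.subset_samples(disc_ids)
    g_valid = g_qc.subset_samples(valid_ids)

    # Discovery: scan -> prune -> orient -> nested sets -> evaluate -> select
    ranked = run_association_scan(g_disc, samples)
    assoc = association_table(ranked, g_disc)
    # separation-flagged fits carry no usable OR: they cannot be oriented or
    # scored, so they are excluded from the scoring stage (they rank last)
    scoreable = [r for r in ranked if np.isfinite(r.or_)]
    pruned = ld_prune_ranked(scoreable, g_disc, config.ld_threshold)
    sets = build_nested_score_sets(pruned, config.max_sets)
    disc_labels = np.array([by_id[s].is_case for s in disc_ids])
    evaluations = evaluate_score_sets(sets, g_disc, disc_labels)
    selected = select_optimal_set(evaluations, config.stopping_rule)
    selected_set = sets[selected - 1]
    score_text = _score_file_text(selected_set, g_qc)
    sha = hashlib.sha256(score_text.encode()).hexdigest()

    # Validation: frozen scoring file, compared against the first-set score
    valid_labels = np.array([by_id[s].is_case for s in valid_ids])
    rows = []
    first_scores_v = compute_sample_scores(sets[0], g_valid)["score"].to_numpy()
    sel_scores_v = compute_sample_scores(selected_set, g_valid)["score"].to_numpy()
    first_scores_d = compute_sample_scores(sets[0], g_disc)["score"].to_numpy()
    sel_scores_d = compute_sample_scores(selected_set, g_disc)["score"].to_numpy()
    for stage, labels, first_sc, sel_sc, n in (
        ("discovery", disc_labels, first_scores_d, sel_scores_d, len(disc_ids)),
        ("validation", valid_labels, first_scores_v, sel_scores_v, len(valid_ids)),
    ):
        auc_first = auc_mann_whitney(first_sc, labels)
        auc_sel = auc_mann_whitney(sel_sc, labels)
        _, p = compare_paired_auc(sel_sc, first_sc, labels)
        rows.append((stage, sets[0].label, auc_first.auc, auc_first.se, np.nan, n))
        rows.append((stage, selected_set.label, auc_sel.auc, auc_sel.se, p, n))
    validation_table = pd.DataFrame(
        rows, columns=["stage", "Score", "AUC", "SE", "P_vs_first", "N"]
    )

    # Classification sweep of the selected score in the validation stage
    sweep_rows = []
    for t in np.unique(sel_scores_v):
        m = classification_metrics(sel_scores_v, valid_labels, t)
        sweep_rows.append(
            (t, m.sensitivity, m.specificity, m.percent_correct)
        )
    classification_sweep = pd.DataFrame(
        sweep_rows, columns=["threshold", "sensitivity", "specificity", "percent_correct"]
    )

    log = {
        "seed": config.seed,
        "n_markers_input": g.n_markers,
        "n_markers_qc": g_qc.n_markers,
        "bonferroni_k": config.bonferroni_k,
        "ld_threshold": config.ld_threshold,
        "stopping_rule": config.stopping_rule,
        "selected_label": selected_set.label,
        "selected_size": selected,
        "score_file_sha256": sha,
        "n_discovery": len(disc_ids),
        "n_validation": len(valid_ids),
    }
    return TwoStageResult(
        qc_report=qc_report,
        association=assoc,
        discovery_evaluations=evaluations,
        selected_index=selected,
        selected_label=selected_set.label,
        score_sets=sets,
        score_file_sha256=sha,
        validation_table=validation_table,
        classification_sweep=classification_sweep,
        n_discovery=len(disc_ids),
        n_validation=len(valid_ids),
        log=log,
    )


# ---------------------------------------------------------------------------
# Decision trees

def build_predictors(
    g: GenotypeMatrix, samples: list[SampleRecord], apoe_marker: str = presets.APOE_MARKER_ID
) -> list[Predictor]:
    """Predictor manifest: sex (0 male / 1 female), age (years), the APOE
    epsilon-4 dose, then every marker dose, aligned to ``g``'s sample order.

    When the epsilon-4 composite marker is present in the matrix it doubles
    as the derived epsilon-4 dose predictor (named APOE_e4) and is not
    repeated under its marker id.
    """
    by_id = {s.sample_id: s for s in samples}
    ordered = [by_id[sid] for sid in g.sample_ids]
    preds = [
        Predictor("sex", "binary", [1.0 if s.sex == "female" else 0.0 for s in ordered]),
        Predictor("age", "continuous", [float(s.age) for s in ordered]),
    ]
    for v in g.variants:
        name = "APOE_e4" if v.marker_id == apoe_marker else v.marker_id
        preds.append(Predictor(name, "dose", g.column(v.marker_id)))
    return preds


def run_subtype_trees(
    g: GenotypeMatrix,
    samples: list[SampleRecord],
    tree_config: TreeConfig | None = None,
    qc: QCThresholds | None = None,
) -> dict[str, DecisionTree]:
    """Fit the three stratified analyses: all AD, AmnAD-only, AtAD-only, each
    versus controls.  A stratum lacking both classes is skipped with a
    warning."""
    tree_config = tree_config or TreeConfig()
    controls = [
        s.sample_id for s in samples
        if s.group == "control" and s.sample_id in set(g.sample_ids)
    ]
    g_qc, _ = apply_qc(g, qc, hwe_sample_ids=controls or None)
    trees: dict[str, DecisionTree] = {}
    strata = {
        "all_ad": ("AmnAD", "AtAD"),
        "amnestic": ("AmnAD",),
        "atypical": ("AtAD",),
    }
    by_id = {s.sample_id: s for s in samples}
    for name, case_groups in strata.items():
        keep, labels = [], []
        for sid in g_qc.sample_ids:
            s = by_id.get(sid)
            if s is None:
                continue
            if s.group in case_groups:
                keep.append(sid)
                labels.append(True)
            elif s.group == "control":
                keep.append(sid)
                labels.append(False)
        labels = np.array(labels, dtype=bool)
        if labels.size == 0 or labels.all() or not labels.any():
            warnings.warn(f"stratum {name!r} lacks both classes; tree skipped")
            continue
        g_sub = g_qc.subset_samples(keep)
        preds = build_predictors(g_sub, samples)
        trees[name] = grow_tree(labels, preds, tree_config)
    return trees


# ---------------------------------------------------------------------------
# Report bundle

def write_report_bundle(
    result: TwoStageResult,
    trees: dict[str, DecisionTree],
    outdir,
) -> dict[str, str]:
    """Write all report tables/exports under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, writer):
        path = outdir / name
        writer(path)
        paths[name] = str(path)

    save("qc_report.tsv", lambda p: write_qc_report(result.qc_report, p))
    save(
        "association.tsv",
        lambda p: result.association.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    )
    save(
        "score_set_evaluation.tsv",
        lambda p: evaluation_table(result.discovery_evaluations).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        ),
    )
    save(
        "two_stage_auc.tsv",
        lambda p: result.validation_table.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    )
    save(
        "classification_sweep.tsv",
        lambda p: result.classification_sweep.to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        ),
    )
    for name, tree in trees.items():
        save(f"tree_{name}.json", lambda p, t=tree: Path(p).write_text(export_tree(t, "json")))
        save(f"tree_{name}.dot", lambda p, t=tree: Path(p).write_text(export_tree(t, "dot")))
    save("run_log.json", lambda p: Path(p).write_text(json.dumps(result.log, indent=1)))
    return paths
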