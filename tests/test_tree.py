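"""Kappa-weighted ROC recursive partitioning: candidate cuts, split quality,
oracle equivalence, stopping rules, exports."""

import numpy as np
import pytest

from adrisk.cohort import CohortValidationError
from adrisk.tree import (
    Predictor,
    SplitRule,
    TreeConfig,
    best_split_at_node,
    candidate_splits,
    export_tree,
    grow_tree,
    split_quality,
    tree_from_json,
)
from oracles import oracle_best_split, oracle_grow


# --- candidate splits ------------------------------------------------------

def test_candidate_cuts_by_kind():
    dose = Predictor("d", "dose", [0, 1, 2, 0, 1])
    assert [r.cut for r in candidate_splits(dose)] == [1.0, 2.0]
    binary = Predictor("b", "binary", [0, 1, 0, 1])
    assert [r.cut for r in candidate_splits(binary)] == [1.0]
    ages = Predictor("age", "continuous", [66, 70, 77, 66])
    assert [r.cut for r in candidate_splits(ages)] == [70.0, 77.0]  # min cut degenerate
    assert candidate_splits(Predictor("const", "binary", [0, 0, 0])) == []


# --- split quality ---------------------------------------------------------

def test_split_quality_weighted_sesp():
    labels = np.array([True] * 5 + [False] * 5)
    assert split_quality(labels, labels.copy()) == pytest.approx(1.0)  # perfect
    # Se 0.8, Sp 0.6 at r = 0.5 -> 0.7
    positive = np.array([1, 1, 1, 1, 0, 1, 1, 0, 0, 0], bool)
    assert split_quality(labels, positive) == pytest.approx(0.7)
    assert split_quality(labels, positive, kappa_weight=1.0) == pytest.approx(0.8)


def test_split_quality_kraemer_equals_cohens_kappa():
    # 2x2: TP 40, FN 10, FP 20, TN 30 -> po 0.7, pe 0.5, kappa 0.4
    labels = np.repeat([True, False], 50)
    positive = np.concatenate([np.repeat([True, False], [40, 10]),
                               np.repeat([True, False], [20, 30])])
    q = split_quality(labels, positive, criterion="kraemer_kappa")
    assert q == pytest.approx(0.4, abs=1e-12)
    po, pe = 0.7, 0.5
    assert q == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


def test_split_quality_kraemer_matches_agreement_formula(rng):
    for _ in range(20):
        labels = rng.random(60) < 0.5
        positive = rng.random(60) < 0.5
        if labels.all() or not labels.any():
            continue
        q = split_quality(labels, positive, criterion="kraemer_kappa")
        po = (labels == positive).mean()
        p_yes = labels.mean() * positive.mean()
        p_no = (1 - labels.mean()) * (1 - positive.mean())
        pe = p_yes + p_no
        assert q == pytest.approx((po - pe) / (1 - pe), abs=1e-12)


def test_split_quality_single_class_rejected():
    with pytest.raises(CohortValidationError):
        split_quality(np.ones(5, bool), np.zeros(5, bool))


# --- best split ------------------------------------------------------------

def make_noise_predictors(rng, n, k=4):
    return [
        Predictor(f"noise{j}", "dose", rng.integers(0, 3, n).astype(float))
        for j in range(k)
    ]


def test_best_split_finds_perfect_binary_predictor(rng):
    n = 60
    labels = np.repeat([True, False], 30)
    preds = [Predictor("perfect", "binary", labels.astype(float))] + \
        make_noise_predictors(rng, n)
    found = best_split_at_node(labels, preds, TreeConfig())
    assert found.status == "found"
    assert found.rule.predictor == "perfect" and found.quality == pytest.approx(1.0)
    assert found.rule.positive_side == "ge"


def test_best_split_pure_noise_rarely_significant():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        labels = np.repeat([True, False], 100)
        preds = make_noise_predictors(rng, 200, k=6)
        found = best_split_at_node(labels, preds, TreeConfig())
        hits += found.status == "found"
    assert hits <= 5  # alpha 0.01 with Bonferroni over predictors


@pytest.mark.parametrize("criterion", ["weighted_sesp", "kraemer_kappa"])
@pytest.mark.parametrize("seed", range(12))
def test_best_split_matches_exhaustive_oracle(seed, criterion):
    rng = np.random.default_rng(seed)
    n = 30 + int(rng.integers(0, 21))
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        return
    vals_age = rng.integers(65, 95, n).astype(float)
    preds = [
        Predictor("sex", "binary", rng.integers(0, 2, n).astype(float)),
        Predictor("age", "continuous", vals_age),
        Predictor("snp1", "dose", rng.integers(0, 3, n).astype(float)),
        Predictor("snp2", "dose", rng.integers(0, 3, n).astype(float)),
    ]
    # sprinkle missing values
    preds[2].values[rng.integers(0, n, 2)] = np.nan
    cfg = TreeConfig(min_subgroup=5, alpha=0.5, criterion=criterion)
    found = best_split_at_node(labels, preds, cfg)
    rule, p_raw, p_corr, status = oracle_best_split(
        labels,
        [(p.name, p.kind, p.values) for p in preds],
        min_subgroup=5,
        alpha=0.5,
        criterion=criterion,
    )
    assert found.status == status
    if status == "found":
        assert (found.rule.predictor, found.rule.cut, found.rule.positive_side) == rule
        assert found.p_raw == pytest.approx(p_raw, abs=1e-12)
        assert found.p_corrected == pytest.approx(p_corr, abs=1e-12)


def test_best_split_min_subgroup_blocks_tiny_children():
    labels = np.repeat([True, False], [12, 12])
    lop = np.array([1.0] * 3 + [0.0] * 21)  # 3 vs 21: below min_subgroup 10
    preds = [Predictor("lop", "binary", lop)]
    found = best_split_at_node(labels, preds, TreeConfig())
    assert found.status == "no_admissible"


# --- tree growth -----------------------------------------------------------

def test_grow_tree_single_class_root_rejected(rng):
    preds = make_noise_predictors(rng, 20)
    with pytest.raises(CohortValidationError):
        grow_tree(np.zeros(20, bool), preds)


def planted_two_level(rng, n=120):
    """Labels driven by predictor A, then by B within A-positive."""
    a = rng.integers(0, 2, n).astype(float)
    b = rng.integers(0, 3, n).astype(float)
    p = 0.15 + 0.55 * a + 0.25 * (a * (b >= 1))
    labels = rng.random(n) < p
    preds = [
        Predictor("A", "binary", a),
        Predictor("B", "dose", b),
        Predictor("noise", "dose", rng.integers(0, 3, n).astype(float)),
    ]
    return labels, preds


@pytest.mark.parametrize("seed", range(6))
def test_grow_tree_matches_recursive_oracle(seed):
    rng = np.random.default_rng(seed)
    labels, preds = planted_two_level(rng, n=40)
    if labels.all() or not labels.any():
        return
    cfg = TreeConfig(min_subgroup=5, alpha=0.2)
    tree = grow_tree(labels, preds, cfg)
    oracle = oracle_grow(
        labels,
        [(p.name, p.kind, p.values) for p in preds],
        min_subgroup=5,
        alpha=0.2,
    )

    def compare(node, onode):
        assert (node.n_case, node.n_control) == onode["counts"]
        if "leaf" in onode:
            assert node.is_leaf and node.leaf_reason == onode["leaf"]
        else:
            assert (node.split.predictor, node.split.cut, node.split.positive_side) == onode["rule"]
            for child, ochild in zip(node.children, onode["children"]):
                compare(child, ochild)

    compare(tree.root, oracle)


def test_tree_counts_conserved_and_leaves_reasoned(rng):
    labels, preds = planted_two_level(rng, n=300)
    tree = grow_tree(labels, preds, TreeConfig())
    for node in tree.nodes():
        if node.children:
            assert node.n_case == sum(c.n_case for c in node.children)
            assert node.n_control == sum(c.n_control for c in node.children)
            assert node.chi2_p_corrected <= tree.config.alpha
        else:
            assert node.leaf_reason in {"min_subgroup", "not_significant", "max_depth", "pure"}
        assert node.depth <= tree.config.max_path_splits


def test_tree_depth_cap(rng):
    labels, preds = planted_two_level(rng, n=400)
    tree = grow_tree(labels, preds, TreeConfig(alpha=0.9, max_path_splits=2))
    assert max(n.depth for n in tree.nodes()) <= 2


def test_node_membership_metrics(rng):
    labels, preds = planted_two_level(rng, n=200)
    tree = grow_tree(labels, preds, TreeConfig())
    total_case = int(labels.sum())
    total_control = int((~labels).sum())
    root = tree.root
    assert root.metrics.sensitivity == 1.0 and root.metrics.specificity == 0.0
    assert root.metrics.pvp == pytest.approx(total_case / labels.size)
    for node in tree.nodes():
        m = node.metrics
        assert m.sensitivity == pytest.approx(node.n_case / total_case)
        assert m.specificity == pytest.approx((total_control - node.n_control) / total_control)
        assert m.pvp == pytest.approx(node.n_case / node.n)
        assert m.pvn == pytest.approx(node.n_control / node.n)


def test_export_json_roundtrip_and_dot(rng):
    labels, preds = planted_two_level(rng, n=200)
    tree = grow_tree(labels, preds, TreeConfig())
    doc = export_tree(tree, "json")
    tree2 = tree_from_json(doc)
    assert export_tree(tree2, "json") == doc
    assert tree2.config == tree.config
    dot = export_tree(tree, "dot")
    assert dot.count("label=") >= len(tree.nodes())
    text = export_tree(tree, "text")
    assert "split on" in text or "leaf" in text
    with pytest.raises(CohortValidationError):
        export_tree(tree, "png")


def test_export_single_leaf_tree(rng):
    # alpha so small nothing is significant -> root is the only node
    labels = np.repeat([True, False], 15)
    preds = make_noise_predictors(rng, 30, k=2)
    tree = grow_tree(labels, preds, TreeConfig(alpha=1e-12))
    assert len(tree.nodes()) == 1 and tree.root.leaf_reason is not None
    doc = export_tree(tree, "json")
    assert len(tree_from_json(doc).nodes()) == 1
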