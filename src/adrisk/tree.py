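"""Kappa-weighted ROC recursive partitioning.

At each node, every admissible (predictor, cut) pair is treated as a binary
diagnostic test for case status and scored by a sensitivity/specificity
trade-off governed by the kappa weight r: the default criterion is
``r * Se + (1 - r) * Sp`` (r = 0.5 weighs them equally); the alternative is
Kraemer's weighted-kappa quality index, which at r = 0.5 equals Cohen's
kappa of the 2x2 table.  The winning split must pass a multiple-testing-
corrected Pearson chi-square test; growth stops when prospective subgroups
are too small, the corrected p exceeds alpha, the maximum interaction depth
is reached, or a node is single-class.

Predictor kinds follow the study's coding: binary 0/1 (e.g. sex), additive
dose 0/1/2 (candidate cuts >= 1 and >= 2), and continuous (age; one
candidate cut at each distinct observed value).  The test-positive side of
a split is the side with the higher case fraction at fit time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortValidationError
from .roc import ClassificationMetrics


@dataclass
class Predictor:
    name: str
    kind: str             # "binary" | "dose" | "continuous"
    values: np.ndarray    # per-sample, NaN = missing

    def __post_init__(self):
        if self.kind not in ("binary", "dose", "continuous"):
            raise CohortValidationError(f"unknown predictor kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        nonmiss = self.values[~np.isnan(self.values)]
        if self.kind == "dose" and not np.isin(nonmiss, (0, 1, 2)).all():
            raise CohortValidationError(f"{self.name}: dose values must be 0/1/2")
        if self.kind == "binary" and not np.isin(nonmiss, (0, 1)).all():
            raise CohortValidationError(f"{self.name}: binary values must be 0/1")


@dataclass(frozen=True)
class TreeConfig:
    kappa_weight: float = 0.5
    min_subgroup: int = 10
    alpha: float = 0.01
    max_path_splits: int = 4
    correction: str = "bonferroni_predictors"  # or "bonferroni_cuts"
    criterion: str = "weighted_sesp"           # or "kraemer_kappa"

    def __post_init__(self):
        if not (0 <= self.kappa_weight <= 1):
            raise CohortValidationError("kappa_weight must lie in [0, 1]")
        if self.min_subgroup < 1 or self.max_path_splits < 1 or not (0 < self.alpha <= 1):
            raise CohortValidationError("tree thresholds must be positive")
        if self.correction not in ("bonferroni_predictors", "bonferroni_cuts"):
            raise CohortValidationError(f"unknown correction {self.correction!r}")
        if self.criterion not in ("weighted_sesp", "kraemer_kappa"):
            raise CohortValidationError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class SplitRule:
    predictor: str
    cut: float
    positive_side: str = "ge"  # side designated test-positive ("ge" or "lt")

    def describe(self, kind: str | None = None) -> str:
        return f"{self.predictor} >= {self.cut:g}"


def candidate_splits(p: Predictor) -> list[SplitRule]:
    """Candidate '>= cut' rules for one predictor.

    Dose predictors propose cuts at 1 and 2, binary at 1, continuous at each
    distinct observed value; cuts that put every sample on one side (e.g. a
    cut at the minimum observed value) are dropped.  A constant predictor
    has no candidates.
    """
    nonmiss = p.values[~np.isnan(p.values)]
    distinct = np.unique(nonmiss)
    if distinct.size < 2:
        return []
    if p.kind == "binary":
        cuts = [1.0]
    elif p.kind == "dose":
        cuts = [1.0, 2.0]
    else:
        cuts = list(distinct)
    out = []
    for c in cuts:
        if (distinct >= c).any() and (distinct < c).any():
            out.append(SplitRule(p.name, float(c)))
    return out


def _confusion(labels: np.ndarray, positive: np.ndarray):
    tp = float((positive & labels).sum())
    fn = float((~positive & labels).sum())
    fp = float((positive & ~labels).sum())
    tn = float((~positive & ~labels).sum())
    return tp, fn, fp, tn


def split_quality(
    labels: np.ndarray,
    positive: np.ndarray,
    kappa_weight: float = 0.5,
    criterion: str = "weighted_sesp",
) -> float:
    """Quality of a candidate split viewed as a diagnostic test.

    ``weighted_sesp``: r*Se + (1-r)*Sp.  ``kraemer_kappa``: the weighted-
    kappa quality index (ad - bc) / (r*(a+b)(b+d) + (1-r)*(a+c)(c+d)) for
    the 2x2 table [[TP, FN], [FP, TN]]; at r = 0.5 this equals Cohen's
    kappa.
    """
    labels = np.asarray(labels, dtype=bool)
    positive = np.asarray(positive, dtype=bool)
    if labels.all() or not labels.any():
        raise CohortValidationError("split quality undefined for single-class node")
    a, b, c, d = _confusion(labels, positive)
    r = kappa_weight
    if criterion == "weighted_sesp":
        se = a / (a + b)
        sp = d / (c + d)
        return float(r * se + (1 - r) * sp)
    denom = r * (a + b) * (b + d) + (1 - r) * (a + c) * (c + d)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / denom)


@dataclass
class BestSplit:
    status: str                   # "found" | "no_admissible" | "not_significant"
    rule: SplitRule | None = None
    p_raw: float = np.nan
    p_corrected: float = np.nan
    quality: float = np.nan
    n_predictors_evaluated: int = 0
    n_cuts_evaluated: int = 0


def best_split_at_node(
    labels: np.ndarray,
    predictors: list[Predictor],
    config: TreeConfig,
    idx: np.ndarray | None = None,
) -> BestSplit:
    """Exhaustive search for the best admissible split of one node.

    ``idx`` selects the node's samples within the predictors' full-cohort
    arrays (default: all).  Samples missing a predictor are excluded from
    that predictor's search; admissibility requires both prospective
    children (missing samples joining the larger side) to reach the minimum
    subgroup size.  The winner maximizes the quality criterion, ties broken
    by predictor manifest order then lower cut; it is then tested by Pearson
    chi-square (1 df, no continuity correction) with Bonferroni correction
    over predictors (default) or over all cuts evaluated.
    """
    labels = np.asarray(labels, dtype=bool)
    if idx is None:
        idx = np.arange(labels.size)
    y = labels[idx]
    if y.all() or not y.any():
        raise CohortValidationError("cannot split a single-class node")
    best: tuple | None = None  # (quality, pred_order, cut, rule, p_raw)
    n_pred_eval = 0
    n_cuts_eval = 0
    for order, p in enumerate(predictors):
        vals = p.values[idx]
        nonmiss = ~np.isnan(vals)
        v = vals[nonmiss]
        yy = y[nonmiss]
        if yy.size == 0 or yy.all() or not yy.any():
            continue
        n_missing = int((~nonmiss).sum())
        any_admissible = False
        for rule in candidate_splits(Predictor(p.name, p.kind, v)):
            ge = v >= rule.cut
            n_ge, n_lt = int(ge.sum()), int((~ge).sum())
            if n_ge >= n_lt:
                n_ge += n_missing
            else:
                n_lt += n_missing
            if n_ge < config.min_subgroup or n_lt < config.min_subgroup:
                continue
            any_admissible = True
            n_cuts_eval += 1
            case_frac_ge = yy[ge].mean()
            case_frac_lt = yy[~ge].mean()
            positive_side = "ge" if case_frac_ge >= case_frac_lt else "lt"
            positive = ge if positive_side == "ge" else ~ge
            q = split_quality(yy, positive, config.kappa_weight, config.criterion)
            if best is None or q > best[0] + 1e-12:
                table = np.array(
                    [
                        [(ge & yy).sum(), (ge & ~yy).sum()],
                        [(~ge & yy).sum(), (~ge & ~yy).sum()],
                    ],
                    dtype=float,
                )
                chi2, p_raw, _, _ = stats.chi2_contingency(table, correction=False)
                best = (
                    q,
                    order,
                    rule.cut,
                    SplitRule(p.name, rule.cut, positive_side),
                    float(p_raw),
                )
        if any_admissible:
            n_pred_eval += 1
    if best is None:
        return BestSplit("no_admissible", n_predictors_evaluated=n_pred_eval)
    factor = n_pred_eval if config.correction == "bonferroni_predictors" else n_cuts_eval
    p_corr = min(1.0, best[4] * max(factor, 1))
    status = "found" if p_corr <= config.alpha else "not_significant"
    return BestSplit(
        status, best[3], best[4], p_corr, best[0], n_pred_eval, n_cuts_eval
    )


@dataclass
class TreeNode:
    id: int
    depth: int
    n_case: int
    n_control: int
    split: SplitRule | None = None
    leaf_reason: str | None = None  # min_subgroup | not_significant | max_depth | pure
    chi2_p_raw: float = np.nan
    chi2_p_corrected: float = np.nan
    metrics: ClassificationMetrics | None = None
    children: list = field(default_factory=list)  # [ge child, lt child]

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class DecisionTree:
    root: TreeNode
    config: TreeConfig
    predictor_names: list[str]

    def nodes(self):
        return list(self.root.walk())


def _node_metrics(n_case, n_control, total_case, total_control) -> ClassificationMetrics:
    n = n_case + n_control
    return ClassificationMetrics(
        sensitivity=n_case / total_case,
        specificity=(total_control - n_control) / total_control,
        pvp=n_case / n if n else np.nan,
        pvn=n_control / n if n else np.nan,
        percent_correct=(n_case + (total_control - n_control))
        / (total_case + total_control),
    )


def grow_tree(
    labels: np.ndarray, predictors: list[Predictor], config: TreeConfig | None = None
) -> DecisionTree:
    """Recursively partition the cohort until a stopping rule fires.

    ``labels`` is the per-sample case indicator, aligned with every
    predictor's values.  Missing predictor values follow the larger child
    at the split that uses them.
    """
    config = config or TreeConfig()
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise CohortValidationError("root must contain both classes")
    total_case = int(labels.sum())
    total_control = int((~labels).sum())
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_id = counter[0]
        counter[0] += 1
        y = labels[idx]
        node = TreeNode(
            node_id,
            depth,
            int(y.sum()),
            int((~y).sum()),
            metrics=_node_metrics(
                int(y.sum()), int((~y).sum()), total_case, total_control
            ),
        )
        if y.all() or not y.any():
            node.leaf_reason = "pure"
            return node
        if depth >= config.max_path_splits:
            node.leaf_reason = "max_depth"
            return node
        found = best_split_at_node(labels, predictors, config, idx)
        node.chi2_p_raw = found.p_raw
        node.chi2_p_corrected = found.p_corrected
        if found.status == "no_admissible":
            node.leaf_reason = "min_subgroup"
            return node
        if found.status == "not_significant":
            node.leaf_reason = "not_significant"
            return node
        rule = found.rule
        node.split = rule
        pvals = next(p for p in predictors if p.name == rule.predictor).values[idx]
        ge = pvals >= rule.cut          # NaN compares False
        lt = pvals < rule.cut
        missing = np.isnan(pvals)
        if ge.sum() >= lt.sum():
            ge = ge | missing
        else:
            lt = lt | missing
        node.children = [build(idx[ge], depth + 1), build(idx[lt], depth + 1)]
        return node

    root = build(np.arange(labels.size), 0)
    return DecisionTree(root, config, [p.name for p in predictors])


def node_path_metrics(tree: DecisionTree) -> dict[int, ClassificationMetrics]:
    """Membership-based metrics per node: treating membership in the node as
    a positive test against the whole root sample."""
    return {node.id: node.metrics for node in tree.nodes()}


# ---------------------------------------------------------------------------
# Export / import

def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "id": node.id,
        "depth": node.depth,
        "n_case": node.n_case,
        "n_control": node.n_control,
        "chi2_p_raw": None if np.isnan(node.chi2_p_raw) else node.chi2_p_raw,
        "chi2_p_corrected": None
        if np.isnan(node.chi2_p_corrected)
        else node.chi2_p_corrected,
        "split": None
        if node.split is None
        else {
            "predictor": node.split.predictor,
            "cut": node.split.cut,
            "positive_side": node.split.positive_side,
        },
        "leaf_reason": node.leaf_reason,
        "metrics": None
        if node.metrics is None
        else {
            "sensitivity": node.metrics.sensitivity,
            "specificity": node.metrics.specificity,
            "pvp": None if np.isnan(node.metrics.pvp) else node.metrics.pvp,
            "pvn": None if np.isnan(node.metrics.pvn) else node.metrics.pvn,
            "percent_correct": node.metrics.percent_correct,
        },
        "children": [_node_to_dict(c) for c in node.children],
    }
    return d


def _node_from_dict(d: dict) -> TreeNode:
    metrics = None
    if d["metrics"] is not None:
        m = d["metrics"]
        metrics = ClassificationMetrics(
            m["sensitivity"],
            m["specificity"],
            np.nan if m["pvp"] is None else m["pvp"],
            np.nan if m["pvn"] is None else m["pvn"],
            m["percent_correct"],
        )
    split = None
    if d["split"] is not None:
        split = SplitRule(d["split"]["predictor"], d["split"]["cut"], d["split"]["positive_side"])
    return TreeNode(
        d["id"],
        d["depth"],
        d["n_case"],
        d["n_control"],
        split,
        d["leaf_reason"],
        np.nan if d["chi2_p_raw"] is None else d["chi2_p_raw"],
        np.nan if d["chi2_p_corrected"] is None else d["chi2_p_corrected"],
        metrics,
        [_node_from_dict(c) for c in d["children"]],
    )


def export_tree(tree: DecisionTree, format: str = "json") -> str:
    """Serialize a fitted tree: lossless ``json``, or ``dot``/``text`` views."""
    if format == "json":
        doc = {
            "config": {
                "kappa_weight": tree.config.kappa_weight,
                "min_subgroup": tree.config.min_subgroup,
                "alpha": tree.config.alpha,
                "max_path_splits": tree.config.max_path_splits,
                "correction": tree.config.correction,
                "criterion": tree.config.criterion,
            },
            "predictor_names": tree.predictor_names,
            "root": _node_to_dict(tree.root),
        }
        return json.dumps(doc, indent=1)
    if format == "dot":
        lines = ["digraph decision_tree {", "  node [shape=box];"]
        for node in tree.nodes():
            label = f"{node.n_case} case / {node.n_control} control"
            if node.split:
                label += f"\\nsplit: {node.split.describe()}"
            elif node.leaf_reason:
                label += f"\\nleaf: {node.leaf_reason}"
            lines.append(f'  n{node.id} [label="{label}"];')
            for child, edge in zip(node.children, (">=", "<")):
                lines.append(
                    f'  n{node.id} -> n{child.id} [label="{edge} {node.split.cut:g}"];'
                )
        lines.append("}")
        return "\n".join(lines)
    if format == "text":
        out = []

        def rec(node: TreeNode, prefix: str, branch: str):
            desc = f"[{node.n_case}/{node.n_control}]"
            if node.split:
                desc += f" split on {node.split.describe()}"
                if np.isfinite(node.chi2_p_corrected):
                    desc += f" (corrected p={node.chi2_p_corrected:.3g})"
            else:
                desc += f" leaf ({node.leaf_reason})"
            out.append(f"{prefix}{branch}{desc}")
            for child, b in zip(node.children, ("|-- >= ", "`-- <  ")):
                rec(child, prefix + "    ", b)

        rec(tree.root, "", "")
        return "\n".join(out)
    raise CohortValidationError(f"unknown export format {format!r}")


def tree_from_json(doc: str) -> DecisionTree:
    d = json.loads(doc)
    config = TreeConfig(**d["config"])
    return DecisionTree(_node_from_dict(d["root"]), config, d["predictor_names"])
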