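"""Informative-feature selection for MOB profiling.

A feature is kept only if it (i) discriminates stem from differentiated
cells — per-feature logistic regression trained on 60% of the cells, F1
on the held-out 40% strictly above 0.6 — and (ii) trends monotonically
across differentiation stages — trending index

    TI = sum_n (m_n - m_{n-1}) / sum_n |m_n - m_{n-1}|

on population-level stage means, with |TI| strictly above 0.5 — in BOTH
of two independent differentiation datasets.  The surviving features are
then reduced to one canonical representative per knowledge-graph node
(feature subcategory), and the value of any subset is benchmarked with a
held-out SVM ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "F1_CUT",
    "TI_CUT",
    "KnowledgeGraph",
    "f1_score_from_counts",
    "evaluate_feature",
    "trending_index",
    "select_features",
    "representatives",
    "classifier_roc",
    "build_default_knowledge_graph",
]

F1_CUT = 0.6
TI_CUT = 0.5


def f1_score_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 when tp == 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp + fn == 0:
        return float("nan")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def evaluate_feature(values, labels, positive_label=1, test_size: float = 0.4,
                     seed: int = 0):
    """Held-out F1 of a single-covariate logistic model.

    Trains on a stratified 60% split, predicts at probability threshold
    0.5, and scores F1 with the stem class positive.  A constant feature
    cannot be fit; the majority-class rule is scored instead and the
    result is flagged degenerate.  Returns ``(f1, degenerate)``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed)
    if np.ptp(x_tr) < 1e-12:
        pred = np.full(y_te.shape, y_tr.mean() >= 0.5)
        degenerate = True
    else:
        model = LogisticRegression(max_iter=1000)
        model.fit(x_tr, y_tr)
        pred = model.predict(x_te)
        degenerate = False
    tp = int(np.sum(pred & y_te))
    fp = int(np.sum(pred & ~y_te))
    fn = int(np.sum(~pred & y_te))
    return f1_score_from_counts(tp, fp, fn), degenerate


def trending_index(stage_means) -> float:
    """Signed net change over total change of ordered stage means.

    +1/-1 for strictly monotone sequences; values in (-0.5, 0.5) mark
    "fluctuating" features; NaN (undefined) when all stage means are
    equal.
    """
    means = np.asarray(stage_means, dtype=float)
    if means.ndim != 1 or means.size < 2:
        raise ValueError("need at least two ordered stage means")
    steps = np.diff(means)
    denom = np.abs(steps).sum()
    if denom == 0:
        return float("nan")
    return float(steps.sum() / denom)


@dataclass
class SelectionResult:
    """Per-feature gates in both datasets plus the conjunction verdict."""

    table: pd.DataFrame
    f1_cut: float = F1_CUT
    ti_cut: float = TI_CUT
    require_ti_sign_match: bool = True
    seed: int = 0

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _stage_means(df: pd.DataFrame, feature: str, stage_col: str) -> np.ndarray:
    return df.groupby(stage_col, sort=True)[feature].mean().to_numpy()


def select_features(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    feature_ids: list[str], stage_col: str = "stage",
                    stem_stage=0, f1_cut: float = F1_CUT,
                    ti_cut: float = TI_CUT,
                    require_ti_sign_match: bool = True,
                    seed: int = 0) -> SelectionResult:
    """Apply the two gates in both datasets and intersect.

    ``stem_stage`` identifies the stem population (the F1 positive class;
    stage 0 by convention).  ``require_ti_sign_match`` additionally
    demands the trend direction agree between datasets (a feature rising
    in one model and falling in the other is not reporting the same
    biology); switch off for the literal threshold-only rule.
    """
    records = {}
    for name, df in (("a", table_a), ("b", table_b)):
        counts = df[stage_col].value_counts()
        if (counts < 1).any() or df[stage_col].nunique() < 2:
            raise ValueError(f"dataset {name}: every stage needs cells")
        labels = (df[stage_col] == stem_stage).astype(int)
        for feat in feature_ids:
            f1, degen = evaluate_feature(df[feat], labels, positive_label=1,
                                         seed=seed)
            ti = trending_index(_stage_means(df, feat, stage_col))
            rec = records.setdefault(feat, {})
            rec[f"F1_{name}"] = f1
            rec[f"TI_{name}"] = ti
            rec[f"degenerate_{name}"] = degen
    out = pd.DataFrame.from_dict(records, orient="index").loc[feature_ids]
    out["pass_f1"] = (out["F1_a"] > f1_cut) & (out["F1_b"] > f1_cut)
    ti_ok = (out["TI_a"].abs() > ti_cut) & (out["TI_b"].abs() > ti_cut)
    if require_ti_sign_match:
        ti_ok &= np.sign(out["TI_a"]) == np.sign(out["TI_b"])
    out["pass_ti"] = ti_ok.fillna(False)
    out["selected"] = out["pass_f1"] & out["pass_ti"]
    return SelectionResult(out, f1_cut=f1_cut, ti_cut=ti_cut,
                           require_ti_sign_match=require_ti_sign_match,
                           seed=seed)


@dataclass
class KnowledgeGraph:
    """Feature subcategories (leaf nodes) with canonical representatives.

    ``nodes`` maps node id -> member feature ids.  Each registry feature
    belongs to exactly one leaf.  ``canonical_priority`` orders the
    statistic preferred as a node's representative.
    """

    nodes: dict[str, list[str]]
    canonical_priority: tuple[str, ...] = ("average", "median", "variance")

    def node_of(self, feature_id: str) -> str:
        for node, members in self.nodes.items():
            if feature_id in members:
                return node
        raise KeyError(f"feature {feature_id!r} not covered by the graph")

    def canonical(self, node: str) -> str:
        members = self.nodes[node]
        for stat in self.canonical_priority:
            for m in members:
                if m.endswith("_" + stat):
                    return m
        return members[0]


def build_default_knowledge_graph(registry) -> KnowledgeGraph:
    """Leaf nodes by (channel, region, statistic family).

    Mirrors the four stems of the feature hierarchy — morphology,
    mitochondria, cytoplasm/nucleus, compartmentalization — with one leaf
    per channel and statistic family under each regional stem.
    """
    nodes: dict[str, list[str]] = {}
    for e in registry:
        if e.channel == "morphology":
            node = "morphology"
        elif e.region == "compartmentalization":
            node = f"comp/{e.channel}/{e.family if e.family != 'comp' else _family_of(e.statistic)}"
        else:
            node = f"{e.region}/{e.channel}/{_family_of(e.statistic)}"
        nodes.setdefault(node, []).append(e.feature_id)
    return KnowledgeGraph(nodes)


def _family_of(stat: str) -> str:
    from .features import STRENGTH_STATS, DISTRIBUTION_STATS
    if stat in STRENGTH_STATS:
        return "strength"
    if stat in DISTRIBUTION_STATS:
        return "distribution"
    if stat == "corrected":
        return "strength"
    return "texture"


def representatives(selection: SelectionResult, graph: KnowledgeGraph,
                    node_fraction_cut: float = 0.5) -> list[str]:
    """Reduce the selected set to one representative per retained node.

    A node is retained when at least ``node_fraction_cut`` of its members
    were selected (a mostly-selected subcategory is genuinely informative;
    a single stray member is not).  Retained nodes emit their canonical
    member, whether or not that member itself passed.
    """
    selected = selection.selected
    for feat in selected:
        graph.node_of(feat)  # raises if uncovered
    reps = []
    for node, members in graph.nodes.items():
        frac = np.mean([m in selected for m in members])
        if frac >= node_fraction_cut and frac > 0:
            reps.append(graph.canonical(node))
    return reps


def classifier_roc(features: pd.DataFrame | np.ndarray, labels,
                   positive_label=1, test_size: float = 0.3, seed: int = 0):
    """Held-out SVM ROC for a feature subset.

    Trains an RBF-kernel SVM on a stratified 70% split and evaluates
    margin scores on the remaining 30%; AUC by the trapezoid rule.
    Returns ``(auc, fpr, tpr)``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    y = np.asarray(labels) == positive_label
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed)
    if y_te.all() or not y_te.any():
        raise ValueError("held-out split must contain both classes")
    model = SVC(kernel="rbf", gamma="scale", random_state=seed)
    model.fit(x_tr, y_tr)
    scores = model.decision_function(x_te)
    fpr, tpr, _ = roc_curve(y_te, scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr
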