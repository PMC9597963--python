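"""Model interpretability: gain importance, additive contributions, tree export.

Importance is the total gain — the cumulative improvement of the
squared-error objective contributed by all splits on a feature across
every tree — normalized so the table sums to 1.  Per-prediction
explanations decompose a score additively into the training grand mean
(the first tree's root internal value) plus one signed contribution per
feature.  Trees export with their internal values: the running branch
mean for the first tree, residual means (root = 0) for all later trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TrainedModel, conform_features

__all__ = [
    "feature_importance",
    "ContributionBreakdown",
    "predict_with_contributions",
    "TreeNode",
    "export_tree",
    "tree_to_dot",
]


def feature_importance(model: TrainedModel) -> pd.DataFrame:
    """Normalized gain importance, descending, ties broken by feature name.

    Columns: ``feature``, ``gain``, ``gain_fraction``, ``rank``.  The
    gain fractions sum to 1 whenever the model contains at least one
    split; a split-free model yields an empty table with a warning.
    """
    booster = model.booster
    names = booster.feature_name()
    gains = booster.feature_importance(importance_type="gain")
    total = float(gains.sum())
    if total <= 0:
        warnings.warn("model has no splits; importance table is empty", stacklevel=2)
        return pd.DataFrame(columns=["feature", "gain", "gain_fraction", "rank"])
    table = pd.DataFrame({"feature": names, "gain": gains.astype(float)})
    table["gain_fraction"] = table["gain"] / total
    table = table.sort_values(
        ["gain", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass(frozen=True)
class ContributionBreakdown:
    """Additive explanation of one prediction.

    ``base_value + sum(contributions.values()) == prediction`` to
    numerical precision; contributions are per-feature aggregates over
    every tree, so the same feature value may contribute differently in
    different guides depending on the other features' path choices.
    """

    base_value: float
    contributions: dict[str, float]
    prediction: float

    def top(self, n: int = 10) -> list[tuple[str, float]]:
        """The n features with the largest absolute contribution."""
        ranked = sorted(
            self.contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0])
        )
        return ranked[:n]


def predict_with_contributions(
    model: TrainedModel, features: pd.DataFrame
) -> list[ContributionBreakdown]:
    """Per-feature additive decomposition for each row of a feature table."""
    X = conform_features(features, model.schema)
    contrib = model.booster.predict(X, pred_contrib=True)
    names = model.booster.feature_name()
    out = []
    for row in np.atleast_2d(contrib):
        base = float(row[-1])
        per_feature = {n: float(v) for n, v in zip(names, row[:-1])}
        out.append(
            ContributionBreakdown(
                base_value=base,
                contributions=per_feature,
                prediction=base + float(row[:-1].sum()),
            )
        )
    return out


@dataclass
class TreeNode:
    """One node of an exported regression tree."""

    node_id: int
    depth: int
    internal_value: float
    is_leaf: bool
    split_feature: str | None = None
    rule: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


def _categorical_rule(model: TrainedModel, feature: str, threshold) -> str:
    # LightGBM encodes categorical splits as '||'-joined category codes.
    codes = [int(c) for c in str(threshold).split("||")]
    vocab = model.schema.vocabularies.get(feature)
    if vocab is not None:
        levels = [vocab[c] for c in codes if c < len(vocab)]
    else:  # pragma: no cover - schema always carries vocabularies
        levels = [str(c) for c in codes]
    return f"{feature} in {{{','.join(levels)}}}"


def export_tree(
    model: TrainedModel, tree_index: int, max_depth: int | None = None
) -> TreeNode:
    """Export one tree with split rules and internal values.

    The first tree's root internal value equals the training grand mean;
    every later tree fits residuals, so its root internal value is 0.
    Categorical splits report the explicit category subset sent left.
    ``max_depth`` truncates the export below that depth (truncated
    branches appear as leaves carrying their internal value).
    """
    n = model.booster.num_trees()
    if not 0 <= tree_index < n:
        raise IndexError(f"tree_index {tree_index} outside [0, {n})")
    dump = model.booster.dump_model()
    tree = dump["tree_info"][tree_index]["tree_structure"]
    counter = iter(range(10**9))

    def build(node: dict, depth: int) -> TreeNode:
        node_id = next(counter)
        if "leaf_value" in node and "split_feature" not in node:
            return TreeNode(
                node_id=node_id,
                depth=depth,
                internal_value=float(node["leaf_value"]),
                is_leaf=True,
            )
        feature = model.booster.feature_name()[node["split_feature"]]
        if node.get("decision_type") == "==":
            rule = _categorical_rule(model, feature, node["threshold"])
        else:
            rule = f"{feature} <= {node['threshold']:g}"
        out = TreeNode(
            node_id=node_id,
            depth=depth,
            internal_value=float(node.get("internal_value", 0.0)),
            is_leaf=False,
            split_feature=feature,
            rule=rule,
        )
        if max_depth is not None and depth + 1 > max_depth:
            out.is_leaf = True  # truncated for display; value retained
            return out
        for key in ("left_child", "right_child"):
            out.children.append(build(node[key], depth + 1))
        return out

    return build(tree, 0)


def tree_to_dot(root: TreeNode, title: str = "tree") -> str:
    """Render an exported tree as a Graphviz DOT document."""
    lines = [f'digraph "{title}" {{', "  node [fontname=Helvetica];"]
    for node in root.walk():
        if node.is_leaf and node.split_feature is None:
            label = f"value = {node.internal_value:.4g}"
            shape = "oval"
        else:
            label = f"{node.rule}\\ninternal_value = {node.internal_value:.4g}"
            shape = "oval" if node.is_leaf else "box"
        lines.append(f'  n{node.node_id} [shape={shape}, label="{label}"];')
        for child, branch in zip(node.children, ("yes", "no")):
            lines.append(f'  n{node.node_id} -> n{child.node_id} [label="{branch}"];')
    lines.append("}")
    return "\n".join(lines)
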