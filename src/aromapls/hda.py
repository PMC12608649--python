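"""Hierarchical OPLS discriminant analysis (OPLS-HDA).

Classes are merged agglomeratively using Cohen's d distances between the
cross-validated predictions of pairwise two-class OPLS-DA models; the merge
order, read top-down, gives a binary dendrogram.  Each internal node is then
refit as a left-vs-right OPLS-DA model with feature diagnostics, stringent
discriminant selection (VIPpred > 1.5, |p(corr)| > 0.6, jack-knife pass) and
optional CV-ANOVA/permutation validation.  A cross-validated confusion
matrix is obtained by routing every sample from the root to a leaf.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import opls


@dataclass
class CvConfig:
    """Cross-validation / modelling configuration shared by HDA stages."""

    n_folds: int = 7
    n_orth: int | str = "auto"   # "auto": add while Q² gains >= min_gain
    max_orth: int = 3
    min_gain: float = 0.01
    n_perm: int = 0              # permutations per node model (0 = skip)
    alpha: float = 0.05
    vip_min: float = 1.5
    pcorr_min: float = 0.6
    seed: int = 0


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled standard deviation.

    Groups with zero pooled spread return 0 when the means agree and a
    signed infinity sentinel when they do not (perfect separation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d needs at least 2 observations per group")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


def _binary_cv(
    X: np.ndarray,
    side: np.ndarray,
    cfg: CvConfig,
    seed: int,
) -> tuple[opls.OplsModel, opls.CvResult, np.ndarray, int]:
    """Fit + cross-validate a two-class OPLS-DA (left = −1, right = +1)."""
    y = np.where(side, 1.0, -1.0)
    if cfg.n_orth == "auto":
        n_orth = opls.choose_n_orth(
            X, y, cfg.n_folds, seed, stratify=side,
            max_orth=cfg.max_orth, min_gain=cfg.min_gain,
        )
    else:
        n_orth = int(cfg.n_orth)
    model = opls.fit_opls(X, y, n_orth)
    cv = opls.cross_validate(X, y, n_orth, cfg.n_folds, seed, stratify=side)
    return model, cv, y, n_orth


@dataclass
class ClassDistanceMatrix:
    groups: list[tuple[str, ...]]
    d: np.ndarray   # |Cohen's d|, symmetric, zero diagonal

    def as_frame(self) -> pd.DataFrame:
        labels = ["+".join(g) for g in self.groups]
        return pd.DataFrame(self.d, index=labels, columns=labels)


def _group_distance(
    X: np.ndarray,
    classes: np.ndarray,
    left: tuple[str, ...],
    right: tuple[str, ...],
    cfg: CvConfig,
) -> float:
    rows = np.isin(classes, left + right)
    side = np.isin(classes[rows], right)
    _, cv, _, _ = _binary_cv(X[rows], side, cfg, cfg.seed)
    return abs(cohens_d(cv.y_hat_cv[side], cv.y_hat_cv[~side]))


def class_distances(
    X: np.ndarray,
    classes,
    cfg: CvConfig | None = None,
    groups: list[tuple[str, ...]] | None = None,
) -> ClassDistanceMatrix:
    """Pairwise |Cohen's d| between cross-validated OPLS-DA predictions.

    Each pair of groups gets its own binary model; the distance is the
    absolute standardized difference between the two groups' cross-validated
    predicted responses.
    """
    cfg = cfg or CvConfig()
    classes = np.asarray(classes)
    if groups is None:
        groups = [(c,) for c in pd.unique(classes)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        n = int(np.isin(classes, g).sum())
        if n < 3:
            raise ValueError(f"group {g} has {n} samples; need >= 3")
    D = np.zeros((len(groups), len(groups)))
    for i, j in itertools.combinations(range(len(groups)), 2):
        D[i, j] = D[j, i] = _group_distance(X, classes, groups[i], groups[j], cfg)
    return ClassDistanceMatrix(list(groups), D)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

@dataclass
class HdaNode:
    """One binary split: a validated left-vs-right OPLS-DA model."""

    left_classes: tuple[str, ...]
    right_classes: tuple[str, ...]
    distance: float                      # cv |d| at merge
    left_child: "HdaNode | None" = None  # None = leaf (single class)
    right_child: "HdaNode | None" = None
    model: opls.OplsModel = None
    cv: opls.CvResult = None
    stats: opls.FeatureStats = None
    validation: opls.ValidationReport = None
    selected: list[dict] = field(default_factory=list)
    sample_idx: np.ndarray = None        # global row indices used by the model
    left_mean: float = 0.0               # cv-prediction group means (routing)
    right_mean: float = 0.0

    @property
    def classes(self) -> tuple[str, ...]:
        return self.left_classes + self.right_classes


@dataclass
class HdaTree:
    root: HdaNode
    nodes: list[HdaNode]        # top-down split order (root first)
    classes: list[str]
    feature_names: list[str] | None = None

    @property
    def n_splits(self) -> int:
        return len(self.nodes)


def build_tree(
    X: np.ndarray,
    classes,
    cfg: CvConfig | None = None,
    feature_names: list[str] | None = None,
) -> HdaTree:
    """Agglomerate classes by cross-validated distance and fit split models.

    At each step the two current groups with the smallest cross-validated
    |Cohen's d| are merged; distances to merged groups are recomputed with a
    fresh group-vs-group model rather than linkage-updated.  The reversed
    merge order gives the top-down binary splits; each is refit with feature
    diagnostics and the stringent discriminant selection rule.
    """
    cfg = cfg or CvConfig()
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    class_list = list(pd.unique(classes))
    if len(class_list) < 2:
        raise ValueError("need at least 2 classes")
    for c in class_list:
        if (classes == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")

    items: list[tuple[tuple[str, ...], HdaNode | None]] = [
        ((c,), None) for c in class_list
    ]
    cache: dict[frozenset, float] = {}
    merges: list[HdaNode] = []
    while len(items) > 1:
        best = None
        for (gi, _), (gj, _) in itertools.combinations(items, 2):
            key = frozenset((gi, gj))
            if key not in cache:
                cache[key] = _group_distance(X, classes, gi, gj, cfg)
            if best is None or cache[key] < best[0]:
                best = (cache[key], gi, gj)
        d, gi, gj = best
        ni = next(n for g, n in items if g == gi)
        nj = next(n for g, n in items if g == gj)
        node = HdaNode(gi, gj, d, ni, nj)
        items = [(g, n) for g, n in items if g not in (gi, gj)]
        items.append((gi + gj, node))
        merges.append(node)

    root = merges[-1]
    nodes = list(reversed(merges))  # top-down: root split first

    for k, node in enumerate(nodes):
        rows = np.flatnonzero(np.isin(classes, node.classes))
        side = np.isin(classes[rows], node.right_classes)
        seed = cfg.seed + 97 * k
        model, cv, y, n_orth = _binary_cv(X[rows], side, cfg, seed)
        stats = opls.feature_stats(model, cv, X[rows], y)
        node.model, node.cv, node.stats = model, cv, stats
        node.sample_idx = rows
        node.left_mean = float(cv.y_hat_cv[~side].mean())
        node.right_mean = float(cv.y_hat_cv[side].mean())
        node.validation = opls.validate_model(
            X[rows], y, n_orth, n_perm=cfg.n_perm, seed=seed,
            n_folds=cfg.n_folds, stratify=side, alpha=cfg.alpha,
        )
        selected = opls.select_features(stats, cfg.vip_min, cfg.pcorr_min)
        node.selected = []
        for j, sign in selected:
            # enriched side by group means of the variable itself; coding is
            # left = −1 / right = +1, so positive p(corr) should mean "right"
            mean_diff = X[rows][side, j].mean() - X[rows][~side, j].mean()
            enriched = "right" if mean_diff > 0 else "left"
            consistent = (sign > 0) == (mean_diff > 0)
            node.selected.append({
                "feature": j,
                "sign": sign,
                "enriched_in": enriched,
                "consistent": bool(consistent),
                "vip_pred": float(stats.vip_pred[j]),
                "p_corr": float(stats.p_corr[j]),
            })
    return HdaTree(root, nodes, class_list, feature_names)


# ---------------------------------------------------------------------------
# Confusion matrix by hierarchical routing
# ---------------------------------------------------------------------------

def _route(tree: HdaTree, i: int, x_row: np.ndarray) -> str:
    node = tree.root
    while True:
        if node.sample_idx is not None and i in node.sample_idx:
            y_hat = float(node.cv.y_hat_cv[np.flatnonzero(node.sample_idx == i)[0]])
        else:  # sample not in this node's training classes: model prediction
            y_hat = float(node.model.predict(x_row[None, :])[0])
        go_right = abs(y_hat - node.right_mean) < abs(y_hat - node.left_mean)
        child = node.right_child if go_right else node.left_child
        side = node.right_classes if go_right else node.left_classes
        if child is None:
            return side[0]
        node = child


def confusion_matrix(tree: HdaTree, X: np.ndarray, classes) -> pd.DataFrame:
    """Cross-validated confusion matrix from root-to-leaf routing.

    At each node a sample's cross-validated prediction (or the fitted
    model's prediction, if the sample does not belong to the node's class
    set) is compared with the two groups' mean cross-validated predictions;
    the nearer side is taken.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    labels = tree.classes
    cm = pd.DataFrame(0, index=labels, columns=labels)
    for i in range(X.shape[0]):
        pred = _route(tree, i, X[i])
        cm.loc[classes[i], pred] += 1
    return cm


def split_report(
    tree: HdaTree,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-split table of selected discriminants (one row per feature).

    ``enriched_in`` names the class group whose samples carry more of the
    feature; where the p(corr) sign disagrees with the group means (signal
    suppression), the row is flagged ``consistent=False`` but still reported
    by mean direction.
    """
    names = tree.feature_names
    rows = []
    for s, node in enumerate(tree.nodes, start=1):
        comparison = "+".join(node.left_classes) + " vs " + "+".join(node.right_classes)
        for sel in node.selected:
            j = sel["feature"]
            feat = names[j] if names else f"feature_{j}"
            group = (node.right_classes if sel["enriched_in"] == "right"
                     else node.left_classes)
            row = {
                "split": s,
                "comparison": comparison,
                "feature": feat,
                "enriched_in": "+".join(group),
                "vip_pred": sel["vip_pred"],
                "p_corr": sel["p_corr"],
                "jk_pass": True,
                "consistent": sel["consistent"],
            }
            if annotations is not None and feat in annotations.index:
                for col in annotations.columns:
                    row[col] = annotations.loc[feat, col]
            rows.append(row)
    return pd.DataFrame(rows)


def to_newick(tree: HdaTree) -> str:
    """Export the dendrogram as Newick text, branch lengths = merge |d|."""

    def fmt(d: float) -> str:
        return "Inf" if np.isinf(d) else f"{d:.4g}"

    def render(node: HdaNode | None, side: tuple[str, ...], d: float) -> str:
        if node is None:
            return f"{side[0]}:{fmt(d)}"
        inner = (render(node.left_child, node.left_classes, node.distance)
                 + ","
                 + render(node.right_child, node.right_classes, node.distance))
        return f"({inner}):{fmt(d)}"

    root = tree.root
    inner = (render(root.left_child, root.left_classes, root.distance)
             + ","
             + render(root.right_child, root.right_classes, root.distance))
    return f"({inner});"
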