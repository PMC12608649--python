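"""Synthetic GC-MS peak tables and hedonic sensory panels with known ground
truth.

The peak-table generator emulates an aligned, post-detection volatile table:
six variety classes with ten biological replicates each, a few hundred
features with log-normally distributed positive areas, blank injections, and
planted class-discriminant markers laid out along a known class hierarchy.
The sensory generator emulates a 55-judge hedonic panel (nine-point scale,
five attributes) with correlated latent attribute scores, judge main
effects, and planted reversed-scale judges.

Ground truth (marker placement, hierarchy, background features, outlier
judges) is returned alongside the data, never embedded in it, so recovery
can be verified downstream without leaking the answer into the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import PeakTable

# ---------------------------------------------------------------------------
# Class hierarchy helpers (nested 2-tuples; a str is a leaf)
# ---------------------------------------------------------------------------

#: Default 6-variety hierarchy: one singleton split, then a second singleton,
#: then a 2+2 partition resolved by two pairwise splits.
DEFAULT_CLASS_TREE = (
    "TulaMagic",
    ("GlenDee", (("Adelita", "HimboTop"), ("CascadeHarvest", "SanRafael"))),
)


def tree_leaves(tree) -> tuple[str, ...]:
    if isinstance(tree, str):
        return (tree,)
    left, right = tree
    return tree_leaves(left) + tree_leaves(right)


def tree_splits(tree) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Top-down list of (left classes, right classes) for each internal node."""
    if isinstance(tree, str):
        return []
    left, right = tree
    out = [(tree_leaves(left), tree_leaves(right))]
    return out + tree_splits(left) + tree_splits(right)


def _tree_depths(tree, depth=0) -> list[int]:
    if isinstance(tree, str):
        return []
    left, right = tree
    return [depth] + _tree_depths(left, depth + 1) + _tree_depths(right, depth + 1)


# ---------------------------------------------------------------------------
# Peak-table synthesis
# ---------------------------------------------------------------------------

@dataclass
class PeakSynthConfig:
    """Configuration of the synthetic peak-table generator.

    Areas are generated log-normally: each feature gets a log2 baseline
    drawn around ``baseline_mean``, planted markers add their log2 effect
    for samples of the listed classes, Gaussian noise with ``noise_sd``
    (log2 scale) is added, and the result is exponentiated.  Blank rows
    carry ``blank_fraction`` of the baseline signal except for the last
    ``n_background`` features, which appear in blanks at sample level so
    the blank filter has true positives to find.
    """

    n_classes: int = 6
    reps_per_class: int = 10
    n_features: int = 200
    n_blanks: int = 3
    planted_markers: list = field(default_factory=list)  # (idx, classes, log2 effect)
    replicate_factors: list = field(default_factory=list)  # (idxs, classes, log2 sd)
    class_tree: tuple = DEFAULT_CLASS_TREE
    noise_sd: float = 0.2
    baseline_mean: float = 14.0
    blank_fraction: float = 0.02
    n_background: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        leaves = tree_leaves(self.class_tree)
        if len(set(leaves)) != len(leaves):
            raise ValueError("class_tree leaves must be unique")
        if len(leaves) != self.n_classes:
            raise ValueError(
                f"class_tree has {len(leaves)} leaves but n_classes={self.n_classes}"
            )
        if self.reps_per_class < 3:
            raise ValueError("reps_per_class must be >= 3")
        if not (0 <= self.blank_fraction < 1):
            raise ValueError("blank_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_background < 0 or self.n_background >= self.n_features:
            raise ValueError("n_background must lie in [0, n_features)")
        bg_start = self.n_features - self.n_background
        for idx, classes, _ in self.planted_markers:
            if not (0 <= idx < self.n_features):
                raise ValueError(f"marker feature index {idx} out of range")
            if idx >= bg_start:
                raise ValueError(f"marker index {idx} collides with background features")
            unknown = set(classes) - set(leaves)
            if unknown:
                raise ValueError(f"marker classes {sorted(unknown)} not in class_tree")
        for idxs, classes, sd in self.replicate_factors:
            if sd < 0:
                raise ValueError("replicate factor sd must be non-negative")
            if any(not (0 <= i < self.n_features) for i in idxs):
                raise ValueError("replicate factor feature index out of range")
            unknown = set(classes) - set(leaves)
            if unknown:
                raise ValueError(
                    f"replicate factor classes {sorted(unknown)} not in class_tree"
                )

    @property
    def classes(self) -> tuple[str, ...]:
        return tree_leaves(self.class_tree)


def plant_hierarchy_markers(
    class_tree,
    n_features: int,
    markers_per_split: int = 3,
    height_extra_markers: int = 3,
    base_effect: float = 2.0,
    depth_boost: float = 1.0,
    marker_rep_sd: float = 0.15,
    rep_depth_scale: float = 1.55,
    start_feature: int = 0,
) -> tuple[list, list, dict]:
    """Lay out discriminant markers along a class hierarchy.

    Each internal split, top-down, receives a block of marker features
    enriched (positive log2 effect) in its left group.  Shallower splits
    carry more markers (``markers_per_split + height_extra_markers ×
    (max_depth − depth)``) with larger effects (``base_effect +
    depth_boost × (max_depth − depth)``): chemically distant branches
    differ in more volatiles, and more strongly, than close relatives.

    Each split's marker set also gets a coherent per-sample replicate
    factor (log2 sd ``marker_rep_sd × rep_depth_scale^depth``): individual
    berries vary in how strongly they express a volatile signature, so a
    signature's features move together within a class, and the signatures
    distinguishing close relatives vary more than those separating distant
    branches.  The standardized separation (effect over coherent spread)
    therefore grows with split height, which is what makes cross-validated
    Cohen's d distances order the merges the same way the planted tree
    does; without coherent within-class spread every split would be
    saturated and the distance ordering arbitrary.

    Returns the marker list, the replicate-factor list (both ready for
    :class:`PeakSynthConfig`) and a dict mapping each split
    ``(left, right)`` to its planted feature indices.
    """
    splits = tree_splits(class_tree)
    depths = _tree_depths(class_tree)
    max_depth = max(depths)
    markers, rep_factors, split_markers = [], [], {}
    f = start_feature
    for (left, right), depth in zip(splits, depths):
        height = max_depth - depth
        eff = base_effect + depth_boost * height
        m = markers_per_split + height_extra_markers * height
        idxs = list(range(f, f + m))
        f += m
        if f > n_features:
            raise ValueError("not enough features to plant all split markers")
        for idx in idxs:
            markers.append((idx, tuple(left), eff))
        if marker_rep_sd > 0:
            rep_factors.append(
                (tuple(idxs), tuple(left), marker_rep_sd * rep_depth_scale**depth)
            )
        split_markers[(tuple(left), tuple(right))] = idxs
    return markers, rep_factors, split_markers


def plant_flavor_markers(
    flavor_means: dict[str, float],
    n_positive: int = 3,
    n_negative: int = 4,
    start_feature: int = 0,
    scale: float = 1.0,
) -> tuple[list, dict]:
    """Plant features whose class profile is (anti-)collinear with flavor.

    Positive features get per-class log2 effects proportional to the
    centered class flavor mean; negative features get the reversed sign.
    Returns marker entries and a dict mapping feature index to its true
    contribution sign (+1 / −1).
    """
    classes = list(flavor_means)
    centered = {c: flavor_means[c] - np.mean(list(flavor_means.values()))
                for c in classes}
    markers, truth = [], {}
    f = start_feature
    for _ in range(n_positive):
        for c in classes:
            markers.append((f, (c,), scale * centered[c]))
        truth[f] = +1
        f += 1
    for _ in range(n_negative):
        for c in classes:
            markers.append((f, (c,), -scale * centered[c]))
        truth[f] = -1
        f += 1
    return markers, truth


def generate_peak_table(cfg: PeakSynthConfig) -> tuple[PeakTable, dict]:
    """Generate a peak table plus its ground-truth record (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    classes = cfg.classes
    n_samples = cfg.n_classes * cfg.reps_per_class
    feature_names = [f"F{j + 1:03d}" for j in range(cfg.n_features)]
    bg_start = cfg.n_features - cfg.n_background
    background = feature_names[bg_start:]

    baseline = rng.uniform(cfg.baseline_mean - 2, cfg.baseline_mean + 2,
                           cfg.n_features)
    effects = np.zeros((cfg.n_classes, cfg.n_features))
    for idx, marker_classes, eff in cfg.planted_markers:
        for c in marker_classes:
            effects[classes.index(c), idx] += eff

    rows, ids, cls, roles = [], [], [], []
    for ci, c in enumerate(classes):
        log2 = (baseline + effects[ci]
                + rng.normal(0, cfg.noise_sd, (cfg.reps_per_class, cfg.n_features)))
        for idxs, factor_classes, sd in cfg.replicate_factors:
            if c in factor_classes:
                delta = rng.normal(0, sd, cfg.reps_per_class)
                log2[:, list(idxs)] += delta[:, None]
        rows.append(np.exp2(log2))
        ids += [f"{c}_r{r + 1:02d}" for r in range(cfg.reps_per_class)]
        cls += [c] * cfg.reps_per_class
        roles += ["sample"] * cfg.reps_per_class

    blank_log2 = np.where(
        np.arange(cfg.n_features) < bg_start,
        baseline + (np.log2(cfg.blank_fraction) if cfg.blank_fraction > 0 else -np.inf),
        baseline,  # background features carry sample-level signal in blanks
    )
    for bi in range(cfg.n_blanks):
        noise = rng.normal(0, cfg.noise_sd / 2, cfg.n_features)
        rows.append(np.exp2(blank_log2 + noise))
        ids.append(f"blank_{bi + 1:02d}")
        cls.append("blank")
        roles.append("blank")

    areas = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                         columns=feature_names)
    table = PeakTable(areas, pd.Series(cls, index=areas.index, name="class"),
                      pd.Series(roles, index=areas.index, name="role"))
    assert table.areas.iloc[:n_samples].gt(0).all().all()
    truth = {
        "planted_markers": [
            (feature_names[i], tuple(cs), e) for i, cs, e in cfg.planted_markers
        ],
        "class_tree": cfg.class_tree,
        "background_features": background,
        "baseline_log2": baseline,
        "noise_sd": cfg.noise_sd,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Sensory-panel synthesis
# ---------------------------------------------------------------------------

DEFAULT_VARIETIES = tree_leaves(DEFAULT_CLASS_TREE)
DEFAULT_ATTRIBUTES = ("appearance", "color", "flavor", "taste", "overall")

#: Variety × attribute hedonic means (1-9 scale) emulating a panel where
#: flavor and taste track overall acceptability while color does not, one
#: variety leads on eating quality and another on visual appeal.
DEFAULT_VARIETY_MEANS = pd.DataFrame(
    [
        [6.8, 5.9, 7.8, 7.5, 7.6],   # TulaMagic: best flavor/taste/overall
        [7.0, 7.4, 6.2, 6.3, 6.5],   # GlenDee: visual, weaker taste
        [6.4, 6.3, 6.0, 6.1, 6.2],   # Adelita: uniformly lower
        [6.3, 6.0, 6.1, 6.2, 6.2],   # HimboTop: uniformly lower
        [7.1, 7.6, 6.5, 6.4, 6.6],   # CascadeHarvest: best color
        [6.9, 6.8, 6.8, 6.7, 6.9],   # SanRafael: consistent middle
    ],
    index=list(DEFAULT_VARIETIES),
    columns=list(DEFAULT_ATTRIBUTES),
)

#: Moderate positive inter-attribute correlations: visual attributes pair
#: up, taste-related attributes pair up, weaker cross-block correlation.
DEFAULT_ATTRIBUTE_CORR = pd.DataFrame(
    [
        [1.00, 0.60, 0.30, 0.30, 0.30],
        [0.60, 1.00, 0.30, 0.30, 0.30],
        [0.30, 0.30, 1.00, 0.60, 0.60],
        [0.30, 0.30, 0.60, 1.00, 0.65],
        [0.30, 0.30, 0.60, 0.65, 1.00],
    ],
    index=list(DEFAULT_ATTRIBUTES),
    columns=list(DEFAULT_ATTRIBUTES),
)


@dataclass
class SensorySynthConfig:
    """Configuration of the synthetic hedonic panel generator.

    Latent scores are multivariate normal per judge × variety: variety mean
    plus a judge main effect (sd ``judge_sd``) plus correlated attribute
    noise (sd ``noise_sd``, correlation ``attribute_corr``), rounded and
    then clamped to the integer 1-9 scale.  Planted outlier judges use the
    scale in reverse (score ↦ 10 − score).
    """

    n_judges: int = 55
    varieties: tuple = DEFAULT_VARIETIES
    attributes: tuple = DEFAULT_ATTRIBUTES
    variety_means: pd.DataFrame = None
    judge_sd: float = 0.8
    noise_sd: float = 1.0
    n_outlier_judges: int = 0
    attribute_corr: pd.DataFrame = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variety_means is None:
            self.variety_means = DEFAULT_VARIETY_MEANS.loc[
                list(self.varieties), list(self.attributes)
            ]
        if self.attribute_corr is None:
            self.attribute_corr = DEFAULT_ATTRIBUTE_CORR.loc[
                list(self.attributes), list(self.attributes)
            ]
        M = np.asarray(self.variety_means, dtype=float)
        if M.shape != (len(self.varieties), len(self.attributes)):
            raise ValueError("variety_means must be varieties × attributes")
        if (M < 1).any() or (M > 9).any():
            raise ValueError("variety_means entries must lie in [1, 9]")
        C = np.asarray(self.attribute_corr, dtype=float)
        if C.shape != (len(self.attributes),) * 2 or not np.allclose(C, C.T):
            raise ValueError("attribute_corr must be square and symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("attribute_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("attribute_corr must be positive semi-definite")
        if self.n_outlier_judges >= self.n_judges:
            raise ValueError("n_outlier_judges must be < n_judges")


def generate_sensory_panel(cfg: SensorySynthConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format ratings table plus its ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    judges = [f"J{j + 1:02d}" for j in range(cfg.n_judges)]
    outliers = sorted(rng.choice(judges, cfg.n_outlier_judges, replace=False))

    C = np.asarray(cfg.attribute_corr, dtype=float)
    vals, vecs = np.linalg.eigh(C)
    L = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    M = np.asarray(cfg.variety_means, dtype=float)
    offsets = rng.normal(0, cfg.judge_sd, cfg.n_judges)

    rows = []
    for j, judge in enumerate(judges):
        for v, variety in enumerate(cfg.varieties):
            z = rng.standard_normal(len(cfg.attributes))
            latent = M[v] + offsets[j] + cfg.noise_sd * (L @ z)
            score = np.clip(np.round(latent), 1, 9).astype(int)
            if judge in outliers:
                score = 10 - score
            for a, attribute in enumerate(cfg.attributes):
                rows.append((judge, variety, attribute, int(score[a])))
    ratings = pd.DataFrame(rows, columns=["judge", "variety", "attribute", "score"])
    truth = {
        "outlier_judges": outliers,
        "variety_means": cfg.variety_means,
        "attribute_corr": cfg.attribute_corr,
        "judge_offsets": dict(zip(judges, offsets)),
    }
    return ratings, truth


def write_ground_truth(truth: dict, path) -> None:
    """Persist a ground-truth record as a plain-text key-value file."""
    with open(path, "w") as fh:
        for key, value in truth.items():
            if isinstance(value, pd.DataFrame):
                value = value.to_dict()
            elif isinstance(value, np.ndarray):
                value = value.tolist()
            fh.write(f"{key}\t{json.dumps(value, default=str)}\n")
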