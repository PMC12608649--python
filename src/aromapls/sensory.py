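"""Hedonic sensory panel statistics: judge screening, Tukey-fence outlier
removal, attribute summaries with ANOVA/Tukey HSD, and two-level Spearman
correlation analysis.

Ratings are long-format rows ``(judge, variety, attribute, score)`` on the
nine-point hedonic scale (1 = dislike extremely ... 9 = like extremely).
Panel screening is two-step: first whole judges are removed as global
outliers (Hotelling T² on a 2-component PCA of the judge × product score
matrix — a reproducible surrogate for visual score-plot inspection), then
individual scores outside the Tukey fences within each variety × attribute
cell are removed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

RATING_COLS = ("judge", "variety", "attribute", "score")
DEFAULT_ATTRIBUTES = ("appearance", "color", "flavor", "taste", "overall")


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLS if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table lacks column(s) {missing}")
    s = ratings["score"]
    if len(s):
        if s.isna().any():
            raise ValueError("ratings contain missing scores")
        if not np.allclose(s.astype(float), np.round(s.astype(float))):
            raise ValueError("scores must be integers on the 1-9 hedonic scale")
        if (s < 1).any() or (s > 9).any():
            raise ValueError("scores must lie in [1, 9]")
    keys = ratings[["judge", "variety", "attribute"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (judge, variety, attribute) rating")
    return ratings


def read_ratings(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Judge screening
# ---------------------------------------------------------------------------

@dataclass
class PanelScreenResult:
    removed_judges: list[str]
    scores_matrix: pd.DataFrame   # judges × (variety, attribute)
    t2: pd.Series                 # Hotelling T² per judge
    t2_cutoff: float
    component_count: int
    n_imputed: int


def _pca_t2(W: pd.DataFrame, n_components: int) -> tuple[pd.Series, float, int]:
    """Hotelling T² of each row on the first PCA components, with F cutoff."""
    n = W.shape[0]
    Xc = W.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    A = min(n_components, int(np.sum(s > 1e-10)))
    if A == 0:
        return pd.Series(0.0, index=W.index), float("inf"), 0
    T = U[:, :A] * s[:A]
    lam = T.var(axis=0, ddof=1)
    t2 = pd.Series((T**2 / lam).sum(axis=1), index=W.index)
    return t2, float(A * (n - 1) / (n - A)), A


def screen_judges(
    ratings: pd.DataFrame,
    n_components: int = 2,
    alpha: float = 0.05,
) -> PanelScreenResult:
    """Flag globally inconsistent judges via Hotelling T² on PCA scores.

    The judge × (variety·attribute) matrix is mean-centered by column and
    decomposed by SVD; a judge whose T² over the first ``n_components``
    scores exceeds the F-based (1−alpha) cutoff is flagged.  Removal is
    sequential — the most extreme judge is removed and the PCA recomputed
    until no judge exceeds the cutoff — because a group of aberrant judges
    inflates the component variances and masks its own members under a
    single-pass rule.  Missing cells are imputed with the column
    (variety × attribute) mean and counted.
    """
    validate_ratings(ratings)
    wide = ratings.pivot_table(
        index="judge", columns=["variety", "attribute"], values="score"
    )
    n_imputed = int(wide.isna().sum().sum())
    if n_imputed:
        wide = wide.fillna(wide.mean(axis=0))
    if wide.shape[0] < n_components + 2:
        raise ValueError("need at least n_components + 2 judges")

    if np.allclose(wide.to_numpy() - wide.to_numpy().mean(axis=0), 0):
        warnings.warn("all judges identical; no variance to screen", stacklevel=2)
        t2 = pd.Series(0.0, index=wide.index)
        return PanelScreenResult([], wide, t2, float("inf"), n_components, n_imputed)

    t2_full, factor, A = _pca_t2(wide, n_components)
    n = wide.shape[0]
    cutoff_full = factor * stats.f.ppf(1 - alpha, A, n - A)

    removed: list[str] = []
    while wide.shape[0] - len(removed) >= n_components + 2:
        W = wide.drop(index=removed)
        t2, factor, A = _pca_t2(W, n_components)
        if A == 0:
            break
        n = W.shape[0]
        cutoff = factor * stats.f.ppf(1 - alpha, A, n - A)
        worst = t2.idxmax()
        if t2[worst] <= cutoff:
            break
        removed.append(worst)
    return PanelScreenResult(
        sorted(removed), wide, t2_full, float(cutoff_full), A, n_imputed
    )


def drop_judges(ratings: pd.DataFrame, judges) -> pd.DataFrame:
    return ratings[~ratings["judge"].isin(set(judges))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tukey-fence outlier removal
# ---------------------------------------------------------------------------

def iqr_filter(
    ratings: pd.DataFrame, k: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove scores outside Tukey's fences within each variety × attribute.

    Quartiles use linear interpolation between order statistics; a score
    below ``Q1 − k·IQR`` or above ``Q3 + k·IQR`` is removed.  Returns the
    surviving rows and a report of the removals.
    """
    validate_ratings(ratings)
    if ratings.empty:
        raise ValueError("empty ratings table")
    ratings = ratings.reset_index(drop=True)
    keep_mask = np.ones(len(ratings), dtype=bool)
    removed = []
    for (variety, attribute), grp in ratings.groupby(["variety", "attribute"]):
        if not np.isfinite(k):
            continue
        q1, q3 = np.percentile(grp["score"], [25, 75])
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        out = (grp["score"] < lo) | (grp["score"] > hi)
        keep_mask[grp.index[out]] = False
        for _, row in grp[out].iterrows():
            removed.append(
                {"judge": row["judge"], "variety": variety,
                 "attribute": attribute, "score": row["score"],
                 "low_fence": lo, "high_fence": hi}
            )
    report = pd.DataFrame(
        removed,
        columns=["judge", "variety", "attribute", "score", "low_fence", "high_fence"],
    )
    return ratings[keep_mask].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Spearman correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    level: str
    attributes: list[str]
    rho: pd.DataFrame
    undefined: list[str]   # constant attributes with no defined correlation


def attribute_correlations(ratings: pd.DataFrame, level: str) -> CorrelationMatrix:
    """Spearman ρ between attributes at the judge or variety level.

    ``level='judge'`` correlates each judge's mean rating across varieties
    (intra-judge consistency); ``level='variety'`` correlates variety mean
    scores (inter-attribute co-variation across products).  Ties take
    average ranks.  Constant attributes are reported as undefined (NaN row
    and column), never silently zero.
    """
    validate_ratings(ratings)
    if level not in ("judge", "variety"):
        raise ValueError("level must be 'judge' or 'variety'")
    unit = "judge" if level == "judge" else "variety"
    means = ratings.groupby([unit, "attribute"])["score"].mean().unstack("attribute")
    if means.shape[0] < 3:
        raise ValueError(f"need at least 3 {unit}s for correlations")
    attrs = list(means.columns)
    constant = [a for a in attrs if means[a].nunique() <= 1]
    rho = pd.DataFrame(np.nan, index=attrs, columns=attrs)
    for a, b in itertools.combinations_with_replacement(attrs, 2):
        if a in constant or b in constant:
            continue
        if a == b:
            rho.loc[a, a] = 1.0
        else:
            r = stats.spearmanr(means[a], means[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = r
    for a in constant:
        rho.loc[a, a] = 1.0
    if constant:
        warnings.warn(f"constant attribute(s) {constant}: ρ undefined", stacklevel=2)
    return CorrelationMatrix(level, attrs, rho, constant)


def leave_one_variety_out(ratings: pd.DataFrame) -> pd.DataFrame:
    """Robustness check: variety-level ρ recomputed dropping each variety.

    Returns one row per (dropped variety, attribute pair) with the ρ on the
    reduced panel and a flag where its sign differs from the full-panel ρ.
    """
    full = attribute_correlations(ratings, "variety").rho
    rows = []
    for v in ratings["variety"].unique():
        sub = ratings[ratings["variety"] != v]
        if sub["variety"].nunique() < 3:
            continue
        rho = attribute_correlations(sub, "variety").rho
        for a, b in itertools.combinations(rho.columns, 2):
            r_full, r_sub = full.loc[a, b], rho.loc[a, b]
            rows.append({
                "dropped_variety": v, "attr_a": a, "attr_b": b,
                "rho": r_sub, "rho_full": r_full,
                "sign_flip": bool(np.sign(r_sub) * np.sign(r_full) < 0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Attribute summaries: ANOVA + Tukey HSD with letter display
# ---------------------------------------------------------------------------

def _compact_letters(groups: list[str], ns_pairs: set[frozenset]) -> dict[str, str]:
    # maximal cliques of the "not significantly different" graph, brute force
    # (group counts here are single digits)
    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            if all(frozenset(p) in ns_pairs for p in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    letters = {g: "" for g in groups}
    for i, cl in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in cl:
            letters[g] += ch
    return letters


@dataclass
class AttributeSummary:
    means: pd.DataFrame   # variety, attribute, n, mean, sd, letters
    anova: pd.DataFrame   # attribute, F, p
    excluded: list[tuple[str, str]]


def summarize_attributes(ratings: pd.DataFrame, alpha: float = 0.05) -> AttributeSummary:
    """Per-attribute one-way ANOVA across varieties with Tukey HSD letters.

    Varieties sharing a letter within an attribute are not significantly
    different at ``alpha``.  Varieties with fewer than 2 ratings for an
    attribute are excluded from that attribute's test with a warning.
    """
    validate_ratings(ratings)
    mean_rows, anova_rows, excluded = [], [], []
    for attribute, grp in ratings.groupby("attribute"):
        counts = grp.groupby("variety")["score"].size()
        small = counts[counts < 2].index.tolist()
        for v in small:
            excluded.append((v, attribute))
            warnings.warn(
                f"variety {v!r} has <2 ratings for {attribute!r}; excluded",
                stacklevel=2,
            )
        grp = grp[~grp["variety"].isin(small)]
        varieties = sorted(grp["variety"].unique())
        if len(varieties) < 2:
            raise ValueError(f"attribute {attribute!r}: fewer than 2 varieties")
        samples = [grp.loc[grp["variety"] == v, "score"].to_numpy() for v in varieties]
        F, p = stats.f_oneway(*samples)
        anova_rows.append({"attribute": attribute, "F": float(F), "p": float(p)})

        if np.ptp(np.concatenate(samples)) == 0:
            ns_pairs = {frozenset(p_) for p_ in itertools.combinations(varieties, 2)}
        else:
            hsd = pairwise_tukeyhsd(
                grp["score"].to_numpy(), grp["variety"].to_numpy(), alpha=alpha
            )
            res = pd.DataFrame(
                hsd.summary().data[1:], columns=hsd.summary().data[0]
            )
            ns_pairs = {
                frozenset((r["group1"], r["group2"]))
                for _, r in res.iterrows() if not r["reject"]
            }
        letters = _compact_letters(varieties, ns_pairs)
        for v, x in zip(varieties, samples):
            mean_rows.append({
                "variety": v, "attribute": attribute, "n": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
                "letters": letters[v],
            })
    return AttributeSummary(pd.DataFrame(mean_rows), pd.DataFrame(anova_rows), excluded)


def variety_attribute_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Variety × attribute mean-score matrix (post-screening panel means)."""
    validate_ratings(ratings)
    return ratings.groupby(["variety", "attribute"])["score"].mean().unstack("attribute")
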