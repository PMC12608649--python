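"""OPLS regression of mean flavor scores on the volatile matrix.

The panel's mean flavor rating per variety is used as the response: every
replicate of a variety shares that variety's mean score (the default), or
optionally the matrix is collapsed to one averaged row per variety.  The
fitted model is cross-validated, validated by CV-ANOVA and permutation
testing, and features passing VIPpred > 1 and |p(corr)| > 0.5 with a
jack-knife interval excluding zero are reported as positive or negative
flavor contributors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import opls
from .peaks import ScaledMatrix


@dataclass
class FlavorModelResult:
    model: opls.OplsModel
    cv: opls.CvResult
    stats: opls.FeatureStats
    validation: opls.ValidationReport
    contributors: pd.DataFrame
    y: np.ndarray
    n_orth: int
    q2_optimistic: bool


def fit_flavor_opls(
    X: ScaledMatrix | np.ndarray,
    flavor_means: Mapping[str, float],
    classes=None,
    n_orth: int | str = "auto",
    n_folds: int = 7,
    seed: int = 0,
    n_perm: int = 200,
    vip_min: float = 1.0,
    pcorr_min: float = 0.5,
    per_class_x: bool = False,
    alpha: float = 0.05,
    feature_names: list[str] | None = None,
    max_orth: int = 5,
) -> FlavorModelResult:
    """Fit, cross-validate and validate the flavor OPLS model.

    Parameters
    ----------
    X
        Scaled matrix (a :class:`~aromapls.peaks.ScaledMatrix`, which carries
        its own class labels and feature names, or a plain array with
        ``classes`` given).
    flavor_means
        Mean flavor score per class, typically from
        :func:`aromapls.sensory.variety_attribute_means`.
    per_class_x
        If True, average the rows of each class and regress the class-mean
        matrix on the class means (one row per class, leave-one-out CV)
        instead of replicating the response per sample.
    """
    if isinstance(X, ScaledMatrix):
        feature_names = X.features
        classes = X.classes.to_numpy()
        X = X.X
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    missing = set(classes) - set(flavor_means)
    if missing:
        raise ValueError(f"no flavor mean for class(es) {sorted(missing)}")

    if per_class_x:
        labels = list(pd.unique(classes))
        X = np.vstack([X[classes == c].mean(axis=0) for c in labels])
        y = np.array([float(flavor_means[c]) for c in labels])
        stratify = None
        n_folds = X.shape[0]  # leave-one-out on the class-mean rows
    else:
        y = np.array([float(flavor_means[c]) for c in classes])
        stratify = classes

    if np.ptp(y) == 0:
        raise ValueError("flavor means are all equal; no response variance")
    q2_optimistic = np.unique(y).size < y.size / 2
    if q2_optimistic:
        warnings.warn(
            "response has few distinct values (class-replicated scores); "
            "Q² is optimistic relative to sample-level noise",
            stacklevel=2,
        )

    if n_orth == "auto":
        n_orth = opls.choose_n_orth(
            X, y, n_folds, seed, stratify=stratify, max_orth=max_orth
        )
    model = opls.fit_opls(X, y, int(n_orth))
    cv = opls.cross_validate(X, y, int(n_orth), n_folds, seed, stratify)
    stats = opls.feature_stats(model, cv, X, y)
    validation = opls.validate_model(
        X, y, int(n_orth), n_perm=n_perm, seed=seed,
        n_folds=n_folds, stratify=stratify, alpha=alpha,
    )
    selected = dict(opls.select_features(stats, vip_min, pcorr_min))
    names = feature_names or [f"feature_{j}" for j in range(X.shape[1])]
    contributors = pd.DataFrame({
        "feature": names,
        "vip_pred": stats.vip_pred,
        "p_corr": stats.p_corr,
        "ci_low": stats.ci_low,
        "ci_high": stats.ci_high,
        "jk_pass": stats.jk_pass,
        "selected": [j in selected for j in range(X.shape[1])],
        "sign": [
            ("positive" if selected[j] > 0 else "negative") if j in selected else ""
            for j in range(X.shape[1])
        ],
    })
    return FlavorModelResult(
        model, cv, stats, validation, contributors, y, int(n_orth), q2_optimistic
    )
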