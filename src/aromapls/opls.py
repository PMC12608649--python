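"""Core OPLS engine: NIPALS PLS1, orthogonal filtering, cross-validation,
VIP/p(corr) diagnostics, jack-knifed coefficient intervals, CV-ANOVA and
permutation testing.

The model here is orthogonal projections to latent structures (OPLS) for a
single response: X-variation is split into one y-predictive component and
``n_orth`` components orthogonal to y (Trygg-Wold filtering).  Fitting a
model with zero orthogonal components reduces exactly to single-component
NIPALS PLS1.

All fitting functions accept the matrix on whatever scale the caller chose
(typically Pareto-scaled peak areas); columns and the response are centered
internally with the training means, which makes the same code usable for
per-fold refits during cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_EPS = 1e-12


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class Pls1Model:
    """Multi-component NIPALS PLS1 fit for a single response.

    Attributes
    ----------
    weights, loadings : (K, A) arrays of per-component weight/loading vectors.
    scores : (n, A) array of training scores.
    q : (A,) inner regression coefficients.
    b : (K,) regression coefficients on the (centered) input variables.
    x_center, y_center : training means used for centering.
    r2y : fraction of response variance explained on the training data.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    q: np.ndarray
    b: np.ndarray
    x_center: np.ndarray
    y_center: float
    r2y: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_center) @ self.b + self.y_center


def fit_pls1(X: np.ndarray, y: np.ndarray, n_comp: int) -> Pls1Model:
    """Fit ``n_comp`` NIPALS PLS1 components of y on X.

    For a single response NIPALS needs no inner iteration: each component's
    weight vector is the unit-normalized covariance ``X'y``, followed by the
    usual score/loading extraction and deflation of both blocks.

    Raises
    ------
    ValueError
        If y is constant, or ``n_comp`` exceeds the rank of X (detected as a
        vanishing weight or score norm during extraction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    n, K = X.shape
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xd = X - x_center
    yd = y - y_center
    ss_y = float(yd @ yd)
    if ss_y < _EPS:
        raise ValueError("response y is constant; nothing to fit")
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")

    W = np.empty((K, n_comp))
    P = np.empty((K, n_comp))
    T = np.empty((n, n_comp))
    q = np.empty(n_comp)
    yres = yd.copy()
    for a in range(n_comp):
        w = Xd.T @ yres
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError(
                f"n_comp={n_comp} exceeds the predictive rank of X "
                f"(component {a + 1} has zero weight)"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ValueError(
                f"n_comp={n_comp} exceeds the rank of X (zero score norm)"
            )
        p = Xd.T @ t / tt
        q[a] = float(yres @ t) / tt
        Xd = Xd - np.outer(t, p)
        yres = yres - q[a] * t
        W[:, a], P[:, a], T[:, a] = w, p, t

    # b maps centered X to centered predictions: b = W (P'W)^-1 q
    b = W @ np.linalg.solve(P.T @ W, q)
    r2y = 1.0 - float(yres @ yres) / ss_y
    return Pls1Model(W, P, T, q, b, x_center, y_center, r2y)


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted OPLS model: one predictive plus ``n_orth`` orthogonal components.

    ``w_pred`` is unit norm; every orthogonal score vector is orthogonal to
    the centered response.  ``b`` collapses the whole pipeline (orthogonal
    filtering followed by the predictive component) into a single coefficient
    vector on the centered input variables.
    """

    w_pred: np.ndarray
    t_pred: np.ndarray
    p_pred: np.ndarray
    q: float
    w_orth: np.ndarray   # (K, n_orth)
    t_orth: np.ndarray   # (n, n_orth)
    p_orth: np.ndarray   # (K, n_orth)
    b: np.ndarray
    n_orth: int
    r2y: float
    x_center: np.ndarray
    y_center: float

    def filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        """Remove the model's orthogonal variation from new (raw-scale) rows."""
        Xc = np.asarray(X, dtype=float) - self.x_center
        for k in range(self.n_orth):
            t_o = Xc @ self.w_orth[:, k]
            Xc = Xc - np.outer(t_o, self.p_orth[:, k])
        return Xc

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xf = self.filter_orthogonal(np.atleast_2d(np.asarray(X, dtype=float)))
        return Xf @ self.w_pred * self.q + self.y_center


def fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int) -> OplsModel:
    """Fit an OPLS model with ``n_orth`` orthogonal components.

    Orthogonal filtering follows the canonical formulation: with
    ``w ∝ X'y`` (unit norm), each round computes the loading
    ``p = X't/t't`` of the predictive score, strips its y-predictive part
    ``w_orth = p − (w'p)w``, extracts the orthogonal score
    ``t_orth = X w_orth`` and deflates ``X ← X − t_orth p_orth'``.  A single
    predictive PLS component is then fitted on the filtered matrix.

    If no orthogonal variation remains (``‖w_orth‖ < 1e-12``) extraction stops
    early with a warning and the model carries fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    n, K = X.shape
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xd = X - x_center
    yc = y - y_center
    ss_y = float(yc @ yc)
    if ss_y < _EPS:
        raise ValueError("response y is constant; nothing to fit")

    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError("X carries no covariance with y")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < _EPS:
            warnings.warn(
                "no orthogonal variation left; stopping at "
                f"{len(W_o)} orthogonal component(s)",
                stacklevel=2,
            )
            break
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    n_o = len(W_o)
    w_orth = np.column_stack(W_o) if n_o else np.empty((K, 0))
    t_orth = np.column_stack(T_o) if n_o else np.empty((n, 0))
    p_orth = np.column_stack(P_o) if n_o else np.empty((K, 0))

    # predictive component on the filtered matrix
    w_pred = Xd.T @ yc
    nw = np.linalg.norm(w_pred)
    if nw < _EPS:
        raise ValueError("filtered X carries no covariance with y")
    w_pred /= nw
    t_pred = Xd @ w_pred
    tt = float(t_pred @ t_pred)
    p_pred = Xd.T @ t_pred / tt
    q = float(yc @ t_pred) / tt

    # collapse filtering + prediction into one coefficient vector
    v = w_pred.copy()
    for k in reversed(range(n_o)):
        v = v - w_orth[:, k] * float(p_orth[:, k] @ v)
    b = q * v

    resid = yc - q * t_pred
    r2y = 1.0 - float(resid @ resid) / ss_y
    return OplsModel(
        w_pred, t_pred, p_pred, q, w_orth, t_orth, p_orth, b,
        n_o, r2y, x_center, y_center,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Cross-validated predictions and per-fold loadings.

    Every sample is predicted exactly once, by the fold model that did not
    see it.  ``q2 = 1 − PRESS/SS_tot`` with SS_tot the total (centered)
    response sum of squares.  Per-fold predictive weights are sign-aligned to
    the full model's ``w_pred`` so they can be pooled for jack-knifing.
    """

    y_hat_cv: np.ndarray
    press: float
    ss_total: float
    q2: float
    folds: np.ndarray
    fold_w_pred: np.ndarray  # (n_folds, K), sign-aligned
    fold_b: np.ndarray       # (n_folds, K)
    seed: int
    n_folds: int


def assign_folds(
    n: int,
    n_folds: int,
    seed: int,
    stratify: np.ndarray | None = None,
) -> np.ndarray:
    """Seeded ordered-interleaved ('venetian blind') fold assignment.

    With ``stratify`` the interleaving runs within each stratum so every fold
    receives a proportional share of each class.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError("n_folds cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratify is None:
        order = rng.permutation(n)
        folds[order] = np.arange(n) % n_folds
    else:
        stratify = np.asarray(stratify)
        for lev in np.unique(stratify):
            idx = np.flatnonzero(stratify == lev)
            idx = rng.permutation(idx)
            folds[idx] = np.arange(idx.size) % n_folds
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int,
    n_folds: int = 7,
    seed: int = 0,
    stratify: np.ndarray | None = None,
) -> CvResult:
    """K-fold cross-validation of an OPLS model with fixed component structure.

    Each fold refits the model (including re-centering with the training
    means) and predicts the held-out rows.  With ``stratify`` given (class
    labels for discriminant use), a fold whose training set would lose an
    entire level raises a stratification error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, K = X.shape
    folds = assign_folds(n, n_folds, seed, stratify)

    if stratify is not None:
        stratify = np.asarray(stratify)
        levels = np.unique(stratify)
        for f in range(n_folds):
            train_levels = np.unique(stratify[folds != f])
            if train_levels.size < levels.size:
                raise ValueError(
                    f"stratification error: fold {f} removes an entire level "
                    "from the training set"
                )

    full = fit_opls(X, y, n_orth)
    y_hat = np.empty(n)
    fold_w = np.empty((n_folds, K))
    fold_b = np.empty((n_folds, K))
    for f in range(n_folds):
        test = folds == f
        m = fit_opls(X[~test], y[~test], n_orth)
        y_hat[test] = m.predict(X[test])
        sign = 1.0 if float(m.w_pred @ full.w_pred) >= 0 else -1.0
        fold_w[f] = sign * m.w_pred
        fold_b[f] = m.b

    press = float(np.sum((y - y_hat) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_total
    return CvResult(y_hat, press, ss_total, q2, folds, fold_w, fold_b, seed, n_folds)


def choose_n_orth(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 7,
    seed: int = 0,
    stratify: np.ndarray | None = None,
    max_orth: int = 5,
    min_gain: float = 0.01,
) -> int:
    """Auto rule for the orthogonal component count: keep adding while the
    cross-validated Q² improves by at least ``min_gain``."""
    best_q2 = cross_validate(X, y, 0, n_folds, seed, stratify).q2
    n_orth = 0
    for k in range(1, max_orth + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                q2 = cross_validate(X, y, k, n_folds, seed, stratify).q2
        except ValueError:
            break
        if q2 - best_q2 >= min_gain:
            best_q2, n_orth = q2, k
        else:
            break
    return n_orth


# ---------------------------------------------------------------------------
# Feature diagnostics
# ---------------------------------------------------------------------------

@dataclass
class FeatureStats:
    """Per-feature diagnostics of a fitted + cross-validated OPLS model.

    vip_pred
        Variable importance on the predictive component only,
        ``sqrt(K)·|w_pred|``; its squared values average to 1.
    p_corr
        Pearson correlation between the predictive score vector and each
        variable (NaN for zero-variance variables, which are flagged in
        ``undefined`` and never selectable).
    ci_low, ci_high
        Jack-knifed 95% confidence interval of the regression coefficient,
        pooled over cross-validation folds (Martens' formulation with a
        t-quantile at ``n_folds − 1`` degrees of freedom).
    jk_pass
        True where the interval excludes zero.
    """

    vip_pred: np.ndarray
    p_corr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    jk_pass: np.ndarray
    undefined: np.ndarray = field(default=None)


def feature_stats(
    model: OplsModel,
    cv: CvResult,
    X: np.ndarray,
    y: np.ndarray,
    ci_level: float = 0.95,
) -> FeatureStats:
    X = np.asarray(X, dtype=float)
    K = X.shape[1]
    vip = np.sqrt(K) * np.abs(model.w_pred)

    t = model.t_pred - model.t_pred.mean()
    Xc = X - X.mean(axis=0)
    col_ss = np.sqrt(np.sum(Xc**2, axis=0))
    t_ss = np.sqrt(float(t @ t))
    undefined = col_ss < _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        p_corr = (Xc.T @ t) / (col_ss * t_ss)
    p_corr[undefined] = np.nan
    p_corr = np.clip(p_corr, -1.0, 1.0, out=p_corr)

    G = cv.n_folds
    b_bar = cv.fold_b.mean(axis=0)
    se = np.sqrt((G - 1) / G * np.sum((cv.fold_b - b_bar) ** 2, axis=0))
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df=G - 1)
    ci_low = model.b - tq * se
    ci_high = model.b + tq * se
    jk_pass = (ci_low > 0) | (ci_high < 0)
    jk_pass[undefined] = False
    return FeatureStats(vip, p_corr, ci_low, ci_high, jk_pass, undefined)


def select_features(
    stats_: FeatureStats,
    vip_min: float,
    pcorr_min: float,
) -> list[tuple[int, int]]:
    """Apply the VIP / p(corr) / jack-knife selection rule.

    A feature is selected iff ``vip_pred > vip_min`` and
    ``|p_corr| > pcorr_min`` and its jack-knife interval excludes zero.
    Returns ``(feature index, sign)`` pairs, the sign taken from p(corr).
    """
    with np.errstate(invalid="ignore"):
        keep = (
            (stats_.vip_pred > vip_min)
            & (np.abs(stats_.p_corr) > pcorr_min)
            & stats_.jk_pass
        )
    keep &= ~np.isnan(stats_.p_corr)
    return [(int(j), int(np.sign(stats_.p_corr[j]))) for j in np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# Model validation
# ---------------------------------------------------------------------------

def cv_anova(cv: CvResult, n_components_total: int) -> tuple[float, float]:
    """F-test of cross-validated predictions against total response variance.

    ``F = ((SS_tot − PRESS)/df_model) / (PRESS/df_resid)`` with
    ``df_model`` = total fitted components (predictive + orthogonal) and
    ``df_resid = n − 1 − df_model``.  PRESS above SS_tot clamps F to 0
    (p = 1): the model predicts worse than the mean.
    """
    n = cv.y_hat_cv.shape[0]
    df_model = n_components_total
    df_resid = n - 1 - df_model
    if df_model < 1 or df_resid < 1:
        raise ValueError("not enough samples for CV-ANOVA degrees of freedom")
    if cv.press >= cv.ss_total:
        return 0.0, 1.0
    F = ((cv.ss_total - cv.press) / df_model) / (cv.press / df_resid)
    p = float(stats.f.sf(F, df_model, df_resid))
    return float(F), p


def _r2_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int,
    n_folds: int,
    seed: int,
    stratify: np.ndarray | None,
) -> tuple[float, float]:
    model = fit_opls(X, y, n_orth)
    cv = cross_validate(X, y, n_orth, n_folds, seed, stratify)
    return model.r2y, cv.q2


@dataclass
class ValidationReport:
    """Joint CV-ANOVA + permutation validation of one model.

    ``valid`` applies the rule used throughout: CV-ANOVA p below ``alpha``
    and every permuted R² and Q² strictly below the observed values.  With
    ``n_perm = 0`` the permutation part is vacuously true and only the
    CV-ANOVA gate applies.
    """

    cv_anova_f: float
    cv_anova_p: float
    perm_r2: np.ndarray
    perm_q2: np.ndarray
    perm_p: float
    r2y: float
    q2: float
    valid: bool


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int,
    n_perm: int,
    seed: int,
    n_folds: int = 7,
    stratify: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Response-permutation reference distribution of R² and Q².

    Refits the full model (same component structure, same fold scheme) on
    ``n_perm`` seeded permutations of y.  Returns
    ``(perm_r2, perm_q2, perm_p, r2_obs, q2_obs)`` with
    ``perm_p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    r2_obs, q2_obs = _r2_q2(X, y, n_orth, n_folds, seed, stratify)
    rng = np.random.default_rng(seed)
    perm_r2 = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = y[rng.permutation(y.shape[0])]
        perm_r2[i], perm_q2[i] = _r2_q2(X, yp, n_orth, n_folds, seed, stratify)
    perm_p = (1 + int(np.sum(perm_q2 >= q2_obs))) / (n_perm + 1)
    return perm_r2, perm_q2, float(perm_p), r2_obs, q2_obs


def validate_model(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    stratify: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ValidationReport:
    """Run CV-ANOVA and (optionally) permutation testing on one model."""
    model = fit_opls(X, y, n_orth)
    cv = cross_validate(X, y, n_orth, n_folds, seed, stratify)
    F, p = cv_anova(cv, n_orth + 1)
    if n_perm > 0:
        perm_r2, perm_q2, perm_p, r2_obs, q2_obs = permutation_test(
            X, y, n_orth, n_perm, seed, n_folds, stratify
        )
        perm_ok = bool(np.all(perm_r2 < r2_obs) and np.all(perm_q2 < q2_obs))
    else:
        perm_r2 = np.empty(0)
        perm_q2 = np.empty(0)
        perm_p = float("nan")
        r2_obs, q2_obs = model.r2y, cv.q2
        perm_ok = True
    valid = bool(p < alpha) and perm_ok
    return ValidationReport(F, p, perm_r2, perm_q2, perm_p, r2_obs, q2_obs, valid)
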