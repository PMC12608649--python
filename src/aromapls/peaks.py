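"""Aligned GC-MS peak tables: I/O, detection/blank filtering, TIC
normalization and Pareto scaling.

A :class:`PeakTable` holds a samples × features matrix of peak areas plus the
per-sample class label and role (``sample`` or ``blank``).  Filtering applies
two table-level rules: a minimum-peak-height rule (maximum area across sample
rows must reach a threshold, default 2500 area units) and a blank filter
(mean over sample rows must exceed a fold-change, default 10, times the mean
over blank rows).  Normalization divides each row by its total signal (TIC);
scaling mean-centers each variable and, for Pareto, divides by the square
root of its standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_META_COLS = ("sample_id", "class", "role")
ROLES = ("sample", "blank")


@dataclass
class PeakTable:
    """Samples × features peak-area matrix with sample metadata.

    ``areas`` is a DataFrame indexed by sample id with one column per
    feature; ``classes`` and ``roles`` are Series on the same index.
    ``annotations`` optionally maps feature ids to compound name / odor
    descriptor text.
    """

    areas: pd.DataFrame
    classes: pd.Series
    roles: pd.Series
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.areas.index.has_duplicates:
            dup = self.areas.index[self.areas.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.areas.columns.has_duplicates:
            dup = self.areas.columns[self.areas.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.areas.isna().any().any():
            col = self.areas.columns[self.areas.isna().any()][0]
            row = self.areas.index[self.areas[col].isna()][0]
            raise ValueError(f"missing area at sample {row!r}, feature {col!r}")
        if (self.areas.values < 0).any():
            col = self.areas.columns[(self.areas < 0).any()][0]
            row = self.areas.index[self.areas[col] < 0][0]
            raise ValueError(f"negative area at sample {row!r}, feature {col!r}")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown role(s) {sorted(bad)}; expected {ROLES}")
        if not (self.classes.index.equals(self.areas.index)
                and self.roles.index.equals(self.areas.index)):
            raise ValueError("classes/roles index must match the area matrix")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def features(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def is_sample(self) -> np.ndarray:
        return (self.roles == "sample").to_numpy()

    def samples_only(self) -> "PeakTable":
        keep = self.is_sample
        return PeakTable(
            self.areas.loc[keep], self.classes.loc[keep],
            self.roles.loc[keep], self.annotations,
        )


def read_peak_table(path) -> PeakTable:
    """Read the CSV dialect ``sample_id,class,role,<feature>,...``."""
    df = pd.read_csv(path, dtype={c: str for c in _META_COLS})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table CSV lacks column(s) {missing}")
    feat_cols = [c for c in df.columns if c not in _META_COLS]
    df = df.set_index("sample_id")
    areas = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    return PeakTable(areas, df["class"], df["role"])


def write_peak_table(table: PeakTable, path) -> None:
    out = table.areas.copy()
    out.insert(0, "role", table.roles)
    out.insert(0, "class", table.classes)
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_features(
    table: PeakTable,
    min_height: float = 2500.0,
    blank_fold: float | None = 10.0,
) -> tuple[PeakTable, pd.DataFrame]:
    """Apply the detection-height and blank fold-change filters.

    A feature is kept iff its maximum area over sample rows reaches
    ``min_height`` AND its mean over sample rows is at least ``blank_fold``
    times its mean over blank rows.  A blank mean of exactly zero counts as
    an infinite ratio (the feature passes the blank rule).  Blank rows are
    dropped from the returned table.  The report lists each removed feature
    with the rule(s) that removed it.
    """
    samp = table.areas.loc[table.is_sample]
    if blank_fold is not None:
        blanks = table.areas.loc[~table.is_sample]
        if blanks.shape[0] == 0:
            raise ValueError("blank filter requested but the table has no blank rows")
        blank_mean = blanks.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = samp.mean(axis=0) / blank_mean
        pass_blank = (blank_mean == 0) | (ratio >= blank_fold)
    else:
        pass_blank = pd.Series(True, index=table.areas.columns)

    pass_height = samp.max(axis=0) >= min_height
    keep = pass_height & pass_blank

    rules = []
    for f in table.areas.columns[~keep]:
        why = []
        if not pass_height[f]:
            why.append("height")
        if not pass_blank[f]:
            why.append("blank")
        rules.append({"feature": f, "rule": "+".join(why)})
    report = pd.DataFrame(rules, columns=["feature", "rule"])

    kept_cols = table.areas.columns[keep]
    # blank rows are consumed by the blank rule; a height-only pass keeps
    # them so the two rules can be applied in either order
    samp_mask = table.is_sample if blank_fold is not None else np.ones(
        table.areas.shape[0], dtype=bool
    )
    ann = None
    if table.annotations is not None:
        ann = table.annotations.loc[table.annotations.index.intersection(kept_cols)]
    out = PeakTable(
        table.areas.loc[samp_mask, kept_cols],
        table.classes.loc[samp_mask],
        table.roles.loc[samp_mask],
        ann,
    )
    return out, report


def tic_normalize(table: PeakTable) -> PeakTable:
    """Divide each row by its own total signal; row sums become 1."""
    totals = table.areas.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        raise ValueError(
            f"sample {totals.index[zero][0]!r} has zero total area; cannot normalize"
        )
    return PeakTable(
        table.areas.div(totals, axis=0), table.classes, table.roles, table.annotations
    )


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    """Centered (and optionally scaled) data matrix ready for modelling.

    ``method`` is one of ``pareto`` (divide by sqrt of the sample sd),
    ``unit-variance`` (divide by the sd) or ``none`` (center only).
    Zero-variance variables are dropped and listed in ``dropped``.
    """

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    method: str
    classes: pd.Series
    dropped: list[str]

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def inverse(self) -> pd.DataFrame:
        """Undo centering/scaling (reconstructs the retained variables)."""
        return self.values * self.scale + self.center


def scale_matrix(table: PeakTable, method: str = "pareto") -> ScaledMatrix:
    """Mean-center and scale the sample rows of a peak table.

    Standard deviations use the n−1 (sample) convention.  Constant variables
    cannot be scaled; they are dropped with a warning.
    """
    if method not in ("pareto", "unit-variance", "none"):
        raise ValueError(f"unknown scaling method {method!r}")
    samp = table.samples_only()
    A = samp.areas
    if A.shape[0] < 2:
        raise ValueError("scaling needs at least 2 sample rows")
    center = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {constant[:5]}...",
            stacklevel=2,
        )
        A = A.drop(columns=constant)
        center = center.drop(constant)
        sd = sd.drop(constant)
    if method == "pareto":
        scale = np.sqrt(sd)
    elif method == "unit-variance":
        scale = sd
    else:
        scale = pd.Series(1.0, index=A.columns)
    values = (A - center) / scale
    return ScaledMatrix(values, center, scale, method, samp.classes, constant)
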