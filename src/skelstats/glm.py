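"""Voxelwise general linear models on skeletonized metric stacks.

All maps are ordinary least squares fitted independently per skeleton voxel
with a shared design matrix, the workhorse of TBSS-style inference.  The
engine is closed-form and vectorized across voxels: for ``n`` subjects,
``p`` predictors and ``V`` voxels one call costs a single ``n x V`` matrix
product rather than ``V`` model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .skeleton import MetricStack, SkeletonSpace, StatMap

__all__ = [
    "DesignMatrix",
    "Contrast",
    "fit_voxelwise_glm",
    "residualize",
    "partial_correlation",
    "compare_condition_slopes",
    "group_contrast",
]


@dataclass
class DesignMatrix:
    """Subjects x predictors design with named columns.

    The first column is the intercept when ``intercept=True`` (the default
    builders always include one).  Construction fails on rank deficiency,
    naming the collinear columns.
    """

    values: np.ndarray
    names: list[str]
    intercept: bool = True

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("names must match the number of predictor columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")
        rank = np.linalg.matrix_rank(self.values)
        if rank < self.values.shape[1]:
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(self._collinear_columns())
            )

    def _collinear_columns(self) -> list[str]:
        # columns whose removal restores full rank among the remainder
        bad = []
        p = self.values.shape[1]
        full = np.linalg.matrix_rank(self.values)
        for j in range(p):
            others = np.delete(self.values, j, axis=1)
            if np.linalg.matrix_rank(others) == full:
                bad.append(self.names[j])
        return bad or list(self.names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_columns(cls, columns: dict[str, np.ndarray], intercept: bool = True) -> "DesignMatrix":
        cols = {k: np.asarray(v, dtype=float).ravel() for k, v in columns.items()}
        n = {len(v) for v in cols.values()}
        if len(n) != 1:
            raise ValueError("all predictor columns must have equal length")
        names = list(cols)
        mat = np.column_stack([cols[k] for k in names])
        if intercept:
            mat = np.column_stack([np.ones(mat.shape[0]), mat])
            names = ["intercept"] + names
        return cls(values=mat, names=names, intercept=intercept)

    @classmethod
    def from_table(cls, table: pd.DataFrame, predictors: Sequence[str], intercept: bool = True) -> "DesignMatrix":
        return cls.from_columns({p: table[p].to_numpy(float) for p in predictors}, intercept=intercept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class Contrast:
    """Weight per predictor plus a one-sided direction."""

    weights: np.ndarray
    direction: str = "greater"  # "greater" | "less"
    name: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.any(self.weights != 0):
            raise ValueError("contrast weights must not be all zero")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")

    @classmethod
    def on(cls, design: DesignMatrix, predictor: str, direction: str = "greater") -> "Contrast":
        w = np.zeros(design.p)
        w[design.names.index(predictor)] = 1.0
        return cls(weights=w, direction=direction, name=f"{predictor}:{direction}")


def _check_design(design: DesignMatrix, contrast: Contrast | None, n: int) -> None:
    if design.n != n:
        raise ValueError("design rows must match the number of subjects")
    if contrast is not None and len(contrast.weights) != design.p:
        raise ValueError("contrast length must equal the number of predictors")
    if n <= design.p + 1:
        raise ValueError("need more subjects than predictors + 1")


def ols_tmap(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """t statistic of contrast ``c`` for OLS of each column of Y on X.

    Returns t with residual df = n - p.  Columns with zero residual
    variance get t = +/-inf (sign of the contrast estimate) or 0.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # p x V
    resid = Y - X @ beta
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    cvar = float(c @ XtX_inv @ c)
    se = np.sqrt(np.maximum(rss / df, 0.0) * cvar)
    est = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    t = np.where(se == 0, np.where(est == 0, 0.0, np.sign(est) * np.inf), t)
    return t


def fit_voxelwise_glm(
    stack: MetricStack | np.ndarray,
    design: DesignMatrix,
    contrast: Contrast,
    space: SkeletonSpace | None = None,
) -> StatMap:
    """Per-voxel OLS t-map for a contrast; positive t favors its direction.

    The metric is the dependent variable at every voxel, regressed on the
    shared design.  ``t = c'beta / se(c'beta)`` with residual df = n - p;
    for ``direction='less'`` the sign is flipped so that positive t always
    supports the one-sided alternative.
    """
    if isinstance(stack, MetricStack):
        Y = stack.data  # n x V
        space = stack.space
    else:
        Y = np.asarray(stack, dtype=float)
        if space is None:
            raise ValueError("space required when passing a raw matrix")
    _check_design(design, contrast, Y.shape[0])
    t = ols_tmap(Y, design.values, contrast.weights)
    if contrast.direction == "less":
        t = -t
    return StatMap(values=t, kind="t", space=space, direction=contrast.direction)


def residualize(values: np.ndarray, covariates: DesignMatrix | None) -> np.ndarray:
    """Residuals of ``values`` after OLS on the covariates (with intercept).

    ``values`` may be a vector or an ``n x V`` matrix; residuals are exactly
    orthogonal to every covariate column.  ``covariates=None`` or an
    intercept-only design mean-centers.
    """
    v = np.asarray(values, dtype=float)
    y = v[:, None] if v.ndim == 1 else v
    n = y.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = covariates.values
        if not covariates.intercept:
            X = np.column_stack([np.ones(n), X])
        if X.shape[0] != n:
            raise ValueError("covariate rows must match values")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid[:, 0] if v.ndim == 1 else resid


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: DesignMatrix | None = None
) -> float:
    """Pearson correlation of x and y after removing the covariates from both."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    p_cov = 0 if covariates is None else covariates.p
    if len(x) <= p_cov + 2:
        raise ValueError("too few observations for a partial correlation")
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance residual")
    return float(np.dot(rx, ry) / (len(x) * sx * sy))


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float).ravel()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def compare_condition_slopes(
    stack: MetricStack,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    covariates: DesignMatrix | None = None,
    direction: str = "greater",
) -> StatMap:
    """t-map for the difference of two condition slopes at each voxel.

    Both behavioral scores are z-scored, entered jointly (plus covariates),
    and the (1, -1) contrast tests whether the metric's slope on condition A
    exceeds that on condition B.  Swapping A and B negates the map.
    """
    a = np.asarray(scores_a, float).ravel()
    b = np.asarray(scores_b, float).ravel()
    if np.allclose(a - b, (a - b)[0]):
        raise ValueError("condition scores are identical up to a shift; no slope difference to test")
    cols: dict[str, np.ndarray] = {"score_a": _zscore(a), "score_b": _zscore(b)}
    if covariates is not None:
        extra = covariates.to_frame()
        for name in covariates.names:
            if name == "intercept":
                continue
            cols[name] = extra[name].to_numpy()
    design = DesignMatrix.from_columns(cols)
    w = np.zeros(design.p)
    w[design.names.index("score_a")] = 1.0
    w[design.names.index("score_b")] = -1.0
    return fit_voxelwise_glm(stack, design, Contrast(weights=w, direction=direction, name="A-B"))


def group_contrast(
    stack: MetricStack,
    table: pd.DataFrame,
    group_col: str,
    pair: tuple,
    covariates: Sequence[str] = ("age", "sex"),
    interaction_col: str | None = None,
    direction: str = "greater",
) -> StatMap:
    """Two-group metric contrast (e.g. genotype), adjusted for covariates.

    Subjects outside the two requested levels are dropped (per-model
    listwise deletion).  The t-map tests level1 > level2.  With
    ``interaction_col`` (a binary 0/1 column such as an age split), the
    tested contrast is instead the group x split product term, i.e. whether
    the group difference differs between the two strata.
    """
    level1, level2 = pair
    g = table[group_col]
    keep = (g == level1) | (g == level2)
    cols = [group_col, *covariates] + ([interaction_col] if interaction_col else [])
    keep &= table[cols].notna().all(axis=1)
    idx = np.flatnonzero(keep.to_numpy())
    if (g.iloc[idx] == level1).sum() < 3 or (g.iloc[idx] == level2).sum() < 3:
        raise ValueError(f"each of {pair} needs at least 3 subjects")
    sub = table.iloc[idx]
    indicator = (sub[group_col] == level1).to_numpy(float)
    design_cols: dict[str, np.ndarray] = {"group": indicator}
    for cv in covariates:
        design_cols[cv] = sub[cv].to_numpy(float)
    if interaction_col is not None:
        split = sub[interaction_col].to_numpy(float)
        design_cols["split"] = split
        design_cols["group_x_split"] = indicator * split
    design = DesignMatrix.from_columns(design_cols)
    target = "group_x_split" if interaction_col is not None else "group"
    contrast = Contrast.on(design, target, direction=direction)
    return fit_voxelwise_glm(stack.subset(idx), design, contrast)
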