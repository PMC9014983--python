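"""Voxelwise Sobel mediation of age effects on working memory through
white-matter integrity.

The model at each skeleton voxel, after regressing the covariates (sex)
out of age (x), the behavioral score (y) and the voxel metric (m):

    m = a*x + e1          (path a, with standard error S_a)
    y = b*m + c'*x + e2   (path b controlling x, with standard error S_b)

The indirect effect a*b is tested with the Sobel statistic

    z = a*b / sqrt(b^2*S_a^2 + a^2*S_b^2 + S_a^2*S_b^2)

and the |z| map is TFCE-enhanced inside an age-effect mask; family-wise
error over voxels is controlled by a Freedman-Lane permutation of the
outcome model: the residuals of y after removing x are permuted and the b
path refitted, which breaks only the metric->y link while preserving both
the x->metric association and the direct x->y effect.  This matches the
composite null actually at stake inside an age-effect mask (where every
voxel carries a real a path): permuting the mediator instead would build a
"both paths null" reference distribution and grossly inflate the
family-wise error at a-strong, b-null voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import Contrast, DesignMatrix, residualize
from .skeleton import MetricStack, SkeletonSpace, StatMap
from .tfce import TFCEParams, PermutationResult, _tfce_columns, permutation_fwe, significant_mask

__all__ = [
    "sobel_z",
    "age_effect_mask",
    "voxelwise_mediation",
    "change_in_effect",
    "MediationResult",
    "EffectChange",
]


def sobel_z(a, b, s_a, s_b):
    """Sobel z for the indirect effect a*b; accepts scalars or arrays.

    Raises on degenerate (all-zero) standard errors, which leave the
    statistic undefined.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    if np.any(s_a < 0) or np.any(s_b < 0):
        raise ValueError("standard errors must be non-negative")
    den_sq = b**2 * s_a**2 + a**2 * s_b**2 + s_a**2 * s_b**2
    if np.any(den_sq == 0):
        raise ValueError("degenerate standard errors: Sobel denominator is zero")
    z = a * b / np.sqrt(den_sq)
    return float(z) if z.ndim == 0 else z


@dataclass
class MediationResult:
    """Per-voxel mediation paths and permutation inference, on the mask."""

    mask: np.ndarray  # boolean per skeleton column
    a: np.ndarray
    s_a: np.ndarray
    b: np.ndarray
    s_b: np.ndarray
    z_map: StatMap
    enhanced: StatMap
    p_map: StatMap
    null_max: np.ndarray
    peak_column: int
    n_perm: int
    seed: int
    n_excluded: int = 0  # constant-metric voxels dropped from the mask

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        out = np.zeros_like(self.mask)
        out[self.mask] = self.p_map.values[self.mask] < alpha
        return out


@dataclass
class EffectChange:
    """Variance accounting before/after adding the peak-voxel metric."""

    r2_before: float
    r2_after: float
    relative_change: float  # (r2_after - r2_before)/r2_before, the literal rule
    age_t_before: float
    age_t_after: float
    age_sr2_before: float  # squared semipartial of age
    age_sr2_after: float
    age_attenuation: float  # (sr2_after - sr2_before)/sr2_before, the drop

    def __post_init__(self) -> None:
        if not 0 <= self.r2_before <= 1 or not 0 <= self.r2_after <= 1:
            raise ValueError("r^2 must lie in [0, 1]")
        if self.r2_after < self.r2_before - 1e-10:
            raise ValueError("nested models require r2_after >= r2_before")


def age_effect_mask(
    stack: MetricStack,
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex",),
    params: TFCEParams = TFCEParams(),
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    age_col: str = "age",
) -> tuple[np.ndarray, PermutationResult]:
    """FWE-significant voxels for the negative age effect on the metric.

    Returns the boolean column mask and the underlying permutation result.
    An empty mask triggers a warning (downstream mediation is then skipped).
    """
    design = DesignMatrix.from_table(table, [age_col, *covariates])
    contrast = Contrast.on(design, age_col, direction="less")
    result = permutation_fwe(stack, design, contrast, params=params, n_perm=n_perm, seed=seed)
    mask = significant_mask(result, alpha=alpha)
    if not mask.any():
        warnings.warn("no FWE-significant age-effect voxels; mediation mask is empty", RuntimeWarning, stacklevel=2)
    return mask, result


def _paths_on_residuals(
    m: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form per-voxel paths on centered (residualized) variables.

    m: n x V metric residuals; x, y: length-n residual vectors.  Path a
    from simple OLS of m on x (df = n-2); path b from OLS of y on (m, x)
    jointly (df = n-3).  Vectorized over voxels.
    """
    n = len(x)
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    smx = m.T @ x  # V
    smy = m.T @ y
    smm = np.einsum("ij,ij->j", m, m)

    # a and S_a: m = a*x + resid (variables centered; intercept absorbed)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = smx / sxx
        rss_a = smm - a * smx
        s_a = np.sqrt(np.maximum(rss_a, 0.0) / (n - 2) / sxx)

        # b and S_b: y = b*m + c*x + resid
        det = smm * sxx - smx**2
        b = (smy * sxx - sxy * smx) / det
        c = (smm * sxy - smx * smy) / det
        rss_b = syy - b * smy - c * sxy
        sigma2 = np.maximum(rss_b, 0.0) / (n - 3)
        s_b = np.sqrt(sigma2 * sxx / det)
    return a, s_a, b, s_b


def voxelwise_mediation(
    stack: MetricStack,
    x: np.ndarray,
    y: np.ndarray,
    covariates: DesignMatrix | None,
    mask: np.ndarray,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 5000,
    seed: int = 0,
    standardize: bool = True,
) -> MediationResult:
    """Sobel mediation at every masked voxel with max-TFCE permutation FWE.

    x (age), y (WM score) and each voxel's metric are residualized on the
    covariates (intercept always included) and, by default, z-scored so a
    and b are standardized path coefficients comparable across voxels.
    TFCE is applied to |z| restricted to the mask; the null is built by
    permuting the residuals of y about its fit on x (Freedman-Lane on the
    outcome model, shared across voxels), which nulls the b path only.
    The identity permutation is permutation 1 and p(v) = #{null max >=
    enhanced(v)} / n_perm.  Constant-metric voxels are excluded with a
    logged count.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != (stack.space.n_columns,):
        raise ValueError("mask must have one entry per skeleton column")
    if not mask.any():
        raise ValueError("mediation mask is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = stack.n_subjects
    if len(x) != n or len(y) != n:
        raise ValueError("x and y must match the stack's subjects")

    xr = residualize(x, covariates)
    yr = residualize(y, covariates)
    mr = residualize(stack.data[:, mask], covariates)

    sd_m = mr.std(axis=0, ddof=1)
    keep_cols = sd_m > 0
    n_excluded = int((~keep_cols).sum())
    mask = mask.copy()
    mask[np.flatnonzero(mask)[~keep_cols]] = False
    mr = mr[:, keep_cols]
    if mr.shape[1] == 0:
        raise ValueError("all masked voxels have constant metric values")
    if standardize:
        if xr.std(ddof=1) == 0 or yr.std(ddof=1) == 0:
            raise ValueError("x or y residuals are constant")
        xr = xr / xr.std(ddof=1)
        yr = yr / yr.std(ddof=1)
        mr = mr / mr.std(axis=0, ddof=1)

    # restrict TFCE connectivity to the analysis mask
    sub_space = SkeletonSpace(mask=stack.space.to_volume(mask.astype(float)) > 0, affine=stack.space.affine)

    a, s_a, b, s_b = _paths_on_residuals(mr, xr, yr)
    z = sobel_z(a, s_a=s_a, b=b, s_b=s_b)
    obs_enh = _tfce_columns(np.abs(z), sub_space, params)

    # Freedman-Lane parts of the outcome model: y = c*x + e_y
    c0 = float(xr @ yr) / float(xr @ xr)
    y_fit = c0 * xr
    e_y = yr - y_fit

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    null_max[0] = obs_enh.max()
    for i in range(1, n_perm):
        y_star = y_fit + e_y[rng.permutation(n)]
        _, _, bp, sbp = _paths_on_residuals(mr, xr, y_star)
        with np.errstate(divide="ignore", invalid="ignore"):
            zp = np.abs(a * bp) / np.sqrt(bp**2 * s_a**2 + a**2 * sbp**2 + s_a**2 * sbp**2)
        zp = np.nan_to_num(zp, nan=0.0, posinf=0.0)
        null_max[i] = _tfce_columns(zp, sub_space, params).max()

    p = (null_max[None, :] >= obs_enh[:, None]).mean(axis=1)

    # expand masked-column vectors to full skeleton maps (NaN off-mask)
    def expand(v: np.ndarray, fill: float = np.nan) -> np.ndarray:
        full = np.full(stack.space.n_columns, fill)
        full[mask] = v
        return full

    peak_local = int(np.argmax(obs_enh))
    peak_column = int(np.flatnonzero(mask)[peak_local])
    return MediationResult(
        mask=mask,
        a=expand(a),
        s_a=expand(s_a),
        b=expand(b),
        s_b=expand(s_b),
        z_map=StatMap(expand(z, fill=0.0), "z", stack.space),
        enhanced=StatMap(expand(obs_enh, fill=0.0), "tfce", stack.space),
        p_map=StatMap(expand(p, fill=1.0), "p", stack.space),
        null_max=null_max,
        peak_column=peak_column,
        n_perm=n_perm,
        seed=seed,
        n_excluded=n_excluded,
    )


def change_in_effect(
    age: np.ndarray,
    sex: np.ndarray,
    metric_at_peak: np.ndarray,
    y: np.ndarray,
) -> EffectChange:
    """Variance explained before vs after adding the peak-voxel metric.

    Fits ``y ~ age + sex`` and ``y ~ age + sex + metric``.  Reports both
    models' r^2 and age-coefficient t, the literal relative r^2 change
    (positive for nested models, since adding a regressor cannot lower
    r^2), and the attenuation of age's unique contribution (squared
    semipartial correlation), which is the quantity that *drops* when the
    mediator absorbs age-related variance.
    """
    age = np.asarray(age, float).ravel()
    sex = np.asarray(sex, float).ravel()
    m = np.asarray(metric_at_peak, float).ravel()
    y = np.asarray(y, float).ravel()
    X0 = sm.add_constant(np.column_stack([age, sex]))
    X1 = sm.add_constant(np.column_stack([age, sex, m]))
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    r2_before = float(fit0.rsquared)
    r2_after = float(fit1.rsquared)
    if not np.isfinite(r2_before) or r2_before < 1e-12:
        raise ValueError("r^2 before mediation is zero; relative change undefined")
    if not np.isfinite(r2_after):
        raise ValueError("r^2 after mediation is undefined")

    def age_sr2(fit, X):
        # squared semipartial: r^2 minus r^2 of the model without age
        X_wo = np.delete(X, 1, axis=1)
        return float(fit.rsquared - sm.OLS(y, X_wo).fit().rsquared)

    sr2_0 = age_sr2(fit0, X0)
    sr2_1 = age_sr2(fit1, X1)
    return EffectChange(
        r2_before=r2_before,
        r2_after=r2_after,
        relative_change=(r2_after - r2_before) / r2_before,
        age_t_before=float(fit0.tvalues[1]),
        age_t_after=float(fit1.tvalues[1]),
        age_sr2_before=sr2_0,
        age_sr2_after=sr2_1,
        age_attenuation=(sr2_1 - sr2_0) / sr2_0 if sr2_0 > 0 else float("nan"),
    )
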