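"""Summary statistics: Hardy-Weinberg tests, slice profiles, tract
coverage, cross-metric overlap and demographic group tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton import SkeletonSpace, StatMap

__all__ = [
    "GenotypeCounts",
    "HWEResult",
    "SliceProfile",
    "hwe_test",
    "slice_profile",
    "tract_coverage",
    "metric_overlap",
    "demographic_tests",
]

AXES = {"x": 0, "y": 1, "z": 2, "anterior-posterior": 1, "inferior-superior": 2}


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts (hom for allele 1, het, hom for allele 2)."""

    locus: str
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if sum(self.counts) < 2:
            raise ValueError("need at least 2 genotyped subjects")

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class HWEResult:
    chi_square: float
    allele_freq: float  # frequency of the designated allele
    expected: tuple[float, float, float]
    p_value: float


def hwe_test(counts: GenotypeCounts, allele: str = "first") -> HWEResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    With allele-1 frequency ``p = (2*hom1 + het) / 2n``, expected counts
    are ``(n*p^2, 2*n*p*q, n*q^2)``; no continuity correction.  The
    reported allele frequency is for the caller-designated allele
    (``'first'`` or ``'second'``).
    """
    if allele not in ("first", "second"):
        raise ValueError("allele must be 'first' or 'second'")
    hom1, het, hom2 = counts.counts
    n = counts.n
    p = (2 * hom1 + het) / (2 * n)
    q = 1 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if any(e == 0 for e in expected):
        raise ValueError("zero expected genotype count; test undefined")
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts.counts, expected))
    return HWEResult(
        chi_square=float(chi2),
        allele_freq=float(p if allele == "first" else q),
        expected=expected,
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


@dataclass
class SliceProfile:
    """Per-slice mean statistic along one volume axis."""

    axis: int
    means: np.ndarray  # NaN where a slice holds no skeleton voxels
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.means) != len(self.counts):
            raise ValueError("means and counts must align")


def slice_profile(stat_map: StatMap, axis: int | str) -> SliceProfile:
    """Mean of the statistic over skeleton voxels in each slice.

    ``axis`` is a volume axis index (0/1/2) or one of the configured names
    in ``AXES`` (the anatomical meaning of each axis is a property of how
    the volume was stored, not of this function).
    """
    if isinstance(axis, str):
        if axis not in AXES:
            raise ValueError(f"unknown axis '{axis}'; use 0/1/2 or one of {sorted(AXES)}")
        axis = AXES[axis]
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    space = stat_map.space
    extent = space.shape[axis]
    idx = space.column_to_voxel(np.arange(space.n_columns))[:, axis]
    counts = np.bincount(idx, minlength=extent).astype(int)
    sums = np.bincount(idx, weights=stat_map.values, minlength=extent)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SliceProfile(axis=axis, means=means, counts=counts)


def tract_coverage(significant: np.ndarray, space: SkeletonSpace) -> pd.DataFrame:
    """Percentage of each labeled tract (and the whole skeleton) that is
    significant.

    Returns a table with one row per tract label plus a ``whole-skeleton``
    row; percentages are ``100 * |significant in tract| / |tract|``.
    """
    if space.tract_labels is None:
        raise ValueError("space has no tract labels")
    significant = np.asarray(significant, bool)
    if significant.shape != (space.n_columns,):
        raise ValueError("significant mask must have one entry per column")
    rows = []
    labels = space.tract_labels
    for lab in np.unique(labels):
        if lab == 0:
            continue
        in_tract = labels == lab
        name = (space.tract_names or {}).get(int(lab), f"label_{lab}")
        rows.append(
            {
                "tract": name,
                "label": int(lab),
                "n_voxels": int(in_tract.sum()),
                "n_significant": int((significant & in_tract).sum()),
                "percent": 100.0 * (significant & in_tract).sum() / in_tract.sum(),
            }
        )
    rows.append(
        {
            "tract": "whole-skeleton",
            "label": 0,
            "n_voxels": int(space.n_columns),
            "n_significant": int(significant.sum()),
            "percent": 100.0 * significant.sum() / space.n_columns,
        }
    )
    return pd.DataFrame(rows)


def metric_overlap(
    p_maps: Mapping[str, StatMap | np.ndarray], alpha: float = 0.05
) -> dict[str, float]:
    """Partition of the union of significant voxels by metric combination.

    Every voxel significant (p < alpha) in at least one metric is assigned
    to its exact combination (e.g. ``'FA'``, ``'FA+MD'``); the returned
    proportions sum to 1.  An empty union returns an empty dict.
    """
    names = list(p_maps)
    arrays = []
    length = None
    for name in names:
        pm = p_maps[name]
        v = pm.values if isinstance(pm, StatMap) else np.asarray(pm, float)
        if length is None:
            length = len(v)
        elif len(v) != length:
            raise ValueError("all p-maps must share one skeleton space")
        arrays.append(v < alpha)
    sig = np.column_stack(arrays)  # V x metrics
    union = sig.any(axis=1)
    total = int(union.sum())
    if total == 0:
        return {}
    out: dict[str, float] = {}
    combos, counts = np.unique(sig[union], axis=0, return_counts=True)
    for combo, count in zip(combos, counts):
        key = "+".join(n for n, on in zip(names, combo) if on)
        out[key] = count / total
    return out


def demographic_tests(
    table: pd.DataFrame,
    group_col: str,
    numeric_vars: Sequence[str],
    sex_col: str | None = "sex",
) -> pd.DataFrame:
    """Group comparisons as in a demographics table: one-way ANOVA F per
    numeric variable and a contingency chi-square for sex composition."""
    groups = [g for _, g in table.groupby(group_col, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for var in numeric_vars:
        samples = [g[var].dropna().to_numpy(float) for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"every group needs >= 2 observations of '{var}'")
        f, p = stats.f_oneway(*samples)
        rows.append({"variable": var, "statistic": float(f), "kind": "F", "p_value": float(p)})
    if sex_col is not None:
        ct = pd.crosstab(table[sex_col], table[group_col])
        chi2, p, _, _ = stats.chi2_contingency(ct, correction=False)
        rows.append({"variable": sex_col, "statistic": float(chi2), "kind": "chi2", "p_value": float(p)})
    return pd.DataFrame(rows)
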