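"""Synthetic aging-cohort generator.

Emulates the data structure of a narrow-age-cohort (NAC) aging study:
discrete recruitment ages between 25 and 80 skewed toward older adults,
Hardy-Weinberg genotypes at three dopamine-related loci, working-memory
accuracies under three load conditions (manipulation, maintenance, control)
with load-graded negative age effects, a processing-speed composite, and
skeletonized FA stacks carrying tract-structured negative age effects.

The age -> white-matter -> working-memory mediation path is planted
explicitly: a latent white-matter factor ``f = a*z_age + sqrt(1-a^2)*e_f``
feeds both the manipulation score (through the ``b`` path) and a designated
block of "mediating" skeleton voxels, so the standardized path coefficients
a and b are recoverable by the mediation module.  A second, spatially
separate block carries the age effect only (b = 0), and the rest of the
skeleton is pure noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .skeleton import MetricStack, SkeletonSpace

__all__ = [
    "MediationSpec",
    "CohortParams",
    "ExclusionLedger",
    "generate_genotypes",
    "generate_cohort",
    "generate_metric_stack",
    "effect_voxel_sets",
    "apply_exclusions",
    "remove_outliers",
    "GENOTYPE_COLUMNS",
    "WM_CONDITIONS",
]

GENOTYPE_COLUMNS = ("taq1a", "c957t", "comt")
WM_CONDITIONS = ("wm_manipulation", "wm_maintenance", "wm_control")

# Table-1-like NAC recruitment ages and weights: 5-year cohorts 25..80 with
# the older cohorts heavily over-represented (weights from the study-scale
# group sizes 18/18/19/100/104/89 split over paired recruitment ages).
DEFAULT_AGE_COHORTS: tuple[tuple[float, float], ...] = (
    (25, 9), (30, 9), (35, 9), (40, 9), (45, 9.5), (50, 9.5),
    (55, 50), (60, 50), (65, 52), (70, 52), (75, 44.5), (80, 44.5),
)


@dataclass(frozen=True)
class MediationSpec:
    """Planted age -> FA -> WM structure.

    frac_age_effect:
        Fraction of skeleton voxels carrying the negative age->FA slope.
    frac_mediating:
        Fraction *of those* that additionally load on the latent factor
        driving the manipulation score (the b path); the rest carry the age
        effect only.
    a, b:
        Standardized path slopes (age->FA and FA->WM given age).
    voxel_noise:
        Fraction of a mediating voxel's non-age variance that is voxel-
        specific rather than shared with the latent factor; keeps effect
        voxels distinct while attenuating the voxel-level b path only by
        sqrt(1 - voxel_noise^2).
    """

    frac_age_effect: float = 0.05
    frac_mediating: float = 0.5
    a: float = -0.4
    b: float = 0.3
    voxel_noise: float = 0.3

    def __post_init__(self) -> None:
        for name in ("frac_age_effect", "frac_mediating", "voxel_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (abs(self.a) < 1 and abs(self.b) < 1):
            raise ValueError("standardized slopes must have magnitude < 1")


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults emulate the study-scale conditions."""

    n_subjects: int = 328
    age_cohorts: tuple[tuple[float, float], ...] = DEFAULT_AGE_COHORTS
    sex_ratio: float = 0.527  # proportion female
    allele_freqs: tuple[float, float, float] = (0.192, 0.562, 0.471)
    wm_ceiling: float = 18.0
    load_age_slopes: tuple[float, float, float] = (-0.33, -0.22, -0.12)
    mediation: MediationSpec = field(default_factory=MediationSpec)
    noise_sd: float | None = None  # None = normalize latent scores to unit variance
    wm_scale: float = 2.5  # accuracy points per latent SD
    shared_ability: float = 0.8  # within-residual loading on a common factor
    speed_age_slope: float = -0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        w = np.array([w for _, w in self.age_cohorts], float)
        if len(w) == 0 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("age cohort weights must be non-negative and sum > 0")
        for f in self.allele_freqs:
            if not 0 < f < 1:
                raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def cohort_weights(self) -> np.ndarray:
        w = np.array([w for _, w in self.age_cohorts], float)
        return w / w.sum()


def generate_genotypes(n: int, allele_freq: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """HWE genotypes as copies (0/1/2) of the designated allele.

    Each subject's genotype is drawn from the Hardy-Weinberg probabilities
    (p^2, 2pq, q^2) for carrying (2, 1, 0) copies of the allele with
    frequency ``allele_freq = p``.
    """
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = allele_freq
    probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    return rng.choice(np.array([2, 1, 0]), size=n, p=probs)


def _zscore_sample(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a subject table.

    Columns: ``subject_id, age, sex`` (0 = female), three genotype columns
    (copies of the designated allele), the three WM accuracies on the
    ``[0, wm_ceiling]`` scale, and the ``speed`` composite (sum of three
    z-scored subscores).  Latent helper columns prefixed with ``_`` carry
    the standardized age and the white-matter factor pieces that
    :func:`generate_metric_stack` re-uses, keeping cohort and imaging
    simulations mutually consistent.
    """
    streams = {k: np.random.default_rng(s) for k, s in zip(
        ("age", "sex", "geno", "factor", "wm", "speed"),
        np.random.SeedSequence(params.seed).generate_state(6) % (2**31),
    )}
    n = params.n_subjects
    ages = np.array([a for a, _ in params.age_cohorts], float)
    age = streams["age"].choice(ages, size=n, p=params.cohort_weights)
    if np.ptp(age) == 0:  # single cohort drawn: degenerate z-score guard
        z_age = np.zeros(n)
    else:
        z_age = _zscore_sample(age)
    sex = (streams["sex"].random(n) >= params.sex_ratio).astype(int)  # 0 = female

    table = pd.DataFrame({"subject_id": np.arange(n), "age": age, "sex": sex})
    for col, freq in zip(GENOTYPE_COLUMNS, params.allele_freqs):
        table[col] = generate_genotypes(n, freq, streams["geno"])

    med = params.mediation
    noise_on = 1.0 if params.noise_sd is None else float(params.noise_sd > 0)
    e_f = streams["factor"].standard_normal(n)
    f = med.a * z_age + np.sqrt(1 - med.a**2) * e_f * noise_on

    u = streams["wm"].standard_normal(n)  # shared ability factor
    lam = params.shared_ability
    z_min = z_age.min()
    for cond, direct in zip(WM_CONDITIONS, params.load_age_slopes):
        b_c = med.b if cond == "wm_manipulation" else 0.0
        if params.noise_sd is None:
            # residual sd chosen so the latent score has unit variance
            explained = direct**2 + b_c**2 + 2 * direct * b_c * med.a
            resid_sd = np.sqrt(max(1.0 - explained, 0.04))
        else:
            resid_sd = params.noise_sd
        e_c = streams["wm"].standard_normal(n)
        residual = resid_sd * (lam * u + np.sqrt(1 - lam**2) * e_c)
        g = direct * z_age + b_c * f + residual
        score = params.wm_ceiling + params.wm_scale * (g - direct * z_min)
        table[cond] = np.clip(score, 0.0, params.wm_ceiling)

    sub = np.empty((n, 3))
    slope = params.speed_age_slope
    for j in range(3):
        e = streams["speed"].standard_normal(n) * noise_on
        raw = slope * z_age + np.sqrt(max(1 - slope**2, 0.0)) * e
        sub[:, j] = raw if raw.std() == 0 else _zscore_sample(raw)
    table["speed"] = sub.sum(axis=1)

    table["_z_age"] = z_age
    table["_wm_factor"] = f
    table["_wm_factor_resid"] = e_f * noise_on
    return table


def effect_voxel_sets(space: SkeletonSpace, spec: MediationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (mediating, age-only) column index sets for a space.

    Effect voxels occupy leading blocks of the skeleton's C-order columns
    (contiguous slabs in a cuboid mask, so TFCE sees clustered signal); the
    two blocks are separated by a guard gap of three grid lines so they are
    not 26-connected to each other.
    """
    v = space.n_columns
    n_eff = int(round(spec.frac_age_effect * v))
    n_med = int(round(spec.frac_mediating * n_eff))
    n_age_only = n_eff - n_med
    gap = 3 * space.shape[2]
    start2 = n_med + gap
    if start2 + n_age_only > v:
        start2 = max(n_med, v - n_age_only)  # small mask: shrink the gap
    mediating = np.arange(n_med)
    age_only = np.arange(start2, start2 + n_age_only)
    return mediating, age_only


def generate_metric_stack(
    table: pd.DataFrame,
    space: SkeletonSpace,
    spec: MediationSpec | None = None,
    seed: int = 0,
    metric: str = "FA",
    fa_mean: float = 0.5,
    fa_sd: float = 0.08,
) -> MetricStack:
    """Skeleton FA stack with planted negative age effects.

    Mediating voxels: ``m = a*z_age + sqrt(1-a^2) * (sqrt(1-tau^2)*e_f +
    tau*eps)`` where ``e_f`` is the cohort's latent factor residual, so the
    voxel-level standardized age slope is exactly ``a`` and the FA->WM
    partial slope is ``b*sqrt(1-tau^2)``.  Age-only voxels replace ``e_f``
    with fresh noise; remaining voxels are pure noise.  Latent values are
    mapped to the FA scale as ``fa_mean + fa_sd * m`` and clipped to
    (0.01, 0.99).  The effect-voxel index sets depend only on the space and
    spec, never on the seed.
    """
    if len(table) == 0 or space.n_columns == 0:
        raise ValueError("table and space must be nonempty")
    spec = spec if spec is not None else MediationSpec()
    rng = np.random.default_rng(seed)
    n, v = len(table), space.n_columns
    z_age = table["_z_age"].to_numpy() if "_z_age" in table else _zscore_sample(table["age"].to_numpy(float))
    e_f = table["_wm_factor_resid"].to_numpy() if "_wm_factor_resid" in table else np.zeros(n)

    mediating, age_only = effect_voxel_sets(space, spec)
    latent = rng.standard_normal((n, v))  # pure-noise baseline, unit variance
    tau = spec.voxel_noise
    amp = np.sqrt(1 - spec.a**2)
    if mediating.size:
        eps = rng.standard_normal((n, mediating.size))
        shared = np.sqrt(1 - tau**2) * e_f[:, None] + tau * eps
        latent[:, mediating] = spec.a * z_age[:, None] + amp * shared
    if age_only.size:
        eps = rng.standard_normal((n, age_only.size))
        latent[:, age_only] = spec.a * z_age[:, None] + amp * eps

    data = np.clip(fa_mean + fa_sd * latent, 0.01, 0.99)
    if metric != "FA":
        data = fa_mean + fa_sd * latent
    return MetricStack(metric=metric, data=data, subject_ids=table["subject_id"].to_numpy(), space=space)


@dataclass
class ExclusionLedger:
    """Per-stage removal counts; conserves subjects exactly."""

    initial: int
    stage_counts: dict[str, int]
    final: int

    def __post_init__(self) -> None:
        if self.initial < 0 or self.final < 0 or any(c < 0 for c in self.stage_counts.values()):
            raise ValueError("counts must be non-negative")
        if self.final != self.initial - sum(self.stage_counts.values()):
            raise ValueError("ledger does not conserve subjects")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"initial": self.initial, "stages": self.stage_counts, "final": self.final},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_exclusions(
    table: pd.DataFrame,
    flags: Mapping[str, Sequence[bool]],
    stages: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Drop flagged subjects; tally removals per stage in declared order.

    ``flags`` maps stage label -> per-subject boolean; ``stages`` fixes the
    order (defaults to mapping order).  A subject flagged at several stages
    is counted only at the first.
    """
    stages = list(stages) if stages is not None else list(flags)
    unknown = set(flags) - set(stages)
    if unknown:
        raise ValueError(f"flags reference undeclared stages: {sorted(unknown)}")
    n = len(table)
    removed = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for stage in stages:
        flag = np.asarray(flags.get(stage, np.zeros(n, bool)), dtype=bool)
        if flag.shape != (n,):
            raise ValueError(f"flag vector for stage '{stage}' has wrong length")
        new = flag & ~removed
        counts[stage] = int(new.sum())
        removed |= new
    ledger = ExclusionLedger(initial=n, stage_counts=counts, final=int(n - removed.sum()))
    return table.loc[~removed].reset_index(drop=True), ledger


def remove_outliers(
    x: np.ndarray, y: np.ndarray, k: float = 3.5
) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop pairs where either value is more than k SDs from its mean.

    Mean and SD are computed once on the full input (not iteratively),
    matching the usual scatter-plot outlier rule.  A zero-SD variable
    removes nothing and emits a warning.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if k <= 0:
        raise ValueError("k must be positive")
    keep = np.ones(len(x), dtype=bool)
    for v in (x, y):
        sd = v.std()
        if sd == 0:
            warnings.warn("constant variable: no outliers removable", RuntimeWarning, stacklevel=2)
            continue
        keep &= np.abs(v - v.mean()) <= k * sd
    return x[keep], y[keep], int((~keep).sum())


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the subject table as TSV (latent helper columns excluded)."""
    cols = [c for c in table.columns if not c.startswith("_")]
    table[cols].to_csv(path, sep="\t", index=False)
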