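"""Config-driven orchestration of the full study replica.

Sequences: cohort (simulated or loaded) -> exclusions -> per-condition
metric-behavior GLMs with age+sex -> speed-controlled repeat -> load
contrasts -> age-effect mask -> mediation -> genotype contrasts and
age x gene interaction -> summary reports.  Every stage is deterministic
given the config seed; outputs are NIfTI maps plus TSV/JSON summaries and
a manifest recording the config hash and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortParams,
    MediationSpec,
    WM_CONDITIONS,
    GENOTYPE_COLUMNS,
    apply_exclusions,
    generate_cohort,
    generate_metric_stack,
    save_table,
)
from .glm import Contrast, DesignMatrix, compare_condition_slopes, group_contrast
from .mediate import age_effect_mask, change_in_effect, voxelwise_mediation
from .report import GenotypeCounts, demographic_tests, hwe_test, slice_profile, tract_coverage
from .skeleton import MetricStack, SkeletonSpace
from .tfce import TFCEParams, permutation_fwe, significant_mask

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML."""

    seed: int = 0
    n_perm: int = 200  # smoke-test profile; the study-scale setting is 5000
    alpha: float = 0.05
    age_split: float = 60.0
    skeleton_shape: tuple[int, int, int] = (10, 10, 10)
    n_tracts: int = 4
    cohort: CohortParams = field(default_factory=lambda: CohortParams(n_subjects=120))
    tfce: TFCEParams = field(default_factory=TFCEParams)
    exclusions: dict[str, int] = field(default_factory=dict)
    genetics_locus: str = "comt"
    genetics_pair: tuple[int, int] = (1, 2)  # het vs hom-designated
    # real-data mode: paths to a subject TSV, 4D stack and mask NIfTI
    table_path: str | None = None
    stack_path: str | None = None
    mask_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        for p in (self.table_path, self.stack_path, self.mask_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            c = raw["cohort"]
            if "mediation" in c:
                c["mediation"] = MediationSpec(**c["mediation"])
            if "age_cohorts" in c:
                c["age_cohorts"] = tuple(tuple(p) for p in c["age_cohorts"])
            raw["cohort"] = CohortParams(**c)
        if "tfce" in raw:
            raw["tfce"] = TFCEParams(**raw["tfce"])
        for key in ("skeleton_shape", "genetics_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def synthetic_space(shape: tuple[int, int, int], n_tracts: int) -> SkeletonSpace:
    """Cuboid skeleton with labels splitting the columns into n_tracts slabs."""
    mask = np.ones(shape, dtype=bool)
    n_cols = int(np.prod(shape))
    labels = 1 + (np.arange(n_cols) * n_tracts) // n_cols
    names = {i: f"synthetic_tract_{i}" for i in range(1, n_tracts + 1)}
    return SkeletonSpace(mask=mask, tract_labels=labels, tract_names=names)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "skelstats_version": __version__,
        "seed": config.seed,
        "stages": {},
        "results": {},
    }
    rng = np.random.default_rng(config.seed)

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            manifest["results"].update(info)

        return done

    try:
        # ---- cohort ----------------------------------------------------
        done = stage("cohort")
        if config.table_path is not None:
            table = pd.read_csv(config.table_path, sep="\t")
            space = SkeletonSpace.load(config.mask_path)
            stack = MetricStack.load(config.stack_path, "FA", space, subject_ids=table["subject_id"])
        else:
            table = generate_cohort(config.cohort)
            space = synthetic_space(config.skeleton_shape, config.n_tracts)
            stack = generate_metric_stack(table, space, config.cohort.mediation, seed=config.seed + 1)
        done(n_subjects_initial=len(table))

        # ---- exclusions ------------------------------------------------
        done = stage("exclusions")
        flags = {}
        for stage_name, count in config.exclusions.items():
            flag = np.zeros(len(table), bool)
            flag[rng.choice(len(table), size=min(count, len(table)), replace=False)] = True
            flags[stage_name] = flag
        table, ledger = apply_exclusions(table, flags)
        keep = np.isin(stack.subject_ids, table["subject_id"].to_numpy())
        stack = stack.subset(np.flatnonzero(keep))
        ledger.to_json(outdir / "exclusions.json")
        save_table(table, outdir / "subjects.tsv")
        stack.save(outdir / "fa_stack.nii.gz")
        space.save_mask(outdir / "skeleton_mask.nii.gz")
        done(n_subjects_final=ledger.final, exclusions=ledger.stage_counts)

        # ---- per-condition GLMs (age+sex nuisance, then +speed) --------
        done = stage("condition_glms")
        glm_results = {}
        for cond in WM_CONDITIONS:
            for covs, tag in ((["age", "sex"], cond), (["age", "sex", "speed"], f"{cond}_speedctl")):
                design = DesignMatrix.from_columns(
                    {"score": table[cond].to_numpy(float), **{c: table[c].to_numpy(float) for c in covs}}
                )
                res = permutation_fwe(
                    stack, design, Contrast.on(design, "score", "greater"),
                    params=config.tfce, n_perm=config.n_perm, seed=config.seed + 10,
                )
                sig = significant_mask(res, config.alpha)
                res.p_map.save(outdir / f"pmap_{tag}.nii.gz", fill=1.0)
                glm_results[tag] = {
                    "n_significant": int(sig.sum()),
                    "percent_skeleton": 100.0 * sig.sum() / space.n_columns,
                }
                if tag == "wm_manipulation":
                    profile = slice_profile(res.observed_t, axis=1)
                    pd.DataFrame({"slice": np.arange(len(profile.means)), "mean_t": profile.means,
                                  "n_voxels": profile.counts}).to_csv(outdir / "slice_profile_ap.tsv", sep="\t", index=False)
                    tract_coverage(sig, space).to_csv(outdir / "tract_coverage_manipulation.tsv", sep="\t", index=False)
        done(condition_glms=glm_results)

        # ---- load contrasts -------------------------------------------
        done = stage("load_contrasts")
        covs = DesignMatrix.from_table(table, ["age", "sex"])
        load_results = {}
        pairs = [(WM_CONDITIONS[0], WM_CONDITIONS[1]), (WM_CONDITIONS[1], WM_CONDITIONS[2]),
                 (WM_CONDITIONS[0], WM_CONDITIONS[2])]
        for ca, cb in pairs:
            tmap = compare_condition_slopes(stack, table[ca].to_numpy(), table[cb].to_numpy(), covs)
            load_results[f"{ca}_vs_{cb}"] = {"max_abs_t": float(np.abs(tmap.values).max())}
        done(load_contrasts=load_results)

        # ---- age-effect mask + mediation ------------------------------
        done = stage("mediation")
        mask, age_res = age_effect_mask(
            stack, table, params=config.tfce, n_perm=config.n_perm, seed=config.seed + 20, alpha=config.alpha
        )
        med_summary: dict = {"age_mask_voxels": int(mask.sum())}
        if mask.any():
            sex_cov = DesignMatrix.from_table(table, ["sex"])
            med = voxelwise_mediation(
                stack, table["age"].to_numpy(float), table["wm_manipulation"].to_numpy(float),
                sex_cov, mask, params=config.tfce, n_perm=config.n_perm, seed=config.seed + 30,
            )
            med.p_map.save(outdir / "pmap_mediation.nii.gz", fill=1.0)
            sig_med = med.significant(config.alpha)
            change = change_in_effect(
                table["age"], table["sex"], stack.data[:, med.peak_column], table["wm_manipulation"]
            )
            med_summary.update(
                n_significant=int(sig_med.sum()),
                peak_voxel=[int(i) for i in space.column_to_voxel(med.peak_column)],
                effect_change=asdict(change),
            )
        done(mediation=med_summary)

        # ---- genetics --------------------------------------------------
        done = stage("genetics")
        table["age_group"] = (table["age"] > config.age_split).astype(int)
        gen_results = {}
        for mode, interaction in (("main", None), ("age_x_gene", "age_group")):
            try:
                tmap = group_contrast(
                    stack, table, config.genetics_locus, config.genetics_pair,
                    covariates=("age", "sex"), interaction_col=interaction,
                )
                gen_results[mode] = {"max_abs_t": float(np.abs(tmap.values).max())}
            except ValueError as err:
                gen_results[mode] = {"error": str(err)}
        done(genetics=gen_results)

        # ---- reports ---------------------------------------------------
        done = stage("reports")
        hwe = {}
        for locus in GENOTYPE_COLUMNS:
            g = table[locus].to_numpy()
            counts = GenotypeCounts(locus, (int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())))
            res = hwe_test(counts)
            hwe[locus] = {"chi_square": res.chi_square, "allele_freq": res.allele_freq, "p_value": res.p_value}
        demo = demographic_tests(
            table, config.genetics_locus, [c for c in ("age", *WM_CONDITIONS, "speed")]
        )
        demo.to_csv(outdir / "demographic_tests.tsv", sep="\t", index=False)
        done(hwe=hwe)
    except Exception as err:  # annotate the failing stage; keep partial outputs
        failed = len(manifest["stages"])
        raise RuntimeError(f"pipeline failed at stage index {failed}: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
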