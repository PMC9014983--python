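"""Synthetic cohort generator: HWE genotypes, planted age effects,
exclusion bookkeeping and the outlier rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skelstats import (
    CohortParams,
    MediationSpec,
    SkeletonSpace,
    apply_exclusions,
    effect_voxel_sets,
    generate_cohort,
    generate_genotypes,
    generate_metric_stack,
    remove_outliers,
)
from skelstats.cohort import WM_CONDITIONS


class TestGenerateCohort:
    def test_seed_reproducibility(self):
        params = CohortParams(n_subjects=60, seed=11)
        pd.testing.assert_frame_equal(generate_cohort(params), generate_cohort(params))

    def test_zero_effects_zero_noise_scores_at_ceiling(self):
        params = CohortParams(
            n_subjects=50,
            load_age_slopes=(0.0, 0.0, 0.0),
            noise_sd=0.0,
            mediation=MediationSpec(a=-0.4, b=0.0),
            seed=1,
        )
        table = generate_cohort(params)
        for cond in WM_CONDITIONS:
            assert np.all(table[cond] == params.wm_ceiling)

    def test_scores_bounded(self):
        table = generate_cohort(CohortParams(n_subjects=400, seed=2))
        for cond in WM_CONDITIONS:
            assert table[cond].between(0, 18).all()

    def test_age_drawn_from_declared_cohorts(self):
        params = CohortParams(n_subjects=300, seed=3)
        table = generate_cohort(params)
        declared = {a for a, _ in params.age_cohorts}
        assert set(table["age"]).issubset(declared)

    def test_negative_age_association_with_wm(self):
        table = generate_cohort(CohortParams(n_subjects=400, seed=4))
        r = np.corrcoef(table["age"], table["wm_manipulation"])[0, 1]
        assert r < -0.2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortParams(n_subjects=1)

    def test_large_sample_allele_frequency(self):
        params = CohortParams(n_subjects=10_000, allele_freqs=(0.47, 0.47, 0.47), seed=5)
        table = generate_cohort(params)
        freq = table["comt"].mean() / 2  # copies of the designated allele
        assert freq == pytest.approx(0.47, abs=0.02)


class TestGenerateGenotypes:
    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError, match="allele_freq"):
            generate_genotypes(100, 1.0)

    def test_expected_counts_at_study_frequency(self):
        """At p = 297/630 and n = 315, HWE expectation is (70, 157, 88)
        for (hom-designated, het, hom-other); replicate means agree."""
        p = 297 / 630
        reps = 300
        counts = np.zeros(3)
        rng = np.random.default_rng(6)
        for _ in range(reps):
            g = generate_genotypes(315, p, rng)
            counts += [(g == 2).sum(), (g == 1).sum(), (g == 0).sum()]
        counts /= reps
        assert counts == pytest.approx([70.0, 157.0, 88.0], abs=1.5)

    def test_hwe_chi_square_rejects_at_nominal_rate(self):
        """Generated genotypes are in HWE: the 1-df GOF test fires ~5%."""
        from skelstats import GenotypeCounts, hwe_test

        rng = np.random.default_rng(7)
        rejections = 0
        reps = 500
        for _ in range(reps):
            g = generate_genotypes(500, 0.4, rng)
            res = hwe_test(GenotypeCounts("x", ((g == 2).sum(), (g == 1).sum(), (g == 0).sum())))
            rejections += res.p_value < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_proportions_converge_to_hwe(self):
        g = generate_genotypes(100_000, 0.3, seed=8)
        props = np.array([(g == 2).mean(), (g == 1).mean(), (g == 0).mean()])
        assert props == pytest.approx([0.09, 0.42, 0.49], abs=0.01)


class TestMetricStack:
    @staticmethod
    def _space(v=2000, shape=(13, 13, 12)):
        mask = np.zeros(shape, bool)
        mask.ravel()[:v] = True
        return SkeletonSpace(mask=mask)

    def test_null_stack_t_calibration(self):
        """With a zero age slope, voxelwise age regressions are null."""
        spec = MediationSpec(a=0.0, b=0.0, frac_age_effect=0.0)
        params = CohortParams(n_subjects=100, mediation=spec, seed=9)
        table = generate_cohort(params)
        space = self._space()
        stack = generate_metric_stack(table, space, spec, seed=10)
        z = stats.zscore(table["age"])
        X = np.column_stack([np.ones(100), z])
        beta, *_ = np.linalg.lstsq(X, stack.data, rcond=None)
        resid = stack.data - X @ beta
        t = beta[1] / np.sqrt((resid**2).sum(axis=0) / 98 * np.linalg.inv(X.T @ X)[1, 1])
        rate = np.mean(np.abs(t) > stats.t.ppf(0.975, 98))
        assert 0.03 < rate < 0.07

    def test_planted_slope_recovered(self):
        """Standardized age slope -0.4 recovered within 0.05 averaged over
        100 effect voxels at n = 200."""
        spec = MediationSpec(a=-0.4, b=0.3, frac_age_effect=0.05, frac_mediating=0.5)
        params = CohortParams(n_subjects=200, mediation=spec, seed=11)
        table = generate_cohort(params)
        space = self._space()
        stack = generate_metric_stack(table, space, spec, seed=12)
        med, age_only = effect_voxel_sets(space, spec)
        eff = np.concatenate([med, age_only])
        assert len(eff) == 100
        z = stats.zscore(table["age"], ddof=1)
        m = stats.zscore(stack.data[:, eff], axis=0, ddof=1)
        slopes = (m.T @ z) / (z @ z)
        assert slopes.mean() == pytest.approx(-0.4, abs=0.05)

    def test_effect_sets_deterministic_noise_differs(self):
        spec = MediationSpec()
        params = CohortParams(n_subjects=50, seed=13)
        table = generate_cohort(params)
        space = self._space(500, (8, 8, 8))
        s1 = generate_metric_stack(table, space, spec, seed=1)
        s2 = generate_metric_stack(table, space, spec, seed=2)
        med1, age1 = effect_voxel_sets(space, spec)
        med2, age2 = effect_voxel_sets(space, spec)
        assert np.array_equal(med1, med2) and np.array_equal(age1, age2)
        null_cols = np.setdiff1d(np.arange(500), np.concatenate([med1, age1]))
        assert not np.allclose(s1.data[:, null_cols], s2.data[:, null_cols])

    def test_mediating_and_age_only_blocks_disjoint(self):
        med, age_only = effect_voxel_sets(self._space(), MediationSpec())
        assert len(np.intersect1d(med, age_only)) == 0

    def test_fa_range(self):
        params = CohortParams(n_subjects=80, seed=14)
        table = generate_cohort(params)
        stack = generate_metric_stack(table, self._space(500, (8, 8, 8)), params.mediation, seed=15)
        assert stack.data.min() > 0 and stack.data.max() < 1


class TestApplyExclusions:
    def test_study_scale_ledger(self):
        """372 initial minus 20 medical, 9 morphology, 3 missing DTI and
        12 artifact exclusions leaves 328."""
        rng = np.random.default_rng(16)
        table = pd.DataFrame({"subject_id": np.arange(372)})
        flags = {}
        start = 0
        for stage, count in [("medical", 20), ("morphology", 9), ("missing_dti", 3), ("artifacts", 12)]:
            f = np.zeros(372, bool)
            f[start : start + count] = True
            flags[stage] = f
            start += count
        out, ledger = apply_exclusions(table, flags)
        assert ledger.initial == 372 and ledger.final == 328 == len(out)
        assert ledger.stage_counts == {"medical": 20, "morphology": 9, "missing_dti": 3, "artifacts": 12}

    def test_no_flags_identity(self):
        table = pd.DataFrame({"subject_id": [0, 1, 2]})
        out, ledger = apply_exclusions(table, {})
        pd.testing.assert_frame_equal(out, table)
        assert ledger.stage_counts == {} and ledger.final == 3

    def test_all_flagged_empty_table(self):
        table = pd.DataFrame({"subject_id": [0, 1, 2]})
        out, ledger = apply_exclusions(table, {"s": np.ones(3, bool)})
        assert len(out) == 0 and ledger.final == 0
        assert sum(ledger.stage_counts.values()) == ledger.initial

    def test_subject_counted_at_first_stage_only(self):
        table = pd.DataFrame({"subject_id": [0, 1]})
        flags = {"first": np.array([True, False]), "second": np.array([True, True])}
        _, ledger = apply_exclusions(table, flags)
        assert ledger.stage_counts == {"first": 1, "second": 1}
        assert ledger.final == 0

    def test_undeclared_stage_rejected(self):
        table = pd.DataFrame({"subject_id": [0, 1, 2]})
        with pytest.raises(ValueError, match="undeclared"):
            apply_exclusions(table, {"ghost": np.zeros(3, bool)}, stages=["real"])


class TestRemoveOutliers:
    def test_tight_data_untouched(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(-0.5, 0.5, 50)
        y = rng.uniform(-0.5, 0.5, 50)
        xf, yf, removed = remove_outliers(x, y)
        assert removed == 0 and len(xf) == 50

    def test_planted_outlier_removed_exactly(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        x[7] = x.mean() + 5 * x.std()  # plant one gross x outlier
        xf, yf, removed = remove_outliers(x, y, k=3.5)
        assert removed == 1
        assert x[7] not in xf and y[7] not in yf

    def test_constant_vector_warns_and_keeps_all(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            xf, yf, removed = remove_outliers(np.ones(10), np.arange(10.0))
        assert removed == 0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            remove_outliers([1.0, 2.0], [1.0, 2.0])
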