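"""Hardy-Weinberg statistics, slice profiles, tract coverage, metric
overlap and demographic group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skelstats import (
    GenotypeCounts,
    SkeletonSpace,
    StatMap,
    demographic_tests,
    hwe_test,
    metric_overlap,
    slice_profile,
    tract_coverage,
)


class TestHWE:
    @pytest.mark.parametrize(
        "counts, allele, chi2, freq",
        [
            # DRD2/ANKK1-Taq1A genotype counts (GG, GA, AA); A-allele frequency
            ((208, 93, 14), "second", 0.746891, 0.192063),
            # DRD2-C957T (TT, CT, CC); T-allele frequency
            ((93, 168, 54), "first", 2.184277, 0.561905),
            # COMT Val/Met (ValVal, ValMet, MetMet); Val-allele frequency
            ((69, 159, 87), "first", 0.051860, 0.471429),
        ],
    )
    def test_study_locus_statistics(self, counts, allele, chi2, freq):
        res = hwe_test(GenotypeCounts("locus", counts), allele=allele)
        assert res.chi_square == pytest.approx(chi2, abs=1e-5)
        assert res.allele_freq == pytest.approx(freq, abs=1e-5)

    @pytest.mark.parametrize(
        "counts, allele, printed_chi2, printed_freq",
        [
            ((208, 93, 14), "second", 0.75, 0.19),
            ((93, 168, 54), "first", 2.18, 0.56),
            ((69, 159, 87), "first", 0.05, 0.47),
        ],
    )
    def test_rounds_to_published_values(self, counts, allele, printed_chi2, printed_freq):
        res = hwe_test(GenotypeCounts("locus", counts), allele=allele)
        assert round(res.chi_square, 2) == pytest.approx(printed_chi2, abs=0.005)
        assert round(res.allele_freq, 2) == pytest.approx(printed_freq, abs=0.005)

    def test_exact_hwe_proportions_give_zero(self):
        assert hwe_test(GenotypeCounts("x", (25, 50, 25))).chi_square == pytest.approx(0.0, abs=1e-12)

    def test_expected_counts_at_study_frequency(self):
        res = hwe_test(GenotypeCounts("comt", (69, 159, 87)))
        assert res.expected == pytest.approx((70.0, 157.0, 88.0), abs=0.05)

    def test_invariant_under_homozygote_swap(self):
        a = hwe_test(GenotypeCounts("x", (30, 44, 26)))
        b = hwe_test(GenotypeCounts("x", (26, 44, 30)))
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_zero_iff_counts_match_expectation(self):
        res = hwe_test(GenotypeCounts("x", (30, 44, 26)))
        assert res.chi_square > 0  # observed != HWE expectation here

    def test_monomorphic_counts_rejected(self):
        with pytest.raises(ValueError, match="zero expected"):
            hwe_test(GenotypeCounts("x", (50, 0, 0)))


class TestSliceProfile:
    @staticmethod
    def _map(space, values):
        return StatMap(np.asarray(values, float), "t", space)

    def test_constant_map(self, flat_space):
        prof = slice_profile(self._map(flat_space, np.full(flat_space.n_columns, 2.5)), axis=0)
        defined = ~np.isnan(prof.means)
        assert np.allclose(prof.means[defined], 2.5)
        assert len(prof.means) == flat_space.shape[0]

    def test_two_slice_enumeration(self):
        # slice 0 holds {1, 2}, slice 1 holds {3}
        mask = np.zeros((2, 1, 2), bool)
        mask[0, 0, :] = True
        mask[1, 0, 0] = True
        space = SkeletonSpace(mask=mask)
        prof = slice_profile(self._map(space, [1.0, 2.0, 3.0]), axis=0)
        assert prof.means == pytest.approx([1.5, 3.0])
        assert list(prof.counts) == [2, 1]

    def test_permuting_within_slice_invariant(self, flat_space):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(flat_space.n_columns)
        prof1 = slice_profile(self._map(flat_space, vals), axis=0)
        # shuffle columns within each slice of axis 0
        idx = flat_space.column_to_voxel(np.arange(flat_space.n_columns))[:, 0]
        shuffled = vals.copy()
        for s in np.unique(idx):
            cols = np.flatnonzero(idx == s)
            shuffled[cols] = shuffled[rng.permutation(cols)]
        prof2 = slice_profile(self._map(flat_space, shuffled), axis=0)
        assert np.allclose(prof1.means, prof2.means, equal_nan=True)

    def test_named_axes_and_invalid_axis(self, flat_space):
        m = self._map(flat_space, np.zeros(flat_space.n_columns))
        assert slice_profile(m, "anterior-posterior").axis == 1
        with pytest.raises(ValueError, match="axis"):
            slice_profile(m, "diagonal")


class TestTractCoverage:
    @staticmethod
    def _space(v=20, n_tracts=2):
        mask = np.zeros((1, 1, v), bool)
        mask[..., :v] = True
        labels = 1 + (np.arange(v) * n_tracts) // v
        return SkeletonSpace(mask=mask, tract_labels=labels,
                             tract_names={i: f"t{i}" for i in range(1, n_tracts + 1)})

    def test_full_skeleton_significant(self):
        space = self._space()
        cov = tract_coverage(np.ones(20, bool), space)
        assert np.allclose(cov["percent"], 100.0)

    def test_empty_set(self):
        cov = tract_coverage(np.zeros(20, bool), self._space())
        assert np.allclose(cov["percent"], 0.0)

    def test_enumerated_fraction(self):
        space = self._space(v=20, n_tracts=2)
        sig = np.zeros(20, bool)
        sig[:3] = True  # 3 of tract 1's 10 voxels
        cov = tract_coverage(sig, space).set_index("tract")
        assert cov.loc["t1", "percent"] == pytest.approx(30.0)
        assert cov.loc["t2", "percent"] == pytest.approx(0.0)
        assert cov.loc["whole-skeleton", "percent"] == pytest.approx(15.0)

    def test_whole_skeleton_is_weighted_mean_of_tracts(self):
        rng = np.random.default_rng(1)
        space = self._space(v=20, n_tracts=2)
        sig = rng.random(20) < 0.4
        cov = tract_coverage(sig, space).set_index("tract")
        weighted = (
            cov.loc[["t1", "t2"], "percent"] * cov.loc[["t1", "t2"], "n_voxels"]
        ).sum() / 20
        assert cov.loc["whole-skeleton", "percent"] == pytest.approx(weighted)

    def test_unlabeled_space_rejected(self, flat_space):
        with pytest.raises(ValueError, match="labels"):
            tract_coverage(np.zeros(flat_space.n_columns, bool), flat_space)


class TestMetricOverlap:
    def test_identical_maps_single_cell(self):
        p = np.ones(50)
        p[:10] = 0.01
        out = metric_overlap({"FA": p, "MD": p, "RD": p, "AD": p})
        assert out == {"FA+MD+RD+AD": pytest.approx(1.0)}

    def test_disjoint_sets_share_by_size(self):
        fa = np.ones(100)
        md = np.ones(100)
        fa[:30] = 0.01
        md[30:40] = 0.01
        out = metric_overlap({"FA": fa, "MD": md})
        assert out["FA"] == pytest.approx(0.75)
        assert out["MD"] == pytest.approx(0.25)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        maps = {m: rng.random(200) for m in ("FA", "MD", "RD", "AD")}
        out = metric_overlap(maps, alpha=0.3)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError, match="share"):
            metric_overlap({"FA": np.ones(10), "MD": np.ones(12)})


class TestDemographicTests:
    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"g": np.repeat([0, 1], 30), "age": rng.uniform(25, 80, 60)})
        out = demographic_tests(table, "g", ["age"], sex_col=None)
        t, _ = stats.ttest_ind(
            table.loc[table.g == 0, "age"], table.loc[table.g == 1, "age"]
        )
        assert out.loc[0, "statistic"] == pytest.approx(t**2, rel=1e-10)

    def test_sex_chi_square_matches_textbook_formula(self):
        table = pd.DataFrame(
            {
                "g": [0] * 30 + [1] * 40 + [2] * 30,
                "sex": [0] * 20 + [1] * 10 + [0] * 15 + [1] * 25 + [0] * 10 + [1] * 20,
                "age": 50.0,
            }
        )
        out = demographic_tests(table, "g", [], sex_col="sex").set_index("variable")
        ct = pd.crosstab(table["sex"], table["g"]).to_numpy().astype(float)
        exp = ct.sum(1)[:, None] * ct.sum(0)[None, :] / ct.sum()
        chi2 = ((ct - exp) ** 2 / exp).sum()
        assert out.loc["sex", "statistic"] == pytest.approx(chi2, rel=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 300
        for _ in range(reps):
            table = pd.DataFrame(
                {"g": np.repeat([0, 1, 2], 40), "v": rng.standard_normal(120)}
            )
            out = demographic_tests(table, "g", ["v"], sex_col=None)
            rejections += out.loc[0, "p_value"] < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_single_group_rejected(self):
        table = pd.DataFrame({"g": [0, 0, 0], "age": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="2 groups"):
            demographic_tests(table, "g", ["age"])
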