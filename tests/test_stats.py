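"""Group-comparison statistics, normality gating, and Bonferroni handling."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from thalmod.stats import (
    StatResult,
    anova_from_summary,
    auto_two_sample,
    bonferroni,
    chi_square,
    classify_moca,
    kruskal_wallis,
    ks_normality,
    mann_whitney_u,
    metric_moca_correlation,
    one_way_anova,
    run_table1,
    student_t,
    student_t_from_summary,
)


class TestMocaClassification:
    @pytest.mark.parametrize("score, expected", [(25, "CI"), (26, "CN"), (30, "CN"), (0, "CI")])
    def test_cutoff(self, score, expected):
        assert classify_moca(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_moca(31)


class TestNormalityGate:
    def test_normal_sample_passes(self, rng):
        _, is_normal = ks_normality(rng.standard_normal(500))
        assert is_normal

    def test_exponential_sample_fails(self, rng):
        _, is_normal = ks_normality(rng.exponential(size=500))
        assert not is_normal

    def test_constant_sample_flagged(self):
        res, is_normal = ks_normality(np.full(20, 3.0))
        assert not is_normal and res.p_value == 0.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0]))


class TestStudentT:
    def test_identical_groups_give_zero(self, rng):
        x = rng.standard_normal(20)
        assert student_t(x, x).statistic == pytest.approx(0.0)

    def test_summary_agrees_with_raw(self, rng):
        g1, g2 = rng.standard_normal(18) + 0.5, rng.standard_normal(35)
        raw = student_t(g1, g2)
        summ = student_t_from_summary(
            g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size
        )
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-10)

    def test_matches_textbook_pooled_formula(self, rng):
        g1, g2 = rng.standard_normal(12), rng.standard_normal(15) + 1
        res = student_t(g1, g2)
        sp2 = ((g1.size - 1) * g1.var(ddof=1) + (g2.size - 1) * g2.var(ddof=1)) / (
            g1.size + g2.size - 2
        )
        t_oracle = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / g1.size + 1 / g2.size))
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            student_t(np.full(5, 1.0), np.full(5, 2.0))


class TestAnova:
    def test_two_groups_equals_t_squared(self, rng):
        g1, g2 = rng.standard_normal(10), rng.standard_normal(12) + 0.3
        f = one_way_anova(g1, g2).statistic
        t = student_t(g1, g2).statistic
        assert f == pytest.approx(t**2, abs=1e-10)

    def test_summary_agrees_with_raw(self, rng):
        groups = [rng.standard_normal(n) + d for n, d in [(18, 0), (35, 0.5), (37, 1)]]
        raw = one_way_anova(*groups)
        summ = anova_from_summary([(g.mean(), g.std(ddof=1), g.size) for g in groups])
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-10)

    def test_degenerate_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(np.full(5, 1.0), np.full(5, 1.0))
        with pytest.raises(ValueError):
            one_way_anova(np.ones(3))


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12, 13], method="asymptotic")
        assert res.extra["U"] == 0.0
        assert res.statistic < 0

    def test_interleaved_groups_are_null(self):
        g1, g2 = [1, 3, 5, 7], [2, 4, 6, 8]
        res = mann_whitney_u(g1, g2, method="asymptotic")
        assert abs(res.statistic) < 1.0
        assert res.extra["U"] == pytest.approx(4 * 4 / 2, abs=2)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        g1 = rng.standard_normal(4)
        g2 = rng.standard_normal(5) + 0.8
        res = mann_whitney_u(g1, g2)  # auto -> exact for n <= 10
        pooled = np.concatenate([g1, g2])
        n1 = g1.size

        def u_stat(idx):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(pooled.size) if i not in idx]]
            return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

        u_obs = u_stat(range(n1))
        mu = n1 * g2.size / 2
        count = total = 0
        for idx in itertools.combinations(range(pooled.size), n1):
            total += 1
            if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_near_zero(self):
        res = kruskal_wallis([1.0, 2, 3, 4], [1.5, 2.5, 3.5], [1.2, 2.2, 3.2],
                             method="asymptotic")
        assert res.statistic < 1.0

    def test_statistic_matches_scipy(self, rng):
        groups = [rng.standard_normal(8), rng.standard_normal(9) + 0.5, rng.standard_normal(7)]
        res = kruskal_wallis(*groups, method="asymptotic")
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_two_group_direction_consistent_with_mann_whitney(self, rng):
        g1 = rng.standard_normal(12)
        g2 = rng.standard_normal(12) + 1.5
        kw = kruskal_wallis(g1, g2, method="asymptotic")
        mw = mann_whitney_u(g1, g2, method="asymptotic")
        assert kw.statistic == pytest.approx(mw.statistic**2, abs=1e-8)

    def test_exact_p_matches_permutation_oracle(self, rng):
        groups = [rng.standard_normal(3), rng.standard_normal(2) + 1, rng.standard_normal(2)]
        res = kruskal_wallis(*groups)  # auto -> exact, n = 7
        pooled = np.concatenate(groups)
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        for perm in itertools.permutations(range(7)):
            parts = [pooled[list(perm[:3])], pooled[list(perm[3:5])], pooled[list(perm[5:])]]
            total += 1
            if sps.kruskal(*parts).statistic >= h_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-9)


class TestChiSquare:
    def test_table_equal_to_expected_gives_zero(self):
        assert chi_square([[10, 20], [20, 40]]).statistic == pytest.approx(0.0)

    def test_matches_exact_rational_expansion(self, rng):
        for _ in range(20):
            table = rng.integers(1, 30, size=(2, rng.integers(2, 4)))
            res = chi_square(table)
            t = [[Fraction(int(x)) for x in row] for row in table]
            total = sum(sum(row) for row in t)
            rows = [sum(row) for row in t]
            cols = [sum(t[r][c] for r in range(len(t))) for c in range(len(t[0]))]
            chi2 = sum(
                (t[r][c] - rows[r] * cols[c] / total) ** 2 / (rows[r] * cols[c] / total)
                for r in range(len(t))
                for c in range(len(t[0]))
            )
            assert res.statistic == pytest.approx(float(chi2), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 3]])


class TestBonferroni:
    def test_arithmetic(self):
        fam = [StatResult("t", 1.0, p) for p in (0.01, 0.001, 0.2)]
        out = bonferroni(fam, family_id="demo")
        assert out[0].corrected_p == pytest.approx(0.03)
        assert out[2].corrected_p == pytest.approx(0.6)
        assert all(r.family_id == "demo" for r in out)

    def test_single_member_identity(self):
        out = bonferroni([StatResult("t", 1.0, 0.04)])
        assert out[0].corrected_p == pytest.approx(0.04)

    def test_monotone_in_family_size(self):
        p = 0.01
        prev = 0.0
        for m in range(1, 30):
            fam = [StatResult("t", 1.0, p)] * m
            corrected = bonferroni(fam)[0].corrected_p
            assert corrected >= prev
            prev = corrected

    def test_capped_at_one(self):
        out = bonferroni([StatResult("t", 1.0, 0.3)] * 10)
        assert out[0].corrected_p == 1.0


class TestCorrelation:
    def test_perfect_linear_relation(self, rng):
        moca = rng.normal(24, 2, size=30)
        res = metric_moca_correlation(2 * moca + 1, moca)
        assert res.statistic == pytest.approx(1.0)

    def test_skewed_metric_switches_to_spearman(self, rng):
        moca = rng.normal(24, 2, size=400)
        metric = rng.exponential(size=400) ** 3
        res = metric_moca_correlation(metric, moca)
        assert res.test_name == "spearman_rho"

    def test_constant_metric_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            metric_moca_correlation(np.full(10, 1.0), rng.normal(24, 2, size=10))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.standard_normal(18), rng.standard_normal(18)
            if sps.pearsonr(x, y).pvalue < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.02)


class TestTable1Battery:
    def test_schema_complete_on_synthetic_cohort(self, tiny_cohort):
        report = run_table1(tiny_cohort.phenotypes())
        cells = set(zip(report.variable, report.comparison))
        for var in ("age", "education", "moca", "sex"):
            assert (var, "3-group") in cells
            assert (var, "TLE-vs-HC") in cells
        for var in ("onset_age", "duration", "seizure_freq", "aed"):
            assert (var, "CI-vs-CN") in cells
        assert report.p_value.between(0, 1).all()

    def test_missing_columns_listed(self, tiny_cohort):
        pheno = tiny_cohort.phenotypes().drop(columns=["moca", "aed"])
        with pytest.raises(ValueError, match="moca"):
            run_table1(pheno)

    def test_group_permutation_destroys_moca_effect(self):
        # a real group effect (HC/CN vs CI scores) vanishes under label permutation
        from thalmod.cohort import default_cohort_spec, generate_cohort

        spec = default_cohort_spec(seed=21)
        spec.n_per_group = {"HC": 12, "TLE-CN": 12, "TLE-CI": 12}
        spec.n_timepoints = 60
        spec.n_parcels = 14
        spec.partition = None
        spec.__post_init__()
        spec.thal_grid = (2, 2, 2)
        moca = generate_cohort(spec).phenotypes().moca.to_numpy(dtype=float)
        groups = np.repeat([0, 1, 2], 12)
        assert one_way_anova(*(moca[groups == g] for g in range(3))).p_value < 0.001
        rng = np.random.default_rng(5)
        significant = 0
        for _ in range(100):
            perm = rng.permutation(groups)
            f = one_way_anova(*(moca[perm == g] for g in range(3)))
            significant += f.p_value < 0.05
        assert significant <= 15  # effect destroyed in >= 85% of permutations


def test_auto_two_sample_gates_on_normality(rng):
    normal1, normal2 = rng.standard_normal(40), rng.standard_normal(40) + 0.5
    assert auto_two_sample(normal1, normal2).test_name == "student_t"
    skewed = rng.exponential(size=400) ** 3
    assert auto_two_sample(skewed, rng.exponential(size=400) ** 3).test_name == "mann_whitney_u"
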