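import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import metabotype as mt
from metabotype.comorbidity_stats import fit_logistic, group_compare
from metabotype.exceptions import ConfigError, DegenerateTableError, TransformError
from metabotype.subtype_clustering import Partition


def two_by_two(a, b, c, d):
    """Design/outcome for an exposed(a cases, b controls) / unexposed(c, d) table."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, pd.DataFrame({"exposed": x})


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        y, X = two_by_two(30, 70, 10, 90)
        fit = fit_logistic(y, X)
        beta = fit.coef[fit.names.index("exposed")]
        assert math.exp(beta) == pytest.approx((30 * 90) / (70 * 10), abs=1e-6)

    def test_intercept_is_log_odds_of_prevalence(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.coef[0] == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_null_association_ci_covers_one_at_nominal_rate(self):
        covered = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            y = rng.integers(0, 2, size=300).astype(float)
            X = pd.DataFrame({"g": rng.integers(0, 2, size=300).astype(float)})
            fit = fit_logistic(y, X)
            j = fit.names.index("g")
            lo = fit.coef[j] - 1.96 * fit.se()[j]
            hi = fit.coef[j] + 1.96 * fit.se()[j]
            covered += lo <= 0.0 <= hi
        assert covered >= 24  # ~95% nominal over 30 replicates

    def test_separation_flagged_not_raised(self):
        y, X = two_by_two(50, 0, 0, 50)  # perfect separation
        fit = fit_logistic(y, X)
        assert fit.separation

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ConfigError):
            fit_logistic(np.array([0.0, 1.0, 2.0]), pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


@pytest.fixture(scope="module")
def cohort_truth_partition():
    cfg = mt.SyntheticConfig(n=800)
    cohort, truth = mt.generate_cohort(cfg, seed=17)
    ids = tuple(r.patient_id for r in cohort)
    part = Partition(ids, tuple(truth.subtype[i] for i in ids),
                     tuple(r.sex for r in cohort))
    return cohort, truth, part


class TestAorTable:

    def test_reference_subtype_aor_is_one(self, cohort_truth_partition):
        cohort, _, part = cohort_truth_partition
        res = mt.aor_table(cohort, part, comorbidities=["diabetes"])
        mho = [r for r in res if r.subtype == "MHO"][0]
        assert mho.aor == 1.0 and mho.ci_low == 1.0 and mho.ci_high == 1.0

    def test_generating_log_odds_recovered_within_ci(self, cohort_truth_partition):
        cohort, truth, part = cohort_truth_partition
        res = mt.aor_table(cohort, part)
        covered = total = 0
        for r in res:
            if r.subtype == "MHO":
                continue
            true_aor = math.exp(
                truth.config.comorbidity_spec[r.comorbidity].subtype_shift[r.subtype])
            total += 1
            covered += r.ci_low <= true_aor <= r.ci_high
        assert covered / total >= 0.75  # single replicate; nominal 95% per cell

    def test_large_lmo_diabetes_effect_direction(self, cohort_truth_partition):
        cohort, _, part = cohort_truth_partition
        res = mt.aor_table(cohort, part, comorbidities=["diabetes"])
        lmo = [r for r in res if r.subtype == "LMO"][0]
        assert lmo.aor > 10.0 and lmo.ci_low > 1.0

    def test_zero_cases_in_subtype_propagates_separation_flag(self, make_record):
        records = []
        for i in range(120):
            subtype_case = i % 2 == 0
            rec = make_record(pid=f"p{i}", sex="male" if i % 4 < 2 else "female",
                              comorbidities={"x": "present" if subtype_case and i < 40
                                             else "absent"})
            records.append(rec)
        cohort = mt.CohortTable(records=records)
        labels = tuple("MHO" if i < 40 else ("LMO" if i < 80 else "HMO-U")
                       for i in range(120))
        part = Partition(tuple(r.patient_id for r in records), labels,
                         tuple(r.sex for r in records))
        res = mt.aor_table(cohort, part, comorbidities=["x"])
        assert any(r.separation for r in res if r.subtype != "MHO")


class TestChiSquare:
    def test_hand_worked_2x2(self):
        stat, p = mt.chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        assert p == pytest.approx(sps.chi2.sf(20 / 3, df=1))

    def test_proportional_table_is_null(self):
        stat, p = mt.chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 8]])
        s1, _ = mt.chi_square(t)
        s2, _ = mt.chi_square(t[:, [2, 0, 1]])
        s3, _ = mt.chi_square(t[[1, 0]])
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            mt.chi_square([[0, 0], [5, 10]])


class TestGroupCompare:
    def test_identical_groups_yield_null_omnibus(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        res = group_compare(vals, groups)
        assert res.omnibus_f == pytest.approx(0.0, abs=1e-20)
        assert res.omnibus_p == pytest.approx(1.0)

    def test_f_statistic_matches_scipy_anova(self, rng):
        groups = np.repeat(["a", "b", "c"], 15)
        vals = rng.normal(size=45) + np.repeat([0.0, 0.5, 1.0], 15)
        res = group_compare(vals, groups)
        f, p = sps.f_oneway(vals[:15], vals[15:30], vals[30:])
        assert res.omnibus_f == pytest.approx(f, rel=1e-9)
        assert res.omnibus_p == pytest.approx(p, rel=1e-9)

    def test_bonferroni_is_capped_raw_times_pair_count(self, rng):
        groups = np.repeat(["a", "b", "c", "d"], 12)
        vals = rng.normal(size=48) + np.repeat([0.0, 0.2, 1.5, 0.1], 12)
        res = group_compare(vals, groups)
        assert len(res.pairwise_p) == 6
        for (a, b), adj in res.pairwise_p.items():
            ga = vals[groups == a]
            gb = vals[groups == b]
            raw = sps.ttest_ind(ga, gb, equal_var=True).pvalue
            assert adj == pytest.approx(min(1.0, raw * 6), rel=1e-6)

    def test_ancova_adjusts_for_covariate(self, rng):
        # group effect entirely mediated by the covariate vanishes under ANCOVA
        groups = np.repeat(["a", "b"], 40)
        cov = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
        vals = 2.0 * cov + rng.normal(0, 0.1, 80)
        plain = group_compare(vals, groups)
        adjusted = group_compare(vals, groups, covariates=pd.DataFrame({"c": cov}))
        assert plain.omnibus_p < 1e-6
        assert adjusted.omnibus_p > 0.01

    def test_log_transform_rejects_nonpositive_rows(self):
        vals = np.array([1.0, -1.0, 2.0, 3.0])
        groups = np.array(["a", "a", "b", "b"])
        with pytest.raises(TransformError, match="1"):
            group_compare(vals, groups, transform="log")

    def test_sqrt_transform_applied(self, rng):
        vals = np.abs(rng.normal(size=20)) + 0.1
        groups = np.repeat(["a", "b"], 10)
        res = group_compare(vals, groups, transform="sqrt")
        f, _ = sps.f_oneway(np.sqrt(vals[:10]), np.sqrt(vals[10:]))
        assert res.omnibus_f == pytest.approx(f, rel=1e-9)
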