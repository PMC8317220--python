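import itertools

import numpy as np
import pytest

import metabotype as mt
from metabotype.exceptions import (
    ConfigError,
    DegenerateVariableError,
    LabelingError,
    SizeError,
    StratumError,
)
from metabotype.subtype_clustering import SUBTYPE_ORDER, twostep_cluster

MALE_T2 = np.array([[993, 17089, 405], [982, 19951, 585], [1008, 50543, 489],
                    [1845, 9477, 404]], dtype=float)
FEMALE_T2 = np.array([[928, 12894, 331], [1100, 21895, 454], [1094, 54645, 392],
                      [1829, 9320, 356]], dtype=float)


def blobs(rng, centers, n_per, scale=0.1):
    pts = np.vstack([c + rng.normal(scale=scale, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestZScore:
    def test_two_point_hand_case_sample_sd(self):
        params = mt.zscore_fit(np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]))
        assert params.mean == pytest.approx([2.0, 2.0, 2.0])
        z = mt.zscore_apply(params, np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]))
        assert np.allclose(z, [[-2 ** -0.5] * 3, [2 ** -0.5] * 3])

    def test_fit_then_apply_centers_the_data(self, rng):
        X = rng.normal(5.0, 2.0, size=(50, 3))
        z = mt.zscore_apply(mt.zscore_fit(X), X)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert z.std(axis=0, ddof=1) == pytest.approx(np.ones(3))

    def test_roundtrip_invertible(self, rng):
        from metabotype.subtype_clustering import zscore_invert

        X = rng.normal(size=(20, 3)) * [100, 5000, 50] + [1000, 20000, 400]
        params = mt.zscore_fit(X)
        assert zscore_invert(params, mt.zscore_apply(params, X)) == pytest.approx(X)

    def test_degenerate_variable_rejected(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 4.0, 5.0], [1.0, 6.0, 7.0]])
        with pytest.raises(DegenerateVariableError):
            mt.zscore_fit(X)


class TestKMeans:
    def test_recovers_well_separated_blobs(self, rng):
        centers = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
        X, _ = blobs(rng, centers, 50)
        res = mt.kmeans_cluster(X, 4, seed=0)
        found = res.centers[np.lexsort(res.centers.T[::-1])]
        want = centers[np.lexsort(centers.T[::-1])]
        se = 0.1 / np.sqrt(50)
        assert np.abs(found - want).max() < 3 * se

    def test_k1_disallowed_and_k_equals_n(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ConfigError):
            mt.kmeans_cluster(X, 1)
        res = mt.kmeans_cluster(X, 6, seed=0)
        assert res.wcss == pytest.approx(0.0, abs=1e-20)

    def test_more_clusters_than_points_raises(self, rng):
        with pytest.raises(SizeError):
            mt.kmeans_cluster(rng.normal(size=(3, 2)), 4)

    def test_wcss_equals_exhaustive_optimum_tiny_instance(self, rng):
        """Restarted Lloyd must reach the global optimum enumerable at n=8."""
        X = rng.normal(size=(8, 2))
        res = mt.kmeans_cluster(X, 2, seed=3)
        best = np.inf
        for assignment in itertools.product((0, 1), repeat=8):
            a = np.array(assignment)
            if len(set(assignment)) < 2:
                continue
            wcss = sum(((X[a == j] - X[a == j].mean(axis=0)) ** 2).sum() for j in (0, 1))
            best = min(best, wcss)
        assert res.wcss == pytest.approx(best, rel=1e-10)


def _silhouette_oracle(X, labels):
    # direct per-point evaluation of (b - a) / max(a, b)
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestSilhouette:
    def test_matches_hand_oracle_on_small_instance(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 1, 1, 1, 0])
        assert mt.mean_silhouette(X, labels) == pytest.approx(
            _silhouette_oracle(X, labels), rel=1e-12)

    def test_matches_sklearn_on_blobs(self, rng):
        from sklearn.metrics import silhouette_score

        X, labels = blobs(rng, np.array([[0.0, 0.0], [3.0, 0.0]]), 30, scale=0.5)
        assert mt.mean_silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), rel=1e-10)

    def test_separated_tight_blobs_approach_one(self, rng):
        X, labels = blobs(rng, np.array([[0.0, 0.0], [1e6, 0.0]]), 20, scale=0.01)
        assert mt.mean_silhouette(X, labels) > 0.999

    def test_random_labels_on_one_blob_near_zero(self, rng):
        X = rng.normal(size=(500, 3))
        labels = rng.integers(0, 2, size=500)
        assert abs(mt.mean_silhouette(X, labels)) < 0.05

    def test_single_cluster_undefined(self, rng):
        with pytest.raises(ConfigError):
            mt.mean_silhouette(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestSelectK:
    def test_two_blobs_select_two(self, rng):
        X, _ = blobs(rng, np.array([[0.0, 0.0], [6.0, 0.0]]), 40, scale=0.5)
        k, sils = mt.select_k(X, range(2, 6), seed=0)
        assert k == 2

    def test_single_blob_reports_low_silhouette(self, rng):
        X = rng.normal(size=(150, 3))
        k, sils = mt.select_k(X, range(2, 5), seed=0)
        assert sils[k] < 0.4  # callers can flag "no structure"


class TestTwoStep:
    def test_two_blobs_k2_identical_to_kmeans(self, rng):
        X, _ = blobs(rng, np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]), 30, scale=0.3)
        res = twostep_cluster(X, max_k=6)
        assert res.k == 2
        km = mt.kmeans_cluster(X, 2, seed=0)
        # same bipartition up to label names
        a = res.labels == res.labels[0]
        b = km.labels == km.labels[0]
        assert np.array_equal(a, b)

    def test_merge_sequence_equals_bruteforce_greedy(self, rng):
        """Exact agglomeration from singletons, cross-checked against a naive
        recompute-everything greedy implementation at n=10."""
        X = rng.normal(size=(10, 3))
        overall = X.var(axis=0)

        def xi(members):
            sub = X[list(members)]
            return -len(members) * 0.5 * np.log(overall + sub.var(axis=0, ddof=0)).sum()

        clusters = [frozenset([i]) for i in range(10)]
        oracle_seq = []
        while len(clusters) > 1:
            best, pair = np.inf, None
            for a, b in itertools.combinations(clusters, 2):
                d = xi(a) + xi(b) - xi(a | b)
                if d < best:
                    best, pair = d, (a, b)
            oracle_seq.append({pair[0], pair[1]})
            clusters = [c for c in clusters if c not in pair] + [pair[0] | pair[1]]

        res = twostep_cluster(X, max_k=8)
        got_seq = [{frozenset(a), frozenset(b)} for a, b in res.merge_sequence]
        assert got_seq == oracle_seq

    def test_too_small_instance_raises(self, rng):
        with pytest.raises(SizeError):
            twostep_cluster(rng.normal(size=(3, 2)))

    def test_generator_cohort_k4_and_agrees_with_kmeans(self):
        cfg = mt.SyntheticConfig(n=250)
        cohort, _ = mt.generate_cohort(cfg, seed=11)
        km = mt.fit_sex_stratified(cohort, "kmeans", seed=11)
        ts = mt.fit_sex_stratified(cohort, "twostep", seed=11)
        assert ts.model.k == 4
        report = mt.agreement_report(km.partition, ts.partition)
        assert report.mean_jaccard >= 0.9


class TestLabelSubtypes:
    @pytest.mark.parametrize("centers", [MALE_T2, FEMALE_T2], ids=["men", "women"])
    def test_published_centers_get_canonical_names(self, centers):
        assert mt.label_subtypes(centers) == ["MHO", "HMO-U", "HMO-I", "LMO"]

    def test_order_invariance(self, rng):
        for _ in range(10):
            perm = rng.permutation(4)
            labels = mt.label_subtypes(MALE_T2[perm])
            assert [labels[list(perm).index(i)] for i in range(4)] == [
                "MHO", "HMO-U", "HMO-I", "LMO"]

    def test_tie_in_deciding_variable_rejected(self):
        centers = MALE_T2.copy()
        centers[0, 0] = centers[3, 0]  # tie for max glucose AUC
        with pytest.raises(LabelingError):
            mt.label_subtypes(centers)

    def test_wrong_center_count_rejected(self):
        with pytest.raises(LabelingError):
            mt.label_subtypes(MALE_T2[:3])


class TestFitSexStratified:
    def test_model_reproduces_published_geometry(self, main_fit, main_cohort):
        cohort, truth = main_cohort
        model = main_fit.model
        assert model.k == 4
        assert model.labels == SUBTYPE_ORDER
        for sex, published in (("male", MALE_T2), ("female", FEMALE_T2)):
            sm = model.strata[sex]
            n_sex = {s: sum(1 for r in cohort if r.sex == sex
                            and truth.subtype[r.patient_id] == s)
                     for s in SUBTYPE_ORDER}
            sds = np.array(truth.config.feature_sds)
            for i, s in enumerate(SUBTYPE_ORDER):
                se = sds / np.sqrt(n_sex[s])
                assert np.all(np.abs(sm.centers_raw[i] - published[i]) < 3 * se)

    def test_normalization_roundtrip_on_centers(self, main_fit):
        from metabotype.subtype_clustering import zscore_invert

        for sm in main_fit.model.strata.values():
            z = sm.centers_normalized()
            assert zscore_invert(sm.normalization, z) == pytest.approx(
                sm.centers_raw, abs=1e-10)

    def test_record_order_invariance_with_fixed_seed(self):
        cfg = mt.SyntheticConfig(n=120)
        cohort, _ = mt.generate_cohort(cfg, seed=13)
        shuffled = mt.CohortTable(records=list(reversed(cohort.records)))
        f1 = mt.fit_sex_stratified(cohort, seed=13)
        f2 = mt.fit_sex_stratified(shuffled, seed=13)
        assert f1.partition.label_of() == f2.partition.label_of()
        for sex in ("male", "female"):
            assert np.array_equal(f1.model.strata[sex].centers_raw,
                                  f2.model.strata[sex].centers_raw)

    def test_single_sex_cohort_rejected(self):
        cfg = mt.SyntheticConfig(n=60, sex_ratio=1.0)
        cohort, _ = mt.generate_cohort(cfg, seed=2)
        with pytest.raises(StratumError):
            mt.fit_sex_stratified(cohort, seed=2)

    def test_fixed_k_pins_cluster_count(self):
        cfg = mt.SyntheticConfig(n=150)
        cohort, _ = mt.generate_cohort(cfg, seed=4)
        fit = mt.fit_sex_stratified(
            cohort, config=mt.ClusterConfig(fixed_k=3), seed=4)
        assert fit.model.k == 3
        assert fit.model.labels == ("C1", "C2", "C3")

    def test_pooled_normalization_option(self):
        cfg = mt.SyntheticConfig(n=150)
        cohort, _ = mt.generate_cohort(cfg, seed=4)
        fit = mt.fit_sex_stratified(
            cohort, config=mt.ClusterConfig(pooled_normalization=True), seed=4)
        male, female = (fit.model.strata[s].normalization for s in ("male", "female"))
        assert male.mean == pytest.approx(female.mean)
        assert fit.model.k == 4
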