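"""PheWAS rollup, prevalence filter, silhouette-selected k-means,
cluster profiling, and 2-D embedding."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import ehrpheno as e
from ehrpheno.core_io import ValidationError

from conftest import make_patient


def binary_matrix(X, prefix="c"):
    X = np.asarray(X, dtype=float)
    return e.PhewasMatrix(
        patient_ids=[f"p{i}" for i in range(X.shape[0])],
        categories=[f"{prefix}{j}" for j in range(X.shape[1])],
        X=X,
    )


def brute_force_silhouette(X, labels):
    """Mean of (b - a) / max(a, b) straight from the definition."""
    n = len(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels)
            if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestPhewasRollup:
    def test_multiple_codes_one_category_gives_indicator_one(self, phewas_map):
        p = make_patient(icd9=("345.0", "345.1"))  # both map to epilepsy
        m = e.map_to_phewas([p], phewas_map)
        assert m.X[0, m.categories.index("epilepsy")] == 1.0
        assert m.X.sum() == 1.0

    def test_unmapped_codes_give_zero_vector(self, phewas_map):
        m = e.map_to_phewas([make_patient(icd9=("999.99",))], phewas_map)
        assert m.X.sum() == 0.0

    def test_category_universe_fixed_across_cohort(self, phewas_map):
        pats = [
            make_patient(pid="a", icd9=("345.0",)),
            make_patient(pid="b", icd9=("311",)),
        ]
        m = e.map_to_phewas(pats, phewas_map)
        assert m.categories == sorted(set(phewas_map.values()))

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            e.map_to_phewas([make_patient()], {})


class TestPrevalenceFilter:
    def test_boundary_below_removed_at_kept(self):
        X = np.zeros((1000, 2))
        X[:4, 0] = 1  # 0.4% -> removed at 0.5% threshold
        X[:5, 1] = 1  # exactly 0.5% -> retained
        kept = e.filter_prevalence(binary_matrix(X), 0.005)
        assert kept.categories == ["c1"]

    def test_zero_threshold_rejected_identity_via_tiny(self):
        X = np.eye(3)
        kept = e.filter_prevalence(binary_matrix(X), 1e-9)
        assert kept.categories == ["c0", "c1", "c2"]

    def test_all_columns_removed_is_error(self):
        X = np.zeros((10, 2))
        X[0, 0] = 1
        with pytest.raises(ValidationError, match="threshold"):
            e.filter_prevalence(binary_matrix(X), 0.5)

    def test_output_columns_satisfy_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = (rng.random((50, 12)) < rng.random(12) * 0.3).astype(float)
            thr = float(rng.uniform(0.01, 0.3))
            try:
                kept = e.filter_prevalence(binary_matrix(X), thr)
            except ValidationError:
                continue
            assert (kept.prevalence() >= thr).all()


class TestClusterSelectK:
    def test_two_blobs_select_k2(self):
        X = np.zeros((200, 10))
        X[:100, :5] = 1.0
        X[100:, 5:] = 1.0
        res = e.cluster_select_k(
            binary_matrix(X),
            e.ClusterConfig(k_range=tuple(range(2, 8)), seed=11),
        )
        assert res.k == 2
        assert res.silhouette == pytest.approx(1.0)

    def test_four_point_silhouette_hand_value(self):
        # two pairs separated by 10: s = 1 - 1/mean(10, sqrt(101))
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        m = e.PhewasMatrix(
            patient_ids=list("abcd"),
            categories=["x", "y"],
            X=(X > 0).astype(float),  # placeholder to satisfy binary check
        )
        m.X = X  # silhouette itself is metric-agnostic
        res = e.cluster_select_k(
            m, e.ClusterConfig(k_range=(2,), seed=0)
        )
        expected = 1 - 1 / np.mean([10.0, np.sqrt(101)])
        assert res.silhouette == pytest.approx(expected, abs=1e-6)
        assert res.silhouette == pytest.approx(0.900, abs=1e-3)

    def test_silhouette_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            X = (rng.random((30, 6)) < 0.4).astype(float)
            m = binary_matrix(X)
            res = e.cluster_select_k(
                m, e.ClusterConfig(k_range=(2, 3), seed=int(rng.integers(99)))
            )
            assert res.silhouette == pytest.approx(
                brute_force_silhouette(m.X, res.labels), abs=1e-9
            )

    def test_oversized_k_skipped_with_warning(self):
        X = np.eye(5)
        with pytest.warns(UserWarning, match="skipping"):
            res = e.cluster_select_k(
                binary_matrix(X),
                e.ClusterConfig(k_range=(2, 8), seed=0),
            )
        assert 8 not in res.silhouette_by_k

    def test_every_patient_assigned_exactly_once(self, comorb_cohort, phewas_map):
        patients, _ = comorb_cohort
        m = e.filter_prevalence(
            e.map_to_phewas(patients[:300], phewas_map), 0.005
        )
        res = e.cluster_select_k(
            m, e.ClusterConfig(k_range=(2, 3, 4), seed=5)
        )
        assert sorted(res.assignments) == sorted(m.patient_ids)
        assert sum(res.cluster_sizes().values()) == m.n


class TestCompareClusterings:
    def test_planted_three_clusters_recovered_by_kmeans_and_agglomerative(
        self, phewas_map, group_map
    ):
        cfg = e.ComorbSimConfig(
            n_patients=600,
            cluster_mix={
                "psychiatric": 1 / 3,
                "developmental": 1 / 3,
                "seizures": 1 / 3,
                "background": 0.0,
            },
            seed=11,
        )
        patients, latent = e.gen_comorbidity_cohort(cfg, phewas_map, group_map)
        m = e.filter_prevalence(e.map_to_phewas(patients, phewas_map), 0.005)
        truth = [latent[pid] for pid in m.patient_ids]
        rows = {
            r["method"]: r
            for r in e.compare_clusterings(
                m, e.ClusterConfig(k_range=tuple(range(2, 8)), seed=11)
            )
        }
        for method in ("kmeans", "agglomerative"):
            assert rows[method]["n_clusters"] == 3
            ari = adjusted_rand_score(truth, rows[method]["labels"])
            assert ari >= 0.8

    def test_uniform_random_matrix_has_near_zero_silhouette(self):
        rng = np.random.default_rng(19)
        X = (rng.random((300, 30)) < 0.3).astype(float)
        rows = e.compare_clusterings(
            binary_matrix(X),
            e.ClusterConfig(k_range=tuple(range(2, 6)), seed=19),
        )
        km = next(r for r in rows if r["method"] == "kmeans")
        assert abs(km["silhouette"]) <= 0.15

    def test_smoke_run_reports_all_three_methods(self, phewas_map, comorb_cohort):
        patients, _ = comorb_cohort
        m = e.filter_prevalence(
            e.map_to_phewas(patients[:25], phewas_map), 0.005
        )
        rows = e.compare_clusterings(
            m, e.ClusterConfig(k_range=(2, 3), seed=1)
        )
        assert {r["method"] for r in rows} == {
            "kmeans",
            "dbscan",
            "agglomerative",
        }


class TestCharacterizeClusters:
    def _result_for(self, X, labels):
        m = binary_matrix(X)
        res = e.ClusterResult(
            assignments=dict(zip(m.patient_ids, map(int, labels))),
            k=len(set(labels)),
            silhouette=0.0,
            silhouette_by_k={},
            labels=np.asarray(labels),
        )
        return res, m

    def test_relative_prevalence_ratio(self):
        # category 0: 50% in cluster 0, 10% overall -> relative 5.0
        X = np.zeros((10, 2))
        X[0, 0] = 1
        X[:, 1] = 1
        labels = [0, 0] + [1] * 8
        res, m = self._result_for(X, labels)
        res = e.characterize_clusters(res, m)
        prev, rel = res.profiles[0]["c0"]
        assert (prev, rel) == (0.5, 5.0)

    def test_absent_code_gives_zero(self):
        X = np.zeros((4, 1))
        X[2:, 0] = 1
        res, m = self._result_for(X, [0, 0, 1, 1])
        res = e.characterize_clusters(res, m)
        assert res.profiles[0]["c0"] == (0.0, 0.0)

    def test_single_cluster_all_relative_prevalences_one(self):
        rng = np.random.default_rng(5)
        X = (rng.random((20, 4)) < 0.5).astype(float)
        X[0] = 1  # ensure no zero-prevalence column
        res, m = self._result_for(X, [0] * 20)
        res = e.characterize_clusters(res, m)
        for _, rel in res.profiles[0].values():
            assert rel == pytest.approx(1.0)

    def test_group_profile_is_mean_over_member_categories(self, group_map):
        X = np.zeros((10, 2))
        X[:2, 0] = 1
        X[:5, 1] = 1
        m = e.PhewasMatrix(
            patient_ids=[f"p{i}" for i in range(10)],
            categories=["epilepsy", "convulsions"],
            X=X,
        )
        labels = [0, 0] + [1] * 8
        res = e.ClusterResult(
            assignments=dict(zip(m.patient_ids, labels)),
            k=2,
            silhouette=0.0,
            silhouette_by_k={},
            labels=np.asarray(labels),
        )
        res = e.characterize_clusters(res, m, e.GroupMap(group_map))
        rel_epilepsy = res.profiles[0]["epilepsy"][1]
        rel_convulsions = res.profiles[0]["convulsions"][1]
        assert res.group_profiles[0]["seizures"] == pytest.approx(
            (rel_epilepsy + rel_convulsions) / 2
        )


class TestEmbed2d:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(3)
        X = (rng.random((40, 8)) < 0.4).astype(float)
        m = binary_matrix(X)
        a = e.embed_2d(m, seed=9)
        b = e.embed_2d(m, seed=9)
        assert a.shape == (40, 2)
        np.testing.assert_allclose(a, b)

    def test_too_few_patients_rejected(self):
        m = binary_matrix(np.eye(4))
        with pytest.raises(ValidationError):
            e.embed_2d(m, seed=0)

    def test_planted_clusters_stay_neighbors_in_embedding(
        self, phewas_map, group_map
    ):
        cfg = e.ComorbSimConfig(n_patients=300, seed=11)
        patients, latent = e.gen_comorbidity_cohort(cfg, phewas_map, group_map)
        m = e.filter_prevalence(e.map_to_phewas(patients, phewas_map), 0.005)
        truth = np.array([latent[pid] for pid in m.patient_ids])
        coords = e.embed_2d(m, seed=11)
        d = ((coords[:, None] - coords[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :5]
        same = np.mean(truth[nn] == truth[:, None])
        rng = np.random.default_rng(11)
        null = []
        for _ in range(20):
            perm = rng.permutation(truth)
            null.append(np.mean(perm[nn] == perm[:, None]))
        assert same > max(null)
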