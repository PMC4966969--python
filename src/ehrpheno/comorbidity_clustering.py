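"""Comorbidity structure of a flagged cohort: PheWAS rollup, prevalence
filtering, silhouette-selected k-means, cluster profiling, 2-D embedding.

Each patient's ICD-9 code set rolls up to a binary indicator vector over
PheWAS categories.  Rare categories (< 0.5% of patients by default) are
dropped, k-means is run for k = 2..20 and the k with the highest mean
silhouette coefficient wins.  Clusters are then profiled by the relative
prevalence of each PheWAS category — prevalence inside the cluster
divided by cohort prevalence — and aggregated into comorbidity groups
(seizures, psychiatric, auditory, developmental, GI, cardiac).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .core_io import PatientRecord, ValidationError

logger = logging.getLogger(__name__)

COMORBIDITY_GROUPS = (
    "seizures",
    "psychiatric",
    "auditory",
    "developmental",
    "gi",
    "cardiac",
    "other",
)


@dataclass
class PhewasMatrix:
    """Cohort as a binary patients x PheWAS-categories indicator matrix."""

    patient_ids: list[str]
    categories: list[str]
    X: np.ndarray  # shape (n, p), values in {0, 1}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.patient_ids), len(self.categories)):
            raise ValidationError("matrix shape disagrees with labels")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValidationError("indicators must be 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def prevalence(self) -> np.ndarray:
        """Fraction of patients with each category present."""
        return self.X.mean(axis=0)


@dataclass(frozen=True)
class GroupMap:
    """PheWAS category -> comorbidity group; unmapped categories are
    'other', making the mapping total."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.entries.values()} - set(COMORBIDITY_GROUPS)
        if bad:
            raise ValidationError(f"unknown comorbidity groups: {sorted(bad)}")

    def group(self, phewas: str) -> str:
        return self.entries.get(phewas, "other")


@dataclass(frozen=True)
class ClusterConfig:
    k_range: tuple[int, ...] = tuple(range(2, 21))
    n_restarts: int = 10
    seed: int = 0
    prevalence_threshold: float = 0.005

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_threshold < 1):
            raise ValidationError("prevalence threshold must be in (0,1)")
        if min(self.k_range) < 2:
            raise ValidationError("k must be at least 2")


@dataclass
class ClusterResult:
    assignments: dict[str, int]  # patient_id -> cluster id
    k: int
    silhouette: float
    silhouette_by_k: dict[int, float]
    labels: np.ndarray = field(repr=False, default=None)
    profiles: Optional[dict] = None        # cluster -> code -> (prev, rel-prev)
    group_profiles: Optional[dict] = None  # cluster -> group -> rel-prev

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def map_to_phewas(
    patients: Sequence[PatientRecord], phewas_map: Mapping[str, str]
) -> PhewasMatrix:
    """Roll each patient's ICD-9 set up to binary PheWAS indicators.

    Multiple ICD-9 codes hitting one category still give an indicator of
    1.  Unmapped ICD-9 codes are dropped; their count is logged.
    """
    if not phewas_map:
        raise ValidationError("empty ICD-9 -> PheWAS map")
    categories = sorted(set(phewas_map.values()))
    col = {c: j for j, c in enumerate(categories)}
    X = np.zeros((len(patients), len(categories)))
    n_unmapped = 0
    for i, p in enumerate(patients):
        for code in p.icd9_codes:
            cat = phewas_map.get(code)
            if cat is None:
                n_unmapped += 1
            else:
                X[i, col[cat]] = 1.0
    if n_unmapped:
        logger.warning("dropped %d unmapped ICD-9 code occurrences", n_unmapped)
    return PhewasMatrix(
        patient_ids=[p.patient_id for p in patients],
        categories=categories,
        X=X,
    )


def filter_prevalence(
    matrix: PhewasMatrix, threshold: float = 0.005
) -> PhewasMatrix:
    """Drop PheWAS categories present in fewer than ``threshold`` of
    patients; a category at exactly the threshold is retained."""
    if matrix.n < 1:
        raise ValidationError("empty cohort")
    prev = matrix.prevalence()
    keep = np.flatnonzero(prev >= threshold)
    if keep.size == 0:
        raise ValidationError(
            f"prevalence filter at {threshold} removed every category; "
            "lower the threshold"
        )
    return PhewasMatrix(
        patient_ids=matrix.patient_ids,
        categories=[matrix.categories[j] for j in keep],
        X=matrix.X[:, keep],
    )


def _kmeans_best_of(X: np.ndarray, k: int, n_restarts: int, seed: int):
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


def cluster_select_k(
    matrix: PhewasMatrix, config: ClusterConfig | None = None
) -> ClusterResult:
    """k-means over a range of k; keep the k with the highest mean
    silhouette coefficient (ties -> smallest k).

    Each k runs ``n_restarts`` seeded restarts keeping the best-inertia
    solution; the silhouette is computed on that solution with Euclidean
    distance.  Values of k with too few points, or where k-means returns
    a degenerate single cluster, are skipped with a warning.
    """
    config = config or ClusterConfig()
    sil_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in config.k_range:
        if matrix.n <= k:
            warnings.warn(f"skipping k={k}: only {matrix.n} patients")
            continue
        labels = _kmeans_best_of(matrix.X, k, config.n_restarts, config.seed)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"skipping k={k}: degenerate single cluster")
            continue
        sil_by_k[k] = float(silhouette_score(matrix.X, labels))
        labels_by_k[k] = labels
    if not sil_by_k:
        raise ValidationError("no k in range produced a valid clustering")
    best_k = min(sil_by_k, key=lambda k: (-sil_by_k[k], k))
    labels = labels_by_k[best_k]
    return ClusterResult(
        assignments=dict(zip(matrix.patient_ids, map(int, labels))),
        k=best_k,
        silhouette=sil_by_k[best_k],
        silhouette_by_k=dict(sorted(sil_by_k.items())),
        labels=labels,
    )


def compare_clusterings(
    matrix: PhewasMatrix,
    config: ClusterConfig | None = None,
    dbscan_eps: float = 0.9,
    dbscan_min_samples: int = 5,
) -> list[dict]:
    """Run k-means (silhouette-selected), DBSCAN and agglomerative
    clustering on the same matrix and report silhouette, cluster count
    and size distribution for each.

    DBSCAN noise points are kept as their own pseudo-cluster (-1); a
    single-cluster outcome is reported with silhouette None rather than
    treated as an error.
    """
    config = config or ClusterConfig()
    rows: list[dict] = []

    km = cluster_select_k(matrix, config)
    rows.append(
        {
            "method": "kmeans",
            "n_clusters": km.k,
            "silhouette": km.silhouette,
            "sizes": sorted(km.cluster_sizes().values(), reverse=True),
            "labels": km.labels,
        }
    )

    db_labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit_predict(
        matrix.X
    )
    uniq = np.unique(db_labels)
    db_sil = (
        float(silhouette_score(matrix.X, db_labels)) if len(uniq) > 1 else None
    )
    sizes = sorted(
        (int((db_labels == u).sum()) for u in uniq), reverse=True
    )
    rows.append(
        {
            "method": "dbscan",
            "n_clusters": int(len(uniq[uniq >= 0])),
            "silhouette": db_sil,
            "sizes": sizes,
            "labels": db_labels,
        }
    )

    ag_labels = AgglomerativeClustering(n_clusters=km.k).fit_predict(matrix.X)
    rows.append(
        {
            "method": "agglomerative",
            "n_clusters": int(len(np.unique(ag_labels))),
            "silhouette": float(silhouette_score(matrix.X, ag_labels)),
            "sizes": sorted(
                (int((ag_labels == u).sum()) for u in np.unique(ag_labels)),
                reverse=True,
            ),
            "labels": ag_labels,
        }
    )
    return rows


def characterize_clusters(
    result: ClusterResult,
    matrix: PhewasMatrix,
    group_map: GroupMap | None = None,
) -> ClusterResult:
    """Fill per-cluster PheWAS and comorbidity-group prevalence profiles.

    Relative prevalence of category c in cluster g is
    prevalence(c | g) / prevalence(c | cohort); a group's relative
    prevalence is the mean over its member categories.  Within-cluster
    prevalences are reported alongside.
    """
    labels = result.labels
    if labels is None or len(labels) != matrix.n:
        raise ValidationError("cluster result does not match the cohort")
    cohort_prev = matrix.prevalence()
    assert (cohort_prev > 0).all(), "zero-prevalence category survived filter"
    profiles: dict[int, dict[str, tuple[float, float]]] = {}
    group_profiles: dict[int, dict[str, float]] = {}
    for g in np.unique(labels):
        in_g = labels == g
        prev_g = matrix.X[in_g].mean(axis=0)
        rel = prev_g / cohort_prev
        profiles[int(g)] = {
            cat: (float(prev_g[j]), float(rel[j]))
            for j, cat in enumerate(matrix.categories)
        }
        if group_map is not None:
            by_group: dict[str, list[float]] = {}
            for j, cat in enumerate(matrix.categories):
                by_group.setdefault(group_map.group(cat), []).append(rel[j])
            group_profiles[int(g)] = {
                grp: float(np.mean(vals)) for grp, vals in by_group.items()
            }
    result.profiles = profiles
    result.group_profiles = group_profiles if group_map is not None else None
    return result


def embed_2d(
    matrix: PhewasMatrix, seed: int = 0, perplexity: float | None = None
) -> np.ndarray:
    """t-SNE embedding of the PheWAS vectors into two dimensions.

    Deterministic given the seed.  Perplexity defaults to
    min(30, (n - 1) / 3) so small cohorts embed without error.
    """
    if matrix.n < 5:
        raise ValidationError("need at least 5 patients to embed")
    if perplexity is None:
        perplexity = min(30.0, (matrix.n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
    )
    return tsne.fit_transform(matrix.X)


def plot_embedding(coords: np.ndarray, labels: np.ndarray, path: str) -> None:
    """Scatter the 2-D embedding colored by cluster id (file output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels, s=8, cmap="tab10")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
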