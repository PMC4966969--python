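"""Two-stage linear-SVM cohort classifier with chi-square feature selection.

Stage 1 separates probable cases (gold ``yes``/``maybe``) from
non-cases (``no``/``unknown``); stage 2 runs only on stage-1 positives
and separates definite ``yes`` from ``maybe``.  Each stage is a linear
maximum-margin classifier restricted to the top-k features ranked by
the chi-square statistic of the 2x2 (feature-present x class) table on
the training rows only.  Feature count and cost are tuned by grid
search maximizing PPV on a held-out development split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .core_io import PatientRecord, ValidationError

STAGE1_POSITIVE = frozenset({"yes", "maybe"})
LABEL_NO_OR_UNKNOWN = "no_or_unknown"


@dataclass
class FeatureMatrix:
    """Patients x concept-codes count matrix with aligned gold labels.

    Columns are sorted concept codes recorded in ``feature_names``; the
    cell value is the number of mentions of that code in the patient's
    record (every mention counts here — attribute filtering belongs to
    the rule engine, while the margin model sees the raw vector).
    """

    X: sparse.csr_matrix
    feature_names: list[str]
    patient_ids: list[str]
    labels: list[Optional[str]]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValidationError("matrix shape disagrees with row/col names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            X=self.X[idx],
            feature_names=self.feature_names,
            patient_ids=[self.patient_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


def build_feature_matrix(
    patients: Sequence[PatientRecord],
    vocabulary: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Convert patient concept vectors into a sparse count matrix.

    With no explicit vocabulary the sorted union of observed codes is
    used; passing the training vocabulary keeps prediction-time columns
    aligned with a fitted model.
    """
    if vocabulary is None:
        vocab = sorted({m.code for p in patients for m in p.mentions})
    else:
        vocab = list(vocabulary)
    col = {c: j for j, c in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for i, p in enumerate(patients):
        counts: dict[int, int] = {}
        for m in p.mentions:
            j = col.get(m.code)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, v in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(v)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(patients), len(vocab)), dtype=np.float64
    )
    return FeatureMatrix(
        X=X,
        feature_names=vocab,
        patient_ids=[p.patient_id for p in patients],
        labels=[p.gold_label for p in patients],
    )


# ---------------------------------------------------------------------------
# Train / development / test split


@dataclass(frozen=True)
class SplitSpec:
    """60/20/20 train-development-test split, stratified by gold label.

    Allocation per stratum is by floor, with the remainder going to the
    training partition; reproducible given the seed.
    """

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


def split_data(
    patients: Sequence[PatientRecord], spec: SplitSpec | None = None
) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
    """Partition labeled patients into train/dev/test cohorts."""
    spec = spec or SplitSpec()
    if len(patients) < 3:
        raise ValidationError("need at least as many patients as partitions")
    missing = [p.patient_id for p in patients if p.gold_label is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} patients lack gold labels; cannot split"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.stratify:
        strata: dict[str, list[int]] = {}
        for i, p in enumerate(patients):
            strata.setdefault(p.gold_label, []).append(i)
        groups = [strata[k] for k in sorted(strata)]
    else:
        groups = [list(range(len(patients)))]
    train_idx, dev_idx, test_idx = [], [], []
    for g in groups:
        g = list(g)
        rng.shuffle(g)
        n = len(g)
        n_dev = int(np.floor(spec.fractions[1] * n))
        n_test = int(np.floor(spec.fractions[2] * n))
        n_train = n - n_dev - n_test  # remainder to train
        train_idx += g[:n_train]
        dev_idx += g[n_train : n_train + n_dev]
        test_idx += g[n_train + n_dev :]
    pick = lambda idx: [patients[i] for i in sorted(idx)]
    return pick(train_idx), pick(dev_idx), pick(test_idx)


# ---------------------------------------------------------------------------
# Chi-square feature ranking


def chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Chi-square of a 2x2 contingency table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); degenerate margins
    give 0.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi_square_rank(
    fm: FeatureMatrix, y: Sequence[bool]
) -> list[tuple[str, float]]:
    """Rank features by the chi-square of (presence x class).

    Feature values are binarized to presence/absence before tabulation.
    Returns (code, score) pairs sorted by descending score, ties broken
    by lexicographic code so the ranking is fully deterministic.
    """
    y = np.asarray(y, dtype=bool)
    if fm.n < 2:
        raise ValidationError("need at least two patients to rank features")
    if y.all() or not y.any():
        raise ValidationError("both classes must be present to rank features")
    present = (fm.X > 0).toarray()
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    a = present[y].sum(axis=0).astype(float)      # present & positive
    c = present[~y].sum(axis=0).astype(float)     # present & negative
    b = n_pos - a                                 # absent & positive
    d = n_neg - c                                 # absent & negative
    n = float(fm.n)
    denom = (a + c) * (b + d) * n_pos * n_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    order = sorted(
        range(len(fm.feature_names)),
        key=lambda j: (-scores[j], fm.feature_names[j]),
    )
    return [(fm.feature_names[j], float(scores[j])) for j in order]


# ---------------------------------------------------------------------------
# Single-stage model


@dataclass
class StageModel:
    """One fitted linear stage: selected features, weights, bias, cost."""

    features: list[str]
    weights: np.ndarray
    bias: float
    cost: float

    def decision_scores(self, fm: FeatureMatrix) -> np.ndarray:
        cols = {c: j for j, c in enumerate(fm.feature_names)}
        missing = [f for f in self.features if f not in cols]
        if missing:
            raise ValidationError(
                f"feature matrix lacks {len(missing)} model columns, "
                f"e.g. {missing[:3]}"
            )
        idx = [cols[f] for f in self.features]
        return np.asarray(
            fm.X[:, idx] @ self.weights + self.bias
        ).ravel()

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        return self.decision_scores(fm) > 0


def train_stage(
    fm_train: FeatureMatrix,
    y: Sequence[bool],
    n_features: int,
    cost: float,
    seed: int = 0,
) -> StageModel:
    """Fit one linear stage on the top-n_features chi-square features.

    Feature ranking uses the training rows only; the margin model then
    sees raw mention counts for the selected columns.
    """
    y = np.asarray(y, dtype=bool)
    if n_features > len(fm_train.feature_names):
        raise ValidationError(
            f"n_features={n_features} exceeds available "
            f"{len(fm_train.feature_names)} columns"
        )
    if y.all() or not y.any():
        raise ValidationError("training labels are single-class")
    ranked = chi_square_rank(fm_train, y)
    selected = [code for code, _ in ranked[:n_features]]
    cols = {c: j for j, c in enumerate(fm_train.feature_names)}
    idx = [cols[f] for f in selected]
    clf = LinearSVC(C=cost, random_state=seed, max_iter=5000)
    clf.fit(fm_train.X[:, idx], y.astype(int))
    return StageModel(
        features=selected,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        cost=float(cost),
    )


# ---------------------------------------------------------------------------
# PPV-maximizing grid search


def default_feature_counts(n_columns: int, cap: int = 250) -> list[int]:
    """Feature-count ladder {10, 20, ..., cap}, truncated to n_columns."""
    counts = [k for k in range(10, cap + 1, 10) if k <= n_columns]
    return counts or [min(n_columns, cap)]


@dataclass(frozen=True)
class GridSpec:
    """Search grid: costs 2^-10 .. 2^10, feature counts capped at 250."""

    cost_values: tuple[float, ...] = tuple(
        float(2.0**e) for e in range(-10, 11)
    )
    feature_counts: tuple[int, ...] = tuple(range(10, 251, 10))

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cost_values):
            raise ValidationError("cost values must be positive")
        if any(k > 250 for k in self.feature_counts):
            raise ValidationError("feature counts are capped at 250")


@dataclass
class GridSearchResult:
    best_n_features: int
    best_cost: float
    best_ppv: float
    surface: list[dict]  # one row per (n_features, cost) with dev PPV


def grid_search(
    fm_train: FeatureMatrix,
    y_train: Sequence[bool],
    fm_dev: FeatureMatrix,
    y_dev: Sequence[bool],
    grid: GridSpec | None = None,
    seed: int = 0,
) -> GridSearchResult:
    """Pick (n_features, cost) maximizing PPV on the development split.

    The full PPV surface is retained for plotting.  Ties prefer fewer
    features, then smaller cost.  Cells with no predicted positives have
    undefined PPV and are recorded as such; if every cell is undefined
    the search fails with a diagnostic.
    """
    grid = grid or GridSpec()
    y_train = np.asarray(y_train, dtype=bool)
    y_dev = np.asarray(y_dev, dtype=bool)
    if not y_dev.any():
        raise ValidationError("development set has no positives; PPV undefined")
    n_cols = len(fm_train.feature_names)
    counts = sorted({min(k, n_cols) for k in grid.feature_counts})
    ranked = chi_square_rank(fm_train, y_train)
    cols = {c: j for j, c in enumerate(fm_train.feature_names)}
    surface: list[dict] = []
    best: tuple | None = None  # (-ppv, n_features, cost)
    for k in counts:
        selected = [code for code, _ in ranked[:k]]
        idx = [cols[f] for f in selected]
        Xtr = fm_train.X[:, idx]
        for cost in sorted(grid.cost_values):
            clf = LinearSVC(C=cost, random_state=seed, max_iter=5000)
            clf.fit(Xtr, y_train.astype(int))
            model = StageModel(
                features=selected,
                weights=clf.coef_.ravel().copy(),
                bias=float(clf.intercept_[0]),
                cost=float(cost),
            )
            pred = model.predict(fm_dev)
            n_pred = int(pred.sum())
            ppv = float((pred & y_dev).sum() / n_pred) if n_pred else None
            surface.append(
                {"n_features": k, "cost": cost, "dev_ppv": ppv,
                 "n_predicted_positive": n_pred}
            )
            if ppv is not None:
                key = (-ppv, k, cost)
                if best is None or key < best:
                    best = key
    if best is None:
        raise ValidationError(
            "no grid cell produced a predicted positive on the development "
            "set; PPV objective undefined everywhere"
        )
    neg_ppv, k, cost = best
    return GridSearchResult(
        best_n_features=k, best_cost=cost, best_ppv=-neg_ppv, surface=surface
    )


# ---------------------------------------------------------------------------
# Two-stage model


@dataclass
class TwoStageModel:
    """Stage-1 (case vs non-case) and stage-2 (yes vs maybe) classifiers.

    Stage 2 is only ever applied to stage-1 positives.
    """

    stage1: StageModel
    stage2: StageModel
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        def enc(m: StageModel) -> dict:
            return {
                "features": m.features,
                "weights": m.weights.tolist(),
                "bias": m.bias,
                "cost": m.cost,
            }

        payload = {
            "stage1": enc(self.stage1),
            "stage2": enc(self.stage2),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TwoStageModel":
        payload = json.loads(Path(path).read_text())

        def dec(d: dict) -> StageModel:
            return StageModel(
                features=list(d["features"]),
                weights=np.asarray(d["weights"], dtype=float),
                bias=float(d["bias"]),
                cost=float(d["cost"]),
            )

        return cls(
            stage1=dec(payload["stage1"]),
            stage2=dec(payload["stage2"]),
            meta=payload.get("meta", {}),
        )


def fit_two_stage(
    fm_train: FeatureMatrix,
    fm_dev: FeatureMatrix,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> TwoStageModel:
    """Tune and fit both stages.

    Stage 1 trains on all rows with positive = gold in {yes, maybe};
    stage 2 trains on the gold-positive rows only, with positive = yes.
    Each stage gets its own grid search against the corresponding
    development objective.
    """
    y1_train = [lab in STAGE1_POSITIVE for lab in fm_train.labels]
    y1_dev = [lab in STAGE1_POSITIVE for lab in fm_dev.labels]
    gs1 = grid_search(fm_train, y1_train, fm_dev, y1_dev, grid, seed)
    stage1 = train_stage(
        fm_train, y1_train, gs1.best_n_features, gs1.best_cost, seed
    )

    tr_pos = [i for i, lab in enumerate(fm_train.labels) if lab in STAGE1_POSITIVE]
    dev_pos = [i for i, lab in enumerate(fm_dev.labels) if lab in STAGE1_POSITIVE]
    fm2_train = fm_train.subset_rows(tr_pos)
    fm2_dev = fm_dev.subset_rows(dev_pos)
    y2_train = [lab == "yes" for lab in fm2_train.labels]
    y2_dev = [lab == "yes" for lab in fm2_dev.labels]
    gs2 = grid_search(fm2_train, y2_train, fm2_dev, y2_dev, grid, seed)
    stage2 = train_stage(
        fm2_train, y2_train, gs2.best_n_features, gs2.best_cost, seed
    )
    return TwoStageModel(
        stage1=stage1,
        stage2=stage2,
        meta={
            "seed": seed,
            "stage1": {"n_features": gs1.best_n_features,
                       "cost": gs1.best_cost, "dev_ppv": gs1.best_ppv},
            "stage2": {"n_features": gs2.best_n_features,
                       "cost": gs2.best_cost, "dev_ppv": gs2.best_ppv},
        },
    )


@dataclass
class TwoStagePrediction:
    patient_ids: list[str]
    labels: list[str]  # yes / maybe / no_or_unknown
    stage1_scores: np.ndarray
    stage2_scores: list[Optional[float]]  # None for stage-1 negatives


def predict_two_stage(
    model: TwoStageModel, fm: FeatureMatrix
) -> TwoStagePrediction:
    """Apply both stages; stage-1 negatives are never scored by stage 2."""
    s1 = model.stage1.decision_scores(fm)
    labels: list[str] = []
    s2: list[Optional[float]] = []
    pos_idx = [i for i in range(fm.n) if s1[i] > 0]
    s2_scores = {}
    if pos_idx:
        s2_all = model.stage2.decision_scores(fm.subset_rows(pos_idx))
        s2_scores = dict(zip(pos_idx, s2_all))
    for i in range(fm.n):
        if s1[i] > 0:
            labels.append("yes" if s2_scores[i] > 0 else "maybe")
            s2.append(float(s2_scores[i]))
        else:
            labels.append(LABEL_NO_OR_UNKNOWN)
            s2.append(None)
    return TwoStagePrediction(
        patient_ids=list(fm.patient_ids),
        labels=labels,
        stage1_scores=s1,
        stage2_scores=s2,
    )
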