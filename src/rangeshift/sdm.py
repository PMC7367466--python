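"""Per-taxon suitability modelling.

Three algorithm families are fitted per taxon on five bootstrap 70/30
partitions of presences and an equal number of random pseudo-absences:

* ``maxent_like`` — a penalized log-linear presence-background learner:
  logistic contrast of presences against a background cell sample, with the
  fitted relative occurrence rate squashed to [0, 1) complementary-log-log
  style;
* ``margin_classifier`` — an RBF-kernel maximum-margin discriminator with
  Platt probability calibration (presence vs pseudo-absence);
* ``tree_bag`` — bagged randomized decision trees voting a class-1 fraction.

Each fit is scored with the threshold-dependent Sørensen (Dice) index on its
test fold; the full ensemble is the Sørensen-weighted cellwise average of
the fits scoring above the mean.  Dispersal limitation enters as an extra
predictor: the min-max normalized cumulative distance from every cell to all
occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import Grid, GridSpec
from .maps import DispersalLayer, SuitabilityMap
from .occurrences import OccurrenceSet

__all__ = [
    "ALGORITHMS",
    "TrainingSet",
    "ModelFit",
    "ModelScore",
    "EnsembleModel",
    "sample_pseudo_absences",
    "bootstrap_partitions",
    "fit_model",
    "sorensen_index",
    "select_threshold",
    "score_fit",
    "ensemble",
    "build_ensemble",
    "cumulative_distance_layer",
]

ALGORITHMS = ("maxent_like", "margin_classifier", "tree_bag")


def _quadratic_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([X, X**2])


@dataclass
class TrainingSet:
    """One bootstrap partition: 70% train / 30% test, stratified by class."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    partition_id: int
    feature_names: list[str] = field(default_factory=list)


@dataclass
class ModelScore:
    sorensen: float
    threshold_used: float

    def __post_init__(self) -> None:
        if not (0 <= self.sorensen <= 1):
            raise ValueError("Sørensen score must lie in [0, 1]")


@dataclass
class ModelFit:
    """A fitted algorithm plus the state needed to predict on new cells."""

    algorithm_id: str
    scaler: StandardScaler
    estimator: object
    feature_names: list[str]
    partition_id: int = 0
    taxon_id: str = ""
    bg_rate_mean: float = 1.0  # maxent_like only: background mean of exp(eta)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for an (n, d) predictor matrix."""
        if self.algorithm_id == "maxent_like":
            Z = self.scaler.transform(_quadratic_features(X))
            eta = self.estimator.decision_function(Z)
            rate = np.exp(np.clip(eta, -500, 500)) / self.bg_rate_mean
            p = 1.0 - np.exp(-rate)
        else:
            p = self.estimator.predict_proba(self.scaler.transform(X))[:, 1]
        return np.clip(p, 0.0, 1.0)


def sample_pseudo_absences(
    occ: OccurrenceSet, spec: GridSpec, seed: int = 0, n: Optional[int] = None
) -> np.ndarray:
    """Random-space-allocation pseudo-absences: uniform over cells holding no
    presence, as many as there are presences, without replacement."""
    cells = spec.cells_of(occ.points)
    presence_flat = set(cells[:, 0] * spec.n_cols + cells[:, 1])
    if n is None:
        n = len(occ)
    empty = np.setdiff1d(np.arange(spec.n_cells), np.fromiter(presence_flat, dtype=int))
    if empty.size < n:
        raise ValueError(
            f"grid has only {empty.size} presence-free cells, cannot draw {n} pseudo-absences"
        )
    rng = np.random.default_rng([seed, 91])
    chosen = rng.choice(empty, size=n, replace=False)
    centers = spec.all_centers()
    return centers[chosen]


def bootstrap_partitions(
    presences: np.ndarray,
    absences: np.ndarray,
    train_frac: float = 0.7,
    n_reps: int = 5,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> list[TrainingSet]:
    """``n_reps`` independent stratified splits of presence/absence rows.

    Per class, the train portion has ``round(train_frac * n)`` rows; train
    and test are disjoint and jointly exhaustive within a replicate.
    """
    P = np.asarray(presences, dtype=float)
    A = np.asarray(absences, dtype=float)
    for name, arr in (("presence", P), ("absence", A)):
        if arr.shape[0] < 2:
            raise ValueError(f"{name} class needs at least 2 records")
    out: list[TrainingSet] = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 101, rep])
        parts = {}
        for label, arr in ((1, P), (0, A)):
            n = arr.shape[0]
            k = int(round(train_frac * n))
            perm = rng.permutation(n)
            parts[label] = (arr[perm[:k]], arr[perm[k:]])
        X_train = np.vstack([parts[1][0], parts[0][0]])
        y_train = np.concatenate([np.ones(len(parts[1][0])), np.zeros(len(parts[0][0]))])
        X_test = np.vstack([parts[1][1], parts[0][1]])
        y_test = np.concatenate([np.ones(len(parts[1][1])), np.zeros(len(parts[0][1]))])
        out.append(
            TrainingSet(
                X_train, y_train.astype(int), X_test, y_test.astype(int),
                partition_id=rep + 1,
                feature_names=list(feature_names or []),
            )
        )
    return out


def fit_model(
    algorithm_id: str,
    train: TrainingSet,
    background: Optional[np.ndarray] = None,
    seed: int = 0,
    taxon_id: str = "",
) -> ModelFit:
    """Fit one algorithm on one partition; deterministic under the seed.

    ``background`` (a predictor sample of the landscape) is required by the
    presence-background ``maxent_like`` learner and ignored by the two
    presence-absence learners.
    """
    if algorithm_id not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm_id!r}; expected one of {ALGORITHMS}")
    rs = int(np.random.default_rng([seed, 113, train.partition_id]).integers(2**31 - 1))

    if algorithm_id == "maxent_like":
        if background is None:
            raise ValueError("maxent_like needs a background predictor sample")
        pres = train.X_train[train.y_train == 1]
        if len(pres) == 0:
            raise ValueError("maxent_like needs at least one presence row")
        # linear + quadratic feature classes so the log-density can express a
        # unimodal niche; mild ridge penalty
        Fp, Fb = _quadratic_features(pres), _quadratic_features(background)
        scaler = StandardScaler().fit(np.vstack([Fp, Fb]))
        Xc = scaler.transform(np.vstack([Fp, Fb]))
        yc = np.concatenate([np.ones(len(pres)), np.zeros(len(background))])
        est = LogisticRegression(C=10.0, max_iter=5000).fit(Xc, yc)
        eta_bg = est.decision_function(scaler.transform(Fb))
        bg_mean = float(np.exp(np.clip(eta_bg, -500, 500)).mean())
        return ModelFit(algorithm_id, scaler, est, list(train.feature_names),
                        train.partition_id, taxon_id, bg_rate_mean=max(bg_mean, 1e-300))

    if len(np.unique(train.y_train)) < 2:
        raise ValueError(f"{algorithm_id} needs both classes in the training data")
    scaler = StandardScaler().fit(train.X_train)
    Z = scaler.transform(train.X_train)
    if algorithm_id == "margin_classifier":
        # Platt-calibrated RBF margin classifier; cv=3 keeps calibration
        # feasible at the small presence counts of rare taxa
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", C=10.0, gamma="scale"), method="sigmoid",
            cv=3, ensemble=False,
        )
    else:  # tree_bag
        est = RandomForestClassifier(n_estimators=200, random_state=rs)
    est.fit(Z, train.y_train)
    return ModelFit(algorithm_id, scaler, est, list(train.feature_names),
                    train.partition_id, taxon_id)


def sorensen_index(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sørensen (Dice) overlap of boolean vectors: 2TP / (2TP + FP + FN)."""
    p = np.asarray(predicted, dtype=bool).ravel()
    o = np.asarray(observed, dtype=bool).ravel()
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if not o.any():
        raise ValueError("Sørensen index is undefined without observed positives")
    tp = int((p & o).sum())
    fp = int((p & ~o).sum())
    fn = int((~p & o).sum())
    return 2 * tp / (2 * tp + fp + fn)


def select_threshold(scores: np.ndarray, observed: np.ndarray) -> ModelScore:
    """Binarization threshold maximizing Sørensen over the unique score values.

    Ties break toward the larger threshold (the more conservative range).
    """
    s = np.asarray(scores, dtype=float).ravel()
    o = np.asarray(observed, dtype=bool).ravel()
    best: Optional[tuple[float, float]] = None
    for t in np.unique(s):
        val = sorensen_index(s >= t, o)
        if best is None or val > best[0] or (val == best[0] and t > best[1]):
            best = (val, float(t))
    return ModelScore(sorensen=best[0], threshold_used=best[1])


def score_fit(fit: ModelFit, X_test: np.ndarray, y_test: np.ndarray) -> ModelScore:
    """Evaluate a fit on its test fold: Sørensen at its best threshold."""
    return select_threshold(fit.predict(X_test), y_test)


def _weighted_members(scores: Sequence[float]) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    keep = s > s.mean()
    if not keep.any():  # all scores equal: include every member
        keep = np.ones_like(keep)
    return keep


def ensemble(maps: Sequence[SuitabilityMap], scores: Sequence[ModelScore]) -> SuitabilityMap:
    """Sørensen-weighted full ensemble of member suitability maps.

    Members scoring strictly above the mean Sørensen enter the cellwise
    weighted average with weight equal to their score; if every member has
    the same score all members enter.
    """
    if len(maps) == 0:
        raise ValueError("ensemble needs at least one member map")
    if len(maps) != len(scores):
        raise ValueError("one score per member map required")
    spec = maps[0].spec
    for m in maps[1:]:
        if m.spec != spec:
            raise ValueError("member maps must share a grid geometry")
    s = np.array([sc.sorensen for sc in scores])
    keep = _weighted_members(s)
    w = s[keep]
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w / w.sum()
    stack = np.stack([maps[i].grid.data for i in np.flatnonzero(keep)])
    out = np.tensordot(w, stack, axes=1)
    prov = [
        (maps[i].provenance, float(wi))
        for i, wi in zip(np.flatnonzero(keep), w)
    ]
    return SuitabilityMap(
        grid=Grid(spec, out),
        taxon_id=maps[0].taxon_id,
        scenario_tag=maps[0].scenario_tag,
        provenance=prov,
    )


@dataclass
class EnsembleModel:
    """The full ensemble as a reusable predictor.

    Holds the above-mean-Sørensen member fits and their weights, so the same
    ensemble can be projected onto current and future climate stacks.
    """

    members: list[ModelFit]
    weights: np.ndarray
    feature_names: list[str]
    taxon_id: str = ""
    uses_dispersal: bool = False
    dispersal_feature: str = "cumdist"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        self.weights = self.weights / self.weights.sum()

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return np.tensordot(self.weights, preds, axes=1)


def build_ensemble(
    fits: Sequence[ModelFit],
    scores: Sequence[ModelScore],
    uses_dispersal: bool = False,
) -> EnsembleModel:
    """Assemble the Sørensen-weighted ensemble from scored fits."""
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    s = np.array([sc.sorensen for sc in scores])
    keep = _weighted_members(s)
    members = [fits[i] for i in np.flatnonzero(keep)]
    w = s[keep]
    if w.sum() == 0:
        w = np.ones_like(w)
    return EnsembleModel(
        members=members,
        weights=w,
        feature_names=list(fits[0].feature_names),
        taxon_id=fits[0].taxon_id,
        uses_dispersal=uses_dispersal,
    )


def cumulative_distance_layer(occ: OccurrenceSet, spec: GridSpec) -> DispersalLayer:
    """Summed Euclidean distance from every cell to all occurrences,
    min-max normalized to [0, 1] over the grid."""
    if len(occ) == 0:
        raise ValueError("cumulative distance needs at least one occurrence")
    centers = spec.all_centers()
    raw = cdist(centers, occ.points).sum(axis=1)
    lo, hi = raw.min(), raw.max()
    norm = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return DispersalLayer(grid=Grid(spec, norm.reshape(spec.shape)))
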