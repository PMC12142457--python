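"""Handcrafted geometric features and the classical-ML benchmark.

Twenty features characterize a rasterized insertion: the CTV volume (cc),
the average and maximum lateral extension of the CTV relative to the
central tandem across CTV-involved axial slices, the average and maximum
per-slice offset between the CTV center of mass and the tandem (an
asymmetry measure), and, for each of the five OARs, the maximum, minimum
and average distance to the CTV surface over the nearest-2cc portion of
that organ (the spatial analogue of the D2cc planning metric).

The benchmark ranks features by one-way ANOVA F-score, balances classes
with SMOTE, grid-searches four classifier families (SVM, random forest,
k-nearest-neighbors, decision tree) and aggregates them with a soft-voting
ensemble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ClassMissing, FitError, MissingTarget, SmoteError
from .grid import GridSpec
from .structures import (
    OAR_ROLES,
    StructureRole,
)

logger = logging.getLogger(__name__)

#: Sentinel distance (mm) for an OAR that was not contoured: far enough to
#: be dosimetrically irrelevant.
MISSING_OAR_SENTINEL = 999.0

#: Volume (mm^3) of the nearest-OAR selection, mirroring the D2cc metric.
D2CC_VOLUME_MM3 = 2000.0

#: Fixed order of the 20 features; also the CSV column schema.
FEATURE_NAMES = [
    "ctv_volume_cc",
    "lat_ext_avg_mm",
    "lat_ext_max_mm",
    "com_offset_avg_mm",
    "com_offset_max_mm",
] + [
    f"{role.value.lower()}_d2cc_{stat}_mm"
    for role in OAR_ROLES
    for stat in ("max", "min", "avg")
]


# ---------------------------------------------------------------------------
# tandem axis helpers
# ---------------------------------------------------------------------------


def _axis_points_at(tandem: np.ndarray, z_values: np.ndarray) -> np.ndarray:
    """In-plane (x, y) of the tandem axis at each z plane.

    Within the polyline's z range the axis is the polyline itself
    (piecewise-linear in z; tandem z is strictly monotone).  Beyond the
    endpoints the axis continues as the straight line least-squares fitted
    to the polyline vertices.
    """
    t = np.asarray(tandem, dtype=float)
    order = np.argsort(t[:, 2])
    t = t[order]
    z = np.asarray(z_values, dtype=float)
    x = np.interp(z, t[:, 2], t[:, 0])
    y = np.interp(z, t[:, 2], t[:, 1])
    # straight-line extension beyond the endpoints
    A = np.column_stack([t[:, 2], np.ones(len(t))])
    cx, _, _, _ = np.linalg.lstsq(A, t[:, 0], rcond=None)
    cy, _, _, _ = np.linalg.lstsq(A, t[:, 1], rcond=None)
    below = z < t[0, 2]
    above = z > t[-1, 2]
    for sel in (below, above):
        x[sel] = cx[0] * z[sel] + cx[1]
        y[sel] = cy[0] * z[sel] + cy[1]
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def ctv_volume_cc(ctv_mask: np.ndarray, grid: GridSpec) -> float:
    """Voxel count times voxel volume, in cc."""
    n = int(np.asarray(ctv_mask, dtype=bool).sum())
    if n == 0:
        raise MissingTarget("empty CTV mask")
    return n * grid.voxel_volume_mm3 / 1000.0


def _per_slice_inplane(ctv_mask, tandem, grid):
    """Yield (slice z-index, CTV (x, y) centers, axis (x, y)) per CTV slice."""
    mask = np.asarray(ctv_mask, dtype=bool)
    if not mask.any():
        raise MissingTarget("empty CTV mask")
    zs = np.nonzero(mask.any(axis=(1, 2)))[0]
    axis_xy = _axis_points_at(tandem, grid.z_coords[zs])
    for zi, axy in zip(zs, axis_xy):
        yy, xx = np.nonzero(mask[zi])
        pts = np.column_stack(
            [grid.x_coords[xx], grid.y_coords[yy]]
        )
        yield zi, pts, axy


def lateral_extension(ctv_mask, tandem, grid: GridSpec) -> tuple[float, float]:
    """(avg, max) over CTV slices of the max in-plane distance to the axis."""
    per_slice = [
        np.sqrt(((pts - axy) ** 2).sum(axis=1)).max()
        for _, pts, axy in _per_slice_inplane(ctv_mask, tandem, grid)
    ]
    mx = float(np.max(per_slice))
    return min(float(np.mean(per_slice)), mx), mx


def com_offset(ctv_mask, tandem, grid: GridSpec) -> tuple[float, float]:
    """(avg, max) over CTV slices of the centroid-to-axis in-plane offset."""
    per_slice = [
        float(np.sqrt(((pts.mean(axis=0) - axy) ** 2).sum()))
        for _, pts, axy in _per_slice_inplane(ctv_mask, tandem, grid)
    ]
    mx = float(np.max(per_slice))
    return min(float(np.mean(per_slice)), mx), mx


def nearest_2cc_distances(
    oar_mask, ctv_mask, grid: GridSpec
) -> tuple[float, float, float]:
    """(max, min, avg) distance to the CTV surface over the nearest-2cc OAR.

    Distance of an OAR voxel is the unsigned Euclidean distance from its
    center to the nearest CTV boundary voxel center, and 0 when it lies
    inside the CTV.  The selection is the floor(2000 mm^3 / voxel volume)
    OAR voxels with the smallest distances (all of them when the organ is
    smaller than 2 cc); ties break on distance then lexicographic index.
    """
    oar = np.asarray(oar_mask, dtype=bool)
    ctv = np.asarray(ctv_mask, dtype=bool)
    if not ctv.any():
        raise MissingTarget("empty CTV mask")
    if not oar.any():
        raise ValueError("empty OAR mask; caller should use the sentinel")
    boundary = ctv & ~ndimage.binary_erosion(
        ctv, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    dist_to_boundary = ndimage.distance_transform_edt(
        ~boundary, sampling=grid.spacing
    )
    dist = np.where(ctv, 0.0, dist_to_boundary)[oar]
    n_sel = int(D2CC_VOLUME_MM3 // grid.voxel_volume_mm3)
    if len(dist) > n_sel:
        flat_idx = np.flatnonzero(oar)
        order = np.lexsort((flat_idx, dist))[:n_sel]
        dist = dist[order]
    return float(dist.max()), float(dist.min()), float(dist.mean())


@dataclass
class FeatureVector:
    """The 20 features in fixed order, with names."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError("a feature vector has exactly 20 entries")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_NAMES)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def feature_vector(masks: dict, tandem, grid: GridSpec) -> FeatureVector:
    """Assemble the 20 features from rasterized masks.

    ``masks`` maps roles (StructureRole or role names) to boolean arrays;
    the CTV entry is the HR/IR union under key ``StructureRole.HR_CTV`` (or
    "CTV").  Missing OAR entries get the 999 mm sentinel with a log entry.
    """

    def get(key):
        for k in (key, getattr(key, "value", key), str(key)):
            if k in masks:
                return masks[k]
        return None

    ctv = get(StructureRole.HR_CTV)
    if ctv is None:
        ctv = get("CTV")
    if ctv is None or not np.asarray(ctv).any():
        raise MissingTarget("no CTV mask in feature input")
    ir = get(StructureRole.IR_CTV)
    if ir is not None:
        ctv = np.asarray(ctv, dtype=bool) | np.asarray(ir, dtype=bool)
    vals = [ctv_volume_cc(ctv, grid)]
    vals.extend(lateral_extension(ctv, tandem, grid))
    vals.extend(com_offset(ctv, tandem, grid))
    for role in OAR_ROLES:
        oar = get(role)
        if oar is None or not np.asarray(oar).any():
            logger.info("OAR %s missing; using %.0f mm sentinel", role.value, MISSING_OAR_SENTINEL)
            vals.extend([MISSING_OAR_SENTINEL] * 3)
        else:
            vals.extend(nearest_2cc_distances(oar, ctv, grid))
    return FeatureVector(np.asarray(vals))


def feature_table(feature_vectors, ids=None) -> pd.DataFrame:
    """Stack FeatureVectors into the fixed 20-column schema."""
    df = pd.DataFrame(
        [fv.values for fv in feature_vectors], columns=FEATURE_NAMES
    )
    if ids is not None:
        df.insert(0, "insertion_id", [i[1] for i in ids])
        df.insert(0, "patient_id", [i[0] for i in ids])
    return df


# ---------------------------------------------------------------------------
# ranking / oversampling
# ---------------------------------------------------------------------------


def rank_features(X, y) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F-score per feature; descending rank order.

    Returns (ordered feature indices, F-scores aligned to the original
    columns).  Constant features get F = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassMissing("ANOVA ranking needs both classes")
    constant = X.std(axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on constant features
        scores, _ = f_classif(X, y)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) assigned F = 0", stacklevel=2
        )
    scores = np.where(constant | ~np.isfinite(scores), 0.0, scores)
    order = np.argsort(-scores, kind="stable")
    return order, scores


def smote_oversample(X, y, k: int = 5, rng: np.random.Generator | None = None):
    """Synthetic minority oversampling (SMOTE) to balanced class counts.

    Each synthetic sample is x + u * (neighbor - x) with u ~ U(0, 1) and
    the neighbor drawn among the k nearest minority samples of x.
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ClassMissing("SMOTE needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X.copy(), y.copy()
    X_min = X[y == minority]
    if len(X_min) < 2:
        raise SmoteError("minority class needs >= 2 samples")
    k_eff = min(k, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, neighbors = nn.kneighbors(X_min)  # column 0 is the sample itself
    base_idx = rng.integers(len(X_min), size=n_needed)
    nb_choice = rng.integers(1, k_eff + 1, size=n_needed)
    u = rng.random(n_needed)
    base = X_min[base_idx]
    nb = X_min[neighbors[base_idx, nb_choice]]
    synthetic = base + u[:, None] * (nb - base)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# classical-ML benchmark
# ---------------------------------------------------------------------------

#: Hyperparameter search spaces (not published; defaults chosen as the
#: standard small-cohort grids and logged with every run).
DEFAULT_GRIDS = {
    "svm": (
        lambda seed: SVC(probability=True, random_state=seed),
        {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", "auto"]},
    ),
    "rf": (
        lambda seed: RandomForestClassifier(random_state=seed),
        {"clf__n_estimators": [100], "clf__max_depth": [None, 3, 5]},
    ),
    "knn": (
        lambda seed: KNeighborsClassifier(),
        {"clf__n_neighbors": [3, 5, 7]},
    ),
    "dt": (
        lambda seed: DecisionTreeClassifier(random_state=seed),
        {"clf__max_depth": [None, 3, 5]},
    ),
}


class BenchmarkModel:
    """Soft-voting ensemble of four classical classifiers on ranked features.

    statsmodels-style: construct from the training table, ``fit()`` returns
    a :class:`BenchmarkResults`.
    """

    def __init__(self, X, y, n_top_features: int = 8, grids=None, seed: int = 0, smote_k: int = 5):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if len(np.unique(self.y)) < 2:
            raise ClassMissing("training data must contain both classes")
        if not 1 <= n_top_features <= self.X.shape[1]:
            raise ValueError("n_top_features out of range")
        self.n_top = int(n_top_features)
        self.grids = grids or DEFAULT_GRIDS
        self.seed = int(seed)
        self.smote_k = smote_k

    def fit(self) -> "BenchmarkResults":
        order, scores = rank_features(self.X, self.y)
        top = order[: self.n_top]
        rng = np.random.default_rng(self.seed)
        X_bal, y_bal = smote_oversample(self.X[:, top], self.y, k=self.smote_k, rng=rng)
        counts = np.bincount(y_bal)
        cv = int(min(5, counts[counts > 0].min()))
        fitted = {}
        for name, (factory, grid) in self.grids.items():
            pipe = Pipeline([("scale", StandardScaler()), ("clf", factory(self.seed))])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", FutureWarning)
                    if cv >= 2:
                        search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy")
                        search.fit(X_bal, y_bal)
                        fitted[name] = search.best_estimator_
                    else:
                        pipe.fit(X_bal, y_bal)
                        fitted[name] = pipe
            except Exception as exc:  # noqa: BLE001 - surfaced as FitError
                raise FitError(f"{name}: grid search failed ({exc})") from exc
        return BenchmarkResults(self, fitted, top, scores)


@dataclass
class BenchmarkResults:
    model: BenchmarkModel
    estimators: dict
    selected_features: np.ndarray
    f_scores: np.ndarray

    def predict_proba(self, X) -> pd.DataFrame:
        """Per-model Syed probabilities plus the soft-vote mean."""
        X = np.asarray(X, dtype=float)[:, self.selected_features]
        cols = {}
        for name, est in self.estimators.items():
            classes = list(est.classes_)
            cols[name] = est.predict_proba(X)[:, classes.index(1)]
        df = pd.DataFrame(cols)
        df["soft_vote"] = df.mean(axis=1)
        return df

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Soft-vote labels: Syed iff the mean probability >= threshold."""
        return (self.predict_proba(X)["soft_vote"].to_numpy() >= threshold).astype(int)

    def accuracy(self, X, y, threshold: float = 0.5) -> float:
        return float((self.predict(X, threshold) == np.asarray(y, dtype=int)).mean())

    def summary(self) -> str:
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in self.selected_features]
        lines = [
            "Classical-ML benchmark (soft-voting ensemble)",
            f"top-ranked features ({len(names)}): " + ", ".join(names),
            "models: " + ", ".join(self.estimators),
        ]
        return "\n".join(lines)


def ml_benchmark(
    X_train,
    y_train,
    X_test,
    n_top_features: int = 8,
    grids=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Functional wrapper: per-model test probabilities and soft-vote labels."""
    results = BenchmarkModel(
        X_train, y_train, n_top_features=n_top_features, grids=grids, seed=seed
    ).fit()
    probs = results.predict_proba(X_test)
    return probs, (probs["soft_vote"].to_numpy() >= 0.5).astype(int)
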