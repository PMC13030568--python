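"""Cost-sensitive boosted classification with hybrid imbalance handling.

Training-set-only Z-score normalization; SMOTE oversampling of the fatigue
minority (synthetic points on segments between a minority sample and one of
its k = 5 nearest minority neighbours); a per-fold positive-class weight
``w_pos = N_neg / N_pos`` applied to the weighted binary log-loss (realised
as per-instance weights — for log-loss this scales gradients and hessians of
positive instances exactly); and Youden-J threshold moving in place of the
default 0.5 cutoff, with ties broken toward the smallest threshold (the
safety-first preference: favour sensitivity).

Per-subject calibration freezes the generic ensemble and (a) appends a small
number of strongly shrunk trees fit on the calibration windows, (b) refits
the decision threshold on calibration scores.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import xgboost as xgb
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NormStats",
    "ImbalanceConfig",
    "BoostParams",
    "TrainedModel",
    "fit_normalizer",
    "apply_normalizer",
    "smote_oversample",
    "fold_pos_weight",
    "train_cost_sensitive_gbt",
    "optimal_threshold",
    "fit_pipeline",
    "predict",
    "calibrate_subject",
    "save_model",
    "load_model",
]


@dataclass
class NormStats:
    """Per-feature training-set mean and (sample) standard deviation."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ImbalanceConfig:
    """Hybrid imbalance-handling knobs.

    ``smote_ratio`` is the target minority/majority fraction after
    oversampling; 0.5 keeps the class weight mechanism active alongside
    SMOTE rather than letting oversampling balance the problem outright.
    """

    smote_k: int = 5
    smote_ratio: float = 0.5
    use_smote: bool = True
    use_weight: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be at least 1")
        if not 0 < self.smote_ratio <= 1:
            raise ValueError("smote_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class BoostParams:
    """Boosted-tree hyperparameters (binary log-loss objective)."""

    learning_rate: float = 0.01
    n_estimators: int = 500
    max_depth: int = 8
    subsample: float = 0.7
    colsample_bytree: float = 0.8
    reg_alpha: float = 0.0
    reg_lambda: float = 1.0

    def as_xgb_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "alpha": self.reg_alpha,
            "lambda": self.reg_lambda,
            "tree_method": "hist",
            "nthread": 1,
            "base_score": 0.5,
        }


@dataclass
class TrainedModel:
    """The deployable unit: normalization stats + ensemble + weight + threshold."""

    norm: NormStats
    booster: xgb.Booster
    w_pos: float
    threshold: float
    feature_names: list[str]
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("decision threshold must lie in [0, 1]")


def fit_normalizer(X: np.ndarray, feature_names: list[str] | None = None) -> NormStats:
    """Z-score statistics from training rows only (sample SD, N-1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("normalizer needs a 2-D array with at least 2 training rows")
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length does not match the feature dimension")
    return NormStats(np.mean(X, axis=0), np.std(X, axis=0, ddof=1), list(names))


def apply_normalizer(
    stats: NormStats, X: np.ndarray, feature_names: list[str] | None = None
) -> np.ndarray:
    """``x' = (x - mu) / sigma`` per feature; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != stats.mean.size:
        raise ValueError("feature dimension does not match the fitted normalizer")
    if feature_names is not None and list(feature_names) != stats.feature_names:
        raise ValueError("feature ordering does not match the fitted normalizer")
    safe = np.where(stats.std == 0, 1.0, stats.std)
    out = (X - stats.mean) / safe
    return np.where(stats.std == 0, 0.0, out)


def smote_oversample(
    X: np.ndarray, y: np.ndarray, cfg: ImbalanceConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the minority (positive) class.

    Synthetic count = ``round(smote_ratio * N_neg) - N_pos`` (floored at 0).
    Each synthetic point is ``x_i + delta * (x_hat_i - x_i)`` with ``x_i``
    cycled round-robin through the minority rows, ``x_hat_i`` drawn uniformly
    from its ``k`` nearest minority neighbours (euclidean — call this in
    normalized feature space), and ``delta ~ U[0, 1]``.  Training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_syn = max(int(round(cfg.smote_ratio * neg.size)) - pos.size, 0)
    if n_syn == 0:
        return X, y
    if pos.size < 2:
        warnings.warn("fewer than 2 minority samples: SMOTE skipped", stacklevel=2)
        return X, y
    k = cfg.smote_k
    if pos.size <= k:
        warnings.warn(
            f"minority count {pos.size} <= k={k}; truncating k to {pos.size - 1}",
            stacklevel=2,
        )
        k = pos.size - 1
    Xp = X[pos]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xp)
    _, idx = nn.kneighbors(Xp)  # column 0 is the point itself
    synth = np.empty((n_syn, X.shape[1]))
    for s in range(n_syn):
        i = s % pos.size
        j = idx[i][1:][rng.integers(k)]
        delta = rng.uniform()
        synth[s] = Xp[i] + delta * (Xp[j] - Xp[i])
    return np.vstack([X, synth]), np.concatenate([y, np.ones(n_syn, dtype=int)])


def fold_pos_weight(y: np.ndarray) -> float:
    """``w_pos = N_neg / N_pos`` on the fold's original (pre-SMOTE) labels."""
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("training fold contains no positive (fatigue) samples")
    return float(np.sum(y == 0)) / n_pos


def train_cost_sensitive_gbt(
    X: np.ndarray,
    y: np.ndarray,
    w_pos: float,
    params: BoostParams = BoostParams(),
    seed: int = 42,
) -> xgb.Booster:
    """Boosted trees with the positive class up-weighted by ``w_pos``.

    Positive instances carry weight ``w_pos`` in the binary log-loss, which
    scales their gradients and hessians exactly as a weighted gradient
    update would.  Deterministic given the seed (single-threaded hist).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        bad = np.flatnonzero(~np.all(np.isfinite(X), axis=1))
        raise ValueError(f"non-finite features in rows {bad[:10].tolist()}")
    weights = np.where(y == 1, w_pos, 1.0)
    dtrain = xgb.DMatrix(X, label=y, weight=weights)
    p = params.as_xgb_params()
    p["seed"] = int(seed)
    return xgb.train(p, dtrain, num_boost_round=params.n_estimators)


def optimal_threshold(
    scores: np.ndarray, y: np.ndarray, tie: str = "smallest"
) -> tuple[float, float]:
    """Youden-J-maximizing decision threshold by exhaustive candidate search.

    Candidates are every unique score, midpoints between consecutive unique
    scores, and {0, 1}.  ``J(Th) = sensitivity + specificity - 1`` with
    "predict positive iff score >= Th".  Ties go to the smallest optimal
    threshold (the safety-first preference: favour sensitivity); with
    ``tie="midpoint"`` the centre of the optimal interval is returned
    instead, which generalizes better from very small validation sets.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if scores.size != y.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to optimize Youden's J")
    uniq = np.unique(scores)
    cand = np.unique(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0, [0.0, 1.0]]))
    pred = scores[None, :] >= cand[:, None]
    pos = y == 1
    sens = np.sum(pred[:, pos], axis=1) / np.sum(pos)
    spec = np.sum(~pred[:, ~pos], axis=1) / np.sum(~pos)
    j = sens + spec - 1.0
    j_max = float(np.max(j))
    best = cand[j >= j_max - 1e-12]
    if tie == "midpoint":
        return float((np.min(best) + np.max(best)) / 2.0), j_max
    if tie != "smallest":
        raise ValueError(f"unknown tie-break {tie!r}")
    # J is a step function that changes only at observed scores, so midpoint
    # candidates never attain a J that no score attains; tie-break over the
    # score-valued candidates (plus the {0, 1} sentinels).
    at_scores = best[np.isin(best, np.concatenate([uniq, [0.0, 1.0]]))]
    return float(np.min(at_scores if at_scores.size else best)), j_max


def _booster_proba(booster: xgb.Booster, X: np.ndarray) -> np.ndarray:
    return np.asarray(booster.predict(xgb.DMatrix(np.asarray(X, dtype=float))), dtype=float)


def fit_pipeline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    imbalance: ImbalanceConfig = ImbalanceConfig(),
    params: BoostParams = BoostParams(),
    seed: int = 42,
    feature_names: list[str] | None = None,
    threshold: float = 0.5,
) -> TrainedModel:
    """Normalize -> (SMOTE) -> (weight) -> boost, on training data only.

    The decision threshold is *not* searched here — pass one obtained from
    validation scores (see the evaluation protocols) or keep the 0.5 default.
    """
    y_train = np.asarray(y_train, dtype=int)
    norm = fit_normalizer(X_train, feature_names)
    Xn = apply_normalizer(norm, X_train)
    w_pos = fold_pos_weight(y_train) if imbalance.use_weight else 1.0
    if imbalance.use_smote:
        Xn, y_fit = smote_oversample(Xn, y_train, imbalance, seed=seed)
    else:
        y_fit = y_train
    booster = train_cost_sensitive_gbt(Xn, y_fit, w_pos, params, seed)
    return TrainedModel(
        norm,
        booster,
        w_pos,
        threshold,
        norm.feature_names,
        seed,
        metadata={"imbalance": asdict(imbalance), "boost": asdict(params)},
    )


def predict(
    model: TrainedModel, X: np.ndarray, feature_names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels (positive iff p >= threshold)."""
    Xn = apply_normalizer(model.norm, X, feature_names)
    proba = _booster_proba(model.booster, Xn)
    return proba, (proba >= model.threshold).astype(int)


def calibrate_subject(
    model: TrainedModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    seed: int = 42,
    n_extra_trees: int = 10,
    extra_learning_rate: float = 0.002,
    extra_max_depth: int = 2,
) -> TrainedModel:
    """Adapt a generic model to one subject using its first windows.

    The generic ensemble is frozen; adaptation appends ``n_extra_trees``
    shallow, strongly shrunk trees fit on the calibration windows (continued
    boosting from the generic model's margins) and refits the Youden-J
    threshold on calibration scores.  Both steps need both classes in the
    calibration set; a single-class or empty set returns the generic model
    unchanged (with a status note).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=int)
    if X_cal.size == 0:
        return model
    if len(np.unique(y_cal)) < 2:
        out = replace(model)
        out.metadata = {**model.metadata, "calibration": "skipped: single-class calibration set"}
        return out
    Xn = apply_normalizer(model.norm, X_cal)
    weights = np.where(y_cal == 1, model.w_pos, 1.0)
    dcal = xgb.DMatrix(Xn, label=y_cal, weight=weights)
    p = BoostParams(
        learning_rate=extra_learning_rate, max_depth=extra_max_depth, subsample=1.0, colsample_bytree=1.0
    ).as_xgb_params()
    p["seed"] = int(seed)
    booster = xgb.train(
        p, dcal, num_boost_round=n_extra_trees, xgb_model=model.booster.copy()
    )
    scores = _booster_proba(booster, Xn)
    # Threshold refit, with three robustness rules for tiny calibration sets:
    # (1) fewer than 3 examples of either class -> keep the generic threshold
    # (a refit would be statistically meaningless);
    # (2) midpoint of the J-optimal interval rather than its lower edge (the
    # smallest optimal threshold sits directly on the highest calibration
    # alert score and transfers poorly);
    # (3) the generic threshold is a lower bound: it was validated on large
    # cross-subject pools with the safety-first preference, and the failure
    # mode calibration exists to repair is subject-specific FP-proneness,
    # so per-subject refits may raise the threshold but never lower it.
    if min(int(np.sum(y_cal == 1)), int(np.sum(y_cal == 0))) >= 3:
        th_refit, _ = optimal_threshold(scores, y_cal, tie="midpoint")
        th = max(model.threshold, th_refit)
    else:
        th = model.threshold
    return TrainedModel(
        model.norm,
        booster,
        model.w_pos,
        th,
        list(model.feature_names),
        model.seed,
        metadata={**model.metadata, "calibration": f"appended {n_extra_trees} trees"},
    )


def config_hash(*objs) -> str:
    """Short stable hash of dataclass/dict configuration objects."""
    def _conv(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return o

    payload = json.dumps([_conv(o) for o in objs], sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def save_model(model: TrainedModel, path) -> None:
    """Serialize the full deployable unit to one JSON artifact."""
    raw = model.booster.save_raw("json").decode()
    doc = {
        "schema": "rtfatigue-model-v1",
        "feature_names": model.feature_names,
        "norm_mean": model.norm.mean.tolist(),
        "norm_std": model.norm.std.tolist(),
        "w_pos": model.w_pos,
        "threshold": model.threshold,
        "seed": model.seed,
        "metadata": model.metadata,
        "config_hash": config_hash(model.metadata),
        "booster": raw,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "rtfatigue-model-v1":
        raise ValueError(f"{path}: not an rtfatigue model artifact")
    booster = xgb.Booster()
    booster.load_model(bytearray(doc["booster"].encode()))
    norm = NormStats(doc["norm_mean"], doc["norm_std"], doc["feature_names"])
    return TrainedModel(
        norm,
        booster,
        doc["w_pos"],
        doc["threshold"],
        doc["feature_names"],
        doc["seed"],
        doc.get("metadata", {}),
    )
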