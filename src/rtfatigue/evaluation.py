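"""Evaluation protocols and statistics.

Protocol A (mixed-subject): stratified 80:20 split, inner stratified 5-fold
cross-validation on the training portion supplying pooled out-of-fold scores
for threshold selection, final refit on the full training portion, report on
the untouched test portion.

Protocol B (LOSO): leave-one-subject-out; threshold search uses inner
out-of-fold pools within the N-1 training subjects only.  Train and test
subject sets are asserted disjoint on every fold.

Also: the per-subject calibration experiment (first-30-windows calibration
set), the modality x imbalance-strategy ablation harness, and the
Friedman + Nemenyi multi-model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import dataset, model as mdl
from .model import BoostParams, ImbalanceConfig

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "STRATEGIES",
    "confusion_metrics",
    "roc_auc",
    "cv_threshold",
    "run_protocol_a",
    "run_protocol_loso",
    "run_calibration_experiment",
    "ablation_harness",
    "friedman_nemenyi",
    "run_study",
]

log = logging.getLogger(__name__)

METRIC_KEYS = ["accuracy", "precision", "sensitivity", "specificity", "f1"]

# imbalance-handling strategies: (use_smote, use_weight, use_threshold_moving)
STRATEGIES: dict[str, tuple[bool, bool, bool]] = {
    "none": (False, False, False),
    "weight": (False, True, False),
    "smote": (True, False, False),
    "hybrid": (True, True, True),
}


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    """Overall metrics plus per-fold / per-subject breakdowns with mean +/- SD."""

    overall: dict
    per_unit: pd.DataFrame
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Threshold metrics from the confusion matrix.

    Accuracy, precision, sensitivity (recall), specificity and F1
    (``2TP / (2TP + FP + FN)``).  Ratios with a zero denominator are
    reported as 0 and listed under ``flags`` rather than raising, so that
    degenerate folds do not abort a sweep.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("need equal-length, non-empty label vectors")
    cm = ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
    flags: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    out = {
        "accuracy": _ratio(cm.TP + cm.TN, cm.n, "accuracy"),
        "precision": _ratio(cm.TP, cm.TP + cm.FP, "precision"),
        "sensitivity": _ratio(cm.TP, cm.TP + cm.FN, "sensitivity"),
        "specificity": _ratio(cm.TN, cm.TN + cm.FP, "specificity"),
        "f1": _ratio(2 * cm.TP, 2 * cm.TP + cm.FP + cm.FN, "f1"),
        "confusion": cm,
        "flags": flags,
    }
    return out


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve (tie-corrected concordance)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y_true, scores))


def _xy(df: pd.DataFrame, modality: str = "fusion") -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = dataset.modality_columns(modality)
    labelled = df[df["label"] != dataset.LABEL_EXCLUDED]
    return labelled[cols].to_numpy(float), labelled["label"].to_numpy(int), cols


def cv_threshold(
    X: np.ndarray,
    y: np.ndarray,
    imbalance: ImbalanceConfig,
    params: BoostParams,
    seed: int,
    n_folds: int = 5,
) -> float:
    """Youden-J threshold from pooled out-of-fold validation scores."""
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    folds = max(2, min(n_folds, n_pos))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(y.size, np.nan)
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            continue
        m = mdl.fit_pipeline(X[tr], y[tr], imbalance, params, seed=seed)
        oof[va], _ = mdl.predict(m, X[va])
    ok = ~np.isnan(oof)
    th, _ = mdl.optimal_threshold(oof[ok], y[ok])
    return th


def _fit_with_strategy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    strategy: str,
    imbalance: ImbalanceConfig,
    params: BoostParams,
    seed: int,
    inner_folds: int,
    feature_names: list[str] | None = None,
) -> mdl.TrainedModel:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown imbalance strategy {strategy!r}")
    use_smote, use_weight, use_thresh = STRATEGIES[strategy]
    imb = ImbalanceConfig(
        smote_k=imbalance.smote_k,
        smote_ratio=imbalance.smote_ratio,
        use_smote=use_smote,
        use_weight=use_weight,
        seed=imbalance.seed,
    )
    th = cv_threshold(X_train, y_train, imb, params, seed, inner_folds) if use_thresh else 0.5
    return mdl.fit_pipeline(
        X_train, y_train, imb, params, seed=seed, feature_names=feature_names, threshold=th
    )


def run_protocol_a(
    df: pd.DataFrame,
    seed: int = 42,
    imbalance: ImbalanceConfig = ImbalanceConfig(),
    params: BoostParams = BoostParams(),
    inner_folds: int = 5,
    test_size: float = 0.2,
    modality: str = "fusion",
    strategy: str = "hybrid",
) -> EvalReport:
    """Mixed-subject evaluation: stratified 80:20 split + inner-CV threshold."""
    X, y, cols = _xy(df, modality)
    idx = np.arange(y.size)
    tr_idx, te_idx = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    if len(np.unique(y[te_idx])) < 2:
        raise ValueError("stratified split produced a single-class test set")
    m = _fit_with_strategy(
        X[tr_idx], y[tr_idx], strategy, imbalance, params, seed, inner_folds, cols
    )
    proba, pred = mdl.predict(m, X[te_idx])
    overall = confusion_metrics(y[te_idx], pred)
    overall["auc"] = roc_auc(y[te_idx], proba)
    overall["threshold"] = m.threshold
    per_unit = pd.DataFrame(
        {"split": ["test"], "n": [te_idx.size], "accuracy": [overall["accuracy"]]}
    )
    return EvalReport(
        overall,
        per_unit,
        extras={
            "seed": seed,
            "model": m,
            "train_index": tr_idx,
            "test_index": te_idx,
            "config_hash": mdl.config_hash(imbalance, params),
        },
    )


def _subject_folds(df: pd.DataFrame):
    labelled = df[df["label"] != dataset.LABEL_EXCLUDED].reset_index(drop=True)
    for subject in sorted(labelled["subject_id"].unique()):
        te = labelled[labelled["subject_id"] == subject]
        tr = labelled[labelled["subject_id"] != subject]
        yield subject, tr, te


def run_protocol_loso(
    df: pd.DataFrame,
    seed: int = 42,
    imbalance: ImbalanceConfig = ImbalanceConfig(),
    params: BoostParams = BoostParams(),
    inner_folds: int = 3,
    modality: str = "fusion",
    strategy: str = "hybrid",
) -> EvalReport:
    """Leave-one-subject-out evaluation with per-subject metric breakdown."""
    labelled = df[df["label"] != dataset.LABEL_EXCLUDED]
    if labelled["subject_id"].nunique() < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    cols = dataset.modality_columns(modality)
    rows = []
    pooled_y, pooled_p, pooled_pred = [], [], []
    for subject, tr, te in _subject_folds(df):
        assert set(tr["subject_id"]) & set(te["subject_id"]) == set(), "subject leakage"
        y_tr = tr["label"].to_numpy(int)
        if len(np.unique(y_tr)) < 2:
            log.warning("LOSO fold %s skipped: single-class training pool", subject)
            rows.append({"subject_id": subject, "status": "skipped_single_class_pool"})
            continue
        m = _fit_with_strategy(
            tr[cols].to_numpy(float), y_tr, strategy, imbalance, params, seed, inner_folds, cols
        )
        y_te = te["label"].to_numpy(int)
        proba, pred = mdl.predict(m, te[cols].to_numpy(float))
        met = confusion_metrics(y_te, pred)
        rec = {"subject_id": subject, "status": "ok", "n": y_te.size, "threshold": m.threshold}
        rec.update({k: met[k] for k in METRIC_KEYS})
        rec["auc"] = roc_auc(y_te, proba) if len(np.unique(y_te)) == 2 else np.nan
        rows.append(rec)
        pooled_y.append(y_te)
        pooled_p.append(proba)
        pooled_pred.append(pred)
    per_subject = pd.DataFrame(rows)
    ok = per_subject[per_subject["status"] == "ok"]
    mean = {k: float(ok[k].mean()) for k in METRIC_KEYS}
    sd = {k: float(ok[k].std(ddof=1)) for k in METRIC_KEYS}
    mean["auc"] = float(ok["auc"].mean(skipna=True))
    y_all = np.concatenate(pooled_y)
    overall = confusion_metrics(y_all, np.concatenate(pooled_pred))
    overall["auc"] = (
        roc_auc(y_all, np.concatenate(pooled_p)) if len(np.unique(y_all)) == 2 else np.nan
    )
    return EvalReport(overall, per_subject, mean, sd, extras={"seed": seed})


def run_calibration_experiment(
    df: pd.DataFrame,
    seed: int = 42,
    n_cal: int = 30,
    imbalance: ImbalanceConfig = ImbalanceConfig(),
    params: BoostParams = BoostParams(),
    inner_folds: int = 3,
    modality: str = "fusion",
) -> EvalReport:
    """Per-subject cold-start calibration: first ``n_cal`` windows adapt the model.

    For each LOSO fold: the generic model is scored on the subject's windows
    after the first ``n_cal`` (chronological order), then calibrated on those
    first windows and re-scored on the same test windows.  Subjects with at
    most ``n_cal`` labelled windows are excluded (logged).  A paired t-test
    compares per-subject accuracies before/after calibration.
    """
    cols = dataset.modality_columns(modality)
    rows = []
    for subject, tr, te in _subject_folds(df):
        te = te.sort_values(["t0"]).reset_index(drop=True)
        if len(te) <= n_cal:
            log.info("calibration: subject %s excluded (%d <= %d windows)", subject, len(te), n_cal)
            continue
        y_tr = tr["label"].to_numpy(int)
        if len(np.unique(y_tr)) < 2:
            continue
        generic = _fit_with_strategy(
            tr[cols].to_numpy(float), y_tr, "hybrid", imbalance, params, seed, inner_folds, cols
        )
        cal, test = te.iloc[:n_cal], te.iloc[n_cal:]
        assert float(cal["t0"].max()) < float(test["t0"].min()), "calibration must precede test"
        X_te, y_te = test[cols].to_numpy(float), test["label"].to_numpy(int)
        _, pred_g = mdl.predict(generic, X_te)
        acc_g = confusion_metrics(y_te, pred_g)["accuracy"]
        calibrated = mdl.calibrate_subject(
            generic, cal[cols].to_numpy(float), cal["label"].to_numpy(int), seed=seed
        )
        _, pred_c = mdl.predict(calibrated, X_te)
        acc_c = confusion_metrics(y_te, pred_c)["accuracy"]
        rows.append(
            {
                "subject_id": subject,
                "n_test": len(test),
                "cal_two_class": len(np.unique(cal["label"])) == 2,
                "generic_accuracy": acc_g,
                "calibrated_accuracy": acc_c,
                "delta": acc_c - acc_g,
            }
        )
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValueError("no subject had enough windows for the calibration experiment")
    mean = {
        "generic_accuracy": float(per_subject["generic_accuracy"].mean()),
        "calibrated_accuracy": float(per_subject["calibrated_accuracy"].mean()),
        "delta": float(per_subject["delta"].mean()),
    }
    sd = {"delta": float(per_subject["delta"].std(ddof=1))}
    if len(per_subject) >= 2 and per_subject["delta"].std(ddof=1) > 0:
        t, p = stats.ttest_rel(
            per_subject["calibrated_accuracy"], per_subject["generic_accuracy"]
        )
        extras = {"paired_t": float(t), "paired_p": float(p)}
    else:
        extras = {"paired_t": 0.0, "paired_p": 1.0}
    extras["seed"] = seed
    return EvalReport(mean, per_subject, mean, sd, extras)


def ablation_harness(
    df: pd.DataFrame,
    seed: int = 42,
    modalities: tuple[str, ...] = ("eye", "ecg", "fusion"),
    strategies: tuple[str, ...] = ("none", "weight", "smote", "hybrid"),
    n_folds: int = 5,
    inner_folds: int = 3,
    imbalance: ImbalanceConfig = ImbalanceConfig(),
    params: BoostParams = BoostParams(),
) -> pd.DataFrame:
    """Modality x imbalance-strategy grid under stratified 5-fold CV.

    Returns a tidy table with per-configuration mean +/- SD of accuracy,
    AUC, sensitivity and F1 across folds, plus the per-fold values.
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown imbalance strategy {s!r}")
    X_all, y_all, _ = _xy(df, "fusion")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X_all, y_all))
    records = []
    for modality in modalities:
        X, y, cols = _xy(df, modality)
        for strategy in strategies:
            for fold, (tr, te) in enumerate(splits):
                m = _fit_with_strategy(
                    X[tr], y[tr], strategy, imbalance, params, seed, inner_folds, cols
                )
                proba, pred = mdl.predict(m, X[te])
                met = confusion_metrics(y[te], pred)
                records.append(
                    {
                        "modality": modality,
                        "strategy": strategy,
                        "fold": fold,
                        "n_features": len(cols),
                        "accuracy": met["accuracy"],
                        "sensitivity": met["sensitivity"],
                        "f1": met["f1"],
                        "auc": roc_auc(y[te], proba)
                        if len(np.unique(y[te])) == 2
                        else np.nan,
                    }
                )
    folds_df = pd.DataFrame(records)
    summary = (
        folds_df.groupby(["modality", "strategy"])[["accuracy", "auc", "sensitivity", "f1"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    summary.attrs["per_fold"] = folds_df
    return summary


def friedman_nemenyi(metric_matrix: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> dict:
    """Friedman test over blocks x models, with Nemenyi post hoc comparisons.

    Within-block ranks (1 = best, average ranks on ties) feed the classic
    chi-square statistic ``12 b / (k (k + 1)) * sum_j (Rbar_j - (k+1)/2)^2``.
    When the statistic is non-zero, pairwise mean-rank differences are
    compared against the Nemenyi critical difference at ``alpha``.
    """
    if isinstance(metric_matrix, pd.DataFrame):
        names = list(metric_matrix.columns)
        m = metric_matrix.to_numpy(float)
    else:
        m = np.asarray(metric_matrix, dtype=float)
        names = [f"model_{j}" for j in range(m.shape[1])]
    b, k = m.shape
    if b < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 models")
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in m])
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * b / (k * (k + 1)) * float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    if chi2 <= 1e-12:
        return {
            "chi2": 0.0,
            "p": 1.0,
            "mean_ranks": dict(zip(names, mean_ranks)),
            "critical_difference": np.nan,
            "pairwise": None,
        }
    p = float(stats.chi2.sf(chi2, k - 1))
    q = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0)
    cd = float(q * np.sqrt(k * (k + 1) / (6.0 * b)))
    pairwise = pd.DataFrame(
        np.abs(mean_ranks[:, None] - mean_ranks[None, :]), index=names, columns=names
    )
    return {
        "chi2": chi2,
        "p": p,
        "mean_ranks": dict(zip(names, mean_ranks)),
        "critical_difference": cd,
        "pairwise": pairwise,
        "significant": pairwise > cd,
    }


def run_study(
    seed: int = 42,
    cohort_config=None,
    ablation_strategies: tuple[str, ...] = ("none", "weight", "smote", "hybrid"),
    ablation_modalities: tuple[str, ...] = ("eye", "ecg", "fusion"),
) -> dict:
    """End-to-end desk-scale study on a synthetic cohort.

    Generates the cohort, extracts features through the full signal pipeline,
    validates labels, then runs Protocol A, LOSO, the calibration experiment
    and the ablation grid.  Returns a dict of headline quantities.
    """
    from . import synthetic

    cfg = cohort_config or synthetic.CohortConfig.compact(seed=seed)
    cohort = synthetic.gen_cohort(cfg)
    features, rejections = dataset.build_feature_table(
        cohort.gaze, cohort.ecg, cohort.session, cohort.grid
    )
    labelled = features[features["label"] != dataset.LABEL_EXCLUDED]
    n_alert = int((labelled["label"] == 0).sum())
    n_fatigue = int((labelled["label"] == 1).sum())
    validation = dataset.validate_labels(features)

    rep_a = run_protocol_a(features, seed=seed)
    rep_loso = run_protocol_loso(features, seed=seed)
    rep_cal = run_calibration_experiment(features, seed=seed)
    ablation = ablation_harness(
        features, seed=seed, modalities=ablation_modalities, strategies=ablation_strategies
    )

    def _cell(modality: str, strategy: str, col: str) -> float:
        row = ablation[(ablation["modality"] == modality) & (ablation["strategy"] == strategy)]
        return float(row[col].iloc[0])

    return {
        "features": features,
        "rejections": rejections,
        "n_windows": int(len(features)),
        "n_alert": n_alert,
        "n_fatigue": n_fatigue,
        "imbalance_ratio": n_alert / n_fatigue if n_fatigue else float("inf"),
        "label_validation": validation,
        "protocol_a": rep_a,
        "loso": rep_loso,
        "calibration": rep_cal,
        "ablation": ablation,
        "protocol_a_accuracy": rep_a.overall["accuracy"],
        "protocol_a_auc": rep_a.overall["auc"],
        "protocol_a_sensitivity": rep_a.overall["sensitivity"],
        "loso_accuracy": rep_loso.mean["accuracy"],
        "generalization_gap": rep_a.overall["accuracy"] - rep_loso.mean["accuracy"],
        "calibration_gain": rep_cal.mean["delta"],
        "fusion_auc": _cell("fusion", "hybrid", "auc_mean"),
        "eye_auc": _cell("eye", "hybrid", "auc_mean"),
        "ecg_auc": _cell("ecg", "hybrid", "auc_mean"),
        "hybrid_sensitivity": _cell("fusion", "hybrid", "sensitivity_mean"),
        "none_sensitivity": _cell("fusion", "none", "sensitivity_mean"),
        "seed": seed,
    }
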