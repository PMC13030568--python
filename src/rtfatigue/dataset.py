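"""Windowing, labeling and feature fusion.

Recordings are cut into non-overlapping 60-s windows aligned to scenario
start (trailing partial windows dropped).  Each window inherits the SP-7
rating its scenario received and is labelled by the extreme-group rule:
scores 1-3 -> alert (0), 5-7 -> fatigue (1), 4 -> excluded from model
fitting but retained in the table.  The 8 ocular and 4 cardiac features are
serially concatenated into a fixed-order 12-dimensional vector (early
fusion); normalization happens later, inside training partitions only.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import cardiac, ocular
from .ocular import AOIGrid

__all__ = [
    "FEATURE_NAMES",
    "OCULAR_FEATURES",
    "CARDIAC_FEATURES",
    "LABEL_EXCLUDED",
    "sp7_accounting",
    "sp7_to_label",
    "segment_windows",
    "assign_labels",
    "fuse_features",
    "modality_columns",
    "build_feature_table",
    "validate_labels",
]

log = logging.getLogger(__name__)

OCULAR_FEATURES = ["PERCLOS", "BF", "MBD", "MFD", "FF", "PDV", "SGE", "TGE"]
CARDIAC_FEATURES = ["MeanRR", "SDNN", "RMSSD", "LFHF"]
FEATURE_NAMES = OCULAR_FEATURES + CARDIAC_FEATURES  # canonical 12-D ordering

LABEL_ALERT = 0
LABEL_FATIGUE = 1
LABEL_EXCLUDED = -1

MAX_INVALID_GAZE_FRACTION = 0.30


def sp7_accounting(counts: Mapping[int, int]) -> dict:
    """Dataset bookkeeping from per-score SP-7 window counts.

    Returns totals for the alert (1-3) and fatigue (5-7) extreme groups, the
    excluded transitional share (score 4), the retained sample count and the
    alert:fatigue imbalance ratio.
    """
    if any(s not in range(1, 8) for s in counts):
        raise ValueError("SP-7 scores must lie in 1..7")
    n_alert = sum(counts.get(s, 0) for s in (1, 2, 3))
    n_fatigue = sum(counts.get(s, 0) for s in (5, 6, 7))
    n_excluded = counts.get(4, 0)
    n_total = n_alert + n_fatigue + n_excluded
    return {
        "n_total": n_total,
        "n_alert": n_alert,
        "n_fatigue": n_fatigue,
        "n_excluded": n_excluded,
        "n_retained": n_alert + n_fatigue,
        "excluded_pct": 100.0 * n_excluded / n_total if n_total else float("nan"),
        "imbalance_ratio": n_alert / n_fatigue if n_fatigue else float("inf"),
    }


def sp7_to_label(sp7: int) -> int:
    if sp7 in (1, 2, 3):
        return LABEL_ALERT
    if sp7 in (5, 6, 7):
        return LABEL_FATIGUE
    if sp7 == 4:
        return LABEL_EXCLUDED
    raise ValueError(f"SP-7 score {sp7} outside the 1-7 range")


def segment_windows(session: pd.DataFrame, window_s: float = 60.0) -> pd.DataFrame:
    """Non-overlapping half-open windows aligned to scenario start.

    One row per window with identity, time span and the scenario's SP-7
    score; trailing partial windows are dropped.  Scenarios shorter than one
    window yield nothing (logged).
    """
    rows = []
    for row in session.itertuples(index=False):
        dur = row.end_s - row.start_s
        n = int(dur // window_s)
        if n == 0:
            log.info("scenario %s shorter than %.0f s: no windows", row.scenario_id, window_s)
            continue
        for k in range(n):
            rows.append(
                {
                    "subject_id": row.subject_id,
                    "scenario_id": row.scenario_id,
                    "window_index": k,
                    "t0": row.start_s + window_s * k,
                    "t1": row.start_s + window_s * (k + 1),
                    "sp7": int(row.sp7_post),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "scenario_id", "window_index", "t0", "t1", "sp7"]
    )


def assign_labels(windows: pd.DataFrame) -> pd.DataFrame:
    """Extreme-group labels: 0 alert (SP-7 1-3), 1 fatigue (5-7), -1 excluded (4)."""
    out = windows.copy()
    out["label"] = out["sp7"].map(sp7_to_label)
    return out


def fuse_features(
    ocular_feats: ocular.OcularFeatures,
    cardiac_feats: cardiac.CardiacFeatures,
    modality: str = "fusion",
) -> np.ndarray:
    """Serial concatenation of the ocular and cardiac vectors.

    ``fusion`` -> 12-D (canonical order), ``eye`` -> 8-D, ``ecg`` -> 4-D.
    """
    if modality == "fusion":
        return np.concatenate([ocular_feats.as_vector(), cardiac_feats.as_vector()])
    if modality == "eye":
        return ocular_feats.as_vector()
    if modality == "ecg":
        return cardiac_feats.as_vector()
    raise ValueError(f"unknown modality {modality!r}")


def modality_columns(modality: str) -> list[str]:
    if modality == "fusion":
        return FEATURE_NAMES
    if modality == "eye":
        return OCULAR_FEATURES
    if modality == "ecg":
        return CARDIAC_FEATURES
    raise ValueError(f"unknown modality {modality!r}")


def build_feature_table(
    gaze: Mapping[tuple[str, str], ocular.GazeStream],
    ecg: Mapping[tuple[str, str], cardiac.ECGTrace],
    session: pd.DataFrame,
    grid: AOIGrid | None = None,
    velocity_threshold: float = 30.0,
    min_fix_dur_ms: float = 100.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full preprocessing + feature pipeline over a recorded cohort.

    Per scenario: blink repair and I-VT parsing of the gaze stream; wavelet
    denoising, Pan-Tompkins detection and ectopic rejection of the ECG.  Per
    window: the fused 12-D feature vector plus label.  Windows failing the
    artifact-rejection rules (over 30% invalid gaze samples, an unusable
    cardiac segment, or an implausible heart rate) are dropped; each
    rejection is returned with its reason.

    Returns ``(features, rejections)`` where ``features`` has one row per
    retained window: identity and timing columns, ``sp7``, ``label`` and the
    12 named feature columns.
    """
    grid = grid or AOIGrid()
    windows = assign_labels(segment_windows(session))
    rejections: list[dict] = []
    rows: list[dict] = []

    for key in session[["subject_id", "scenario_id"]].itertuples(index=False):
        key = (key.subject_id, key.scenario_id)
        scen_windows = windows[windows["scenario_id"] == key[1]]
        if scen_windows.empty:
            continue
        try:
            repaired, _ = ocular.repair_blinks(gaze[key])
            events = ocular.ivt_classify(repaired, velocity_threshold, min_fix_dur_ms)
        except ocular.UnusableSignalError as exc:
            for w in scen_windows.itertuples(index=False):
                rejections.append({**w._asdict(), "reason": f"gaze: {exc}"})
            continue
        denoised = cardiac.wavelet_denoise(ecg[key])
        peaks = cardiac.pan_tompkins(denoised)
        cardiac_ok = len(peaks) >= 3 and cardiac.heart_rate_plausible(
            peaks, denoised.duration
        )
        rr = cardiac.clean_rr(peaks) if cardiac_ok else None
        if rr is not None and rr.rejected_fraction > 0.5:
            cardiac_ok = False

        for w in scen_windows.itertuples(index=False):
            rec = w._asdict()
            if not cardiac_ok:
                rejections.append({**rec, "reason": "cardiac segment unusable"})
                continue
            gm = (repaired.t >= w.t0) & (repaired.t < w.t1)
            invalid_frac = 1.0 - float(np.mean(repaired.valid[gm])) if gm.any() else 1.0
            if invalid_frac > MAX_INVALID_GAZE_FRACTION:
                rejections.append(
                    {**rec, "reason": f"{invalid_frac:.0%} invalid gaze samples"}
                )
                continue
            try:
                ofeat = ocular.extract_window_features(repaired, events, grid, (w.t0, w.t1))
                cfeat = cardiac.extract_window_features(rr, (w.t0, w.t1))
            except (ValueError, ocular.UnusableSignalError) as exc:
                rejections.append({**rec, "reason": str(exc)})
                continue
            if "heart_rate_implausible" in cfeat.flags:
                rejections.append({**rec, "reason": "window heart rate implausible"})
                continue
            vec = fuse_features(ofeat, cfeat)
            rows.append(
                {**rec, **dict(zip(FEATURE_NAMES, vec)), "quality_flags": ";".join(ofeat.flags + cfeat.flags)}
            )

    features = pd.DataFrame(rows)
    for r in rejections:
        log.info("rejected window %s/%s#%d: %s", r["subject_id"], r["scenario_id"], r["window_index"], r["reason"])
    return features, rejections


def validate_labels(features: pd.DataFrame, equal_var: bool = True) -> dict:
    """Physiological sanity checks of the extreme-group labels via PERCLOS.

    On the cleaned table (excluded windows omitted): Spearman rank
    correlation between per-window SP-7 and PERCLOS, and a two-sample t-test
    of PERCLOS between label groups.  The t statistic is reported as
    fatigue-minus-alert, so a positive value means the fatigue group closes
    its eyes more.
    """
    clean = features[features["label"] != LABEL_EXCLUDED]
    out: dict = {"status": "ok"}
    if len(clean) < 3:
        return {"status": "too few labelled windows"}
    r, p = stats.spearmanr(clean["sp7"], clean["PERCLOS"])
    out["spearman_r"], out["spearman_p"] = float(r), float(p)
    g0 = clean.loc[clean["label"] == LABEL_ALERT, "PERCLOS"]
    g1 = clean.loc[clean["label"] == LABEL_FATIGUE, "PERCLOS"]
    if len(g0) < 2 or len(g1) < 2:
        out["status"] = "t-test skipped: a label group is (nearly) empty"
        out["t_stat"] = out["t_p"] = float("nan")
        return out
    t, tp = stats.ttest_ind(g1, g0, equal_var=equal_var)
    out["t_stat"], out["t_p"] = float(t), float(tp)
    return out
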