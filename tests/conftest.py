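"""Shared fixtures: tiny signal-level cohorts and the multi-seed study battery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtfatigue import dataset, evaluation, synthetic

BATTERY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small fully generated cohort (3 subjects x 3 scenarios x 2 min)."""
    cfg = synthetic.CohortConfig(
        n_subjects=3, scenarios_per_subject=3, scenario_len_s=120.0, seed=7
    )
    return synthetic.gen_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    feats, rejections = dataset.build_feature_table(
        tiny_cohort.gaze, tiny_cohort.ecg, tiny_cohort.session, tiny_cohort.grid
    )
    return feats, rejections


def make_feature_frame(
    n_subjects: int = 8,
    windows_per_subject: int = 40,
    pos_rate: float = 0.10,
    subject_shift_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic window-level feature table (no signal generation).

    A linearly separable-ish two-class layout with per-subject offsets; used
    by protocol/model tests that need a labelled table quickly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject = f"T{s + 1:02d}"
        shift = rng.normal(0, subject_shift_sd, size=len(dataset.FEATURE_NAMES))
        for w in range(windows_per_subject):
            label = int(rng.random() < pos_rate)
            base = rng.normal(0, 1, size=len(dataset.FEATURE_NAMES)) + shift
            base[:4] += 2.0 * label  # informative block
            rows.append(
                {
                    "subject_id": subject,
                    "scenario_id": f"{subject}-R{w // 6 + 1:02d}",
                    "window_index": w,
                    "t0": 60.0 * w,
                    "t1": 60.0 * (w + 1),
                    "sp7": 6 if label else 2,
                    "label": label,
                    **dict(zip(dataset.FEATURE_NAMES, base)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def feature_frame():
    return make_feature_frame()


@pytest.fixture(scope="session")
def study_battery():
    """Five-seed end-to-end study on the desk-scale cohort.

    Shared by the directional acceptance checks; computed once per session.
    Only scalar summaries are retained.
    """
    keep = [
        "n_windows",
        "n_alert",
        "n_fatigue",
        "imbalance_ratio",
        "protocol_a_accuracy",
        "protocol_a_auc",
        "protocol_a_sensitivity",
        "loso_accuracy",
        "generalization_gap",
        "calibration_gain",
        "fusion_auc",
        "eye_auc",
        "ecg_auc",
        "hybrid_sensitivity",
        "none_sensitivity",
        "seed",
    ]
    out = []
    for seed in BATTERY_SEEDS:
        res = evaluation.run_study(seed=seed, ablation_strategies=("none", "hybrid"))
        rec = {k: res[k] for k in keep}
        rec["spearman_r"] = res["label_validation"]["spearman_r"]
        rec["t_stat"] = res["label_validation"]["t_stat"]
        out.append(rec)
    return out
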