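"""Synthetic multi-subject gaze + ECG cohort with known ground truth.

No public dataset exists for remote-tower controller fatigue, so every
downstream stage is exercised on a generated cohort that emulates the study
conditions: scenario physiology placed on an alert-to-fatigue severity
continuum indexed by the scenario's SP-7 rating, 60-s analysis windows, a
rating distribution that reproduces the ~17:1 alert:fatigue window imbalance
reported for this population, per-subject multiplicative baseline offsets
(the cross-subject shift that leave-one-subject-out evaluation probes), and
raw signals at the native rates (gaze 100 Hz, ECG 512 Hz).

The RR tachogram is a direct sinusoid-plus-noise model: an LF tone at
0.10 Hz and an HF tone at 0.25 Hz (the band centres of the spectral HRV
definitions) on top of the regime's mean RR, which makes the generator-true
LF/HF ratio a closed-form quantity, ``(lf_amp/hf_amp)^2``.  ECG morphology is
a Gaussian-kernel PQRST template placed at each beat time, contaminated with
0.2 Hz baseline wander, 50 Hz powerline interference and white noise.  Gaze
is a fixation/saccade state machine over a Markov chain of AOI cells whose
mixing is set by ``aoi_concentration`` (1 -> uniform chain, maximal scan
entropy), with Poisson blinks and rarer long closures driving PERCLOS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .cardiac import ECGTrace, RRSeries
from .ocular import AOIGrid, GazeStream

__all__ = [
    "RegimeParams",
    "ECGNoise",
    "CohortConfig",
    "Cohort",
    "GroundTruth",
    "ALERT",
    "FATIGUE",
    "TRANSITION",
    "SP7_WINDOW_COUNTS",
    "gen_rr_series",
    "gen_ecg",
    "gen_gaze_stream",
    "plan_sessions",
    "gen_cohort",
]

# Reference per-score SP-7 window distribution for this population (simulated
# remote-tower campaigns report roughly 77% alert [scores 1-3], 18.5%
# transitional [score 4] and 4.5% fatigue [scores 5-7] windows, a ~16.9:1
# alert:fatigue imbalance).  Used as the default scenario-rating mixture.
SP7_WINDOW_COUNTS: dict[int, int] = {1: 1245, 2: 890, 3: 520, 4: 638, 5: 112, 6: 35, 7: 10}


@dataclass(frozen=True)
class RegimeParams:
    """Generator parameters of one physiological regime.

    Units: RR quantities in ms, blink/closure rates in events per minute,
    durations in ms, pupil in mm.  ``aoi_concentration`` in (0, 1] mixes the
    AOI Markov chain between a self-biased kernel (0 -> stereotyped scanning,
    low entropy) and the uniform chain (1 -> maximal entropy).
    """

    mean_rr: float
    sdnn_target: float
    rmssd_target: float
    lf_amp: float
    hf_amp: float
    blink_rate: float
    blink_dur_mean: float
    closure_rate: float
    fix_dur_mean: float
    aoi_concentration: float
    pupil_base: float
    pupil_sd: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"RegimeParams.{f.name} must be positive")
        if self.aoi_concentration > 1.0:
            raise ValueError("aoi_concentration must lie in (0, 1]")

    @property
    def lfhf_true(self) -> float:
        """Power ratio of the two spectral tones, ``(lf_amp/hf_amp)^2``."""
        return (self.lf_amp / self.hf_amp) ** 2


# Alert vs fatigue presets.  Fatigue direction: slower heart rate (longer
# mean RR), higher vagally mediated variability (RMSSD), lower LF/HF, more
# and longer blinks, frequent long closures (PERCLOS), longer fixations,
# narrowed scanning (lower AOI mixing), smaller and less stable pupil.
ALERT = RegimeParams(
    mean_rr=750.0,
    sdnn_target=40.0,
    rmssd_target=25.0,
    lf_amp=25.0,
    hf_amp=12.0,
    blink_rate=10.0,
    blink_dur_mean=150.0,
    closure_rate=0.4,
    fix_dur_mean=240.0,
    aoi_concentration=0.75,
    pupil_base=3.6,
    pupil_sd=0.15,
)
FATIGUE = RegimeParams(
    mean_rr=820.0,
    sdnn_target=50.0,
    rmssd_target=38.0,
    lf_amp=15.0,
    hf_amp=22.0,
    blink_rate=16.0,
    blink_dur_mean=240.0,
    closure_rate=3.2,
    fix_dur_mean=310.0,
    aoi_concentration=0.55,
    pupil_base=3.4,
    pupil_sd=0.20,
)
TRANSITION = RegimeParams(
    **{
        f.name: 0.5 * (getattr(ALERT, f.name) + getattr(FATIGUE, f.name))
        for f in fields(RegimeParams)
    }
)

REGIME_PRESETS = {"alert": ALERT, "transition": TRANSITION, "fatigue": FATIGUE}
_SP7_BY_REGIME = {"alert": (1, 2, 3), "transition": (4,), "fatigue": (5, 6, 7)}


def severity_of_sp7(sp7: int) -> float:
    """Map an SP-7 rating onto the fatigue-severity continuum [0, 1]."""
    if sp7 not in range(1, 8):
        raise ValueError("SP-7 score must lie in 1..7")
    return (sp7 - 1) / 6.0


def params_for_severity(s: float) -> RegimeParams:
    """Field-wise linear interpolation between the alert and fatigue presets.

    Scenario physiology follows the subjective rating continuously (fully
    alert = 0 ... completely exhausted = 1) rather than jumping between two
    discrete presets: ratings adjacent across the extreme-group boundary
    (3 vs 5) therefore yield overlapping physiology, which is what makes the
    binary problem non-trivial and the transitional score 4 ambiguous.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    return RegimeParams(
        **{
            f.name: (1 - s) * getattr(ALERT, f.name) + s * getattr(FATIGUE, f.name)
            for f in fields(RegimeParams)
        }
    )


@dataclass(frozen=True)
class ECGNoise:
    """Additive contamination of the synthetic ECG (amplitudes in mV)."""

    baseline_amp: float = 0.15  # 0.2 Hz baseline wander
    powerline_amp: float = 0.05  # 50 Hz mains interference
    white_sd: float = 0.03


def _default_fatigue_prevalence() -> float:
    tot = sum(SP7_WINDOW_COUNTS.values())
    return sum(SP7_WINDOW_COUNTS[s] for s in (5, 6, 7)) / tot


def _default_transition_prevalence() -> float:
    return SP7_WINDOW_COUNTS[4] / sum(SP7_WINDOW_COUNTS.values())


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level design: who, how long, and how imbalanced.

    Defaults mirror the target study design: 36 subjects, 10 scenarios each,
    ~10 min of recording per scenario, and regime prevalences that reproduce
    the reference SP-7 distribution (=> ~17:1 alert:fatigue windows).
    """

    n_subjects: int = 36
    scenarios_per_subject: int = 10
    scenario_len_s: float = 600.0
    subject_baseline_sd: float = 0.30
    fatigue_prevalence: float = field(default_factory=_default_fatigue_prevalence)
    transition_prevalence: float = field(default_factory=_default_transition_prevalence)
    scenario_jitter: float = 0.12
    seed: int = 42
    ecg_fs: float = 512.0

    def __post_init__(self) -> None:
        if self.scenario_len_s < 60:
            raise ValueError("scenario_len_s must be at least 60 s")
        if not 0 < self.fatigue_prevalence < 1:
            raise ValueError("fatigue_prevalence must lie in (0, 1)")
        if self.fatigue_prevalence + self.transition_prevalence >= 1:
            raise ValueError("prevalences must leave room for alert scenarios")
        if self.n_subjects < 1 or self.scenarios_per_subject < 1:
            raise ValueError("cohort must contain at least one subject and scenario")

    @classmethod
    def compact(cls, seed: int = 42) -> "CohortConfig":
        """Desk-scale evaluation cohort: 12 subjects x 12 scenarios x 6 min.

        Preserves the default regime prevalences (and hence the ~17:1 window
        imbalance) at a size where the full signal-level pipeline plus model
        evaluation runs in minutes on one CPU.
        """
        return cls(n_subjects=12, scenarios_per_subject=12, scenario_len_s=360.0, seed=seed)


@dataclass
class GroundTruth:
    """Generator-side truth: one row per emitted 60-s window, plus per-scenario
    event lists (R-peak times, scripted fixations/blinks/closures, the jittered
    regime parameters)."""

    windows: pd.DataFrame
    scenarios: dict[tuple[str, str], dict]


@dataclass
class Cohort:
    """A fully generated dataset: session table, raw streams and ground truth."""

    config: CohortConfig
    grid: AOIGrid
    session: pd.DataFrame
    gaze: dict[tuple[str, str], GazeStream]
    ecg: dict[tuple[str, str], ECGTrace]
    truth: GroundTruth


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_rr_series(
    params: RegimeParams, duration: float, seed
) -> tuple[RRSeries, dict]:
    """Sinusoid-plus-noise tachogram covering ``duration`` seconds.

    ``RR_i = mean_rr + lf_amp sin(2 pi 0.10 t_i) + hf_amp sin(2 pi 0.25 t_i)
    + N(0, rmssd_target/sqrt(2))`` — white noise of that scale alone yields
    successive differences with RMS ~ ``rmssd_target``.  Returns the series
    and a ground-truth dict with the beat times and realized HRV statistics.
    """
    if duration <= 0 or params.mean_rr <= 0:
        raise ValueError("duration and mean RR must be positive")
    rng = _rng(seed)
    noise_sd = params.rmssd_target / math.sqrt(2.0)
    t = 0.4  # first beat offset, s
    beats = [t]
    intervals: list[float] = []
    while True:
        rr = (
            params.mean_rr
            + params.lf_amp * math.sin(2 * math.pi * 0.10 * t)
            + params.hf_amp * math.sin(2 * math.pi * 0.25 * t)
            + rng.normal(0.0, noise_sd)
        )
        rr = max(rr, 0.3 * params.mean_rr)
        if t + rr / 1000.0 > duration:
            break
        t += rr / 1000.0
        beats.append(t)
        intervals.append(rr)
    if len(intervals) < 2:
        raise ValueError("duration too short for the requested mean RR")
    arr = np.asarray(intervals)
    diffs = np.diff(arr)
    truth = {
        "beat_times": np.asarray(beats),
        "mean_rr": float(np.mean(arr)),
        "sdnn": float(np.std(arr, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
        "lfhf": params.lfhf_true,
    }
    rr_series = RRSeries(arr, np.asarray(beats[:-1]), np.zeros(arr.size, dtype=bool))
    return rr_series, truth


# Gaussian PQRST template: (amplitude mV, centre offset s, width s)
_PQRST = (
    (0.12, -0.200, 0.025),
    (-0.15, -0.030, 0.010),
    (1.20, 0.000, 0.012),
    (-0.25, 0.030, 0.010),
    (0.35, 0.250, 0.045),
)


def gen_ecg(
    rr: RRSeries,
    fs: float = 512.0,
    noise: ECGNoise = ECGNoise(),
    seed=0,
    duration: float | None = None,
) -> tuple[ECGTrace, dict]:
    """Synthetic single-lead ECG from an RR series.

    A Gaussian-kernel PQRST template is placed at each cumulative beat time;
    baseline wander (0.2 Hz), powerline interference (50 Hz) and white noise
    are added on top.  Returns the trace and the true R-peak times.
    """
    if fs < 100:
        raise ValueError("sampling rate below 100 Hz cannot resolve the QRS template")
    rng = _rng(seed)
    peaks = np.concatenate([rr.start_times, [rr.start_times[-1] + rr.intervals[-1] / 1000.0]])
    if duration is None:
        duration = float(peaks[-1] + 0.6)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    half = int(round(0.45 * fs))
    for pt in peaks:
        c = int(round(pt * fs))
        a, b = max(c - half, 0), min(c + half, n)
        if a >= b:
            continue
        tt = t[a:b] - pt
        for amp, mu, sig in _PQRST:
            v[a:b] += amp * np.exp(-0.5 * ((tt - mu) / sig) ** 2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    v += noise.baseline_amp * np.sin(2 * np.pi * 0.2 * t + ph1)
    v += noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t + ph2)
    v += rng.normal(0.0, noise.white_sd, size=n)
    return ECGTrace(t, v), {"r_peak_times": peaks[peaks < duration]}


def _transition_matrix(grid: AOIGrid, concentration: float) -> np.ndarray:
    """Row-stochastic AOI chain: uniform mixed with a self/neighbour kernel."""
    k = grid.n_cells
    self_biased = np.zeros((k, k))
    for i in range(k):
        r, c = divmod(i, grid.cols)
        neigh = [
            rr * grid.cols + cc
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= rr < grid.rows and 0 <= cc < grid.cols
        ]
        self_biased[i, i] = 0.7
        for j in neigh:
            self_biased[i, j] = 0.3 / len(neigh)
    uniform = np.full((k, k), 1.0 / k)
    return concentration * uniform + (1.0 - concentration) * self_biased


def gen_gaze_stream(
    params: RegimeParams, grid: AOIGrid, duration: float, seed
) -> tuple[GazeStream, dict]:
    """Scripted gaze stream at 100 Hz with known event ground truth.

    Fixation targets follow the AOI Markov chain; fixation durations are
    log-normal around ``fix_dur_mean``; saccades are ballistic raised-cosine
    sweeps with peak velocity well above the 30 deg/s fixation threshold;
    Poisson blinks (and rarer long closures) zero the pupil; pupil diameter
    is an AR(1) process around ``pupil_base``.
    """
    if duration < 60:
        raise ValueError("gaze stream duration must be at least 60 s")
    if grid.n_cells < 2:
        raise ValueError("AOI grid needs at least 2 cells")
    rng = _rng(seed)
    fs = 100.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    P = _transition_matrix(grid, params.aoi_concentration)
    k = grid.n_cells
    cw = (grid.x_max - grid.x_min) / grid.cols
    ch = (grid.y_max - grid.y_min) / grid.rows

    sigma_f = 0.35
    mu_f = math.log(params.fix_dur_mean / 1000.0) - sigma_f**2 / 2

    def _target(cell: int, away_from: tuple[float, float] | None) -> tuple[float, float]:
        cx, cy = grid.cell_center(cell)
        for _ in range(20):
            px = cx + rng.normal(0, 0.22 * cw)
            py = cy + rng.normal(0, 0.22 * ch)
            px = float(np.clip(px, grid.x_min + 0.1, grid.x_max - 0.1))
            py = float(np.clip(py, grid.y_min + 0.1, grid.y_max - 0.1))
            if away_from is None or math.hypot(px - away_from[0], py - away_from[1]) >= 1.5:
                return px, py
        return px, py  # accept last draw; min-amplitude misses are rare

    # build the fixation/saccade timeline
    cell = int(rng.integers(k))
    pos = _target(cell, None)
    clock = 0.0
    fixations: list[dict] = []  # onset, offset, cell, x, y
    segments: list[tuple[float, float, str, tuple, tuple]] = []
    while clock < duration:
        fdur = max(float(rng.lognormal(mu_f, sigma_f)), 0.12)
        f_end = min(clock + fdur, duration)
        segments.append((clock, f_end, "fix", pos, pos))
        fixations.append(
            {"onset": clock, "offset": f_end, "cell": cell, "x": pos[0], "y": pos[1]}
        )
        clock = f_end
        if clock >= duration:
            break
        nxt = int(rng.choice(k, p=P[cell]))
        npos = _target(nxt, pos)
        amp = math.hypot(npos[0] - pos[0], npos[1] - pos[1])
        sdur = min(max(0.020 + 0.0022 * amp, 0.020), 0.080)
        s_end = min(clock + sdur, duration)
        segments.append((clock, s_end, "sac", pos, npos))
        clock = s_end
        cell, pos = nxt, npos

    # sample the trajectory at 100 Hz
    x = np.empty(n)
    y = np.empty(n)
    for a, b, kind, p0, p1 in segments:
        m = (t >= a) & (t < b)
        if not np.any(m):
            continue
        if kind == "fix":
            x[m], y[m] = p0[0], p0[1]
        else:
            u = (t[m] - a) / (b - a)
            s = (1.0 - np.cos(np.pi * u)) / 2.0
            x[m] = p0[0] + (p1[0] - p0[0]) * s
            y[m] = p0[1] + (p1[1] - p0[1]) * s
    fix_mask = np.zeros(n, dtype=bool)
    for f in fixations:
        fix_mask |= (t >= f["onset"]) & (t < f["offset"])
    x[fix_mask] += rng.normal(0, 0.05, size=int(fix_mask.sum()))
    y[fix_mask] += rng.normal(0, 0.05, size=int(fix_mask.sum()))

    # pupil AR(1)
    phi = 0.995
    eps = rng.normal(0.0, params.pupil_sd * math.sqrt(1 - phi**2), size=n)
    pupil = np.empty(n)
    pupil[0] = params.pupil_base + rng.normal(0, params.pupil_sd)
    for i in range(1, n):
        pupil[i] = params.pupil_base + phi * (pupil[i - 1] - params.pupil_base) + eps[i]
    pupil = np.maximum(pupil, 0.5)

    # blinks and long closures (Poisson counts, uniform placement)
    def _spans(rate_per_min: float, med_ms: float, sig: float, lo: float, hi: float):
        count = rng.poisson(rate_per_min * duration / 60.0)
        onsets = np.sort(rng.uniform(0, duration, size=count))
        durs = np.clip(rng.lognormal(math.log(med_ms), sig, size=count), lo, hi) / 1000.0
        return list(zip(onsets, onsets + durs))

    blink_spans = [(a, b, "blink") for a, b in _spans(params.blink_rate, params.blink_dur_mean, 0.30, 80, 480)]
    closure_spans = [(a, b, "closure") for a, b in _spans(params.closure_rate, 700.0, 0.30, 550, 2000)]
    spans = sorted(blink_spans + closure_spans)
    kept: list[tuple[float, float, str]] = []
    for a, b, kind in spans:
        if kept and a < kept[-1][1] + 0.2:
            continue
        kept.append((min(a, duration), min(b, duration), kind))
    valid = np.ones(n, dtype=bool)
    for a, b, kind in kept:
        m = (t >= a) & (t < b)
        pupil[m] = 0.0
        x[m] = 0.0
        y[m] = 0.0
        valid[m] = False

    stream = GazeStream(t, x, y, pupil, valid)
    truth = {
        "fixations": fixations,
        "blinks": [(a, b) for a, b, kind in kept if kind == "blink"],
        "closures": [(a, b) for a, b, kind in kept if kind == "closure"],
    }
    return stream, truth


def _largest_remainder(n: int, probs: list[float]) -> list[int]:
    raw = [p * n for p in probs]
    out = [int(math.floor(r)) for r in raw]
    rem = n - sum(out)
    order = sorted(range(len(probs)), key=lambda i: raw[i] - out[i], reverse=True)
    for i in order[:rem]:
        out[i] += 1
    return out


def plan_sessions(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Session table with per-scenario regimes and SP-7 ratings.

    Regime counts follow the configured prevalences exactly (largest-remainder
    apportionment over all subject x scenario slots), then land on random
    slots; SP-7 scores are drawn from the regime-conditional reference
    distribution.  Scenario start/end times are sequential within subject
    with 5-min rest gaps.
    """
    rng = _rng(config.seed if rng is None else rng)
    n_total = config.n_subjects * config.scenarios_per_subject
    p_fat, p_tr = config.fatigue_prevalence, config.transition_prevalence
    n_alert, n_tr, n_fat = _largest_remainder(n_total, [1 - p_fat - p_tr, p_tr, p_fat])
    regimes = np.array(["alert"] * n_alert + ["transition"] * n_tr + ["fatigue"] * n_fat)
    regimes = regimes[rng.permutation(n_total)]

    rows = []
    i = 0
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        for k in range(config.scenarios_per_subject):
            regime = str(regimes[i])
            scores = _SP7_BY_REGIME[regime]
            w = np.array([SP7_WINDOW_COUNTS[sc] for sc in scores], dtype=float)
            sp7 = int(rng.choice(scores, p=w / w.sum()))
            start = k * (config.scenario_len_s + 300.0)
            rows.append(
                {
                    "subject_id": subject,
                    "scenario_id": f"{subject}-R{k + 1:02d}",
                    "scenario_type": int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2])),
                    "start_s": start,
                    "end_s": start + config.scenario_len_s,
                    "sp7_post": sp7,
                    "regime": regime,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def _jitter_params(
    params: RegimeParams, jitter: float, rng: np.random.Generator
) -> RegimeParams:
    """Per-scenario log-normal jitter; slow-moving baselines jitter less."""
    upd = {}
    for f in fields(RegimeParams):
        sd = jitter
        if f.name in ("mean_rr", "pupil_base"):
            sd = jitter / 3.0
        val = getattr(params, f.name) * float(np.exp(rng.normal(0.0, sd)))
        if f.name == "aoi_concentration":
            val = float(np.clip(val, 0.05, 1.0))
        upd[f.name] = val
    return replace(params, **upd)


def _clip_spans(spans, t0: float, t1: float) -> list[tuple[float, float]]:
    out = []
    for a, b in spans:
        aa, bb = max(a, t0), min(b, t1)
        if bb - aa > 1e-9:
            out.append((aa, bb))
    return out


def gen_cohort(config: CohortConfig, grid: AOIGrid | None = None) -> Cohort:
    """Generate the full cohort: session plan, raw streams, ground truth.

    Per-subject baselines are drawn once (multiplicative log-normal offsets on
    mean RR, pupil base and fixation duration); each scenario additionally
    jitters all regime parameters so that regimes overlap rather than
    separate trivially.  Fully reproducible from ``config.seed``.
    """
    grid = grid or AOIGrid()
    ss = np.random.SeedSequence(config.seed)
    rng_plan, rng_subj, rng_scen = (np.random.default_rng(s) for s in ss.spawn(3))

    session = plan_sessions(config, rng_plan)
    # Per-subject multiplicative baselines.  Autonomic set-points (resting
    # heart rate, HRV magnitude), pupil size and fixation habits vary at full
    # scale across people; sympathovagal balance and blink/closure habits are
    # idiosyncratic too but somewhat less variable.  This between-subject
    # spread on the very features that carry the fatigue signal is what
    # creates the cross-subject generalization gap the LOSO protocol probes.
    _BASELINE_SCALE = {
        "mean_rr": 0.5,
        "rmssd_target": 1.0,
        "sdnn_target": 1.0,
        "lf_amp": 0.7,
        "hf_amp": 0.7,
        "pupil_base": 1.0,
        "pupil_sd": 1.0,
        "fix_dur_mean": 1.0,
        "blink_rate": 0.5,
        "blink_dur_mean": 0.4,
        "closure_rate": 0.3,
    }
    baselines = {
        f"S{s + 1:02d}": {
            name: float(np.exp(rng_subj.normal(0.0, scale * config.subject_baseline_sd)))
            for name, scale in _BASELINE_SCALE.items()
        }
        for s in range(config.n_subjects)
    }

    gaze: dict[tuple[str, str], GazeStream] = {}
    ecg: dict[tuple[str, str], ECGTrace] = {}
    scen_truth: dict[tuple[str, str], dict] = {}
    window_rows: list[dict] = []

    for row in session.itertuples(index=False):
        key = (row.subject_id, row.scenario_id)
        base = params_for_severity(severity_of_sp7(int(row.sp7_post)))
        bl = baselines[row.subject_id]
        base = replace(base, **{k: getattr(base, k) * v for k, v in bl.items()})
        params = _jitter_params(base, config.scenario_jitter, rng_scen)
        child = rng_scen.integers(0, 2**31 - 1, size=3)
        dur = row.end_s - row.start_s

        rr, rr_truth = gen_rr_series(params, dur, int(child[0]))
        trace, ecg_truth = gen_ecg(rr, fs=config.ecg_fs, seed=int(child[1]), duration=dur)
        gz, gz_truth = gen_gaze_stream(params, grid, dur, int(child[2]))

        # shift to absolute session time
        t0 = row.start_s
        gaze[key] = GazeStream(gz.t + t0, gz.x, gz.y, gz.pupil, gz.valid)
        ecg[key] = ECGTrace(trace.t + t0, trace.v)
        scen_truth[key] = {
            "params": params,
            "r_peak_times": ecg_truth["r_peak_times"] + t0,
            "fixations": [
                {**f, "onset": f["onset"] + t0, "offset": f["offset"] + t0}
                for f in gz_truth["fixations"]
            ],
            "blinks": [(a + t0, b + t0) for a, b in gz_truth["blinks"]],
            "closures": [(a + t0, b + t0) for a, b in gz_truth["closures"]],
        }

        n_windows = int(dur // 60)
        rr_t = rr.start_times + t0
        for w in range(n_windows):
            w0, w1 = t0 + 60.0 * w, t0 + 60.0 * (w + 1)
            blinks = _clip_spans(scen_truth[key]["blinks"], w0, w1)
            closures = _clip_spans(scen_truth[key]["closures"], w0, w1)
            fx = [
                f
                for f in scen_truth[key]["fixations"]
                if min(f["offset"], w1) - max(f["onset"], w0) > 1e-9
            ]
            m = (rr_t >= w0) & (rr_t < w1)
            iv = rr.intervals[m]
            dif = np.diff(iv)
            window_rows.append(
                {
                    "subject_id": row.subject_id,
                    "scenario_id": row.scenario_id,
                    "window_index": w,
                    "t0": w0,
                    "t1": w1,
                    "regime": row.regime,
                    "sp7": row.sp7_post,
                    "perclos_true": sum(b - a for a, b in blinks + closures) / 60.0,
                    "mbd_true": float(np.mean([(b - a) * 1000 for a, b in blinks])) if blinks else 0.0,
                    "blink_count": len(blinks),
                    "fix_count": len(fx),
                    "mfd_true": float(
                        np.mean(
                            [
                                (min(f["offset"], w1) - max(f["onset"], w0)) * 1000
                                for f in fx
                            ]
                        )
                    )
                    if fx
                    else 0.0,
                    "meanrr_true": float(np.mean(iv)) if iv.size else float("nan"),
                    "sdnn_true": float(np.std(iv, ddof=1)) if iv.size > 1 else 0.0,
                    "rmssd_true": float(np.sqrt(np.mean(dif**2))) if dif.size else 0.0,
                    "lfhf_true": params.lfhf_true,
                }
            )

    windows = pd.DataFrame(window_rows)
    if not (windows["regime"] == "fatigue").any():
        warnings.warn(
            "cohort contains zero fatigue windows; downstream classification "
            "experiments will be degenerate",
            stacklevel=2,
        )
    return Cohort(config, grid, session, gaze, ecg, GroundTruth(windows, scen_truth))
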