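"""ECG processing and heart-rate-variability features.

Pipeline: wavelet denoising (sym8, 8-level soft thresholding with the
universal threshold, approximation zeroed to remove baseline wander) ->
Pan-Tompkins QRS detection (5-15 Hz band-pass, derivative, squaring, 150 ms
moving-window integration, adaptive dual thresholds with search-back) ->
ectopic-beat rejection on the RR series (|RR - local mean| > 20%) -> the four
cardiac features MeanRR, SDNN, RMSSD and LF/HF.

LF/HF uses the conventional bands 0.04-0.15 Hz (LF) and 0.15-0.40 Hz (HF) on
a tachogram resampled to 4 Hz; a lower ratio is the fatigue direction
(parasympathetic dominance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import interp1d

__all__ = [
    "ECGTrace",
    "RPeakSeries",
    "RRSeries",
    "CardiacFeatures",
    "wavelet_denoise",
    "pan_tompkins",
    "heart_rate_plausible",
    "clean_rr",
    "time_domain_hrv",
    "freq_domain_hrv",
    "extract_window_features",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
HR_BPM_BOUNDS = (40.0, 180.0)
REFRACTORY_S = 0.200
LFHF_SENTINEL = 1e6


@dataclass
class ECGTrace:
    """Uniformly sampled single-lead ECG; time in seconds, amplitude in mV."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("ECG time and value arrays must share one length")
        if self.t.size < 2:
            raise ValueError("ECG trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("ECG time base must be strictly increasing")
        if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt) + 1e-9:
            raise ValueError("ECG time base must be uniform within 1%")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("ECG values must be finite")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def slice(self, t0: float, t1: float) -> "ECGTrace":
        m = (self.t >= t0) & (self.t < t1)
        return ECGTrace(self.t[m], self.v[m])


@dataclass
class RPeakSeries:
    """Detected R-peak times (seconds) and 0-based sample indices."""

    times: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RRSeries:
    """Cleaned inter-beat intervals in ms with gap marks.

    ``gap_before[i]`` is True when interval ``i`` is not consecutive with
    interval ``i-1`` (an ectopic interval was removed between them), so
    successive-difference statistics must not pair across it.
    """

    intervals: np.ndarray  # ms
    start_times: np.ndarray  # s, time of the beat opening each interval
    gap_before: np.ndarray
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.gap_before = np.asarray(self.gap_before, dtype=bool)
        if not (self.intervals.size == self.start_times.size == self.gap_before.size):
            raise ValueError("RR series arrays must share one length")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def rejected_fraction(self) -> float:
        tot = len(self) + self.n_removed
        return self.n_removed / tot if tot else 0.0

    def slice(self, t0: float, t1: float) -> "RRSeries":
        m = (self.start_times >= t0) & (self.start_times < t1)
        gaps = self.gap_before[m].copy()
        if gaps.size:
            gaps[0] = False
        return RRSeries(self.intervals[m], self.start_times[m], gaps, n_removed=0)


@dataclass
class CardiacFeatures:
    """The 4 cardiac features of one analysis window, in canonical order."""

    MeanRR: float
    SDNN: float
    RMSSD: float
    LFHF: float
    flags: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.array([self.MeanRR, self.SDNN, self.RMSSD, self.LFHF])


def wavelet_denoise(trace: ECGTrace, wavelet: str = "sym8", level: int = 8) -> ECGTrace:
    """Soft-threshold wavelet denoising with baseline-wander removal.

    All detail coefficients are soft-thresholded at the universal threshold
    ``lambda = sigma * sqrt(2 log N)`` with the noise scale ``sigma`` estimated
    from the finest detail level (median absolute deviation / 0.6745).  The
    deepest approximation band is zeroed, which removes baseline drift (below
    ~1 Hz at 512 Hz sampling).  Traces shorter than the decomposition needs
    are symmetrically padded and trimmed on return.
    """
    v = trace.v
    n = v.size
    min_len = 2**level
    pad = 0
    if n < min_len:
        pad = min_len - n
        v = np.pad(v, (0, pad), mode="symmetric")
    coeffs = pywt.wavedec(v, wavelet, level=level, mode="symmetric")
    d_fine = coeffs[-1]
    sigma = float(np.median(np.abs(d_fine - np.median(d_fine)))) / 0.6745
    lam = sigma * np.sqrt(2.0 * np.log(v.size))
    out = [np.zeros_like(coeffs[0])]  # drop the approximation: baseline wander
    # soft threshold: shrink by lambda, zero below it
    out.extend(np.sign(d) * np.maximum(np.abs(d) - lam, 0.0) for d in coeffs[1:])
    rec = pywt.waverec(out, wavelet, mode="symmetric")[: v.size]
    if pad:
        rec = rec[:n]
    return ECGTrace(trace.t, rec)


def _mwi(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving-window integration (mean of squared derivative)."""
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def pan_tompkins(trace: ECGTrace, mwi_ms: float = 150.0) -> RPeakSeries:
    """Pan-Tompkins QRS detection on a (denoised) ECG trace.

    Band-pass 5-15 Hz -> 5-point derivative -> squaring -> moving-window
    integration over ``mwi_ms`` -> adaptive dual-threshold peak picking with a
    200 ms refractory period and a search-back pass at half threshold.  Peak
    times are refined to the local maximum of the filtered trace within
    +/- 40 ms.  Returns an empty series when nothing resembling a QRS complex
    is found; use :func:`heart_rate_plausible` to screen the result.
    """
    fs = trace.fs
    if trace.duration < 5.0:
        raise ValueError("Pan-Tompkins needs at least 5 s of ECG")
    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, trace.v)
    # centered 5-point derivative (classic kernel, zero group delay)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    integ = _mwi(deriv**2, max(int(round(mwi_ms / 1000.0 * fs)), 1))

    min_dist = max(int(REFRACTORY_S * fs), 1)
    cand, _ = sps.find_peaks(integ, distance=min_dist)
    if cand.size == 0 or np.max(integ) <= 0:
        return RPeakSeries(np.array([]), np.array([], dtype=int))

    head = integ[: int(2 * fs)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    accepted: list[int] = []
    noise_cand: list[int] = []
    rr_hist: list[float] = []
    for idx in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if integ[idx] > thr1:
            if accepted and (idx - accepted[-1]) / fs < REFRACTORY_S:
                continue
            # search-back before committing: long pause since the last beat
            if accepted and rr_hist:
                expect = (idx - accepted[-1]) / fs
                if expect > 1.66 * float(np.mean(rr_hist[-8:])):
                    back = [
                        j for j in noise_cand if accepted[-1] < j < idx and integ[j] > 0.5 * thr1
                    ]
                    if back:
                        j = max(back, key=lambda k: integ[k])
                        rr_hist.append((j - accepted[-1]) / fs)
                        accepted.append(j)
            if accepted:
                rr_hist.append((idx - accepted[-1]) / fs)
            accepted.append(idx)
            spki = 0.125 * float(integ[idx]) + 0.875 * spki
        else:
            noise_cand.append(idx)
            npki = 0.125 * float(integ[idx]) + 0.875 * npki

    if not accepted:
        return RPeakSeries(np.array([]), np.array([], dtype=int))

    # refine to the local maximum of the filtered trace within +/- 40 ms
    half = int(round(0.040 * fs))
    refined = []
    for idx in accepted:
        a, b = max(idx - half, 0), min(idx + half + 1, trace.v.size)
        refined.append(a + int(np.argmax(trace.v[a:b])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement (keep the larger peak)
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) / fs < REFRACTORY_S:
            if trace.v[idx] > trace.v[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    keep_arr = np.asarray(keep, dtype=int)
    return RPeakSeries(trace.t[keep_arr], keep_arr)


def heart_rate_plausible(peaks: RPeakSeries, duration_s: float) -> bool:
    """True when the detected beat rate lies in the 40-180 bpm screening band."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    bpm = len(peaks) / (duration_s / 60.0)
    return HR_BPM_BOUNDS[0] <= bpm <= HR_BPM_BOUNDS[1]


def clean_rr(peaks: RPeakSeries, max_dev: float = 0.20, n_neighbors: int = 5) -> RRSeries:
    """Build the RR series and reject ectopic intervals in a single pass.

    ``RRI_i = T_R(i+1) - T_R(i)`` in ms.  An interval is ectopic when it
    deviates from the local mean by strictly more than ``max_dev`` (20%); the
    local mean is taken over up to ``n_neighbors`` nearest accepted intervals,
    excluding the interval itself.  Removed intervals leave a gap flag.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 R-peaks to build an RR series")
    rri = np.diff(peaks.times) * 1000.0
    starts = peaks.times[:-1]
    n = rri.size
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        order = np.argsort(np.abs(np.arange(n) - i), kind="stable")
        neigh = [j for j in order if j != i and not removed[j]][:n_neighbors]
        if not neigh:
            continue
        local = float(np.mean(rri[neigh]))
        if np.abs(rri[i] - local) > max_dev * local * (1 + 1e-12):
            removed[i] = True

    keep = ~removed
    gaps = np.zeros(int(keep.sum()), dtype=bool)
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size:
        gaps[1:] = np.diff(kept_idx) > 1
    rr = RRSeries(rri[keep], starts[keep], gaps, n_removed=int(removed.sum()))
    if rr.rejected_fraction > 0.5:
        warnings.warn(
            f"{rr.rejected_fraction:.0%} of RR intervals rejected as ectopic; "
            "window should be treated as unusable",
            stacklevel=2,
        )
    return rr


def time_domain_hrv(rr: RRSeries) -> CardiacFeatures:
    """MeanRR, SDNN (sample SD, N-1) and RMSSD over gap-free successive pairs."""
    if len(rr) < 2:
        raise ValueError("need at least 2 RR intervals for time-domain HRV")
    flags: list[str] = []
    mean_rr = float(np.mean(rr.intervals))
    sdnn = float(np.std(rr.intervals, ddof=1))
    pair_ok = ~rr.gap_before[1:]
    diffs = np.diff(rr.intervals)[pair_ok]
    if diffs.size < 2:
        rmssd = 0.0
        flags.append("rmssd_unreliable")
    else:
        rmssd = float(np.sqrt(np.mean(diffs**2)))
    return CardiacFeatures(mean_rr, sdnn, rmssd, float("nan"), flags)


def freq_domain_hrv(rr: RRSeries, resample_fs: float = 4.0) -> tuple[float, float, float, list[str]]:
    """LF, HF band powers and the LF/HF ratio from the resampled tachogram.

    The unevenly sampled tachogram is cubic-interpolated onto a uniform
    ``resample_fs`` grid, linearly detrended, Hann-tapered, and integrated
    (trapezoidal) over the LF and HF bands of the periodogram.
    """
    if len(rr) < 4:
        raise ValueError("need at least 4 RR intervals for spectral HRV")
    span = float(rr.start_times[-1] - rr.start_times[0])
    if span < 30.0:
        raise ValueError("need at least 30 s of usable RR data for spectral HRV")
    flags: list[str] = []
    grid = np.arange(rr.start_times[0], rr.start_times[-1], 1.0 / resample_fs)
    tach = interp1d(rr.start_times, rr.intervals, kind="cubic")(grid)
    tach = sps.detrend(tach, type="linear")
    freqs, psd = sps.periodogram(tach, fs=resample_fs, window="hann", detrend=False)
    lf_m = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_m = (freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])
    lf = float(np.trapezoid(psd[lf_m], freqs[lf_m]))
    hf = float(np.trapezoid(psd[hf_m], freqs[hf_m]))
    if hf <= 1e-10:  # numerically zero: real HRV has HF power of order ms^2
        flags.append("hf_zero")
        return lf, hf, LFHF_SENTINEL, flags
    return lf, hf, lf / hf, flags


def extract_window_features(rr: RRSeries, window: tuple[float, float]) -> CardiacFeatures:
    """Full 4-feature cardiac vector for one window, with quality flags."""
    t0, t1 = window
    sub = rr.slice(t0, t1)
    if len(sub) < 2:
        raise ValueError(f"fewer than 2 RR intervals in window [{t0}, {t1})")
    feats = time_domain_hrv(sub)
    try:
        _, _, lfhf, fflags = freq_domain_hrv(sub)
        feats.LFHF = lfhf
        feats.flags.extend(fflags)
    except ValueError:
        feats.LFHF = 0.0
        feats.flags.append("spectral_unavailable")
    bpm = 60000.0 / feats.MeanRR
    if not (HR_BPM_BOUNDS[0] <= bpm <= HR_BPM_BOUNDS[1]):
        feats.flags.append("heart_rate_implausible")
    return feats
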