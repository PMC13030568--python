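"""Ocular signal processing: blink repair, I-VT event parsing, and gaze features.

The gaze pipeline turns a raw wearable-tracker stream (gaze angles in degrees
of visual angle plus pupil diameter, nominally 100 Hz) into a set of eight
window-level oculometric features:

``PERCLOS`` (fraction of time the eye is closed — proxied by zero-pupil time,
since wearable trackers report no eyelid aperture), blink frequency ``BF`` and
mean blink duration ``MBD``, mean fixation duration ``MFD`` and fixation
frequency ``FF``, pupil-diameter variability ``PDV``, and two scanpath-entropy
measures over a grid of areas of interest (AOIs): stationary gaze entropy
``SGE`` and transition gaze entropy ``TGE``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AOIGrid",
    "GazeStream",
    "OcularEvent",
    "OcularFeatures",
    "UnusableSignalError",
    "repair_blinks",
    "ivt_classify",
    "basic_ocular_features",
    "stationary_gaze_entropy",
    "transition_gaze_entropy",
    "extract_window_features",
]

BLINK_MIN_MS = 75.0
BLINK_MAX_MS = 500.0


class UnusableSignalError(ValueError):
    """Raised when a signal segment cannot support feature extraction."""


@dataclass(frozen=True)
class AOIGrid:
    """Rectangular grid of areas of interest tiling the panoramic display.

    Cells are half-open in x and y; the right/top screen edges belong to the
    last cell so the grid tiles the bounds exactly.  The default spans a
    three-screen panorama of roughly 48 x 16 degrees of visual angle.
    """

    rows: int = 4
    cols: int = 8
    x_min: float = -24.0
    x_max: float = 24.0
    y_min: float = -8.0
    y_max: float = 8.0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("AOI grid must contain at least 2 cells")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("AOI grid bounds are degenerate")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map gaze coordinates to flat cell indices (row-major).

        Points outside the bounds are clipped to the nearest edge cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / (self.x_max - self.x_min) * self.cols)
        row = np.floor((y - self.y_min) / (self.y_max - self.y_min) * self.rows)
        col = np.clip(col, 0, self.cols - 1).astype(int)
        row = np.clip(row, 0, self.rows - 1).astype(int)
        return row * self.cols + col

    def cell_center(self, idx: int) -> tuple[float, float]:
        row, col = divmod(int(idx), self.cols)
        cw = (self.x_max - self.x_min) / self.cols
        ch = (self.y_max - self.y_min) / self.rows
        return (self.x_min + (col + 0.5) * cw, self.y_min + (row + 0.5) * ch)


@dataclass
class GazeStream:
    """Uniformly sampled gaze record.

    ``pupil == 0`` marks a closed or lost eye; ``valid`` marks samples usable
    for event parsing (closures longer than the blink bound are invalidated by
    :func:`repair_blinks`).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not all(a.size == n for a in (self.x, self.y, self.pupil, self.valid)):
            raise ValueError("gaze stream arrays must share one length")
        if n == 0:
            raise ValueError("gaze stream is empty")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("gaze time base must be strictly increasing")
            if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt) + 1e-9:
                raise ValueError("gaze time base must be uniform within 1%")
        if np.any(self.pupil < 0):
            raise ValueError("pupil diameter must be non-negative")

    @property
    def fs(self) -> float:
        if self.t.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if self.t.size > 1 else float("nan")

    def slice(self, t0: float, t1: float) -> "GazeStream":
        m = (self.t >= t0) & (self.t < t1)
        if not np.any(m):
            raise ValueError(f"gaze stream has no samples in [{t0}, {t1})")
        return GazeStream(self.t[m], self.x[m], self.y[m], self.pupil[m], self.valid[m])


@dataclass(frozen=True)
class OcularEvent:
    """One parsed ocular event; times in seconds, duration in milliseconds."""

    kind: str  # fixation | saccade | blink | closure | dropout
    onset: float
    offset: float
    centroid_x: float = float("nan")
    centroid_y: float = float("nan")

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("event offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


@dataclass
class OcularFeatures:
    """The 8 ocular features of one analysis window, in canonical order."""

    PERCLOS: float
    BF: float
    MBD: float
    MFD: float
    FF: float
    PDV: float
    SGE: float
    TGE: float
    flags: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.PERCLOS, self.BF, self.MBD, self.MFD, self.FF, self.PDV, self.SGE, self.TGE]
        )


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as (start, stop) index pairs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def repair_blinks(stream: GazeStream) -> tuple[GazeStream, list[OcularEvent]]:
    """Partition zero-pupil runs into dropouts, blinks and long closures.

    Runs shorter than 75 ms are treated as tracker dropouts: x, y and pupil
    are linearly interpolated and no blink is counted.  Runs of 75-500 ms are
    blinks: gaze coordinates are interpolated to keep the trajectory
    continuous, but the pupil remains recorded as closed so that eye-closure
    time (PERCLOS) is preserved.  Runs longer than 500 ms are eye closures:
    their samples are marked invalid and excluded from fixation parsing.
    """
    closed = (stream.pupil == 0) | (~stream.valid)
    if np.all(closed):
        raise UnusableSignalError("pupil signal is zero for the entire stream")

    t = stream.t
    x = stream.x.copy()
    y = stream.y.copy()
    pupil = stream.pupil.copy()
    valid = stream.valid.copy()
    dt = stream.dt
    open_idx = np.flatnonzero(~closed)

    def _interp(col: np.ndarray, sl: slice) -> None:
        col[sl] = np.interp(t[sl], t[open_idx], col[open_idx])

    events: list[OcularEvent] = []
    for start, stop in _zero_runs(closed):
        dur_ms = (stop - start) * dt * 1000.0
        sl = slice(start, stop)
        onset, offset = t[start], t[start] + (stop - start) * dt
        if dur_ms < BLINK_MIN_MS:
            _interp(x, sl)
            _interp(y, sl)
            _interp(pupil, sl)
            valid[sl] = True
            events.append(OcularEvent("dropout", onset, offset))
        elif dur_ms <= BLINK_MAX_MS:
            _interp(x, sl)
            _interp(y, sl)
            pupil[sl] = 0.0
            valid[sl] = True
            events.append(OcularEvent("blink", onset, offset))
        else:
            pupil[sl] = 0.0
            valid[sl] = False
            events.append(OcularEvent("closure", onset, offset))

    return GazeStream(t, x, y, pupil, valid), events


def angular_velocity(stream: GazeStream) -> np.ndarray:
    """Per-sample angular speed (deg/s), central difference in the interior."""
    t, x, y = stream.t, stream.x, stream.y
    n = t.size
    v = np.empty(n)
    if n < 2:
        v[:] = 0.0
        return v
    # interior: central difference; ends: one-sided
    v[1:-1] = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2]) / (t[2:] - t[:-2])
    v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / (t[1] - t[0])
    v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / (t[-1] - t[-2])
    return v


def ivt_classify(
    stream: GazeStream,
    velocity_threshold: float = 30.0,
    min_fix_dur_ms: float = 100.0,
) -> list[OcularEvent]:
    """Velocity-threshold (I-VT) parsing of a blink-repaired stream.

    Samples with angular speed below ``velocity_threshold`` are fixation
    samples; speeds at or above the threshold are saccade samples.  Blink
    samples (pupil zero, still valid) split fixations; invalid samples
    (closures) are excluded entirely.  Fixation runs shorter than
    ``min_fix_dur_ms`` are relabelled as saccade.
    """
    n = stream.t.size
    if int(np.sum(stream.valid)) < 2:
        warnings.warn("fewer than 2 valid gaze samples; no events parsed", stacklevel=2)
        return []

    v = angular_velocity(stream)
    FIX, SAC, BLK, EXC = 0, 1, 2, 3
    cls = np.where(v < velocity_threshold, FIX, SAC)
    cls[(stream.pupil == 0) & stream.valid] = BLK
    cls[~stream.valid] = EXC

    dt = stream.dt
    runs: list[tuple[int, int, int]] = []  # (class, start, stop)
    bounds = np.flatnonzero(np.diff(cls)) + 1
    edges = np.concatenate(([0], bounds, [n]))
    for a, b in zip(edges[:-1], edges[1:]):
        runs.append((int(cls[a]), int(a), int(b)))

    # short fixations -> saccade, then re-merge adjacent saccade runs
    runs = [
        (SAC, a, b) if c == FIX and (b - a) * dt * 1000.0 < min_fix_dur_ms else (c, a, b)
        for c, a, b in runs
    ]
    merged: list[tuple[int, int, int]] = []
    for c, a, b in runs:
        if merged and merged[-1][0] == c:
            merged[-1] = (c, merged[-1][1], b)
        else:
            merged.append((c, a, b))

    kind_of = {FIX: "fixation", SAC: "saccade", BLK: "blink"}
    events: list[OcularEvent] = []
    for c, a, b in merged:
        onset = stream.t[a]
        offset = stream.t[b] if b < n else stream.t[-1] + dt
        if c == EXC:
            events.append(OcularEvent("closure", onset, offset))
        elif c == FIX:
            events.append(
                OcularEvent(
                    "fixation",
                    onset,
                    offset,
                    centroid_x=float(np.mean(stream.x[a:b])),
                    centroid_y=float(np.mean(stream.y[a:b])),
                )
            )
        else:
            events.append(OcularEvent(kind_of[c], onset, offset))
    return events


def clip_events(events: list[OcularEvent], t0: float, t1: float) -> list[OcularEvent]:
    """Restrict events to the half-open window [t0, t1), truncating at edges."""
    out = []
    for ev in events:
        a, b = max(ev.onset, t0), min(ev.offset, t1)
        if b - a > 1e-9:
            out.append(replace(ev, onset=a, offset=b))
    return out


def basic_ocular_features(
    stream: GazeStream,
    events: list[OcularEvent],
    window: tuple[float, float],
) -> OcularFeatures:
    """Window-level PERCLOS, blink, fixation and pupil statistics.

    Entropies (SGE/TGE) are filled with zeros here; use
    :func:`extract_window_features` for the full 8-feature set.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    events = clip_events(events, t0, t1)
    minutes = (t1 - t0) / 60.0
    flags: list[str] = []

    blinks = [e for e in events if e.kind == "blink"]
    closures = [e for e in events if e.kind == "closure"]
    fixations = [e for e in events if e.kind == "fixation"]

    closed_s = sum(e.offset - e.onset for e in blinks + closures)
    perclos = min(closed_s / (t1 - t0), 1.0)
    bf = len(blinks) / minutes
    mbd = float(np.mean([e.duration_ms for e in blinks])) if blinks else 0.0
    if fixations:
        mfd = float(np.mean([e.duration_ms for e in fixations]))
    else:
        mfd = 0.0
        flags.append("no_fixations")
    ff = len(fixations) / minutes

    m = (stream.t >= t0) & (stream.t < t1) & stream.valid & (stream.pupil > 0)
    if np.sum(m) >= 2:
        pdv = float(np.std(stream.pupil[m], ddof=1))
    else:
        pdv = 0.0
        flags.append("no_open_eye_samples")

    return OcularFeatures(perclos, bf, mbd, mfd, ff, pdv, 0.0, 0.0, flags)


def _fixation_cells(fixations: list[OcularEvent], grid: AOIGrid) -> np.ndarray:
    cx = np.array([e.centroid_x for e in fixations])
    cy = np.array([e.centroid_y for e in fixations])
    return grid.cell_of(cx, cy)


def stationary_gaze_entropy(fixations: list[OcularEvent], grid: AOIGrid) -> float:
    """Shannon entropy (bits) of the fixation distribution over non-empty AOIs.

    With ``p_i`` the share of fixations landing in cell ``i`` (over the K
    non-empty cells only), returns ``-sum_i p_i log2 p_i``; ``0 log 0 == 0``.
    """
    if not fixations:
        return 0.0
    cells = _fixation_cells(fixations, grid)
    _, counts = np.unique(cells, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def transition_entropy_from_counts(counts: np.ndarray) -> float:
    """Conditional transition entropy (bits) from a square count matrix.

    Rows are normalised to transition probabilities ``p_ij`` and weighted by
    the empirical source-cell shares ``p_i`` (row totals over all
    transitions): ``-sum_i p_i sum_j p_ij log2 p_ij``; ``0 log 0 == 0``.
    """
    counts = np.asarray(counts, dtype=float)
    row_tot = counts.sum(axis=1)
    total = row_tot.sum()
    if total == 0:
        return 0.0
    h = 0.0
    for i in range(counts.shape[0]):
        if row_tot[i] == 0:
            continue
        p_ij = counts[i] / row_tot[i]
        nz = p_ij > 0
        h -= (row_tot[i] / total) * np.sum(p_ij[nz] * np.log2(p_ij[nz]))
    return float(h)


def transition_gaze_entropy(fixations: list[OcularEvent], grid: AOIGrid) -> float:
    """Conditional entropy (bits) of AOI-to-AOI gaze transitions.

    Transitions are counted between the AOI cells of consecutive fixations
    (self-transitions included); see :func:`transition_entropy_from_counts`.
    """
    if len(fixations) < 2:
        return 0.0
    cells = _fixation_cells(fixations, grid)
    labels = np.unique(cells)
    lut = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((labels.size, labels.size))
    for a, b in zip(cells[:-1], cells[1:]):
        counts[lut[a], lut[b]] += 1
    return transition_entropy_from_counts(counts)


def extract_window_features(
    stream: GazeStream,
    events: list[OcularEvent],
    grid: AOIGrid,
    window: tuple[float, float],
) -> OcularFeatures:
    """Full 8-feature ocular vector for one window, with quality flags."""
    feats = basic_ocular_features(stream, events, window)
    fixations = [e for e in clip_events(events, *window) if e.kind == "fixation"]
    feats.SGE = stationary_gaze_entropy(fixations, grid)
    feats.TGE = transition_gaze_entropy(fixations, grid)
    if not fixations and "no_fixations" not in feats.flags:
        feats.flags.append("no_fixations")
    if len(fixations) < 2:
        feats.flags.append("too_few_fixations_for_tge")
    return feats
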