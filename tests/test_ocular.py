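"""Gaze pipeline: blink repair boundaries, I-VT classification, features, entropies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtfatigue import ocular, synthetic
from rtfatigue.ocular import AOIGrid, GazeStream, OcularEvent


def make_stream(n=6000, fs=100.0, x=None, y=None, pupil=None):
    t = np.arange(n) / fs
    x = np.full(n, 1.0) if x is None else np.asarray(x, float)
    y = np.full(n, 1.0) if y is None else np.asarray(y, float)
    pupil = np.full(n, 3.0) if pupil is None else np.asarray(pupil, float)
    return GazeStream(t, x, y, pupil, pupil > 0)


def fixation_at(grid, cell, onset, dur=0.2):
    cx, cy = grid.cell_center(cell)
    return OcularEvent("fixation", onset, onset + dur, centroid_x=cx, centroid_y=cy)


class TestBlinkRepair:
    @pytest.mark.parametrize(
        "run_ms, expected_kind",
        [(200, "blink"), (40, "dropout"), (900, "closure")],
    )
    def test_zero_run_partitioning(self, run_ms, expected_kind):
        n_zero = int(run_ms / 10)
        pupil = np.full(1000, 3.0)
        pupil[300 : 300 + n_zero] = 0.0
        stream = make_stream(n=1000, pupil=pupil)
        repaired, events = ocular.repair_blinks(stream)
        kinds = [e.kind for e in events]
        assert kinds == [expected_kind]
        if expected_kind == "blink":
            # gaze interpolated and continuous, pupil stays closed for PERCLOS
            assert np.all(np.isfinite(repaired.x))
            assert np.all(repaired.pupil[300 : 300 + n_zero] == 0)
            assert repaired.valid[300 : 300 + n_zero].all()
        elif expected_kind == "dropout":
            assert np.all(repaired.pupil > 0)
        else:
            assert not repaired.valid[300 : 300 + n_zero].any()

    def test_all_zero_stream_is_unusable(self):
        stream = make_stream(n=500, pupil=np.zeros(500))
        with pytest.raises(ocular.UnusableSignalError):
            ocular.repair_blinks(stream)

    def test_interpolation_bridges_gaze_linearly(self):
        x = np.linspace(0.0, 10.0, 1000)
        pupil = np.full(1000, 3.0)
        pupil[400:420] = 0.0
        stream = make_stream(n=1000, x=x.copy(), pupil=pupil)
        stream.x[400:420] = 0.0
        repaired, _ = ocular.repair_blinks(stream)
        assert repaired.x[400:420] == pytest.approx(x[400:420], abs=1e-9)


class TestIVT:
    def _ramp_stream(self, deg_per_s):
        """1 s still, 1 s constant-velocity drift, 1 s still."""
        n = 300
        x = np.zeros(n)
        step = deg_per_s / 100.0
        x[100:200] = np.arange(1, 101) * step
        x[200:] = x[199]
        return make_stream(n=n, x=x)

    def test_velocity_below_threshold_is_fixation(self):
        events = ocular.ivt_classify(self._ramp_stream(20.0))
        assert all(e.kind == "fixation" for e in events)

    def test_velocity_above_threshold_is_saccade(self):
        events = ocular.ivt_classify(self._ramp_stream(50.0))
        kinds = [e.kind for e in events]
        assert kinds == ["fixation", "saccade", "fixation"]

    def test_exact_threshold_velocity_is_saccade(self):
        # 0.3 deg per 10 ms sample = 30.0 deg/s: the boundary goes to saccade
        events = ocular.ivt_classify(self._ramp_stream(30.0))
        assert "saccade" in [e.kind for e in events]

    def test_short_fixations_relabelled_as_saccade(self):
        n = 400
        x = np.zeros(n)
        x[200:] = 8.0  # instantaneous jump -> saccade samples around 200
        x[195:200] = 4.0  # 50 ms plateau: too short to be a fixation
        stream = make_stream(n=n, x=x)
        events = ocular.ivt_classify(stream, min_fix_dur_ms=100.0)
        fix = [e for e in events if e.kind == "fixation"]
        assert len(fix) == 2  # the 50 ms plateau did not survive

    def test_too_few_valid_samples_warns_and_returns_empty(self):
        stream = make_stream(n=10, pupil=np.concatenate([[3.0], np.zeros(9)]))
        stream.valid[1:] = False
        with pytest.warns(UserWarning):
            assert ocular.ivt_classify(stream) == []

    def test_events_partition_valid_samples(self):
        gz, _ = synthetic.gen_gaze_stream(synthetic.FATIGUE, AOIGrid(), 60.0, seed=4)
        repaired, _ = ocular.repair_blinks(gz)
        events = ocular.ivt_classify(repaired)
        spans = [(e.onset, e.offset) for e in events]
        assert all(b1 <= a2 + 1e-9 for (_, b1), (a2, _) in zip(spans, spans[1:]))
        hits = np.zeros(repaired.t.size, dtype=int)
        for a, b in spans:
            hits += (repaired.t >= a - 1e-9) & (repaired.t < b - 1e-9)
        assert np.all(hits == 1)

    def test_fixation_recovery_against_generator_script(self):
        """>= 95% of recoverable scripted fixations found within 20 ms onset error."""
        ok = tot = 0
        grid = AOIGrid()
        for seed in range(5):
            for params in (synthetic.ALERT, synthetic.FATIGUE):
                gz, truth = synthetic.gen_gaze_stream(params, grid, 60.0, seed=seed)
                repaired, _ = ocular.repair_blinks(gz)
                det = [e for e in ocular.ivt_classify(repaired) if e.kind == "fixation"]
                onsets = np.array([e.onset for e in det])
                obscured = truth["blinks"] + truth["closures"]
                for f in truth["fixations"]:
                    if f["offset"] - f["onset"] < 0.12 or f["offset"] > 59.9:
                        continue
                    if any(a - 0.02 <= f["onset"] <= b + 0.02 for a, b in obscured):
                        continue
                    tot += 1
                    if onsets.size and np.abs(onsets - f["onset"]).min() <= 0.020:
                        ok += 1
        assert tot > 500
        assert ok / tot >= 0.95


class TestBasicFeatures:
    def test_perclos_is_closed_time_fraction(self):
        stream = make_stream(n=6000)
        events = [
            OcularEvent("closure", 5.0, 8.0),
            OcularEvent("closure", 20.0, 23.0),
        ]
        feats = ocular.basic_ocular_features(stream, events, (0.0, 60.0))
        assert feats.PERCLOS == pytest.approx(0.10)

    def test_blink_rate_per_minute(self):
        stream = make_stream(n=6000)
        events = [OcularEvent("blink", 2.0 * i, 2.0 * i + 0.2) for i in range(5)]
        feats = ocular.basic_ocular_features(stream, events, (0.0, 60.0))
        assert feats.BF == pytest.approx(5.0)
        assert feats.MBD == pytest.approx(200.0)

    def test_constant_pupil_has_zero_pdv(self):
        feats = ocular.basic_ocular_features(make_stream(n=6000), [], (0.0, 60.0))
        assert feats.PDV == 0.0
        assert "no_fixations" in feats.flags and feats.MFD == 0.0

    def test_perclos_monotone_in_closure_time(self):
        stream = make_stream(n=6000)
        events = [OcularEvent("blink", 1.0, 1.2)]
        base = ocular.basic_ocular_features(stream, events, (0.0, 60.0)).PERCLOS
        more = ocular.basic_ocular_features(
            stream, events + [OcularEvent("closure", 30.0, 31.0)], (0.0, 60.0)
        ).PERCLOS
        assert more > base


class TestEntropies:
    grid = AOIGrid()

    def test_uniform_occupancy_hits_log2_k(self):
        fixations = [fixation_at(self.grid, c, onset=0.3 * c) for c in range(32)]
        assert ocular.stationary_gaze_entropy(fixations, self.grid) == pytest.approx(5.0)

    def test_single_cell_has_zero_entropy(self):
        fixations = [fixation_at(self.grid, 3, onset=0.3 * i) for i in range(10)]
        assert ocular.stationary_gaze_entropy(fixations, self.grid) == 0.0

    def test_three_to_one_split(self):
        fixations = [fixation_at(self.grid, 0, 0.1 * i) for i in range(3)]
        fixations.append(fixation_at(self.grid, 1, 0.9))
        h = ocular.stationary_gaze_entropy(fixations, self.grid)
        assert h == pytest.approx(0.8113, abs=1e-4)

    def test_strict_alternation_has_zero_transition_entropy(self):
        cells = [0, 1, 0, 1, 0, 1]
        fixations = [fixation_at(self.grid, c, 0.3 * i) for i, c in enumerate(cells)]
        assert ocular.transition_gaze_entropy(fixations, self.grid) == 0.0

    def test_uniform_transition_matrix_hits_log2_k(self):
        # de Bruijn-style tour: every ordered pair over 4 cells exactly once
        pairs = [(i, j) for i in range(4) for j in range(4)]
        seq = [0]
        remaining = set(pairs)
        while remaining:  # greedy Eulerian walk on the complete digraph
            nxt = next(j for (i, j) in sorted(remaining, reverse=True) if i == seq[-1])
            remaining.discard((seq[-1], nxt))
            seq.append(nxt)
        fixations = [fixation_at(self.grid, c, 0.3 * i) for i, c in enumerate(seq)]
        h = ocular.transition_gaze_entropy(fixations, self.grid)
        assert h == pytest.approx(2.0, abs=1e-9)

    def test_weighted_conditional_entropy_hand_case(self):
        # p_i = (0.5, 0.5); rows (0.9, 0.1) and (0.5, 0.5)
        counts = np.array([[9.0, 1.0], [5.0, 5.0]])
        h = ocular.transition_entropy_from_counts(counts)
        assert h == pytest.approx(0.7345, abs=1e-4)

    def test_degenerate_inputs_give_zero(self):
        assert ocular.stationary_gaze_entropy([], self.grid) == 0.0
        assert ocular.transition_gaze_entropy([fixation_at(self.grid, 0, 0.0)], self.grid) == 0.0

    @given(
        cells=st.lists(st.integers(min_value=0, max_value=31), min_size=1, max_size=60),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounds_hold_for_any_scanpath(self, cells):
        fixations = [fixation_at(self.grid, c, 0.3 * i) for i, c in enumerate(cells)]
        k = self.grid.n_cells
        sge = ocular.stationary_gaze_entropy(fixations, self.grid)
        tge = ocular.transition_gaze_entropy(fixations, self.grid)
        assert -1e-9 <= sge <= math.log2(k) + 1e-9
        assert -1e-9 <= tge <= math.log2(k) + 1e-9


class TestAOIGrid:
    def test_rejects_degenerate_grids(self):
        with pytest.raises(ValueError):
            AOIGrid(rows=1, cols=1)

    def test_edges_belong_to_last_cell(self):
        g = AOIGrid()
        assert g.cell_of(g.x_max, g.y_max) == g.n_cells - 1
        assert g.cell_of(g.x_min, g.y_min) == 0
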