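"""Chewing signal H, windowed peak–valley extraction and phase detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumitrack.chew import (
    ChewSignal,
    ExtremaParams,
    compute_signal,
    detect_phases,
    extract_extrema,
    summarize,
)
from rumitrack.io import BoxRecord
from rumitrack.simulate import SimConfig, simulate_cow


def sig(values, start=1, identity=1):
    values = np.asarray(values, float)
    return ChewSignal(
        identity=identity,
        frames=np.arange(start, start + len(values)),
        H=values,
    )


# ---------------------------------------------------------------------------
# independent oracle: naive linear-scan re-implementation of the windowed
# alternating search (explicit loops, no numpy)
# ---------------------------------------------------------------------------

def naive_extrema(H, init_window=25, search_window=12):
    H = list(H)
    n = len(H)

    def scan(lo, hi, want_max):
        best = lo
        for i in range(lo, hi):
            if (want_max and H[i] > H[best]) or (not want_max and H[i] < H[best]):
                best = i
        return best

    def run(start):
        first = scan(start, start + init_window, True)
        ext = [(first, "peak")]
        pos = first
        want_max = False
        while n - 1 - pos >= 2:
            end = min(pos + search_window, n)
            idx = scan(pos, end, want_max)
            while idx == end - 1 and end < n:
                end += 1
                idx = scan(pos, end, want_max)
            if idx <= pos:
                return ext, pos, True
            ext.append((idx, "peak" if want_max else "valley"))
            pos = idx
            want_max = not want_max
        return ext, pos, False

    out = []
    start = 0
    first_group = True
    while n - start >= init_window:
        ext, pos, stalled = run(start)
        if not first_group and len(ext) >= 2:
            p = ext[0][0]
            if p > 0 and H[p - 1] >= H[p]:
                ext = ext[2:]
        if ext and (first_group or any(k == "valley" for _, k in ext)):
            out.extend(ext)
            first_group = False
        if not stalled:
            break
        start = pos + 1
    return out


# ---------------------------------------------------------------------------
# compute_signal
# ---------------------------------------------------------------------------

class TestComputeSignal:
    def test_single_box_h(self):
        s = compute_signal([BoxRecord(1, 10, 20, 50, 60, identity=1)])
        assert s.H.tolist() == [80.0]

    def test_constant_box_train(self):
        recs = [BoxRecord(f, 0, 0, 30, 50, identity=1) for f in range(1, 11)]
        s = compute_signal(recs)
        assert len(s) == 10
        assert np.all(s.H == 80.0)

    def test_gap_interpolated_linearly(self):
        recs = [
            BoxRecord(1, 0, 0, 5, 5, identity=1),
            BoxRecord(2, 0, 0, 10, 10, identity=1),
            BoxRecord(4, 0, 0, 20, 20, identity=1),
        ]
        s = compute_signal(recs, gap_fill=1)
        assert s.frames.tolist() == [1, 2, 3, 4]
        assert s.H.tolist() == [10.0, 20.0, 30.0, 40.0]

    def test_long_gap_splits_segments(self):
        recs = [BoxRecord(f, 0, 0, 10, 10, identity=1) for f in (1, 2, 20, 21)]
        s = compute_signal(recs, gap_fill=5)
        segs = s.segments()
        assert [f.tolist() for f, _ in segs] == [[1, 2], [20, 21]]

    def test_duplicate_frame_rejected(self):
        recs = [
            BoxRecord(1, 0, 0, 10, 10, identity=1),
            BoxRecord(1, 0, 0, 12, 12, identity=1),
        ]
        with pytest.raises(ValueError, match="duplicate frame"):
            compute_signal(recs)

    def test_mixed_identities_rejected(self):
        recs = [
            BoxRecord(1, 0, 0, 10, 10, identity=1),
            BoxRecord(2, 0, 0, 10, 10, identity=2),
        ]
        with pytest.raises(ValueError, match="mixes identities"):
            compute_signal(recs)

    def test_empty_track(self):
        s = compute_signal([])
        assert len(s) == 0
        assert extract_extrema(s).chew_count == 0


# ---------------------------------------------------------------------------
# extract_extrema
# ---------------------------------------------------------------------------

class TestExtractExtrema:
    def test_constant_signal_one_peak_no_valleys(self):
        res = extract_extrema(sig(np.full(50, 7.0)))
        assert res.chew_count == 0
        assert [e.kind for e in res.extrema] == ["peak"]
        assert res.extrema[0].frame == 1  # earliest-frame tie break

    def test_short_signal_empty(self):
        res = extract_extrema(sig(np.arange(10.0)))
        assert res.extrema == [] and res.chew_count == 0

    def test_period_eight_wave_hand_trace(self):
        """Hand-traced alternating extrema on a period-8 wave."""
        wave = [5, 6, 9, 6, 5, 2, 1, 2] * 5
        res = extract_extrema(sig(wave))
        # initial peak: earliest maximum of the first 25 frames
        assert res.extrema[0].kind == "peak"
        assert res.extrema[0].value == 9.0
        assert res.extrema[0].frame == 3
        # thereafter alternating valley/peak every 4 frames
        frames = [e.frame for e in res.extrema]
        kinds = [e.kind for e in res.extrema]
        assert frames[:6] == [3, 7, 11, 15, 19, 23]
        assert kinds[:6] == ["peak", "valley", "peak", "valley", "peak", "valley"]
        assert res.chew_count == len([e for e in res.extrema if e.kind == "valley"])

    @pytest.mark.parametrize("period", [18, 20, 22, 24, 25])
    def test_cycle_train_count_exact(self, period):
        """A noiseless train of 20 raised-cosine cycles yields 20 chews."""
        t = np.arange(20 * period)
        H = 20.0 * (1 - np.cos(2 * np.pi * (t % period) / period))
        res = extract_extrema(sig(H + 100))
        assert res.chew_count == 20

    def test_alternation_and_peak_dominance(self, rng):
        for _ in range(20):
            H = rng.uniform(0, 100, size=rng.integers(25, 200))
            res = extract_extrema(sig(H))
            kinds = [e.kind for e in res.extrema]
            for a, b in zip(kinds, kinds[1:]):
                assert a != b
            for i, e in enumerate(res.extrema):
                if e.kind == "peak":
                    if i > 0:
                        assert e.value >= res.extrema[i - 1].value
                    if i + 1 < len(res.extrema):
                        assert e.value >= res.extrema[i + 1].value
            frames = [e.frame for e in res.extrema]
            assert frames == sorted(frames)

    def test_matches_brute_force_oracle(self, rng):
        """1,000 random signals: implementation == naive window scanner."""
        for _ in range(1000):
            n = int(rng.integers(1, 301))
            kind = rng.integers(0, 3)
            if kind == 0:
                H = rng.uniform(0, 50, size=n)
            elif kind == 1:
                t = np.arange(n)
                H = 20 * (1 - np.cos(2 * np.pi * t / max(2, int(rng.integers(5, 30)))))
                H = H + rng.normal(0, 2, size=n).clip(-10, 10) + 50
                H = np.abs(H)
            else:
                H = np.round(rng.uniform(0, 5, size=n))  # heavy ties
            res = extract_extrema(sig(H))
            expect = naive_extrema(H)
            got = [(e.frame - 1, e.kind) for e in res.extrema]
            assert got == expect

    @given(st.integers(-50, 50))
    @settings(max_examples=20)
    def test_translation_invariance(self, shift):
        t = np.arange(200)
        H = 20 * (1 - np.cos(2 * np.pi * t / 20)) + 100
        base = extract_extrema(sig(H))
        shifted = extract_extrema(sig(H + shift))
        assert [e.frame for e in base.extrema] == [e.frame for e in shifted.extrema]
        assert [e.kind for e in base.extrema] == [e.kind for e in shifted.extrema]

    @given(st.sampled_from([0.5, 2.0, 10.0]))
    @settings(max_examples=10)
    def test_positive_scaling_keeps_frames(self, c):
        t = np.arange(200)
        H = 20 * (1 - np.cos(2 * np.pi * t / 20)) + 100
        base = extract_extrema(sig(H))
        scaled = extract_extrema(sig(c * H))
        assert [e.frame for e in base.extrema] == [e.frame for e in scaled.extrema]
        assert [e.value * c for e in base.extrema] == pytest.approx(
            [e.value for e in scaled.extrema]
        )

    def test_min_amplitude_filters_ripple(self):
        t = np.arange(300)
        H = 20 * (1 - np.cos(2 * np.pi * t / 20)) + 100
        # small ripple bout appended: amplitude 2 oscillation
        ripple = 1 - np.cos(2 * np.pi * np.arange(100) / 20) + 100
        full = np.concatenate([H, ripple])
        loose = extract_extrema(sig(full), ExtremaParams(min_amplitude=0))
        strict = extract_extrema(sig(full), ExtremaParams(min_amplitude=10))
        assert strict.chew_count <= loose.chew_count
        assert strict.chew_count == 15  # the 15 real cycles only


# ---------------------------------------------------------------------------
# detect_phases
# ---------------------------------------------------------------------------

class TestDetectPhases:
    def test_constant_signal_single_swallow(self):
        s = sig(np.full(120, 80.0))
        report = detect_phases(s, extract_extrema(s))
        assert report.swallow_segments == [(1, 120)]
        assert report.angle_changes == []

    def test_plateau_between_bouts_is_swallowing(self):
        period = 20
        bout = 20 * (1 - np.cos(2 * np.pi * np.arange(10 * period) / period)) + 100
        plateau = np.full(75, 100.0)  # 3 s at 25 fps
        s = sig(np.concatenate([bout, plateau, bout]))
        report = detect_phases(s, extract_extrema(s))
        assert len(report.swallow_segments) == 1
        start, end = report.swallow_segments[0]
        assert start >= 195 and end <= 280  # covers the plateau, nothing else

    def test_step_drop_between_bouts_is_angle_change(self):
        period = 20
        bout = 20 * (1 - np.cos(2 * np.pi * np.arange(10 * period) / period))
        # 40% of the oscillation amplitude, dropped over 2 frames
        lower = -0.4 * 40.0
        pause1 = np.zeros(40)
        drop = np.array([lower / 2, lower])
        pause2 = np.full(40, lower)
        H = np.concatenate([bout, pause1, drop, pause2, bout + lower]) + 120
        s = sig(H)
        report = detect_phases(s, extract_extrema(s))
        assert len(report.angle_changes) == 1
        assert 240 <= report.angle_changes[0] <= 244

    def test_pure_chewing_has_no_angle_changes(self):
        period = 20
        H = 20 * (1 - np.cos(2 * np.pi * np.arange(20 * period) / period)) + 100
        s = sig(H)
        report = detect_phases(s, extract_extrema(s))
        assert report.angle_changes == []


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_empty_track(self):
        signal, extrema, phases = summarize([])
        assert len(signal) == 0 and extrema.chew_count == 0

    def test_single_bout_matches_simulator_truth(self):
        cfg = SimConfig(duration_s=78.0, bout_length_s=(78.0, 78.0), seed=7)
        recs, truth = simulate_cow(cfg, 0)
        _, extrema, _ = summarize(recs)
        assert extrema.chew_count == truth.chew_count

    def test_two_bouts_one_swallow_between(self):
        cfg = SimConfig(
            duration_s=60.0,
            bout_length_s=(25.0, 25.0),
            pause_length_s=(4.0, 4.0),
            seed=3,
        )
        recs, truth = simulate_cow(cfg, 0)
        _, extrema, phases = summarize(recs)
        assert extrema.chew_count == truth.chew_count
        assert len(truth.pauses) >= 1
        p_start, p_end = truth.pauses[0]
        assert any(
            s <= p_start and e >= p_end for s, e in phases.swallow_segments
        )
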