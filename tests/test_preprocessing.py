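"""SNR, R-peak detection, consensus (with union-find oracle), segmentation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgaging.preprocessing import (
    SEGMENT_POST_S,
    SEGMENT_PRE_S,
    ZERO_LEAD_SNR_DB,
    WaveformWindows,
    compute_snr,
    consensus_rpeaks,
    default_windows,
    detect_rpeaks,
    detect_rpeaks_lead,
    segment_beats,
)
from ecgaging.synthetic import EcgRecord, generator_r_times, morphology_from_age, simulate_ecg


def _sine_record(freq, amp, noise_sd, fs=400.0, duration=10.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * duration)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    sig = np.tile(x, (12, 1)) + rng.normal(0, noise_sd, (12, int(fs * duration)))
    return EcgRecord(sig, fs)


class TestSnr:
    def test_in_band_sine_has_high_snr(self):
        rec = _sine_record(1.0, 1.0, 0.01)
        snr = compute_snr(rec)
        assert snr.record_db > 20.0
        assert snr.band == (0.66, 2.5)

    def test_out_of_band_sine_has_low_snr(self):
        rec = _sine_record(10.0, 1.0, 0.0, seed=1)
        assert compute_snr(rec).record_db < 0.0

    def test_scale_invariance(self):
        rec = _sine_record(1.2, 0.5, 0.05, seed=2)
        scaled = EcgRecord(rec.signals * 7.3, rec.fs)
        np.testing.assert_allclose(
            compute_snr(rec).per_lead_db, compute_snr(scaled).per_lead_db, rtol=1e-9
        )

    def test_zero_lead_sentinel(self):
        rec = _sine_record(1.0, 1.0, 0.01, seed=3)
        rec.signals[4] = 0.0
        assert compute_snr(rec).per_lead_db[4] == ZERO_LEAD_SNR_DB

    def test_short_record_rejected(self):
        rec = EcgRecord(np.random.default_rng(0).normal(size=(12, 400)), 400.0)
        with pytest.raises(ValueError):
            compute_snr(rec)


class TestDetector:
    def test_recall_precision_on_noise_free_cohort(self):
        rng = np.random.default_rng(10)
        hits = total = detected = 0
        for i in range(12):
            m = morphology_from_age(rng.uniform(25, 85), "female" if i % 2 else "male",
                                    heart_rate=rng.uniform(50, 115))
            rec = simulate_ecg(m, noise_sd=0.0)
            truth = generator_r_times(m, 10.0)
            cons = consensus_rpeaks(detect_rpeaks(rec), fs=rec.fs)
            total += truth.size
            detected += cons.size
            for t in truth:
                if cons.size and np.min(np.abs(cons - t)) <= 0.02:
                    hits += 1
        assert hits / total >= 0.99  # recall
        assert hits / detected >= 0.99  # precision

    def test_polarity_insensitive(self):
        m = morphology_from_age(55.0, "male", heart_rate=65.0)
        rec = simulate_ecg(m, noise_sd=0.0)
        up = detect_rpeaks_lead(rec.signals[1], rec.fs)
        down = detect_rpeaks_lead(-rec.signals[1], rec.fs)
        assert up.size == down.size
        np.testing.assert_allclose(up, down, atol=0.010)

    def test_flat_signal_empty(self):
        assert detect_rpeaks_lead(np.zeros(4000), 400.0).size == 0

    def test_nonfinite_rejected(self):
        x = np.zeros(4000)
        x[5] = np.nan
        with pytest.raises(ValueError):
            detect_rpeaks_lead(x, 400.0)


def _oracle_consensus(per_lead, tolerance=0.010, min_leads=7):
    """Independent union-find oracle: pairwise single-linkage clustering."""
    items = [(float(t), lead) for lead, ts in enumerate(per_lead) for t in ts]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(items[i][0] - items[j][0]) <= tolerance + 1e-12:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for members in clusters.values():
        ts = np.array([items[i][0] for i in members])
        med0 = float(np.median(ts))
        best: dict[int, float] = {}
        for i in members:
            t, lead = items[i]
            if lead not in best or abs(t - med0) < abs(best[lead] - med0):
                best[lead] = t
        if len(best) >= min_leads:
            out.append(float(np.median(list(best.values()))))
    return np.asarray(sorted(out))


class TestConsensus:
    def test_exactly_seven_leads_accepts(self):
        peaks = [np.array([1.0])] * 7 + [np.array([])] * 5
        np.testing.assert_allclose(consensus_rpeaks(peaks), [1.0])

    def test_six_leads_rejects(self):
        peaks = [np.array([1.0])] * 6 + [np.array([])] * 6
        assert consensus_rpeaks(peaks).size == 0

    def test_median_of_contributing_times(self):
        times = [0.995, 0.997, 1.000, 1.001, 1.002, 1.004, 1.005]
        peaks = [np.array([t]) for t in times] + [np.array([])] * 5
        assert consensus_rpeaks(peaks)[0] == pytest.approx(np.median(times))

    def test_oracle_equality_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_beats = rng.integers(1, 6)
            centres = np.sort(rng.uniform(0.5, 9.5, n_beats))
            per_lead = []
            for _lead in range(12):
                keep = rng.random(n_beats) < 0.85
                ts = centres[keep] + rng.uniform(-0.015, 0.015, keep.sum())
                per_lead.append(np.sort(ts))
            got = consensus_rpeaks(per_lead)
            want = _oracle_consensus(per_lead)
            assert got.size == want.size
            if got.size:
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_sample_quantisation(self):
        # with fs given, times are compared on the sample grid
        peaks = [np.array([1.0001 * k / k])for k in range(1, 8)] + [np.array([])] * 5
        out = consensus_rpeaks(peaks, fs=400.0)
        assert out.size == 1
        assert out[0] == pytest.approx(round(1.0001 * 400) / 400)

    def test_empty_input(self):
        assert consensus_rpeaks([np.array([])] * 12).size == 0


class TestSegmentation:
    def _record(self, fs=400.0, duration=10.0):
        return EcgRecord(np.zeros((12, int(fs * duration))), fs)

    def test_widely_spaced_all_retained(self):
        segs = segment_beats(self._record(), np.array([1.0, 2.0, 3.0]))
        assert [s.valid for s in segs] == [True, True, True]
        assert all(s.n_samples == round(0.65 * 400) for s in segs)

    def test_overlap_invalidates_both(self):
        segs = segment_beats(self._record(), np.array([1.0, 1.6]))
        assert [s.valid for s in segs] == [False, False]

    def test_exact_touch_retained(self):
        segs = segment_beats(self._record(), np.array([1.0, 1.65]))
        assert [s.valid for s in segs] == [True, True]

    def test_out_of_record_windows_dropped(self):
        segs = segment_beats(self._record(), np.array([0.1, 5.0, 9.9]))
        assert len(segs) == 1 and segs[0].r_time == 5.0

    def test_retained_windows_pairwise_disjoint(self):
        rng = np.random.default_rng(6)
        times = np.sort(rng.uniform(0.3, 9.5, 12))
        segs = [s for s in segment_beats(self._record(), times) if s.valid]
        for a, b in zip(segs, segs[1:]):
            assert b.start_sample >= a.start_sample + a.n_samples

    @given(rr=st.floats(0.3, 1.5), k=st.integers(2, 10))
    @settings(max_examples=60, deadline=None)
    def test_constant_rr_closed_form(self, rr, k):
        fs = 400.0
        times = 0.3 + rr * np.arange(k)
        rec = self._record(duration=float(times[-1] + 1.0))
        segs = segment_beats(rec, times)
        L = round((SEGMENT_PRE_S + SEGMENT_POST_S) * fs)
        overlap = round((times[1] - SEGMENT_PRE_S) * fs) - round((times[0] - SEGMENT_PRE_S) * fs) < L
        expected = 0 if overlap else k
        assert sum(s.valid for s in segs) == expected


class TestWindows:
    def test_default_windows_partition(self):
        w = default_windows()
        assert w.windows["P"] == (-250.0, -120.0)
        assert w.windows["QRS"] == (-60.0, 100.0)
        spans = sorted(w.windows.values())
        assert spans[0][0] == -250.0 and spans[-1][1] == 400.0
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c  # contiguous, non-overlapping

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            WaveformWindows(windows={"A": (-100.0, -200.0)})
        with pytest.raises(ValueError):
            WaveformWindows(windows={"A": (-100.0, 0.0), "B": (-50.0, 50.0)})
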