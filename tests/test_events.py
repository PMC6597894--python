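"""Envelope, cycle segmentation and valve-event detection."""
import numpy as np
import pytest
from scipy import signal as sps

from swdus import (
    CycleSegment,
    DecompositionResult,
    EventWindows,
    OscillatoryComponent,
    PipelineConfig,
    SignalRecord,
    SyntheticConfig,
    compute_envelope,
    detect_cycle_anchors,
    detect_valve_events,
    generate_dus,
    normalize_segment,
    run_event_pipeline,
    segment_cycles,
    select_valve_component,
)

from conftest import FS, pearson, tone


def burst_train(centers_ms, duration_s=2.0, carrier_hz=250.0, sd_ms=10.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    x = np.zeros_like(t)
    for c in centers_ms:
        tc = c / 1000.0
        x += np.exp(-0.5 * ((t - tc) / (sd_ms / 1000.0)) ** 2) * np.sin(
            2 * np.pi * carrier_hz * (t - tc)
        )
    return x


class TestEnvelope:
    def test_zero_input(self):
        assert np.all(compute_envelope(np.zeros(500), FS, 25.0) == 0)

    def test_unit_tone_flat_near_one(self):
        env = compute_envelope(tone(300), FS, 25.0)
        mid = env[1000:3000]
        assert np.all(np.abs(mid - 1.0) < 0.05)

    def test_burst_maxima_at_burst_centers(self):
        centers = [300.0, 800.0, 1300.0]
        env = compute_envelope(burst_train(centers), FS, 25.0)
        peaks, _ = sps.find_peaks(env, height=0.3)
        assert len(peaks) == len(centers)
        for p, c in zip(peaks, centers):
            assert abs(p - c) <= 5  # ms at 1 kHz

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            compute_envelope(np.zeros(100), FS, 600.0)


def _fake_decomp(centers, energies, n=1000):
    comps = [
        OscillatoryComponent(np.zeros(n), c, i + 1, e)
        for i, (c, e) in enumerate(zip(centers, energies))
    ]
    return DecompositionResult(components=comps, residual=np.zeros(n), fs=FS)


class TestSelectValveComponent:
    def test_only_one_qualifies(self):
        d = _fake_decomp([20.0, 250.0], [5.0, 3.0])
        assert select_valve_component(d, 100.0) == 1

    def test_highest_energy_among_qualifying(self):
        d = _fake_decomp([150.0, 300.0], [2.0, 4.0])
        assert select_valve_component(d) == 1

    def test_fallback_to_highest_center(self):
        d = _fake_decomp([20.0, 60.0], [5.0, 1.0])
        assert select_valve_component(d, 100.0) == 1

    def test_empty_decomposition(self):
        d = DecompositionResult(components=[], residual=np.zeros(10), fs=FS)
        with pytest.raises(ValueError):
            select_valve_component(d)

    def test_synthetic_dus_selected_component_matches_valve_track(self):
        sig, truth = generate_dus(SyntheticConfig(duration_s=12.0), seed=11)
        from swdus import swarm_decompose

        decomp = swarm_decompose(sig)
        idx = select_valve_component(decomp)
        corrs = [abs(pearson(c.samples, truth.valve_track)) for c in decomp.components]
        assert corrs[idx] == max(corrs)


class TestAnchors:
    def test_noiseless_synthetic_anchor_accuracy(self):
        cfg = SyntheticConfig(duration_s=20.0, snr_db=float("inf"))
        sig, truth = generate_dus(cfg, seed=4)
        res = run_event_pipeline(sig)
        true_t = truth.anchor_times_s
        # one anchor per interior generated beat
        assert abs(len(res.anchors_idx) - len(true_t)) <= 2
        errs = [
            1000 * abs(a - true_t[np.argmin(np.abs(true_t - a))]) for a in res.anchor_times_s
        ]
        assert np.median(errs) <= 10.0

    def test_ecg_reference_passthrough(self):
        env = np.abs(np.sin(np.arange(3000) / 50.0))
        peaks = np.array([100, 600, 1100, 1600])
        out = detect_cycle_anchors(env, FS, r_peak_indices=peaks)
        assert np.array_equal(out, peaks)

    def test_nonmonotone_reference_rejected(self):
        env = np.zeros(3000)
        with pytest.raises(ValueError, match="increasing"):
            detect_cycle_anchors(env, FS, r_peak_indices=np.array([100, 90, 500]))

    def test_constant_envelope_fails(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            detect_cycle_anchors(np.full(4000, 2.0), FS)


class TestSegmentation:
    def test_equal_segments(self):
        segs = segment_cycles(1200, np.array([0, 400, 800]), FS)
        assert [(a, b) for a, b, _ in segs] == [(0, 400), (400, 800)]
        assert all(rr == 400.0 for _, _, rr in segs)

    def test_two_anchors_one_segment(self):
        assert len(segment_cycles(1000, np.array([10, 500]), FS)) == 1

    def test_partition_conservation(self):
        anchors = np.array([13, 400, 777, 1204, 1600])
        segs = segment_cycles(2000, anchors, FS)
        assert sum(b - a for a, b, _ in segs) == anchors[-1] - anchors[0]
        # consecutive boundaries meet exactly
        for (_, b1, _), (a2, _, _) in zip(segs[:-1], segs[1:]):
            assert b1 == a2

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            segment_cycles(1000, np.array([0, 500, 400]), FS)


class TestNormalize:
    def test_three_point_example(self):
        out = normalize_segment(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        v = normalize_segment(rng.normal(3, 5, 400))
        assert abs(v.mean()) < 1e-12
        assert abs(np.std(v, ddof=1) - 1) < 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_segment(np.array([5.0, 5.0, 5.0]))


def _segment_from_bursts(centers_ms, rr_ms=400.0):
    x = burst_train(centers_ms, duration_s=rr_ms / 1000.0, sd_ms=8.0)
    env = compute_envelope(x, FS, 60.0)
    return CycleSegment(0, int(rr_ms), rr_ms, normalize_segment(env))


class TestValveEvents:
    def test_four_bursts_recovered(self):
        centers = [25.0, 75.0, 200.0, 290.0]
        seg = _segment_from_bursts(centers)
        ev = detect_valve_events(seg, FS)
        assert ev.all_present()
        for name, c in zip(("mc", "ao", "ac", "mo"), centers):
            assert abs(ev.time(name) - c) <= 5.0

    def test_single_burst_only_ao(self):
        seg = _segment_from_bursts([75.0])
        ev = detect_valve_events(seg, FS)
        assert not np.isnan(ev.t_ao_ms)
        assert np.isnan(ev.t_mc_ms) and np.isnan(ev.t_ac_ms) and np.isnan(ev.t_mo_ms)

    def test_short_cycle_clips_mo_window(self):
        seg = _segment_from_bursts([25.0, 75.0, 200.0, 280.0], rr_ms=300.0)
        ev = detect_valve_events(seg, FS)  # Mo window clips to [260, 300)
        assert np.isnan(ev.t_mo_ms) or 260.0 <= ev.t_mo_ms < 300.0

    def test_ordering_when_all_present(self):
        seg = _segment_from_bursts([20.0, 70.0, 190.0, 285.0])
        ev = detect_valve_events(seg, FS)
        assert ev.all_present()
        assert ev.t_mc_ms < ev.t_ao_ms < ev.t_ac_ms < ev.t_mo_ms

    def test_window_containment_always(self):
        rng = np.random.default_rng(5)
        windows = EventWindows()
        for _ in range(10):
            centers = sorted(rng.uniform(10, 330, size=4))
            seg = _segment_from_bursts(list(centers))
            ev = detect_valve_events(seg, FS, windows)
            for name in ("mc", "ao", "ac", "mo"):
                t = ev.time(name)
                if not np.isnan(t):
                    a, b = windows.window(name)
                    assert max(a, 0.0) <= t < min(b, seg.rr_ms)


class TestPipeline:
    def test_short_signal_rejected(self):
        sig, _ = generate_dus(SyntheticConfig(duration_s=3.0), seed=0)
        with pytest.raises(ValueError, match="5 s"):
            run_event_pipeline(sig)

    def test_high_snr_run_recovers_most_beats(self):
        sig, truth = generate_dus(SyntheticConfig(duration_s=30.0), seed=1)
        res = run_event_pipeline(sig)
        frac = np.mean([e.all_present() for e in res.events])
        assert frac >= 0.85
        # ordering and containment on every complete beat
        for ev in res.events:
            if ev.all_present():
                assert ev.t_mc_ms < ev.t_ao_ms < ev.t_ac_ms < ev.t_mo_ms

    def test_ecg_reference_mode_timing(self):
        sig, truth = generate_dus(SyntheticConfig(duration_s=30.0), seed=2)
        res = run_event_pipeline(sig, r_peak_times_s=truth.anchor_times_s)
        errs = []
        for ev in res.events:
            k = ev.beat_index
            for name in ("mc", "ao", "ac", "mo"):
                t = ev.time(name)
                if not np.isnan(t):
                    errs.append(abs(t - truth.event_offsets_ms[name][k]))
        assert np.median(errs) <= 10.0
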