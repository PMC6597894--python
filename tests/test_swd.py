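"""Swarm filter and swarm decomposition."""
import numpy as np
import pytest
from scipy import signal as sps

from swdus import (
    DecompositionConfig,
    SignalRecord,
    SwFParams,
    SwarmDivergenceError,
    calibrate_swf,
    estimate_dominant_frequency,
    extract_oscillatory_component,
    instantaneous_energy,
    swarm_decompose,
    swarm_filter,
)

from conftest import FS, pearson, tone


class TestDominantFrequency:
    def test_single_tone(self, record):
        f = estimate_dominant_frequency(record(tone(300, 1.0)))
        assert abs(f - 300) <= FS / 1024  # within a couple of Welch bins

    def test_dominant_of_two_tones(self, record):
        x = tone(50) + 2.0 * tone(300)
        assert abs(estimate_dominant_frequency(record(x)) - 300) < 5

    def test_bandpassed_noise_matches_periodogram_argmax(self, record):
        rng = np.random.default_rng(42)
        w = rng.normal(0, 1, 8000)
        sos = sps.butter(4, [140, 160], btype="band", fs=FS, output="sos")
        x = sps.sosfilt(sos, w)
        f = estimate_dominant_frequency(record(x))
        ff, pxx = sps.periodogram(x, fs=FS, nfft=2**16)
        f_oracle = ff[np.argmax(pxx)]
        assert abs(f - 150) <= 15
        assert abs(f - f_oracle) <= 15

    def test_constant_signal_rejected(self, record):
        with pytest.raises(ValueError, match="no oscillatory content"):
            estimate_dominant_frequency(record(np.full(256, 3.0)))


class TestSwarmFilter:
    def test_zero_input_equilibrium(self, record, calibration):
        params = calibration.entries[4].params
        y = swarm_filter(record(np.zeros(500)), params)
        assert np.max(np.abs(y)) < 1e-12

    @pytest.mark.parametrize("c", [-1.0, 2.0])
    def test_homogeneity_in_scale(self, record, calibration, c):
        """All force terms are degree-1 in state, so scaling input and
        initial spread scales the output."""
        params = calibration.entries[5].params
        x = tone(50) + 0.3 * tone(120)
        y = swarm_filter(record(x), params, init_spread=1e-6)
        y2 = swarm_filter(record(c * x), params, init_spread=c * 1e-6)
        assert np.linalg.norm(y2 - c * y) <= 1e-6 * np.linalg.norm(y)

    def test_center_tone_passes_with_high_correlation(self, record, calibration):
        e = calibration.entries[7]
        x = tone(e.center_freq_hz)
        y = swarm_filter(record(x), e.params)
        lo, hi = len(x) // 4, 3 * len(x) // 4
        assert pearson(x[lo:hi], y[lo:hi]) >= 0.99

    def test_octave_below_attenuated(self, record, calibration):
        e = calibration.entries[9]

        def gain(f):
            x = tone(f)
            y = swarm_filter(record(x), e.params)
            lo, hi = len(x) // 4, 3 * len(x) // 4
            return np.sqrt(np.mean(y[lo:hi] ** 2) / np.mean(x[lo:hi] ** 2))

        assert gain(e.center_freq_hz / 2) <= 0.5 * gain(e.center_freq_hz)

    def test_divergence_raises(self, record):
        params = SwFParams(delta=2.5, drive_gain=1.0)
        with pytest.raises(SwarmDivergenceError, match="reduce delta"):
            swarm_filter(record(tone(50)), params)

    def test_deterministic(self, record, calibration):
        params = calibration.entries[6].params
        x = tone(60) + 0.1 * tone(200)
        y1 = swarm_filter(record(x), params)
        y2 = swarm_filter(record(x), params)
        assert np.array_equal(y1, y2)


class TestCalibration:
    def test_centers_strictly_increasing(self, calibration):
        centers = calibration.centers_hz
        assert len(calibration) >= 5
        assert np.all(np.diff(centers) > 0)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            calibrate_swf([], FS)

    def test_single_preset(self):
        params = SwFParams.for_band(100.0, FS)
        table = calibrate_swf([params], FS, probe_freqs=np.geomspace(20, 400, 25))
        assert len(table) == 1
        assert 60 < table.entries[0].center_freq_hz < 160

    def test_nearest_lookup_log_distance(self, calibration):
        for e in calibration.entries:
            assert calibration.nearest(e.center_freq_hz).preset_id == e.preset_id

    def test_packaged_table_matches_live_calibration(self, calibration):
        from importlib import resources

        from swdus.swd import CalibrationTable

        path = resources.files("swdus").joinpath("data/default_calibration_fs1000.csv")
        with resources.as_file(path) as p:
            shipped = CalibrationTable.from_csv(p, fs=FS)
        assert len(shipped) == len(calibration)
        assert np.allclose(shipped.centers_hz, calibration.centers_hz, rtol=0.05)

    def test_csv_round_trip(self, calibration, tmp_path):
        path = tmp_path / "cal.csv"
        calibration.to_csv(path)
        back = type(calibration).from_csv(path, fs=FS)
        assert np.allclose(back.centers_hz, calibration.centers_hz)
        assert back.entries[3].params.delta == pytest.approx(
            calibration.entries[3].params.delta
        )


class TestExtractComponent:
    def test_pure_tone_at_center_preserved(self, record, calibration):
        e = calibration.entries[7]
        x = tone(e.center_freq_hz)
        oc = extract_oscillatory_component(record(x), e.params)
        assert pearson(oc.samples, x) >= 0.99

    def test_zero_input(self, record, calibration):
        oc = extract_oscillatory_component(record(np.zeros(1000)), calibration.entries[5].params)
        assert np.all(oc.samples == 0)
        assert oc.energy_fraction == 0.0

    def test_two_tone_high_preset_selects_high_tone(self, record, calibration):
        x = tone(50) + tone(300)
        e = calibration.nearest(300.0)
        oc = extract_oscillatory_component(record(x), e.params)
        assert pearson(oc.samples, tone(300)) >= 0.95


class TestDecomposition:
    def test_two_tone_separation(self, record, calibration):
        t = np.arange(int(10 * FS)) / FS
        t50, t300 = np.sin(2 * np.pi * 50 * t), np.sin(2 * np.pi * 300 * t)
        rec = record(t50 + t300)
        result = swarm_decompose(rec, DecompositionConfig(calibration=calibration))
        assert len(result.components) == 2
        corr = sorted(
            max(abs(pearson(c.samples, t50)), abs(pearson(c.samples, t300)))
            for c in result.components
        )
        assert corr[0] >= 0.95
        e_res = np.dot(result.residual, result.residual)
        assert e_res < 0.05 * np.dot(rec.samples, rec.samples)

    def test_zero_signal_yields_no_components(self, record, calibration):
        result = swarm_decompose(record(np.zeros(512)), DecompositionConfig(calibration=calibration))
        assert result.components == []
        assert np.all(result.residual == 0)

    @pytest.mark.parametrize("make", ["tones", "noise", "chirp"])
    def test_reconstruction_is_exact(self, record, calibration, make):
        rng = np.random.default_rng(7)
        t = np.arange(3000) / FS
        x = {
            "tones": np.sin(2 * np.pi * 40 * t) + 0.5 * np.sin(2 * np.pi * 220 * t),
            "noise": rng.normal(0, 1, t.size),
            "chirp": sps.chirp(t, 30, t[-1], 300),
        }[make]
        rec = record(x)
        result = swarm_decompose(rec, DecompositionConfig(calibration=calibration))
        recon = result.reconstruction()
        assert np.linalg.norm(recon - x) <= 1e-9 * np.linalg.norm(x)

    def test_deterministic(self, record, calibration):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 2000)
        r1 = swarm_decompose(record(x), DecompositionConfig(calibration=calibration))
        r2 = swarm_decompose(record(x), DecompositionConfig(calibration=calibration))
        assert len(r1.components) == len(r2.components)
        for a, b in zip(r1.components, r2.components):
            assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(r1.residual, r2.residual)

    def test_requires_calibration_when_auto_disabled(self, record):
        cfg = DecompositionConfig(calibration=None, auto_calibrate=False)
        with pytest.raises(ValueError, match="calibration"):
            swarm_decompose(record(tone(100)), cfg)


class TestInstantaneousEnergy:
    def test_zero_input(self):
        assert np.all(instantaneous_energy(np.zeros(500), FS) == 0)

    def test_unit_tone_near_one(self):
        ie = instantaneous_energy(tone(300), FS)
        mid = ie[1000:3000]
        assert np.all(np.abs(mid - 1.0) < 0.1)

    def test_am_tone_tracks_squared_modulation(self):
        n = 8000
        tt = np.arange(n) / FS
        a = 1 + 0.5 * np.sin(2 * np.pi * 2 * tt)
        x = a * np.sin(2 * np.pi * 200 * tt)
        ie = instantaneous_energy(x, FS)
        mid = slice(500, n - 500)
        rmse = np.sqrt(np.mean((ie[mid] - a[mid] ** 2) ** 2))
        assert rmse <= 0.10 * np.sqrt(np.mean(a[mid] ** 4))
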