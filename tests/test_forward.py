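import dataclasses
import math

import numpy as np
import pytest

from mwangio import forward as f
from mwangio import geometry as g
from conftest import static_scenario


def brute_force_circular_autocorr(x):
    """O(N^2) oracle for circular autocorrelation."""
    n = len(x)
    return np.array([sum(x[t] * x[(t + k) % n] for t in range(n)) for k in range(n)])


class TestMSequence:
    def test_length_order9(self):
        m = f.generate_msequence(9)
        assert len(m) == 511
        assert set(np.unique(m.chips)) == {-1.0, 1.0}

    def test_autocorrelation_order9(self):
        m = f.generate_msequence(9)
        ac = m.circular_autocorrelation()
        assert ac[0] == pytest.approx(511.0, abs=1e-9)
        assert np.allclose(ac[1:], -1.0, atol=1e-9)

    def test_autocorrelation_brute_force_oracle(self):
        m = f.generate_msequence(5)
        expected = brute_force_circular_autocorr(m.chips)
        assert np.allclose(m.circular_autocorrelation(), expected, atol=1e-9)
        assert expected[0] == 31.0
        assert np.allclose(expected[1:], -1.0)

    def test_order2(self):
        m = f.generate_msequence(2)
        assert len(m) == 3
        assert m.circular_autocorrelation()[0] == pytest.approx(3.0)

    def test_non_primitive_taps_rejected(self):
        # x^4 + x^2 + 1 = (x^2 + x + 1)^2 is not primitive
        with pytest.raises(ValueError, match="primitive"):
            f.generate_msequence(4, taps=(4, 2))

    @pytest.mark.parametrize("order", [1, 17])
    def test_order_bounds(self, order):
        with pytest.raises(ValueError):
            f.generate_msequence(order)


def _cube_from_traces(traces, fast_rate=13e9, compressed=False):
    """Single-channel cube wrapping [n_fast, n_slow] traces."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[:, None]
    nf, ns = traces.shape
    return f.RadarDataCube(
        data=traces[:, :, None],
        fast_time_axis=np.arange(nf) / fast_rate,
        slow_time_axis=np.arange(ns) * 1.25,
        channel_tx=np.array([0]),
        channel_rx=np.array([1]),
        compressed=compressed,
    )


class TestPulseCompression:
    def test_sequence_compresses_to_autocorrelation(self, mseq9):
        cube = _cube_from_traces(mseq9.chips)
        out = f.pulse_compress(cube, mseq9)
        trace = out.data[:, 0, 0]
        assert trace[0] == pytest.approx(511.0, abs=1e-8)
        assert np.allclose(trace[1:], -1.0, atol=1e-8)
        assert out.compressed

    def test_zero_in_zero_out(self, mseq9):
        cube = _cube_from_traces(np.zeros(511))
        out = f.pulse_compress(cube, mseq9)
        assert np.all(out.data == 0.0)

    @pytest.mark.parametrize("k", [1, 17, 300])
    def test_delayed_sequence_peaks_at_lag(self, mseq9, k):
        cube = _cube_from_traces(np.roll(mseq9.chips, k))
        trace = f.pulse_compress(cube, mseq9).data[:, 0, 0]
        assert int(np.argmax(trace)) == k
        assert trace[k] == pytest.approx(511.0, abs=1e-8)

    def test_linearity(self, mseq9):
        rng = np.random.default_rng(0)
        a = rng.normal(size=511)
        b = rng.normal(size=511)
        ca = f.pulse_compress(_cube_from_traces(a), mseq9).data
        cb = f.pulse_compress(_cube_from_traces(b), mseq9).data
        cab = f.pulse_compress(_cube_from_traces(2 * a + 3 * b), mseq9).data
        assert np.allclose(cab, 2 * ca + 3 * cb, atol=1e-8)

    def test_double_compression_rejected(self, mseq9):
        cube = _cube_from_traces(mseq9.chips, compressed=True)
        with pytest.raises(ValueError):
            f.pulse_compress(cube, mseq9)

    def test_length_mismatch(self, mseq9):
        cube = _cube_from_traces(np.zeros(100))
        with pytest.raises(ValueError):
            f.pulse_compress(cube, mseq9)


class TestRadiusWaveform:
    def test_phase_at_zero(self):
        a = g.ArteryModel.with_amplitude((0, 0), 0.15e-3)
        assert f.radius_waveform(a, 0.0) == pytest.approx(0.15e-3)

    def test_zero_pressure_amplitude(self):
        a = g.ArteryModel.with_amplitude((0, 0), 0.0)
        T = np.linspace(0, 100, 17)
        assert np.all(f.radius_waveform(a, T) == 0.0)

    def test_quarter_period_zero_crossing(self):
        a = g.ArteryModel.with_amplitude((0, 0), 0.15e-3, pulsation_frequency=0.08)
        # cos(2*pi*0.08*3.125) = cos(pi/2) = 0
        assert f.radius_waveform(a, 3.125) == pytest.approx(0.0, abs=1e-18)

    def test_non_pulsating_rejected(self):
        a = g.ArteryModel.with_amplitude((0, 0), 0.15e-3, pulsating=False)
        with pytest.raises(ValueError):
            f.radius_waveform(a, 0.0)


class TestFresnel:
    def test_air_fill(self):
        lam = f.fresnel_reflectivity(30.0, 1.0)
        assert lam == pytest.approx((math.sqrt(30) - 1) / (math.sqrt(30) + 1), rel=1e-15)
        assert lam == pytest.approx(0.69, abs=0.01)

    def test_water_fill(self):
        lam = f.fresnel_reflectivity(30.0, 78.0)
        assert lam == pytest.approx(-0.23, abs=0.01)


class TestChannelResponse:
    medium = g.PhantomModel(radius=0.2)  # wide phantom for free placement

    def _single(self, d, amp=1.0):
        sc = f.ScattererResponse(position=(d, 0.0, 0.0), static_amplitude=amp)
        m = f.generate_msequence(9)
        irf = f.default_irf()
        origin = np.zeros(3)
        raw = f.channel_response([sc], origin, origin, 0.0, self.medium, irf, m)
        comp = f.pulse_compress(_cube_from_traces(raw), m).data[:, 0, 0]
        return comp

    def test_empty_scene(self, mseq9):
        raw = f.channel_response(
            [], np.zeros(3), np.ones(3) * 0.1, 0.0, self.medium, f.default_irf(), mseq9
        )
        assert np.all(raw == 0.0)

    def test_static_scatterer_time_invariant(self, mseq9):
        sc = f.ScattererResponse(position=(0.03, 0.0, 0.0), static_amplitude=0.5)
        irf = f.default_irf()
        tx, rx = np.zeros(3), np.array([0.0, 0.01, 0.0])
        t1 = f.channel_response([sc], tx, rx, 0.0, self.medium, irf, mseq9)
        t2 = f.channel_response([sc], tx, rx, 37.5, self.medium, irf, mseq9)
        assert np.allclose(t1, t2)

    def test_distance_scaling_and_delay(self):
        c = self.medium.wave_speed
        fs = 13e9
        # distances chosen so the round-trip delays land on integer samples
        d1 = 40 * c / (2 * fs)
        d2 = 80 * c / (2 * fs)
        c1 = self._single(d1)
        c2 = self._single(d2)
        assert int(np.argmax(np.abs(c1))) == 40
        assert int(np.argmax(np.abs(c2))) == 80
        # each leg contributes 1/(2*pi*r): doubling both halves twice
        assert np.abs(c2).max() / np.abs(c1).max() == pytest.approx(0.25, rel=1e-6)

    def test_scatterer_at_antenna_rejected(self, mseq9):
        sc = f.ScattererResponse(position=(0.0, 0.0, 0.0), static_amplitude=1.0)
        with pytest.raises(ValueError, match="singular"):
            f.channel_response(
                [sc], np.zeros(3), np.ones(3) * 0.1, 0.0, self.medium, f.default_irf(), mseq9
            )


class TestSimulateCube:
    def test_static_scenario_constant_along_slow_time(self, small_geom, small_acq):
        scen = static_scenario(g.build_scenario(1))
        cube = f.simulate_cube(scen, small_geom, small_acq)
        assert np.allclose(cube.data, cube.data[:, :1, :])

    def test_artery_bin_pulsates_at_configured_frequency(self, small_geom):
        scen = g.build_scenario(1)
        acq = f.AcquisitionConfig(m_order=8, duration=125.0)  # 100 samples
        cube = f.simulate_cube(scen, small_geom, acq)
        resid = cube.data - cube.data.mean(axis=1, keepdims=True)
        # strongest time-varying fast-time bin of channel 0
        b = int(np.argmax(resid[:, :, 0].var(axis=1)))
        spec = np.abs(np.fft.rfft(resid[b, :, 0]))
        assert int(np.argmax(spec[1:])) + 1 == 10  # 0.08 Hz = bin 10 of 1/125 Hz grid
        freqs = np.fft.rfftfreq(100, d=1.25)
        assert freqs[10] == pytest.approx(0.08)

    def test_linearity_in_pulsation_amplitude(self, small_geom, small_acq):
        base = g.build_scenario(1)
        static = f.simulate_cube(static_scenario(base), small_geom, small_acq)

        def with_amp(amp):
            s = dataclasses.replace(
                base,
                arteries=tuple(
                    dataclasses.replace(a, pressure_amplitude=amp) for a in base.arteries
                ),
            )
            return f.simulate_cube(s, small_geom, small_acq)

        c1 = with_amp(0.05e-3).data - static.data
        c2 = with_amp(0.10e-3).data - static.data
        assert np.allclose(c2, 2.0 * c1, atol=1e-12 * np.abs(static.data).max())

    def test_superposition(self, small_geom, small_acq, phantom):
        a1 = g.ArteryModel.with_amplitude((0.02, 0.0))
        a2 = g.ArteryModel.with_amplitude((-0.01, 0.03))
        s1 = f.ScattererResponse((0.02, 0.0, -0.05), 0.5, 100.0, a1)
        s2 = f.ScattererResponse((-0.01, 0.03, -0.05), 0.3, 50.0, a2)
        cA = f.simulate_from_scatterers([s1], small_geom, small_acq, medium=phantom)
        cB = f.simulate_from_scatterers([s2], small_geom, small_acq, medium=phantom)
        cAB = f.simulate_from_scatterers([s1, s2], small_geom, small_acq, medium=phantom)
        assert np.allclose(cAB.data, cA.data + cB.data, atol=1e-12)

    def test_slow_time_mean_equals_static(self, small_geom, small_acq):
        scen = g.build_scenario(1)
        cube = f.simulate_cube(scen, small_geom, small_acq)
        static = f.simulate_cube(static_scenario(scen), small_geom, small_acq)
        # whole number of periods: cosine averages to zero
        scale = np.abs(static.data).max()
        assert np.allclose(cube.data.mean(axis=1), static.data[:, 0, :], atol=1e-12 * scale)

    def test_compressed_peak_delay(self, phantom, small_acq):
        geom = g.build_default_array(n_tx=1, n_rx=1, ring_z=(-0.05,))
        sc = f.ScattererResponse((0.0, 0.0, -0.05), 1.0)
        cube = f.simulate_from_scatterers([sc], geom, small_acq, medium=phantom)
        tx, rx = geom.channel_endpoints()
        ri = np.linalg.norm(tx[0] - np.array([0.0, 0.0, -0.05]))
        rj = np.linalg.norm(rx[0] - np.array([0.0, 0.0, -0.05]))
        expected = (ri + rj) / phantom.wave_speed * small_acq.fast_rate
        peak = int(np.argmax(np.abs(cube.data[:, 0, 0])))
        assert abs(peak - expected) <= 1.0

    def test_noise_snr_within_1db(self, small_geom, phantom):
        acq_clean = f.AcquisitionConfig(m_order=8, duration=125.0)
        acq_noisy = dataclasses.replace(acq_clean, snr_db=20.0, seed=7)
        scen = g.build_scenario(1)
        clean = f.simulate_cube(scen, small_geom, acq_clean)
        noisy = f.simulate_cube(scen, small_geom, acq_noisy)
        assert clean.data.size >= 1e5
        noise = noisy.data - clean.data
        snr = 10 * np.log10(np.mean(clean.data**2) / np.mean(noise**2))
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_noise_reproducible(self, small_geom, small_acq):
        acq = dataclasses.replace(small_acq, snr_db=10.0, seed=42)
        scen = g.build_scenario(2)
        c1 = f.simulate_cube(scen, small_geom, acq)
        c2 = f.simulate_cube(scen, small_geom, acq)
        assert np.array_equal(c1.data, c2.data)

    def test_aliasing_warning(self, small_geom):
        scen = g.build_scenario(1)
        acq = f.AcquisitionConfig(m_order=8, slow_rate=0.1, duration=100.0)
        with pytest.warns(UserWarning, match="aliasing"):
            f.simulate_cube(scen, small_geom, acq)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            f.AcquisitionConfig(duration=-1.0)

    def test_matches_channel_response_reference(self, phantom):
        """Vectorized cube equals the per-channel reference path."""
        geom = g.build_default_array(n_tx=1, n_rx=1, ring_z=(-0.05,))
        acq = f.AcquisitionConfig(m_order=8, duration=25.0, compress=False)
        artery = g.ArteryModel.with_amplitude((0.01, 0.02))
        scs = [
            f.ScattererResponse((0.01, 0.02, -0.05), 0.6, 200.0, artery),
            f.ScattererResponse((-0.02, 0.0, -0.04), 0.4),
        ]
        cube = f.simulate_from_scatterers(scs, geom, acq, medium=phantom)
        m = f.generate_msequence(8, chip_rate=acq.fast_rate)
        irf = f.default_irf(fs=acq.fast_rate)
        tx, rx = geom.channel_endpoints()
        for ti in [0, 7, 19]:
            ref = f.channel_response(
                scs, tx[0], rx[0], cube.slow_time_axis[ti], phantom, irf, m
            )
            assert np.allclose(cube.data[:, ti, 0], ref, atol=1e-12)
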