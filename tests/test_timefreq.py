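"""Morlet decomposition, PLF/PLA and window reductions against oracles."""

import numpy as np
import pytest
import scipy.special as sps

from assrshift.containers import EvokedResponse
from assrshift.timefreq import (
    circular_mean,
    default_n_cycles,
    evoked_power_map,
    morlet_kernel,
    morlet_tfr,
    nc_reference_angles,
    pla_relative,
    plf_map,
    reduce_window,
    wrap_angle,
)

FS = 500.0


def _sine(freq, n=550, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestMorlet:
    def test_matches_direct_convolution_oracle(self, rng):
        """FFT implementation equals brute-force time-domain convolution."""
        x = rng.standard_normal(550)
        freqs = np.array([6.0, 23.0, 40.0, 97.0])
        coefs, _ = morlet_tfr(x, FS, freqs)
        for i, f in enumerate(freqs):
            k = morlet_kernel(f, max(2.0, f / 4.0), FS)
            oracle = np.convolve(x, k, mode="same")
            num = np.abs(coefs[i] - oracle).max()
            den = np.abs(oracle).max()
            assert num / den < 1e-10

    def test_frequency_localization(self):
        x = _sine(40.0)
        freqs = np.arange(4.0, 101.0)
        coefs, edge = morlet_tfr(x, FS, freqs)
        power = (np.abs(coefs) ** 2)
        mid = ~edge  # avoid edge bins
        mean_power = np.where(mid, power, 0).sum(axis=1) / np.maximum(mid.sum(axis=1), 1)
        assert freqs[np.argmax(mean_power)] == 40.0

    def test_power_linearity(self, rng):
        x = rng.standard_normal(550)
        c1, _ = morlet_tfr(x, FS, np.array([10.0, 40.0]))
        c2, _ = morlet_tfr(2 * x, FS, np.array([10.0, 40.0]))
        assert np.allclose(np.abs(c2) ** 2, 4 * np.abs(c1) ** 2, rtol=1e-12)

    def test_amplitude_calibration(self):
        """A unit sinusoid at the centre frequency gives |coef| ~ 1."""
        coefs, edge = morlet_tfr(_sine(40.0, n=1100), FS, np.array([40.0]))
        interior = np.abs(coefs[0])[~edge[0]]
        assert interior.mean() == pytest.approx(1.0, rel=0.01)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(np.zeros(550), FS, np.array([250.0]))

    def test_long_wavelet_flags_whole_row(self):
        # at 4 Hz with 2 cycles the kernel spans ~477 samples > a 100-sample epoch
        _, edge = morlet_tfr(np.zeros(100), FS, np.array([4.0]))
        assert edge.all()

    def test_edge_mask_clears_analysis_window(self):
        freqs = np.arange(38.0, 43.0)
        _, edge = morlet_tfr(np.zeros(550), FS, freqs)
        times = -0.4 + np.arange(550) / FS
        window = (times >= 0.1) & (times <= 0.5)
        assert not edge[:, window].any()


class TestPLF:
    def test_identical_phases_give_one(self):
        tfr = np.exp(1j * 0.7) * np.ones((120, 2, 3, 4))
        plf, _ = plf_map(tfr)
        assert np.allclose(plf, 1.0, atol=1e-15)

    def test_antipodal_phases_give_zero(self):
        tfr = np.stack([np.exp(1j * 0.3) * np.ones((1, 1, 2)),
                        np.exp(1j * (0.3 + np.pi)) * np.ones((1, 1, 2))])
        plf, _ = plf_map(tfr)
        assert np.allclose(plf, 0.0, atol=1e-15)

    def test_von_mises_kappa2_matches_bessel_expectation(self, rng):
        """PLF of kappa=2 phases sits in the Monte-Carlo band around I1(2)/I0(2)."""
        expected = sps.iv(1, 2.0) / sps.iv(0, 2.0)  # ~0.698
        n_epochs = 120
        # Monte-Carlo oracle: distribution of the estimator at this n
        sims = np.array([
            np.abs(np.exp(1j * rng.vonmises(0.0, 2.0, n_epochs)).mean())
            for _ in range(2000)
        ])
        lo, hi = np.quantile(sims, [0.025, 0.975])
        assert lo < expected < hi
        phases = rng.vonmises(0.0, 2.0, n_epochs)
        tfr = np.exp(1j * phases)[:, None, None, None] * np.ones((1, 1, 1, 1))
        plf, _ = plf_map(tfr)
        assert lo <= plf[0, 0, 0] <= hi

    def test_amplitude_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (50, 2, 3, 4))
        amps = rng.uniform(0.1, 10.0, (50, 2, 3, 4))
        plf1, _ = plf_map(np.exp(1j * phases))
        plf2, _ = plf_map(amps * np.exp(1j * phases))
        assert np.allclose(plf1, plf2, atol=1e-12)

    def test_zero_magnitude_coefficients_treated_missing(self):
        tfr = np.exp(1j * 0.5) * np.ones((4, 1, 1, 1))
        tfr[0] = 0.0  # dead trial at this bin
        plf, _ = plf_map(tfr)
        assert plf[0, 0, 0] == pytest.approx(1.0, abs=1e-15)

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError):
            plf_map(np.ones((1, 2, 2), complex))


class TestEvokedPower:
    def _evoked(self, data):
        return EvokedResponse(data=data, fs=FS, t0=-0.4,
                              channel_names=("Fp1", "Fp2")[: data.shape[0]],
                              subject_id="S", group="NC")

    def test_baseline_identity(self, rng):
        data = 1e-6 * rng.standard_normal((2, 550))
        power, _ = evoked_power_map(self._evoked(data), np.arange(10.0, 50.0, 10))
        times = -0.4 + np.arange(550) / FS
        sel = (times >= -0.1) & (times <= 0.0)
        # exact up to float cancellation at the ~1e-12 V^2 power scale
        assert np.allclose(power[..., sel].mean(axis=-1), 0.0, atol=1e-25)

    def test_stationary_signal_near_zero_everywhere(self):
        t = np.arange(550) / FS
        data = 1e-6 * np.sin(2 * np.pi * 40 * t)[None, :] * np.ones((2, 1))
        power, edge = evoked_power_map(self._evoked(data), np.array([40.0]))
        interior = power[:, 0, :][:, ~edge[0]]
        scale = 1e-12  # single-trial 40 Hz power
        assert np.abs(interior).max() < 0.05 * scale

    def test_burst_gives_positive_power_in_window(self):
        times = -0.4 + np.arange(550) / FS
        burst = np.where((times >= 0) & (times <= 0.5),
                         np.sin(2 * np.pi * 40 * times), 0.0)
        data = 1e-6 * burst[None, :]
        ev = EvokedResponse(data=data, fs=FS, t0=-0.4, channel_names=("Fp1",),
                            subject_id="S", group="NC")
        power, _ = evoked_power_map(ev, np.array([40.0]))
        sel = (times >= 0.1) & (times <= 0.5)
        assert power[0, 0, sel].mean() > 0.5e-12

    def test_baseline_outside_epoch_errors(self):
        ev = self._evoked(np.zeros((2, 550)))
        with pytest.raises(ValueError):
            evoked_power_map(ev, np.array([40.0]), baseline=(-2.0, -1.9))


class TestAngles:
    def test_wrap_into_half_open_interval(self):
        assert wrap_angle(np.pi) == pytest.approx(np.pi)
        assert wrap_angle(-np.pi) == pytest.approx(np.pi)
        assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)

    def test_pla_zero_for_identical_angles(self, rng):
        a = rng.uniform(-np.pi, np.pi, (3, 4))
        assert np.allclose(pla_relative(a, a), 0.0)

    def test_quarter_cycle_lag(self):
        """A 3.125 ms delay at 40 Hz is a quarter-cycle phase lag (-pi/4...
        -pi/2 of a full cycle is 0.125) recovered from the shifted signal."""
        delay = 0.003125  # s -> 0.125 cycle at 40 Hz
        t = np.arange(1100) / FS
        ref_sig = np.sin(2 * np.pi * 40 * t)
        lag_sig = np.sin(2 * np.pi * 40 * (t - delay))
        cr, er = morlet_tfr(ref_sig, FS, np.array([40.0]))
        cl, _ = morlet_tfr(lag_sig, FS, np.array([40.0]))
        mid = ~er[0]
        dphi = wrap_angle(np.angle(cl[0, mid]) - np.angle(cr[0, mid]))
        assert np.median(dphi) == pytest.approx(-np.pi / 4, abs=1e-3)

    def test_wrapping_avoids_long_way_round(self):
        theta = np.deg2rad(170.0)
        ref = np.deg2rad(-170.0)
        assert pla_relative(theta, np.array(ref)) == pytest.approx(np.deg2rad(-20.0))

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            pla_relative(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_nc_reference_order_invariant(self, rng):
        angles = rng.uniform(-np.pi, np.pi, (10, 3, 4))
        ref1 = nc_reference_angles(angles)
        ref2 = nc_reference_angles(angles[rng.permutation(10)])
        assert np.allclose(ref1, ref2)


class TestReduceWindow:
    def test_constant_map(self):
        times = np.linspace(-0.4, 0.7, 56)
        freqs = np.arange(4.0, 101.0)
        vals = np.full((2, freqs.size, times.size), 3.14)
        out = reduce_window(vals, times, freqs)
        assert np.allclose(out, 3.14)

    def test_circular_mean_of_opposed_angles(self):
        angles = np.array([np.deg2rad(170.0), np.deg2rad(-170.0)])
        m = circular_mean(angles)
        assert abs(wrap_angle(m - np.pi)) < 1e-12

    def test_matches_enumeration_oracle(self, rng):
        times = np.linspace(-0.4, 0.7, 56)
        freqs = np.arange(4.0, 101.0)
        vals = rng.standard_normal((3, freqs.size, times.size))
        out = reduce_window(vals, times, freqs, (0.1, 0.5), (38.0, 42.0))
        acc = []
        for fi, f in enumerate(freqs):
            for ti, t in enumerate(times):
                if 38 <= f <= 42 and 0.1 <= t <= 0.5:
                    acc.append(vals[:, fi, ti])
        oracle = np.mean(acc, axis=0)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            reduce_window(np.zeros((1, 2, 3)), np.arange(3.0), np.arange(2.0) + 4,
                          (10.0, 11.0), (38.0, 42.0))

    def test_consistency_plf_and_evoked_for_locked_trials(self, rng):
        """Fully phase-locked constant-amplitude trials: PLF = 1 and evoked
        power equals single-trial power."""
        t = np.arange(550) / FS
        epoch = np.sin(2 * np.pi * 40 * t)
        trials = np.tile(epoch, (20, 1, 1))  # epochs x 1 channel x samples
        coefs, edge = morlet_tfr(trials, FS, np.array([40.0]))
        plf, _ = plf_map(coefs)
        assert np.allclose(plf[0, 0, ~edge[0]], 1.0, atol=1e-12)
        mean_power = np.abs(coefs.mean(axis=0)) ** 2
        single = np.abs(coefs[0]) ** 2
        assert np.allclose(mean_power, single, atol=1e-20)


def test_default_n_cycles_floor_and_slope():
    freqs = np.array([4.0, 8.0, 16.0, 40.0, 100.0])
    assert np.allclose(default_n_cycles(freqs), [2.0, 2.0, 4.0, 10.0, 25.0])
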