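"""STFT, Morse CWT and superlet engines, regridding and normalisation."""

import numpy as np
import pytest

from superlet_toolkit import (
    CWTConfig,
    DegenerateInputError,
    InputError,
    ParameterError,
    SignalConfig,
    SLTConfig,
    STFTConfig,
    TimeSeries,
    adaptive_order,
    cwt_tfr,
    make_test_signal,
    morlet_wavelet,
    nfft_from_resolution,
    normalize_max,
    regrid_tfr,
    stft_tfr,
    superlet_tfr,
)
from superlet_toolkit.tfr_engines import TFRMatrix

FS = 250.0


def tone(freq: float, fs: float = FS, duration: float = 2.0) -> TimeSeries:
    t = np.arange(int(fs * duration)) / fs
    return TimeSeries(np.sin(2 * np.pi * freq * t), fs)


SMALL_SLT = SLTConfig(base_cycles=3, order_min=2, order_max=5,
                      fmin=30.0, fmax=70.0, f_res=1.0)
SMALL_CWT = CWTConfig(time_bandwidth=60.0, voices_per_octave=16,
                      fmin=30.0, fmax=70.0)
SMALL_STFT = STFTConfig(n=100, overlap=0.75, nfft=500, fmin=30.0, fmax=70.0)


class TestNfft:
    @pytest.mark.parametrize(
        "fs,f_res,expected",
        [(250.0, 0.2, 1250), (250.0, 0.1, 2500), (2000.0, 0.1, 20000)],
    )
    def test_resolution_rule(self, fs, f_res, expected):
        assert nfft_from_resolution(fs, f_res) == expected

    def test_rejects_resolution_coarser_than_fs(self):
        with pytest.raises(ParameterError):
            nfft_from_resolution(250.0, 300.0)


class TestSTFT:
    def test_zero_signal_gives_zero_tfr(self):
        tfr = stft_tfr(TimeSeries(np.zeros(500), FS), SMALL_STFT)
        assert np.all(tfr.values == 0.0)

    def test_bin_centred_tone_peaks_at_tone(self):
        cfg = STFTConfig(n=250, overlap=0.75, nfft=1250, fmin=10.0, fmax=125.0)
        tfr = stft_tfr(tone(50.0, duration=4.0), cfg)
        assert np.all(tfr.freqs[np.argmax(tfr.values, axis=0)] == 50.0)

    def test_row_spacing_is_dft_bin_width(self):
        cfg = STFTConfig(n=250, overlap=0.75, nfft=1250, fmin=10.0, fmax=125.0)
        tfr = stft_tfr(tone(50.0), cfg)
        assert np.allclose(np.diff(tfr.freqs), FS / 1250)

    def test_signal_shorter_than_frame_rejected(self):
        with pytest.raises(InputError):
            stft_tfr(TimeSeries(np.zeros(40), FS), SMALL_STFT)

    def test_hop_rounding(self):
        assert STFTConfig(n=250, overlap=0.75, nfft=1250).hop == 62
        assert STFTConfig(n=50, overlap=0.75, nfft=1250).hop == 12


class TestMorlet:
    def test_envelope_width_follows_cycles_over_frequency(self):
        # sigma = cycles / (k_sd * f) = 3/(5*10) = 0.06 s -> support +/-3 sigma
        k10 = morlet_wavelet(10.0, 3, FS)
        assert len(k10) == 91  # 2*ceil(3*0.06*250) + 1
        k20 = morlet_wavelet(20.0, 3, FS)  # doubling f halves sigma
        assert len(k20) == 47  # 2*ceil(3*0.03*250) + 1

    def test_modulus_symmetric_about_centre(self):
        k = morlet_wavelet(25.0, 4, FS)
        assert np.allclose(np.abs(k), np.abs(k[::-1]))

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ParameterError):
            morlet_wavelet(0.0, 3, FS)


class TestCWT:
    def test_zero_signal_gives_zero_tfr(self):
        tfr = cwt_tfr(TimeSeries(np.zeros(400), FS), SMALL_CWT)
        assert np.all(tfr.values == 0.0)

    def test_voice_count_for_default_band(self):
        cfg = CWTConfig(fmin=10.0, fmax=125.0, voices_per_octave=48)
        assert len(cfg.freq_grid) == 176

    def test_tone_ridge_within_one_voice(self):
        tfr = cwt_tfr(tone(50.0), SMALL_CWT)
        interior = slice(100, 400)
        ridge = tfr.freqs[np.argmax(tfr.values[:, interior], axis=0)]
        step = 2 ** (1 / SMALL_CWT.voices_per_octave)
        assert np.all((ridge >= 50.0 / step) & (ridge <= 50.0 * step))

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(800)
        shift = 40
        a = cwt_tfr(TimeSeries(x, FS), SMALL_CWT)
        b = cwt_tfr(TimeSeries(np.r_[np.zeros(shift), x[:-shift]], FS), SMALL_CWT)
        core = slice(300, 500)
        assert np.allclose(
            a.values[:, core], b.values[:, shift + 300 : shift + 500], rtol=1e-6
        )


class TestAdaptiveOrder:
    @pytest.mark.parametrize("f,expected", [(10.0, 10.0), (125.0, 40.0), (67.5, 25.0)])
    def test_linear_interpolation_over_band(self, f, expected):
        cfg = SLTConfig(order_min=10, order_max=40, fmin=10.0, fmax=125.0)
        assert adaptive_order(f, cfg) == pytest.approx(expected)

    def test_out_of_band_rejected(self):
        with pytest.raises(ParameterError):
            adaptive_order(5.0, SLTConfig(fmin=10.0, fmax=125.0))


def brute_force_scalogram(x, fs, freqs, cycles, k_sd=5.0):
    """Independent single-wavelet scalogram: direct time-domain convolution."""
    out = np.empty((len(freqs), len(x)))
    for i, f in enumerate(freqs):
        sigma = cycles / (k_sd * f)
        half = int(np.ceil(3 * sigma * fs))
        t = np.arange(-half, half + 1) / fs
        env = np.exp(-(t**2) / (2 * sigma**2))
        kernel = env * np.exp(2j * np.pi * f * t) * 2.0 / env.sum()
        out[i] = np.abs(np.convolve(x, kernel, mode="same"))
    return out


class TestSuperlet:
    def test_zero_signal_gives_zero_tfr(self):
        tfr = superlet_tfr(TimeSeries(np.zeros(300), FS), SMALL_SLT)
        assert np.all(tfr.values == 0.0)

    def test_order_one_matches_brute_force_convolution(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        cfg = SLTConfig(base_cycles=3, order_min=1, order_max=1,
                        fmin=20.0, fmax=60.0, f_res=5.0)
        tfr = superlet_tfr(TimeSeries(x, FS), cfg)
        ref = brute_force_scalogram(x, FS, cfg.freq_grid, 3)
        assert np.allclose(tfr.values, ref, rtol=1e-6, atol=1e-12)

    def test_tone_ridge_within_one_grid_step(self):
        tfr = superlet_tfr(tone(50.0), SMALL_SLT)
        interior = slice(100, 400)
        ridge = tfr.freqs[np.argmax(tfr.values[:, interior], axis=0)]
        assert np.all(np.abs(ridge - 50.0) <= SMALL_SLT.f_res)

    def test_geometric_mean_bounded_by_individual_responses(self):
        # combined response lies between the min and max single-wavelet
        # responses at every cell (weighted geometric mean property)
        x = tone(45.0, duration=1.5)
        cfg = SLTConfig(base_cycles=3, order_min=3, order_max=3,
                        fmin=40.0, fmax=50.0, f_res=5.0)
        combined = superlet_tfr(x, cfg).values
        singles = np.stack([
            brute_force_scalogram(x.samples, FS, cfg.freq_grid, 3 * i)
            for i in (1, 2, 3)
        ])
        eps = 1e-9
        assert np.all(combined <= singles.max(axis=0) + eps)
        assert np.all(combined >= singles.min(axis=0) - eps)

    def test_fractional_order_interpolates_between_integers(self):
        x = tone(45.0, duration=1.0)
        def total(order):
            cfg = SLTConfig(base_cycles=3, order_min=order, order_max=order,
                            fmin=45.0, fmax=46.0, f_res=2.0)
            return superlet_tfr(x, cfg).values[0, 125]
        lo, mid, hi = total(2.0), total(2.5), total(3.0)
        assert min(lo, hi) <= mid <= max(lo, hi)

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(300)
        shift = 30
        a = superlet_tfr(TimeSeries(x, FS), SMALL_SLT)
        b = superlet_tfr(
            TimeSeries(np.r_[np.zeros(shift), x[:-shift]], FS), SMALL_SLT
        )
        core = slice(120, 220)
        assert np.allclose(
            a.values[:, core], b.values[:, shift + 120 : shift + 220], rtol=1e-6
        )


def test_single_wavelet_response_matches_pywavelets():
    """Independent oracle: a single-wavelet scalogram row at the tone
    frequency matches pywavelets' complex-Morlet CWT for the equivalent
    kernel (sigma = cycles/(5 f) maps to cmor2-1 at scale fs/f)."""
    import pywt

    fs, f, cycles = 250.0, 40.0, 5.0
    x = tone(f, duration=2.0)
    cfg = SLTConfig(base_cycles=cycles, order_min=1, order_max=1,
                    fmin=f, fmax=f + 1, f_res=5.0)
    ours = superlet_tfr(x, cfg).values[0]
    scale = fs / f  # sigma_samples = scale * sqrt(B/2) = fs/f * 1 = cycles/(5f)*fs
    coef, _ = pywt.cwt(x.samples, [scale], "cmor2-1", sampling_period=1 / fs)
    ref = np.abs(coef[0])
    core = slice(100, 400)
    assert np.allclose(
        ours[core] / ours[core].max(), ref[core] / ref[core].max(), atol=0.02
    )


class TestRegridAndNormalize:
    def _tfr(self, rng):
        vals = rng.random((20, 30))
        return TFRMatrix(vals, np.linspace(10, 50, 20), np.linspace(0, 2, 30))

    def test_identity_regrid_preserves_values(self, rng):
        tfr = self._tfr(rng)
        out = regrid_tfr(tfr, tfr.freqs, tfr.times)
        assert np.allclose(out.values, tfr.values)

    def test_interpolation_respects_value_bounds(self, rng):
        tfr = self._tfr(rng)
        out = regrid_tfr(tfr, np.linspace(5, 60, 41), np.linspace(-0.5, 2.5, 77))
        assert out.values.min() >= tfr.values.min() - 1e-12
        assert out.values.max() <= tfr.values.max() + 1e-12

    def test_constant_field_stays_constant(self):
        tfr = TFRMatrix(np.full((5, 7), 3.5), np.arange(1.0, 6.0), np.arange(7.0))
        out = regrid_tfr(tfr, np.linspace(1, 5, 13), np.linspace(0, 6, 10))
        assert np.allclose(out.values, 3.5)

    def test_log_spaced_source_interpolated_in_log_frequency(self):
        freqs = 10.0 * 2 ** (np.arange(17) / 4)
        # values linear in log2(f): exact under log-frequency interpolation
        vals = np.repeat(np.log2(freqs / 10.0)[:, None], 3, axis=1)
        tfr = TFRMatrix(vals, freqs, np.arange(3.0))
        target = np.array([20.0, 40.0, 80.0, 113.14])
        out = regrid_tfr(tfr, target, tfr.times)
        assert np.allclose(out.values[:, 0], np.log2(target / 10.0), rtol=1e-4)

    def test_non_monotonic_axes_rejected(self, rng):
        tfr = TFRMatrix(rng.random((3, 3)), np.array([1.0, 3.0, 2.0]), np.arange(3.0))
        with pytest.raises(InputError):
            regrid_tfr(tfr, np.arange(3.0) + 1, np.arange(3.0))

    def test_normalize_max_scale_invariance(self, rng):
        tfr = self._tfr(rng)
        a = normalize_max(tfr)
        b = normalize_max(TFRMatrix(tfr.values * 7.3, tfr.freqs, tfr.times))
        assert a.values.max() == 1.0
        assert np.allclose(a.values, b.values)

    def test_normalize_max_rejects_all_zero(self):
        tfr = TFRMatrix(np.zeros((4, 4)), np.arange(4.0) + 1, np.arange(4.0))
        with pytest.raises(DegenerateInputError):
            normalize_max(tfr)


def test_all_engines_localise_pulsed_tone_during_pulses():
    cfg = SignalConfig(f0=40.0, f1=40.0, fmod0=4.0, fmod1=4.0, duration=2.0,
                       fmin=30.0, fmax=70.0, f_res=1.0)
    x = make_test_signal(cfg)
    slt = superlet_tfr(x, SMALL_SLT)
    on = np.flatnonzero(x.samples != 0.0)
    on = on[(on > 50) & (on < 450)]
    ridge = slt.freqs[np.argmax(slt.values[:, on], axis=0)]
    assert np.all(np.abs(ridge - 40.0) <= 2 * SMALL_SLT.f_res)
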