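"""Time-frequency representation engines: STFT, Morse-wavelet CWT and SLT.

All engines return a :class:`TFRMatrix` — a non-negative linear-magnitude
matrix with explicit frequency (rows) and time (columns) coordinates — so
that any TFR can be regridded onto a common reference grid and scored
against a ground truth.

The superlet transform (SLT) sharpens both time and frequency localisation
by combining, per frequency, the magnitude responses of several Morlet
wavelets with increasing cycle counts through a geometric mean.  The number
of wavelets (the superresolution "order") grows linearly across the analysis
band, so low frequencies keep temporal detail while high frequencies gain
spectral detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy import fft as spfft

from ._errors import DegenerateInputError, InputError, ParameterError
from .signal_synth import TimeSeries

__all__ = [
    "TFRMatrix",
    "STFTConfig",
    "CWTConfig",
    "SLTConfig",
    "nfft_from_resolution",
    "stft_tfr",
    "morlet_wavelet",
    "cwt_tfr",
    "adaptive_order",
    "superlet_tfr",
    "regrid_tfr",
    "normalize_max",
]


@dataclass(frozen=True)
class TFRMatrix:
    """Magnitude time-frequency matrix with explicit axis coordinates."""

    values: np.ndarray  # (n_freqs, n_times), >= 0, finite
    freqs: np.ndarray  # ascending, Hz
    times: np.ndarray  # ascending, s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise InputError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.freqs)}, {len(self.times)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings.

    ``n`` is the window length in samples, ``overlap`` the fractional frame
    overlap, ``nfft`` the zero-padded FFT length (see
    :func:`nfft_from_resolution`), and ``window_shape`` one of
    ``"hamming"``/``"hann"``.
    """

    n: int = 250
    overlap: float = 0.75
    nfft: int = 1250
    window_shape: str = "hamming"
    fmin: float = 10.0
    fmax: float = 125.0

    def __post_init__(self) -> None:
        if self.nfft < self.n:
            raise ParameterError(f"nfft ({self.nfft}) must be >= n ({self.n})")
        if not (0 <= self.overlap < 1):
            raise ParameterError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.window_shape not in ("hamming", "hann"):
            raise ParameterError(f"unsupported window shape {self.window_shape!r}")

    @property
    def hop(self) -> int:
        return max(1, round(self.n * (1.0 - self.overlap)))


@dataclass(frozen=True)
class CWTConfig:
    """Continuous wavelet transform with generalized Morse wavelets.

    ``time_bandwidth`` is the Morse time-bandwidth product P^2 and ``gamma``
    the symmetry parameter (gamma = 3 gives the symmetric family); the Morse
    beta is ``time_bandwidth / gamma``.  Scales are log-spaced at
    ``voices_per_octave`` across [fmin, fmax].
    """

    time_bandwidth: float = 120.0
    gamma: float = 3.0
    voices_per_octave: int = 48
    fmin: float = 10.0
    fmax: float = 125.0

    def __post_init__(self) -> None:
        if self.time_bandwidth <= self.gamma:
            raise ParameterError("time_bandwidth must exceed gamma")
        if self.voices_per_octave < 1:
            raise ParameterError("voices_per_octave must be >= 1")
        if not (0 < self.fmin < self.fmax):
            raise ParameterError("need 0 < fmin < fmax")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def freq_grid(self) -> np.ndarray:
        """Log-spaced centre frequencies, ``voices_per_octave`` per doubling."""
        n_octaves = np.log2(self.fmax / self.fmin)
        k = np.arange(int(np.ceil(self.voices_per_octave * n_octaves)) + 1)
        return self.fmin * 2.0 ** (k / self.voices_per_octave)


@dataclass(frozen=True)
class SLTConfig:
    """Superlet transform settings.

    ``base_cycles`` is the cycle count of the first wavelet; the i-th wavelet
    in multiplicative mode has ``base_cycles * i`` cycles (additive:
    ``base_cycles + i - 1``).  The superresolution order interpolates
    linearly from ``order_min`` at ``fmin`` to ``order_max`` at ``fmax``.
    """

    base_cycles: float = 3.0
    order_min: float = 10.0
    order_max: float = 40.0
    mode: Literal["multiplicative", "additive"] = "multiplicative"
    fmin: float = 10.0
    fmax: float = 125.0
    f_res: float = 0.2

    def __post_init__(self) -> None:
        if self.base_cycles < 1:
            raise ParameterError("base_cycles must be >= 1")
        if not (1 <= self.order_min <= self.order_max):
            raise ParameterError("need 1 <= order_min <= order_max")
        if self.mode not in ("multiplicative", "additive"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not (0 < self.fmin < self.fmax):
            raise ParameterError("need 0 < fmin < fmax")
        if self.f_res <= 0:
            raise ParameterError("f_res must be positive")

    @property
    def freq_grid(self) -> np.ndarray:
        n = int(np.floor((self.fmax - self.fmin) / self.f_res + 1e-6)) + 1
        return self.fmin + self.f_res * np.arange(n)


def nfft_from_resolution(fs: float, f_res: float) -> int:
    """FFT length achieving a target frequency resolution.

    With a one-sided spectrum spanning fs/2, resolving steps of ``f_res``
    needs 2*(fs/2)/f_res = fs/f_res points; rounded to the nearest integer.
    """
    if fs <= 0 or f_res <= 0:
        raise ParameterError("fs and f_res must be positive")
    if f_res >= fs:
        raise ParameterError(f"f_res ({f_res}) must be smaller than fs ({fs})")
    return int(round(fs / f_res))


def stft_tfr(signal: TimeSeries, config: STFTConfig) -> TFRMatrix:
    """One-sided magnitude STFT, band-limited to [fmin, fmax].

    Frames of length ``n`` advance by ``hop = round(n*(1-overlap))`` samples,
    each windowed (symmetric window) and zero-padded to ``nfft``.  Column
    time stamps sit at frame centres.
    """
    x = np.asarray(signal.samples, dtype=float)
    if len(x) < config.n:
        raise InputError(
            f"signal ({len(x)} samples) shorter than one frame ({config.n})"
        )
    win = sps.get_window(config.window_shape, config.n, fftbins=False)
    hop = config.hop
    n_frames = 1 + (len(x) - config.n) // hop
    starts = hop * np.arange(n_frames)
    frames = np.lib.stride_tricks.sliding_window_view(x, config.n)[starts]
    spec = np.abs(spfft.rfft(frames * win, n=config.nfft, axis=1)).T
    freqs = np.arange(spec.shape[0]) * signal.fs / config.nfft
    band = (freqs >= config.fmin - 1e-9) & (freqs <= config.fmax + 1e-9)
    times = (starts + (config.n - 1) / 2.0) / signal.fs
    return TFRMatrix(
        values=spec[band],
        freqs=freqs[band],
        times=times,
        meta={"method": "stft", "config": asdict(config)},
    )


def morlet_wavelet(
    f: float,
    cycles: float,
    fs: float,
    k_sd: float = 5.0,
    norm: Literal["amplitude", "energy"] = "amplitude",
) -> np.ndarray:
    """Complex Morlet kernel at centre frequency ``f``.

    The Gaussian envelope has standard deviation ``sigma = cycles/(k_sd*f)``
    seconds and the kernel spans +/-3 sigma.  With ``norm="amplitude"`` the
    envelope is scaled to unit integral (times 2 for the analytic one-sided
    spectrum) so a unit-amplitude tone at ``f`` yields a response magnitude
    of ~1 at every frequency; ``norm="energy"`` gives a unit-energy kernel.
    """
    if f <= 0:
        raise ParameterError(f"centre frequency must be positive, got {f}")
    if cycles < 1:
        raise ParameterError(f"cycles must be >= 1, got {cycles}")
    sigma = cycles / (k_sd * f)
    half = int(np.ceil(3.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma**2))
    kernel = envelope * np.exp(2j * np.pi * f * t)
    if norm == "amplitude":
        kernel *= 2.0 / envelope.sum()
    elif norm == "energy":
        kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2) / fs)
    else:
        raise ParameterError(f"unknown norm {norm!r}")
    return kernel


def _morse_spectrum(omega: np.ndarray, beta: float, gamma: float) -> np.ndarray:
    """Generalized Morse wavelet spectrum, peak-normalised to 2.

    omega is in radians/sample and must be >= 0; the analytic wavelet is
    zero at negative frequencies.
    """
    peak = (beta / gamma) ** (1.0 / gamma)
    out = np.zeros_like(omega)
    pos = omega > 0
    # log-domain evaluation keeps beta=40 within float range
    log_psi = beta * np.log(omega[pos] / peak) - omega[pos] ** gamma + peak**gamma
    out[pos] = 2.0 * np.exp(log_psi)
    return out


def cwt_tfr(signal: TimeSeries, config: CWTConfig) -> TFRMatrix:
    """Magnitude scalogram via generalized Morse wavelets.

    Filtering is done in the frequency domain on a zero-padded copy of the
    signal (padding suppresses circular wrap-around); one column per signal
    sample.  The wavelet peak is normalised so a unit tone maps to ~1.
    """
    x = np.asarray(signal.samples, dtype=float)
    if len(x) == 0:
        raise InputError("empty signal")
    freqs = config.freq_grid
    if len(freqs) == 0 or config.fmax > signal.fs / 2 + 1e-9:
        raise ParameterError("analysis band empty or beyond Nyquist")
    n = len(x)
    nfft = spfft.next_fast_len(2 * n)
    X = spfft.fft(x, nfft)
    omega = 2.0 * np.pi * spfft.fftfreq(nfft)  # rad/sample, signed
    omega_pos = np.where(omega > 0, omega, 0.0)
    peak = (config.beta / config.gamma) ** (1.0 / config.gamma)
    values = np.empty((len(freqs), n))
    for i, f in enumerate(freqs):
        scale = peak / (2.0 * np.pi * f / signal.fs)
        psi = _morse_spectrum(scale * omega_pos, config.beta, config.gamma)
        values[i] = np.abs(spfft.ifft(X * psi)[:n])
    return TFRMatrix(
        values=values,
        freqs=freqs,
        times=signal.times,
        meta={"method": "cwt", "config": asdict(config)},
    )


def adaptive_order(f: float, config: SLTConfig) -> float:
    """Superresolution order at frequency ``f``: linear across the band."""
    if not (config.fmin - 1e-9 <= f <= config.fmax + 1e-9):
        raise ParameterError(
            f"frequency {f} outside band [{config.fmin}, {config.fmax}]"
        )
    frac = (f - config.fmin) / (config.fmax - config.fmin)
    return config.order_min + (config.order_max - config.order_min) * frac


def _slt_cycles(config: SLTConfig, i: int) -> float:
    """Cycle count of the i-th wavelet (1-based) in the superlet set."""
    if config.mode == "multiplicative":
        return config.base_cycles * i
    return config.base_cycles + i - 1


def superlet_tfr(
    signal: TimeSeries,
    config: SLTConfig,
    k_sd: float = 5.0,
    norm: Literal["amplitude", "energy"] = "amplitude",
) -> TFRMatrix:
    """Fractional adaptive superlet transform.

    For each frequency f on the linear grid, the magnitude responses of
    ``ceil(o(f))`` Morlet wavelets with growing cycle counts are combined by
    a weighted geometric mean; the last wavelet's weight is the fractional
    part of the order, so the order varies smoothly across the band.
    """
    x = np.asarray(signal.samples, dtype=float)
    if len(x) == 0:
        raise InputError("empty signal")
    freqs = config.freq_grid
    if len(freqs) == 0:
        raise ParameterError("empty frequency grid")
    n = len(x)
    values = np.empty((len(freqs), n))
    tiny = np.finfo(float).tiny
    for row, f in enumerate(freqs):
        order = adaptive_order(f, config)
        n_wavelets = int(np.ceil(order - 1e-12))
        log_acc = np.zeros(n)
        weight_sum = 0.0
        for i in range(1, n_wavelets + 1):
            weight = 1.0 if i <= int(order) else order - int(order)
            kernel = morlet_wavelet(f, _slt_cycles(config, i), signal.fs, k_sd, norm)
            resp = np.abs(sps.fftconvolve(x, kernel, mode="same"))
            log_acc += weight * np.log(np.maximum(resp, tiny))
            weight_sum += weight
        values[row] = np.exp(log_acc / weight_sum)
    values[values <= tiny * 10] = 0.0
    return TFRMatrix(
        values=values,
        freqs=freqs,
        times=signal.times,
        meta={"method": "slt", "config": asdict(config), "k_sd": k_sd, "norm": norm},
    )


def _is_log_spaced(axis: np.ndarray) -> bool:
    if len(axis) < 3 or np.any(axis <= 0):
        return False
    lin = np.diff(axis)
    log = np.diff(np.log(axis))
    return np.allclose(log, log[0], rtol=1e-6) and not np.allclose(
        lin, lin[0], rtol=1e-6
    )


def regrid_tfr(
    tfr: TFRMatrix, target_freqs: np.ndarray, target_times: np.ndarray
) -> TFRMatrix:
    """Bilinear interpolation of a TFR onto target axes.

    Interpolation is linear in time and linear in frequency — or in
    log-frequency when the source rows are log-spaced (CWT scalograms).
    Values outside the source axes are held constant at the edge.
    """
    for axis in (tfr.freqs, tfr.times):
        if len(axis) > 1 and np.any(np.diff(axis) <= 0):
            raise InputError("source axes must be strictly ascending")
    src_f, tgt_f = np.asarray(tfr.freqs, float), np.asarray(target_freqs, float)
    if _is_log_spaced(src_f) and np.all(tgt_f > 0):
        src_f, tgt_f = np.log(src_f), np.log(tgt_f)

    if len(tfr.freqs) == 1:
        on_freq = np.repeat(tfr.values, len(target_freqs), axis=0)
    else:
        on_freq = np.empty((len(target_freqs), tfr.values.shape[1]))
        for j in range(tfr.values.shape[1]):
            on_freq[:, j] = np.interp(tgt_f, src_f, tfr.values[:, j])
    if len(tfr.times) == 1:
        out = np.repeat(on_freq, len(target_times), axis=1)
    else:
        out = np.empty((len(target_freqs), len(target_times)))
        for i in range(on_freq.shape[0]):
            out[i] = np.interp(target_times, tfr.times, on_freq[i])
    return TFRMatrix(
        values=out,
        freqs=np.asarray(target_freqs, float),
        times=np.asarray(target_times, float),
        meta=dict(tfr.meta, regridded=True),
    )


def normalize_max(tfr: TFRMatrix) -> TFRMatrix:
    """Scale a TFR so its global maximum is 1."""
    peak = float(tfr.values.max(initial=0.0))
    if peak <= 0:
        raise DegenerateInputError("cannot max-normalise an all-zero TFR")
    return TFRMatrix(
        values=tfr.values / peak, freqs=tfr.freqs, times=tfr.times, meta=dict(tfr.meta)
    )
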