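"""Synthetic AM/FM test signal and its analytic ground-truth TFR.

The benchmark signal emulates a pulsed, low-frequency animal sound: a sine
carrier swept linearly downward (50 -> 30 Hz by default) and gated by a
unipolar square-wave amplitude modulator whose rate itself sweeps linearly
(2 -> 7 Hz).  Square-wave gating of a tone produces a carrier line plus
sideband pairs at odd multiples of the momentary modulation rate, with
amplitudes given by the square wave's Fourier series.  The ground truth
paints exactly those tonal tracks — carrier plus ``n_sideband_pairs`` pairs —
onto a linear frequency grid, one column per signal sample, everything else
silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ParameterError

__all__ = [
    "SignalConfig",
    "TimeSeries",
    "GroundTruth",
    "sweep_phase",
    "make_carrier",
    "make_modulator",
    "make_test_signal",
    "sideband_amplitude",
    "build_ground_truth",
]


@dataclass(frozen=True)
class SignalConfig:
    """Full parameter set of the synthetic test signal and analysis band.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    duration : float
        Signal length in seconds.
    f0, f1 : float
        Carrier start and end frequency in Hz (downward sweep by default).
    fmod0, fmod1 : float
        Modulator start and end rate in Hz.
    fmin, fmax : float
        Analysis band limits in Hz; the ground-truth grid spans this band.
    f_res : float
        Frequency grid step in Hz.
    n_sideband_pairs : int
        Number of sideband pairs per side of the carrier; a 50 %-duty square
        modulator contributes pairs at odd offsets ``(2k-1) * f_mod``.
    gate_tracks : bool
        If True (default) the ground-truth tracks are gated by the square-wave
        modulator, so the spaces between AM pulses are silence; if False the
        tonal tracks run continuously through the pulse gaps.
    """

    fs: float = 250.0
    duration: float = 6.0
    f0: float = 50.0
    f1: float = 30.0
    fmod0: float = 2.0
    fmod1: float = 7.0
    fmin: float = 10.0
    fmax: float = 125.0
    f_res: float = 0.2
    n_sideband_pairs: int = 5
    gate_tracks: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if not (0 < self.fmin < self.fmax <= self.fs / 2):
            raise ParameterError(
                f"need 0 < fmin < fmax <= fs/2, got fmin={self.fmin}, "
                f"fmax={self.fmax}, fs/2={self.fs / 2}"
            )
        if self.f_res <= 0:
            raise ParameterError(f"f_res must be positive, got {self.f_res}")
        if self.n_sideband_pairs < 0:
            raise ParameterError("n_sideband_pairs must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def freq_grid(self) -> np.ndarray:
        """Linear frequency grid fmin..fmax with step f_res (inclusive)."""
        n = int(np.floor((self.fmax - self.fmin) / self.f_res + 1e-6)) + 1
        return self.fmin + self.f_res * np.arange(n)


@dataclass(frozen=True)
class TimeSeries:
    """A real, uniformly sampled amplitude sequence."""

    samples: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference TFR: tonal tracks on a linear grid, else silence."""

    values: np.ndarray  # (n_freqs, n_times), linear magnitude in [0, 1]
    freqs: np.ndarray  # ascending, Hz
    times: np.ndarray  # per-sample stamps, s
    meta: dict = field(default_factory=dict)


def sweep_phase(f_start: float, f_end: float, duration: float, fs: float) -> np.ndarray:
    """Phase of a linear frequency sweep, sampled at ``fs``.

    phi(t) = 2*pi*(f_start*t + (f_end - f_start)*t**2/(2*T)); the
    instantaneous frequency d(phi)/dt / (2*pi) runs linearly from
    ``f_start`` to ``f_end`` over ``duration`` seconds.
    """
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    t = np.arange(int(round(fs * duration))) / fs
    return 2.0 * np.pi * (f_start * t + (f_end - f_start) * t**2 / (2.0 * duration))


def make_carrier(config: SignalConfig) -> TimeSeries:
    """Linearly swept sine carrier x_c(t)."""
    phase = sweep_phase(config.f0, config.f1, config.duration, config.fs)
    return TimeSeries(np.sin(phase), config.fs)


def make_modulator(config: SignalConfig) -> TimeSeries:
    """Unipolar {0, 1} square wave whose rate sweeps fmod0 -> fmod1.

    sgn(0) is taken as +1 so sample values are deterministic.
    """
    phase = sweep_phase(config.fmod0, config.fmod1, config.duration, config.fs)
    return TimeSeries(np.where(np.sin(phase) >= 0.0, 1.0, 0.0), config.fs)


def make_test_signal(config: SignalConfig) -> TimeSeries:
    """Final test signal x(t) = x_m(t) * x_c(t)."""
    carrier = make_carrier(config)
    modulator = make_modulator(config)
    return TimeSeries(carrier.samples * modulator.samples, config.fs)


def sideband_amplitude(k: int) -> float:
    """Magnitude of the k-th sideband pair relative to the carrier.

    A 50 %-duty unipolar square modulator has Fourier series
    1/2 + (2/pi) * sum_odd sin(n*phi)/n, so the pair at offset
    ``(2k-1) * f_mod`` has amplitude ``2 / (pi * (2k-1))`` relative to the
    carrier line.
    """
    if k < 1:
        raise ParameterError(f"sideband pair index must be >= 1, got {k}")
    return 2.0 / (np.pi * (2 * k - 1))


def _instantaneous(config: SignalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Momentary carrier and modulator frequency per sample."""
    t = config.times
    fc = config.f0 + (config.f1 - config.f0) * t / config.duration
    fm = config.fmod0 + (config.fmod1 - config.fmod0) * t / config.duration
    return fc, fm


def build_ground_truth(config: SignalConfig) -> GroundTruth:
    """Paint the analytic tonal tracks on the reference grid.

    The carrier track carries value 1; sideband pair ``k`` carries
    ``sideband_amplitude(k)`` at offsets ``+/-(2k-1)*f_m(t)``.  Each track
    occupies the single nearest frequency bin per column; tracks leaving the
    analysis band are omitted at those times; all other cells are zero.
    With ``gate_tracks`` (the default) the tracks are switched on and off by
    the square-wave modulator, so the silent spaces between AM pulses appear
    as silence in the reference, alongside everything outside the tracks.
    """
    freqs = config.freq_grid
    if len(freqs) == 0:
        raise ParameterError("empty frequency grid")
    times = config.times
    fc, fm = _instantaneous(config)
    values = np.zeros((len(freqs), len(times)))
    cols = np.arange(len(times))

    def paint(track_freqs: np.ndarray, amplitude: float) -> None:
        inside = (track_freqs >= config.fmin) & (track_freqs <= config.fmax)
        rows = np.round((track_freqs[inside] - config.fmin) / config.f_res).astype(int)
        rows = np.clip(rows, 0, len(freqs) - 1)
        values[rows, cols[inside]] = np.maximum(values[rows, cols[inside]], amplitude)

    paint(fc, 1.0)
    for k in range(1, config.n_sideband_pairs + 1):
        offset = (2 * k - 1) * fm
        amp = sideband_amplitude(k)
        paint(fc + offset, amp)
        paint(fc - offset, amp)

    if config.gate_tracks:
        values *= make_modulator(config).samples[np.newaxis, :]

    return GroundTruth(values=values, freqs=freqs, times=times, meta={"config": config})
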