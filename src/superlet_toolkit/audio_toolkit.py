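"""Pre-processing and SLT analysis chain for short animal-sound recordings.

Mirrors the workflow of a desktop superlet-scalogram analyser: load a mono
WAV, trim to the call of interest, resample to a low analysis rate,
peak-normalise, then compute a superlet scalogram and export it as a
heatmap and/or CSV.  Because the per-sample superlet transform is costly,
recordings are guarded by a maximum sample rate (1 kHz) and maximum length
(80,000 samples); violating either raises a :class:`GuardrailError` naming
the exceeded limit.

Species presets bundle the analysis settings used for six exemplar
low-frequency calls (whale song, elephant rumble, whipbird song, cassowary
and mulloway grunts, crocodile growl).  The recordings themselves are
rights-restricted and not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from ._errors import FormatError, GuardrailError, ParameterError
from .io import tfr_to_csv, tfr_to_png
from .signal_synth import TimeSeries
from .tfr_engines import SLTConfig, TFRMatrix, normalize_max, superlet_tfr

__all__ = [
    "Recording",
    "Guardrails",
    "SPECIES_PRESETS",
    "species_preset",
    "load_audio",
    "preprocess",
    "analyze_recording",
    "export_visualisation",
]


@dataclass(frozen=True)
class Recording:
    """A mono audio recording scaled to [-1, 1]."""

    samples: np.ndarray
    fs: float
    source_path: str = "<memory>"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Guardrails:
    """Processing limits protecting the per-sample SLT from oversized input."""

    max_fs: float = 1000.0
    max_samples: int = 80_000

    def __post_init__(self) -> None:
        if self.max_fs <= 0 or self.max_samples <= 0:
            raise ParameterError("guardrail limits must be positive")

    def check(self, rec: Recording) -> None:
        if rec.fs > self.max_fs:
            raise GuardrailError(
                f"sample rate {rec.fs:g} Hz exceeds the {self.max_fs:g} Hz limit"
            )
        if len(rec.samples) > self.max_samples:
            raise GuardrailError(
                f"length {len(rec.samples)} samples exceeds the "
                f"{self.max_samples} sample limit"
            )


def _clamped_band(fmin: float, fmax: float, f_res: float) -> tuple[float, float]:
    # wavelets are undefined at 0 Hz: clamp the low edge to one grid step
    return max(fmin, f_res), fmax


def _preset(cycles, omin, omax, fmin, fmax, f_res) -> SLTConfig:
    lo, hi = _clamped_band(fmin, fmax, f_res)
    return SLTConfig(
        base_cycles=cycles, order_min=omin, order_max=omax,
        mode="multiplicative", fmin=lo, fmax=hi, f_res=f_res,
    )


#: Analysis settings per species (band in Hz, resolution in Hz).
SPECIES_PRESETS: dict[str, SLTConfig] = {
    "chagos_blue_whale": _preset(4, 10, 40, 10.0, 60.0, 0.1),
    "asian_elephant": _preset(4, 10, 40, 0.0, 250.0, 0.1),
    "eastern_whipbird": _preset(4, 10, 40, 1000.0, 10_000.0, 2.0),
    "southern_cassowary": _preset(4, 10, 40, 0.0, 1000.0, 0.1),
    "mulloway": _preset(4, 10, 40, 10.0, 1000.0, 0.1),
    "american_crocodile": _preset(4, 10, 40, 10.0, 1000.0, 0.1),
}


def species_preset(name: str) -> SLTConfig:
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown species preset {name!r}; available: "
            f"{', '.join(sorted(SPECIES_PRESETS))}"
        ) from None


_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def load_audio(path: str | Path) -> Recording:
    """Load a WAV file as a mono recording scaled to [-1, 1].

    Multi-channel input is down-mixed by channel mean.  Integer PCM is
    scaled by its full-scale value; float data is taken as-is.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in _INT_SCALE:
        samples = data.astype(float) / _INT_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    elif samples.ndim != 1:
        raise FormatError(f"unsupported channel layout in {path}")
    return Recording(samples=samples, fs=float(fs), source_path=str(path))


def preprocess(
    rec: Recording,
    t0: float = 0.0,
    t1: float | None = None,
    target_fs: float | None = None,
    guards: Guardrails = Guardrails(),
) -> Recording:
    """Trim to [t0, t1), polyphase-resample and peak-normalise.

    The result must satisfy the guardrails; otherwise a
    :class:`GuardrailError` names the exceeded limit.
    """
    if t1 is None:
        t1 = rec.duration
    if not (0 <= t0 < t1 <= rec.duration + 1e-9):
        raise ParameterError(f"need 0 <= t0 < t1 <= duration, got [{t0}, {t1})")
    i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
    samples = np.asarray(rec.samples, dtype=float)[i0:i1]
    fs = rec.fs
    if target_fs is not None and target_fs != fs:
        if target_fs <= 0:
            raise ParameterError("target_fs must be positive")
        ratio = Fraction(target_fs / fs).limit_denominator(10_000)
        samples = sps.resample_poly(samples, ratio.numerator, ratio.denominator)
        fs = float(target_fs)
    peak = np.max(np.abs(samples), initial=0.0)
    if peak > 0:
        samples = samples / peak
    out = Recording(samples=samples, fs=fs, source_path=rec.source_path)
    guards.check(out)
    return out


def analyze_recording(
    rec: Recording,
    config: SLTConfig,
    guards: Guardrails = Guardrails(),
    preset_name: str | None = None,
) -> TFRMatrix:
    """Superlet scalogram of a recording, max-normalised."""
    guards.check(rec)
    if config.fmax > rec.fs / 2:
        config = replace(config, fmax=rec.fs / 2)
    tfr = normalize_max(
        superlet_tfr(TimeSeries(np.asarray(rec.samples, float), rec.fs), config)
    )
    if preset_name:
        tfr.meta["preset"] = preset_name
    tfr.meta["source"] = rec.source_path
    return tfr


def export_visualisation(
    tfr: TFRMatrix,
    out_path: str | Path,
    db: bool = False,
    fmin: float | None = None,
    fmax: float | None = None,
    cmap: str = "magma",
    csv_path: str | Path | None = None,
) -> list[Path]:
    """Write a PNG heatmap (and optionally the matrix as CSV)."""
    written = [
        tfr_to_png(tfr, out_path, title=tfr.meta.get("preset"),
                   db=db, fmin=fmin, fmax=fmax, cmap=cmap)
    ]
    if csv_path is not None:
        written.append(tfr_to_csv(tfr, csv_path))
    return written
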