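"""CSV / PNG / WAV serialisation of TFR matrices and signals."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from ._errors import InputError
from .tfr_engines import TFRMatrix

__all__ = ["tfr_to_csv", "tfr_from_csv", "tfr_to_png", "write_wav"]


def tfr_to_csv(tfr: TFRMatrix, path: str | Path) -> Path:
    """Write a TFR as CSV: first column frequency, header row time stamps."""
    path = Path(path)
    frame = pd.DataFrame(tfr.values, index=tfr.freqs, columns=tfr.times)
    frame.index.name = "frequency_hz"
    frame.to_csv(path)
    return path


def tfr_from_csv(path: str | Path) -> TFRMatrix:
    """Read a TFR written by :func:`tfr_to_csv`."""
    frame = pd.read_csv(path, index_col=0)
    try:
        times = frame.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise InputError(f"non-numeric time header in {path}") from exc
    return TFRMatrix(
        values=frame.to_numpy(dtype=float),
        freqs=frame.index.to_numpy(dtype=float),
        times=times,
        meta={"source": str(path)},
    )


def tfr_to_png(
    tfr: TFRMatrix,
    path: str | Path,
    title: str | None = None,
    db: bool = False,
    db_floor: float = -60.0,
    fmin: float | None = None,
    fmax: float | None = None,
    cmap: str = "magma",
) -> Path:
    """Render a TFR heatmap (time on X, frequency on Y) to a PNG file.

    With ``db=True`` magnitudes are mapped to 20*log10(v + 1e-12), clipped
    at ``db_floor``.  ``fmin``/``fmax`` crop the frequency axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    values, freqs = tfr.values, tfr.freqs
    if fmin is not None or fmax is not None:
        lo = fmin if fmin is not None else freqs[0]
        hi = fmax if fmax is not None else freqs[-1]
        keep = (freqs >= lo) & (freqs <= hi)
        values, freqs = values[keep], freqs[keep]
    if db:
        values = np.maximum(20.0 * np.log10(values + 1e-12), db_floor)
        label = "magnitude (dB)"
    else:
        label = "magnitude"
    fig, ax = plt.subplots(figsize=(8, 4.5))
    mesh = ax.pcolormesh(tfr.times, freqs, values, cmap=cmap, shading="nearest")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_wav(path: str | Path, samples: np.ndarray, fs: float) -> Path:
    """Write a float32 mono WAV file."""
    path = Path(path)
    wavfile.write(path, int(round(fs)), np.asarray(samples, dtype=np.float32))
    return path
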