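"""End-to-end quantitative evaluation of the four TFR methods.

Synthesizes the AM/FM test signal and its analytic ground truth, runs the
short-STFT, long-STFT, CWT and SLT engines, max-normalises and regrids each
TFR onto the ground-truth grid, and scores all four on the three RMSE
formulations and the structural similarity index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import SuperletToolkitError
from .metrics import ScoreTable, spectral_rmse, ssi, temporal_rmse, total_rmse
from .signal_synth import GroundTruth, SignalConfig, build_ground_truth, make_test_signal
from .tfr_engines import (
    CWTConfig,
    SLTConfig,
    STFTConfig,
    TFRMatrix,
    cwt_tfr,
    nfft_from_resolution,
    normalize_max,
    regrid_tfr,
    stft_tfr,
    superlet_tfr,
)

__all__ = [
    "MethodSet",
    "BenchmarkReport",
    "default_method_set",
    "run_benchmark",
    "export_report",
]

METHOD_ORDER = ("short-STFT", "long-STFT", "CWT", "SLT")


@dataclass(frozen=True)
class MethodSet:
    """The four method configurations evaluated by the benchmark."""

    stft_short: STFTConfig
    stft_long: STFTConfig
    cwt: CWTConfig
    slt: SLTConfig


@dataclass(frozen=True)
class BenchmarkReport:
    """Scores, configuration snapshot and per-metric method rankings."""

    scores: list[ScoreTable]
    signal_config: SignalConfig
    methods: MethodSet
    rankings: dict[str, list[str]]
    tfrs: dict[str, TFRMatrix] = field(default_factory=dict, repr=False)
    ground_truth: GroundTruth | None = field(default=None, repr=False)

    def score_for(self, method: str) -> ScoreTable:
        for s in self.scores:
            if s.method == method:
                return s
        raise KeyError(method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.scores])


def default_method_set(signal_config: SignalConfig | None = None) -> MethodSet:
    """Benchmark configurations: two STFTs, Morse CWT and adaptive SLT.

    Band limits and frequency resolution are shared across methods;
    ``nfft`` follows the resolution rule (fs / f_res).
    """
    cfg = signal_config or SignalConfig()
    nfft = nfft_from_resolution(cfg.fs, cfg.f_res)
    band = dict(fmin=cfg.fmin, fmax=cfg.fmax)
    return MethodSet(
        stft_short=STFTConfig(n=50, overlap=0.75, nfft=nfft, **band),
        stft_long=STFTConfig(n=250, overlap=0.75, nfft=nfft, **band),
        cwt=CWTConfig(time_bandwidth=120.0, gamma=3.0, voices_per_octave=48, **band),
        slt=SLTConfig(
            base_cycles=3.0,
            order_min=10.0,
            order_max=40.0,
            mode="multiplicative",
            f_res=cfg.f_res,
            **band,
        ),
    )


def _rank(scores: list[ScoreTable], metric: str, ascending: bool) -> list[str]:
    key = lambda s: getattr(s, metric)  # noqa: E731
    return [s.method for s in sorted(scores, key=key, reverse=not ascending)]


def run_benchmark(
    signal_config: SignalConfig | None = None,
    methods: MethodSet | None = None,
    keep_tfrs: bool = False,
) -> BenchmarkReport:
    """Run the full deterministic evaluation.

    Each engine's TFR is max-normalised, bilinearly regridded to the
    ground-truth grid (one column per signal sample, rows fmin..fmax at
    f_res) and scored on all four metrics.  Raises with the failing method
    named if any engine errors out.
    """
    cfg = signal_config or SignalConfig()
    methods = methods or default_method_set(cfg)
    x = make_test_signal(cfg)
    truth = build_ground_truth(cfg)
    truth_tfr = TFRMatrix(
        values=truth.values, freqs=truth.freqs, times=truth.times,
        meta={"method": "ground-truth"},
    )

    engines = {
        "short-STFT": lambda: stft_tfr(x, methods.stft_short),
        "long-STFT": lambda: stft_tfr(x, methods.stft_long),
        "CWT": lambda: cwt_tfr(x, methods.cwt),
        "SLT": lambda: superlet_tfr(x, methods.slt),
    }
    scores: list[ScoreTable] = []
    tfrs: dict[str, TFRMatrix] = {}
    for name in METHOD_ORDER:
        try:
            tfr = normalize_max(
                regrid_tfr(engines[name](), truth.freqs, truth.times)
            )
        except SuperletToolkitError as exc:
            raise SuperletToolkitError(f"method {name!r} failed: {exc}") from exc
        scores.append(
            ScoreTable(
                method=name,
                spectral_rmse=spectral_rmse(tfr, truth_tfr),
                temporal_rmse=temporal_rmse(tfr, truth_tfr),
                total_rmse=total_rmse(tfr, truth_tfr),
                ssi=ssi(tfr, truth_tfr),
            )
        )
        if keep_tfrs:
            tfrs[name] = tfr
    rankings = {
        "spectral_rmse": _rank(scores, "spectral_rmse", ascending=True),
        "temporal_rmse": _rank(scores, "temporal_rmse", ascending=True),
        "total_rmse": _rank(scores, "total_rmse", ascending=True),
        "ssi": _rank(scores, "ssi", ascending=False),
    }
    return BenchmarkReport(
        scores=scores,
        signal_config=cfg,
        methods=methods,
        rankings=rankings,
        tfrs=tfrs,
        ground_truth=truth if keep_tfrs else None,
    )


def export_report(report: BenchmarkReport, out_dir: str | Path) -> list[Path]:
    """Write scores CSV, per-method heatmaps, bar charts and config JSON.

    Requires a report built with ``keep_tfrs=True`` for the heatmaps.
    Returns the list of files written.
    """
    from .io import tfr_to_png  # deferred: matplotlib import is slow

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "scores.csv"
    report.to_frame().to_csv(csv_path, index=False)
    written.append(csv_path)

    config = {
        "signal": dataclasses.asdict(report.signal_config),
        "methods": dataclasses.asdict(report.methods),
        "rankings": report.rankings,
    }
    json_path = out / "config.json"
    json_path.write_text(json.dumps(config, indent=2))
    written.append(json_path)

    if report.ground_truth is not None:
        gt = report.ground_truth
        written.append(
            tfr_to_png(
                TFRMatrix(gt.values, gt.freqs, gt.times, {"method": "ground-truth"}),
                out / "tfr_ground_truth.png",
                title="Ground truth",
            )
        )
    for name, tfr in report.tfrs.items():
        slug = name.lower().replace("-", "_")
        written.append(tfr_to_png(tfr, out / f"tfr_{slug}.png", title=name))

    frame = report.to_frame().set_index("method")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    frame[["spectral_rmse", "temporal_rmse", "total_rmse"]].plot.bar(ax=axes[0])
    axes[0].set_ylabel("RMSE (lower is better)")
    frame[["ssi"]].plot.bar(ax=axes[1], legend=False)
    axes[1].set_ylabel("SSI (higher is better)")
    for ax in axes:
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    bars_path = out / "scores_bars.png"
    fig.savefig(bars_path, dpi=120)
    plt.close(fig)
    written.append(bars_path)
    return written
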