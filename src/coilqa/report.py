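"""Human-reviewable outputs: tidy CSVs, plots, ROI overlays and frame sequences.

All plotting uses the non-interactive Agg backend with fixed figure
settings so reruns on identical inputs reproduce identical artifacts.
The per-element "video" deliverable is a numbered PNG frame sequence
(one frame per slice, Noise and Signal panels with their ROIs and
statistics), which is portable and diff-able; an MP4 can be assembled
externally if desired.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Circle

from .combined import SliceMetrics
from .dicom_io import ImagePair
from .elements import ElementSliceMetrics, ElementSummary
from .segmentation import CircularRoi, PhantomGeometry


def combined_metrics_frame(metrics: list[SliceMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slice_location_mm": [m.slice_location for m in metrics],
            "mean_signal": [m.mean_signal for m in metrics],
            "noise_sd": [m.noise_sd for m in metrics],
            "snr": [m.snr for m in metrics],
            "s_max": [m.s_max for m in metrics],
            "s_min": [m.s_min for m in metrics],
            "piu_pct": [m.piu for m in metrics],
            "roi_row": [m.roi.center[0] for m in metrics],
            "roi_col": [m.roi.center[1] for m in metrics],
            "roi_radius_px": [m.roi.radius for m in metrics],
        }
    )


def element_metrics_frame(metrics: dict[str, list[ElementSliceMetrics]]) -> pd.DataFrame:
    rows = []
    for label in sorted(metrics):
        for m in metrics[label]:
            rows.append(
                {
                    "element": label,
                    "slice_location_mm": m.slice_location,
                    "noise_sd": m.noise_sd,
                    "mean_peak_signal": m.mean_peak_signal,
                    "snr": m.snr,
                    "peak_row": m.peak_center[0],
                    "peak_col": m.peak_center[1],
                }
            )
    return pd.DataFrame(rows)


def element_summary_frame(
    summaries: list[ElementSummary], absent: frozenset[str] = frozenset()
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element": [s.element_label for s in summaries],
            "group": [s.group for s in summaries],
            "peak_snr_mean": [s.peak_snr_mean for s in summaries],
            "peak_snr_sd": [s.peak_snr_sd for s in summaries],
            "slices_used_mm": ["|".join(f"{x:+.0f}" for x in s.slices_used) for s in summaries],
            "physically_absent": [s.element_label in absent for s in summaries],
        }
    )


def plot_combined_metrics(
    metrics_by_condition: dict[str, list[SliceMetrics]], path: str | Path, title: str = ""
) -> Path:
    """Four stacked panels (signal, noise, SNR, PIU) vs slice location,
    one line per filtering condition."""
    fig, axes = plt.subplots(4, 1, figsize=(7, 10), sharex=True)
    panels = [
        ("mean_signal", "mean signal (a.u.)"),
        ("noise_sd", "noise SD (a.u.)"),
        ("snr", "SNR"),
        ("piu", "uniformity (%)"),
    ]
    for condition, metrics in sorted(metrics_by_condition.items()):
        locs = [m.slice_location for m in metrics]
        for ax, (attr, _) in zip(axes, panels):
            ax.plot(locs, [getattr(m, attr) for m in metrics], marker="o", label=condition)
    for ax, (_, ylabel) in zip(axes, panels):
        ax.set_ylabel(ylabel)
        ax.grid(True, alpha=0.3)
    axes[0].legend(loc="best", fontsize=8)
    axes[-1].set_xlabel("slice location (mm)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def plot_element_metrics(
    metrics: dict[str, list[ElementSliceMetrics]], path: str | Path, title: str = ""
) -> Path:
    """Noise, peak signal and SNR vs slice location, one line per element."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    for label in sorted(metrics):
        ms = metrics[label]
        locs = [m.slice_location for m in ms]
        axes[0].plot(locs, [m.noise_sd for m in ms], label=label)
        axes[1].plot(locs, [m.mean_peak_signal for m in ms], label=label)
        axes[2].plot(locs, [m.snr for m in ms], label=label)
    for ax, ylabel in zip(axes, ["noise SD (a.u.)", "peak signal (a.u.)", "SNR"]):
        ax.set_ylabel(ylabel)
        ax.grid(True, alpha=0.3)
    axes[0].legend(loc="upper right", fontsize=6, ncol=4)
    axes[-1].set_xlabel("slice location (mm)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def render_roi_overlay(
    pair: ImagePair, metrics: SliceMetrics, path: str | Path
) -> Path:
    """Noise and Signal panels with the analysis ROI and its statistics."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, (img, name) in zip(
        axes, [(pair.noise_pixels, "Noise"), (pair.signal_pixels, "Signal")]
    ):
        ax.imshow(np.asarray(img, dtype=float), cmap="gray")
        ax.add_patch(
            Circle(
                (metrics.roi.center[1], metrics.roi.center[0]),
                metrics.roi.radius,
                fill=False,
                color="yellow",
                lw=1.2,
            )
        )
        ax.set_title(f"{name}  z={pair.meta.slice_location:+.0f} mm", fontsize=9)
        ax.axis("off")
    stats = (
        f"mean={metrics.mean_signal:.1f}  sd={metrics.noise_sd:.2f}  "
        f"SNR={metrics.snr:.1f}  PIU={metrics.piu:.1f}%"
    )
    fig.suptitle(stats, fontsize=9)
    path = Path(path)
    fig.savefig(path, dpi=80)
    plt.close(fig)
    return path


def render_element_frames(
    label: str,
    pairs: list[ImagePair],
    metrics: list[ElementSliceMetrics],
    directory: str | Path,
) -> list[Path]:
    """One PNG frame per slice for one element (the review "video")."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_loc = {m.slice_location: m for m in metrics}
    paths = []
    for i, pair in enumerate(sorted(pairs, key=lambda p: p.meta.slice_location)):
        m = by_loc[pair.meta.slice_location]
        fig, axes = plt.subplots(1, 2, figsize=(6, 3))
        axes[0].imshow(np.asarray(pair.noise_pixels, dtype=float), cmap="gray")
        axes[0].set_title(f"Noise sd={m.noise_sd:.2f}", fontsize=8)
        axes[1].imshow(np.asarray(pair.signal_pixels, dtype=float), cmap="gray")
        axes[1].plot([m.peak_center[1]], [m.peak_center[0]], "r.", ms=4)
        axes[1].add_patch(
            Circle((m.peak_center[1], m.peak_center[0]), m.roi.radius, fill=False, color="cyan", lw=1)
        )
        axes[1].set_title(f"Signal peak={m.mean_peak_signal:.1f} SNR={m.snr:.1f}", fontsize=8)
        for ax in axes:
            ax.axis("off")
        fig.suptitle(f"{label}  z={pair.meta.slice_location:+.0f} mm", fontsize=9)
        path = directory / f"{label}_{i:03d}.png"
        fig.savefig(path, dpi=70)
        plt.close(fig)
        paths.append(path)
    return paths


def decisions_frame(decisions: dict[str, "object"]) -> pd.DataFrame:
    rows = []
    for key in sorted(decisions):
        d = decisions[key]
        rows.append(
            {
                "metric_key": key,
                "status": d.status,
                "criterion": d.criterion,
                "deviation": d.deviation,
                "baseline_n": d.baseline_n,
            }
        )
    return pd.DataFrame(rows)
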