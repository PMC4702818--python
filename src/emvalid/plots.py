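"""PNG plot rendering for curves, spectra and map images."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fsc import CRITERIA, FSCCurve, criterion_threshold, estimate_resolution
from .mapstats import ContourCurve, RadialSpectrum
from .volume import DensityMap

__all__ = [
    "plot_fsc",
    "plot_histogram",
    "plot_power_spectrum",
    "plot_contour_curve",
    "plot_images",
]


def plot_fsc(curve: FSCCurve, path, criteria=CRITERIA) -> None:
    """FSC curve with criterion thresholds and estimated resolutions."""
    fig, ax = plt.subplots(figsize=(6.5, 4))
    ax.plot(curve.frequencies, curve.correlations, "k-", lw=1.6, label="FSC")
    labels = []
    for criterion in criteria:
        try:
            thresholds = criterion_threshold(criterion, curve)
            est = estimate_resolution(curve, criterion)
        except ValueError:
            continue
        (line,) = ax.plot(curve.frequencies, thresholds, "--", lw=0.9)
        if est.reached:
            ax.axvline(est.crossing_frequency, color=line.get_color(), lw=0.7, alpha=0.6)
            labels.append(f"{criterion}: {est.resolution:.2f} Å")
        else:
            labels.append(f"{criterion}: not reached")
    ax.axhline(0, color="0.6", lw=0.5)
    ax.set_xlabel("Spatial frequency (1/Å)")
    ax.set_ylabel("Correlation")
    ax.set_title("Fourier Shell Correlation")
    if labels:
        ax.text(
            0.98, 0.97, "\n".join(labels), transform=ax.transAxes,
            ha="right", va="top", fontsize=8,
            bbox=dict(boxstyle="round", fc="white", alpha=0.8),
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_histogram(edges, counts, path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.stairs(counts, edges, fill=True, alpha=0.7)
    ax.set_xlabel("Density (map units)")
    ax.set_ylabel("Voxels")
    ax.set_yscale("log")
    ax.set_title("Map density distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_power_spectrum(spectrum: RadialSpectrum, path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.semilogy(spectrum.frequencies, spectrum.power, "k-")
    ax.set_xlabel("Spatial frequency (1/Å)")
    ax.set_ylabel("Mean |F|²")
    ax.set_title("Rotationally averaged power spectrum")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contour_curve(curve: ContourCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.plot(curve.levels, curve.volumes, "k-")
    ax.set_xlabel("Contour level (map units)")
    ax.set_ylabel("Enclosed volume (Å³)")
    ax.set_title("Volume vs contour level")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_images(images, path, titles=None) -> None:
    """Render a row of 2D images (projections or slices) to one PNG."""
    images = list(images)
    fig, axes = plt.subplots(1, len(images), figsize=(3 * len(images), 3))
    if len(images) == 1:
        axes = [axes]
    for i, (ax, image) in enumerate(zip(axes, images)):
        ax.imshow(np.asarray(image).T, origin="lower", cmap="gray")
        ax.set_xticks([])
        ax.set_yticks([])
        if titles:
            ax.set_title(titles[i], fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
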