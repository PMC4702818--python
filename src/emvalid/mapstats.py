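"""Visual-analysis statistics for a single density map.

These are the per-entry summaries shown on archive visual-analysis pages:
density histogram, rotationally averaged power spectrum, enclosed volume
versus contour level, orthogonal projections and central slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fsc import hermitian_unique_mask, shell_bins
from .volume import DensityMap

__all__ = [
    "ContourCurve",
    "RadialSpectrum",
    "Projections",
    "density_histogram",
    "rotational_power_spectrum",
    "volume_vs_contour",
    "orthogonal_projections",
    "central_slices",
]


@dataclass
class ContourCurve:
    """Enclosed volume (Å³) as a function of density threshold (ascending)."""

    levels: np.ndarray
    volumes: np.ndarray


@dataclass
class RadialSpectrum:
    """Mean squared Fourier amplitude per frequency shell (1/Å centers)."""

    frequencies: np.ndarray
    power: np.ndarray
    dc_power: float


@dataclass
class Projections:
    """Axis sums of the density: raw values and [0,1]-normalized renderings."""

    raw: tuple
    normalized: tuple


def density_histogram(density_map: DensityMap, n_bins: int):
    """Equal-width histogram of voxel densities spanning [min, max].

    Bins are right-open except the last, so counts always sum to the voxel
    count.  A constant map degenerates to a single occupied bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    data = density_map.data.ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        hi = lo + 1.0  # arbitrary unit width; everything lands in bin 0
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    return edges, counts


def rotational_power_spectrum(density_map: DensityMap) -> RadialSpectrum:
    """Mean |F|^2 per spatial-frequency shell (shells as in the FSC module).

    The DC term is reported separately in ``dc_power`` so the decaying
    structure of the spectrum is not dwarfed by the mean density.
    """
    shape = density_map.shape
    f = np.fft.fftn(density_map.data)
    power = np.abs(f) ** 2
    mask = hermitian_unique_mask(shape)
    bins, freqs, _ = shell_bins(shape, density_map.voxel_size)
    keep = mask & (bins >= 0)
    b = bins[keep]
    sums = np.bincount(b, weights=power[keep], minlength=len(freqs))
    counts = np.bincount(b, minlength=len(freqs))
    occupied = counts > 0
    mean_power = sums[occupied] / counts[occupied]
    freqs = freqs[occupied]
    dc = float(mean_power[0]) if freqs[0] == 0.0 else float("nan")
    if freqs[0] == 0.0:
        freqs, mean_power = freqs[1:], mean_power[1:]
    return RadialSpectrum(frequencies=freqs, power=mean_power, dc_power=dc)


def volume_vs_contour(density_map: DensityMap, levels) -> ContourCurve:
    """Enclosed volume at each threshold: (# voxels >= level) x voxel volume."""
    levels = np.sort(np.asarray(levels, dtype=float))
    if not np.all(np.isfinite(levels)):
        raise ValueError("contour levels must be finite")
    data = np.sort(density_map.data.ravel())
    # voxels >= level via binary search on the sorted densities
    counts = data.size - np.searchsorted(data, levels, side="left")
    return ContourCurve(levels=levels, volumes=counts * density_map.voxel_volume)


def orthogonal_projections(density_map: DensityMap) -> Projections:
    """Density sums along x, y and z, plus [0,1]-normalized copies."""
    raw = tuple(density_map.data.sum(axis=axis) for axis in range(3))
    normalized = []
    for image in raw:
        lo, hi = image.min(), image.max()
        normalized.append(
            np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        )
    return Projections(raw=raw, normalized=tuple(normalized))


def central_slices(density_map: DensityMap) -> tuple:
    """The plane at index floor(N/2) along each axis (0-based)."""
    data = density_map.data
    return (
        data[data.shape[0] // 2, :, :].copy(),
        data[:, data.shape[1] // 2, :].copy(),
        data[:, :, data.shape[2] // 2].copy(),
    )
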