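"""Fourier Shell Correlation between independent half-maps.

FSC measures, per shell of spatial-frequency magnitude, the normalized
cross-correlation of two reconstructions computed from independent halves of
the data:

    FSC(s) = Re( sum_k F_a(k) conj(F_b(k)) )
             / sqrt( sum_k |F_a(k)|^2 * sum_k |F_b(k)|^2 )

with k running over Fourier voxels in shell s.  The estimated map resolution
is the reciprocal of the frequency at which the curve first drops below a
threshold criterion; several conventions coexist (fixed 0.5, fixed 0.143,
the half-bit information criterion, and the 3-sigma noise criterion), so all
four are provided.

Shells are one reciprocal-grid step wide (bin index = round(|s| / Δs),
Δs = 1 / (N·voxel)).  The transforms are treated as Hermitian half-volumes:
each conjugate voxel pair contributes once to the shell sums, so
``shell_counts`` are counts of independent Fourier voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lxml import etree

from .volume import DensityMap

__all__ = [
    "FSCCurve",
    "ResolutionEstimate",
    "CRITERIA",
    "compute_fsc",
    "estimate_resolution",
    "write_fsc_xml",
    "read_fsc_xml",
]

_VOXEL_RTOL = 1e-3

CRITERIA = ("fixed-0.5", "fixed-0.143", "half-bit", "three-sigma")


@dataclass
class FSCCurve:
    """Per-shell correlation between two half-maps.

    ``frequencies`` are shell-center spatial frequencies in 1/Å, strictly
    increasing, beginning with the origin-only DC shell at 0.  ``shell_counts``
    are independent (conjugate-collapsed) Fourier voxel counts per shell; they
    are ``None`` for curves read back from XML, which does not carry them.
    """

    frequencies: np.ndarray
    correlations: np.ndarray
    shell_counts: Optional[np.ndarray]
    nyquist: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.shell_counts is not None:
            self.shell_counts = np.asarray(self.shell_counts, dtype=np.int64)
        if self.frequencies.ndim != 1 or len(self.frequencies) != len(self.correlations):
            raise ValueError("frequencies and correlations must be 1D and equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class ResolutionEstimate:
    """Threshold crossing of an FSC curve under one criterion.

    ``resolution`` is 1/crossing_frequency in Å, or ``None`` when the curve
    never falls below the threshold; then ``resolution_bound`` holds the
    Nyquist-limited bound.
    """

    criterion: str
    resolution: Optional[float]
    crossing_frequency: Optional[float]
    resolution_bound: Optional[float] = None

    @property
    def reached(self) -> bool:
        return self.resolution is not None

    def __str__(self) -> str:
        if self.reached:
            return f"{self.criterion}: {self.resolution:.2f} Å"
        return f"{self.criterion}: not reached (better than {self.resolution_bound:.2f} Å)"


def hermitian_unique_mask(shape) -> np.ndarray:
    """Mask over a full FFT grid selecting one voxel per conjugate pair.

    A voxel at index ``k`` is kept iff its index tuple is lexicographically
    <= that of its conjugate ``(-k) mod N``; self-conjugate voxels (DC and
    half-Nyquist corners) are kept exactly once.
    """
    idx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    conj = [(-i) % n for i, n in zip(idx, shape)]
    x, y, z = idx
    cx, cy, cz = conj
    lt = (x < cx) | ((x == cx) & ((y < cy) | ((y == cy) & (z <= cz))))
    return np.broadcast_to(lt, shape) if lt.shape != tuple(shape) else lt


def shell_bins(shape, voxel_size) -> tuple:
    """Per-voxel shell index and shell-center frequencies for an FFT grid.

    Returns ``(bins, freqs, delta)`` where ``bins[k]`` is
    round(|s(k)| / Δs) with Δs = 1/(N_max · voxel) and ``freqs[j] = j·Δs``;
    bins whose center exceeds Nyquist get index -1 (excluded).
    """
    voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    ratio = voxel.max() / voxel.min()
    if ratio > 1 + _VOXEL_RTOL:
        raise ValueError(
            f"voxels too anisotropic for shell binning (max/min = {ratio:.4f})"
        )
    delta = 1.0 / (max(shape) * float(voxel.min()))
    nyquist = 1.0 / (2.0 * float(voxel.min()))
    coords = [
        np.fft.fftfreq(n, d=d).astype(float) for n, d in zip(shape, voxel)
    ]
    grids = np.meshgrid(*coords, indexing="ij", sparse=True)
    smag = np.sqrt(sum(g * g for g in grids))
    bins = np.rint(smag / delta).astype(np.int64)
    n_shells = int(math.floor(nyquist / delta + 1e-9)) + 1
    bins[bins * delta > nyquist * (1 + 1e-9)] = -1
    freqs = np.arange(n_shells) * delta
    return bins, freqs, delta


def _check_pair(map_a: DensityMap, map_b: DensityMap) -> None:
    if map_a.shape != map_b.shape:
        raise ValueError(
            f"grid mismatch: {map_a.shape} vs {map_b.shape}"
        )
    rel = np.abs(map_a.voxel_size - map_b.voxel_size) / map_a.voxel_size
    if np.any(rel > _VOXEL_RTOL):
        raise ValueError(
            f"voxel-size mismatch: {tuple(map_a.voxel_size)} vs "
            f"{tuple(map_b.voxel_size)}"
        )


def compute_fsc(half_map_a: DensityMap, half_map_b: DensityMap) -> FSCCurve:
    """Compute the FSC curve between two half-maps on identical grids.

    The DC term is reported as its own first shell with correlation 1; it is
    excluded from resolution estimation downstream.
    """
    _check_pair(half_map_a, half_map_b)
    if not np.any(half_map_a.data) or not np.any(half_map_b.data):
        raise ValueError("all-zero map: FSC normalization undefined")

    shape = half_map_a.shape
    fa = np.fft.fftn(half_map_a.data)
    fb = np.fft.fftn(half_map_b.data)
    mask = hermitian_unique_mask(shape)
    bins, freqs, _ = shell_bins(shape, half_map_a.voxel_size)

    keep = mask & (bins >= 0)
    b = bins[keep]
    n_shells = len(freqs)
    cross = np.bincount(b, weights=(fa * np.conj(fb)).real[keep], minlength=n_shells)
    pa = np.bincount(b, weights=(np.abs(fa) ** 2)[keep], minlength=n_shells)
    pb = np.bincount(b, weights=(np.abs(fb) ** 2)[keep], minlength=n_shells)
    counts = np.bincount(b, minlength=n_shells)

    occupied = counts > 0
    denom = np.sqrt(pa * pb)
    corr = np.ones(n_shells)
    nz = occupied & (denom > 0)
    corr[nz] = cross[nz] / denom[nz]
    corr[0] = 1.0  # DC shell by convention

    return FSCCurve(
        frequencies=freqs[occupied],
        correlations=corr[occupied],
        shell_counts=counts[occupied],
        nyquist=half_map_a.nyquist,
    )


def criterion_threshold(criterion: str, curve: FSCCurve) -> np.ndarray:
    """Per-shell threshold values for a named criterion.

    half-bit: T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n));
    three-sigma: 3/sqrt(n/2); both with n the independent voxel count of the
    shell.  Fixed criteria are constant.
    """
    n_shells = len(curve)
    if criterion == "fixed-0.5":
        return np.full(n_shells, 0.5)
    if criterion == "fixed-0.143":
        return np.full(n_shells, 0.143)
    if curve.shell_counts is None:
        raise ValueError(f"criterion {criterion!r} requires shell voxel counts")
    n = curve.shell_counts.astype(float)
    sqrt_n = np.sqrt(np.maximum(n, 1.0))
    if criterion == "half-bit":
        return (0.2071 + 1.9102 / sqrt_n) / (1.2071 + 0.9102 / sqrt_n)
    if criterion == "three-sigma":
        return 3.0 / np.sqrt(np.maximum(n, 2.0) / 2.0)
    raise ValueError(f"unknown criterion {criterion!r}; known: {CRITERIA}")


def estimate_resolution(curve: FSCCurve, criterion: str) -> ResolutionEstimate:
    """Estimate resolution as the first sub-threshold crossing of the curve.

    Scanning from low to high frequency (DC excluded), the first shell whose
    correlation falls strictly below the criterion threshold defines the
    crossing; its position is refined by linear interpolation of
    (correlation - threshold) between adjacent shell centers.  A curve that
    never crosses yields ``resolution=None`` with the Nyquist bound recorded.
    """
    thresholds = criterion_threshold(criterion, curve)
    freqs = curve.frequencies
    corr = curve.correlations
    start = 1 if freqs[0] == 0.0 else 0  # skip the DC shell

    excess = corr - thresholds
    for i in range(start, len(curve)):
        if excess[i] < 0:
            if i == start:
                crossing = freqs[i]
            else:
                left, right = excess[i - 1], excess[i]
                t = left / (left - right)
                crossing = freqs[i - 1] + t * (freqs[i] - freqs[i - 1])
            resolution = float("inf") if crossing == 0 else 1.0 / crossing
            return ResolutionEstimate(criterion, resolution, float(crossing))
    return ResolutionEstimate(
        criterion, None, None, resolution_bound=1.0 / curve.nyquist
    )


def write_fsc_xml(curve: FSCCurve, path, title: str = "FSC curve") -> None:
    """Write the curve in the standardized deposition XML dialect.

    One ``<coordinate>`` element per shell, each with ``<x>`` (spatial
    frequency, 1/Å) and ``<y>`` (correlation) children at 6 significant
    digits, in ascending x.
    """
    root = etree.Element(
        "fsc",
        title=title,
        xaxis="Resolution (A-1)",
        yaxis="Correlation Coefficient",
    )
    for f, c in zip(curve.frequencies, curve.correlations):
        coord = etree.SubElement(root, "coordinate")
        etree.SubElement(coord, "x").text = f"{f:.6g}"
        etree.SubElement(coord, "y").text = f"{c:.6g}"
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_fsc_xml(path) -> FSCCurve:
    """Read a curve written by :func:`write_fsc_xml` (shell counts are lost)."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "fsc":
        raise ValueError(f"root element is {root.tag!r}, expected 'fsc'")
    freqs, corrs = [], []
    for coord in root.iter("coordinate"):
        x = coord.find("x")
        y = coord.find("y")
        if x is None or y is None or x.text is None or y.text is None:
            raise ValueError("coordinate element missing x or y child")
        freqs.append(float(x.text))
        corrs.append(float(y.text))
    if not freqs:
        raise ValueError("no coordinates in fsc element")
    freqs = np.asarray(freqs)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("non-monotone frequencies in fsc document")
    return FSCCurve(
        frequencies=freqs,
        correlations=np.asarray(corrs),
        shell_counts=None,
        nyquist=float(freqs[-1]),
    )
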