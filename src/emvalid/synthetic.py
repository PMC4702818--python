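"""Synthetic fixtures: Gaussian-atom maps, half-map pairs, trace models.

Everything here is seeded and deterministic: the same spec and seed produce
bit-identical arrays (and therefore bit-identical files through the mode-2
writer).  Half-map pairs draw their two noise fields from independent
streams spawned from a single seed, mirroring the practice of splitting the
particle data in two and reconstructing each half independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_checks import Atom, AtomModel, Chain, Residue
from .volume import DensityMap

__all__ = [
    "FixtureSpec",
    "gaussian_atom_map",
    "half_map_pair",
    "designed_fsc",
    "helix_trace",
    "p_trace",
    "noise_map",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic map fixture.

    ``sigma`` is the Gaussian atom width in Å; the defaults (32³ grid,
    1.0 Å voxels, σ = 1.5 Å) give atoms resolved over several voxels, the
    regime where voxel-center sampling of the Gaussian is accurate.
    """

    seed: int = 0
    shape: tuple = (32, 32, 32)
    voxel_size: float = 1.0
    sigma: float = 1.5
    noise_sigma: float = 0.1
    origin: tuple = (0.0, 0.0, 0.0)


def gaussian_atom_map(model: AtomModel, spec: FixtureSpec) -> DensityMap:
    """Render a model as a sum of isotropic Gaussians sampled at voxel centers.

    Every atom must lie inside the grid bounding box; fixtures are required
    to be fully contained so that downstream checks see the whole model.
    """
    shape = np.array(spec.shape)
    voxel = np.broadcast_to(np.asarray(spec.voxel_size, dtype=float), (3,))
    origin = np.asarray(spec.origin, dtype=float)
    axes = [origin[i] + voxel[i] * np.arange(shape[i]) for i in range(3)]
    box_max = origin + voxel * (shape - 1)

    data = np.zeros(tuple(shape))
    two_sigma_sq = 2.0 * spec.sigma**2
    for chain, residue, atom in model.all_atoms():
        p = atom.position
        if np.any(p < origin) or np.any(p > box_max):
            raise ValueError(
                f"atom {chain.chain_id}/{residue.number}/{atom.name} at {tuple(p)} "
                "lies outside the grid bounding box"
            )
        gx = np.exp(-((axes[0] - p[0]) ** 2) / two_sigma_sq)
        gy = np.exp(-((axes[1] - p[1]) ** 2) / two_sigma_sq)
        gz = np.exp(-((axes[2] - p[2]) ** 2) / two_sigma_sq)
        data += gx[:, None, None] * gy[None, :, None] * gz[None, None, :]

    return DensityMap(data=data, voxel_size=voxel, origin=origin)


def noise_map(spec: FixtureSpec, stream: int = 0) -> DensityMap:
    """Seeded white Gaussian noise volume (mean 0, sd ``spec.noise_sigma``)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(stream + 1)[stream])
    data = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return DensityMap(data=data, voxel_size=spec.voxel_size, origin=spec.origin)


def half_map_pair(signal: DensityMap, noise_sigma: float, seed: int):
    """Two half-maps: the same signal plus independent white Gaussian noise.

    The designed per-shell signal-to-noise ratio is
    SNR(s) = P_signal(s) / (N_voxels · noise_sigma²) with P_signal the
    signal's rotationally averaged power spectrum (unnormalized FFT), so the
    expected FSC is SNR/(SNR+1) per shell (see :func:`designed_fsc`).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(2)
    halves = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        noise = rng.normal(0.0, noise_sigma, size=signal.shape)
        halves.append(
            DensityMap(
                data=signal.data + noise,
                voxel_size=signal.voxel_size,
                origin=signal.origin,
            )
        )
    return halves[0], halves[1]


def designed_fsc(signal: DensityMap, noise_sigma: float):
    """Expected FSC per shell for :func:`half_map_pair` outputs.

    Returns (frequencies, expected_fsc).  White noise of variance σ² has
    expected Fourier power N·σ² per voxel (unnormalized FFT of N voxels), so
    SNR(s) = P_signal(s)/(N·σ²) and E[FSC(s)] ≈ SNR/(SNR+1).
    """
    from .mapstats import rotational_power_spectrum

    spectrum = rotational_power_spectrum(signal)
    n_vox = float(np.prod(signal.shape))
    if noise_sigma == 0:
        return spectrum.frequencies, np.ones_like(spectrum.power)
    snr = spectrum.power / (n_vox * noise_sigma**2)
    return spectrum.frequencies, snr / (snr + 1.0)


def _single_atom_chain(chain_id, positions, residue_name, atom_name, element, polymer):
    residues = [
        Residue(
            number=i + 1,
            icode="",
            name=residue_name,
            atoms=[Atom(name=atom_name, element=element, position=pos)],
        )
        for i, pos in enumerate(positions)
    ]
    return AtomModel(chains=[Chain(chain_id=chain_id, polymer_type=polymer, residues=residues)])


def helix_trace(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    center=(0.0, 0.0, 0.0),
) -> AtomModel:
    """Ideal Cα-only helix: CAᵢ on a regular helix (default α-helix geometry).

    All consecutive Cα–Cα distances equal the helix chord
    sqrt((2 r sin(twist/2))² + rise²) by construction, and every interior
    (pseudo-angle, pseudo-torsion) pair is identical.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    center = np.asarray(center, dtype=float)
    omega = np.radians(twist)
    positions = [
        center
        + np.array(
            [radius * np.cos(i * omega), radius * np.sin(i * omega), i * rise]
        )
        for i in range(n_res)
    ]
    return _single_atom_chain("A", positions, "ALA", "CA", "C", "protein")


def helix_chord_length(rise: float = 1.5, twist: float = 100.0, radius: float = 2.3) -> float:
    """Closed-form consecutive Cα–Cα distance of :func:`helix_trace`."""
    return float(np.hypot(2.0 * radius * np.sin(np.radians(twist) / 2.0), rise))


def p_trace(n_res: int = None, spacing=5.9, start=(0.0, 0.0, 0.0)) -> AtomModel:
    """Collinear P-only nucleic trace with uniform or per-bond spacing.

    ``spacing`` may be a scalar (uniform, requires ``n_res``) or a sequence
    of per-bond distances (then ``n_res`` defaults to len+1), which makes
    fixtures for the short/long threshold tests one-liners.
    """
    if np.isscalar(spacing):
        if n_res is None or n_res < 2:
            raise ValueError("n_res must be >= 2 for uniform spacing")
        gaps = [float(spacing)] * (n_res - 1)
    else:
        gaps = [float(g) for g in spacing]
        if n_res is None:
            n_res = len(gaps) + 1
        elif n_res != len(gaps) + 1:
            raise ValueError("len(spacing) must be n_res - 1")
    if any(g <= 0 for g in gaps):
        raise ValueError("spacing must be > 0")
    start = np.asarray(start, dtype=float)
    xs = np.concatenate([[0.0], np.cumsum(gaps)])
    positions = [start + np.array([x, 0.0, 0.0]) for x in xs]
    return _single_atom_chain("B", positions, "U", "P", "P", "nucleic")
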