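"""Visual-analysis statistics for a single synthetic density map.

Prints the header-style summary statistics, the enclosed volume at a few
contour levels (non-increasing by construction), and the decay of the
rotationally averaged power spectrum that a smooth Gaussian-atom map shows.
"""

import numpy as np

import emvalid as ev

density_map = ev.gaussian_atom_map(
    ev.helix_trace(12, center=(16.0, 16.0, 8.0)),
    ev.FixtureSpec(shape=(32, 32, 32), sigma=1.5),
)

dmin, dmax, dmean, rms = ev.recompute_stats(density_map)
print(f"map {density_map.shape}, voxel {density_map.voxel_size[0]:.1f} Å")
print(f"density min {dmin:.3f}  max {dmax:.3f}  mean {dmean:.3f}  rms {rms:.3f}")

levels = np.linspace(dmin, dmax, 6)
curve = ev.volume_vs_contour(density_map, levels)
print("\ncontour level -> enclosed volume (Å³):")
for level, volume in zip(curve.levels, curve.volumes):
    print(f"  {level:7.3f} -> {volume:9.1f}")

spectrum = ev.rotational_power_spectrum(density_map)
print("\npower spectrum (every 3rd shell):")
for f, p in list(zip(spectrum.frequencies, spectrum.power))[::3]:
    print(f"  {f:.3f} 1/Å -> {p:10.3e}")
print("the smooth decay reflects the Gaussian atom width (σ = 1.5 Å)")
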