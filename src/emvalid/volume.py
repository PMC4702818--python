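"""CCP4/MRC density map I/O.

EMDB distributes maps in a CCP4-compatible dialect of the MRC format: a
1024-byte binary header (56 four-byte words plus ten 80-character labels),
an optional extended header, and the voxel data block.  This module reads
modes 0 (int8), 1 (int16) and 2 (float32), always canonicalizes the axis
order so that in-memory ``data[ix, iy, iz]`` is indexed by Cartesian x/y/z,
and writes mode-2 files.

Two origin dialects occur in the wild: the MRC2014 Å-valued ORIGIN words
(49-51) and the older CCP4 start-index words (NXSTART..NZSTART).  On read,
the Å-valued origin wins when any component is nonzero; otherwise the origin
is start-index x voxel size.  The choice is recorded on the returned map.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensityMap", "MapFormatError", "read_map", "write_map", "recompute_stats"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}
_HEADER_SIZE = 1024
_MAP_MAGIC = b"MAP "


class MapFormatError(ValueError):
    """A CCP4/MRC file could not be parsed; the message names the bad field."""


@dataclass
class DensityMap:
    """A 3D scalar density field on a regular grid.

    Attributes
    ----------
    data:
        float array indexed ``[ix, iy, iz]`` (canonical x/y/z order).
    voxel_size:
        Å per voxel along x, y, z.
    origin:
        Position of voxel (0, 0, 0) in Å.
    axis_order:
        The (MAPC, MAPR, MAPS) permutation of the source file, as 0-based
        xyz indices of (column, row, section); ``(0, 1, 2)`` for maps built
        in memory.
    header_stats:
        (min, max, mean, rms) recorded in the file header, or recomputed
        for in-memory maps.
    origin_source:
        "origin-words", "start-indices" or "memory".
    """

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    axis_order: tuple = (0, 1, 2)
    header_stats: tuple = None  # type: ignore[assignment]
    origin_source: str = "memory"
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density data must be a 3D array with all dims >= 1")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if sorted(self.axis_order) != [0, 1, 2]:
            raise ValueError("axis_order must be a permutation of (0, 1, 2)")
        if self.header_stats is None:
            self.header_stats = recompute_stats(self)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        return float(np.prod(self.voxel_size))

    @property
    def nyquist(self) -> float:
        """Nyquist spatial frequency 1/(2·voxel) in 1/Å (finest axis)."""
        return float(1.0 / (2.0 * np.min(self.voxel_size)))


def recompute_stats(density_map: DensityMap) -> tuple:
    """Return (min, max, mean, rms) of the density.

    ``rms`` is the root mean square deviation about the mean (population
    standard deviation), the convention used in the map header RMS word.
    """
    data = density_map.data
    return (
        float(data.min()),
        float(data.max()),
        float(data.mean()),
        float(data.std()),
    )


def _axis_permutation(mapc: int, mapr: int, maps: int) -> np.ndarray:
    """pos[xyz axis] = which of (col, row, sec) runs along that axis."""
    perm = np.full(3, -1, dtype=int)
    for file_axis, xyz in enumerate((mapc - 1, mapr - 1, maps - 1)):
        if xyz not in (0, 1, 2) or perm[xyz] != -1:
            raise MapFormatError(
                f"MAPC/MAPR/MAPS = ({mapc}, {mapr}, {maps}) is not a "
                "permutation of (1, 2, 3)"
            )
        perm[xyz] = file_axis
    return perm


def read_map(path) -> DensityMap:
    """Read a CCP4/MRC map (modes 0, 1, 2) into a canonical :class:`DensityMap`.

    The data array is permuted so that axis 0/1/2 of ``data`` are Cartesian
    x/y/z regardless of the file's MAPC/MAPR/MAPS ordering, and converted to
    floating point.  Header min/max/mean/rms that disagree with the actual
    data (beyond rounding) trigger a warning; recomputed statistics win.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MapFormatError(
                f"file shorter than the 1024-byte header ({len(header)} bytes)"
            )
        words_i = np.frombuffer(header, dtype="<i4", count=56)
        words_f = np.frombuffer(header, dtype="<f4", count=56)
        ncols, nrows, nsecs = (int(v) for v in words_i[0:3])
        mode = int(words_i[3])
        if min(ncols, nrows, nsecs) < 1:
            raise MapFormatError(
                f"NX/NY/NZ = ({ncols}, {nrows}, {nsecs}); all dims must be >= 1"
            )
        if mode not in _MODE_DTYPES:
            raise MapFormatError(f"unsupported MODE {mode} (supported: 0, 1, 2)")
        starts = words_i[4:7].astype(int)
        grid_sampling = words_i[7:10].astype(int)
        cell = words_f[10:13].astype(float)
        mapc, mapr, maps = (int(v) for v in words_i[16:19])
        header_min, header_max, header_mean = (float(v) for v in words_f[19:22])
        nsymbt = int(words_i[23])
        origin_words = words_f[49:52].astype(float)
        magic = header[208:212]
        header_rms = float(words_f[54])
        label = header[224:304].decode("ascii", errors="replace").rstrip("\x00 ")

        if np.any(grid_sampling < 1):
            raise MapFormatError(f"MX/MY/MZ = {tuple(grid_sampling)}; must be >= 1")
        if np.any(cell <= 0):
            raise MapFormatError(f"CELLA = {tuple(cell)}; cell lengths must be > 0")
        if magic != _MAP_MAGIC and magic != b"\x00\x00\x00\x00":
            raise MapFormatError(f"bad MAP magic word {magic!r}")

        perm = _axis_permutation(mapc, mapr, maps)

        if nsymbt < 0:
            raise MapFormatError(f"negative extended header size NSYMBT = {nsymbt}")
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = ncols * nrows * nsecs
        raw = np.frombuffer(fh.read(count * dtype().itemsize), dtype=f"<{np.dtype(dtype).str[1:]}")
        if raw.size < count:
            raise MapFormatError(
                f"truncated data block: expected {count} voxels, got {raw.size}"
            )

    # file layout: columns fastest -> [sec, row, col]; swap to [col, row, sec]
    arr_crs = raw.reshape(nsecs, nrows, ncols).transpose(2, 1, 0)
    data = arr_crs.transpose(tuple(perm))

    voxel_size = cell / grid_sampling  # cell is already along x/y/z

    if np.any(origin_words != 0.0):
        origin = origin_words.copy()
        origin_source = "origin-words"
    else:
        starts_xyz = np.empty(3, dtype=float)
        starts_xyz[[mapc - 1, mapr - 1, maps - 1]] = starts
        origin = starts_xyz * voxel_size
        origin_source = "start-indices"

    density_map = DensityMap(
        data=data,
        voxel_size=voxel_size,
        origin=origin,
        axis_order=(mapc - 1, mapr - 1, maps - 1),
        header_stats=(header_min, header_max, header_mean, header_rms),
        origin_source=origin_source,
        label=label,
    )

    actual = recompute_stats(density_map)
    recorded = (header_min, header_max, header_mean, header_rms)
    scale = max(abs(actual[0]), abs(actual[1]), 1e-30)
    if any(abs(a - r) > 1e-5 * scale + 1e-6 for a, r in zip(actual, recorded)):
        warnings.warn(
            f"header statistics {recorded} disagree with data statistics "
            f"{actual}; using recomputed values",
            stacklevel=2,
        )
    density_map.header_stats = actual
    return density_map


def write_map(density_map: DensityMap, path, axis_order=(0, 1, 2), sanitize=False) -> None:
    """Write a mode-2 (32-bit float) CCP4/MRC file.

    Header statistics are recomputed from the data.  ``axis_order`` selects
    the on-disk (column, row, section) -> xyz mapping; the default writes x
    fastest.  Non-finite densities raise unless ``sanitize`` replaces them
    with zero.
    """
    data = np.asarray(density_map.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        if not sanitize:
            raise ValueError(
                "density contains non-finite values; pass sanitize=True to zero them"
            )
        data = np.where(np.isfinite(data), data, np.float32(0.0))

    if sorted(axis_order) != [0, 1, 2]:
        raise ValueError("axis_order must be a permutation of (0, 1, 2)")
    mapc, mapr, maps = (a + 1 for a in axis_order)

    nx, ny, nz = data.shape
    dims_xyz = np.array([nx, ny, nz])
    voxel = np.asarray(density_map.voxel_size, dtype=float)
    cell = dims_xyz * voxel

    stats_map = DensityMap(data=data.astype(np.float64), voxel_size=voxel)
    dmin, dmax, dmean, rms = recompute_stats(stats_map)

    header = bytearray(_HEADER_SIZE)
    ncols, nrows, nsecs = (int(dims_xyz[a]) for a in axis_order)
    struct.pack_into("<3i", header, 0, ncols, nrows, nsecs)
    struct.pack_into("<i", header, 12, 2)  # MODE 2
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # NXSTART..NZSTART
    struct.pack_into("<3i", header, 28, *(int(v) for v in dims_xyz))
    struct.pack_into("<3f", header, 40, *(float(v) for v in cell))
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1)  # ISPG: P1 volume
    struct.pack_into("<i", header, 92, 0)  # NSYMBT
    struct.pack_into("<3f", header, 196, *(float(v) for v in density_map.origin))
    header[208:212] = _MAP_MAGIC
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 1)  # NLABL
    label = (density_map.label or "emvalid map")[:80]
    header[224 : 224 + len(label)] = label.encode("ascii", errors="replace")

    # [col, row, sec] view of the xyz data, written sections-slowest
    arr_crs = data.transpose(axis_order)
    file_array = np.ascontiguousarray(arr_crs.transpose(2, 1, 0))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(file_array.astype("<f4").tobytes())
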