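"""Coordinate-model parsing and trace-geometry validation.

A sizeable fraction of EM-derived models are deposited as atom traces — one
Cα per protein residue or one P per nucleotide — for which conventional
covalent-geometry validation does not apply.  This module implements the
trace assessments: consecutive Cα–Cα distance outliers against reference
cis/trans peptide distributions, consecutive P–P distance bounds,
pseudo-Ramachandran (Cα pseudo-angle vs pseudo-torsion) outliers, plus the
model-vs-model close-contact check and model-in-map atom inclusion at a
contour level.

Consecutiveness follows residue numbering, not spatial proximity: a gap in
sequence numbers marks unmodeled residues, and the flanking pair is skipped
rather than flagged as an absurdly long bond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

import gemmi

from .reference import ReferenceDistributions
from .volume import DensityMap

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "AtomModel",
    "TraceAnnotation",
    "GeometryFindings",
    "InclusionResult",
    "DEFAULT_VDW_RADII",
    "DEFAULT_OVERLAP_TOLERANCE",
    "parse_model",
    "classify_trace",
    "caca_distance_outliers",
    "pp_distance_outliers",
    "pseudo_ramachandran",
    "close_contacts",
    "atom_inclusion",
    "run_all_checks",
]

logger = logging.getLogger(__name__)

PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE SEC PYL".split()
)
NUCLEIC_RESIDUES = frozenset("A C G U I DA DC DG DT DU DI".split())

# Bondi-style radii (Å); CA/P trace pseudo-atoms use their element's radius.
DEFAULT_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "FE": 1.80,
    "ZN": 1.39, "MG": 1.73, "CA": 1.94, "MN": 1.80, "NA": 2.27, "K": 2.75,
}
DEFAULT_OVERLAP_TOLERANCE = 0.4


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    polymer_type: str  # protein | nucleic | other
    residues: list


@dataclass
class AtomModel:
    chains: list

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def all_atoms(self):
        """Yield (chain, residue, atom) triples in model order."""
        for chain in self.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    yield chain, residue, atom


@dataclass
class TraceAnnotation:
    """Per-chain trace classification: calpha-only, p-only, or none."""

    per_chain: dict

    def is_trace(self, chain_id: str) -> bool:
        return self.per_chain.get(chain_id, "none") != "none"


@dataclass
class CacaOutlier:
    chain_id: str
    residue_a: tuple  # (number, icode)
    residue_b: tuple
    distance: float
    nearest_class: str  # cis | trans
    deviation_sigma: float


@dataclass
class PPOutlier:
    chain_id: str
    residue_a: tuple
    residue_b: tuple
    distance: float
    reason: str  # short | long


@dataclass
class RamaOutlier:
    chain_id: str
    residue: tuple
    pseudo_angle: float
    pseudo_torsion: float
    frequency: float


@dataclass
class Clash:
    atom_a: tuple  # (chain_id, residue number, icode, atom name)
    atom_b: tuple
    distance: float
    overlap: float


@dataclass
class FindingSet:
    """Outliers from one check plus how many items were evaluated."""

    outliers: list
    n_evaluated: int

    @property
    def outlier_fraction(self) -> Optional[float]:
        if self.n_evaluated == 0:
            return None
        return len(self.outliers) / self.n_evaluated


@dataclass
class GeometryFindings:
    """All model-assessment findings, with per-category summary counts."""

    caca: Optional[FindingSet] = None
    pp: Optional[FindingSet] = None
    rama: Optional[FindingSet] = None
    clashes: Optional[FindingSet] = None

    def summary(self) -> dict:
        out = {}
        for name in ("caca", "pp", "rama", "clashes"):
            fs = getattr(self, name)
            if fs is not None:
                out[name] = {
                    "n_outliers": len(fs.outliers),
                    "n_evaluated": fs.n_evaluated,
                }
        return out


# ---------------------------------------------------------------------------
# parsing


def _polymer_type(residues) -> str:
    n_protein = sum(1 for r in residues if r.name in PROTEIN_RESIDUES)
    n_nucleic = sum(1 for r in residues if r.name in NUCLEIC_RESIDUES)
    if n_protein > n_nucleic and n_protein > 0:
        return "protein"
    if n_nucleic > n_protein and n_nucleic > 0:
        return "nucleic"
    return "other"


def parse_model(path, format: Optional[str] = None) -> AtomModel:
    """Parse a PDB or mmCIF coordinate file into an :class:`AtomModel`.

    Format is auto-detected unless given as ``"pdb"`` or ``"mmcif"``.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file order).  Only the first model of multi-model files
    is read.
    """
    fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (use 'pdb' or 'mmcif')")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"no models in coordinate file {path}")

    chains = []
    for g_chain in structure[0]:
        residues = []
        for g_res in g_chain:
            # resolve altlocs: per atom name keep highest occupancy, ties first
            chosen: dict = {}
            for g_atom in g_res:
                prev = chosen.get(g_atom.name)
                if prev is None or g_atom.occ > prev.occ:
                    chosen[g_atom.name] = g_atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                )
                for a in chosen.values()
            ]
            residues.append(
                Residue(
                    number=g_res.seqid.num,
                    icode=(g_res.seqid.icode or "").strip(),
                    name=g_res.name,
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: (r.number, r.icode))
        chains.append(
            Chain(
                chain_id=g_chain.name,
                polymer_type=_polymer_type(residues),
                residues=residues,
            )
        )
    return AtomModel(chains=chains)


def classify_trace(model: AtomModel) -> TraceAnnotation:
    """Classify each chain as calpha-only, p-only or none (full/mixed atom).

    A chain is calpha-only iff it is protein and every residue has exactly
    one atom, named CA; p-only iff nucleic with exactly one P atom per
    residue.  Chains mixing trace and full-atom residues classify as none.
    """
    per_chain = {}
    for chain in model.chains:
        kind = "none"
        if chain.residues:
            if chain.polymer_type == "protein" and all(
                len(r.atoms) == 1 and r.atoms[0].name == "CA" for r in chain.residues
            ):
                kind = "calpha-only"
            elif chain.polymer_type == "nucleic" and all(
                len(r.atoms) == 1 and r.atoms[0].name == "P" for r in chain.residues
            ):
                kind = "p-only"
        per_chain[chain.chain_id] = kind
    return TraceAnnotation(per_chain=per_chain)


# ---------------------------------------------------------------------------
# trace-distance checks


def _consecutive(res_a: Residue, res_b: Residue) -> bool:
    """Numbering-successor rule: n+1, or same number with a new icode."""
    if res_b.number == res_a.number + 1:
        return True
    return res_b.number == res_a.number and res_b.icode != res_a.icode


def _trace_pairs(chain: Chain, atom_name: str):
    """Consecutive-residue atom pairs (by numbering) carrying ``atom_name``."""
    usable = [r for r in chain.residues if r.atom(atom_name) is not None]
    for res_a, res_b in zip(usable, usable[1:]):
        if _consecutive(res_a, res_b):
            yield res_a, res_b


def caca_distance_outliers(
    model: AtomModel, ref: ReferenceDistributions
) -> FindingSet:
    """Flag consecutive Cα–Cα distances outside both the cis and trans windows.

    A distance is acceptable if it lies within mean ± kσ of *either* the cis
    or the trans peptide reference distribution (k = ``ref.sigma_multiplier``,
    default 3); only distances outside both windows are outliers.  The
    nearest class (smaller |z|) and its z-score are recorded.
    """
    k = ref.sigma_multiplier
    outliers = []
    n_bonds = 0
    for chain in model.chains:
        if chain.polymer_type != "protein":
            continue
        for res_a, res_b in _trace_pairs(chain, "CA"):
            d = float(
                np.linalg.norm(res_a.atom("CA").position - res_b.atom("CA").position)
            )
            n_bonds += 1
            z_cis = (d - ref.caca_cis[0]) / ref.caca_cis[1]
            z_trans = (d - ref.caca_trans[0]) / ref.caca_trans[1]
            if abs(z_cis) > k and abs(z_trans) > k:
                nearest = "cis" if abs(z_cis) < abs(z_trans) else "trans"
                outliers.append(
                    CacaOutlier(
                        chain_id=chain.chain_id,
                        residue_a=(res_a.number, res_a.icode),
                        residue_b=(res_b.number, res_b.icode),
                        distance=d,
                        nearest_class=nearest,
                        deviation_sigma=min(abs(z_cis), abs(z_trans)),
                    )
                )
    return FindingSet(outliers=outliers, n_evaluated=n_bonds)


def pp_distance_outliers(
    model: AtomModel, ref: Optional[ReferenceDistributions] = None
) -> FindingSet:
    """Flag consecutive P–P distances strictly outside [pp_short, pp_long].

    Defaults: shorter than 4.4 Å or longer than 8.0 Å; the boundary values
    themselves are acceptable.
    """
    ref = ref or ReferenceDistributions()
    outliers = []
    n_bonds = 0
    for chain in model.chains:
        if chain.polymer_type != "nucleic":
            continue
        for res_a, res_b in _trace_pairs(chain, "P"):
            d = float(
                np.linalg.norm(res_a.atom("P").position - res_b.atom("P").position)
            )
            n_bonds += 1
            reason = None
            if d < ref.pp_short:
                reason = "short"
            elif d > ref.pp_long:
                reason = "long"
            if reason:
                outliers.append(
                    PPOutlier(
                        chain_id=chain.chain_id,
                        residue_a=(res_a.number, res_a.icode),
                        residue_b=(res_b.number, res_b.icode),
                        distance=d,
                        reason=reason,
                    )
                )
    return FindingSet(outliers=outliers, n_evaluated=n_bonds)


# ---------------------------------------------------------------------------
# pseudo-Ramachandran


def pseudo_bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def pseudo_torsion_angle(a, b, c, d) -> float:
    """Dihedral a-b-c-d in degrees, in (−180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    angle = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if angle <= -180.0 else angle


def pseudo_ramachandran(
    model: AtomModel, ref: ReferenceDistributions
) -> FindingSet:
    """Score Cα pseudo-angle/pseudo-torsion pairs against the reference grid.

    For each residue i with numbering-consecutive neighbors i−1, i+1, i+2
    all carrying CA atoms: θᵢ = angle(CAᵢ₋₁, CAᵢ, CAᵢ₊₁) and
    ηᵢ = dihedral(CAᵢ₋₁, CAᵢ, CAᵢ₊₁, CAᵢ₊₂); the (θ, η) pair is assigned to
    residue i.  Residue i is an outlier iff the reference grid frequency of
    its bin is below ``ref.rama_outlier_cutoff``.
    """
    if ref.pseudo_rama_grid is None or ref.rama_outlier_cutoff is None:
        raise ValueError("reference required: pseudo-Ramachandran grid not provided")
    grid = ref.pseudo_rama_grid
    outliers = []
    n_scored = 0
    for chain in model.chains:
        if chain.polymer_type != "protein":
            continue
        usable = [r for r in chain.residues if r.atom("CA") is not None]
        for w in range(len(usable) - 3):
            window = usable[w : w + 4]
            if not all(_consecutive(x, y) for x, y in zip(window, window[1:])):
                continue
            pos = [r.atom("CA").position for r in window]
            theta = pseudo_bond_angle(pos[0], pos[1], pos[2])
            eta = pseudo_torsion_angle(pos[0], pos[1], pos[2], pos[3])
            freq = grid.lookup(theta, eta)
            n_scored += 1
            if freq < ref.rama_outlier_cutoff:
                res = window[1]
                outliers.append(
                    RamaOutlier(
                        chain_id=chain.chain_id,
                        residue=(res.number, res.icode),
                        pseudo_angle=theta,
                        pseudo_torsion=eta,
                        frequency=freq,
                    )
                )
    return FindingSet(outliers=outliers, n_evaluated=n_scored)


# ---------------------------------------------------------------------------
# close contacts


_BONDED_NAME_PAIRS = ({"C", "N"}, {"O3'", "P"})


def _excluded_pair(info_a, info_b) -> bool:
    """Pairs never scored: same residue, or backbone-bonded/trace-consecutive
    atoms of numbering-consecutive residues in one chain."""
    chain_a, res_a, atom_a = info_a
    chain_b, res_b, atom_b = info_b
    if chain_a.chain_id == chain_b.chain_id and res_a is res_b:
        return True
    if chain_a.chain_id != chain_b.chain_id:
        return False
    first, second = (
        ((res_a, atom_a), (res_b, atom_b))
        if (res_a.number, res_a.icode) <= (res_b.number, res_b.icode)
        else ((res_b, atom_b), (res_a, atom_a))
    )
    if not _consecutive(first[0], second[0]):
        return False
    names = {first[1].name, second[1].name}
    if names in _BONDED_NAME_PAIRS:
        return True
    # trace backbones: consecutive CA-CA / P-P are bonds, not contacts
    return names in ({"CA"}, {"P"})


def close_contacts(
    model: AtomModel,
    vdw_table: Optional[dict] = None,
    overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
) -> FindingSet:
    """Find non-bonded atom pairs closer than r₁ + r₂ − tolerance.

    Candidate pairs come from a k-d tree cut at the largest possible clash
    distance, then are filtered by per-pair radii and the bonded-pair
    exclusions.  Atoms whose element is missing from the radius table are
    skipped with a logged warning.  ``n_evaluated`` is the number of atoms
    scored.
    """
    vdw_table = vdw_table if vdw_table is not None else DEFAULT_VDW_RADII
    infos, radii = [], []
    for chain, residue, atom in model.all_atoms():
        radius = vdw_table.get(atom.element)
        if radius is None:
            logger.warning(
                "element %r of atom %s/%s%s/%s missing from vdW table; skipped",
                atom.element, chain.chain_id, residue.number, residue.icode, atom.name,
            )
            continue
        infos.append((chain, residue, atom))
        radii.append(radius)
    if len(infos) < 2:
        return FindingSet(outliers=[], n_evaluated=len(infos))

    positions = np.array([info[2].position for info in infos])
    radii = np.asarray(radii)
    cutoff = 2.0 * radii.max() - overlap_tolerance
    tree = cKDTree(positions)
    clashes = []
    for i, j in sorted(tree.query_pairs(r=cutoff)):
        d = float(np.linalg.norm(positions[i] - positions[j]))
        limit = radii[i] + radii[j] - overlap_tolerance
        if d >= limit or _excluded_pair(infos[i], infos[j]):
            continue
        chain_i, res_i, atom_i = infos[i]
        chain_j, res_j, atom_j = infos[j]
        clashes.append(
            Clash(
                atom_a=(chain_i.chain_id, res_i.number, res_i.icode, atom_i.name),
                atom_b=(chain_j.chain_id, res_j.number, res_j.icode, atom_j.name),
                distance=d,
                overlap=float(radii[i] + radii[j] - d),
            )
        )
    return FindingSet(outliers=clashes, n_evaluated=len(infos))


# ---------------------------------------------------------------------------
# atom inclusion


@dataclass
class InclusionResult:
    fraction: float
    per_atom: list  # (atom key, density or None, included, inside_grid)
    n_atoms: int
    n_included: int
    n_outside: int


def atom_inclusion(
    model: AtomModel,
    density_map: DensityMap,
    contour: float,
    method: str = "trilinear",
) -> InclusionResult:
    """Fraction of model atoms lying in density at or above the contour.

    The density at each atom position is interpolated from the map
    (trilinear by default; ``method="nearest"`` uses the nearest voxel); an
    atom is included iff that density is >= the contour level.  Atoms outside
    the grid count as excluded and are reported with density ``None``.  The
    map origin is honored, so model and map must share a coordinate frame.
    """
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation method {method!r}")

    data = density_map.data
    shape = np.array(data.shape)
    per_atom = []
    n_included = 0
    n_outside = 0
    n_total = 0
    for chain, residue, atom in model.all_atoms():
        n_total += 1
        key = (chain.chain_id, residue.number, residue.icode, atom.name)
        frac = (atom.position - density_map.origin) / density_map.voxel_size
        if np.any(frac < 0) or np.any(frac > shape - 1):
            n_outside += 1
            per_atom.append((key, None, False, False))
            continue
        if method == "nearest":
            idx = np.rint(frac).astype(int)
            value = float(data[tuple(np.minimum(idx, shape - 1))])
        else:
            i0 = np.floor(frac).astype(int)
            i0 = np.minimum(i0, shape - 2)
            t = frac - i0
            corner = data[i0[0] : i0[0] + 2, i0[1] : i0[1] + 2, i0[2] : i0[2] + 2]
            wx = np.array([1 - t[0], t[0]])
            wy = np.array([1 - t[1], t[1]])
            wz = np.array([1 - t[2], t[2]])
            value = float(np.einsum("ijk,i,j,k->", corner, wx, wy, wz))
        included = value >= contour
        n_included += included
        per_atom.append((key, value, bool(included), True))

    return InclusionResult(
        fraction=n_included / n_total,
        per_atom=per_atom,
        n_atoms=n_total,
        n_included=n_included,
        n_outside=n_outside,
    )


def run_all_checks(
    model: AtomModel,
    ref: Optional[ReferenceDistributions] = None,
    vdw_table: Optional[dict] = None,
    overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
) -> GeometryFindings:
    """Run every applicable geometry check and collect the findings."""
    from .reference import default_reference

    ref = ref or default_reference()
    findings = GeometryFindings(
        caca=caca_distance_outliers(model, ref),
        pp=pp_distance_outliers(model, ref),
        clashes=close_contacts(model, vdw_table, overlap_tolerance),
    )
    if ref.pseudo_rama_grid is not None:
        findings.rama = pseudo_ramachandran(model, ref)
    return findings
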