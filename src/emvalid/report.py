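"""Validation report assembly: map info table, key indicators, sliders.

The report mirrors the structure of archive validation reports: a table of
basic experiment information, per-check geometry findings, FSC resolution
estimates when half-maps are supplied, and percentile "sliders" placing each
key indicator against reference populations (all EM structures, and all
archive structures).  The document is a versioned JSON object; plots are
PNG files rendered alongside it.

Reference populations for the sliders are user-supplied sample files
(indicator name -> value list per population); archive-scale populations are
deliberately out of scope and tests use synthetic ones.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .fsc import CRITERIA, compute_fsc, estimate_resolution
from .mapstats import density_histogram, rotational_power_spectrum, volume_vs_contour
from .model_checks import AtomModel, GeometryFindings, atom_inclusion, classify_trace, run_all_checks
from .reference import ReferenceDistributions, default_reference
from .volume import DensityMap, recompute_stats

__all__ = [
    "SCHEMA_VERSION",
    "KeyIndicator",
    "ValidationReport",
    "percentile_rank",
    "map_info_table",
    "assemble_report",
    "validate_report_json",
]

SCHEMA_VERSION = "1.0"

# recognized metadata keys -> (report label, unit or None)
_MAP_INFO_KEYS = (
    ("reconstruction_method", "reconstruction method", None),
    ("reported_resolution", "reported resolution", "Å"),
    ("resolution_method", "resolution method", None),
    ("imposed_symmetry", "imposed symmetry", None),
    ("number_of_images", "number of images used", None),
    ("microscope", "microscope", None),
    ("imaging_parameters", "imaging parameters", None),
    ("detector", "detector", None),
)


class KeyIndicator(BaseModel):
    """One quality indicator with its percentile sliders."""

    name: str
    value: float
    direction: str = Field(pattern="^(lower-better|higher-better)$")
    percentile_vs_em: Optional[float] = Field(default=None, ge=0, le=100)
    percentile_vs_all: Optional[float] = Field(default=None, ge=0, le=100)


class ResolutionEntry(BaseModel):
    criterion: str
    resolution_angstrom: Optional[float]
    crossing_frequency: Optional[float]
    reached: bool


class SectionStatus(BaseModel):
    name: str
    status: str = Field(pattern="^(ok|failed|absent)$")
    error: Optional[str] = None


class ValidationReport(BaseModel):
    """The versioned validation-report document."""

    schema_version: str = SCHEMA_VERSION
    provenance: Dict[str, object]
    map_info: Dict[str, object]
    map_statistics: Optional[Dict[str, object]] = None
    fsc: Optional[List[ResolutionEntry]] = None
    model_findings: Optional[Dict[str, object]] = None
    atom_inclusion: Optional[Dict[str, object]] = None
    indicators: List[KeyIndicator] = []
    sections: List[SectionStatus] = []

    def to_json(self, drop_timestamp: bool = False) -> str:
        doc = self.model_dump(mode="json")
        if drop_timestamp:
            doc["provenance"] = {
                k: v for k, v in doc["provenance"].items() if k != "timestamp"
            }
        return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False)


def validate_report_json(text: str) -> ValidationReport:
    """Parse and validate a report document against the published schema."""
    report = ValidationReport.model_validate_json(text)
    if report.schema_version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {report.schema_version!r}"
        )
    return report


def percentile_rank(value: float, reference_sample, direction: str) -> float:
    """Mid-rank percentile of ``value`` against a reference population.

    percentile = 100 · (worse + 0.5 · equal) / n, where ``worse`` counts
    reference values inferior to ``value`` under ``direction`` and ties count
    half.  100 means better than the whole population.
    """
    sample = np.asarray(reference_sample, dtype=float)
    if sample.size == 0:
        raise ValueError("reference sample is empty")
    if direction == "lower-better":
        worse = int(np.sum(sample > value))
    elif direction == "higher-better":
        worse = int(np.sum(sample < value))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    equal = int(np.sum(sample == value))
    return 100.0 * (worse + 0.5 * equal) / sample.size


def map_info_table(metadata: Optional[dict]) -> dict:
    """Normalize experiment metadata into the report's map-information table.

    Recognized keys get display labels and units; unknown keys are passed
    through under ``other``; missing keys render "not provided".  Sparse or
    empty metadata must never fail.
    """
    metadata = dict(metadata or {})
    table: dict = {}
    for key, label, unit in _MAP_INFO_KEYS:
        if key in metadata:
            value = metadata.pop(key)
            if unit is not None and value not in (None, ""):
                value = f"{value} {unit}"
            table[label] = "not provided" if value in (None, "") else str(value)
        else:
            table[label] = "not provided"
    if metadata:
        table["other"] = {str(k): str(v) for k, v in sorted(metadata.items())}
    return table


def _checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def _slider(value, direction, populations, name):
    em = populations.get(name, {}).get("em") if populations else None
    all_ = populations.get(name, {}).get("all") if populations else None
    return KeyIndicator(
        name=name,
        value=value,
        direction=direction,
        percentile_vs_em=percentile_rank(value, em, direction) if em else None,
        percentile_vs_all=percentile_rank(value, all_, direction) if all_ else None,
    )


def assemble_report(
    density_map: Optional[DensityMap] = None,
    model: Optional[AtomModel] = None,
    half_maps: Optional[tuple] = None,
    metadata: Optional[dict] = None,
    reference: Optional[ReferenceDistributions] = None,
    slider_populations: Optional[dict] = None,
    contour: Optional[float] = None,
    input_paths: Optional[dict] = None,
    timestamp: str = "",
) -> ValidationReport:
    """Run all applicable validation computations and assemble the report.

    At least one of ``density_map``/``model`` must be given.  Sections that
    fail are recorded as failed with their error message; the report is
    still produced.  Given fixed inputs the document is deterministic
    (the provenance timestamp is caller-supplied, empty by default).
    """
    if density_map is None and model is None:
        raise ValueError("at least one of density_map / model is required")
    reference = reference or default_reference()

    sections: list = []
    report = ValidationReport(
        provenance={
            "tool": "emvalid",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "reference_set": reference.label,
            "input_checksums": {
                name: _checksum(p) for name, p in sorted((input_paths or {}).items())
            },
            "timestamp": timestamp,
            "thresholds": {
                "pp_short_angstrom": reference.pp_short,
                "pp_long_angstrom": reference.pp_long,
                "caca_sigma_multiplier": reference.sigma_multiplier,
                "rama_outlier_cutoff": reference.rama_outlier_cutoff,
            },
        },
        map_info=map_info_table(metadata),
    )

    def section(name, fn, absent=False):
        if absent:
            sections.append(SectionStatus(name=name, status="absent"))
            return None
        try:
            result = fn()
            sections.append(SectionStatus(name=name, status="ok"))
            return result
        except Exception as exc:  # failures are reported, not raised
            sections.append(SectionStatus(name=name, status="failed", error=str(exc)))
            return None

    # ---- map sections
    def map_section():
        stats = recompute_stats(density_map)
        edges, counts = density_histogram(density_map, n_bins=128)
        spectrum = rotational_power_spectrum(density_map)
        levels = np.linspace(stats[0], stats[1], 64)
        contour_curve = volume_vs_contour(density_map, levels)
        return {
            "grid": list(density_map.shape),
            "voxel_size_angstrom": [float(v) for v in density_map.voxel_size],
            "density_min": stats[0],
            "density_max": stats[1],
            "density_mean": stats[2],
            "density_rms": stats[3],
            "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
            "power_spectrum": {
                "frequencies": spectrum.frequencies.tolist(),
                "power": spectrum.power.tolist(),
            },
            "volume_vs_contour": {
                "levels": contour_curve.levels.tolist(),
                "volumes_angstrom3": contour_curve.volumes.tolist(),
            },
        }

    report.map_statistics = section(
        "map_statistics", map_section, absent=density_map is None
    )

    def fsc_section():
        curve = compute_fsc(half_maps[0], half_maps[1])
        return [
            ResolutionEntry(
                criterion=est.criterion,
                resolution_angstrom=est.resolution,
                crossing_frequency=est.crossing_frequency,
                reached=est.reached,
            )
            for est in (estimate_resolution(curve, c) for c in CRITERIA)
        ]

    report.fsc = section("fsc", fsc_section, absent=half_maps is None)

    # ---- model sections
    findings: Optional[GeometryFindings] = None
    if model is not None:

        def model_section():
            nonlocal findings
            findings = run_all_checks(model, reference)
            trace = classify_trace(model)
            doc = {
                "n_atoms": model.n_atoms,
                "trace_classification": dict(sorted(trace.per_chain.items())),
                "summary": findings.summary(),
                "convention": "pseudo-angle/torsion assigned to the second residue of each 4-CA window",
                "outliers": {
                    "caca": [vars(o) for o in findings.caca.outliers],
                    "pp": [vars(o) for o in findings.pp.outliers],
                    "rama": [vars(o) for o in (findings.rama.outliers if findings.rama else [])],
                    "clashes": [vars(o) for o in findings.clashes.outliers],
                },
            }
            return doc

        report.model_findings = section("model_findings", model_section)
    else:
        section("model_findings", None, absent=True)

    inclusion = None
    if model is not None and density_map is not None and contour is not None:

        def inclusion_section():
            nonlocal inclusion
            inclusion = atom_inclusion(model, density_map, contour)
            return {
                "contour_level": contour,
                "fraction": inclusion.fraction,
                "n_atoms": inclusion.n_atoms,
                "n_included": inclusion.n_included,
                "n_outside_grid": inclusion.n_outside,
            }

        report.atom_inclusion = section("atom_inclusion", inclusion_section)
    else:
        section("atom_inclusion", None, absent=True)

    # ---- indicators and sliders
    indicators = []
    if findings is not None:
        if findings.clashes.n_evaluated > 0:
            indicators.append(
                _slider(
                    1000.0 * len(findings.clashes.outliers) / findings.clashes.n_evaluated,
                    "lower-better",
                    slider_populations,
                    "clashes_per_1000_atoms",
                )
            )
        for name, fs in (
            ("caca_outlier_fraction", findings.caca),
            ("pp_outlier_fraction", findings.pp),
            ("rama_outlier_fraction", findings.rama),
        ):
            if fs is not None and fs.n_evaluated > 0:
                indicators.append(
                    _slider(fs.outlier_fraction, "lower-better", slider_populations, name)
                )
    if inclusion is not None:
        indicators.append(
            _slider(
                inclusion.fraction, "higher-better", slider_populations, "atom_inclusion"
            )
        )
    report.indicators = indicators
    report.sections = sections
    return report
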