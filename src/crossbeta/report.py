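"""Deterministic TSV/JSON report rendering.

Reports are pure functions of the analysis result and resolved
configuration: no timestamps, no absolute paths, fixed float formatting,
sorted JSON keys — identical inputs give byte-identical output.
"""

from __future__ import annotations

import json

from . import __version__
from .classify import load_class_table
from .config import RunConfig

__all__ = ["classification_report", "energy_report", "geometry_report", "render"]


def _f(x: float) -> str:
    return f"{x:.3f}"


def _meta(config: RunConfig, params_source: str = "") -> dict:
    return {
        "tool_version": __version__,
        "lookup_version": load_class_table().version,
        "params_source": params_source,
        "config": config.resolved(),
    }


def classification_report(result, config: RunConfig, params_source: str = "") -> dict:
    rows = []
    for f in result.interfaces:
        zc = result.topology.per_interface[f.label]
        d = zc.basis
        rows.append(
            {
                "interface": f.label,
                "class": zc.class_id,
                "sheet_sense": d.sheet_sense,
                "surface_parity": d.surface_parity,
                "sheet_direction": d.sheet_direction,
                "face_a": f.face_a,
                "face_b": f.face_b,
                "residues_a": ",".join(f"{n}{s}" for n, s in f.contact_residues("a")),
                "residues_b": ",".join(f"{n}{s}" for n, s in f.contact_residues("b")),
                "buried_area_per_strand_A2": _f(f.buried_area_per_strand),
            }
        )
    return {
        "source": result.structure.source_id,
        "overall_class": result.topology.overall.class_id if result.topology else None,
        "fibril_axis_length_A": _f(result.axis_length),
        "interfaces": rows,
        "meta": _meta(config),
    }


def energy_report(result, config: RunConfig) -> dict:
    rows = []
    for e in result.energies:
        ann = result.stability.get(e.interface_label, {})
        rows.append(
            {
                "interface": e.interface_label,
                "e_form_sheets_kcal_per_strand": _f(e.e_form_sheets),
                "e_form_monomers_kcal_per_strand": _f(e.e_form_monomers),
                "n_strands_summed": e.n_strands_summed,
                "atoms_used": e.atoms_used,
                "stability_tag": ann.get("tag", ""),
            }
        )
    src = result.energies[0].params_source if result.energies else ""
    return {
        "source": result.structure.source_id,
        "interfaces": rows,
        "meta": _meta(config, params_source=src),
    }


def geometry_report(result, summary: dict, config: RunConfig) -> dict:
    return {
        "source": result.structure.source_id,
        "ladders": [
            {
                "residue_type": L.residue_type,
                "spacing_A": _f(L.spacing),
                "n_rungs": L.n_rungs_observed,
                "two_strand_repeat": L.two_strand_repeat,
            }
            for L in summary["ladders"]
        ],
        "aromatic_pairs": [
            {
                "residue_a": g.residue_a,
                "residue_b": g.residue_b,
                "centroid_distance_A": _f(g.centroid_distance),
                "interplanar_angle_deg": _f(g.interplanar_angle),
                "context": g.context,
            }
            for g in summary["aromatic_pairs"]
        ],
        "termini": [
            {
                "interface": t.interface_label,
                "pair_type": t.pair_type,
                "min_distance_A": _f(t.minimum),
                "distances_A": [_f(d) for d in t.distances[:10]],
            }
            for t in summary["termini"]
        ],
        "meta": _meta(config),
    }


def _flatten_tsv(report: dict) -> str:
    """Key-ordered TSV: one section per list of row dicts, meta as
    comment lines."""
    lines = []
    meta = report.get("meta", {})
    lines.append(f"# tool_version\t{meta.get('tool_version', '')}")
    lines.append(f"# lookup_version\t{meta.get('lookup_version', '')}")
    if meta.get("params_source"):
        lines.append(f"# params_source\t{meta['params_source']}")
    for k, v in sorted(meta.get("config", {}).items()):
        lines.append(f"# config.{k}\t{v}")
    for key, value in report.items():
        if key == "meta":
            continue
        if isinstance(value, list) and value and isinstance(value[0], dict):
            lines.append(f"## {key}")
            cols = list(value[0].keys())
            lines.append("\t".join(cols))
            for row in value:
                lines.append("\t".join(str(row.get(c, "")) for c in cols))
        elif not isinstance(value, list):
            lines.append(f"# {key}\t{value}")
    return "\n".join(lines) + "\n"


def render(report: dict, fmt: str = "tsv") -> str:
    if fmt == "json":
        return json.dumps(report, indent=2, sort_keys=True) + "\n"
    if fmt == "tsv":
        return _flatten_tsv(report)
    raise ValueError(f"unknown report format {fmt!r}")
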