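"""End-to-end analysis: parse -> expand -> sheets -> interfaces ->
classification, energetics and geometry.

This is the layer the CLI and the examples sit on; each step is also
available individually from the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    CrystalTopology,
    classify_interface,
    compute_descriptors,
    load_class_table,
    overall_topology,
)
from .config import RunConfig
from .energetics import (
    SolvationParamSet,
    annotate_stability,
    atom_class,
    interface_energy,
    load_default_params,
)
from .geometry import (
    inter_sheet_aromatic_pairs,
    ladder_spacing,
    termini_distances,
)
from .lattice import (
    build_double_layer,
    build_sheets,
    detect_fibril_axis,
    enumerate_interfaces,
    expand_lattice,
)
from .structure import STANDARD_AA, CrystalStructure, parse_structure

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    structure: CrystalStructure
    fibril_axis: np.ndarray
    axis_length: float
    axis_repeat: int
    sheets: list
    interfaces: list
    topology: CrystalTopology | None = None
    energies: list = field(default_factory=list)  # EnergyResult per interface
    stability: dict = field(default_factory=dict)  # label -> annotation


def _load(source, config: RunConfig) -> CrystalStructure:
    if isinstance(source, CrystalStructure):
        return source
    return parse_structure(source, keep_alt=config.keep_alt)


def _params(config: RunConfig) -> SolvationParamSet:
    if config.params_path:
        return SolvationParamSet.from_file(config.params_path)
    return load_default_params()


def _attach_solvent(dl, s: CrystalStructure, config: RunConfig):
    """Carry crystallographic solvent (ethanol/water/...) into the energy
    systems: every expanded solvent copy within the attach distance of a
    trimmed sheet rides with that sheet."""
    from .lattice import _transform_atoms  # same transform as strands
    from scipy.spatial import cKDTree

    solvent = [a for a in s.atoms if a.residue_name not in STANDARD_AA]
    if not solvent:
        return
    sheet_coords = [
        np.vstack([st.coords for st in sh.strands]) for sh in dl.sheets
    ]
    trees = [cKDTree(c) for c in sheet_coords]
    centers = [c.mean(axis=0) for c in sheet_coords]
    span = max(
        float(np.linalg.norm(c - centers[0]).max()) for c in sheet_coords
    ) + 20.0
    nmax = [int(np.ceil(span / L)) + 1 for L in s.cell.lengths]
    seen = set()
    for op in s.sym_ops:
        for na in range(-nmax[0], nmax[0] + 1):
            for nb in range(-nmax[1], nmax[1] + 1):
                for nc in range(-nmax[2], nmax[2] + 1):
                    moved = _transform_atoms(solvent, s.cell, op, (na, nb, nc))
                    for a in moved:
                        key = tuple(np.round(a.xyz, 3))
                        if key in seen:
                            continue
                        dists = [
                            t.query(a.xyz, k=1)[0] for t in trees
                        ]
                        si = int(np.argmin(dists))
                        if dists[si] <= config.solvent_attach_distance:
                            seen.add(key)
                            dl.extra_atoms.append((si, a))


def analyze(
    source,
    config: RunConfig | None = None,
    with_energies: bool = False,
) -> AnalysisResult:
    """Run the full pipeline on a file path or CrystalStructure."""
    config = config or RunConfig()
    s = _load(source, config)
    params = _params(config)
    axis, length, repeat = detect_fibril_axis(
        s, override=config.fibril_axis_override
    )
    strands = expand_lattice(s, radius=config.expansion_radius)
    sheets = build_sheets(strands, axis, hbond_cutoff=config.hbond_cutoff)
    interfaces = enumerate_interfaces(
        sheets,
        cutoff=config.contact_cutoff,
        min_contacts=config.min_contacts,
        params=params,
        n_points=config.sasa_points,
    )
    result = AnalysisResult(
        structure=s,
        fibril_axis=axis,
        axis_length=length,
        axis_repeat=repeat,
        sheets=sheets,
        interfaces=interfaces,
    )
    if interfaces:
        per_iface = {}
        areas = {}
        for f in interfaces:
            d = compute_descriptors(f)
            f.descriptors = d
            per_iface[f.label] = classify_interface(d)
            areas[f.label] = f.buried_area_per_strand
        result.topology = overall_topology(per_iface, areas)
    if with_energies:
        for f in interfaces:
            dl = build_double_layer(f)
            if config.include_solvent_in_energy:
                _attach_solvent(dl, s, config)
            e = interface_energy(
                dl,
                label=f.label,
                params=params,
                n_points=config.sasa_points,
                divisor=config.divisor_convention,
            )
            result.energies.append(e)
            result.stability[f.label] = annotate_stability(e)
    return result


def geometry_summary(result: AnalysisResult, config: RunConfig | None = None) -> dict:
    """Aromatic pairs, ladders and termini distances for a report."""
    ladders = []
    seen = set()
    main_sheet = max(result.sheets, key=lambda sh: len(sh.strands))
    present = {
        next(iter(r.values())).residue_name
        for st in main_sheet.strands
        for r in st.residues().values()
    }
    for rtype in sorted(present & {"TYR", "PHE", "TRP", "HIS", "ASN", "GLN"}):
        if rtype in seen:
            continue
        seen.add(rtype)
        try:
            ladders.append(ladder_spacing(main_sheet, rtype))
        except ValueError:
            pass
    aromatic = []
    termini = []
    for f in result.interfaces:
        aromatic.extend(inter_sheet_aromatic_pairs(f)[:3])
        termini.extend(termini_distances(f))
    return {"ladders": ladders, "aromatic_pairs": aromatic, "termini": termini}
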