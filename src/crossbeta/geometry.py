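"""Interface geometry descriptors.

Aromatic pair geometry (ring-centroid distance and interplanar angle),
side-chain ladder spacings along the fibril axis, and end-to-end
distances between like-charged chain termini across zipper interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import SheetAssembly, ZipperInterface

__all__ = [
    "AromaticPairGeometry",
    "LadderReport",
    "TerminiDistanceReport",
    "IncompleteRingError",
    "ring_atoms",
    "aromatic_pair_geometry",
    "interplanar_distance",
    "ladder_spacing",
    "termini_distances",
    "inter_sheet_aromatic_pairs",
]


class IncompleteRingError(Exception):
    pass


#: ring atom names used for centroid/plane fits (six-membered ring for
#: Tyr/Phe/Trp; imidazole for His). OH/CB are excluded so they cannot
#: bias the centroid.
RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class AromaticPairGeometry:
    residue_a: str
    residue_b: str
    centroid_distance: float
    interplanar_angle: float  # degrees, folded to [0, 90]
    context: str = ""


@dataclass
class LadderReport:
    residue_type: str
    spacing: float
    n_rungs_observed: int
    two_strand_repeat: bool = False


@dataclass
class TerminiDistanceReport:
    pair_type: str  # "N-N" | "C-C"
    distances: list  # sorted ascending, A
    interface_label: str = ""

    @property
    def minimum(self) -> float:
        return self.distances[0]


def _residue_atoms(residue) -> dict:
    """Normalize a residue to {atom_name: xyz}."""
    if isinstance(residue, dict):
        return {k: np.asarray(getattr(v, "xyz", v), dtype=float) for k, v in residue.items()}
    return {a.name: np.asarray(a.xyz, dtype=float) for a in residue}


def _residue_name(residue) -> str:
    if isinstance(residue, dict):
        a = next(iter(residue.values()))
    else:
        a = residue[0]
    name = getattr(a, "residue_name", None)
    seq = getattr(a, "residue_seq", "")
    return f"{name}{seq}" if name else "?"


def ring_atoms(residue) -> np.ndarray:
    """Coordinates of the aromatic ring atoms of a Tyr/Phe/Trp/His residue."""
    atoms = _residue_atoms(residue)
    rname = _residue_name(residue)[:3]
    if rname not in RING_ATOMS:
        raise IncompleteRingError(f"{rname} is not an aromatic residue")
    try:
        return np.array([atoms[n] for n in RING_ATOMS[rname]])
    except KeyError as exc:
        raise IncompleteRingError(
            f"{_residue_name(residue)}: ring atom {exc} missing"
        ) from exc


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]  # smallest principal direction


def aromatic_pair_geometry(res_a, res_b, context: str = "") -> AromaticPairGeometry:
    """Centroid distance and acute interplanar angle of two aromatic rings."""
    ra, rb = ring_atoms(res_a), ring_atoms(res_b)
    ca, cb = ra.mean(axis=0), rb.mean(axis=0)
    na, nb = _plane_normal(ra), _plane_normal(rb)
    cosang = abs(float(na @ nb)) / (np.linalg.norm(na) * np.linalg.norm(nb))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return AromaticPairGeometry(
        residue_a=_residue_name(res_a),
        residue_b=_residue_name(res_b),
        centroid_distance=float(np.linalg.norm(cb - ca)),
        interplanar_angle=min(angle, 180.0 - angle),
        context=context,
    )


def interplanar_distance(res_a, res_b) -> float:
    """Separation of two aromatic rings along their plane normals.

    Mean of the centroid-offset projections onto the two ring normals;
    for parallel rings related by translation this equals the centroid
    distance, and it is 0 for an identical ring.
    """
    ra, rb = ring_atoms(res_a), ring_atoms(res_b)
    d = rb.mean(axis=0) - ra.mean(axis=0)
    na, nb = _plane_normal(ra), _plane_normal(rb)
    return 0.5 * (abs(float(d @ na)) + abs(float(d @ nb)))


def _sidechain_centroid(residue) -> np.ndarray:
    atoms = _residue_atoms(residue)
    side = [p for n, p in atoms.items() if n not in ("N", "CA", "C", "O", "OXT")]
    if not side:
        side = list(atoms.values())
    return np.mean(side, axis=0)


def ladder_spacing(sheet: SheetAssembly, residue_type: str) -> LadderReport:
    """Spacing of equivalent side chains along the fibril axis.

    For parallel sheets this is the rise between adjacent strands (a pure
    ladder); antiparallel sheets report the two-strand repeat distance,
    flagged as such.
    """
    step = sheet.repeat_len
    rungs = []
    for strand in sheet.strands[::step]:
        residues = strand.residues()
        for seq in sorted(residues):
            atoms = residues[seq]
            name = next(iter(atoms.values())).residue_name
            if name == residue_type:
                rungs.append((seq, _sidechain_centroid(atoms)))
    if not rungs:
        raise ValueError(f"no {residue_type} residues in the sheet")
    by_seq: dict = {}
    for seq, c in rungs:
        by_seq.setdefault(seq, []).append(c)
    spacings = []
    n_rungs = 0
    axis = sheet.fibril_axis
    for seq, cents in by_seq.items():
        cents.sort(key=lambda c: float(c @ axis))
        n_rungs = max(n_rungs, len(cents))
        for i in range(len(cents) - 1):
            spacings.append(abs(float((cents[i + 1] - cents[i]) @ axis)))
    if not spacings:
        raise ValueError(
            f"only one {residue_type} rung in the stack; spacing undefined"
        )
    return LadderReport(
        residue_type=residue_type,
        spacing=float(np.mean(spacings)),
        n_rungs_observed=n_rungs,
        two_strand_repeat=(step == 2),
    )


def _terminal_atom(strand, which: str):
    residues = strand.residues()
    if which == "N":
        atoms = residues[min(residues)]
        return atoms.get("N")
    atoms = residues[max(residues)]
    return atoms.get("C")


def termini_distances(iface: ZipperInterface) -> list:
    """N-N and C-C distances between chain termini across an interface.

    Distances are measured between the backbone N of residue 1 (or the
    terminal carboxyl C) of every strand of one sheet and of the other,
    sorted ascending. Unresolved termini produce a partial report with a
    warning rather than an error.
    """
    import warnings

    reports = []
    for which, pair_type in (("N", "N-N"), ("C", "C-C")):
        xs = [_terminal_atom(s, which) for s in iface.sheet_a.strands]
        ys = [_terminal_atom(s, which) for s in iface.sheet_b.strands]
        if any(a is None for a in xs) or any(a is None for a in ys):
            warnings.warn(f"unresolved {pair_type} termini; partial report")
        dists = sorted(
            float(np.linalg.norm(a.xyz - b.xyz))
            for a in xs
            if a is not None
            for b in ys
            if b is not None
        )
        reports.append(
            TerminiDistanceReport(
                pair_type=pair_type, distances=dists, interface_label=iface.label
            )
        )
    return reports


def inter_sheet_aromatic_pairs(
    iface: ZipperInterface, max_distance: float = 8.0
) -> list:
    """All aromatic residue pairs across an interface with ring-centroid
    distance below ``max_distance``, nearest first."""
    out = []
    for sa in iface.sheet_a.strands:
        for seq_a, res_a in sa.residues().items():
            name_a = next(iter(res_a.values())).residue_name
            if name_a not in RING_ATOMS:
                continue
            for sb in iface.sheet_b.strands:
                for seq_b, res_b in sb.residues().items():
                    name_b = next(iter(res_b.values())).residue_name
                    if name_b not in RING_ATOMS:
                        continue
                    try:
                        g = aromatic_pair_geometry(res_a, res_b, context="inter-sheet zipper")
                    except IncompleteRingError:
                        continue
                    if g.centroid_distance <= max_distance:
                        out.append(g)
    out.sort(key=lambda g: g.centroid_distance)
    return out
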