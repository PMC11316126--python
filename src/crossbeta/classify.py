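"""Steric-zipper topology classification.

Every zipper interface is reduced to three binary descriptors measured
directly from geometry — strand sense within the sheets, the parity of
the two surfaces meeting at the zipper (side chains of even-numbered
residues form a strand's "face", odd-numbered its "back"), and the
relative N->C direction of the facing strands — and mapped to one of the
ten topology classes through a versioned lookup table. Combinations
outside the table come back "unclassified"; nothing is ever coerced to
the nearest class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .lattice import SheetAssembly, StrandInstance, ZipperInterface
from .structure import BACKBONE_ATOMS

__all__ = [
    "InterfaceDescriptors",
    "ZipperClass",
    "CrystalTopology",
    "AmbiguousFaceError",
    "ObliqueInterfaceError",
    "load_class_table",
    "assign_faces",
    "sheet_face",
    "compute_descriptors",
    "classify_interface",
    "overall_topology",
]


class AmbiguousFaceError(Exception):
    pass


class ObliqueInterfaceError(Exception):
    pass


@dataclass(frozen=True)
class InterfaceDescriptors:
    sheet_sense: str  # "parallel" | "antiparallel"
    surface_parity: str  # "same" (face-to-face / back-to-back) | "opposite"
    sheet_direction: str  # "same" (N-to-N / up-up) | "opposite" (N-to-C / up-down)


@dataclass(frozen=True)
class ZipperClass:
    class_id: object  # 1..10 or "unclassified"
    basis: InterfaceDescriptors
    lookup_version: str


@dataclass
class CrystalTopology:
    per_interface: dict  # S-label -> ZipperClass
    overall: ZipperClass


class _ClassTable:
    def __init__(self, rows: list, version: str):
        self.rows = rows
        self.version = version

    def lookup(self, d: InterfaceDescriptors, extra_flag: str = "none"):
        for sense, parity, direction, flag, cid in self.rows:
            if (sense, parity, direction, flag) == (
                d.sheet_sense,
                d.surface_parity,
                d.sheet_direction,
                extra_flag,
            ):
                return cid
        return "unclassified"

    def class_descriptors(self, class_id: int):
        """Inverse lookup used by the synthetic generator."""
        for sense, parity, direction, flag, cid in self.rows:
            if cid == class_id:
                return InterfaceDescriptors(sense, parity, direction), flag
        raise KeyError(f"class {class_id} not in lookup table")


_TABLE = None


def load_class_table() -> _ClassTable:
    """The packaged descriptor -> class lookup (cached)."""
    global _TABLE
    if _TABLE is not None:
        return _TABLE
    ref = resources.files("crossbeta.data").joinpath("zipper_classes.tsv")
    rows, version = [], "unversioned"
    header_seen = False
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "version:" in line:
                version = line.split("version:", 1)[1].strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        sense, parity, direction, flag, cid = line.split("\t")
        rows.append((sense, parity, direction, flag, int(cid)))
    if not rows:
        raise ValueError("malformed class table resource: no rows")
    _TABLE = _ClassTable(rows, version)
    return _TABLE


def _partner_centroid(iface: ZipperInterface, side: str) -> np.ndarray:
    other = iface.sheet_b if side == "a" else iface.sheet_a
    return other.centroid


def _cb_projection_parity(strands: list, toward: np.ndarray) -> str:
    """Fallback face test: which residue parity's CA->CB vectors point
    toward the partner sheet."""
    score = {0: 0.0, 1: 0.0}
    n = {0: 0, 1: 0}
    for strand in strands:
        for seq, atoms in strand.residues().items():
            if "CA" not in atoms or "CB" not in atoms:
                continue
            v = atoms["CB"].xyz - atoms["CA"].xyz
            w = toward - atoms["CA"].xyz
            score[seq % 2] += float(v @ w / (np.linalg.norm(v) * np.linalg.norm(w)))
            n[seq % 2] += 1
    means = {p: score[p] / n[p] for p in (0, 1) if n[p]}
    if not means:
        raise AmbiguousFaceError("no CB atoms available for face assignment")
    best = max(means, key=lambda p: means[p])
    if len(means) == 2 and abs(means[0] - means[1]) < 1e-6:
        raise AmbiguousFaceError("CB projections tie; face is ambiguous")
    return "face" if best == 0 else "back"


def sheet_face(iface: ZipperInterface, side: str) -> str:
    """Which surface ("face" = even residues, "back" = odd) a sheet
    presents at the interface, by contact majority over side-chain atoms
    with a CB-projection fallback."""
    idx = 0 if side == "a" else 1
    even = odd = 0
    for pair in iface.contact_pairs:
        a = pair[idx]
        if a.name in BACKBONE_ATOMS or a.name == "CB":
            continue
        if a.residue_seq % 2 == 0:
            even += 1
        else:
            odd += 1
    if even > odd:
        return "face"
    if odd > even:
        return "back"
    sheet = iface.sheet_a if side == "a" else iface.sheet_b
    return _cb_projection_parity(sheet.strands, _partner_centroid(iface, side))


def assign_faces(strand: StrandInstance, iface: ZipperInterface) -> str:
    """Face/back assignment for a single strand within an interface."""
    for side, sheet in (("a", iface.sheet_a), ("b", iface.sheet_b)):
        if any(s is strand for s in sheet.strands):
            idx = 0 if side == "a" else 1
            even = odd = 0
            for pair in iface.contact_pairs:
                a = pair[idx]
                if a.chain_id != strand.atoms[0].chain_id:
                    continue
                if not any(a is x for x in strand.atoms):
                    continue
                if a.name in BACKBONE_ATOMS or a.name == "CB":
                    continue
                if a.residue_seq % 2 == 0:
                    even += 1
                else:
                    odd += 1
            if even > odd:
                return "face"
            if odd > even:
                return "back"
            return _cb_projection_parity([strand], _partner_centroid(iface, side))
    raise ValueError("strand does not participate in the interface")


def _antiparallel_direction(iface: ZipperInterface, dead_zone: float) -> str:
    """Up-up vs up-down for antiparallel sheets: compare N->C directions
    of nearest strand pairs across the interface."""
    votes = []
    cents_b = np.array([s.centroid for s in iface.sheet_b.strands])
    for sa in iface.sheet_a.strands:
        j = int(np.argmin(np.linalg.norm(cents_b - sa.centroid, axis=1)))
        votes.append(float(sa.direction @ iface.sheet_b.strands[j].direction))
    mean = float(np.mean(votes))
    if mean > dead_zone:
        return "same"
    if mean < -dead_zone:
        return "opposite"
    raise ObliqueInterfaceError(
        f"facing strand directions are oblique (mean dot {mean:.2f})"
    )


def compute_descriptors(iface: ZipperInterface, dead_zone: float = 0.3) -> InterfaceDescriptors:
    """Measure the three binary descriptors of a zipper interface."""
    sa, sb = iface.sheet_a, iface.sheet_b
    if sa.sense != sb.sense:
        raise ObliqueInterfaceError(
            f"sheet senses differ across the interface: {sa.sense} vs {sb.sense}"
        )
    face_a = iface.face_a or sheet_face(iface, "a")
    face_b = iface.face_b or sheet_face(iface, "b")
    parity = "same" if face_a == face_b else "opposite"
    if sa.sense == "parallel":
        dot = float(sa.mean_direction @ sb.mean_direction)
        if dot > dead_zone:
            direction = "same"
        elif dot < -dead_zone:
            direction = "opposite"
        else:
            raise ObliqueInterfaceError(
                f"sheet directions are oblique (dot {dot:.2f}); outside the "
                "linear cross-beta regime"
            )
    else:
        direction = _antiparallel_direction(iface, dead_zone)
    return InterfaceDescriptors(
        sheet_sense=sa.sense, surface_parity=parity, sheet_direction=direction
    )


def classify_interface(
    d: InterfaceDescriptors, table: _ClassTable | None = None, extra_flag: str = "none"
) -> ZipperClass:
    table = table or load_class_table()
    cid = table.lookup(d, extra_flag)
    return ZipperClass(class_id=cid, basis=d, lookup_version=table.version)


def overall_topology(per_interface: dict, areas: dict) -> CrystalTopology:
    """Crystal-level topology: the class of the largest-area interface."""
    if not per_interface:
        raise ValueError("no interfaces to rank")
    if set(per_interface) != set(areas):
        raise ValueError("interface and area maps must share keys")
    dominant = max(sorted(areas), key=lambda k: areas[k])
    return CrystalTopology(per_interface=dict(per_interface), overall=per_interface[dominant])
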