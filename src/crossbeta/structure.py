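"""Crystal structure model and I/O.

The in-memory model used by every pipeline stage: a flat list of heavy
atoms plus the unit cell and the space-group operators. Reading goes
through gemmi (PDB and mmCIF); writing emits fixed-format PDB so that
round-trips are byte-stable.

Only the handful of space groups that occur in amyloid-like peptide
crystals are accepted; anything else raises
:class:`UnsupportedSpaceGroupError` rather than silently degrading to P 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "Atom",
    "CrystalStructure",
    "parse_structure",
    "write_structure",
    "StructureError",
    "ParseError",
    "NoSymmetryError",
    "UnsupportedSpaceGroupError",
    "SerializationError",
    "SUPPORTED_SPACEGROUPS",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: normalized symbol -> canonical Hermann-Mauguin name understood by gemmi
SUPPORTED_SPACEGROUPS = {
    "P1": "P 1",
    "P2": "P 1 2 1",
    "P121": "P 1 2 1",
    "P21": "P 1 21 1",
    "P1211": "P 1 21 1",
    "P2111": "P 21 1 1",
    "P1121": "P 1 1 21",
    "P212121": "P 21 21 21",
    "C2": "C 1 2 1",
    "C121": "C 1 2 1",
}


class StructureError(Exception):
    """Base class for structure I/O errors."""


class ParseError(StructureError):
    pass


class NoSymmetryError(StructureError):
    """The file carries no unit cell / space group information."""


class UnsupportedSpaceGroupError(StructureError):
    def __init__(self, symbol: str):
        supported = ", ".join(sorted(set(SUPPORTED_SPACEGROUPS.values())))
        super().__init__(
            f"unsupported space group {symbol!r}; supported symbols: {supported}"
        )
        self.symbol = symbol


class SerializationError(StructureError):
    pass


def normalize_spacegroup_symbol(symbol: str) -> str:
    """Map a space-group symbol to its canonical H-M form.

    Accepts compact spellings such as ``P2_1`` or ``P21 21 21`` alongside
    the full Hermann-Mauguin name. Raises
    :class:`UnsupportedSpaceGroupError` for symbols outside the supported
    table.
    """
    key = symbol.upper().replace("_", "").replace(" ", "")
    if key in SUPPORTED_SPACEGROUPS:
        return SUPPORTED_SPACEGROUPS[key]
    raise UnsupportedSpaceGroupError(symbol)


@dataclass(frozen=True)
class UnitCell:
    """Unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (standard PDB orthogonalization)."""
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        return np.array(g.orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.frac_matrix.T


@dataclass(frozen=True)
class SymOp:
    """Symmetry operator in the fractional basis.

    ``rotation`` entries are integers in {-1, 0, 1}; ``translation``
    components are rational with denominator <= 12, stored as floats.
    """

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # 3 floats

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        rot = tuple(tuple(int(v // op.DEN) for v in row) for row in op.rot)
        tran = tuple(float(Fraction(int(v), op.DEN)) for v in op.tran)
        return cls(rot, tran)

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def is_identity(self) -> bool:
        return self == SymOp.identity()

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.rot_array.T + self.tran_array

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: (self . other)(x) = self(other(x))."""
        rot = self.rot_array @ other.rot_array
        tran = self.rot_array @ other.tran_array + self.tran_array
        return SymOp(
            tuple(tuple(int(round(v)) for v in row) for row in rot),
            tuple(float(v) for v in tran),
        )


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0, 1]")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def moved_to(self, xyz: np.ndarray) -> "Atom":
        return dataclasses.replace(self, xyz=np.asarray(xyz, dtype=float))


STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class CrystalStructure:
    atoms: list  # list[Atom]
    cell: UnitCell
    space_group: str
    sym_ops: list = field(default_factory=lambda: [SymOp.identity()])
    source_id: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ParseError(f"{self.source_id or 'structure'}: zero atoms")
        if not any(op.is_identity() for op in self.sym_ops):
            raise ValueError("sym_ops must contain the identity")

    def chains(self) -> dict:
        """Ordered mapping chain_id -> list of atoms (peptide and solvent)."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def peptide_chains(self) -> dict:
        """chain_id -> atoms, restricted to standard amino-acid residues."""
        out: dict = {}
        for a in self.atoms:
            if a.residue_name in STANDARD_AA:
                out.setdefault(a.chain_id, []).append(a)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])


def _convert_gemmi(st: gemmi.Structure, path: str, keep_alt: str) -> CrystalStructure:
    cell = st.cell
    if cell.a <= 1.0 and cell.b <= 1.0 and cell.c <= 1.0:
        raise NoSymmetryError(f"{path}: no unit cell record")
    symbol = st.spacegroup_hm
    if not symbol:
        raise NoSymmetryError(f"{path}: no space group record")
    hm = normalize_spacegroup_symbol(symbol)
    sg = gemmi.find_spacegroup_by_name(hm)
    sym_ops = [SymOp.from_gemmi(op) for op in sg.operations()]

    atoms = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            # retain a single conformer per residue
            by_name: dict = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif keep_alt == "highest":
                    if at.occ > prev.occ:
                        by_name[at.name] = at
                else:  # keep the requested altloc letter, default 'A'
                    if at.altloc == keep_alt:
                        by_name[at.name] = at
            for at in by_name.values():
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain_id=chain.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(1.0, at.occ),
                        b_factor=at.b_iso,
                        alt_loc="",
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: zero atoms")
    return CrystalStructure(
        atoms=atoms,
        cell=UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        space_group=hm,
        sym_ops=sym_ops,
        source_id=Path(path).stem,
    )


def parse_structure(path, dialect: str | None = None, keep_alt: str = "A") -> CrystalStructure:
    """Read a crystal structure from PDB or mmCIF.

    Parameters
    ----------
    path : str or Path
        Input file. The dialect is inferred from the extension unless
        given explicitly.
    dialect : {"pdb", "mmcif"}, optional
    keep_alt : str
        Alternate-location policy: a conformer letter (default ``"A"``)
        or ``"highest"`` for the highest-occupancy conformer. Hydrogens
        are always dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif dialect == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "dialect" in str(exc):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    return _convert_gemmi(st, str(path), keep_alt)


def _format_spacegroup_pdb(hm: str) -> str:
    # CRYST1 uses the short H-M form, e.g. "P 21 21 21"
    short = {"P 1 21 1": "P 21", "P 1 2 1": "P 2", "C 1 2 1": "C 2"}
    return short.get(hm, hm)


def write_structure(s: CrystalStructure, path) -> Path:
    """Write a structure as fixed-format PDB with a CRYST1 record.

    The emitted text is a pure function of the structure contents, so
    write -> parse -> write is byte-stable.
    """
    path = Path(path)
    lines = [
        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f %-11s%4d"
        % (
            s.cell.a,
            s.cell.b,
            s.cell.c,
            s.cell.alpha,
            s.cell.beta,
            s.cell.gamma,
            _format_spacegroup_pdb(s.space_group),
            len(s.sym_ops),
        )
    ]
    serial = 0
    prev_chain = None
    for a in s.atoms:
        if len(a.chain_id) != 1:
            raise SerializationError(
                f"chain id {a.chain_id!r} not encodable in PDB format"
            )
        if len(a.residue_name) > 3 or a.residue_seq > 9999:
            raise SerializationError(
                f"residue {a.residue_name} {a.residue_seq} not encodable"
            )
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            "ATOM  %5d %4s%1s%3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
            % (
                serial,
                name,
                "",
                a.residue_name,
                a.chain_id,
                a.residue_seq,
                "",
                a.xyz[0],
                a.xyz[1],
                a.xyz[2],
                a.occupancy,
                a.b_factor,
                a.element.rjust(2),
            )
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
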