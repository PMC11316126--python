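"""Double-layer formation energies from buried surface area.

The free energy of assembling a two-sheet "double layer" across a steric
zipper is estimated from the solvent-accessible surface area each atom
loses on assembly, weighted by atomic solvation parameters:

    E_form = sum_i  sigma(class_i) * (ASA_i(assembled) - ASA_i(reference))
             / n_central_strands

with the sum restricted to the central strand(s) of each sheet so that
stack-edge atoms never contribute. Two reference states are supported:
the isolated beta-sheets (zipper formation proper) and the isolated
monomeric strands in their deposited conformation (sheet formation plus
zipper formation). Burial of apolar surface (positive sigma) yields
negative, i.e. favourable, energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .sasa import compute_sasa

__all__ = [
    "SolvationParamSet",
    "EnergyResult",
    "StabilityThresholds",
    "ParameterizationError",
    "load_default_params",
    "atom_class",
    "formation_energy_from_sheets",
    "formation_energy_from_monomers",
    "interface_energy",
    "annotate_stability",
]


class ParameterizationError(Exception):
    """An atom could not be mapped to any solvation-parameter class."""


# charged side-chain / terminal atoms at the mildly acidic pH of the
# crystallization conditions
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass
class SolvationParamSet:
    entries: dict  # atom_class -> kcal mol^-1 A^-2
    radii: dict  # atom_class -> A
    probe_radius: float = 1.4
    source: str = ""

    @classmethod
    def from_file(cls, path) -> "SolvationParamSet":
        entries, radii, source = {}, {}, ""
        text = Path(path).read_text()
        header_seen = False
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "source:" in line:
                    source = line.split("source:", 1)[1].strip()
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            cls_name, asp, radius = line.split("\t")
            entries[cls_name] = float(asp)
            radii[cls_name] = float(radius)
        if not entries:
            raise ParameterizationError(f"no parameter rows in {path}")
        return cls(entries=entries, radii=radii, source=source)


def load_default_params() -> SolvationParamSet:
    """The packaged Eisenberg-McLachlan five-class parameter set."""
    ref = resources.files("crossbeta.data").joinpath("solvation_params.tsv")
    with resources.as_file(ref) as path:
        return SolvationParamSet.from_file(path)


def atom_class(atom, n_terminal_seq: int | None, c_terminal_seq: int | None) -> str:
    """Solvation class of an atom.

    ``n_terminal_seq`` / ``c_terminal_seq`` are the first and last residue
    numbers of the chain the atom belongs to; the terminal amine and
    carboxylate are treated as charged.
    """
    el = atom.element.upper()
    key = (atom.residue_name, atom.name)
    if key in _CHARGED_N:
        return "N_charged"
    if key in _CHARGED_O:
        return "O_charged"
    if el == "N":
        if n_terminal_seq is not None and atom.residue_seq == n_terminal_seq and atom.name == "N":
            return "N_charged"
        return "N"
    if el == "O":
        if (
            c_terminal_seq is not None
            and atom.residue_seq == c_terminal_seq
            and atom.name in ("O", "OXT")
        ):
            return "O_charged"
        return "O"
    if el == "C":
        return "C"
    if el == "S":
        return "S"
    raise ParameterizationError(
        f"no solvation class for atom {atom.name} ({atom.element}) "
        f"in {atom.residue_name} {atom.residue_seq}"
    )


def _strand_classes(atoms) -> list:
    seqs = [a.residue_seq for a in atoms]
    lo, hi = min(seqs), max(seqs)
    return [atom_class(a, lo, hi) for a in atoms]


def _params_arrays(atoms, params: SolvationParamSet):
    classes = _strand_classes(atoms)
    missing = sorted({c for c in classes if c not in params.entries})
    if missing:
        raise ParameterizationError(f"parameter set lacks classes: {missing}")
    sigma = np.array([params.entries[c] for c in classes])
    radii = np.array([params.radii[c] for c in classes])
    return sigma, radii


@dataclass
class EnergyResult:
    interface_label: str
    e_form_sheets: float  # kcal mol^-1 per strand
    e_form_monomers: float
    n_strands_summed: int
    atoms_used: int
    params_source: str


@dataclass(frozen=True)
class StabilityThresholds:
    """Reference medians for report annotation (kcal mol^-1 per strand)."""

    stable_zipper_median: float = -1.417
    larks_median: float = -0.443


def _per_strand_arrays(dl, params):
    """sigma/radii arrays and index bookkeeping for a double layer."""
    strand_atoms = []  # (sheet_idx, strand_idx, atoms, sigma, radii)
    for si, sheet in enumerate(dl.sheets):
        for ti, strand in enumerate(sheet.strands):
            sigma, radii = _params_arrays(strand.atoms, params)
            strand_atoms.append((si, ti, strand.atoms, sigma, radii))
    return strand_atoms


def _extra_for_sheet(dl, params, sheet_idx=None):
    extras = getattr(dl, "extra_atoms", []) or []
    chosen = [a for si, a in extras if sheet_idx is None or si == sheet_idx]
    if not chosen:
        return np.zeros((0, 3)), np.zeros(0)
    coords = np.array([a.xyz for a in chosen])
    radii = np.array([params.radii[atom_class(a, None, None)] for a in chosen])
    return coords, radii


def _delta_energy(dl, params, n_points, reference: str) -> tuple[float, int, int]:
    """Core ASA-difference sum over central-strand atoms."""
    strand_atoms = _per_strand_arrays(dl, params)
    coords_all = np.vstack([np.array([a.xyz for a in at]) for _, _, at, _, _ in strand_atoms])
    radii_all = np.concatenate([r for _, _, _, _, r in strand_atoms])
    xc, xr = _extra_for_sheet(dl, params, None)
    if len(xc):
        coords_all = np.vstack([coords_all, xc])
        radii_all = np.concatenate([radii_all, xr])
    sasa_dl = compute_sasa(coords_all, radii_all, params.probe_radius, n_points).per_atom

    # per-sheet SASA (reference "sheets") and per-strand SASA ("monomers")
    offsets = np.cumsum([0] + [len(at) for _, _, at, _, _ in strand_atoms])
    energy = 0.0
    n_atoms_used = 0
    n_central = 0
    for si, sheet in enumerate(dl.sheets):
        members = [k for k, rec in enumerate(strand_atoms) if rec[0] == si]
        sheet_coords = np.vstack(
            [np.array([a.xyz for a in strand_atoms[k][2]]) for k in members]
        )
        sheet_radii = np.concatenate([strand_atoms[k][4] for k in members])
        xc, xr = _extra_for_sheet(dl, params, si)
        if len(xc):
            sheet_coords = np.vstack([sheet_coords, xc])
            sheet_radii = np.concatenate([sheet_radii, xr])
        sasa_sheet = compute_sasa(
            sheet_coords, sheet_radii, params.probe_radius, n_points
        ).per_atom
        sheet_off = np.cumsum([0] + [len(strand_atoms[k][2]) for k in members])
        for mpos, k in enumerate(members):
            _, ti, atoms, sigma, radii = strand_atoms[k]
            if ti not in dl.central_strands[si]:
                continue
            n_central += 1
            n_atoms_used += len(atoms)
            in_dl = sasa_dl[offsets[k] : offsets[k + 1]]
            if reference == "sheets":
                ref = sasa_sheet[sheet_off[mpos] : sheet_off[mpos + 1]]
            elif reference == "monomers":
                coords = np.array([a.xyz for a in atoms])
                ref = compute_sasa(coords, radii, params.probe_radius, n_points).per_atom
            else:
                raise ValueError(reference)
            energy += float(np.sum(sigma * (in_dl - ref)))
    if n_central == 0:
        raise ValueError("double layer has no central strands defined")
    return energy, n_central, n_atoms_used


def formation_energy_from_sheets(dl, params=None, n_points: int = 960) -> float:
    """Energy of double-layer formation from the two isolated sheets.

    Returned in kcal mol^-1 per strand (divided by the number of central
    strands summed).
    """
    params = params or load_default_params()
    e, n, _ = _delta_energy(dl, params, n_points, "sheets")
    return e / n


def formation_energy_from_monomers(dl, params=None, n_points: int = 960) -> float:
    """Energy of double-layer formation from isolated monomeric strands."""
    params = params or load_default_params()
    e, n, _ = _delta_energy(dl, params, n_points, "monomers")
    return e / n


def interface_energy(
    dl,
    label: str = "S1",
    params=None,
    n_points: int = 960,
    divisor: str = "central",
) -> EnergyResult:
    """Both formation energies of one double layer as an EnergyResult.

    ``divisor`` selects the per-strand normalization: "central" divides
    by the number of central strands actually summed (the default
    convention used throughout), "total" by all strands in the double
    layer.
    """
    params = params or load_default_params()
    e_sheet, n, atoms_used = _delta_energy(dl, params, n_points, "sheets")
    e_mono, _, _ = _delta_energy(dl, params, n_points, "monomers")
    if divisor == "central":
        div = n
    elif divisor == "total":
        div = sum(len(sh.strands) for sh in dl.sheets)
    else:
        raise ValueError(f"unknown divisor convention {divisor!r}")
    return EnergyResult(
        interface_label=label,
        e_form_sheets=e_sheet / div,
        e_form_monomers=e_mono / div,
        n_strands_summed=div,
        atoms_used=atoms_used,
        params_source=params.source,
    )


def annotate_stability(
    e: EnergyResult | float, thresholds: StabilityThresholds | None = None,
    band_halfwidth: float = 0.1,
) -> dict:
    """Annotate a per-strand sheet-formation energy against reference medians.

    Tags the value "zipper-like" or "LARKS-like" by the nearer median,
    with an explicit "intermediate" band of ``band_halfwidth`` around the
    midpoint. Annotation only; numbers are never altered.
    """
    th = thresholds or StabilityThresholds()
    value = e.e_form_sheets if isinstance(e, EnergyResult) else float(e)
    midpoint = 0.5 * (th.stable_zipper_median + th.larks_median)
    if abs(value - midpoint) <= band_halfwidth:
        tag = "intermediate"
    elif value < midpoint:
        tag = "zipper-like"
    else:
        tag = "LARKS-like"
    return {
        "tag": tag,
        "distance_to_zipper_median": abs(value - th.stable_zipper_median),
        "distance_to_larks_median": abs(value - th.larks_median),
    }
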