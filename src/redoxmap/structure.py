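"""Molecular structure containers and PDB/PQR input/output.

The in-memory model is deliberately small: a flat list of atoms with
coordinates (Å), partial charges (e) and radii (Å), plus cofactor labels
for c-type hemes.  Rigid-body mapping and field evaluation only ever need
these per-atom quantities, so no topology beyond residue grouping is kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularModel",
    "RedoxStateSpec",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "write_pqr",
]

#: residue names recognised as c-type heme cofactors
HEME_RESIDUE_NAMES = {"HEC", "HEM", "HEA", "HEB"}

_TWO_LETTER_ELEMENTS = {"FE", "CL", "NA", "MG", "ZN", "CA", "CU", "MN", "BR"}


class ParseError(ValueError):
    """Raised when a structure or grid file cannot be parsed."""


def element_from_name(name: str) -> str:
    """Guess the chemical element from an atom name.

    PDB atom names start with the element, optionally preceded by a digit
    (e.g. ``1HB``).  Two-letter metals such as ``FE`` are recognised
    explicitly; everything else maps to its first alphabetic character.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER_ELEMENTS:
        return upper[:2]
    return upper[0]


@dataclass
class Atom:
    """A single atom: identity, position (Å), partial charge (e), radius (Å)."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    cofactor_id: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius")

    @property
    def element(self) -> str:
        return element_from_name(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class MolecularModel:
    """A rigid molecule: atoms plus the list of heme cofactor labels."""

    atoms: list[Atom] = field(default_factory=list)
    hemes: list[str] = field(default_factory=list)
    pH: float = 7.0
    name: str = ""

    def __post_init__(self) -> None:
        present = {a.cofactor_id for a in self.atoms if a.cofactor_id}
        if not self.hemes:
            self.hemes = sorted(present)
        else:
            missing = set(self.hemes) - present
            if missing:
                raise ValueError(f"heme ids listed but absent from atoms: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.atoms)

    # -- array views -------------------------------------------------
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def center_of_mass(self) -> np.ndarray:
        """Unweighted geometric centre (all atoms treated as unit mass)."""
        return self.coordinates().mean(axis=0)

    def cofactor_atoms(self, cofactor_id: str) -> list[Atom]:
        atoms = [a for a in self.atoms if a.cofactor_id == cofactor_id]
        if not atoms:
            raise KeyError(f"no cofactor {cofactor_id!r} in model")
        return atoms

    def copy(self) -> "MolecularModel":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class RedoxStateSpec:
    """Oxidation state per heme: each cofactor id maps to 'ferric' or 'ferrous'."""

    state_by_heme: dict[str, str]

    def __post_init__(self) -> None:
        for heme, state in self.state_by_heme.items():
            if state not in ("ferric", "ferrous"):
                raise ValueError(f"heme {heme!r}: state must be 'ferric' or 'ferrous', got {state!r}")

    def validate_against(self, model: MolecularModel) -> None:
        missing = set(self.state_by_heme) - set(model.hemes)
        if missing:
            raise KeyError(f"redox spec names hemes absent from model: {sorted(missing)}")


def _cofactor_id_for(residue_name: str, residue_id: int) -> str | None:
    if residue_name.strip().upper() in HEME_RESIDUE_NAMES:
        return f"heme{residue_id}"
    return None


# ----------------------------------------------------------------------
# PDB
# ----------------------------------------------------------------------

def _validate_pdb_lines(lines: Sequence[str]) -> None:
    """Check fixed-column ATOM/HETATM records before handing off to gemmi.

    gemmi is forgiving; this pre-scan gives a line-numbered error for
    records too short to hold coordinates or with unparsable numbers.
    """
    for i, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {i}: truncated {rec} record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {i}: bad coordinate field in {rec} record") from exc


def read_pdb(path: str | Path) -> MolecularModel:
    """Read a PDB file into a :class:`MolecularModel`.

    Charges and radii are left at 0 until :func:`redoxmap.assign_charges`
    or a PQR file supplies them.  HETATM residues named HEC/HEM/HEA/HEB
    are labelled as heme cofactors (``heme<residue id>``).
    """
    import gemmi

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    lines = text.splitlines()
    _validate_pdb_lines(lines)

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    atoms: list[Atom] = []
    for chain in st[0]:
        for residue in chain:
            cof = _cofactor_id_for(residue.name, residue.seqid.num)
            for at in residue:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        residue_name=residue.name,
                        residue_id=residue.seqid.num,
                        chain=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        cofactor_id=cof,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return MolecularModel(atoms=atoms, name=path.stem)


def write_pdb(model: MolecularModel, path: str | Path) -> None:
    """Write the model as a minimal PDB file (ATOM/HETATM + END)."""
    path = Path(path)
    with path.open("w") as fh:
        for a in model.atoms:
            record = "HETATM" if a.cofactor_id else "ATOM"
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"{record:<6s}{a.serial:>5d} {name:<4s}{a.residue_name:>4s} "
                f"{a.chain[:1]:1s}{a.residue_id:>4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ----------------------------------------------------------------------
# PQR (whitespace-separated, charge and radius as the last two fields)
# ----------------------------------------------------------------------

def read_pqr(path: str | Path) -> MolecularModel:
    """Read a whitespace-separated PQR file.

    Accepts both the 10-field layout (with a chain column) and the 9-field
    layout (without); the charge and radius are always the last two fields.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] not in ("ATOM", "HETATM"):
                continue
            if len(fields) == 11:  # with a chain column
                serial, name, resname, chain, resid = fields[1:6]
                x, y, z, q, r = fields[6:11]
            elif len(fields) == 10:  # PDB2PQR's chain-less layout
                serial, name, resname, resid = fields[1:5]
                chain = "A"
                x, y, z, q, r = fields[5:10]
            else:
                raise ParseError(
                    f"{path}:{lineno}: PQR record needs 10 or 11 whitespace fields "
                    f"(missing charge/radius column?), got {len(fields)}"
                )
            try:
                resid_i = int(resid)
                atoms.append(
                    Atom(
                        serial=int(serial),
                        name=name,
                        residue_name=resname,
                        residue_id=resid_i,
                        chain=chain,
                        position=np.array([float(x), float(y), float(z)]),
                        charge=float(q),
                        radius=float(r),
                        cofactor_id=_cofactor_id_for(resname, resid_i),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparsable PQR field: {exc}") from exc
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return MolecularModel(atoms=atoms, name=path.stem)


def write_pqr(model: MolecularModel, path: str | Path) -> None:
    """Write a 10-field PQR file (positions to 3 decimals, charges to 4)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("REMARK  written by redoxmap\n")
        for a in model.atoms:
            record = "HETATM" if a.cofactor_id else "ATOM"
            fh.write(
                f"{record:<6s} {a.serial:>5d} {a.name:<4s} {a.residue_name:<4s} "
                f"{a.chain[:1]:1s} {a.residue_id:>5d} "
                f"{a.position[0]:10.3f} {a.position[1]:10.3f} {a.position[2]:10.3f} "
                f"{a.charge:9.4f} {a.radius:7.3f}\n"
            )
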