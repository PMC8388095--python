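"""Partial-charge and radius assignment at pH 7, including heme redox states.

Charging model
--------------
Per-site pKa prediction is intentionally out of scope: side chains carry
their pH-7 formal charges (Asp/Glu −1, Lys/Arg +1, His 0), free termini
are charged (+1 N-terminal amine, −1 C-terminal carboxylate), and every
other residue is neutral.  Each formal charge is placed on a single,
documented side-chain atom so that charging is united-atom tolerant: a
structure without hydrogens charges identically to one with them.

c-type hemes follow a minimal, explicit convention: the two propionates
contribute −0.5 e per carboxylate oxygen when present, and the iron
carries +1 e in the ferric state and 0 e in the ferrous state.  The
ferric→ferrous difference is therefore exactly one elementary charge,
localised on Fe (falling back to the first cofactor atom when no Fe atom
exists).  Finer heme charge distributions belong in an imported PQR.
"""

from __future__ import annotations

import warnings

from .structure import Atom, MolecularModel, RedoxStateSpec

__all__ = [
    "assign_charges",
    "set_redox_state",
    "formal_residue_charge",
    "PARSE_LIKE_RADII",
]

#: residue → (formal charge, ordered candidate atom names to carry it)
SIDECHAIN_CHARGES: dict[str, tuple[float, tuple[str, ...]]] = {
    "ASP": (-1.0, ("OD2", "OD1", "CG")),
    "GLU": (-1.0, ("OE2", "OE1", "CD")),
    "LYS": (+1.0, ("NZ", "CE")),
    "ARG": (+1.0, ("CZ", "NH2", "NH1")),
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: element → radius (Å); values follow the coarse PARSE-style convention
PARSE_LIKE_RADII: dict[str, float] = {
    "H": 1.00,
    "C": 1.70,
    "N": 1.50,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "FE": 1.30,
}
DEFAULT_RADIUS = 1.50

#: heme propionate carboxylate oxygens, −0.5 e each when present
HEME_PROPIONATE_OXYGENS = ("O1A", "O2A", "O1D", "O2D")

FERRIC_FE_CHARGE = 1.0
FERROUS_FE_CHARGE = 0.0


def formal_residue_charge(residue_name: str, n_term: bool = False, c_term: bool = False) -> float:
    """Net formal charge of one standard residue at pH 7 (termini included)."""
    name = residue_name.strip().upper()
    q = SIDECHAIN_CHARGES.get(name, (0.0, ()))[0] if name in STANDARD_RESIDUES else 0.0
    if n_term:
        q += 1.0
    if c_term:
        q -= 1.0
    return q


def _pick_atom(atoms: list[Atom], names: tuple[str, ...]) -> Atom | None:
    by_name = {a.name.strip().upper(): a for a in atoms}
    for n in names:
        if n in by_name:
            return by_name[n]
    return None


def _charge_heme(atoms: list[Atom], state: str) -> None:
    for a in atoms:
        a.charge = 0.0
        if a.name.strip().upper() in HEME_PROPIONATE_OXYGENS:
            a.charge = -0.5
    fe = _pick_atom(atoms, ("FE",)) or atoms[0]
    fe.charge = FERRIC_FE_CHARGE if state == "ferric" else FERROUS_FE_CHARGE


def assign_charges(
    model: MolecularModel,
    pH: float = 7.0,
    redox: RedoxStateSpec | None = None,
) -> MolecularModel:
    """Return a copy of *model* with pH-7 formal charges and element radii.

    Parameters
    ----------
    model : MolecularModel
        Structure to charge.  Existing charges are overwritten, so the
        operation is idempotent.
    pH : float
        Only 7.0 is supported; the charge table is a fixed-pH table.
    redox : RedoxStateSpec, optional
        Oxidation state per heme cofactor; hemes not named default to
        ferric.  Naming a heme absent from the model is an error.

    Raises
    ------
    ValueError
        For an unsupported pH.
    KeyError
        If *redox* names a heme the model does not contain.
    """
    if abs(pH - 7.0) > 1e-9:
        raise ValueError(f"only pH 7.0 charging is implemented (got pH={pH})")
    if redox is not None:
        redox.validate_against(model)
    states = dict.fromkeys(model.hemes, "ferric")
    if redox is not None:
        states.update(redox.state_by_heme)

    out = model.copy()
    out.pH = pH

    # group atoms by residue within each chain, preserving order
    residues: dict[tuple[str, int, str], list[Atom]] = {}
    for a in out.atoms:
        residues.setdefault((a.chain, a.residue_id, a.residue_name.strip().upper()), []).append(a)

    # terminal residues: first/last *standard* residue per chain
    chain_standard: dict[str, list[tuple[str, int, str]]] = {}
    for key in residues:
        if key[2] in STANDARD_RESIDUES:
            chain_standard.setdefault(key[0], []).append(key)

    termini_n = {keys[0] for keys in chain_standard.values()}
    termini_c = {keys[-1] for keys in chain_standard.values()}

    warned: set[str] = set()
    heme_groups: dict[str, list[Atom]] = {}
    for key, atoms in residues.items():
        resname = key[2]
        cof = atoms[0].cofactor_id
        if cof is not None:
            heme_groups.setdefault(cof, []).extend(atoms)
            continue
        for a in atoms:
            a.charge = 0.0
        if resname not in STANDARD_RESIDUES:
            if resname not in warned:
                warnings.warn(f"unknown residue {resname!r}: assigned zero charge", stacklevel=2)
                warned.add(resname)
            continue
        if resname in SIDECHAIN_CHARGES:
            q, candidates = SIDECHAIN_CHARGES[resname]
            target = _pick_atom(atoms, candidates) or atoms[-1]
            target.charge = q
        if key in termini_n:
            target = _pick_atom(atoms, ("N",)) or atoms[0]
            target.charge += 1.0
        if key in termini_c:
            target = _pick_atom(atoms, ("OXT", "O", "C")) or atoms[-1]
            target.charge += -1.0

    for cof, atoms in heme_groups.items():
        _charge_heme(atoms, states.get(cof, "ferric"))

    for a in out.atoms:
        a.radius = PARSE_LIKE_RADII.get(a.element, DEFAULT_RADIUS)
    return out


def set_redox_state(model: MolecularModel, redox: RedoxStateSpec) -> MolecularModel:
    """Return a copy with only the heme iron charges switched.

    Unlike :func:`assign_charges` this touches nothing but the redox-
    carrying atom of each named heme, so it composes with models whose
    other charges were set elsewhere (imported PQRs, synthetic toys).
    The ferrous iron sits exactly 1 e below the ferric one.
    """
    redox.validate_against(model)
    out = model.copy()
    for cof, state in redox.state_by_heme.items():
        atoms = out.cofactor_atoms(cof)
        fe = _pick_atom(atoms, ("FE",)) or atoms[0]
        fe.charge = FERRIC_FE_CHARGE if state == "ferric" else FERROUS_FE_CHARGE
    return out
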