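"""Synthetic fixtures with known ground truth for every analysis stage.

The structural generators emulate the geometry that matters for
electrostatic steering between a multiheme oxidase and a small
cytochrome, at desk scale:

* a spherical "receptor" (~25 Å, ~400 surface pseudo-atoms) carrying a
  positively charged circular patch, with one heme-like cofactor buried
  just under the patch surface (the heme-3 analogue) and one at the
  antipode (the heme-1 analogue);
* a small spherical "ligand" (~8 Å) with an equatorial ring of charged
  pseudo-atoms around a central heme — sign-switchable, so a negative
  ring (attracted to the patch) and a geometry-identical positive ring
  (repelled) form a built-in specificity pair.

Surface pseudo-atoms sit on a Fibonacci sphere, one single-atom residue
each (patch atoms are named ARG, background atoms GLY, ring atoms ASP or
LYS by sign) so that charge classification is exercised.  A large
zero-charge blocker atom at each centre keeps rigid bodies from
interpenetrating through the sparse surface shells.

The titration and kinetics simulators draw from the same models the
fitting modules assume (Nernstian sigmoid with per-limb hysteresis;
Michaelis–Menten with multiplicative noise; piecewise-linear progress
curves), all seed-deterministic and returning their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import ELECTRONS_PER_NH2OH, ProgressCurve, RatePoint
from .mapping import DEFAULT_OVERLAP_FACTOR, _quat_to_matrix
from .nernst import TitrationCurve, nernst_absorbance
from .structure import Atom, MolecularModel

__all__ = [
    "PatchReceptorSpec",
    "RingLigandSpec",
    "fibonacci_sphere",
    "make_patch_receptor",
    "make_ring_ligand",
    "specificity_pair",
    "simulate_titration",
    "simulate_rates",
    "simulate_progress",
]

SURFACE_RADIUS = 1.7  # Å, carbon-like pseudo-atoms


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return _quat_to_matrix(q / np.linalg.norm(q))


def _blocker_radius(surface_radius: float, clearance: float = 3.0) -> float:
    """Radius of the central blocker so rigid bodies cannot interpenetrate.

    A blocker of this size keeps foreign atoms (radius ~1.7 Å) at least
    ``surface_radius − clearance`` from the centre under the default
    overlap factor, while leaving the surface shell reachable.
    """
    return (surface_radius - clearance) / DEFAULT_OVERLAP_FACTOR - SURFACE_RADIUS


def _heme_number(cofactor_id: str) -> int:
    digits = "".join(ch for ch in cofactor_id if ch.isdigit())
    if not digits:
        raise ValueError(f"cofactor id {cofactor_id!r} needs a numeric suffix (e.g. 'heme3')")
    return int(digits)


@dataclass
class PatchReceptorSpec:
    """A charged-patch sphere emulating the concave positive interface."""

    radius: float = 25.0
    n_atoms: int = 400
    patch_center: tuple[float, float, float] = (0.0, 0.0, 1.0)
    patch_half_angle_deg: float = 30.0
    patch_charge_per_atom: float = 0.5
    background_charge: float = -0.02
    #: (cofactor_id, unit direction, depth below the surface in Å)
    cofactors: tuple = (
        ("heme3", (0.0, 0.0, 1.0), 1.0),
        ("heme1", (0.0, 0.0, -1.0), 1.0),
    )

    def __post_init__(self) -> None:
        if not (0 < self.patch_half_angle_deg < 90):
            raise ValueError("patch half-angle must be in (0, 90) degrees")


@dataclass
class RingLigandSpec:
    """A small sphere with a charged equatorial ring around a central heme."""

    radius: float = 8.0
    n_atoms: int = 50
    ring_size: int = 12
    ring_charge_per_atom: float = -0.5
    cofactor_id: str = "heme1"


def make_patch_receptor(spec: PatchReceptorSpec | None = None, seed: int = 0) -> MolecularModel:
    """Build the patch receptor; deterministic for a given seed.

    The Fibonacci lattice is rotated by a seed-derived random rotation
    (so different seeds give different discretizations), then atoms
    within the patch half-angle of ``patch_center`` receive the patch
    charge and residue name ARG; the rest are GLY at the background
    charge.  Cofactors are single FE pseudo-atoms (HEC residues) at the
    stated depth below the surface, ferric (+1 e) by default.
    """
    spec = spec or PatchReceptorSpec()
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    dirs = fibonacci_sphere(spec.n_atoms) @ rot.T
    center = np.asarray(spec.patch_center, dtype=float)
    center /= np.linalg.norm(center)
    cos_half = np.cos(np.radians(spec.patch_half_angle_deg))
    in_patch = dirs @ center >= cos_half

    atoms: list[Atom] = []
    serial = 1
    for k, (d, patchy) in enumerate(zip(dirs, in_patch)):
        atoms.append(Atom(
            serial=serial, name="C",
            residue_name="ARG" if patchy else "GLY",
            residue_id=100 + k + 1, chain="R",
            position=spec.radius * d,
            charge=spec.patch_charge_per_atom if patchy else spec.background_charge,
            radius=SURFACE_RADIUS,
        ))
        serial += 1
    for cof_id, direction, depth in spec.cofactors:
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        atoms.append(Atom(
            serial=serial, name="FE", residue_name="HEC",
            residue_id=_heme_number(cof_id), chain="R",
            position=(spec.radius - depth) * d,
            charge=1.0, radius=1.3, cofactor_id=cof_id,
        ))
        serial += 1
    atoms.append(Atom(
        serial=serial, name="C", residue_name="BLK", residue_id=9999, chain="R",
        position=np.zeros(3), charge=0.0, radius=_blocker_radius(spec.radius),
    ))
    return MolecularModel(atoms=atoms, name=f"patch_receptor_seed{seed}")


def make_ring_ligand(spec: RingLigandSpec | None = None, seed: int = 0) -> MolecularModel:
    """Build the ring ligand; same seed and size → identical geometry.

    Ring membership (the ``ring_size`` lattice points nearest the
    equator) is decided before the seed-derived rotation, so flipping
    the ring charge sign changes charges and residue names (ASP vs LYS)
    but not a single coordinate.
    """
    spec = spec or RingLigandSpec()
    if spec.ring_size > spec.n_atoms:
        raise ValueError("ring_size cannot exceed n_atoms")
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    lattice = fibonacci_sphere(spec.n_atoms)
    ring_idx = np.argsort(np.abs(lattice[:, 2]), kind="stable")[: spec.ring_size]
    ring_mask = np.zeros(spec.n_atoms, dtype=bool)
    ring_mask[ring_idx] = True
    dirs = lattice @ rot.T
    ring_resname = "ASP" if spec.ring_charge_per_atom < 0 else "LYS"

    atoms: list[Atom] = []
    serial = 1
    for k, (d, ringy) in enumerate(zip(dirs, ring_mask)):
        atoms.append(Atom(
            serial=serial, name="C",
            residue_name=ring_resname if ringy else "GLY",
            residue_id=100 + k + 1, chain="L",
            position=spec.radius * d,
            charge=spec.ring_charge_per_atom if ringy else 0.0,
            radius=SURFACE_RADIUS,
        ))
        serial += 1
    atoms.append(Atom(
        serial=serial, name="FE", residue_name="HEC",
        residue_id=_heme_number(spec.cofactor_id), chain="L",
        position=np.zeros(3), charge=1.0, radius=1.3, cofactor_id=spec.cofactor_id,
    ))
    serial += 1
    atoms.append(Atom(
        serial=serial, name="C", residue_name="BLK", residue_id=9999, chain="L",
        position=np.zeros(3), charge=0.0, radius=_blocker_radius(spec.radius, 2.0),
    ))
    sign = "neg" if spec.ring_charge_per_atom < 0 else "pos"
    return MolecularModel(atoms=atoms, name=f"ring_ligand_{sign}_seed{seed}")


def specificity_pair(seed: int = 0, ring_charge: float = 0.5):
    """Receptor plus geometry-identical negative- and positive-ring ligands."""
    receptor = make_patch_receptor(seed=seed)
    neg = make_ring_ligand(RingLigandSpec(ring_charge_per_atom=-abs(ring_charge)), seed=seed)
    pos = make_ring_ligand(RingLigandSpec(ring_charge_per_atom=+abs(ring_charge)), seed=seed)
    return receptor, neg, pos


# ----------------------------------------------------------------------
# titration and kinetics data
# ----------------------------------------------------------------------

def simulate_titration(
    E_m_mV: float,
    n: int = 1,
    temperature: float = 293.0,
    potentials_mV: np.ndarray | None = None,
    noise_sd: float = 0.02,
    n_experiments: int = 2,
    hysteresis: float = 0.05,
    seed: int = 0,
    experiment_seeds: Sequence[int] | None = None,
) -> tuple[list[TitrationCurve], dict]:
    """Two-limb titration data from the Nernst model, with hysteresis.

    Each experiment contributes an oxidative limb (potentials ascending)
    and a reductive limb (descending).  The reductive limb is distorted
    by a limb-specific affine map (amplitude shrunk by *hysteresis*,
    baseline lifted by it — the drift that per-limb normalization is
    meant to remove), and Gaussian noise of *noise_sd* is added to the
    normalized absorbance.  Returns the curves and the ground truth.
    """
    if potentials_mV is None:
        potentials_mV = np.linspace(-300.0, 300.0, 25)
    potentials_mV = np.asarray(potentials_mV, dtype=float)
    if experiment_seeds is None:
        experiment_seeds = [s.generate_state(1)[0] % (2**31)
                            for s in np.random.SeedSequence(seed).spawn(n_experiments)]
    elif len(experiment_seeds) != n_experiments:
        raise ValueError("need one seed per experiment")

    curves: list[TitrationCurve] = []
    for i, exp_seed in enumerate(experiment_seeds):
        rng = np.random.default_rng(int(exp_seed))
        for limb, E in (("oxidative", np.sort(potentials_mV)),
                        ("reductive", np.sort(potentials_mV)[::-1])):
            clean = nernst_absorbance(E, E_m_mV, 0.0, 1.0, n=n, temperature=temperature)
            if limb == "reductive":
                clean = (1.0 - hysteresis) * clean + hysteresis
            noisy = clean + rng.normal(0.0, noise_sd, size=E.shape)
            curves.append(TitrationCurve(
                potentials_mV=E, absorbance=noisy, limb=limb,
                experiment_id=f"exp{i + 1}",
            ))
    truth = {"E_m_mV": E_m_mV, "n": n, "temperature": temperature,
             "noise_sd": noise_sd, "hysteresis": hysteresis}
    return curves, truth


def simulate_rates(
    Vmax: float,
    Km: float,
    s_levels_uM: np.ndarray | None = None,
    replicates: int = 3,
    noise_frac: float = 0.03,
    seed: int = 0,
) -> tuple[list[RatePoint], dict]:
    """Triplicate initial rates from the Michaelis–Menten law.

    Substrate levels default to 8 log-spaced concentrations spanning
    1–100 μM; each replicate rate carries multiplicative Gaussian noise
    of fractional width *noise_frac*.
    """
    if s_levels_uM is None:
        s_levels_uM = np.geomspace(1.0, 100.0, 8)
    s_levels_uM = np.asarray(s_levels_uM, dtype=float)
    rng = np.random.default_rng(seed)
    points = [
        RatePoint(S=float(s), v=float(Vmax * s / (Km + s) * (1.0 + rng.normal(0.0, noise_frac))))
        for s in s_levels_uM
        for _ in range(replicates)
    ]
    truth = {"Vmax": Vmax, "Km": Km, "replicates": replicates, "noise_frac": noise_frac}
    return points, truth


def simulate_progress(
    v_substrate_uM_min: float,
    substrate_uM: float,
    depsilon_mM_cm: float = 19.1,
    duration_s: float = 120.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    enzyme_ug: float = 0.6,
    volume_mL: float = 0.5,
    stoichiometry: int = ELECTRONS_PER_NH2OH,
    seed: int = 0,
) -> ProgressCurve:
    """A550 progress curve: linear at the given substrate rate, then flat.

    The absorbance rises at the slope implied by the acceptor-reduction
    stoichiometry until the substrate is exhausted, after which it
    saturates; Gaussian absorbance noise is optional.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    consumed_uM = np.minimum(v_substrate_uM_min * t / 60.0, substrate_uM)
    a550 = consumed_uM * stoichiometry * depsilon_mM_cm * 1e-3
    if noise_sd > 0:
        a550 = a550 + rng.normal(0.0, noise_sd, size=t.shape)
    return ProgressCurve(
        times_s=t, a550=a550, substrate_uM=substrate_uM,
        enzyme_ug=enzyme_ug, volume_mL=volume_mL,
        depsilon_mM_cm=depsilon_mM_cm,
    )
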