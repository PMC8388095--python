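"""Interaction-surface extraction from a pose ensemble.

The preferred poses of the ensemble (lowest energies, or densest
occupancy voxels) are turned into a per-residue contact report on the
receptor: how often each residue is touched, its charge class, and how
close each heme cofactor comes to the ligand — the quantity that decides
whether a surface heme can serve as the electron outlet of the complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .mapping import OccupancyMap, PoseEnsemble, _quat_to_matrix, occupancy_map
from .structure import MolecularModel

__all__ = [
    "ChargeClass",
    "classify_residue",
    "select_top_poses",
    "contact_residues",
    "cofactor_in_interface",
    "InterfaceReport",
]

ChargeClass = Literal["negative", "positive", "neutral", "hydrophobic"]

#: every standard residue belongs to exactly one class
RESIDUE_CLASSES: dict[str, str] = {
    "ASP": "negative", "GLU": "negative",
    "LYS": "positive", "ARG": "positive", "HIS": "positive",
    "SER": "neutral", "THR": "neutral", "ASN": "neutral",
    "GLN": "neutral", "TYR": "neutral",
    "ALA": "hydrophobic", "VAL": "hydrophobic", "LEU": "hydrophobic",
    "ILE": "hydrophobic", "PHE": "hydrophobic", "MET": "hydrophobic",
    "TRP": "hydrophobic", "PRO": "hydrophobic", "GLY": "hydrophobic",
    "CYS": "hydrophobic",
}

DEFAULT_CONTACT_CUTOFF = 5.0     # Å
DEFAULT_FREQ_THRESHOLD = 0.25
DEFAULT_TOP_FRACTION = 0.1


def classify_residue(residue_name: str) -> str:
    """Charge class of a standard residue (unknown codes → neutral, warned)."""
    name = residue_name.strip().upper()
    try:
        return RESIDUE_CLASSES[name]
    except KeyError:
        warnings.warn(f"unknown residue code {name!r}: classified neutral", stacklevel=2)
        return "neutral"


class InterfaceEntry(NamedTuple):
    residue_id: int
    chain: str
    residue_name: str
    contact_frequency: float
    charge_class: str


class CofactorHit(NamedTuple):
    cofactor_id: str
    min_distance: float
    contact_frequency: float


@dataclass
class InterfaceReport:
    """Per-residue contact frequencies over the analysed poses."""

    entries: list[InterfaceEntry]
    cofactor_hits: list[CofactorHit]
    n_poses: int
    cutoff: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.entries)

    def frequency_of(self, residue_id: int, chain: str | None = None) -> float:
        for e in self.entries:
            if e.residue_id == residue_id and (chain is None or e.chain == chain):
                return e.contact_frequency
        return 0.0

    def cofactor(self, cofactor_id: str) -> CofactorHit:
        for hit in self.cofactor_hits:
            if hit.cofactor_id == cofactor_id:
                return hit
        raise KeyError(f"no cofactor {cofactor_id!r} in report")

    def summary(self, max_rows: int = 15) -> str:
        lines = [
            f"Interface report over {self.n_poses} poses (cutoff {self.cutoff:.1f} Å)",
            f"{'residue':>10s} {'chain':>5s} {'freq':>6s} {'class':>12s}",
        ]
        for e in self.entries[:max_rows]:
            lines.append(
                f"{e.residue_name + str(e.residue_id):>10s} {e.chain:>5s} "
                f"{e.contact_frequency:6.3f} {e.charge_class:>12s}"
            )
        for hit in self.cofactor_hits:
            lines.append(
                f"cofactor {hit.cofactor_id}: min distance {hit.min_distance:.2f} Å, "
                f"contact frequency {hit.contact_frequency:.3f}"
            )
        return "\n".join(lines)


def select_top_poses(
    ensemble: PoseEnsemble,
    mode: Literal["lowest_energy", "densest_voxels"] = "lowest_energy",
    fraction: float = DEFAULT_TOP_FRACTION,
    voxel_spacing: float = 2.0,
) -> PoseEnsemble:
    """Preferred-pose subset: lowest-energy fraction, or densest voxels.

    ``lowest_energy`` takes the bottom *fraction* of poses by energy
    (stable order, ties broken by index).  ``densest_voxels`` ranks
    occupancy voxels by count and keeps poses in the smallest voxel set
    that accumulates at least *fraction* of all counts.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(ensemble)
    if mode == "lowest_energy":
        k = max(1, int(np.floor(fraction * n + 1e-9)))
        idx = np.argsort(ensemble.energies, kind="stable")[:k]
        return ensemble.subset(np.sort(idx))
    if mode == "densest_voxels":
        occ: OccupancyMap = occupancy_map(ensemble, spacing=voxel_spacing)
        vox = np.floor((ensemble.translations - occ.origin) / occ.spacing).astype(int)
        vox = np.minimum(vox, np.array(occ.counts.shape) - 1)
        flat = np.ravel_multi_index(vox.T, occ.counts.shape)
        counts = occ.counts.reshape(-1)
        order = np.argsort(counts, kind="stable")[::-1]
        cum = np.cumsum(counts[order])
        n_keep = int(np.searchsorted(cum, fraction * n - 1e-9) + 1)
        keep = set(order[:n_keep].tolist())
        idx = np.nonzero(np.isin(flat, list(keep)))[0]
        return ensemble.subset(idx)
    raise ValueError(f"unknown mode {mode!r}")


def contact_residues(
    receptor: MolecularModel,
    ligand: MolecularModel,
    poses: PoseEnsemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InterfaceReport:
    """Contact frequencies of receptor residues over the given poses.

    A residue counts as a contact in a pose when any of its heavy atoms
    lies within *cutoff* of any transformed ligand heavy atom.  Heme
    cofactor atoms accumulate separately into ``cofactor_hits`` with
    their minimum approach distance over all poses.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(poses) == 0:
        raise ValueError("empty pose set")

    heavy_r = receptor.heavy_mask()
    rec_atoms = [a for a, h in zip(receptor.atoms, heavy_r) if h]
    rec_coords = receptor.coordinates()[heavy_r]
    tree = cKDTree(rec_coords)

    # residue key (or cofactor id) per receptor heavy atom
    res_keys: list[tuple] = []
    cof_ids: list[str | None] = []
    for a in rec_atoms:
        res_keys.append((a.chain, a.residue_id, a.residue_name))
        cof_ids.append(a.cofactor_id)

    lig_local = ligand.coordinates() - ligand.coordinates().mean(axis=0)
    lig_heavy = lig_local[ligand.heavy_mask()]

    res_counts: dict[tuple, int] = {}
    cof_counts: dict[str, int] = {str(c): 0 for c in receptor.hemes}
    cof_min: dict[str, float] = {str(c): np.inf for c in receptor.hemes}
    cof_atom_idx = {
        c: np.array([i for i, cid in enumerate(cof_ids) if cid == c])
        for c in receptor.hemes
    }

    n = len(poses)
    rotmats = _quat_to_matrix(poses.quaternions)
    for p in range(n):
        coords = lig_heavy @ rotmats[p].T + poses.translations[p]
        neighbours = tree.query_ball_point(coords, cutoff)
        hit_atoms = {i for nb in neighbours for i in nb}
        hit_res = set()
        hit_cof = set()
        for i in hit_atoms:
            cid = cof_ids[i]
            if cid is not None:
                hit_cof.add(cid)
            hit_res.add(res_keys[i])
        for key in hit_res:
            res_counts[key] = res_counts.get(key, 0) + 1
        for cid in hit_cof:
            cof_counts[cid] += 1
        for cid, idxs in cof_atom_idx.items():
            if len(idxs):
                d = np.linalg.norm(coords[:, None, :] - rec_coords[idxs][None, :, :], axis=2)
                cof_min[cid] = min(cof_min[cid], float(d.min()))

    entries = [
        InterfaceEntry(
            residue_id=key[1], chain=key[0], residue_name=key[2],
            contact_frequency=count / n,
            charge_class=classify_residue(key[2]) if key[2].upper() in RESIDUE_CLASSES
            else _classify_nonstandard(key[2]),
        )
        for key, count in res_counts.items()
    ]
    entries.sort(key=lambda e: (-e.contact_frequency, e.chain, e.residue_id))
    hits = [
        CofactorHit(cofactor_id=c, min_distance=cof_min[c], contact_frequency=cof_counts[c] / n)
        for c in sorted(cof_counts)
    ]
    return InterfaceReport(entries=entries, cofactor_hits=hits, n_poses=n, cutoff=cutoff)


def _classify_nonstandard(residue_name: str) -> str:
    """Non-standard residues are reported as neutral, silently for hemes."""
    if residue_name.strip().upper() in {"HEC", "HEM", "HEA", "HEB"}:
        return "neutral"
    return classify_residue(residue_name)


def cofactor_in_interface(
    report: InterfaceReport,
    cofactor_id: str,
    frequency_threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> tuple[bool, CofactorHit]:
    """Is the cofactor part of the predicted interaction surface?

    True iff its contact frequency over the analysed poses reaches
    *frequency_threshold*; the hit record (minimum distance, frequency)
    is returned alongside.
    """
    hit = report.cofactor(cofactor_id)
    return hit.contact_frequency >= frequency_threshold, hit
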