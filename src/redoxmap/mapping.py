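"""Rigid-body Metropolis Monte Carlo of a ligand in a receptor's field.

A small ligand protein performs random rigid-body moves (Gaussian
translations, small-angle rotations) in the fixed electrostatic field of
a receptor.  Moves are accepted by the Metropolis criterion at the
sampling temperature, producing a Boltzmann-weighted ensemble of mutual
positions and orientations — the transient-encounter picture appropriate
for redox protein pairs, where no single locked complex exists.

The interaction energy of a pose is the sum over ligand atoms of
q_j · φ(x_j) with φ interpolated from the receptor's potential grid
(kBT/e), so energies come out directly in kBT.  Ligand/receptor
heavy-atom overlap (closer than ``overlap_factor`` times the sum of
radii) is a hard clash: the pose gets an infinite energy and is never
accepted.  Atoms outside the grid box see φ = 0 (far field).

All runs advance in deterministic lockstep, vectorized across chains,
drawing from a single seeded PCG64 stream: the same seed always yields a
bit-identical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from scipy.spatial import cKDTree

from .grids import PotentialGrid
from .structure import MolecularModel, RedoxStateSpec

__all__ = [
    "MCConfig",
    "Pose",
    "PoseEnsemble",
    "OccupancyMap",
    "full_scale_config",
    "interaction_energy",
    "metropolis_accept",
    "metropolis_step",
    "run_mapping",
    "occupancy_map",
    "InteractionMapping",
    "MappingResults",
]

DEFAULT_OVERLAP_FACTOR = 0.8
_BIG_RADIUS = 3.0  # receptor atoms larger than this are clash-checked directly


@dataclass
class MCConfig:
    """Sampler configuration.

    The full-scale protocol is 1,000,000 runs of 25,000 steps at
    300 K with a 500 Å maximum centre-of-mass distance
    (:func:`full_scale_config`); the default here is a desk-scale
    configuration with the same move parameters.
    """

    n_runs: int = 2000
    n_steps: int = 5000
    temperature: float = 300.0
    d_max: float = 500.0
    translation_step: float = 2.0
    rotation_step: float = 0.2
    burn_in: int | None = None  # None -> 20% of n_steps
    record_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_steps // 5
        if self.n_runs < 1 or self.n_steps < 1:
            raise ValueError("n_runs and n_steps must be positive")
        if not (0 <= self.burn_in < self.n_steps):
            raise ValueError("need n_steps > burn_in >= 0")
        if self.d_max <= 0 or self.translation_step <= 0 or self.rotation_step <= 0:
            raise ValueError("d_max and step sizes must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_recorded_per_run(self) -> int:
        return (self.n_steps - self.burn_in) // self.record_every


def full_scale_config(seed: int = 0) -> MCConfig:
    """The full-scale sampling protocol (10^6 runs × 25,000 steps, 300 K, 500 Å)."""
    return MCConfig(n_runs=1_000_000, n_steps=25_000, temperature=300.0,
                    d_max=500.0, seed=seed)


# ----------------------------------------------------------------------
# quaternions (scalar-first), shared by sampler and single-pose API so a
# recorded pose re-evaluates to exactly the stored energy
# ----------------------------------------------------------------------

def _quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)

def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b for scalar-first quaternions (broadcasts)."""
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ], axis=-1)

def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) from unit scalar-first quaternions."""
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m

def _random_quats(rng: np.random.Generator, n: int) -> np.ndarray:
    q = rng.normal(size=(n, 4))
    return _quat_normalize(q)

def _axis_angle_quats(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    half = 0.5 * angles
    q = np.empty(axes.shape[:-1] + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1:] = axes * np.sin(half)[..., None]
    return q


@dataclass
class Pose:
    """One rigid-body placement of the ligand.

    ``translation`` is the ligand centre-of-mass position (Å, lab frame);
    ``rotation`` a unit quaternion (w, x, y, z) applied about the COM.
    ``energy`` is the interaction energy in kBT (at the grid temperature).
    """

    translation: np.ndarray
    rotation: np.ndarray
    energy: float = np.nan

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(4)
        norm = np.linalg.norm(self.rotation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"pose quaternion not normalized (|q| = {norm})")

    def rotation_matrix(self) -> np.ndarray:
        return _quat_to_matrix(self.rotation)


# ----------------------------------------------------------------------
# system context: everything the energy kernel needs, precomputed once
# ----------------------------------------------------------------------

@dataclass
class _System:
    lig_local: np.ndarray        # (Aq, 3) charged ligand atoms, COM frame
    lig_q: np.ndarray            # (Aq,) their charges (all non-zero)
    lig_heavy_local: np.ndarray  # (Ah, 3)
    lig_heavy_r: np.ndarray      # (Ah,)
    rec_com: np.ndarray
    reg_classes: list[tuple[cKDTree, float]]  # one tree per distinct radius
    big_coords: np.ndarray
    big_r: np.ndarray
    overlap: float
    clash_reach: float           # COM distance below which clash is possible
    lig_reach: float             # max atom distance from the ligand COM


def _prepare_system(receptor: MolecularModel, ligand: MolecularModel,
                    overlap: float = DEFAULT_OVERLAP_FACTOR) -> _System:
    lig_coords = ligand.coordinates()
    lig_com = lig_coords.mean(axis=0)
    lig_local = lig_coords - lig_com
    heavy_l = ligand.heavy_mask()

    rec_coords = receptor.coordinates()
    rec_radii = receptor.radii()
    heavy_r = receptor.heavy_mask()
    rec_com = rec_coords.mean(axis=0)

    big = heavy_r & (rec_radii > _BIG_RADIUS)
    reg = heavy_r & ~big
    reg_coords, reg_r = rec_coords[reg], rec_radii[reg]
    # exact clash tests stay vectorized by grouping atoms of equal radius;
    # tiny groups are cheaper as direct pairwise checks than as k-d queries
    reg_classes = []
    direct_coords, direct_r = [], []
    if len(reg_coords):
        key = np.round(reg_r, 6)
        for r in np.unique(key):
            mask = key == r
            if mask.sum() <= 4:
                direct_coords.append(reg_coords[mask])
                direct_r.append(reg_r[mask])
            else:
                reg_classes.append((cKDTree(reg_coords[mask]), float(reg_r[mask].max())))

    lig_heavy_reach = float(np.linalg.norm(lig_local[heavy_l], axis=1).max(initial=0.0))
    max_lig_r = float(ligand.radii()[heavy_l].max(initial=0.0))
    # per receptor atom: the largest COM distance at which it can clash
    rec_d = np.linalg.norm(rec_coords[heavy_r] - rec_com, axis=1)
    per_atom_reach = rec_d + overlap * (rec_radii[heavy_r] + max_lig_r)
    clash_reach = float(per_atom_reach.max(initial=0.0)) + lig_heavy_reach + 1e-9

    big_coords = rec_coords[big]
    big_r_arr = rec_radii[big]
    if direct_coords:
        big_coords = np.vstack([big_coords] + direct_coords)
        big_r_arr = np.concatenate([big_r_arr] + direct_r)

    charged = ligand.charges() != 0.0
    return _System(
        lig_local=lig_local[charged],
        lig_q=ligand.charges()[charged],
        lig_heavy_local=lig_local[heavy_l],
        lig_heavy_r=ligand.radii()[heavy_l],
        rec_com=rec_com,
        reg_classes=reg_classes,
        big_coords=big_coords,
        big_r=big_r_arr,
        overlap=overlap,
        clash_reach=clash_reach,
        lig_reach=float(np.linalg.norm(lig_local[charged], axis=1).max(initial=0.0)),
    )


def _clash_flags(sys: _System, trans: np.ndarray, rotmats: np.ndarray) -> np.ndarray:
    """Exact heavy-atom overlap test per chain (pair distance < overlap·(rᵢ+rⱼ))."""
    C = len(trans)
    flags = np.zeros(C, dtype=bool)
    cand = np.linalg.norm(trans - sys.rec_com, axis=1) < sys.clash_reach
    idx = np.nonzero(cand)[0]
    if len(idx) == 0:
        return flags
    coords = np.matmul(rotmats[idx], sys.lig_heavy_local.T).transpose(0, 2, 1) \
        + trans[idx][:, None, :]
    K, Ah = coords.shape[:2]
    pts = coords.reshape(-1, 3)
    hit = np.zeros(K * Ah, dtype=bool)
    lig_r = np.tile(sys.lig_heavy_r, K)
    if len(sys.big_coords):
        d = np.linalg.norm(pts[:, None, :] - sys.big_coords[None, :, :], axis=2)
        cut = sys.overlap * (lig_r[:, None] + sys.big_r[None, :])
        hit |= np.any(d < cut, axis=1)
    for tree, r_class in sys.reg_classes:
        dnn, _ = tree.query(pts, k=1)
        hit |= dnn < sys.overlap * (lig_r + r_class)
    flags[idx] = hit.reshape(K, Ah).any(axis=1)
    return flags


def _batch_energies(sys: _System, grid: PotentialGrid,
                    trans: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """Interaction energies (kBT) for a batch of poses; clash → +inf.

    Chains whose every atom lies outside the grid box see φ = 0 (far
    field) and are skipped without rotating or interpolating anything.
    """
    C = len(trans)
    energies = np.zeros(C)
    lo = grid.origin - sys.lig_reach
    hi = grid.upper_corner + sys.lig_reach
    near = np.all((trans >= lo) & (trans <= hi), axis=1)
    # a grid smaller than the receptor must not bypass the clash test
    near |= np.linalg.norm(trans - sys.rec_com, axis=1) < sys.clash_reach
    if np.any(near):
        rotmats = _quat_to_matrix(quats[near])
        coords = np.matmul(rotmats, sys.lig_local.T).transpose(0, 2, 1) + trans[near][:, None, :]
        K, A = coords.shape[:2]
        phi = np.asarray(grid.sample(coords.reshape(-1, 3))).reshape(K, A)
        e_near = (phi * sys.lig_q[None, :]).sum(axis=1)
        e_near[_clash_flags(sys, trans[near], rotmats)] = np.inf
        energies[near] = e_near
    return energies


def interaction_energy(
    ligand: MolecularModel,
    pose: Pose,
    grid: PotentialGrid,
    receptor: MolecularModel,
    overlap_factor: float = DEFAULT_OVERLAP_FACTOR,
) -> float:
    """Energy of one pose: Σⱼ qⱼ φ(R xⱼ + t) in kBT; +inf on hard clash.

    Uses the same vectorized kernel as :func:`run_mapping`, so a recorded
    pose re-evaluates to exactly its stored energy.
    """
    sys = _prepare_system(receptor, ligand, overlap_factor)
    return float(_batch_energies(sys, grid, pose.translation[None, :], pose.rotation[None, :])[0])


# ----------------------------------------------------------------------
# Metropolis
# ----------------------------------------------------------------------

def metropolis_accept(delta_e: float | np.ndarray, rng: np.random.Generator):
    """Metropolis rule: accept with probability min(1, exp(−ΔE)), ΔE in kBT."""
    delta = np.asarray(delta_e, dtype=float)
    p = np.exp(-np.maximum(delta, 0.0))
    u = rng.random(delta.shape) if delta.shape else rng.random()
    return u < p


def _propose(rng: np.random.Generator, trans: np.ndarray, quats: np.ndarray,
             config: MCConfig) -> tuple[np.ndarray, np.ndarray]:
    C = len(trans)
    new_t = trans + rng.normal(0.0, config.translation_step, size=(C, 3))
    axes = rng.normal(size=(C, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, config.rotation_step, size=C)
    new_q = _quat_normalize(_quat_multiply(_axis_angle_quats(axes, angles), quats))
    return new_t, new_q


def metropolis_step(
    pose: Pose,
    config: MCConfig,
    grid: PotentialGrid,
    receptor: MolecularModel,
    ligand: MolecularModel,
    rng: np.random.Generator,
) -> Pose:
    """One Metropolis step on a single pose.

    Proposes a Gaussian translation and a small-angle rotation, rejects
    proposals whose COM leaves the d_max sphere around the receptor COM,
    and otherwise accepts with probability min(1, exp(−ΔE/kBT)).  On
    rejection the previous pose is returned unchanged.
    """
    sys = _prepare_system(receptor, ligand)
    e_old = pose.energy
    if not np.isfinite(e_old):
        e_old = float(_batch_energies(sys, grid, pose.translation[None, :],
                                      pose.rotation[None, :])[0])
    new_t, new_q = _propose(rng, pose.translation[None, :], pose.rotation[None, :], config)
    beta_scale = grid.temperature / config.temperature
    if np.linalg.norm(new_t[0] - sys.rec_com) > config.d_max:
        return replace(pose, energy=e_old)
    e_new = float(_batch_energies(sys, grid, new_t, new_q)[0])
    if metropolis_accept((e_new - e_old) * beta_scale, rng):
        return Pose(translation=new_t[0], rotation=new_q[0], energy=e_new)
    return replace(pose, energy=e_old)


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------

@dataclass
class PoseEnsemble:
    """Boltzmann-sampled rigid-body poses with their interaction energies."""

    translations: np.ndarray       # (N, 3)
    quaternions: np.ndarray        # (N, 4) scalar-first
    energies: np.ndarray           # (N,) kBT
    run_index: np.ndarray          # (N,)
    config: MCConfig
    receptor_name: str = ""
    ligand_name: str = ""
    redox_state: RedoxStateSpec | None = None
    acceptance_rate: float = np.nan

    def __len__(self) -> int:
        return len(self.energies)

    def poses(self) -> Iterator[Pose]:
        for t, q, e in zip(self.translations, self.quaternions, self.energies):
            yield Pose(translation=t, rotation=q, energy=float(e))

    def subset(self, indices: np.ndarray) -> "PoseEnsemble":
        indices = np.asarray(indices)
        return PoseEnsemble(
            translations=self.translations[indices],
            quaternions=self.quaternions[indices],
            energies=self.energies[indices],
            run_index=self.run_index[indices],
            config=self.config,
            receptor_name=self.receptor_name,
            ligand_name=self.ligand_name,
            redox_state=self.redox_state,
            acceptance_rate=self.acceptance_rate,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "run": self.run_index,
            "tx": self.translations[:, 0], "ty": self.translations[:, 1],
            "tz": self.translations[:, 2],
            "qw": self.quaternions[:, 0], "qx": self.quaternions[:, 1],
            "qy": self.quaternions[:, 2], "qz": self.quaternions[:, 3],
            "energy_kBT": self.energies,
        })

    def save(self, path: str | Path) -> None:
        """One pose per line: run tx ty tz qw qx qy qz energy."""
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, path: str | Path, config: MCConfig | None = None) -> "PoseEnsemble":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            translations=df[["tx", "ty", "tz"]].to_numpy(),
            quaternions=df[["qw", "qx", "qy", "qz"]].to_numpy(),
            energies=df["energy_kBT"].to_numpy(),
            run_index=df["run"].to_numpy(),
            config=config or MCConfig(),
        )


def _random_starts(rng: np.random.Generator, n: int, center: np.ndarray,
                   d_max: float) -> tuple[np.ndarray, np.ndarray]:
    u = rng.random(n)
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = d_max * np.cbrt(u)  # uniform in the d_max ball
    return center + radii[:, None] * directions, _random_quats(rng, n)


def run_mapping(
    receptor: MolecularModel,
    ligand: MolecularModel,
    grid: PotentialGrid,
    config: MCConfig,
    redox_state: RedoxStateSpec | None = None,
    max_start_retries: int = 100,
) -> PoseEnsemble:
    """Run the full mapping: ``n_runs`` chains of ``n_steps`` Metropolis steps.

    Each run starts from a uniformly random pose inside the d_max ball
    (uniform random orientation); clashing starts are resampled.  After
    ``burn_in`` steps, poses are recorded every ``record_every`` steps,
    giving ``n_runs × ⌊(n_steps − burn_in)/record_every⌋`` poses.  All
    chains advance in lockstep from one seeded stream, so an identical
    seed yields a bit-identical ensemble.
    """
    sys = _prepare_system(receptor, ligand)
    rng = np.random.default_rng(config.seed)
    C = config.n_runs
    beta_scale = grid.temperature / config.temperature

    trans, quats = _random_starts(rng, C, sys.rec_com, config.d_max)
    energies = _batch_energies(sys, grid, trans, quats)
    for _ in range(max_start_retries):
        bad = ~np.isfinite(energies)
        if not np.any(bad):
            break
        n_bad = int(bad.sum())
        trans[bad], quats[bad] = _random_starts(rng, n_bad, sys.rec_com, config.d_max)
        energies[bad] = _batch_energies(sys, grid, trans[bad], quats[bad])
    else:
        raise RuntimeError("could not find clash-free starting poses")

    n_rec = config.n_recorded_per_run
    rec_t = np.empty((n_rec, C, 3))
    rec_q = np.empty((n_rec, C, 4))
    rec_e = np.empty((n_rec, C))
    accepted = 0
    rec_slot = 0

    for step in range(config.n_steps):
        new_t, new_q = _propose(rng, trans, quats, config)
        in_bounds = np.linalg.norm(new_t - sys.rec_com, axis=1) <= config.d_max
        new_e = np.full(C, np.inf)
        if np.any(in_bounds):
            new_e[in_bounds] = _batch_energies(sys, grid, new_t[in_bounds], new_q[in_bounds])
        # one uniform draw per chain per step keeps the stream layout fixed
        accept = metropolis_accept((new_e - energies) * beta_scale, rng) & in_bounds
        trans[accept] = new_t[accept]
        quats[accept] = new_q[accept]
        energies[accept] = new_e[accept]
        accepted += int(accept.sum())

        k = step - config.burn_in + 1
        if k > 0 and k % config.record_every == 0:
            rec_t[rec_slot] = trans
            rec_q[rec_slot] = quats
            rec_e[rec_slot] = energies
            rec_slot += 1

    order = np.transpose  # (n_rec, C, ...) -> grouped by run
    return PoseEnsemble(
        translations=order(rec_t, (1, 0, 2)).reshape(-1, 3),
        quaternions=order(rec_q, (1, 0, 2)).reshape(-1, 4),
        energies=rec_e.T.reshape(-1),
        run_index=np.repeat(np.arange(C), n_rec),
        config=config,
        receptor_name=receptor.name,
        ligand_name=ligand.name,
        redox_state=redox_state,
        acceptance_rate=accepted / (C * config.n_steps),
    )


# ----------------------------------------------------------------------
# occupancy maps
# ----------------------------------------------------------------------

@dataclass
class OccupancyMap:
    """Voxel histogram of ligand COM positions."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def occupancy_map(
    ensemble: PoseEnsemble,
    grid: PotentialGrid | None = None,
    spacing: float = 2.0,
) -> OccupancyMap:
    """Histogram the ensemble's ligand COM positions over voxels.

    With *grid* given, its geometry is reused (poses outside its box are
    dropped); otherwise the box is fitted to the poses so that every pose
    is counted.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    pts = ensemble.translations
    if grid is not None:
        origin = grid.origin - grid.spacing / 2
        spacing = grid.spacing
        nbins = np.array(grid.dims)
    else:
        lo = pts.min(axis=0) - 1e-9
        hi = pts.max(axis=0) + 1e-9
        nbins = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
        origin = lo
    edges = [origin[i] + spacing * np.arange(nbins[i] + 1) for i in range(3)]
    counts, _ = np.histogramdd(pts, bins=edges)
    return OccupancyMap(origin=origin, spacing=spacing, counts=counts)


# ----------------------------------------------------------------------
# model-style front end
# ----------------------------------------------------------------------

class InteractionMapping:
    """Model object tying receptor, ligand, field and sampler together.

    Parameters
    ----------
    receptor, ligand : MolecularModel
        Charged structures (receptor fixed, ligand mobile).
    grid : PotentialGrid, optional
        Receptor potential; computed with the stated buffer/spacing when
        omitted.
    config : MCConfig, optional
    redox : RedoxStateSpec, optional
        Heme oxidation states; applied to whichever of the two molecules
        carries each named heme before the field is computed.
    """

    def __init__(
        self,
        receptor: MolecularModel,
        ligand: MolecularModel,
        grid: PotentialGrid | None = None,
        config: MCConfig | None = None,
        redox: RedoxStateSpec | None = None,
        *,
        buffer=None,
        spacing: float = 1.0,
        padding: float = 20.0,
        dielectric: float = 78.5,
    ) -> None:
        from .charges import set_redox_state

        self.config = config or MCConfig()
        self.redox = redox
        if redox is not None:
            rec_states = {h: s for h, s in redox.state_by_heme.items() if h in receptor.hemes}
            lig_states = {h: s for h, s in redox.state_by_heme.items() if h in ligand.hemes}
            unknown = set(redox.state_by_heme) - set(rec_states) - set(lig_states)
            if unknown:
                raise KeyError(f"redox spec names hemes in neither molecule: {sorted(unknown)}")
            if rec_states:
                receptor = set_redox_state(receptor, RedoxStateSpec(rec_states))
            if lig_states:
                ligand = set_redox_state(ligand, RedoxStateSpec(lig_states))
        self.receptor = receptor
        self.ligand = ligand
        if grid is None:
            from .electrostatics import potential_grid

            grid = potential_grid(
                receptor, spacing=spacing, padding=padding, buffer=buffer,
                temperature=self.config.temperature, dielectric=dielectric,
            )
        self.grid = grid

    def run(self, seed: int | None = None) -> "MappingResults":
        config = self.config if seed is None else replace(self.config, seed=seed)
        ensemble = run_mapping(self.receptor, self.ligand, self.grid, config,
                               redox_state=self.redox)
        return MappingResults(self, ensemble)


class MappingResults:
    """Results of a mapping run: the pose ensemble plus analysis helpers."""

    def __init__(self, model: InteractionMapping, ensemble: PoseEnsemble) -> None:
        self.model = model
        self.ensemble = ensemble

    def occupancy(self, grid: PotentialGrid | None = None, spacing: float = 2.0) -> OccupancyMap:
        return occupancy_map(self.ensemble, grid=grid, spacing=spacing)

    def top_poses(self, mode: Literal["lowest_energy", "densest_voxels"] = "lowest_energy",
                  fraction: float = 0.1) -> PoseEnsemble:
        from .interface import select_top_poses

        return select_top_poses(self.ensemble, mode=mode, fraction=fraction)

    def interface_report(self, cutoff: float = 5.0, fraction: float = 0.1,
                         mode: Literal["lowest_energy", "densest_voxels"] = "lowest_energy"):
        from .interface import contact_residues

        top = self.top_poses(mode=mode, fraction=fraction)
        return contact_residues(self.model.receptor, self.model.ligand, top, cutoff=cutoff)

    def summary(self) -> str:
        e = self.ensemble.energies
        finite = e[np.isfinite(e)]
        cfg = self.ensemble.config
        lines = [
            "Monte Carlo interaction mapping",
            "=" * 48,
            f"receptor: {self.ensemble.receptor_name or '<unnamed>'}   "
            f"ligand: {self.ensemble.ligand_name or '<unnamed>'}",
            f"runs: {cfg.n_runs}   steps/run: {cfg.n_steps}   T: {cfg.temperature} K",
            f"d_max: {cfg.d_max} Å   recorded poses: {len(self.ensemble)}",
            f"acceptance rate: {self.ensemble.acceptance_rate:.3f}",
            f"energy (kBT): min {finite.min():.3f}   mean {finite.mean():.3f}   "
            f"median {np.median(finite):.3f}",
        ]
        if self.ensemble.redox_state is not None:
            states = ", ".join(f"{k}={v}" for k, v in
                               sorted(self.ensemble.redox_state.state_by_heme.items()))
            lines.append(f"heme states: {states}")
        return "\n".join(lines)
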