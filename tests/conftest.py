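"""Shared fixtures: the synthetic specificity system and its mapping runs.

The desk-scale specificity experiment (positive-patch receptor vs the
geometry-identical negative/positive ring ligands) is expensive, so it
runs once per session and is shared by the sampler, interface and
acceptance tests.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import redoxmap as rm
from redoxmap.synthetic import specificity_pair

# desk-scale study conditions for the synthetic specificity experiment
DESK_D_MAX = 75.0          # Å; ~3 receptor radii of travel
GRID_SPACING = 2.0         # Å
GRID_PADDING = 20.0        # Å
PHOSPHATE_M = 0.020        # mol/L, pH 7 potassium phosphate
PATCH_DIRECTION = np.array([0.0, 0.0, 1.0])


def desk_config(seed: int, n_runs: int = 2000, n_steps: int = 5000) -> rm.MCConfig:
    return rm.MCConfig(n_runs=n_runs, n_steps=n_steps, d_max=DESK_D_MAX, seed=seed)


PATCH_HALF_ANGLE_DEG = 30.0


def patch_enrichment(ensemble: rm.PoseEnsemble, direction: np.ndarray,
                     half_angle_deg: float = PATCH_HALF_ANGLE_DEG) -> float:
    """Pose-density enrichment over the patch.

    Ratio of pose counts inside the cone of the patch half-angle around
    the patch axis to counts in the antipodal cone of equal solid angle
    (equal volumes, so the count ratio is the density ratio).
    """
    d = ensemble.translations @ direction
    r = np.linalg.norm(ensemble.translations, axis=1)
    cos_half = np.cos(np.radians(half_angle_deg))
    with np.errstate(invalid="ignore"):
        cosine = np.where(r > 0, d / np.maximum(r, 1e-12), 0.0)
    in_patch = (cosine >= cos_half).sum()
    in_antipode = (cosine <= -cos_half).sum()
    return in_patch / max(in_antipode, 1)


@pytest.fixture(scope="session")
def patch_system():
    receptor, neg, pos = specificity_pair(seed=0)
    grid = rm.potential_grid(
        receptor, spacing=GRID_SPACING, padding=GRID_PADDING,
        buffer=rm.BufferSpec.phosphate(PHOSPHATE_M),
    )
    return SimpleNamespace(
        receptor=receptor, neg=neg, pos=pos, grid=grid,
        patch_dir=PATCH_DIRECTION, d_max=DESK_D_MAX,
        patch_residue_ids=[a.residue_id for a in receptor.atoms if a.residue_name == "ARG"],
        # residues under the footprint of a patch-centred ligand (12 deg cone)
        patch_core_residue_ids=[
            a.residue_id for a in receptor.atoms
            if a.residue_name == "ARG"
            and a.position @ PATCH_DIRECTION / np.linalg.norm(a.position)
            >= np.cos(np.radians(12.0))
        ],
        antipode_residue_ids=[
            a.residue_id for a in receptor.atoms
            if a.residue_name == "GLY" and a.position @ PATCH_DIRECTION < -20.0
        ],
    )


@pytest.fixture(scope="session")
def specificity_runs(patch_system):
    s = patch_system
    ens_neg = rm.run_mapping(s.receptor, s.neg, s.grid, desk_config(seed=101))
    ens_pos = rm.run_mapping(s.receptor, s.pos, s.grid, desk_config(seed=102))
    top_neg = rm.select_top_poses(ens_neg, fraction=0.1)
    top_pos = rm.select_top_poses(ens_pos, fraction=0.1)
    report_neg = rm.contact_residues(s.receptor, s.neg, top_neg)
    report_pos = rm.contact_residues(s.receptor, s.pos, top_pos)
    return SimpleNamespace(
        system=s,
        neg=ens_neg, pos=ens_pos,
        top_neg=top_neg, top_pos=top_pos,
        report_neg=report_neg, report_pos=report_pos,
    )
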