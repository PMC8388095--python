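"""Metropolis sampler: acceptance rule, Boltzmann statistics, bookkeeping."""

import numpy as np
import pytest

import redoxmap as rm
from redoxmap.structure import Atom, MolecularModel
from conftest import patch_enrichment


def single_atom_model(charge=0.0, radius=0.0, position=(0.0, 0.0, 0.0), name="C"):
    return MolecularModel(atoms=[Atom(
        serial=1, name=name, residue_name="CHG", residue_id=1, chain="A",
        position=np.asarray(position, dtype=float), charge=charge, radius=radius,
    )])


def constant_grid(value, half_width=30.0, spacing=2.0):
    n = int(2 * half_width / spacing) + 1
    return rm.PotentialGrid(origin=np.full(3, -half_width), spacing=spacing,
                            values=np.full((n, n, n), float(value)))


def step_grid(low, high, half_width=30.0, spacing=2.0):
    """phi = low for x < 0, high for x >= 0."""
    n = int(2 * half_width / spacing) + 1
    x = -half_width + spacing * np.arange(n)
    vals = np.where(x[:, None, None] < 0, low, high) * np.ones((n, n, n))
    return rm.PotentialGrid(origin=np.full(3, -half_width), spacing=spacing, values=vals)


def identity_pose(position=(0.0, 0.0, 0.0), energy=np.nan):
    return rm.Pose(translation=np.asarray(position, dtype=float),
                   rotation=np.array([1.0, 0.0, 0.0, 0.0]), energy=energy)


class TestInteractionEnergy:
    def test_neutral_ligand_zero_everywhere(self):
        lig = single_atom_model(charge=0.0)
        rec = single_atom_model(position=(50, 50, 50))
        grid = constant_grid(-3.0)
        for pos in [(0, 0, 0), (5, -5, 2), (20, 20, -20)]:
            assert rm.interaction_energy(lig, identity_pose(pos), grid, rec) == 0.0

    def test_unit_charge_reads_local_potential(self):
        lig = single_atom_model(charge=1.0)
        rec = single_atom_model(position=(50, 50, 50))
        grid = constant_grid(-2.0)
        assert rm.interaction_energy(lig, identity_pose((4, 4, 4)), grid, rec) == \
            pytest.approx(-2.0)

    def test_matches_direct_pairwise_sum_within_grid_bound(self, patch_system):
        """Grid-interpolated energies vs the direct screened-Coulomb sum."""
        s = patch_system
        kappa = rm.debye_kappa(s.grid.ionic_strength, s.grid.temperature, s.grid.dielectric)
        rng = np.random.default_rng(3)
        lig_local = s.neg.coordinates() - s.neg.coordinates().mean(axis=0)
        q = s.neg.charges()
        for _ in range(10):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            t = direction * rng.uniform(36.0, 42.0)  # clash-free shell inside the grid
            pose = identity_pose(t)
            e_grid = rm.interaction_energy(s.neg, pose, s.grid, s.receptor)
            pts = lig_local + t
            e_direct = float(np.sum(q * rm.potential_at(
                s.receptor, pts, kappa=kappa,
                temperature=s.grid.temperature, dielectric=s.grid.dielectric)))
            bound = float(np.sum(np.abs(q) * rm.interpolation_error_bound(
                s.receptor, s.grid, pts)))
            assert abs(e_grid - e_direct) <= bound

    def test_clash_is_infinite(self):
        lig = single_atom_model(charge=1.0, radius=1.7)
        rec = single_atom_model(charge=0.0, radius=1.7, position=(0, 0, 0))
        grid = constant_grid(0.0)
        assert rm.interaction_energy(lig, identity_pose((0, 0, 1.0)), grid, rec) == np.inf
        # just outside 0.8*(1.7+1.7) = 2.72 A: no clash
        assert rm.interaction_energy(lig, identity_pose((0, 0, 2.8)), grid, rec) == 0.0


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        deltas = np.array([-5.0, -0.1, 0.0])
        assert rm.metropolis_accept(deltas, rng).all()

    def test_acceptance_at_one_kt_matches_exp_minus_one(self):
        """P(accept | dE = 1 kBT) = 1/e within 3 sigma over 1e5 trials."""
        rng = np.random.default_rng(2024)
        n = 100_000
        accepted = rm.metropolis_accept(np.ones(n), rng)
        p_hat = accepted.mean()
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * sigma

    def test_infinite_delta_never_accepted(self):
        rng = np.random.default_rng(0)
        assert not rm.metropolis_accept(np.full(1000, np.inf), rng).any()

    def test_single_step_returns_valid_pose(self):
        lig = single_atom_model(charge=1.0)
        rec = single_atom_model(position=(0, 0, 0))
        grid = step_grid(0.0, 2.0)
        cfg = rm.MCConfig(n_runs=1, n_steps=10, d_max=25.0, seed=0)
        rng = np.random.default_rng(5)
        pose = identity_pose((5.0, 0, 0))
        for _ in range(50):
            pose = rm.metropolis_step(pose, cfg, grid, rec, lig, rng)
            assert np.linalg.norm(pose.translation) <= cfg.d_max + 1e-9
            assert abs(np.linalg.norm(pose.rotation) - 1) < 1e-9
            assert np.isfinite(pose.energy)


class TestRunMapping:
    def _tiny_system(self):
        lig = single_atom_model(charge=1.0)
        rec = single_atom_model(position=(0, 0, 0))
        return rec, lig, constant_grid(0.0, half_width=20.0)

    def test_recorded_pose_count(self):
        rec, lig, grid = self._tiny_system()
        cfg = rm.MCConfig(n_runs=2, n_steps=100, burn_in=0, record_every=10,
                          d_max=15.0, seed=1)
        ens = rm.run_mapping(rec, lig, grid, cfg)
        assert len(ens) == 20

    def test_seed_determinism_bit_identical(self):
        rec, lig, grid = self._tiny_system()
        cfg = rm.MCConfig(n_runs=5, n_steps=200, d_max=15.0, seed=42)
        a = rm.run_mapping(rec, lig, grid, cfg)
        b = rm.run_mapping(rec, lig, grid, cfg)
        np.testing.assert_array_equal(a.translations, b.translations)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_energy_bookkeeping_is_exact(self, specificity_runs):
        """Re-evaluating recorded poses reproduces stored energies bit-for-bit."""
        s = specificity_runs.system
        ens = specificity_runs.neg
        idx = np.linspace(0, len(ens) - 1, 25).astype(int)
        for i in idx:
            pose = rm.Pose(translation=ens.translations[i],
                           rotation=ens.quaternions[i])
            assert rm.interaction_energy(s.neg, pose, s.grid, s.receptor) == \
                ens.energies[i]

    def test_patch_enrichment_at_least_tenfold(self, specificity_runs):
        """Negative ligand density concentrates over the positive patch."""
        enrich = patch_enrichment(specificity_runs.neg,
                                  specificity_runs.system.patch_dir)
        assert enrich >= 10.0

    def test_two_pocket_occupancy_follows_boltzmann(self):
        """Step field of 2 kBT: occupancy ratio ~ e^-2 after long sampling."""
        lig = single_atom_model(charge=1.0)
        rec = single_atom_model(position=(0, 0, 0))
        grid = step_grid(0.0, 2.0, half_width=30.0, spacing=2.0)
        cfg = rm.MCConfig(n_runs=400, n_steps=3000, burn_in=600, record_every=20,
                          translation_step=6.0, d_max=28.0, seed=9)
        ens = rm.run_mapping(rec, lig, grid, cfg)
        x = ens.translations[:, 0]
        slab = 2.0  # exclude the interpolation slab around the step
        ratio = (x > slab).sum() / (x < -slab).sum()
        assert ratio == pytest.approx(np.exp(-2.0), rel=0.15)

    def test_halving_translation_step_keeps_density_maximum(self, patch_system):
        """Move size changes acceptance, not where the density peaks."""
        s = patch_system
        base = rm.MCConfig(n_runs=300, n_steps=1500, d_max=s.d_max, seed=3)
        small = rm.MCConfig(n_runs=300, n_steps=1500, d_max=s.d_max, seed=3,
                            translation_step=base.translation_step / 2)
        ens_a = rm.run_mapping(s.receptor, s.neg, s.grid, base)
        ens_b = rm.run_mapping(s.receptor, s.neg, s.grid, small)
        assert ens_a.acceptance_rate != pytest.approx(ens_b.acceptance_rate, abs=1e-3)
        for ens in (ens_a, ens_b):
            occ = rm.occupancy_map(ens, spacing=5.0)
            peak = np.unravel_index(np.argmax(occ.counts), occ.counts.shape)
            center = occ.origin + (np.array(peak) + 0.5) * occ.spacing
            assert center @ s.patch_dir > 0  # peak sits in the patch hemisphere


class TestOccupancy:
    def test_single_pose_single_voxel(self):
        rec, lig, grid = TestRunMapping()._tiny_system()
        cfg = rm.MCConfig(n_runs=1, n_steps=2, burn_in=0, record_every=2,
                          d_max=15.0, seed=0)
        ens = rm.run_mapping(rec, lig, grid, cfg)
        occ = rm.occupancy_map(ens, spacing=4.0)
        assert occ.total == 1
        assert (occ.counts == 1).sum() == 1

    def test_counts_conserved(self, specificity_runs):
        occ = rm.occupancy_map(specificity_runs.neg, spacing=4.0)
        assert occ.total == len(specificity_runs.neg)

    def test_uniform_field_no_hotspots(self):
        """Zero field: no voxel (well inside the ball) exceeds 5x uniform."""
        lig = single_atom_model(charge=1.0)
        rec = single_atom_model(position=(0, 0, 0))
        grid = constant_grid(0.0, half_width=30.0)
        cfg = rm.MCConfig(n_runs=400, n_steps=1000, burn_in=200, record_every=25,
                          translation_step=8.0, d_max=60.0, seed=4)
        ens = rm.run_mapping(rec, lig, grid, cfg)
        spacing = 15.0
        occ = rm.occupancy_map(ens, spacing=spacing)
        centers = [occ.origin[i] + (np.arange(n) + 0.5) * spacing
                   for i, n in enumerate(occ.counts.shape)]
        xx, yy, zz = np.meshgrid(*centers, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        interior = r < cfg.d_max - spacing  # voxels fully inside the ball
        expected = occ.counts[interior].mean()
        assert occ.counts[interior].max() <= 5 * expected

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            rm.occupancy_map(rm.PoseEnsemble(
                translations=np.empty((0, 3)), quaternions=np.empty((0, 4)),
                energies=np.empty(0), run_index=np.empty(0, dtype=int),
                config=rm.MCConfig()))


class TestEnsembleIO:
    def test_save_load_roundtrip(self, tmp_path):
        rec, lig, grid = TestRunMapping()._tiny_system()
        cfg = rm.MCConfig(n_runs=3, n_steps=100, d_max=15.0, seed=8)
        ens = rm.run_mapping(rec, lig, grid, cfg)
        p = tmp_path / "poses.tsv"
        ens.save(p)
        back = rm.PoseEnsemble.load(p, config=cfg)
        np.testing.assert_allclose(back.translations, ens.translations, rtol=1e-9)
        np.testing.assert_allclose(back.energies, ens.energies, rtol=1e-9)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_steps=10, burn_in=10),
        dict(d_max=-1.0),
        dict(record_every=0),
        dict(translation_step=0.0),
        dict(temperature=-5.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rm.MCConfig(**kwargs)

    def test_full_scale_protocol(self):
        cfg = rm.full_scale_config()
        assert (cfg.n_runs, cfg.n_steps) == (1_000_000, 25_000)
        assert cfg.temperature == 300.0 and cfg.d_max == 500.0
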