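# redoxmap

Electrostatics-driven mapping of redox-partner specificity, with the
accompanying spectroelectrochemical and enzyme-kinetic analyses.

## The problem

Multiheme redox enzymes exchange electrons with small c-type cytochrome
shuttles through transient, electrostatically steered encounters rather
than stable complexes.  Whether a given cytochrome is a competent
partner is then largely a question of surface charge complementarity:
a charged patch around the enzyme's electron-outlet heme concentrates
and pre-orients ligands of opposite charge.  Strikingly, two cytochromes
with nearly identical folds and midpoint potentials can differ
completely as electron acceptors when the surface ring around their heme
carries opposite charge.

`redoxmap` is for structural bioinformaticians and bioenergetics groups
who want to test such steering hypotheses computationally and analyse
the matching bench data.  It provides:

* **Rigid-body Metropolis Monte Carlo interaction mapping** — a ligand
  protein moves in the receptor's electrostatic field,
  E = Σⱼ qⱼ φ(R xⱼ + t), with Gaussian translation/rotation moves,
  hard-core clash rejection and the Metropolis criterion at 300 K,
  yielding a Boltzmann-weighted pose ensemble
  (1,000,000 runs × 25,000 steps at full scale; a desk-scale default of
  2,000 × 5,000 resolves synthetic systems in minutes);
* **screened-Coulomb electrostatics** —
  φ(x) = Σᵢ qᵢ e^{−κrᵢ}/(4πε₀ε_r rᵢ) in kBT/e on a uniform grid, with κ
  from the buffer ionic strength (20 mM pH-7 phosphate → I ≈ 35.5 mM),
  ±1 kBT/e isopotential masks, and OpenDX import/export for grids from
  full Poisson–Boltzmann solvers;
* **interface reports** — per-residue contact frequencies over the
  preferred poses, charge-class labels, and heme-cofactor proximity
  (is the candidate electron-outlet heme part of the interface?);
* **Nernst fitting** — A(E) = A_ox + a/(1 + exp(nF(E−E_m)/RT)) with
  n = 1, T = 293 K, joint over per-limb-normalised oxidative/reductive
  limbs of multiple experiments, referenced to SHE;
* **Michaelis–Menten kinetics** — initial rates from 550 nm progress
  curves via Δε₅₅₀ and the 3-electron stoichiometry of NH₂OH → NO,
  v = Vmax·S/(Km+S) fits, and kcat = Vmax·M·10⁻³/60, kcat/Km;
* **synthetic generators** for all of the above with known ground truth:
  a positive-patch receptor with surface hemes, geometry-identical
  negative/positive ring ligands, titration curves with hysteresis, and
  noisy rate tables.

See `docs/methods.md` for the models, assumptions and limitations.

## Worked example

Fit a two-experiment titration simulated at a midpoint of +268 mV, then
a triplicate rate table simulated at (Vmax 15.8, Km 13.9):

```python
import redoxmap as rm
from redoxmap.synthetic import simulate_titration, simulate_rates

curves, _ = simulate_titration(268.0, noise_sd=0.02, experiment_seeds=[3, 4])
print(rm.fit_nernst(curves).summary())

points, _ = simulate_rates(15.8, 13.9, noise_frac=0.03, seed=7)
print(rm.fit_mm(points).summary(molar_mass_g_mol=1.84e5))
```

```
Nernst fit (joint over limbs/experiments)
============================================
E_m          268.40 ± 1.63 mV vs SHE
A_ox        -0.7851
amplitude    1.7700
n                 1 (fixed)   T = 293 K
RSS       1.469e-01 over 100 points, 4 limbs

Michaelis-Menten fit
========================================
Vmax     15.29 ± 0.20 μmol min⁻¹ mg⁻¹
Km       13.33 ± 0.53 μM
RSS   1.652e-01 over 8 points
kcat      46.9 s⁻¹  (M = 1.84e+05 g/mol)
kcat/Km   3.52 μM⁻¹ s⁻¹
```

The midpoint comes back within 0.4 mV of the generating value and the
kinetic constants within 4%; A_ox and the amplitude are free parameters
that absorb residual normalisation bias when a limb does not quite reach
its plateau inside the potential window.

Mapping a ligand in a receptor field follows the model/results pattern:

```python
from redoxmap.synthetic import specificity_pair

receptor, neg_ligand, pos_ligand = specificity_pair(seed=0)
grid = rm.potential_grid(receptor, spacing=2.0,
                         buffer=rm.BufferSpec.phosphate(0.020))
config = rm.MCConfig(n_runs=2000, n_steps=5000, d_max=75.0, seed=101)
results = rm.InteractionMapping(receptor, neg_ligand, grid=grid,
                                config=config).run()
print(results.summary())
report = results.interface_report()
flagged, hit = rm.cofactor_in_interface(report, "heme3")
```

On the synthetic specificity pair this yields a ~30-fold pose-density
enrichment of the negative-ring ligand over the positive patch (the
geometry-identical positive-ring ligand shows none), mean top-pose
energies of about −20 kBT vs −0.6 kBT, and the in-patch heme flagged as
part of the interface (contact frequency ≈ 1.0) while the antipodal heme
is not — the desk-scale form of the partner-discrimination argument.

A thin CLI covers the pipeline stages
(`redoxmap prep|field|map|surface|fit-redox|fit-kinetics|simulate`);
run any subcommand with `--help`.

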