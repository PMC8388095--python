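# Methods

This note records the models implemented in `redoxmap`, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish.

## Scientific setting

Small c-type cytochromes shuttle electrons between soluble redox enzymes.
Which cytochrome a given enzyme accepts is often decided not by a stable
complex but by electrostatic steering of transient encounters: a charged
patch on the enzyme surface pre-orients and concentrates a ligand of
complementary charge near the heme that serves as the electron outlet.
`redoxmap` implements the computational side of that argument — rigid-body
Monte Carlo mapping of a ligand in the receptor's electrostatic field —
together with the two supporting bench analyses, spectroelectrochemical
midpoint-potential determination and hydroxylamine-oxidation kinetics.

## Structures and charges

Structures are carried as flat atom lists (coordinates in Å, partial
charges in e, radii in Å) read from PDB (via gemmi) or PQR.  Charging is
a fixed pH-7 formal-charge model: Asp/Glu −1, Lys/Arg +1, His neutral,
free termini ±1, each charge placed on a single documented side-chain
atom so that structures without hydrogens charge identically
(united-atom tolerance).  Per-site pKa prediction is deliberately out of
scope; workflows needing it can import a PQR prepared elsewhere.

c-type hemes use a minimal explicit convention: propionate carboxylate
oxygens −0.5 e each when present, and the iron at +1 e (ferric) or 0 e
(ferrous).  The one-electron difference between redox states is thus
localised on Fe.  This is a package convention — published heme charge
sets distribute the electron over the porphyrin — but every analysis here
depends only on the net one-electron difference and on where the heme
sits, not on its internal charge distribution.  `set_redox_state`
switches only the iron charge, so it composes with imported charge sets.

## Electrostatics

The native solver is a uniform-dielectric screened-Coulomb
(Debye–Hückel) superposition,

φ(x) = Σᵢ qᵢ exp(−κ rᵢ) / (4π ε₀ ε_r rᵢ),   in kBT/e at the stated T,

with κ from the buffer ionic strength.  Defaults: ε_r = 78.5, T = 300 K
(the sampling temperature), grid spacing 1.0 Å with 20 Å padding.  The
20 mM pH-7 potassium phosphate assay buffer speciates by
Henderson–Hasselbalch (pKa2 = 7.20) and completes with K⁺, giving
I ≈ 35.5 mM and a Debye length of ≈ 16 Å.  A uniform dielectric misses
the low-dielectric protein interior (two-dielectric boundary effects,
focusing), but is exact under superposition, analytically testable, and
preserves the sign and shape of the surface potential contrasts that
steering arguments rest on.  Fields from a full Poisson–Boltzmann solver
can be imported as OpenDX grids and used everywhere a native grid can.

Potential lookups use one shared trilinear kernel (exact at nodes and
for linear fields; φ = 0 outside the box, i.e. the far field).  A
rigorous per-point error bound for the interpolation,
(3h²/8)·Σᵢ|qᵢ| lB g''(rᵢ*), backs the oracle tests that compare grid
lookups against direct sums.  Grid nodes within 10⁻³ Å of an atom are
clamped and reported.

## Monte Carlo interaction mapping

A rigid ligand moves in the receptor's field.  Pose energy is
E = Σⱼ qⱼ φ(R xⱼ + t) (kBT); any receptor–ligand heavy-atom pair closer
than 0.8 × (rᵢ + rⱼ) is a hard clash (E = +∞).  Moves are isotropic
Gaussian translations (σ = 2 Å) composed with small-angle rotations
about a uniform random axis (σ = 0.2 rad), accepted by the Metropolis
rule at 300 K; proposals taking the ligand centre of mass beyond d_max
from the receptor centre are rejected.  Each run starts from a uniform
random position in the d_max ball with uniform random orientation
(clashing starts are resampled); after a burn-in of 20% of the run,
poses are recorded every 50 steps.

The full-scale protocol (10⁶ runs × 25,000 steps, d_max = 500 Å)
is available as `full_scale_config()`; the default desk-scale
configuration is 2,000 runs × 5,000 steps, which resolves the synthetic
system's interface in minutes on one core.  All chains advance in
lockstep, vectorised, from a single seeded PCG64 stream: the same seed
reproduces the ensemble bit for bit, and every recorded energy
re-evaluates exactly under `interaction_energy` because sampler and
single-pose API share one kernel.  Move sizes, burn-in, thinning and the
overlap factor are package choices (the protocol source states only
runs, steps, temperature and d_max); acceptance rates on the synthetic
system run 0.4–0.8.

## Interface extraction

Preferred poses are the lowest-energy fraction (default 10%) or the
densest occupancy voxels.  A receptor residue is in contact in a pose if
any of its heavy atoms is within 5 Å of a transformed ligand heavy atom;
contact frequencies over the analysed poses, with residues classed as
negative (Asp, Glu), positive (Lys, Arg, His), neutral (Ser, Thr, Asn,
Gln, Tyr) or hydrophobic (the rest), make up the interface report.  Heme
cofactors are tracked separately with their minimum approach distance; a
cofactor is declared part of the interface when its contact frequency
reaches 0.25.  Cutoff, fraction and threshold are package defaults, all
configurable.

## The synthetic specificity system

The structural generators build the smallest system that can express
electrostatic partner discrimination:

* **receptor** — 400 carbon-like pseudo-atoms on a Fibonacci sphere of
  radius 25 Å; a 30° cap carries +0.5 e per atom (27 atoms, "ARG"
  single-atom residues), the rest −0.02 e ("GLY"); one ferric Fe
  pseudo-atom 1 Å under the patch centre (`heme3`) and one at the
  antipode (`heme1`); a large neutral blocker atom at the centre keeps
  rigid bodies from threading through the sparse shell;
* **ligands** — a 50-atom sphere of radius 8 Å whose 12 equatorial atoms
  carry ±0.5 e around a central ferric heme; the negative and positive
  versions are built from the same lattice and differ in charges only.

Sampling uses d_max = 75 Å (three receptor radii): at the desk-scale
step budget a chain's diffusive range (~150 Å RMS) spans the ball, so
runs can actually encounter the receptor, which is the property the
full-scale protocol has on real structures.  Pose-density enrichment
over the patch is quantified as the count ratio between the patch cone
(the 30° half-angle around the patch axis) and the antipodal cone of
equal solid angle; the whole-ensemble cone ratio, the ordering of mean
top-pose energies between the two ligands, and the cofactor flags
(`heme3` in, `heme1` out) constitute the specificity readout.  Heme
redox-state variants (all-ferric, all-ferrous, mixed, single-electron
transfers) perturb the system by ≤ 2 e against a +13.5 e patch, so all
variants locate the same interface — the robustness the mapping method
claims on real systems.

What the toy does not establish: real interface geometry (a concave
binding site between protrusions, here a spherical cap), desolvation and
shape complementarity, heme–heme distance constraints for electron
transfer, or any absolute binding free energy.  Passing these tests
shows the machinery is correct and that charge complementarity alone
suffices for discrimination at this scale — not that the real proteins
bind where the toy does.

## Spectroelectrochemistry

Titration limbs (absorbance at 420 nm vs applied potential) follow

A(E) = A_ox + a / (1 + exp(n F (E − E_m) / (R T))),

with n = 1, T = 293 K, F = 96 485.34 J V⁻¹ mol⁻¹, R = 8.3145
J mol⁻¹ K⁻¹.  The reduced species absorbs more at the Soret band, so A
falls with E; the 10–90% width is 2 ln 9·RT/F ≈ 111 mV.  The sigmoid
direction and algebraic form are this package's reconstruction from the
standard symbol conventions (A_ox, amplitude a) of the method.  Spectra
are baselined to zero at 700 nm; potentials referenced to SHE via the
measured offset to an Ag/AgCl/4 M KCl electrode (+200 mV vs SHE).

Slow denaturation in thin-layer cells drifts the plateaus between the
oxidative and reductive limbs, so each limb is normalised to [0, 1]
before fitting.  Plateaus are estimated from the 3 most extreme-potential
points per limb by default; a per-limb sigmoid-prefit mode
(`plateau="fitted"`) exists for windows that do not reach both plateaus.
All limbs of all experiments are then fitted jointly (shared E_m, shared
amplitude/offset) by least squares; standard errors come from the
covariance of the fit.  The titration generator adds Gaussian noise on
the normalised absorbance and a limb-specific affine distortion
(amplitude shrunk and baseline lifted by the hysteresis parameter,
default 0.05) — the drift normalisation is meant to remove; it does not
model mediator-equilibration lag or potential-sweep direction effects.

## Enzyme kinetics

Hydroxylamine oxidation is assayed by cytochrome reduction at 550 nm
(Δε₅₅₀ = 19.1 mM⁻¹ cm⁻¹ for the natural acceptor, 19.6 for the
mitochondrial control; 0.5 mL, 1 cm path, 0.6 μg enzyme).  The initial
rate is the A₅₅₀ slope over the first 20 s or the first 10% of substrate
consumption, whichever ends first, converted to substrate units by the
3-electron stoichiometry of NH₂OH → NO (configurable) and scaled to
μmol min⁻¹ mg⁻¹.  Replicate rates are averaged per substrate level and
fitted to v = Vmax·S/(Km + S).  The turnover number follows from the
molar mass M of the catalytic assembly (the trimer, supplied by the
user) as kcat = Vmax·M·10⁻³/60 s⁻¹ — one mg of enzyme is 10³/M μmol —
and the efficiency as kcat/Km (μM⁻¹ s⁻¹).  The rate generator produces
piecewise-linear progress curves (linear at the set rate until substrate
exhaustion) and Michaelis–Menten rate tables with multiplicative
Gaussian noise; it does not model substrate inhibition, lag phases or
heteroscedastic error.

## Numerical choices and degenerate inputs

* Nonlinear fits use `scipy.optimize.curve_fit` with tight tolerances
  (ftol = xtol = 10⁻¹⁵), initial values taken from the data (half-signal
  crossing for E_m; max rate and half-max substrate for Vmax, Km).
  Non-convergence and non-physical estimates raise, never return.
* Degenerate titration limbs (no spread), empty ensembles, empty
  structure files, rate windows beyond the data, and redox
  specifications naming absent hemes are all errors.
* Ties in pose selection break by index (stable sort); voxel histograms
  use half-open bins with the last edge closed.
* The d_max constraint is enforced by proposal rejection, not
  reflection.
* Two-state occupancy checks use the discrete two-state chain driven by
  the same acceptance primitive as the sampler, where the multinomial
  3σ band is a conservative bound (the flip-proposal chain has negative
  lag-1 autocorrelation); continuous-chain occupancy tests use wider
  tolerances because their samples are autocorrelated.

## Problem sizes used by the test suite

The suite runs the specificity pair at the desk-scale configuration
(2,000 runs × 5,000 steps per ligand, ~46³ grid at 2 Å spacing) and the
five redox-state variants at 400 runs × 2,000 steps each; titration and
kinetics recoveries use 25-potential two-limb two-experiment data sets
and 8 × 3 rate tables — the sizes a workstation reproduces in minutes.

## Known limitations

Uniform dielectric (no low-ε interior, no ionic exclusion layer); rigid
bodies (no side-chain adaptation); energies are purely electrostatic (no
desolvation, van der Waals or entropy); formal charges at pH 7 only;
single-E_m Nernst model (one heme per titration); Michaelis–Menten only
(no substrate inhibition).  These match the package's purpose — mapping
charge-steered encounter preferences and analysing the accompanying
bench data — rather than free-energy prediction.
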