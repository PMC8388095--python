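"""Screened-Coulomb electrostatics of a charged molecule in salt solution.

The receptor's potential is computed as a Debye–Hückel (linearized
Poisson–Boltzmann, uniform dielectric) superposition

    φ(x) = Σ_i q_i exp(−κ r_i) / (4π ε₀ ε_r r_i),

reported in kBT/e at the stated temperature.  A uniform dielectric keeps
the field analytically testable and preserves the sign and shape
contrasts that drive electrostatic steering; two-dielectric solutions
from an external solver can be imported as OpenDX grids instead
(:func:`redoxmap.grids.read_dx`).

The screening constant κ follows from the buffer ionic strength; a
phosphate shortcut speciates H₂PO₄⁻/HPO₄²⁻ by Henderson–Hasselbalch and
completes the mixture with K⁺ counterions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .grids import PotentialGrid
from .structure import MolecularModel

__all__ = [
    "BufferSpec",
    "ionic_strength",
    "debye_kappa",
    "bjerrum_length",
    "potential_at",
    "potential_grid",
    "interpolation_error_bound",
]

DEFAULT_DIELECTRIC = 78.5
DEFAULT_TEMPERATURE = 300.0  # K; matches the Monte Carlo temperature
PHOSPHATE_PKA2 = 7.20

#: minimum atom–node distance (Å) before the potential is clamped
CLAMP_RADIUS = 1e-3


@dataclass(frozen=True)
class BufferSpec:
    """Ionic composition of a buffer as (concentration mol/L, charge e) pairs.

    Counterions needed for electroneutrality (K⁺ or Cl⁻) are added
    implicitly when the ionic strength is evaluated.
    """

    species: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for c, _z in self.species:
            if c < 0:
                raise ValueError("ion concentrations must be non-negative")

    @classmethod
    def salt(cls, concentration: float, z_cation: int = 1, z_anion: int = -1) -> "BufferSpec":
        """A fully dissociated simple salt such as KCl."""
        return cls(species=((concentration, float(z_cation)), (concentration, float(z_anion))))

    @classmethod
    def phosphate(cls, concentration: float, pH: float = 7.0, pKa2: float = PHOSPHATE_PKA2) -> "BufferSpec":
        """Potassium phosphate at total phosphate *concentration* (mol/L).

        Only the H₂PO₄⁻/HPO₄²⁻ equilibrium matters near neutral pH; the
        two anions are speciated by Henderson–Hasselbalch at *pKa2* and
        K⁺ completes the mixture.
        """
        ratio = 10.0 ** (pH - pKa2)  # [HPO4^2-]/[H2PO4^-]
        f_hpo4 = ratio / (1.0 + ratio)
        return cls(
            species=(
                (concentration * (1.0 - f_hpo4), -1.0),
                (concentration * f_hpo4, -2.0),
            )
        )


def ionic_strength(buffer: BufferSpec) -> float:
    """I = ½ Σ cᵢ zᵢ² (mol/L), after completing with monovalent counterions."""
    species = list(buffer.species)
    net = sum(c * z for c, z in species)
    if abs(net) > 1e-15:
        # add K+ to balance anions, Cl- to balance cations
        species.append((abs(net), -np.sign(net)))
    return 0.5 * float(sum(c * z * z for c, z in species))


def debye_kappa(I: float, temperature: float = DEFAULT_TEMPERATURE,
                dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Inverse Debye length κ in Å⁻¹ for ionic strength *I* (mol/L)."""
    if I < 0:
        raise ValueError("ionic strength must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if I == 0:
        return 0.0
    e = constants.elementary_charge
    kappa_sq_m = (
        2.0 * constants.Avogadro * e * e * I * 1e3
        / (constants.epsilon_0 * dielectric * constants.Boltzmann * temperature)
    )
    return float(np.sqrt(kappa_sq_m) * 1e-10)  # m^-1 -> Å^-1


def bjerrum_length(temperature: float = DEFAULT_TEMPERATURE,
                   dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Bjerrum length e²/(4π ε₀ ε_r kB T) in Å.

    The screened-Coulomb potential of a unit charge in kBT/e equals
    ``bjerrum_length / r`` at κ = 0, which pins the unit conversion.
    """
    e = constants.elementary_charge
    lb_m = e * e / (4.0 * np.pi * constants.epsilon_0 * dielectric
                    * constants.Boltzmann * temperature)
    return float(lb_m * 1e10)


def potential_at(
    model: MolecularModel,
    points: np.ndarray,
    kappa: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
    dielectric: float = DEFAULT_DIELECTRIC,
    *,
    chunk: int = 65536,
) -> np.ndarray:
    """Direct screened-Coulomb sum at arbitrary points, in kBT/e.

    Distances below ``CLAMP_RADIUS`` are clamped (the near-singular
    self-region of a point charge); a warning reports how many points
    were affected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = model.coordinates()
    q = model.charges()
    lb = bjerrum_length(temperature, dielectric)
    out = np.empty(len(pts))
    n_clamped = 0
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - coords[None, :, :], axis=2)
        close = d < CLAMP_RADIUS
        if np.any(close):
            n_clamped += int(np.count_nonzero(np.any(close, axis=1)))
            d = np.maximum(d, CLAMP_RADIUS)
        out[start : start + chunk] = lb * ((q[None, :] * np.exp(-kappa * d) / d).sum(axis=1))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} evaluation points coincide with atoms; potential clamped",
            stacklevel=2,
        )
    return out


def _grid_geometry(model: MolecularModel, spacing: float, padding: float):
    coords = model.coordinates()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    return lo, dims


def potential_grid(
    model: MolecularModel,
    *,
    origin: np.ndarray | None = None,
    spacing: float = 1.0,
    dims: tuple[int, int, int] | None = None,
    padding: float = 20.0,
    buffer: BufferSpec | None = None,
    ionic_strength_M: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    dielectric: float = DEFAULT_DIELECTRIC,
) -> PotentialGrid:
    """Evaluate the model's screened-Coulomb potential on a regular grid.

    The box defaults to the model's bounding box plus *padding* on every
    side.  Ionic strength comes from *buffer* (speciated and completed),
    from *ionic_strength_M* directly, or defaults to 0 (no screening).
    Superposition is exact: the grid of a combined charge set equals the
    sum of the grids of its parts.
    """
    if buffer is not None and ionic_strength_M is not None:
        raise ValueError("give either buffer or ionic_strength_M, not both")
    I = ionic_strength(buffer) if buffer is not None else (ionic_strength_M or 0.0)
    kappa = debye_kappa(I, temperature, dielectric)

    if origin is None or dims is None:
        auto_origin, auto_dims = _grid_geometry(model, spacing, padding)
        origin = auto_origin if origin is None else np.asarray(origin, dtype=float)
        dims = tuple(auto_dims) if dims is None else dims

    ax = [origin[i] + spacing * np.arange(dims[i]) for i in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    vals = potential_at(model, pts, kappa=kappa, temperature=temperature,
                        dielectric=dielectric).reshape(dims)
    return PotentialGrid(
        origin=np.asarray(origin, dtype=float), spacing=spacing, values=vals,
        temperature=temperature, ionic_strength=I, dielectric=dielectric,
    )


def interpolation_error_bound(
    model: MolecularModel,
    grid: PotentialGrid,
    points: np.ndarray,
) -> np.ndarray:
    """Rigorous per-point bound on the trilinear interpolation error.

    For f(x) = Σ qᵢ lB g(rᵢ) with g(r) = e^{−κr}/r, every second partial
    derivative along a grid axis is bounded by |g''(r)|, and trilinear
    interpolation on a cell of spacing h obeys

        |f − I f| ≤ (h²/8) Σ_axes max_cell |∂²f| ≤ (3h²/8) Σᵢ |qᵢ| lB g''(rᵢ*)

    where rᵢ* is the atom's distance to the nearest corner of the cell
    containing the query point (bounded below by rᵢ − √3 h/2).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = model.coordinates()
    absq = np.abs(model.charges())
    kappa = debye_kappa(grid.ionic_strength, grid.temperature, grid.dielectric)
    lb = bjerrum_length(grid.temperature, grid.dielectric)
    h = grid.spacing
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    r = np.maximum(d - np.sqrt(3.0) * h / 2.0, CLAMP_RADIUS)
    g2 = np.exp(-kappa * r) * (kappa**2 / r + 2.0 * kappa / r**2 + 2.0 / r**3)
    return 3.0 * h * h / 8.0 * (absq[None, :] * lb * g2).sum(axis=1)
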