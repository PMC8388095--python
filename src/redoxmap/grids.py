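"""Regular scalar grids of electrostatic potential (kBT/e) and OpenDX I/O.

Grids are axis-aligned with uniform spacing, matching what APBS-style
solvers emit.  Values are stored C-ordered with shape ``dims`` so that
the last (z) index varies fastest, which is also the OpenDX data order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import ParseError

__all__ = ["PotentialGrid", "read_dx", "write_dx", "isopotential_mask"]


def _trilinear(origin: np.ndarray, spacing: float, values: np.ndarray,
               points: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Vectorized trilinear interpolation on a uniform grid.

    Exact at grid nodes and for fields linear in x; points outside the
    box get *fill*.  This single kernel backs every potential lookup in
    the package so that sampled energies are exactly reproducible.
    """
    g = (points - origin) / spacing
    dims = np.array(values.shape)
    inside = np.all((g >= 0.0) & (g <= dims - 1), axis=1)
    out = np.full(len(points), fill, dtype=float)
    if not np.any(inside):
        return out
    gi = g[inside]
    i0 = np.minimum(gi.astype(np.int64), dims - 2)  # keep i0+1 valid at the far face
    f = gi - i0
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    v = values
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    c000 = v[x0, y0, z0]
    c001 = v[x0, y0, z0 + 1]
    c010 = v[x0, y0 + 1, z0]
    c011 = v[x0, y0 + 1, z0 + 1]
    c100 = v[x0 + 1, y0, z0]
    c101 = v[x0 + 1, y0, z0 + 1]
    c110 = v[x0 + 1, y0 + 1, z0]
    c111 = v[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 + (c100 - c000) * fx
    c01 = c001 + (c101 - c001) * fx
    c10 = c010 + (c110 - c010) * fx
    c11 = c011 + (c111 - c011) * fx
    c0 = c00 + (c10 - c00) * fy
    c1 = c01 + (c11 - c01) * fy
    out[inside] = c0 + (c1 - c0) * fz
    return out


@dataclass
class PotentialGrid:
    """A 3-D scalar field φ on a uniform grid.

    Attributes
    ----------
    origin : (3,) ndarray, Å
        Position of node (0, 0, 0).
    spacing : float, Å
        Uniform node spacing on all three axes.
    values : ndarray, shape ``dims``
        Potential in kBT/e.
    temperature : float, K
        Temperature defining the kBT/e unit.
    ionic_strength : float, mol/L
    dielectric : float
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    temperature: float = 300.0
    ionic_strength: float = 0.0
    dielectric: float = 78.5

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-D array")
        if any(d < 2 for d in self.values.shape):
            raise ValueError("grid needs at least 2 nodes per axis")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)
        )  # type: ignore[return-value]

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def node_positions(self) -> np.ndarray:
        ax = self.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo, hi = self.origin, self.upper_corner
        return np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)

    def interpolate(self, points: np.ndarray) -> np.ndarray | float:
        """Trilinear interpolation; raises for points outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.contains(pts)
        if not np.all(inside):
            bad = pts[~inside][0]
            raise ValueError(f"point {bad} lies outside the grid box")
        out = _trilinear(self.origin, self.spacing, self.values, pts)
        return float(out[0]) if np.asarray(points).ndim == 1 else out

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation with φ = 0 outside the box (far field)."""
        return _trilinear(self.origin, self.spacing, self.values, np.atleast_2d(points))


def isopotential_mask(grid: PotentialGrid, level: float) -> np.ndarray:
    """Boolean voxel mask of the ±level isopotential region.

    For a positive *level* the mask marks φ ≥ level; for a negative one,
    φ ≤ level.  These are the regions bounded by the isopotential surfaces
    conventionally rendered at ±1 kBT/e.
    """
    if level == 0:
        raise ValueError("isopotential level must be non-zero")
    if level > 0:
        return grid.values >= level
    return grid.values <= level


# ----------------------------------------------------------------------
# OpenDX scalar grids
# ----------------------------------------------------------------------

def write_dx(grid: PotentialGrid, path: str | Path, comment: str = "redoxmap potential grid") -> None:
    nx, ny, nz = grid.dims
    h = grid.spacing
    vals = grid.values.ravel(order="C")
    with Path(path).open("w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.6e} {grid.origin[1]:.6e} {grid.origin[2]:.6e}\n")
        fh.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.10e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path: str | Path, temperature: float = 300.0,
            ionic_strength: float = 0.0, dielectric: float = 78.5) -> PotentialGrid:
    """Read an OpenDX scalar grid (as written by APBS or :func:`write_dx`).

    Only uniform, axis-aligned grids are supported; anisotropic spacing or
    off-diagonal delta vectors raise :class:`ParseError`.
    """
    path = Path(path)
    counts: list[int] | None = None
    origin: np.ndarray | None = None
    deltas: list[np.ndarray] = []
    n_items: int | None = None
    data: list[float] = []
    reading = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if reading:
                if s.startswith(("attribute", "object", "component")):
                    reading = False
                else:
                    try:
                        data.extend(float(tok) for tok in s.split())
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad data value") from exc
                    continue
            if s.startswith("object") and "gridpositions" in s:
                counts = [int(tok) for tok in s.split()[-3:]]
            elif s.startswith("origin"):
                origin = np.array([float(tok) for tok in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append(np.array([float(tok) for tok in s.split()[1:4]]))
            elif s.startswith("object") and "class array" in s:
                toks = s.split()
                n_items = int(toks[toks.index("items") + 1])
                reading = True
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ParseError(f"{path}: incomplete DX header")
    delta = np.array(deltas)
    offdiag = delta - np.diag(np.diag(delta))
    diag = np.diag(delta)
    if np.any(np.abs(offdiag) > 1e-12) or np.ptp(diag) > 1e-9 * max(1.0, abs(diag[0])):
        raise ParseError(f"{path}: non-uniform or non-axis-aligned grid spacing")
    if len(data) != n_items or n_items != int(np.prod(counts)):
        raise ParseError(
            f"{path}: truncated data section ({len(data)} of {n_items} values)"
        )
    values = np.array(data).reshape(counts)
    return PotentialGrid(
        origin=origin, spacing=float(diag[0]), values=values,
        temperature=temperature, ionic_strength=ionic_strength, dielectric=dielectric,
    )
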