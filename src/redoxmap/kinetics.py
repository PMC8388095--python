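"""Hydroxylamine-oxidation kinetics: initial rates and Michaelis–Menten fits.

The assay follows reduction of a cytochrome electron acceptor at 550 nm.
Hydroxylamine oxidation to NO releases three electrons, so three
cytochromes are reduced per substrate molecule; rates are converted from
acceptor-reduction units to substrate (hydroxylamine) units by dividing
by that electron stoichiometry (configurable), then scaled per minute
and per mg of enzyme.  Initial rates at a series of substrate
concentrations are fitted to v = Vmax·S/(Km + S), and the turnover
number follows from Vmax and the enzyme's molar mass,
kcat = Vmax · M · 10⁻⁶ / 60 (s⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProgressCurve",
    "RatePoint",
    "initial_rate",
    "MichaelisMenten",
    "MMFit",
    "fit_mm",
    "catalytic_constants",
    "FitError",
]

ELECTRONS_PER_NH2OH = 3  # NH2OH -> NO + 3 e- + 3 H+


class FitError(RuntimeError):
    pass


class RatePoint(NamedTuple):
    """Substrate concentration (μM) and initial rate (μmol min⁻¹ mg⁻¹)."""

    S: float
    v: float


@dataclass
class ProgressCurve:
    """A550 vs time for one assay (0.5 mL cuvette, 1 cm path by default)."""

    times_s: np.ndarray
    a550: np.ndarray
    substrate_uM: float
    enzyme_ug: float = 0.6
    volume_mL: float = 0.5
    depsilon_mM_cm: float = 19.1
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.a550 = np.asarray(self.a550, dtype=float)
        if self.times_s.shape != self.a550.shape:
            raise ValueError("time and absorbance arrays differ in length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.depsilon_mM_cm <= 0:
            raise ValueError("extinction coefficient must be positive")


def initial_rate(
    curve: ProgressCurve,
    window_s: float | None = None,
    stoichiometry: int = ELECTRONS_PER_NH2OH,
    max_extent: float = 0.10,
) -> RatePoint:
    """Initial rate from the early linear region of a progress curve.

    The fitting window is *window_s* if given; otherwise the first 20 s
    or the time at which *max_extent* (default 10%) of the substrate has
    been consumed, whichever comes first.  The A550 slope converts to an
    acceptor-reduction rate via ΔA/(Δε·l), to a hydroxylamine rate via
    the electron stoichiometry, and to μmol min⁻¹ mg⁻¹ via the assay
    volume and enzyme mass.
    """
    t, A = curve.times_s, curve.a550
    if window_s is None:
        # substrate consumed so far, μM, from accumulated absorbance change
        consumed = (A - A[0]) / (curve.depsilon_mM_cm * curve.path_cm) * 1e3 / stoichiometry
        limit = max_extent * curve.substrate_uM
        over = np.nonzero(consumed >= limit)[0]
        t_extent = t[over[0]] if len(over) else t[-1]
        window_s = min(20.0, float(t_extent))
    mask = t <= t[0] + window_s
    if mask.sum() < 3:
        raise ValueError("initial-rate window holds fewer than 3 points")
    if t[0] + window_s > t[-1] + 1e-9:
        raise ValueError("initial-rate window exceeds the recorded data")
    slope_per_s = float(np.polyfit(t[mask], A[mask], 1)[0])
    if slope_per_s < 0:
        raise ValueError("negative A550 slope: no acceptor reduction")
    v_acceptor_uM_min = slope_per_s * 60.0 / (curve.depsilon_mM_cm * curve.path_cm) * 1e3
    v_substrate_uM_min = v_acceptor_uM_min / stoichiometry
    umol_min = v_substrate_uM_min * curve.volume_mL * 1e-3
    v = umol_min / (curve.enzyme_ug * 1e-3)
    return RatePoint(S=curve.substrate_uM, v=v)


@dataclass
class MMFit:
    """Michaelis–Menten parameter estimates with standard errors."""

    Vmax: float          # μmol min^-1 mg^-1
    Vmax_se: float
    Km: float            # μM
    Km_se: float
    rss: float
    n_points: int

    def predicted(self, S):
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.Km + S)

    def catalytic_constants(self, molar_mass_g_mol: float) -> tuple[float, float]:
        return catalytic_constants(self, molar_mass_g_mol)

    def summary(self, molar_mass_g_mol: float | None = None) -> str:
        lines = [
            "Michaelis-Menten fit",
            "=" * 40,
            f"Vmax  {self.Vmax:8.2f} ± {self.Vmax_se:.2f} μmol min⁻¹ mg⁻¹",
            f"Km    {self.Km:8.2f} ± {self.Km_se:.2f} μM",
            f"RSS   {self.rss:8.3e} over {self.n_points} points",
        ]
        if molar_mass_g_mol is not None:
            kcat, eff = self.catalytic_constants(molar_mass_g_mol)
            lines += [
                f"kcat  {kcat:8.1f} s⁻¹  (M = {molar_mass_g_mol:.3g} g/mol)",
                f"kcat/Km {eff:6.2f} μM⁻¹ s⁻¹",
            ]
        return "\n".join(lines)


class MichaelisMenten:
    """Michaelis–Menten model over replicate initial-rate measurements.

    Replicates at the same substrate level are averaged before fitting
    (the conventional treatment of technical replicates); pass
    ``average_replicates=False`` to fit every point individually.
    """

    def __init__(self, points: Sequence[RatePoint]) -> None:
        if not points:
            raise ValueError("no rate points")
        self.points = [RatePoint(float(s), float(v)) for s, v in points]
        if any(p.S < 0 for p in self.points):
            raise ValueError("substrate concentrations must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MichaelisMenten":
        """Build from columns S (μM) and v (μmol min⁻¹ mg⁻¹)."""
        return cls([RatePoint(s, v) for s, v in zip(df["S"], df["v"])])

    def fit(self, average_replicates: bool = True) -> MMFit:
        pts = self.points
        if average_replicates:
            by_s: dict[float, list[float]] = {}
            for p in pts:
                by_s.setdefault(p.S, []).append(p.v)
            pts = [RatePoint(s, float(np.mean(vs))) for s, vs in sorted(by_s.items())]
        if len({p.S for p in pts}) < 4:
            raise FitError("need at least 4 distinct substrate levels")
        S = np.array([p.S for p in pts])
        v = np.array([p.v for p in pts])

        def mm(s, vmax, km):
            return vmax * s / (km + s)

        vmax0 = float(v.max())
        km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))]) or 1.0
        try:
            popt, pcov = curve_fit(mm, S, v, p0=[vmax0, km0], maxfev=50000,
                                   ftol=1e-15, xtol=1e-15)
        except RuntimeError as exc:
            raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        if popt[0] <= 0 or popt[1] <= 0:
            raise FitError(f"non-physical estimates Vmax={popt[0]:.3g}, Km={popt[1]:.3g}")
        se = np.sqrt(np.diag(pcov))
        resid = v - mm(S, *popt)
        return MMFit(Vmax=float(popt[0]), Vmax_se=float(se[0]),
                     Km=float(popt[1]), Km_se=float(se[1]),
                     rss=float(np.sum(resid**2)), n_points=len(pts))


def fit_mm(points: Sequence[RatePoint], average_replicates: bool = True) -> MMFit:
    """Least-squares Michaelis–Menten fit of initial-rate data."""
    return MichaelisMenten(points).fit(average_replicates=average_replicates)


def catalytic_constants(fit: MMFit, molar_mass_g_mol: float) -> tuple[float, float]:
    """Turnover number and catalytic efficiency from a fit.

    One mg of enzyme holds 10³/M μmol of catalyst, so

        kcat = Vmax [μmol min⁻¹ mg⁻¹] · M [g/mol] · 10⁻³ / 60   (s⁻¹)
        efficiency = kcat / Km   (μM⁻¹ s⁻¹)

    For an oligomeric enzyme, pass the molar mass of the assembly whose
    turnover you want (e.g. the trimer).
    """
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    kcat = fit.Vmax * molar_mass_g_mol * 1e-3 / 60.0
    return kcat, kcat / fit.Km
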