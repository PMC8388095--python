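"""Spectroelectrochemical titration analysis and Nernst fitting.

A single-heme c-type cytochrome titrated in an optically transparent
thin-layer cell shows a sigmoidal Soret-band (420 nm) absorbance as a
function of applied potential,

    A(E) = A_ox + a / (1 + exp(n F (E − E_m) / (R T))),

with n = 1 electron: the reduced species absorbs more strongly, so A
falls from A_ox + a at low potential to A_ox at high potential, crossing
the midpoint A_ox + a/2 at E = E_m.  Slow protein denaturation in the
cell shifts the plateaus between the oxidative and reductive limbs
(hysteresis); each limb is therefore normalized to [0, 1] individually
before the limbs of all experiments are fitted jointly with a shared
midpoint potential.

The sigmoid direction and the algebraic form above are this package's
reconstruction from the standard symbol conventions of the method
(absorbance of the fully oxidized state A_ox, amplitude a); they define
the model everywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "AG_AGCL_4M_VS_SHE_MV",
    "TitrationCurve",
    "baseline_correct",
    "correct_reference",
    "nernst_absorbance",
    "transition_width",
    "normalize_limbs",
    "fit_nernst",
    "NernstTitration",
    "NernstResults",
]

FARADAY = 96485.34        # J V^-1 mol^-1
GAS_CONSTANT = 8.3145     # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 293.0  # K
#: potential of a commercial Ag/AgCl/4 M KCl reference electrode vs SHE (mV)
AG_AGCL_4M_VS_SHE_MV = 200.0


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is ill-posed."""


@dataclass
class TitrationCurve:
    """One limb of one titration experiment: applied potential vs A420."""

    potentials_mV: np.ndarray
    absorbance: np.ndarray
    limb: str = "oxidative"            # 'oxidative' or 'reductive'
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        self.potentials_mV = np.asarray(self.potentials_mV, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.potentials_mV.shape != self.absorbance.shape:
            raise ValueError("potential and absorbance arrays differ in length")
        if not np.all(np.isfinite(self.potentials_mV)):
            raise ValueError("non-finite potentials")
        if self.limb not in ("oxidative", "reductive"):
            raise ValueError("limb must be 'oxidative' or 'reductive'")

    def __len__(self) -> int:
        return len(self.potentials_mV)


def baseline_correct(spectrum: pd.Series) -> pd.Series:
    """Zero a spectrum at 700 nm: A(λ) − A(700).

    *spectrum* is a Series indexed by wavelength (nm).  If 700 nm is not
    sampled, the nearest wavelength is used with a warning.
    """
    wl = np.asarray(spectrum.index, dtype=float)
    if 700.0 in wl:
        ref = spectrum.loc[700.0]
    else:
        nearest = wl[np.argmin(np.abs(wl - 700.0))]
        warnings.warn(
            f"700 nm not sampled; baseline taken at {nearest:g} nm", stacklevel=2
        )
        ref = spectrum.loc[nearest]
    return spectrum - ref


def correct_reference(E_measured_mV: float | np.ndarray, patch_offset_mV: float = 0.0):
    """Convert a potential measured against the in-cell Ag/AgCl patch to SHE.

    *patch_offset_mV* is the measured voltage between the patch and a
    commercial Ag/AgCl/4 M KCl reference (+200 mV vs SHE), so
    E_SHE = E_measured + patch_offset + 200 mV.  Apply exactly once.
    """
    return np.asarray(E_measured_mV, dtype=float) + patch_offset_mV + AG_AGCL_4M_VS_SHE_MV


def nernst_absorbance(
    E_mV: float | np.ndarray,
    E_m_mV: float,
    A_ox: float = 0.0,
    amplitude: float = 1.0,
    n: int = 1,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """The Nernstian sigmoid A(E) = A_ox + a / (1 + exp(nF(E − E_m)/(RT)))."""
    E = np.asarray(E_mV, dtype=float)
    x = n * FARADAY * (E - E_m_mV) * 1e-3 / (GAS_CONSTANT * temperature)
    out = A_ox + amplitude / (1.0 + np.exp(np.clip(x, -500, 500)))
    return float(out) if np.ndim(E_mV) == 0 else out


def transition_width(n: int = 1, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """10–90% transition width of the sigmoid, 2 ln(9) RT/(nF), in mV."""
    return 2.0 * np.log(9.0) * GAS_CONSTANT * temperature / (n * FARADAY) * 1e3


def _observed_plateaus(curve: TitrationCurve, n_extreme: int) -> tuple[float, float]:
    order = np.argsort(curve.potentials_mV)
    a = curve.absorbance[order]
    low = float(a[:n_extreme].mean())    # most negative potentials: reduced
    high = float(a[-n_extreme:].mean())  # most positive: oxidized
    return low, high


def _fitted_plateaus(curve: TitrationCurve, n: int, temperature: float) -> tuple[float, float]:
    E, A = curve.potentials_mV, curve.absorbance

    def model(e, em, a_ox, amp):
        return nernst_absorbance(e, em, a_ox, amp, n=n, temperature=temperature)

    lo, hi = _observed_plateaus(curve, min(3, max(1, len(curve) // 4)))
    try:
        popt, _ = curve_fit(model, E, A, p0=[float(np.median(E)), hi, lo - hi], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"per-limb plateau prefit failed: {exc}") from exc
    a_ox, amp = popt[1], popt[2]
    return a_ox + amp, a_ox  # (reduced plateau, oxidized plateau)


def normalize_limbs(
    curves: list[TitrationCurve],
    n_extreme: int = 3,
    plateau: str = "observed",
    n: int = 1,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[TitrationCurve]:
    """Rescale each limb so its plateaus map to [0, 1] (oxidized → 0).

    ``plateau='observed'`` estimates the plateaus from the *n_extreme*
    most extreme-potential points of the limb; ``'fitted'`` uses the
    plateaus of a per-limb sigmoid prefit.  The affine rescale removes
    hysteresis offsets between limbs so they can be fitted jointly.
    """
    out = []
    for c in curves:
        if len(c) < 4:
            raise ValueError(f"limb {c.experiment_id}/{c.limb}: need >= 4 points")
        if plateau == "observed":
            low, high = _observed_plateaus(c, min(n_extreme, len(c) // 2))
        elif plateau == "fitted":
            low, high = _fitted_plateaus(c, n, temperature)
        else:
            raise ValueError("plateau must be 'observed' or 'fitted'")
        span = low - high
        if abs(span) < 1e-12:
            raise ValueError(f"limb {c.experiment_id}/{c.limb}: degenerate (no spread)")
        out.append(replace(c, absorbance=(c.absorbance - high) / span))
    return out


@dataclass
class NernstResults:
    """Joint Nernst fit: midpoint potential with standard errors."""

    E_m_mV: float
    E_m_se_mV: float
    A_ox: float
    amplitude: float
    n: int
    temperature: float
    rss: float
    n_points: int
    n_limbs: int

    def predicted(self, E_mV):
        return nernst_absorbance(E_mV, self.E_m_mV, self.A_ox, self.amplitude,
                                 n=self.n, temperature=self.temperature)

    def summary(self) -> str:
        return "\n".join([
            "Nernst fit (joint over limbs/experiments)",
            "=" * 44,
            f"E_m      {self.E_m_mV:10.2f} ± {self.E_m_se_mV:.2f} mV vs SHE",
            f"A_ox     {self.A_ox:10.4f}",
            f"amplitude{self.amplitude:10.4f}",
            f"n        {self.n:10d} (fixed)   T = {self.temperature:.0f} K",
            f"RSS      {self.rss:10.3e} over {self.n_points} points, {self.n_limbs} limbs",
        ])


class NernstTitration:
    """Spectroelectrochemical titration model.

    Parameters
    ----------
    curves : list of TitrationCurve
        Oxidative and reductive limbs, possibly from several experiments.
    n : int
        Number of electrons (fixed, 1 for a single c-type heme).
    temperature : float, K

    ``fit`` normalizes each limb (unless told not to) and then fits all
    points jointly with a shared midpoint potential.
    """

    def __init__(self, curves: list[TitrationCurve], n: int = 1,
                 temperature: float = DEFAULT_TEMPERATURE) -> None:
        if not curves:
            raise ValueError("no titration curves given")
        if n < 1 or int(n) != n:
            raise ValueError("n must be a positive integer")
        self.curves = list(curves)
        self.n = int(n)
        self.temperature = temperature

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n: int = 1,
                       temperature: float = DEFAULT_TEMPERATURE) -> "NernstTitration":
        """Build from tidy columns: experiment, limb, E_mV, A420."""
        curves = [
            TitrationCurve(
                potentials_mV=g["E_mV"].to_numpy(),
                absorbance=g["A420"].to_numpy(),
                limb=str(limb),
                experiment_id=str(exp),
            )
            for (exp, limb), g in df.groupby(["experiment", "limb"], sort=True)
        ]
        return cls(curves, n=n, temperature=temperature)

    def fit(self, normalize: bool = True, plateau: str = "observed") -> NernstResults:
        curves = (
            normalize_limbs(self.curves, plateau=plateau, n=self.n,
                            temperature=self.temperature)
            if normalize else self.curves
        )
        E = np.concatenate([c.potentials_mV for c in curves])
        A = np.concatenate([c.absorbance for c in curves])
        if len(E) < 3:
            raise FitError("fewer points than parameters")

        def model(e, em, a_ox, amp):
            return nernst_absorbance(e, em, a_ox, amp, n=self.n,
                                     temperature=self.temperature)

        # midpoint guess: potential of the point closest to half-signal
        half = 0.5 * (A.max() + A.min())
        p0 = [float(E[np.argmin(np.abs(A - half))]), float(A.min()), float(A.max() - A.min())]
        try:
            popt, pcov = curve_fit(model, E, A, p0=p0, maxfev=50000,
                                   ftol=1e-15, xtol=1e-15, gtol=1e-15)
        except RuntimeError as exc:
            raise FitError(f"Nernst fit did not converge: {exc}") from exc
        resid = A - model(E, *popt)
        se = np.sqrt(np.diag(pcov))
        return NernstResults(
            E_m_mV=float(popt[0]), E_m_se_mV=float(se[0]),
            A_ox=float(popt[1]), amplitude=float(popt[2]),
            n=self.n, temperature=self.temperature,
            rss=float(np.sum(resid**2)), n_points=len(E), n_limbs=len(curves),
        )


def fit_nernst(curves: list[TitrationCurve], n: int = 1,
               temperature: float = DEFAULT_TEMPERATURE,
               normalize: bool = True, plateau: str = "observed") -> NernstResults:
    """Joint Nernst fit of one or more normalized titration limbs."""
    return NernstTitration(curves, n=n, temperature=temperature).fit(
        normalize=normalize, plateau=plateau)
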