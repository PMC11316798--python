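"""Dimer ⇌ tetramer self-association equilibrium.

Two dimers (the "subunit" of the scheme) associate into one tetramer
with equilibrium constant K2 (M^-1):

    2 D  ⇌  T,      K2 = [T] / [D]^2

Mass balance on subunits, C_tot = [D] + 2 K2 [D]^2, gives the closed-form
mole fraction of subunits assembled into tetramers

    Ybar = 2 (4 K2 C_tot + 1 - sqrt(1 + 8 K2 C_tot)) / (8 K2 C_tot)

which this module evaluates in the algebraically equivalent,
cancellation-free form ``4x / (4x + 1 + sqrt(1 + 8x))`` with
``x = K2 * C_tot``.  C_tot is the total molar concentration of intact
dimers; converting from mg/mL uses the dimer molar mass (default 165 kDa
for a 2 x 745-residue chromoprotein).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "AssociationState",
    "AssociationResults",
    "DimerTetramerModel",
    "DEFAULT_DIMER_KDA",
    "invert_yfrac",
    "mgml_to_molar",
    "yfrac_equilibrium",
]

#: default dimer molar mass (kDa) used for mg/mL -> M conversion
DEFAULT_DIMER_KDA = 165.0


def yfrac_equilibrium(k2, c_tot):
    """Tetramer mole fraction Ybar at association constant ``k2`` (1/M)
    and total subunit (dimer) concentration ``c_tot`` (M).

    Continuous at ``c_tot = 0`` with limit 0, strictly increasing in
    ``c_tot`` and bounded in [0, 1).  Vectorises over either argument.
    """
    k2 = np.asarray(k2, dtype=float)
    c = np.asarray(c_tot, dtype=float)
    if np.any(k2 <= 0) or not np.all(np.isfinite(k2)):
        raise ValueError("k2 must be positive and finite")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("c_tot must be nonnegative and finite")
    x = k2 * c
    out = 4.0 * x / (4.0 * x + 1.0 + np.sqrt(1.0 + 8.0 * x))
    return out if out.ndim else float(out)


def invert_yfrac(y_frac):
    """Dimensionless product ``K2 * C_tot`` producing tetramer fraction
    ``y_frac``; the algebraic inverse ``y / (2 (1 - y)^2)``.
    """
    y = np.asarray(y_frac, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1) or not np.all(np.isfinite(y)):
        raise ValueError("y_frac must lie strictly inside (0, 1)")
    out = y / (2.0 * (1.0 - y) ** 2)
    return out if out.ndim else float(out)


def mgml_to_molar(mg_per_ml, molar_mass_kda: float = DEFAULT_DIMER_KDA):
    """Convert a mass concentration (mg/mL) to molar using the dimer mass."""
    if molar_mass_kda <= 0:
        raise ValueError("molar mass must be positive")
    out = np.asarray(mg_per_ml, dtype=float) / (molar_mass_kda * 1000.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AssociationState:
    """One point on the isotherm: (K2, C_tot, Ybar)."""

    k2: float
    c_tot: float
    y_frac: float

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.c_tot < 0:
            raise ValueError("c_tot must be nonnegative")
        if not 0.0 <= self.y_frac < 1.0:
            raise ValueError("y_frac must lie in [0, 1)")
        if self.c_tot == 0 and self.y_frac != 0:
            raise ValueError("y_frac must be 0 at zero concentration")

    @classmethod
    def from_conditions(cls, k2: float, c_tot: float) -> "AssociationState":
        return cls(k2=k2, c_tot=c_tot, y_frac=yfrac_equilibrium(k2, c_tot))


class DimerTetramerModel:
    """Fit K2 to observed (C_tot, Ybar) titration points.

    The fitted constant is a *descriptive trendline*: a titration read off
    chromatographic areas need not represent a closed system at
    equilibrium, and reports carry that caveat.

    Parameters
    ----------
    c_tot : array-like, M
    y_frac : array-like in (0, 1)
    """

    def __init__(self, c_tot, y_frac):
        c = np.atleast_1d(np.asarray(c_tot, dtype=float))
        y = np.atleast_1d(np.asarray(y_frac, dtype=float))
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("c_tot and y_frac must be equal-length 1-D")
        keep = (y > 0) & (y < 1)
        if not keep.any():
            raise ValueError("no informative points: every y_frac sits on a bound")
        self.c_tot = c[keep]
        self.y_frac = y[keep]
        self.n_dropped = int((~keep).sum())

    def fit(self) -> "AssociationResults":
        c, y = self.c_tot, self.y_frac
        if c.size == 1:
            k2 = invert_yfrac(float(y[0])) / float(c[0])
            return AssociationResults(k2=k2, k2_se=float("nan"),
                                      c_tot=c, y_frac=y, residual_rms=0.0)

        # per-point closed-form inverses give a robust start
        k_starts = invert_yfrac(y) / c
        theta0 = float(np.log(np.median(k_starts)))

        def resid(theta):
            return yfrac_equilibrium(np.exp(theta[0]), c) - y

        sol = optimize.least_squares(resid, [theta0], xtol=1e-14, ftol=1e-14)
        k2 = float(np.exp(sol.x[0]))
        dof = max(c.size - 1, 1)
        s2 = 2.0 * sol.cost / dof
        jtj = float((sol.jac.T @ sol.jac).item())
        var_theta = s2 / jtj if jtj > 0 else np.inf
        k2_se = k2 * float(np.sqrt(var_theta))  # delta method from log-space
        rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
        return AssociationResults(k2=k2, k2_se=k2_se, c_tot=c, y_frac=y,
                                  residual_rms=rms)


@dataclass
class AssociationResults:
    """Fitted association constant with its titration data."""

    k2: float
    k2_se: float
    c_tot: np.ndarray
    y_frac: np.ndarray
    residual_rms: float

    descriptive_trendline = True

    def predict(self, c_tot=None):
        c = self.c_tot if c_tot is None else c_tot
        return yfrac_equilibrium(self.k2, c)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Dimer-tetramer association trendline\n")
        buf.write(f"  K2 = {self.k2:.4g} 1/M  (SE {self.k2_se:.2g})\n")
        buf.write(f"  points: {self.c_tot.size}   residual RMS(Ybar): "
                  f"{self.residual_rms:.3g}\n")
        buf.write("  note: descriptive trendline; titration points need not\n"
                  "  represent a closed system at equilibrium.\n")
        return buf.getvalue()

    def to_report(self) -> dict:
        return {
            "k2_per_molar": self.k2,
            "k2_se": None if np.isnan(self.k2_se) else self.k2_se,
            "residual_rms": self.residual_rms,
            "points": [{"c_tot_molar": float(c), "y_frac": float(y),
                        "y_frac_trend": float(self.predict(c))}
                       for c, y in zip(self.c_tot, self.y_frac)],
            "descriptive_trendline": True,
        }
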