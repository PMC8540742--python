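"""van't Hoff analysis of the temperature dependence of the binding constant.

ln Kb = -dH/(R T) + dS/R is fitted by OLS of ln Kb against 1/T, so the slope
gives the standard enthalpy change dH and the intercept the entropy change
dS.  Gibbs energies follow from dG = dH - T dS = -R T ln Kb; the sign pattern
of (dH, dS) classifies the dominant intermolecular force:

    dH < 0, dS < 0  -> van der Waals forces and/or hydrogen bonds
    dH > 0, dS > 0  -> hydrophobic interactions
    dH < 0, dS > 0  -> electrostatic interactions

Note: the van't Hoff relation is often typeset with "log Kb"; natural
logarithms are used here throughout so that the linear form is algebraically
consistent with dG = -R T ln Kb without base-conversion factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import FitError, ValidationError
from .quenching import _ols

#: universal gas constant
R = 8.314  # J mol-1 K-1

#: sign tolerance for classifying fitted dH / dS
_SIGN_TOL = 1e-9


def gibbs_free_energy(Kb: float, T: float) -> float:
    """Standard Gibbs energy of binding, dG = -R T ln Kb (J mol-1)."""
    if not Kb > 0:
        raise ValidationError("Kb must be > 0")
    if not T > 0:
        raise ValidationError("T must be > 0 K")
    return -R * T * math.log(Kb)


@dataclass
class VantHoffFit:
    """dH, dS and derived dG(T) from the van't Hoff regression."""

    dH: float  # J mol-1
    dS: float  # J mol-1 K-1
    r2: float
    dG_by_T: dict[float, float] = field(default_factory=dict)  # K -> J mol-1
    stderr_dH: float = 0.0
    gas_constant: float = R

    def dG(self, T: float) -> float:
        """dG = dH - T dS at an arbitrary temperature (J mol-1)."""
        return self.dH - T * self.dS

    def summary(self) -> str:
        lines = [
            "van't Hoff fit (ln Kb vs 1/T)",
            f"  dH  {self.dH / 1000:+.2f} kJ mol-1 (se {self.stderr_dH / 1000:.2g})",
            f"  dS  {self.dS:+.2f} J mol-1 K-1",
            f"  r^2 {self.r2:.6f}",
        ]
        for T in sorted(self.dG_by_T):
            lines.append(f"  dG({T:.0f} K) {self.dG_by_T[T] / 1000:+.2f} kJ mol-1")
        return "\n".join(lines)


class VantHoffModel:
    """Linear van't Hoff model over a Kb(T) mapping.

    Parameters
    ----------
    kb_by_temperature : mapping
        Temperature (K) -> binding constant Kb (dm3 mol-1); >= 2 distinct
        temperatures, all Kb > 0.  With only two temperatures the line is
        exact and a low-confidence warning is appropriate downstream.
    """

    def __init__(self, kb_by_temperature: Mapping[float, float]):
        temps = np.array(sorted(kb_by_temperature), dtype=float)
        if len(temps) < 2:
            raise FitError("van't Hoff fit needs >= 2 temperatures")
        if (temps <= 0).any():
            raise ValidationError("temperatures must be > 0 K")
        kb = np.array([kb_by_temperature[t] for t in temps], dtype=float)
        if (kb <= 0).any():
            raise ValidationError("all Kb must be > 0")
        self.temperatures = temps
        self.kb = kb

    def fit(self) -> VantHoffFit:
        x = 1.0 / self.temperatures
        y = np.log(self.kb)
        slope, intercept, r2, stderr = _ols(x, y)
        dH = -slope * R
        dS = intercept * R
        dG_by_T = {float(t): dH - float(t) * dS for t in self.temperatures}
        return VantHoffFit(dH=dH, dS=dS, r2=r2, dG_by_T=dG_by_T, stderr_dH=stderr * R)

    def plot(self, ax=None):
        """ln Kb vs 1/T with the fitted van't Hoff line."""
        import matplotlib.pyplot as plt

        fit = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        x = 1.0 / self.temperatures
        ax.plot(x, np.log(self.kb), "o", label="data")
        xx = np.linspace(x.min(), x.max(), 50)
        ax.plot(xx, -fit.dH / R * xx + fit.dS / R, "-", label="van't Hoff fit")
        ax.set_xlabel("1/T / K$^{-1}$")
        ax.set_ylabel(r"$\ln K_b$")
        ax.legend()
        return ax


def fit_vant_hoff(kb_by_temperature: Mapping[float, float]) -> VantHoffFit:
    return VantHoffModel(kb_by_temperature).fit()


@dataclass(frozen=True)
class InteractionCall:
    """Dominant-force classification from the (dH, dS) sign pattern."""

    forces: str  # vdW_or_H_bond | hydrophobic | electrostatic | indeterminate
    spontaneous: bool  # all dG < 0
    dH: float
    dS: float

    def summary(self) -> str:
        return (
            f"Interaction type: {self.forces}"
            f" ({'spontaneous' if self.spontaneous else 'not spontaneous'};"
            f" dH = {self.dH / 1000:+.2f} kJ mol-1, dS = {self.dS:+.2f} J mol-1 K-1)"
        )


def classify_interaction(fit: VantHoffFit) -> InteractionCall:
    """Classify the dominant binding force from the van't Hoff signs.

    Exact zeros (within 1e-9 in fitted units) are indeterminate rather than
    forced into a sign class.
    """
    dH, dS = fit.dH, fit.dS
    if dH < -_SIGN_TOL and dS < -_SIGN_TOL:
        forces = "vdW_or_H_bond"
    elif dH > _SIGN_TOL and dS > _SIGN_TOL:
        forces = "hydrophobic"
    elif dH < -_SIGN_TOL and dS > _SIGN_TOL:
        forces = "electrostatic"
    else:
        forces = "indeterminate"
    spontaneous = bool(fit.dG_by_T) and all(g < 0 for g in fit.dG_by_T.values())
    return InteractionCall(forces=forces, spontaneous=spontaneous, dH=dH, dS=dS)
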