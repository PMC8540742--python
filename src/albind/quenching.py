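"""Fluorescence-quenching analysis of ligand-albumin titrations.

The chain implemented here is the standard tryptophan-quenching workflow:

1. inner-filter correction  F_corr = F_obs * 10**((Aex + Aem) / 2)
2. Stern-Volmer regression  F0/F = 1 + K_SV [Q],  k_q = K_SV / tau0
3. mechanism call: static quenching requires K_SV falling with temperature
   and k_q above the diffusion (scatter-collision) limit 2e10 dm3 mol-1 s-1
4. double-logarithm binding plot  log10((F0-F)/F) = log10 Kb + n log10 [Q]
5. site-marker competition: the marker that suppresses Kb most identifies
   the occupied Sudlow site (phenylbutazone -> site I/IIA, ibuprofen ->
   site II/IIIA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError
from .io import TitrationSeries

log = logging.getLogger(__name__)

#: maximum scatter-collision (diffusion-limited) quenching constant
KQ_DIFFUSION_LIMIT = 2e10  # dm3 mol-1 s-1

#: conventional unquenched biopolymer fluorescence lifetime
DEFAULT_TAU0 = 1e-8  # s


def correct_inner_filter(F_obs: float, A_ex: float = 0.0, A_em: float = 0.0) -> float:
    """Inner-filter correction of an observed fluorescence intensity.

    F_corr = F_obs * 10**((A_ex + A_em)/2).  With zero absorbances this is the
    identity; it is monotone in A_ex + A_em and exactly invertible.
    """
    if A_ex < 0 or A_em < 0:
        raise ValidationError("absorbances must be >= 0")
    if not F_obs > 0:
        raise ValidationError("F_obs must be > 0")
    return F_obs * 10.0 ** ((A_ex + A_em) / 2.0)


def _corrected_intensities(series: TitrationSeries) -> np.ndarray:
    return np.array([correct_inner_filter(p.F, p.Aex, p.Aem) for p in series.points])


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Ordinary least squares y = a*x + b.

    Returns (slope, intercept, r2, stderr_slope).  Degenerate zero-variance
    responses fit exactly (slope 0, r2 defined as 1).
    """
    if np.allclose(y, y[0], rtol=0.0, atol=0.0):
        return 0.0, float(y[0]), 1.0, 0.0
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    return float(res.slope), float(res.intercept), r2, float(res.stderr)


# ---------------------------------------------------------------------------
# Stern-Volmer


@dataclass
class SternVolmerFit:
    """Results of a Stern-Volmer regression at one temperature."""

    K_SV: float  # dm3 mol-1
    intercept: float
    tau0: float  # s
    r2: float
    stderr_KSV: float
    temperature: float  # K
    n_points_used: int = 0
    intercept_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        self.intercept_warning = abs(self.intercept - 1.0) > 0.05

    @property
    def k_q(self) -> float:
        """Bimolecular quenching rate constant K_SV / tau0 (dm3 mol-1 s-1)."""
        return self.K_SV / self.tau0

    def summary(self) -> str:
        lines = [
            "Stern-Volmer fit",
            f"  temperature     {self.temperature:.1f} K",
            f"  K_SV            {self.K_SV:.4g} dm3 mol-1 (se {self.stderr_KSV:.2g})",
            f"  intercept       {self.intercept:.4f}"
            + ("  [deviates from 1]" if self.intercept_warning else ""),
            f"  k_q = K_SV/tau0 {self.k_q:.4g} dm3 mol-1 s-1 (tau0 = {self.tau0:.3g} s)",
            f"  r^2             {self.r2:.6f}  (n = {self.n_points_used})",
        ]
        return "\n".join(lines)


class SternVolmerModel:
    """F0/F versus [Q] linear model for one titration series.

    Parameters
    ----------
    series : TitrationSeries
        Titration with the zero-quencher reference first.  Absorbance columns,
        when present, are used for the inner-filter correction before the
        ratio is formed.
    tau0 : float
        Unquenched fluorophore lifetime in seconds (default 1e-8 s).
    """

    def __init__(self, series: TitrationSeries, tau0: float = DEFAULT_TAU0):
        if tau0 <= 0:
            raise ValidationError("tau0 must be > 0")
        self.series = series
        self.tau0 = tau0

    def fit(self) -> SternVolmerFit:
        F = _corrected_intensities(self.series)
        Q = self.series.quencher_conc
        F0 = F[0]
        mask = Q > 0
        if mask.sum() < 3:
            raise FitError("Stern-Volmer fit needs >= 3 nonzero-quencher points")
        slope, intercept, r2, stderr = _ols(Q[mask], F0 / F[mask])
        fit = SternVolmerFit(
            K_SV=slope,
            intercept=intercept,
            tau0=self.tau0,
            r2=r2,
            stderr_KSV=stderr,
            temperature=self.series.temperature,
            n_points_used=int(mask.sum()),
        )
        if fit.intercept_warning:
            log.warning(
                "Stern-Volmer intercept %.4f deviates from 1 by more than 0.05",
                intercept,
            )
        return fit

    def plot(self, ax=None):
        """Diagnostic F0/F vs [Q] scatter with the fitted line."""
        import matplotlib.pyplot as plt

        fit = self.fit()
        F = _corrected_intensities(self.series)
        Q = self.series.quencher_conc
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(Q[1:], F[0] / F[1:], "o", label="data")
        qq = np.linspace(0, Q.max(), 50)
        ax.plot(qq, fit.intercept + fit.K_SV * qq, "-", label="OLS fit")
        ax.set_xlabel("[Q] / mol dm$^{-3}$")
        ax.set_ylabel("$F_0/F$")
        ax.legend()
        return ax


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> SternVolmerFit:
    return SternVolmerModel(series, tau0=tau0).fit()


# ---------------------------------------------------------------------------
# mechanism classification


@dataclass(frozen=True)
class MechanismCall:
    """Static/dynamic quenching verdict with its evidence."""

    verdict: str  # static | dynamic | ambiguous
    ksv_trend: str  # decreasing | increasing | non-monotone
    kq_exceeds_threshold: tuple[bool, ...]
    temperatures: tuple[float, ...]
    threshold: float = KQ_DIFFUSION_LIMIT

    def summary(self) -> str:
        flags = ", ".join(
            f"{t:.0f} K: {'>' if e else '<='} limit"
            for t, e in zip(self.temperatures, self.kq_exceeds_threshold)
        )
        return (
            f"Quenching mechanism: {self.verdict}\n"
            f"  K_SV trend with T: {self.ksv_trend}\n"
            f"  k_q vs 2e10 dm3 mol-1 s-1: {flags}"
        )


def classify_mechanism(fits: Sequence[SternVolmerFit]) -> MechanismCall:
    """Call the quenching mechanism from Stern-Volmer fits across temperatures.

    static   : K_SV strictly decreasing with T and every k_q above the
               scatter-collision limit (ground-state complex formation).
    dynamic  : K_SV strictly increasing and every k_q below the limit
               (diffusional collision).
    ambiguous: anything else.
    """
    if len(fits) < 2:
        raise ValidationError("need Stern-Volmer fits at >= 2 temperatures")
    temps = np.array([f.temperature for f in fits])
    if len(np.unique(temps)) != len(temps):
        raise ValidationError("duplicate temperatures")
    if (np.diff(temps) <= 0).any():
        raise ValidationError("fits must be ordered by strictly increasing temperature")
    ksv = np.array([f.K_SV for f in fits])
    if (np.diff(ksv) < 0).all():
        trend = "decreasing"
    elif (np.diff(ksv) > 0).all():
        trend = "increasing"
    else:
        trend = "non-monotone"
    exceeds = tuple(f.k_q > KQ_DIFFUSION_LIMIT for f in fits)
    if trend == "decreasing" and all(exceeds):
        verdict = "static"
    elif trend == "increasing" and not any(exceeds):
        verdict = "dynamic"
    else:
        verdict = "ambiguous"
    return MechanismCall(
        verdict=verdict,
        ksv_trend=trend,
        kq_exceeds_threshold=exceeds,
        temperatures=tuple(float(t) for t in temps),
    )


# ---------------------------------------------------------------------------
# double-logarithm binding regression


@dataclass
class BindingFit:
    """Binding constant and stoichiometry from the double-log plot."""

    log10_Kb: float
    n_sites: float
    r2: float
    n_points_used: int
    temperature: float  # K
    marker: str = "none"
    n_points_excluded: int = 0

    @property
    def Kb(self) -> float:
        """Association constant, dm3 mol-1."""
        return 10.0 ** self.log10_Kb

    def summary(self) -> str:
        lines = [
            "Double-logarithm binding fit",
            f"  temperature  {self.temperature:.1f} K   marker: {self.marker}",
            f"  Kb           {self.Kb:.4g} dm3 mol-1 (log10 Kb = {self.log10_Kb:.4f})",
            f"  n (sites)    {self.n_sites:.4f}",
            f"  r^2          {self.r2:.6f}  (n = {self.n_points_used},"
            f" excluded = {self.n_points_excluded})",
        ]
        return "\n".join(lines)


class DoubleLogModel:
    """log10((F0-F)/F) versus log10 [Q] linear model.

    Slope is the number of binding sites n; intercept is log10 Kb.  Points
    with F >= F0 (no net quenching) carry no information about the complex
    and are excluded with a warning.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series

    def fit(self) -> BindingFit:
        F = _corrected_intensities(self.series)
        Q = self.series.quencher_conc
        F0 = F[0]
        usable = (Q > 0) & (F0 - F > 0)
        n_excluded = int((Q > 0).sum() - usable.sum())
        if usable.sum() < 3:
            raise FitError(
                "double-log fit needs >= 3 points with F0 - F > 0 "
                f"(got {int(usable.sum())})"
            )
        if n_excluded:
            msg = f"{n_excluded} non-quenched point(s) excluded from double-log fit"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
        x = np.log10(Q[usable])
        y = np.log10((F0 - F[usable]) / F[usable])
        slope, intercept, r2, _ = _ols(x, y)
        return BindingFit(
            log10_Kb=intercept,
            n_sites=slope,
            r2=r2,
            n_points_used=int(usable.sum()),
            temperature=self.series.temperature,
            marker=self.series.marker,
            n_points_excluded=n_excluded,
        )


def fit_double_log(series: TitrationSeries) -> BindingFit:
    return DoubleLogModel(series).fit()


# ---------------------------------------------------------------------------
# site-marker competition


@dataclass(frozen=True)
class SiteAssignment:
    """Sudlow-site call from marker-induced Kb suppression ratios."""

    ratio_PHB: float  # Kb(with PHB) / Kb(alone)
    ratio_IBP: float  # Kb(with IBP) / Kb(alone)
    site: str  # site_I_IIA | site_II_IIIA | indeterminate

    def summary(self) -> str:
        return (
            f"Site-marker competition: {self.site}\n"
            f"  Kb ratio with phenylbutazone {self.ratio_PHB:.3f}\n"
            f"  Kb ratio with ibuprofen      {self.ratio_IBP:.3f}"
        )


def assess_site_competition(
    fit_alone: BindingFit, fit_PHB: BindingFit, fit_IBP: BindingFit
) -> SiteAssignment:
    """Identify the albumin binding site from marker displacement.

    The marker occupying the ligand's site competes and depresses the apparent
    Kb most: a stronger drop with ibuprofen implicates Sudlow site II
    (subdomain IIIA); a stronger drop with phenylbutazone implicates site I
    (subdomain IIA).  Both ratios must be < 1 for a call.
    """
    temps = {fit_alone.temperature, fit_PHB.temperature, fit_IBP.temperature}
    if len(temps) != 1:
        raise ValidationError("site-marker fits must share one temperature")
    r_phb = fit_PHB.Kb / fit_alone.Kb
    r_ibp = fit_IBP.Kb / fit_alone.Kb
    if r_ibp < r_phb and r_phb < 1 and r_ibp < 1:
        site = "site_II_IIIA"
    elif r_phb < r_ibp and r_phb < 1 and r_ibp < 1:
        site = "site_I_IIA"
    else:
        site = "indeterminate"
    return SiteAssignment(ratio_PHB=r_phb, ratio_IBP=r_ibp, site=site)
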