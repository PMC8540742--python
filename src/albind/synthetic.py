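"""Synthetic titration, CD and FT-IR data with known ground truth.

Each generator samples exactly the model its analysis stage assumes, so in
the noiseless limit the analysis is the generator's inverse and parameter
recovery is exact by construction:

* titrations: 1:1 ground-state complex (static quenching),
  F = F0 / (1 + Kb [Q]^n), with Kb(T) from a van't Hoff law and an optional
  inner-filter attenuation that the Eq.-style correction inverts exactly;
* CD: a smooth two-lobe negative band (208/222 nm) whose 208 nm ellipticity
  encodes a programmed helix fraction through the MRE anchors;
* FT-IR: an amide-I envelope as a sum of Gaussians with class areas equal to
  programmed structure fractions, on a linear baseline.

All randomness flows through one seeded generator per simulation call, so
identical scenario + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cd import MRE_CROSSOVER, MRE_PURE_HELIX
from .errors import ConfigError, ValidationError
from .ftir import ASSIGNMENT_RANGES, GAUSS_AREA_FACTOR
from .io import Spectrum, TitrationPoint, TitrationSeries
from .thermodynamics import R

_MARKER_INDEX = {"none": 0, "PHB": 1, "IBP": 2}


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _default_ratios() -> tuple[float, ...]:
    # ligand:protein molar ratios 0.1 .. 1.9 in 0.2 steps (10 additions)
    return tuple(round(0.1 + 0.2 * i, 10) for i in range(10))


@dataclass
class BindingScenario:
    """Ground truth for a fluorescence titration experiment.

    Defaults encode the study design this package targets: BSA at 1e-6
    mol dm-3 titrated at ligand:protein ratios 0.1-2.0 in 0.2 steps at
    297/303/308 K, with an exothermic, entropy-unfavourable 1:1 complex
    (dH = -40 kJ mol-1, dS = -39 J mol-1 K-1) giving Kb(297 K) ~ 1e5
    dm3 mol-1.
    """

    dH: float = -40000.0  # J mol-1
    dS: float = -39.0  # J mol-1 K-1
    n_sites: float = 1.0
    tau0: float = 1e-8  # s
    F0: float = 1000.0  # a.u.
    emission_peak: float = 348.0  # nm
    emission_fwhm: float = 50.0  # nm
    protein_conc: float = 1e-6  # mol dm-3
    ratios: tuple[float, ...] = field(default_factory=_default_ratios)
    temperatures: tuple[float, ...] = (297.0, 303.0, 308.0)
    marker_factors: dict[str, float] = field(
        default_factory=lambda: {"PHB": 0.9, "IBP": 0.5}
    )
    epsilon_ex: float = 0.0  # dm3 mol-1 cm-1
    epsilon_em: float = 0.0
    pathlength: float = 1.0  # cm, for the inner-filter absorbances
    noise_sigma: float = 0.0  # gaussian sd as a fraction of F0
    seed: int = 42

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, dtype=float)
        if (ratios <= 0).any() or (np.diff(ratios) <= 0).any():
            raise ConfigError("ratios must be positive and strictly increasing")
        temps = np.asarray(self.temperatures, dtype=float)
        if (np.diff(temps) <= 0).any() or (temps <= 0).any():
            raise ConfigError("temperatures must be positive and increasing")
        for name, f in self.marker_factors.items():
            if not 0 < f <= 1:
                raise ConfigError(f"marker factor for {name} must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    def Kb(self, temperature: float) -> float:
        """van't Hoff binding constant at *temperature* (dm3 mol-1)."""
        return math.exp(-self.dH / (R * temperature) + self.dS / R)


def default_scenario() -> BindingScenario:
    """The package's reference binding scenario (noiseless, seed 42)."""
    return BindingScenario()


def simulate_titration(
    scenario: BindingScenario,
    temperature: float,
    marker: str = "none",
    mass_action: bool = False,
) -> TitrationSeries:
    """Simulate one titration series at *temperature* / *marker*.

    By default intensities follow the regression model itself,
    F = F0 / (1 + Kb_eff [Q]^n) with [Q] the total added ligand, so the
    double-log fit recovers (Kb_eff, n) exactly at zero noise.  With
    ``mass_action=True`` (only defined for n_sites == 1) the free-ligand
    1:1 equilibrium is solved instead, which introduces the real-world bias
    of treating total ligand as free ligand in the regression.
    """
    temps = list(scenario.temperatures)
    if temperature not in temps:
        raise ConfigError(f"temperature {temperature} not in scenario.temperatures")
    if marker != "none" and marker not in scenario.marker_factors:
        raise ConfigError(f"no marker factor configured for {marker!r}")
    kb = scenario.Kb(temperature)
    if marker != "none":
        kb *= scenario.marker_factors[marker]

    rng = _rng(scenario.seed, temps.index(temperature), _MARKER_INDEX[marker])
    points = [TitrationPoint(0.0, scenario.F0)]
    for ratio in scenario.ratios:
        Q = ratio * scenario.protein_conc
        if mass_action:
            if scenario.n_sites != 1:
                raise ConfigError("mass_action model is defined for n_sites == 1 only")
            # free-ligand 1:1 equilibrium: solve Kb*Lf^2 + (1 + Kb*(P - Q))*Lf - Q = 0
            P = scenario.protein_conc
            b = 1.0 + kb * (P - Q)
            Lf = (-b + math.sqrt(b * b + 4.0 * kb * Q)) / (2.0 * kb)
            bound_frac = kb * Lf / (1.0 + kb * Lf)
            F = scenario.F0 * (1.0 - bound_frac)
        else:
            F = scenario.F0 / (1.0 + kb * Q**scenario.n_sites)
        Aex = scenario.epsilon_ex * Q * scenario.pathlength
        Aem = scenario.epsilon_em * Q * scenario.pathlength
        F_obs = F / 10.0 ** ((Aex + Aem) / 2.0)
        if scenario.noise_sigma > 0:
            F_obs += rng.normal(0.0, scenario.noise_sigma * scenario.F0)
            F_obs = max(F_obs, 1e-9)
        points.append(TitrationPoint(Q, F_obs, Aex, Aem))
    return TitrationSeries(
        temperature=temperature,
        protein_conc=scenario.protein_conc,
        marker=marker,
        points=points,
        meta={"seed": scenario.seed, "Kb_true": kb, "n_true": scenario.n_sites},
    )


def simulate_emission_spectra(
    scenario: BindingScenario, temperature: float, marker: str = "none"
) -> list[Spectrum]:
    """Full emission spectra (300-500 nm) for each titration point.

    A Gaussian tryptophan-like band at the scenario's emission peak is scaled
    to the titration intensity; the spectra-dialect reader extracts the same
    F values at the reference-spectrum maximum.
    """
    series = simulate_titration(scenario, temperature, marker)
    wl = np.arange(300.0, 500.5, 1.0)
    sigma = scenario.emission_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    band = np.exp(-((wl - scenario.emission_peak) ** 2) / (2.0 * sigma**2))
    spectra = []
    for p in series.points:
        spectra.append(
            Spectrum(
                x=wl,
                y=p.F * band,
                axis_kind="wavelength_nm",
                meta={
                    "quencher_conc_M": p.quencher_conc,
                    "temperature_K": temperature,
                    "marker": marker,
                },
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# structural (CD / FT-IR) scenarios


def _default_fractions() -> dict[str, float]:
    return {"alpha_helix": 0.538, "beta_sheet": 0.292, "beta_turn": 0.170}


def _default_centers() -> dict[str, float]:
    return {
        "alpha_helix": 1658.0,
        "beta_sheet": 1632.0,
        "beta_turn": 1685.0,
        "beta_antiparallel": 1694.0,
        "random_coil": 1645.0,
    }


def _default_fwhms() -> dict[str, float]:
    return {
        "alpha_helix": 14.0,
        "beta_sheet": 16.0,
        "beta_turn": 10.0,
        "beta_antiparallel": 8.0,
        "random_coil": 12.0,
    }


def _default_helix_by_ratio() -> dict[float, float]:
    # free-BSA helix 60% eroding to 55.7% at 10:1 ligand excess (4.3-point loss)
    return {0.0: 0.600, 0.5: 0.595, 1.0: 0.589, 5.0: 0.570, 10.0: 0.557}


@dataclass
class StructureScenario:
    """Ground truth for CD and amide-I secondary-structure data.

    Default amide-I composition mirrors free BSA: 53.8% alpha-helix, 29.2%
    beta-sheet, 17.0% beta-turn.  Noise is Gaussian with sd expressed as a
    fraction of the amide-I peak height (or of the 208 nm CD magnitude).
    """

    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    band_centers: dict[str, float] = field(default_factory=_default_centers)
    band_fwhms: dict[str, float] = field(default_factory=_default_fwhms)
    helix_by_ratio: dict[float, float] = field(default_factory=_default_helix_by_ratio)
    noise_sigma: float = 0.002
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions must sum to 1 (got {total})")
        for cls, frac in self.class_fractions.items():
            if frac < 0:
                raise ConfigError(f"negative fraction for {cls}")
            if cls not in ASSIGNMENT_RANGES:
                raise ConfigError(f"unknown structure class {cls!r}")
            lo, hi = ASSIGNMENT_RANGES[cls]
            center = self.band_centers[cls]
            if not (lo <= center < hi or (cls == "beta_antiparallel" and center == hi)):
                raise ConfigError(
                    f"{cls} band center {center} outside its assignment "
                    f"range [{lo}, {hi})"
                )


def simulate_cd_series(
    scenario: StructureScenario,
    C: float = 1e-6,
    n_residues: int = 583,
    l: float = 1.0,
) -> list[Spectrum]:
    """Far-UV CD spectra (205-250 nm), one per ligand:protein ratio.

    The band is a smooth sum of two negative lobes at 208 and 222 nm (the
    classic alpha-helical double minimum), rescaled so the 205-250 nm curve
    passes exactly through the ellipticity that encodes the programmed helix
    fraction at 208 nm: CD(208) = -(4000 + 29000*h) * (10 C n l) mdeg.
    """
    wl = np.arange(205.0, 250.5, 0.5)
    lobe208 = np.exp(-((wl - 208.0) ** 2) / (2.0 * 4.5**2))
    lobe222 = np.exp(-((wl - 222.0) ** 2) / (2.0 * 6.0**2))
    shape = lobe208 + 0.95 * lobe222
    shape_at_208 = float(np.interp(208.0, wl, shape))
    spectra = []
    for i, (ratio, h) in enumerate(sorted(scenario.helix_by_ratio.items())):
        if not 0.0 <= h <= 1.0:
            raise ValidationError(f"helix fraction {h} outside [0, 1]")
        target208 = -(MRE_CROSSOVER + (MRE_PURE_HELIX - MRE_CROSSOVER) * h) * (
            10.0 * C * n_residues * l
        )
        y = target208 * shape / shape_at_208
        if scenario.noise_sigma > 0:
            rng = _rng(scenario.seed, 10, i)
            y = y + rng.normal(0.0, scenario.noise_sigma * abs(target208), size=wl.shape)
        spectra.append(
            Spectrum(x=wl, y=y, axis_kind="wavelength_nm", meta={"ratio": ratio})
        )
    return spectra


def simulate_ftir_spectrum(scenario: StructureScenario) -> Spectrum:
    """One amide-I IR spectrum (1580-1720 cm-1, 0.5 cm-1 grid).

    Class band areas are proportional to the programmed fractions; a gentle
    linear baseline and seeded Gaussian noise (sd = noise_sigma * peak
    height) are added on top.
    """
    x = np.arange(1580.0, 1720.5, 0.5)
    y = np.zeros_like(x)
    for cls, frac in scenario.class_fractions.items():
        if frac == 0:
            continue
        center = scenario.band_centers[cls]
        fwhm = scenario.band_fwhms[cls]
        height = frac / (fwhm * GAUSS_AREA_FACTOR)  # area == frac
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        y += height * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    peak = y.max()
    baseline = 0.02 + 2e-5 * (x - x[0])
    y = y + baseline
    if scenario.noise_sigma > 0:
        rng = _rng(scenario.seed, 20)
        y = y + rng.normal(0.0, scenario.noise_sigma * peak, size=x.shape)
    return Spectrum(
        x=x, y=y, axis_kind="wavenumber_cm-1", meta={"seed": scenario.seed}
    )
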