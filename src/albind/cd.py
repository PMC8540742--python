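"""Alpha-helix quantification from far-UV circular dichroism spectra.

Observed ellipticity (mdeg) is converted to mean residue ellipticity

    MRE = CD_obs / (10 * C * n * l)

with C the protein molar concentration, n the residue count (583 for BSA)
and l the path length in cm.  The helix fraction follows from the MRE at
208 nm using the standard anchors: -33000 deg cm2 dmol-1 for pure alpha
helix and -4000 at the beta/random-coil crossover,

    helix% = (-MRE208 - 4000) / (33000 - 4000) * 100.

Values outside [0, 100] are reported unclamped with ``in_range`` False so
that inconsistent concentration metadata stays visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Spectrum

#: Eq. anchors for the 208 nm estimator, deg cm2 dmol-1 (magnitudes)
MRE_PURE_HELIX = 33000.0
MRE_CROSSOVER = 4000.0

#: BSA defaults
BSA_N_RESIDUES = 583
DEFAULT_PATHLENGTH_CM = 1.0
DEFAULT_PROTEIN_CONC = 1e-6  # mol dm-3

HELIX_WAVELENGTH_NM = 208.0


def mean_residue_ellipticity(
    observed_cd: float, C: float, n_residues: int, l: float
) -> float:
    """MRE (deg cm2 dmol-1) from observed ellipticity in millidegrees."""
    if not C > 0:
        raise ValidationError("protein concentration must be > 0")
    if not n_residues >= 1:
        raise ValidationError("n_residues must be >= 1")
    if not l > 0:
        raise ValidationError("path length must be > 0")
    return observed_cd / (10.0 * C * n_residues * l)


def alpha_helix_percent(MRE208: float) -> float:
    """Helix content (%) from the mean residue ellipticity at 208 nm."""
    if not math.isfinite(MRE208):
        raise ValidationError("MRE208 must be finite")
    return (-MRE208 - MRE_CROSSOVER) / (MRE_PURE_HELIX - MRE_CROSSOVER) * 100.0


@dataclass(frozen=True)
class HelixContent:
    """Helix percentage at one ligand:protein molar ratio."""

    ratio: float
    MRE208: float
    helix_percent: float

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.helix_percent <= 100.0


@dataclass
class CDHelixResults:
    """Per-ratio helix contents and the overall helix loss."""

    contents: list[HelixContent]

    @property
    def loss(self) -> float:
        """Helix loss in percentage points: helix%(ratio 0) - helix%(max ratio)."""
        by_ratio = {c.ratio: c.helix_percent for c in self.contents}
        return by_ratio[0.0] - by_ratio[max(by_ratio)]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": [c.ratio for c in self.contents],
                "MRE208": [c.MRE208 for c in self.contents],
                "helix_percent": [c.helix_percent for c in self.contents],
                "in_range": [c.in_range for c in self.contents],
            }
        )

    def summary(self) -> str:
        lines = ["CD alpha-helix content (208 nm estimator)"]
        for c in self.contents:
            flag = "" if c.in_range else "  [out of range]"
            lines.append(
                f"  ratio {c.ratio:>5.2f}: MRE208 = {c.MRE208:9.1f},"
                f" helix = {c.helix_percent:6.2f}%{flag}"
            )
        lines.append(f"  helix loss: {self.loss:.2f} percentage points")
        return "\n".join(lines)


def helix_loss_table(
    spectra: list[Spectrum],
    C: float = DEFAULT_PROTEIN_CONC,
    n_residues: int = BSA_N_RESIDUES,
    l: float = DEFAULT_PATHLENGTH_CM,
) -> CDHelixResults:
    """Helix content per ligand:protein ratio and the loss across the series.

    Each spectrum must carry a numeric ``ratio`` metadata key and cover
    208 nm; the ellipticity there is taken by linear interpolation on the
    wavelength grid.  A ratio-0 (free protein) spectrum is required.
    """
    contents = []
    for spec in spectra:
        if "ratio" not in spec.meta:
            raise ValidationError("every CD spectrum needs a 'ratio' metadata key")
        ratio = float(spec.meta["ratio"])
        cd208 = spec.value_at(HELIX_WAVELENGTH_NM)
        mre = mean_residue_ellipticity(cd208, C, n_residues, l)
        contents.append(
            HelixContent(ratio=ratio, MRE208=mre, helix_percent=alpha_helix_percent(mre))
        )
    contents.sort(key=lambda c: c.ratio)
    if not any(c.ratio == 0.0 for c in contents):
        raise ValidationError("no ratio-0 (free protein) spectrum supplied")
    return CDHelixResults(contents=contents)
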