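"""Delimited-text I/O for spectra and fluorescence titration tables.

All files are plain CSV (comma separator, ``.`` decimal, UTF-8) with an
optional metadata header of ``# key: value`` lines.  Recognised metadata keys:
``compound``, ``temperature_K``, ``protein_conc_M``, ``marker``,
``pathlength_cm``, ``n_residues``, ``ratio``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

AXIS_KINDS = ("wavelength_nm", "wavenumber_cm-1")
MARKERS = ("none", "PHB", "IBP")

#: float format used when writing, chosen so a write/read round trip is exact
_FLOAT_FMT = "%.17g"


@dataclass
class Spectrum:
    """A single 1-D spectrum on a strictly increasing axis.

    Parameters
    ----------
    x : array-like
        Axis values (nm or cm^-1 per *axis_kind*).  May arrive in any order;
        the constructor sorts ascending and reorders *y* accordingly.
    y : array-like
        Intensities: fluorescence (a.u.), CD (mdeg) or IR absorbance.
    axis_kind : str
        One of ``wavelength_nm`` or ``wavenumber_cm-1``.
    meta : dict
        Free-form labels (compound, temperature_K, ratio, ...).
    """

    x: np.ndarray
    y: np.ndarray
    axis_kind: str = "wavelength_nm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(f"unknown axis_kind {self.axis_kind!r}")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValidationError("x and y must be 1-D and of equal length")
        if len(x) < 8:
            raise ValidationError(f"spectrum needs >= 8 points, got {len(x)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("spectrum contains non-finite values")
        if (x <= 0).any():
            raise ValidationError("axis values must be positive")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if (np.diff(x) <= 0).any():
            raise ValidationError("duplicate axis values")
        self.x, self.y = x, y

    def value_at(self, x0: float) -> float:
        """Intensity at *x0* by linear interpolation on the axis grid."""
        if not (self.x[0] <= x0 <= self.x[-1]):
            raise ValidationError(
                f"{x0} outside spectral range [{self.x[0]}, {self.x[-1]}]"
            )
        return float(np.interp(x0, self.x, self.y))


@dataclass(frozen=True)
class TitrationPoint:
    """One addition in a fluorescence titration."""

    quencher_conc: float  # total added ligand, mol dm^-3
    F: float  # intensity at the analysis wavelength, a.u.
    Aex: float = 0.0  # absorbance at the excitation wavelength
    Aem: float = 0.0  # absorbance at the emission wavelength

    def __post_init__(self) -> None:
        if self.quencher_conc < 0:
            raise ValidationError("quencher_conc must be >= 0")
        if not self.F > 0:
            raise ValidationError("fluorescence intensity must be > 0")
        if self.Aex < 0 or self.Aem < 0:
            raise ValidationError("absorbances must be >= 0")


@dataclass
class TitrationSeries:
    """A fluorescence titration at one temperature / site-marker condition.

    The first point is the zero-quencher reference (F0).
    """

    temperature: float  # K
    points: list[TitrationPoint]
    protein_conc: float = 1e-6  # mol dm^-3
    marker: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.marker not in MARKERS:
            raise ValidationError(f"marker must be one of {MARKERS}")
        if len(self.points) < 3:
            raise ValidationError("titration needs >= 3 points")
        conc = np.array([p.quencher_conc for p in self.points])
        if conc[0] != 0.0:
            raise ValidationError("first point must be the zero-quencher reference")
        if (np.diff(conc) <= 0).any():
            raise ValidationError("quencher concentrations must be strictly increasing")

    @property
    def F0(self) -> float:
        return self.points[0].F

    @property
    def quencher_conc(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    @property
    def F(self) -> np.ndarray:
        return np.array([p.F for p in self.points])


# ---------------------------------------------------------------------------
# reading


def _read_meta_and_table(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                stripped = line.lstrip()[1:].strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    table = pd.read_csv(_io.StringIO("".join(body_lines)))
    return meta, table


def _numeric_column(table: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(table[col], errors="coerce")
    bad = vals.isna() & table[col].notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise FormatError(f"{path}: missing value in column {col!r} at line {line}")
    return vals.to_numpy(dtype=float)


def read_spectrum(path, axis_kind: str = "wavelength_nm") -> Spectrum:
    """Read a two-column (axis, intensity) CSV into a :class:`Spectrum`.

    Rows may appear in any order; the result is sorted ascending in the axis.
    """
    meta, table = _read_meta_and_table(path)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (axis, intensity)")
    cols = list(table.columns)[:2]
    x = _numeric_column(table, cols[0], path)
    y = _numeric_column(table, cols[1], path)
    if "ratio" in meta:
        meta["ratio"] = float(meta["ratio"])
    return Spectrum(x=x, y=y, axis_kind=axis_kind, meta=meta)


def _series_from_meta(meta: Mapping, points: list[TitrationPoint]) -> TitrationSeries:
    return TitrationSeries(
        temperature=float(meta.get("temperature_K", 297.0)),
        protein_conc=float(meta.get("protein_conc_M", 1e-6)),
        marker=str(meta.get("marker", "none")),
        points=points,
        meta=dict(meta),
    )


def read_titration(path, dialect: str = "summary") -> TitrationSeries:
    """Read a titration table.

    ``summary`` dialect: columns ``quencher_conc_M``, ``F`` and optionally
    ``A_ex``, ``A_em`` — one row per addition.

    ``spectra`` dialect: long-format emission spectra with columns
    ``wavelength_nm``, ``intensity``, ``quencher_conc_M``.  The intensity F for
    every addition is read at the emission-maximum wavelength of the
    zero-quencher spectrum (one fixed wavelength for the whole titration, so a
    ligand-induced red shift cannot masquerade as quenching).
    """
    meta, table = _read_meta_and_table(path)
    if dialect == "summary":
        required = ["quencher_conc_M", "F"]
    elif dialect == "spectra":
        required = ["wavelength_nm", "intensity", "quencher_conc_M"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in required:
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    if dialect == "summary":
        conc = _numeric_column(table, "quencher_conc_M", path)
        F = _numeric_column(table, "F", path)
        aex = (
            _numeric_column(table, "A_ex", path)
            if "A_ex" in table.columns
            else np.zeros_like(F)
        )
        aem = (
            _numeric_column(table, "A_em", path)
            if "A_em" in table.columns
            else np.zeros_like(F)
        )
        order = np.argsort(conc, kind="stable")
        conc, F, aex, aem = conc[order], F[order], aex[order], aem[order]
        if len(np.unique(conc)) != len(conc):
            raise ValidationError(f"{path}: duplicate quencher concentrations")
        if conc[0] != 0.0:
            raise ValidationError(f"{path}: no zero-concentration reference row")
        points = [
            TitrationPoint(c, f, a1, a2) for c, f, a1, a2 in zip(conc, F, aex, aem)
        ]
        return _series_from_meta(meta, points)

    # spectra dialect
    wl = _numeric_column(table, "wavelength_nm", path)
    inten = _numeric_column(table, "intensity", path)
    conc = _numeric_column(table, "quencher_conc_M", path)
    concs = np.unique(conc)
    if 0.0 not in concs:
        raise ValidationError(f"{path}: no zero-concentration reference spectrum")
    ref_mask = conc == 0.0
    ref = Spectrum(wl[ref_mask], inten[ref_mask], "wavelength_nm")
    lam_max = float(ref.x[np.argmax(ref.y)])
    points = []
    for c in concs:
        m = conc == c
        spec = Spectrum(wl[m], inten[m], "wavelength_nm")
        points.append(TitrationPoint(float(c), spec.value_at(lam_max)))
    series = _series_from_meta(meta, points)
    series.meta["analysis_wavelength_nm"] = lam_max
    return series


# ---------------------------------------------------------------------------
# writing


def _write_meta(fh, meta: Mapping) -> None:
    for key in sorted(meta):
        fh.write(f"# {key}: {meta[key]}\n")


def write_spectrum(spectrum: Spectrum, path) -> Path:
    path = Path(path)
    axis_col = "wavelength_nm" if spectrum.axis_kind == "wavelength_nm" else "wavenumber_cm1"
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, spectrum.meta)
        pd.DataFrame({axis_col: spectrum.x, "intensity": spectrum.y}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
        )
    return path


def write_titration(series: TitrationSeries, path) -> Path:
    path = Path(path)
    meta = dict(series.meta)
    meta.update(
        temperature_K=series.temperature,
        protein_conc_M=series.protein_conc,
        marker=series.marker,
    )
    frame = pd.DataFrame(
        {
            "quencher_conc_M": [p.quencher_conc for p in series.points],
            "F": [p.F for p in series.points],
            "A_ex": [p.Aex for p in series.points],
            "A_em": [p.Aem for p in series.points],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


#: canonical stage order for report tables
_STAGES = (
    "stern_volmer",
    "binding",
    "thermodynamics",
    "site_markers",
    "cd_helix",
    "ftir_structure",
    "druglikeness",
)


def write_report_tables(results: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write one CSV per analysis stage; returns paths in deterministic order."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        known = [s for s in _STAGES if s in results]
        extra = sorted(k for k in results if k not in _STAGES)
        paths = []
        for stage in known + extra:
            p = out_dir / f"{stage}.csv"
            results[stage].to_csv(p, index=False, lineterminator="\n")
            paths.append(p)
        return paths
    except OSError as exc:  # unwritable directory and friends
        raise OSError(f"cannot write report tables to {out_dir}: {exc}") from exc
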