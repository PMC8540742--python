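"""End-to-end analysis runs: config, staging, report tables and manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cd as cd_mod
from . import ftir as ftir_mod
from .druglikeness import read_descriptor_table, screen_table
from .errors import AnalysisError, ValidationError
from .io import read_spectrum, read_titration, write_report_tables
from .quenching import (
    DEFAULT_TAU0,
    assess_site_competition,
    classify_mechanism,
    fit_double_log,
    fit_stern_volmer,
)
from .thermodynamics import classify_interaction, fit_vant_hoff

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Modality inputs are optional; a run analyzes whichever are present.
    """

    out_dir: str = "albind_out"
    fluor_dir: str | None = None  # directory of titration CSVs (summary dialect)
    cd_dir: str | None = None  # directory of CD spectrum CSVs with ratio metadata
    ftir_path: str | None = None  # one amide-I spectrum CSV
    descriptors_path: str | None = None  # druglikeness descriptor CSV
    compound: str = "compound"
    tau0: float = DEFAULT_TAU0  # s
    pathlength: float = 1.0  # cm
    n_residues: int = 583
    protein_conc: float = 1e-6  # mol dm-3
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.pathlength <= 0 or self.protein_conc <= 0:
            raise ValidationError("physical parameters must be positive")
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    def hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def _setup_logging(config: RunConfig, out_dir: Path) -> None:
    root = logging.getLogger("albind")
    root.setLevel(config.log_level.upper())
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "run.log"
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s [%(name)s] %(message)s")
        )
        root.addHandler(fh)


def _write_manifest(config: RunConfig, out_dir: Path) -> None:
    (out_dir / "config.json").write_text(config.to_canonical_json())
    manifest = {"config_hash": config.hash(), "seed": config.seed}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))


@dataclass
class FluorescenceReport:
    """Result bundle of the full quenching/thermodynamics chain."""

    sv_fits: list
    mechanism: object
    binding_fits: list
    vant_hoff: object
    interaction: object
    site_assignment: object | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        parts = [f.summary() for f in self.sv_fits]
        parts.append(self.mechanism.summary())
        parts += [f.summary() for f in self.binding_fits]
        parts.append(self.vant_hoff.summary())
        parts.append(self.interaction.summary())
        if self.site_assignment is not None:
            parts.append(self.site_assignment.summary())
        return "\n\n".join(parts)


def run_fluorescence_workflow(config: RunConfig) -> FluorescenceReport:
    """Inner-filter -> Stern-Volmer -> mechanism -> double-log -> van't Hoff
    -> interaction -> site competition (when marker series are present).

    Reads every ``*.csv`` under ``config.fluor_dir`` as a summary-dialect
    titration (temperature and marker from its metadata header) and writes the
    stage tables plus a run manifest to ``config.out_dir``.
    """
    if config.fluor_dir is None:
        raise ValidationError("no fluorescence input directory configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)

    paths = sorted(Path(config.fluor_dir).glob("*.csv"))
    series = [read_titration(p, dialect="summary") for p in paths]
    if not series:
        raise ValidationError(f"no titration CSVs found in {config.fluor_dir}")
    plain = sorted((s for s in series if s.marker == "none"), key=lambda s: s.temperature)
    if len(plain) < 2:
        raise ValidationError("need >= 2 no-marker temperature series")
    if len(plain) == 2:
        log.warning("only 2 temperatures: van't Hoff line is exact (low confidence)")

    log.info("stage: stern_volmer (%d series)", len(plain))
    sv_fits = [fit_stern_volmer(s, tau0=config.tau0) for s in plain]
    log.info("stage: mechanism")
    mechanism = classify_mechanism(sv_fits)
    log.info("stage: double_log (%d series)", len(series))
    binding_fits = [fit_double_log(s) for s in sorted(
        series, key=lambda s: (s.marker, s.temperature))]
    log.info("stage: vant_hoff")
    kb_by_T = {f.temperature: f.Kb for f in binding_fits if f.marker == "none"}
    vant_hoff = fit_vant_hoff(kb_by_T)
    interaction = classify_interaction(vant_hoff)

    tables = {
        "stern_volmer": pd.DataFrame(
            {
                "compound": config.compound,
                "temperature_K": [f.temperature for f in sv_fits],
                "K_SV": [f.K_SV for f in sv_fits],
                "intercept": [f.intercept for f in sv_fits],
                "k_q": [f.k_q for f in sv_fits],
                "r2": [f.r2 for f in sv_fits],
            }
        ),
        "binding": pd.DataFrame(
            {
                "compound": config.compound,
                "temperature_K": [f.temperature for f in binding_fits],
                "marker": [f.marker for f in binding_fits],
                "Kb": [f.Kb for f in binding_fits],
                "n": [f.n_sites for f in binding_fits],
                "r2": [f.r2 for f in binding_fits],
            }
        ),
        "thermodynamics": pd.DataFrame(
            [
                {
                    "compound": config.compound,
                    "dH_kJ_mol": vant_hoff.dH / 1000.0,
                    "dS_J_mol_K": vant_hoff.dS,
                    **{
                        f"dG_kJ_mol_{T:.0f}K": g / 1000.0
                        for T, g in sorted(vant_hoff.dG_by_T.items())
                    },
                    "forces": interaction.forces,
                    "spontaneous": interaction.spontaneous,
                }
            ]
        ),
    }
    # earlier stage outputs are written (and retained) before the
    # site-competition stage, which may fail on mismatched marker series
    write_report_tables(tables, out_dir)
    _write_manifest(config, out_dir)

    site = None
    by_marker_T = {(f.marker, f.temperature): f for f in binding_fits}
    shared_T = [
        T
        for (m, T) in by_marker_T
        if m == "none" and ("PHB", T) in by_marker_T and ("IBP", T) in by_marker_T
    ]
    markers_present = {m for m, _ in by_marker_T if m != "none"}
    if shared_T:
        T = min(shared_T)
        log.info("stage: site_competition at %.0f K", T)
        site = assess_site_competition(
            by_marker_T[("none", T)], by_marker_T[("PHB", T)], by_marker_T[("IBP", T)]
        )
        tables["site_markers"] = pd.DataFrame(
            [
                {
                    "compound": config.compound,
                    "ratio_PHB": site.ratio_PHB,
                    "ratio_IBP": site.ratio_IBP,
                    "site": site.site,
                }
            ]
        )
        write_report_tables({"site_markers": tables["site_markers"]}, out_dir)
    elif markers_present:
        raise AnalysisError(
            "site-competition stage: marker series present but no temperature is "
            "shared by the no-marker, PHB and IBP series"
        )
    return FluorescenceReport(
        sv_fits=sv_fits,
        mechanism=mechanism,
        binding_fits=binding_fits,
        vant_hoff=vant_hoff,
        interaction=interaction,
        site_assignment=site,
        tables=tables,
    )


def run_cd_workflow(config: RunConfig) -> cd_mod.CDHelixResults:
    if config.cd_dir is None:
        raise ValidationError("no CD input directory configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)
    spectra = [
        read_spectrum(p, axis_kind="wavelength_nm")
        for p in sorted(Path(config.cd_dir).glob("*.csv"))
    ]
    if not spectra:
        raise ValidationError(f"no CD spectra found in {config.cd_dir}")
    log.info("stage: cd_helix (%d spectra)", len(spectra))
    results = cd_mod.helix_loss_table(
        spectra,
        C=config.protein_conc,
        n_residues=config.n_residues,
        l=config.pathlength,
    )
    table = results.table()
    table.insert(0, "compound", config.compound)
    summary = pd.DataFrame(
        [{"compound": config.compound, "ratio": "loss_points",
          "MRE208": "", "helix_percent": results.loss, "in_range": ""}]
    )
    write_report_tables({"cd_helix": pd.concat([table, summary], ignore_index=True)}, out_dir)
    return results


def run_ftir_workflow(config: RunConfig) -> ftir_mod.AmideIResults:
    if config.ftir_path is None:
        raise ValidationError("no FT-IR input configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)
    spectrum = read_spectrum(config.ftir_path, axis_kind="wavenumber_cm-1")
    log.info("stage: ftir_structure")
    results = ftir_mod.AmideIModel(spectrum).fit()
    table = results.table()
    table.insert(0, "compound", config.compound)
    write_report_tables({"ftir_structure": table}, out_dir)
    return results


def run_druglikeness_workflow(config: RunConfig) -> pd.DataFrame:
    if config.descriptors_path is None:
        raise ValidationError("no descriptor table configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)
    log.info("stage: druglikeness")
    verdicts = screen_table(read_descriptor_table(config.descriptors_path))
    write_report_tables({"druglikeness": verdicts}, out_dir)
    return verdicts


def run_full_report(config: RunConfig) -> Path:
    """Run every modality whose inputs are configured; write a JSON summary.

    Returns the output directory.  Raises if no modality at all is configured;
    a failure inside one modality propagates with the stage name while the
    tables already written by other modalities are retained.
    """
    if not any([config.fluor_dir, config.cd_dir, config.ftir_path, config.descriptors_path]):
        raise ValidationError("no inputs configured for any modality")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, out_dir)

    summary: dict = {"compound": config.compound, "seed": config.seed}
    if config.fluor_dir:
        rep = run_fluorescence_workflow(config)
        summary["fluorescence"] = {
            "K_SV": {f"{f.temperature:.0f}": f.K_SV for f in rep.sv_fits},
            "mechanism": rep.mechanism.verdict,
            "Kb": {
                f"{f.marker}@{f.temperature:.0f}": f.Kb for f in rep.binding_fits
            },
            "n_sites": {
                f"{f.marker}@{f.temperature:.0f}": f.n_sites for f in rep.binding_fits
            },
            "dH_J_mol": rep.vant_hoff.dH,
            "dS_J_mol_K": rep.vant_hoff.dS,
            "dG_J_mol": {f"{T:.0f}": g for T, g in sorted(rep.vant_hoff.dG_by_T.items())},
            "forces": rep.interaction.forces,
            "spontaneous": rep.interaction.spontaneous,
        }
        if rep.site_assignment is not None:
            summary["fluorescence"]["site"] = rep.site_assignment.site
    if config.cd_dir:
        cd_res = run_cd_workflow(config)
        summary["cd"] = {
            "helix_percent": {f"{c.ratio:g}": c.helix_percent for c in cd_res.contents},
            "loss_points": cd_res.loss,
        }
    if config.ftir_path:
        ftir_res = run_ftir_workflow(config)
        summary["ftir"] = {
            "percent_by_class": dict(sorted(ftir_res.structure.percent_by_class.items())),
            "n_components": ftir_res.structure.n_components,
            "residual_rms": ftir_res.residual_rms,
        }
    if config.descriptors_path:
        verdicts = run_druglikeness_workflow(config)
        summary["druglikeness"] = {
            row["compound_id"]: {
                "ro5_violations": int(row["ro5_violations"]),
                "ro5_pass": bool(row["ro5_pass"]),
                "veber_pass": bool(row["veber_pass"]),
                "tpsa_pass": bool(row["tpsa_pass"]),
            }
            for _, row in verdicts.iterrows()
        }
    (out_dir / "report.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    _write_manifest(config, out_dir)
    return out_dir
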