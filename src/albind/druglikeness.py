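"""Lipinski / Veber / TPSA druglikeness screening over descriptor tables.

Rules use the classic thresholds: Lipinski's rule of five counts violations
over {MW > 500, logP > 5, HBD > 5, HBA > 10} and passes with at most one;
Veber requires rotatable bonds <= 10 and TPSA <= 140 A^2; the standalone
TPSA screen is TPSA < 140 A^2.  Descriptor computation from structures is
out of scope — records are user-supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import pandas as pd

from .errors import ValidationError

DESCRIPTOR_COLUMNS = ("compound_id", "MW", "logP", "HBD", "HBA", "rotatable_bonds", "TPSA")


@dataclass(frozen=True)
class DescriptorRecord:
    """Molecular descriptors for one compound."""

    compound_id: str
    MW: float  # g mol-1
    logP: float
    HBD: int
    HBA: int
    rotatable_bonds: int
    TPSA: float  # A^2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                raise ValidationError(f"missing descriptor {f.name!r}")
        if not self.MW > 0:
            raise ValidationError("MW must be > 0")
        if self.HBD < 0 or self.HBA < 0 or self.rotatable_bonds < 0:
            raise ValidationError("counts must be >= 0")
        if self.TPSA < 0:
            raise ValidationError("TPSA must be >= 0")


@dataclass(frozen=True)
class RuleVerdict:
    """Rule outcomes for one compound."""

    compound_id: str
    ro5_violations: int
    veber_pass: bool
    tpsa_pass: bool

    @property
    def ro5_pass(self) -> bool:
        return self.ro5_violations <= 1


def evaluate_rules(record: DescriptorRecord) -> RuleVerdict:
    """Apply Lipinski, Veber and TPSA screens to one descriptor record."""
    violations = sum(
        [
            record.MW > 500.0,
            record.logP > 5.0,
            record.HBD > 5,
            record.HBA > 10,
        ]
    )
    return RuleVerdict(
        compound_id=record.compound_id,
        ro5_violations=int(violations),
        veber_pass=record.rotatable_bonds <= 10 and record.TPSA <= 140.0,
        tpsa_pass=record.TPSA < 140.0,
    )


def screen_table(records: Sequence[DescriptorRecord]) -> pd.DataFrame:
    """Verdicts for a whole descriptor table, input order preserved."""
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate compound ids")
    rows = []
    for rec in records:
        v = evaluate_rules(rec)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "MW": rec.MW,
                "logP": rec.logP,
                "HBD": rec.HBD,
                "HBA": rec.HBA,
                "rotatable_bonds": rec.rotatable_bonds,
                "TPSA": rec.TPSA,
                "ro5_violations": v.ro5_violations,
                "ro5_pass": v.ro5_pass,
                "veber_pass": v.veber_pass,
                "tpsa_pass": v.tpsa_pass,
            }
        )
    return pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS)
                        + ["ro5_violations", "ro5_pass", "veber_pass", "tpsa_pass"])


def read_descriptor_table(path) -> list[DescriptorRecord]:
    """Load descriptor records from CSV with the documented column set."""
    table = pd.read_csv(path, comment="#")
    for col in DESCRIPTOR_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"missing descriptor column {col!r}")
    records = []
    for _, row in table.iterrows():
        records.append(
            DescriptorRecord(
                compound_id=str(row["compound_id"]),
                MW=float(row["MW"]),
                logP=float(row["logP"]),
                HBD=int(row["HBD"]),
                HBA=int(row["HBA"]),
                rotatable_bonds=int(row["rotatable_bonds"]),
                TPSA=float(row["TPSA"]),
            )
        )
    return records
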