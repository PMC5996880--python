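"""LOAEL dataset handling.

Reads delimited LOAEL tables, applies the preprocessing used throughout the
package (unit conversion to mmol/kg bw/day, rounding to five significant
digits, -log10 transform, duplicate removal) and derives the two working
datasets: the *training* set (union of the source databases) and the *test*
set (all records of compounds occurring in both databases).

Duplicate rule: two records are duplicates when they share the canonical
structure AND the LOAEL value at five significant digits — such pairs are
assumed to originate from the same study.  Rounding happens exactly once, at
unit conversion, and equality is decided on the rounded decimal
representation, never on float closeness, so deduplication is deterministic.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass

import pandas as pd

from .chem import CANONICALIZATION, SmilesParseError, Structure, canonicalize

SIGNIFICANT_DIGITS = 5


class ConfigurationError(ValueError):
    """A required column or option is missing or inconsistent."""


class ValidationError(ValueError):
    """An input value violates a precondition (e.g. non-positive dose)."""


def round_sig(value: float, digits: int = SIGNIFICANT_DIGITS) -> float:
    """Round to ``digits`` significant digits."""
    if value == 0:
        return 0.0
    return float(f"{value:.{digits - 1}e}")


def sig_repr(value: float, digits: int = SIGNIFICANT_DIGITS) -> str:
    """Canonical string at ``digits`` significant digits; used as dedup key."""
    return f"{value:.{digits - 1}e}"


def convert_units(value_mg: float, mol_weight: float) -> float:
    """mg/kg bw/day -> mmol/kg bw/day, rounded to five significant digits."""
    if not value_mg > 0:
        raise ValidationError(f"dose must be positive, got {value_mg}")
    if not mol_weight > 0:
        raise ValidationError(f"molecular weight must be positive, got {mol_weight}")
    return round_sig(value_mg / mol_weight)


def neg_log10(value: float) -> float:
    """-log10 of a positive dose in mmol/kg bw/day."""
    if not value > 0:
        raise ValidationError(f"dose must be positive, got {value}")
    return -math.log10(value)


@dataclass(frozen=True)
class LoaelMeasurement:
    """One LOAEL measurement of one structure.

    ``loael_mmol`` is the preprocessed dose (mmol/kg bw/day, five significant
    digits); ``loael_neg_log10`` its -log10; ``source`` names the database
    the record came from; the original value/unit are kept for reporting.
    """

    structure: Structure
    loael_mmol: float
    loael_neg_log10: float
    source: str
    original_value: float
    original_unit: str

    @property
    def dedup_key(self) -> tuple[str, str]:
        return (self.structure.canonical_smiles, sig_repr(self.loael_mmol))


@dataclass
class RejectedRecord:
    """A table row excluded from a dataset, with the reason."""

    record: str
    smiles: str
    reason: str


class ToxDataset:
    """A named collection of LOAEL measurements, deduplicated on construction.

    The duplicate rule (same canonical structure, same value at five
    significant digits) is applied in the constructor, which makes every
    dataset-producing operation idempotent with respect to deduplication.
    """

    def __init__(
        self,
        name: str,
        records: list[LoaelMeasurement],
        rejects: list[RejectedRecord] | None = None,
        n_dropped_empty: int = 0,
    ):
        self.name = name
        self.rejects = list(rejects or [])
        self.n_dropped_empty = n_dropped_empty
        self.metadata = {"canonicalization": CANONICALIZATION}
        seen: set[tuple[str, str]] = set()
        self.records: list[LoaelMeasurement] = []
        for rec in records:
            if rec.dedup_key not in seen:
                seen.add(rec.dedup_key)
                self.records.append(rec)
        self.index: dict[str, list[LoaelMeasurement]] = {}
        self.structures: dict[str, Structure] = {}
        for rec in self.records:
            smi = rec.structure.canonical_smiles
            self.index.setdefault(smi, []).append(rec)
            self.structures.setdefault(smi, rec.structure)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return (
            f"ToxDataset({self.name!r}, {self.n_records} records, "
            f"{self.n_structures} structures)"
        )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_structures(self) -> int:
        return len(self.index)

    def structure_set(self) -> set[str]:
        return set(self.index)

    def measurements(self, canonical_smiles: str) -> list[float]:
        """All -log10 LOAEL values recorded for a structure."""
        return [r.loael_neg_log10 for r in self.index.get(canonical_smiles, [])]

    def without_structure(self, canonical_smiles: str) -> "ToxDataset":
        """Copy of the dataset with every record of one structure removed."""
        kept = [r for r in self.records if r.structure.canonical_smiles != canonical_smiles]
        return ToxDataset(self.name, kept)

    def subset(self, canonical_smiles: set[str], name: str | None = None) -> "ToxDataset":
        kept = [r for r in self.records if r.structure.canonical_smiles in canonical_smiles]
        return ToxDataset(name or self.name, kept)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"dataset:            {self.name}",
            f"records:            {self.n_records}",
            f"unique structures:  {self.n_structures}",
            f"dropped empty rows: {self.n_dropped_empty}",
            f"rejected rows:      {len(self.rejects)}",
            f"canonicalization:   {self.metadata['canonicalization']}",
        ]
        for rej in self.rejects:
            lines.append(f"  reject {rej.record}: {rej.smiles!r} ({rej.reason})")
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        return {
            "name": self.name,
            "n_records": self.n_records,
            "n_structures": self.n_structures,
            "n_dropped_empty": self.n_dropped_empty,
            "n_rejected": len(self.rejects),
            "rejects": [vars(r) for r in self.rejects],
            "canonicalization": self.metadata["canonicalization"],
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "canonical_smiles": [r.structure.canonical_smiles for r in self.records],
                "loael_mmol_kg_bw_day": [r.loael_mmol for r in self.records],
                "loael_neg_log10": [r.loael_neg_log10 for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


def _make_measurement(
    structure: Structure, value: float, unit: str, source: str
) -> LoaelMeasurement:
    if unit in ("mg/kg", "mg/kg_bw/day", "mg/kg bw/day"):
        mmol = convert_units(value, structure.mol_weight)
    elif unit in ("mmol/kg", "mmol/kg_bw/day", "mmol/kg bw/day"):
        if not value > 0:
            raise ValidationError(f"dose must be positive, got {value}")
        mmol = round_sig(value)
    else:
        raise ConfigurationError(f"unknown dose unit {unit!r}")
    return LoaelMeasurement(
        structure=structure,
        loael_mmol=mmol,
        loael_neg_log10=neg_log10(mmol),
        source=source,
        original_value=value,
        original_unit=unit,
    )


def dataset_from_records(
    name: str, rows: list[tuple[str, float]], unit: str = "mmol/kg_bw/day"
) -> ToxDataset:
    """Build a dataset from in-memory (smiles, dose) pairs.

    Runs the full preprocessing path (canonicalization, unit handling,
    rounding, dedup); parse failures are collected as rejects.
    """
    records: list[LoaelMeasurement] = []
    rejects: list[RejectedRecord] = []
    n_empty = 0
    for i, (smiles, value) in enumerate(rows):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            n_empty += 1
            continue
        try:
            structure = canonicalize(smiles, record=str(i))
            records.append(_make_measurement(structure, float(value), unit, name))
        except SmilesParseError as exc:
            rejects.append(RejectedRecord(str(i), str(smiles), str(exc)))
        except ValidationError as exc:
            rejects.append(RejectedRecord(str(i), str(smiles), str(exc)))
    return ToxDataset(name, records, rejects=rejects, n_dropped_empty=n_empty)


def read_loael_table(
    path,
    smiles_column: str,
    value_column: str,
    unit: str = "mg/kg_bw/day",
    name: str | None = None,
) -> ToxDataset:
    """Read a delimited LOAEL table into a preprocessed :class:`ToxDataset`.

    Rows with empty or undefined LOAEL entries are dropped (their count is
    kept on the dataset); rows whose SMILES fail to parse, or whose dose is
    non-positive, go to the dataset's reject list rather than failing the
    whole read.
    """
    frame = pd.read_csv(path)
    for col in (smiles_column, value_column):
        if col not in frame.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (have: {list(frame.columns)})"
            )
    name = name or str(path)
    values = pd.to_numeric(frame[value_column], errors="coerce")
    rows = list(zip(frame[smiles_column], values))
    rows = [(s, (float(v) if pd.notna(v) else None)) for s, v in rows]
    return dataset_from_records(name, rows, unit=unit)


def build_training_set(a: ToxDataset, b: ToxDataset, name: str = "training") -> ToxDataset:
    """Union of two databases, deduplicated by (structure, 5-digit value)."""
    return ToxDataset(name, a.records + b.records)


def build_test_set(a: ToxDataset, b: ToxDataset, name: str = "test") -> ToxDataset:
    """All records (from both sources) of structures present in both databases.

    Records identical at five significant digits across the sources collapse
    to a single copy, as they are assumed to come from the same study.
    """
    shared = a.structure_set() & b.structure_set()
    if not shared:
        _warnings.warn("no shared structures between the two databases; test set is empty")
    records = [
        r
        for ds in (a, b)
        for r in ds.records
        if r.structure.canonical_smiles in shared
    ]
    return ToxDataset(name, records)
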