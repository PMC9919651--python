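"""Degradation tables: loading, validation, activity binarization, splits.

A degradation table is a CSV with one row per degrader carrying its SMILES,
the recruited E3-ligase class (VHL or CRBN) and the percent target
degradation measured at two concentrations (0.1 uM and 1 uM).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

E3_CLASSES = ("VHL", "CRBN")

REQUIRED_COLUMNS = ("id", "smiles", "e3_class", "deg_low", "deg_high")
OPTIONAL_COLUMNS = ("cell_line", "source")

DEFAULT_ACTIVITY_THRESHOLD = 75.0


class SchemaError(ValueError):
    """The CSV header does not name a required column."""


class ValidationError(ValueError):
    """A row violates a record invariant (range, SMILES, duplicate id)."""


@dataclass(frozen=True)
class DegradationRecord:
    """One degrader: identifier, structure, E3 class, two readouts."""

    id: str
    smiles: str
    e3_class: str
    deg_low: float   # percent degradation at 0.1 uM
    deg_high: float  # percent degradation at 1 uM
    cell_line: str | None = None
    source: str | None = None

    def validate(self, row_index: int | None = None) -> None:
        where = "" if row_index is None else f" (row {row_index})"
        if self.e3_class not in E3_CLASSES:
            raise ValidationError(
                f"unknown E3 class {self.e3_class!r}{where}; expected one of {E3_CLASSES}"
            )
        for name, value in (("deg_low", self.deg_low), ("deg_high", self.deg_high)):
            if not (0.0 <= value <= 100.0):
                raise ValidationError(
                    f"{name}={value} out of range [0, 100] for id {self.id!r}{where}"
                )
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValidationError(f"unparsable SMILES {self.smiles!r} for id {self.id!r}{where}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValidationError(
                f"SMILES {self.smiles!r} is not a single connected molecule for id {self.id!r}{where}"
            )


@dataclass(frozen=True)
class ActivityLabel:
    active: bool
    threshold: float


@dataclass(frozen=True)
class SplitAssignment:
    """A random train/test partition of record ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def _parse_percent(text: str, column: str, row_index: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(
            f"non-numeric {column}={text!r} at row {row_index}"
        ) from exc


def load_degradation_table(path: str | Path) -> list[DegradationRecord]:
    """Read a degradation CSV, validating every row.

    Raises SchemaError for a missing required column and ValidationError for
    out-of-range degradation, unparsable SMILES or duplicate ids; the error
    names the offending column / row.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = reader.fieldnames or []
        for column in REQUIRED_COLUMNS:
            if column not in header:
                raise SchemaError(f"missing required column {column!r} in {path}")
        records: list[DegradationRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader):
            rec = DegradationRecord(
                id=row["id"].strip(),
                smiles=row["smiles"].strip(),
                e3_class=row["e3_class"].strip(),
                deg_low=_parse_percent(row["deg_low"], "deg_low", i),
                deg_high=_parse_percent(row["deg_high"], "deg_high", i),
                cell_line=(row.get("cell_line") or None),
                source=(row.get("source") or None),
            )
            rec.validate(row_index=i)
            if rec.id in seen:
                raise ValidationError(f"duplicate id {rec.id!r} at row {i}")
            seen.add(rec.id)
            records.append(rec)
    return records


def write_degradation_table(records: Iterable[DegradationRecord], path: str | Path) -> None:
    """Write records as CSV in the schema load_degradation_table reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.id, rec.smiles, rec.e3_class, rec.deg_low, rec.deg_high,
                 rec.cell_line or "", rec.source or ""]
            )


def binarize_activity(deg: float, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> ActivityLabel:
    """Label a degradation percentage: active iff deg >= threshold.

    The boundary is inclusive: a compound at exactly the cutoff is active.
    """
    if not (0.0 <= deg <= 100.0):
        raise ValueError(f"degradation {deg} out of range [0, 100]")
    return ActivityLabel(active=deg >= threshold, threshold=threshold)


def train_size(n: int, ratio: float) -> int:
    """Training-set size: n*ratio rounded to nearest, ties up (half-up)."""
    return int(np.floor(n * ratio + 0.5))


def split_dataset(
    records: Sequence[DegradationRecord], ratio: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Plain (unstratified) random train/test split of the records.

    Sizes are deterministic given n and ratio (half-up rounding); membership
    is deterministic given the seed.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    n_train = train_size(n, ratio)
    if n_train == 0 or n_train == n:
        raise ValueError(f"ratio {ratio} leaves an empty partition for n={n}")
    ids = [rec.id for rec in records]
    order = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitAssignment(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


def write_split(split: SplitAssignment, path: str | Path) -> None:
    """Persist a split as a two-column CSV (id, partition)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "partition"])
        for cid in split.train_ids:
            writer.writerow([cid, "train"])
        for cid in split.test_ids:
            writer.writerow([cid, "test"])
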