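"""Sequence and label-table I/O.

Protein sequences are read from FASTA and normalised onto the standard
20-letter amino-acid alphabet.  Per-protein annotations (binding class,
interactor counts, interface counts, mean co-expression PCC, domain counts)
live in a tab-separated label table keyed by sequence id.  A
:class:`LabeledDataset` bundles the two for a single binary classification
task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Canonical amino-acid alphabet, sorted; fixes all Laplace denominators.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Ambiguity codes resolved to a canonical residue so the model alphabet
#: stays at exactly 20 letters.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

#: Symbols kept in stored residues but excluded from k-gram windows.
DROPPED_SYMBOLS = frozenset("X*")

#: Missing-value token used in every tabular file.
NA_TOKEN = "NA"


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA entries or invalid residues."""


class LabelTableError(ValueError):
    """Raised for malformed or inconsistent label tables."""


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Upper-case a raw residue string and resolve ambiguity codes.

    B/Z/J/U/O are mapped to canonical residues; X and ``*`` are retained
    (downstream k-gram extraction skips windows containing them).  Any other
    non-alphabet character is rejected.
    """
    out = []
    for ch in raw.upper():
        ch = AMBIGUITY_MAP.get(ch, ch)
        if ch in AMINO_ACID_SET or ch in DROPPED_SYMBOLS:
            out.append(ch)
        elif ch in ("\n", "\r", " "):
            continue
        else:
            raise SequenceFormatError(
                f"invalid residue {ch!r} in {context}"
            )
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the normalised alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("record id must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - AMINO_ACID_SET - DROPPED_SYMBOLS
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r} contains disallowed symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Residues are upper-cased and ambiguity codes resolved.  Duplicate ids,
    empty sequences and invalid residues raise :class:`SequenceFormatError`
    naming the offending entry.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise SequenceFormatError(f"{path}: entry with empty header")
        if entry.id in seen:
            raise SequenceFormatError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        residues = normalize_residues(str(entry.seq), context=f"entry {entry.id!r}")
        if not residues:
            raise SequenceFormatError(f"{path}: entry {entry.id!r} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, residues=residues))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (fixed line width, deterministic output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

_INT_COLUMNS = ("interactor_count", "interface_count")
_FLOAT_COLUMNS = ("mean_pcc",)


def _parse_domain_counts(cell: str, ident: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            dom, n = part.rsplit(":", 1)
            counts[dom] = int(n)
        except ValueError as exc:
            raise LabelTableError(f"bad domain_counts cell for id {ident!r}: {cell!r}") from exc
        if counts[dom] < 0:
            raise LabelTableError(f"negative domain count for id {ident!r}")
    return counts


def _format_domain_counts(counts: Mapping[str, int]) -> str:
    return ";".join(f"{d}:{n}" for d, n in sorted(counts.items()))


class LabelTable:
    """Per-protein annotation table keyed by id.

    Known columns are typed and validated (`interactor_count`,
    `interface_count` non-negative integers; `mean_pcc` in [-1, 1];
    `domain_counts` a ``dom:count;dom:count`` map).  Any additional column
    (e.g. a derived class label such as ``hub_status``) is kept verbatim as a
    categorical string column.  Missing cells are ``None``.
    """

    def __init__(self, rows: Mapping[str, Mapping[str, object]]):
        self._rows: dict[str, dict[str, object]] = {}
        for ident, row in rows.items():
            if ident in self._rows:
                raise LabelTableError(f"duplicate id {ident!r}")
            self._rows[ident] = dict(row)
        self._validate()

    def _validate(self) -> None:
        for ident, row in self._rows.items():
            for col in _INT_COLUMNS:
                v = row.get(col)
                if v is None:
                    continue
                if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                    raise LabelTableError(f"{col} for id {ident!r} must be a non-negative integer, got {v!r}")
            pcc = row.get("mean_pcc")
            if pcc is not None and not (-1.0 <= float(pcc) <= 1.0):
                raise LabelTableError(f"mean_pcc for id {ident!r} out of [-1, 1]: {pcc!r}")
            dc = row.get("domain_counts")
            if dc is not None and any(n < 0 for n in dc.values()):
                raise LabelTableError(f"negative domain count for id {ident!r}")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(cls, rows: Iterable[Mapping[str, object]]) -> "LabelTable":
        """Build from dict rows each carrying an ``id`` key."""
        table: dict[str, dict[str, object]] = {}
        for row in rows:
            row = dict(row)
            ident = str(row.pop("id"))
            if ident in table:
                raise LabelTableError(f"duplicate id {ident!r}")
            table[ident] = row
        return cls(table)

    # -- access -------------------------------------------------------------
    def ids(self) -> list[str]:
        return list(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    def __contains__(self, ident: str) -> bool:
        return ident in self._rows

    def get(self, ident: str, column: str) -> object | None:
        """Value for (id, column), or None when unset."""
        row = self._rows.get(ident)
        if row is None:
            raise KeyError(f"unknown id {ident!r}")
        return row.get(column)

    def columns(self) -> list[str]:
        cols: list[str] = []
        for row in self._rows.values():
            for c in row:
                if c not in cols:
                    cols.append(c)
        return cols

    def with_column(self, name: str, values: Mapping[str, object]) -> "LabelTable":
        """Return a copy with an added/overwritten column."""
        rows = {i: dict(r) for i, r in self._rows.items()}
        for ident, v in values.items():
            if ident not in rows:
                raise KeyError(f"unknown id {ident!r}")
            rows[ident][name] = v
        return LabelTable(rows)

    def subset(self, ids: Iterable[str]) -> "LabelTable":
        return LabelTable({i: self._rows[i] for i in ids})

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame (domain_counts serialised, NA for missing)."""
        cols = self.columns()
        data = []
        for ident, row in self._rows.items():
            out: dict[str, object] = {"id": ident}
            for c in cols:
                v = row.get(c)
                if v is None:
                    out[c] = NA_TOKEN
                elif c == "domain_counts":
                    out[c] = _format_domain_counts(v)
                else:
                    out[c] = v
            data.append(out)
        return pd.DataFrame(data, columns=["id", *cols])


def read_labels(path: str | Path) -> LabelTable:
    """Read a tab-separated label table with a header row.

    Unknown columns are kept as strings; ``NA`` / empty cells stay unset.
    Duplicate ids and malformed numeric cells raise :class:`LabelTableError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise LabelTableError(f"{path}: label table must have an 'id' column")
    rows: dict[str, dict[str, object]] = {}
    for _, raw in df.iterrows():
        ident = raw["id"]
        if ident in rows:
            raise LabelTableError(f"{path}: duplicate id {ident!r}")
        row: dict[str, object] = {}
        for col in df.columns:
            if col == "id":
                continue
            cell = raw[col].strip()
            if cell == "" or cell == NA_TOKEN:
                continue
            if col in _INT_COLUMNS:
                try:
                    row[col] = int(cell)
                except ValueError as exc:
                    raise LabelTableError(f"{path}: non-integer {col} for id {ident!r}: {cell!r}") from exc
            elif col in _FLOAT_COLUMNS:
                try:
                    row[col] = float(cell)
                except ValueError as exc:
                    raise LabelTableError(f"{path}: non-numeric {col} for id {ident!r}: {cell!r}") from exc
            elif col == "domain_counts":
                row[col] = _parse_domain_counts(cell, ident)
            else:
                row[col] = cell
        rows[ident] = row
    return LabelTable(rows)


def write_labels(table: LabelTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labelled datasets
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Records plus labels, with one column designated as the class field.

    For binary classification tasks (the default) exactly two class values
    must be present; generative model fitting may opt out via ``binary=False``.
    """

    records: list[ProteinRecord]
    labels: LabelTable
    class_field: str
    binary: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise LabelTableError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if rec.id not in self.labels:
                raise LabelTableError(f"record {rec.id!r} missing from label table")
            if self.labels.get(rec.id, self.class_field) is None:
                raise LabelTableError(
                    f"record {rec.id!r} has no value for class field {self.class_field!r}"
                )
        n_classes = len(self.classes)
        if self.binary and n_classes != 2:
            raise LabelTableError(
                f"binary task requires exactly 2 classes, found {n_classes}: {self.classes}"
            )

    @property
    def classes(self) -> list[str]:
        return sorted({str(self.labels.get(r.id, self.class_field)) for r in self.records})

    def class_of(self, ident: str) -> str:
        return str(self.labels.get(ident, self.class_field))

    def record_map(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}

    def y(self) -> list[str]:
        return [self.class_of(r.id) for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        recs = [self.records[i] for i in indices]
        return LabeledDataset(
            records=recs,
            labels=self.labels.subset([r.id for r in recs]),
            class_field=self.class_field,
            binary=self.binary,
        )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Prediction table I/O
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = (
    "id",
    "phase1_label",
    "phase1_score",
    "phase2_status",
    "top_hit_interactors",
    "interactor_range_low",
    "interactor_range_high",
    "interactor_weighted_estimate",
    "phase3_interface_label",
    "phase3_interface_score",
    "phase3_kinetic_label",
    "phase3_kinetic_score",
)


def _fmt(value: object | None) -> str:
    if value is None:
        return NA_TOKEN
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_predictions(records: Sequence[object], path: str | Path) -> None:
    """Write three-phase :class:`~hubseq.pipeline.PredictionRecord` rows as TSV.

    Proteins called non-protein-binding in Phase I carry ``NA`` in every
    Phase II/III column.  The output round-trips through
    :func:`read_predictions`.
    """
    if not records:
        raise ValueError("write_predictions requires at least one record")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(v) for v in rec.as_row()) + "\n")


def read_predictions(path: str | Path) -> list["object"]:
    """Read a prediction TSV back into PredictionRecord objects."""
    from .pipeline import PredictionRecord  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != PREDICTION_COLUMNS:
        raise LabelTableError(f"{path}: unexpected prediction columns {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        out.append(PredictionRecord.from_row([row[c] for c in PREDICTION_COLUMNS]))
    return out
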