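"""Assembly, persistence, querying and export of measurement records.

A measurement record links one parsed table cell to its article, neuron
type, measurement concept and methodological metadata.  Persistence is an
embedded single-file SQLite database, mirroring a relational server setup
without requiring one; export/import round-trips through CSV or JSON.
"""

from __future__ import annotations

import csv
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .annotate import AnnotatedTable
from .ingest import Article
from .metadata import MetadataRecord
from .values import ParsedValue, ParseFailure, parse_data_string
from .vocab import ConceptVocabulary

__all__ = [
    "MeasurementRecord",
    "RecordStore",
    "DuplicatePositionError",
    "UnknownIdentifierError",
    "ImportError_",
    "assemble_records",
    "export_csv",
    "export_json",
    "import_csv",
    "import_json",
    "CSV_COLUMNS",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "pmid", "table_id", "row", "col",
    "neuron_id", "neuron_name", "concept_id", "concept_name",
    "mean", "error", "error_type", "n", "range_low", "range_high",
    "species", "strain", "electrode", "prep", "jp",
    "temp", "age_low", "age_high", "curation_status",
]


class DuplicatePositionError(ValueError):
    pass


class UnknownIdentifierError(KeyError):
    pass


class ImportError_(ValueError):
    """Malformed import file; message carries the offending line number."""


@dataclass(frozen=True)
class MeasurementRecord:
    pmid: str
    table_id: int
    row: int
    col: int
    neuron_id: str
    concept_id: str
    value: ParsedValue
    metadata: MetadataRecord = field(default_factory=MetadataRecord)
    curation_status: str = "algorithmic"  # {"algorithmic", "validated", "corrected"}
    note: str = ""

    @property
    def position(self) -> tuple[str, int, int, int]:
        return (self.pmid, self.table_id, self.row, self.col)


# condition labels that count as normotypic when a condition is present
NORMOTYPIC_LABELS = {"+/+", "wt", "wild-type", "wild type", "control", ""}


def assemble_records(
    annotated: AnnotatedTable,
    article: Article,
    metadata: MetadataRecord,
) -> list[MeasurementRecord]:
    """One record per data cell with a (neuron, concept) pair, a
    normotypic (or absent) condition label, and a parseable value.

    Cells failing the value grammar are logged and skipped, never emitted.
    """
    records: list[MeasurementRecord] = []
    pmid = article.pmid or ""
    for (r, c), (neuron_id, concept_id, condition) in sorted(
        annotated.cell_map.items()
    ):
        if neuron_id is None or concept_id is None:
            continue
        if condition is not None and condition.casefold() not in NORMOTYPIC_LABELS:
            continue
        raw = annotated.raw.grid[r][c]
        parsed = parse_data_string(raw)
        if isinstance(parsed, ParseFailure):
            log.info(
                "pmid %s table %d cell (%d,%d): unparseable value %r",
                pmid, annotated.raw.table_id, r, c, raw,
            )
            continue
        records.append(
            MeasurementRecord(
                pmid=pmid,
                table_id=annotated.raw.table_id,
                row=r,
                col=c,
                neuron_id=neuron_id,
                concept_id=concept_id,
                value=parsed,
                metadata=metadata,
            )
        )
    return records


class RecordStore:
    """In-memory record collection with optional SQLite persistence.

    The position key (pmid, table_id, row, col) is unique; inserting a
    duplicate raises :class:`DuplicatePositionError`.
    """

    def __init__(self, vocab: Optional[ConceptVocabulary] = None) -> None:
        self._records: dict[tuple[str, int, int, int], MeasurementRecord] = {}
        self.vocab = vocab

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self.all())

    def insert(self, record: MeasurementRecord) -> None:
        key = record.position
        if key in self._records:
            raise DuplicatePositionError(f"duplicate record position {key}")
        if self.vocab is not None:
            self.vocab.neuron(record.neuron_id)   # KeyError if unknown
            self.vocab.concept(record.concept_id)
        self._records[key] = record

    def insert_many(self, records: Iterable[MeasurementRecord]) -> None:
        for rec in records:
            self.insert(rec)

    def all(self) -> list[MeasurementRecord]:
        return [self._records[k] for k in sorted(self._records)]

    def query(
        self,
        neuron_id: Optional[str] = None,
        concept_id: Optional[str] = None,
        pmid: Optional[str] = None,
        metadata_predicate=None,
    ) -> list[MeasurementRecord]:
        """Conjunctive filtering, results ordered by position.

        Unknown neuron/concept identifiers (when a vocabulary is attached)
        raise :class:`UnknownIdentifierError` rather than returning empty.
        """
        if self.vocab is not None:
            try:
                if neuron_id is not None:
                    self.vocab.neuron(neuron_id)
                if concept_id is not None:
                    self.vocab.concept(concept_id)
            except KeyError as exc:
                raise UnknownIdentifierError(str(exc)) from exc
        out = []
        for rec in self.all():
            if neuron_id is not None and rec.neuron_id != neuron_id:
                continue
            if concept_id is not None and rec.concept_id != concept_id:
                continue
            if pmid is not None and rec.pmid != pmid:
                continue
            if metadata_predicate is not None and not metadata_predicate(rec.metadata):
                continue
            out.append(rec)
        return out

    # -- SQLite persistence -------------------------------------------------

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS measurements (
        pmid TEXT NOT NULL, table_id INTEGER NOT NULL,
        row INTEGER NOT NULL, col INTEGER NOT NULL,
        neuron_id TEXT NOT NULL, concept_id TEXT NOT NULL,
        mean REAL NOT NULL, error REAL, error_type TEXT NOT NULL,
        n INTEGER, range_low REAL, range_high REAL, raw_text TEXT,
        metadata_json TEXT NOT NULL,
        curation_status TEXT NOT NULL, note TEXT,
        PRIMARY KEY (pmid, table_id, row, col)
    )
    """

    def save(self, path: str | Path) -> None:
        con = sqlite3.connect(str(path))
        try:
            con.execute("DROP TABLE IF EXISTS measurements")
            con.execute(self._SCHEMA)
            con.executemany(
                "INSERT INTO measurements VALUES "
                "(?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                [
                    (
                        rec.pmid, rec.table_id, rec.row, rec.col,
                        rec.neuron_id, rec.concept_id,
                        rec.value.mean, rec.value.error_value,
                        rec.value.error_type, rec.value.n,
                        rec.value.range_low, rec.value.range_high,
                        rec.value.raw_text,
                        json.dumps(rec.metadata.to_dict(), sort_keys=True),
                        rec.curation_status, rec.note,
                    )
                    for rec in self.all()
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str | Path, vocab: Optional[ConceptVocabulary] = None) -> "RecordStore":
        store = cls(vocab=vocab)
        con = sqlite3.connect(str(path))
        try:
            rows = con.execute(
                "SELECT pmid, table_id, row, col, neuron_id, concept_id, "
                "mean, error, error_type, n, range_low, range_high, raw_text, "
                "metadata_json, curation_status, note FROM measurements "
                "ORDER BY pmid, table_id, row, col"
            ).fetchall()
        finally:
            con.close()
        for row in rows:
            store.insert(
                MeasurementRecord(
                    pmid=row[0], table_id=row[1], row=row[2], col=row[3],
                    neuron_id=row[4], concept_id=row[5],
                    value=ParsedValue(
                        mean=row[6], error_value=row[7], error_type=row[8],
                        n=row[9], range_low=row[10], range_high=row[11],
                        raw_text=row[12] or "",
                    ),
                    metadata=MetadataRecord.from_dict(json.loads(row[13])),
                    curation_status=row[14], note=row[15] or "",
                )
            )
        return store


def _record_row(rec: MeasurementRecord, vocab: Optional[ConceptVocabulary]) -> dict:
    md = rec.metadata
    temp = md.temperature
    if isinstance(temp, tuple):
        temp = f"{temp[0]}-{temp[1]}"
    neuron_name = concept_name = ""
    if vocab is not None:
        try:
            neuron_name = vocab.neuron(rec.neuron_id).canonical_name
            concept_name = vocab.concept(rec.concept_id).canonical_name
        except KeyError:
            pass
    return {
        "pmid": rec.pmid, "table_id": rec.table_id, "row": rec.row, "col": rec.col,
        "neuron_id": rec.neuron_id, "neuron_name": neuron_name,
        "concept_id": rec.concept_id, "concept_name": concept_name,
        "mean": rec.value.mean, "error": rec.value.error_value,
        "error_type": rec.value.error_type, "n": rec.value.n,
        "range_low": rec.value.range_low, "range_high": rec.value.range_high,
        "species": md.species, "strain": md.strain,
        "electrode": md.electrode_type, "prep": md.preparation_type,
        "jp": md.jp_corrected, "temp": temp,
        "age_low": md.age_low_days, "age_high": md.age_high_days,
        "curation_status": rec.curation_status,
    }


def export_csv(store: RecordStore, path: str | Path) -> None:
    """Write all records as CSV with the documented stable column order."""
    rows = [_record_row(rec, store.vocab) for rec in store.all()]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def export_json(store: RecordStore, path: str | Path) -> None:
    payload = [
        {
            **_record_row(rec, store.vocab),
            "raw_text": rec.value.raw_text,
            "metadata": rec.metadata.to_dict(),
            "note": rec.note,
        }
        for rec in store.all()
    ]
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False), encoding="utf-8"
    )


def _none_if_blank(v: str) -> Optional[str]:
    return None if v in ("", None) else v


def import_csv(path: str | Path, vocab: Optional[ConceptVocabulary] = None) -> RecordStore:
    """Rebuild a store from an exported CSV.

    The CSV carries no evidence spans or raw text, so metadata comes back
    field-identical but evidence-free; the record fields themselves
    round-trip exactly.
    """
    store = RecordStore(vocab=vocab)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_COLUMNS:
            raise ImportError_(f"line 1: unexpected CSV header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                temp = _none_if_blank(row["temp"])
                if temp is not None and temp != "room":
                    if "-" in temp[1:]:  # range; recording temps are positive
                        lo, hi = temp.split("-", 1)
                        temp = (float(lo), float(hi))
                    else:
                        temp = float(temp)
                md = MetadataRecord(
                    species=_none_if_blank(row["species"]),
                    strain=_none_if_blank(row["strain"]),
                    electrode_type=_none_if_blank(row["electrode"]),
                    preparation_type=_none_if_blank(row["prep"]),
                    jp_corrected=row["jp"] or "unknown",
                    temperature=temp,
                    age_low_days=int(float(row["age_low"])) if row["age_low"] else None,
                    age_high_days=int(float(row["age_high"])) if row["age_high"] else None,
                )
                value = ParsedValue(
                    mean=float(row["mean"]),
                    error_value=float(row["error"]) if row["error"] else None,
                    error_type=row["error_type"] or "unresolved",
                    n=int(float(row["n"])) if row["n"] else None,
                    range_low=float(row["range_low"]) if row["range_low"] else None,
                    range_high=float(row["range_high"]) if row["range_high"] else None,
                )
                store.insert(
                    MeasurementRecord(
                        pmid=row["pmid"],
                        table_id=int(row["table_id"]),
                        row=int(row["row"]),
                        col=int(row["col"]),
                        neuron_id=row["neuron_id"],
                        concept_id=row["concept_id"],
                        value=value,
                        metadata=md,
                        curation_status=row["curation_status"] or "algorithmic",
                    )
                )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, DuplicatePositionError):
                    raise
                raise ImportError_(f"line {lineno}: {exc}") from exc
    return store


def import_json(path: str | Path, vocab: Optional[ConceptVocabulary] = None) -> RecordStore:
    store = RecordStore(vocab=vocab)
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ImportError_(f"line {exc.lineno}: {exc.msg}") from exc
    for i, row in enumerate(payload):
        md = MetadataRecord.from_dict(row.get("metadata", {}))
        value = ParsedValue(
            mean=row["mean"],
            error_value=row.get("error"),
            error_type=row.get("error_type", "unresolved"),
            n=row.get("n"),
            range_low=row.get("range_low"),
            range_high=row.get("range_high"),
            raw_text=row.get("raw_text", ""),
        )
        store.insert(
            MeasurementRecord(
                pmid=row["pmid"], table_id=row["table_id"],
                row=row["row"], col=row["col"],
                neuron_id=row["neuron_id"], concept_id=row["concept_id"],
                value=value, metadata=md,
                curation_status=row.get("curation_status", "algorithmic"),
                note=row.get("note", ""),
            )
        )
    return store
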