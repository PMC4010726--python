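"""Table annotation: headers → concepts/neurons → per-cell assignments.

Given a dense table grid and the dual vocabulary, this module (1) flags
header-like cells (mostly-alphabetic text, or labels on the first
row/column), (2) fuzzily matches each header against both the
measurement-concept and neuron-type synonym lists, letting the namespace
with the higher score claim the cell, (3) resolves whether concepts run
along columns or rows, and (4) maps every data cell to the (neuron,
concept) pair implied by its row and column headers.  A curation overlay
file can overwrite any algorithmic assignment; curated entries are
authoritative and the original algorithmic call is kept for audit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from .ingest import RawTable
from .vocab import ConceptVocabulary, match_term, DEFAULT_MATCH_THRESHOLD

__all__ = [
    "HeaderAssignment",
    "AnnotatedTable",
    "CurationError",
    "detect_header_cells",
    "annotate_table",
    "resolve_orientation",
    "apply_curation",
    "load_overlay",
    "overlay_template",
    "DEFAULT_CONDITION_DENYLIST",
]

# condition labels treated as non-normotypic unless curation says otherwise
DEFAULT_CONDITION_DENYLIST = ("ko", "-/-", "mutant", "tx")

KINDS = ("ephys_concept", "neuron_type", "condition", "unassigned")


class CurationError(ValueError):
    """Overlay refers to a cell position that does not exist."""


@dataclass(frozen=True)
class HeaderAssignment:
    row: int
    col: int
    assigned_kind: str  # one of KINDS
    target_id: Optional[str] = None
    score: Optional[float] = None       # present iff source == "algorithmic"
    source: str = "algorithmic"         # {"algorithmic", "curated"}
    condition_label: Optional[str] = None
    previous: Optional["HeaderAssignment"] = None  # audit trail for curation

    def __post_init__(self) -> None:
        if self.assigned_kind not in KINDS:
            raise ValueError(f"bad kind {self.assigned_kind!r}")
        has_target = self.assigned_kind in ("ephys_concept", "neuron_type")
        if has_target != (self.target_id is not None):
            raise ValueError("target_id present iff kind is concept/neuron")
        if (self.source == "algorithmic") != (self.score is not None):
            raise ValueError("score present iff source is algorithmic")


@dataclass
class AnnotatedTable:
    raw: RawTable
    header_mask: tuple[tuple[bool, ...], ...]
    assignments: list[HeaderAssignment]
    orientation: str  # {"concepts_in_columns", "concepts_in_rows"}
    # data-cell position -> (neuron_id | None, concept_id | None, condition | None)
    cell_map: dict[tuple[int, int], tuple[Optional[str], Optional[str], Optional[str]]] = field(
        default_factory=dict
    )

    def assignment_at(self, row: int, col: int) -> Optional[HeaderAssignment]:
        for a in self.assignments:
            if a.row == row and a.col == col:
                return a
        return None


_ALPHA = re.compile(r"[^\W\d_]")  # unicode letters


def _is_headerish(text: str, row: int, col: int) -> bool:
    chars = [ch for ch in text if not ch.isspace()]
    if not chars:
        return False
    n_alpha = sum(1 for ch in chars if _ALPHA.match(ch))
    if n_alpha / len(chars) > 0.5:
        return True
    return (row == 0 or col == 0) and n_alpha > 0


def detect_header_cells(table: RawTable) -> tuple[tuple[bool, ...], ...]:
    """Boolean mask of header-like cells.

    A cell is header-like iff alphabetic characters make up more than half
    of its non-whitespace characters, or it sits on the first row or first
    column and contains at least one letter (row/column labels such as
    "+/+" with a letter, or terse names, survive this way).
    """
    return tuple(
        tuple(_is_headerish(cell, r, c) for c, cell in enumerate(row))
        for r, row in enumerate(table.grid)
    )


def resolve_orientation(
    assignments: list[HeaderAssignment], table: RawTable
) -> str:
    """Concepts run in columns iff strictly more concept assignments sit in
    row 0 than in column 0; ties go to ``concepts_in_columns``."""
    in_row0 = sum(
        1 for a in assignments if a.assigned_kind == "ephys_concept" and a.row == 0
    )
    in_col0 = sum(
        1
        for a in assignments
        if a.assigned_kind == "ephys_concept" and a.col == 0 and a.row != 0
    )
    return "concepts_in_rows" if in_col0 > in_row0 else "concepts_in_columns"


def _line_lookup(
    assignments: list[HeaderAssignment], orientation: str
) -> tuple[dict[int, HeaderAssignment], dict[int, HeaderAssignment], dict[int, str]]:
    """Per-column concept, per-row neuron (or transposed), plus condition
    labels per line index."""
    if orientation == "concepts_in_columns":
        concept_axis, neuron_axis = "col", "row"
    else:
        concept_axis, neuron_axis = "row", "col"
    concepts: dict[int, HeaderAssignment] = {}
    neurons: dict[int, HeaderAssignment] = {}
    conditions: dict[str, dict[int, str]] = {"row": {}, "col": {}}
    for a in assignments:
        if a.assigned_kind == "ephys_concept":
            concepts.setdefault(getattr(a, concept_axis), a)
        elif a.assigned_kind == "neuron_type":
            neurons.setdefault(getattr(a, neuron_axis), a)
        elif a.assigned_kind == "condition":
            label = a.condition_label or ""
            conditions["row"].setdefault(a.row, label)
            conditions["col"].setdefault(a.col, label)
    return concepts, neurons, conditions


def _build_cell_map(
    table: RawTable,
    header_mask: tuple[tuple[bool, ...], ...],
    assignments: list[HeaderAssignment],
    orientation: str,
) -> dict[tuple[int, int], tuple[Optional[str], Optional[str], Optional[str]]]:
    concepts, neurons, conditions = _line_lookup(assignments, orientation)
    cell_map: dict[tuple[int, int], tuple[Optional[str], Optional[str], Optional[str]]] = {}
    for r in range(table.n_rows):
        for c in range(table.n_cols):
            if header_mask[r][c]:
                continue
            if orientation == "concepts_in_columns":
                concept = concepts.get(c)
                neuron = neurons.get(r)
            else:
                concept = concepts.get(r)
                neuron = neurons.get(c)
            condition = conditions["row"].get(r) or conditions["col"].get(c)
            if concept is None and neuron is None and condition is None:
                continue
            cell_map[(r, c)] = (
                neuron.target_id if neuron else None,
                concept.target_id if concept else None,
                condition,
            )
    return cell_map


def annotate_table(
    table: RawTable,
    vocab: ConceptVocabulary,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    condition_denylist: tuple[str, ...] = DEFAULT_CONDITION_DENYLIST,
) -> AnnotatedTable:
    """Assign concepts and neuron types to a table's header cells.

    Each header cell is matched independently against the concept and the
    neuron namespaces; the namespace with the higher best score claims the
    cell (ties favor the measurement concept).  Cells whose text matches
    the condition deny-list become ``condition`` assignments.  Header cells
    below threshold in both namespaces stay visible as ``unassigned``.
    """
    mask = detect_header_cells(table)
    deny = {d.casefold() for d in condition_denylist}
    assignments: list[HeaderAssignment] = []
    for r in range(table.n_rows):
        for c in range(table.n_cols):
            if not mask[r][c]:
                continue
            text = table.grid[r][c]
            if text.strip().casefold() in deny:
                assignments.append(
                    HeaderAssignment(
                        r, c, "condition", score=0.0, condition_label=text.strip()
                    )
                )
                continue
            cm = match_term(text, vocab.concepts, threshold)
            nm = match_term(text, vocab.neuron_types, threshold)
            best_c = cm[0] if cm else None
            best_n = nm[0] if nm else None
            if best_c is not None and (best_n is None or best_c.score >= best_n.score):
                assignments.append(
                    HeaderAssignment(
                        r, c, "ephys_concept", target_id=best_c.target_id,
                        score=best_c.score,
                    )
                )
            elif best_n is not None:
                assignments.append(
                    HeaderAssignment(
                        r, c, "neuron_type", target_id=best_n.target_id,
                        score=best_n.score,
                    )
                )
            else:
                assignments.append(HeaderAssignment(r, c, "unassigned", score=0.0))
    orientation = resolve_orientation(assignments, table)
    cell_map = _build_cell_map(table, mask, assignments, orientation)
    return AnnotatedTable(
        raw=table,
        header_mask=mask,
        assignments=assignments,
        orientation=orientation,
        cell_map=cell_map,
    )


# ---------------------------------------------------------------------------
# Curation overlays
# ---------------------------------------------------------------------------


def load_overlay(path: str | Path) -> list[dict]:
    """Load a curation overlay: a JSON list of entries
    ``{table_id, row, col, assigned_kind, target_id?, condition_label?}``."""
    entries = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(entries, list):
        raise CurationError("overlay must be a JSON list")
    return entries


def overlay_template(annotated: AnnotatedTable) -> list[dict]:
    """Emit the current assignments as an editable overlay skeleton."""
    return [
        {
            "table_id": annotated.raw.table_id,
            "row": a.row,
            "col": a.col,
            "assigned_kind": a.assigned_kind,
            "target_id": a.target_id,
            "condition_label": a.condition_label,
            "header_text": annotated.raw.grid[a.row][a.col],
        }
        for a in annotated.assignments
    ]


def apply_curation(
    annotated: AnnotatedTable, overlay: list[dict]
) -> AnnotatedTable:
    """Overwrite algorithmic assignments with curated ones and recompute
    the orientation and cell map.  Idempotent for a fixed overlay; the
    overwritten algorithmic assignment is retained in ``previous``."""
    table = annotated.raw
    new_assignments = list(annotated.assignments)
    for entry in overlay:
        if entry.get("table_id", table.table_id) != table.table_id:
            continue
        r, c = entry["row"], entry["col"]
        if not (0 <= r < table.n_rows and 0 <= c < table.n_cols):
            raise CurationError(
                f"overlay cell ({r}, {c}) outside table {table.table_id} "
                f"({table.n_rows}x{table.n_cols})"
            )
        kind = entry["assigned_kind"]
        existing = next(
            (a for a in new_assignments if a.row == r and a.col == c), None
        )
        audit = existing
        if audit is not None and audit.source == "curated":
            audit = audit.previous  # keep the original algorithmic call
        curated = HeaderAssignment(
            r,
            c,
            kind,
            target_id=entry.get("target_id") if kind in ("ephys_concept", "neuron_type") else None,
            score=None,
            source="curated",
            condition_label=entry.get("condition_label"),
            previous=audit,
        )
        if existing is not None:
            new_assignments.remove(existing)
        new_assignments.append(curated)
    new_assignments.sort(key=lambda a: (a.row, a.col))
    mask = [list(row) for row in annotated.header_mask]
    for a in new_assignments:
        mask[a.row][a.col] = True
    mask_t = tuple(tuple(row) for row in mask)
    orientation = resolve_orientation(new_assignments, table)
    cell_map = _build_cell_map(table, mask_t, new_assignments, orientation)
    return AnnotatedTable(
        raw=table,
        header_mask=mask_t,
        assignments=new_assignments,
        orientation=orientation,
        cell_map=cell_map,
    )
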