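"""HTML article ingestion.

Turns a journal article's HTML into a structured :class:`Article`: titled
sections in document order, each ``<table>`` densified into a rectangular
grid of text cells (rowspan/colspan contents replicated into every covered
position), plus optional MeSH terms from a plain-text sidecar file.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import lxml.html

__all__ = [
    "Article",
    "RawTable",
    "ArticleParseError",
    "parse_article",
    "parse_article_file",
    "extract_methods_section",
    "read_mesh_sidecar",
    "DEFAULT_METHODS_FILTERS",
]

log = logging.getLogger(__name__)

DEFAULT_METHODS_FILTERS = (
    "Methods",
    "Experimental procedures",
    "Materials and methods",
)


class ArticleParseError(ValueError):
    """Raised when HTML input is irrecoverably malformed."""


@dataclass(frozen=True)
class RawTable:
    table_id: int
    caption: str
    grid: tuple[tuple[str, ...], ...]  # row-major, dense

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_cols(self) -> int:
        return len(self.grid[0]) if self.grid else 0

    def __post_init__(self) -> None:
        widths = {len(row) for row in self.grid}
        if len(widths) > 1:
            raise ValueError("grid is not rectangular")


@dataclass
class Article:
    title: str = ""
    pmid: Optional[str] = None
    journal: Optional[str] = None
    sections: list[tuple[str, str]] = field(default_factory=list)
    tables: list[RawTable] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pmid is not None and not self.pmid.isdigit():
            raise ValueError(f"pmid must be numeric text, got {self.pmid!r}")

    def full_text(self) -> str:
        return "\n".join(body for _, body in self.sections)

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "pmid": self.pmid,
            "journal": self.journal,
            "sections": [[t, b] for t, b in self.sections],
            "tables": [
                {
                    "table_id": t.table_id,
                    "caption": t.caption,
                    "grid": [list(r) for r in t.grid],
                }
                for t in self.tables
            ],
            "mesh_terms": list(self.mesh_terms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Article":
        return cls(
            title=d.get("title", ""),
            pmid=d.get("pmid"),
            journal=d.get("journal"),
            sections=[(t, b) for t, b in d.get("sections", [])],
            tables=[
                RawTable(
                    table_id=t["table_id"],
                    caption=t.get("caption", ""),
                    grid=tuple(tuple(r) for r in t["grid"]),
                )
                for t in d.get("tables", [])
            ],
            mesh_terms=list(d.get("mesh_terms", [])),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Article":
        return cls.from_dict(json.loads(text))


_WS = re.compile(r"\s+")


def _cell_text(el) -> str:
    return _WS.sub(" ", el.text_content()).strip()


def _densify_table(table_el, table_id: int) -> Optional[RawTable]:
    """Expand a <table> element into a dense grid, replicating spans."""
    rows = table_el.xpath(".//tr")
    if not rows:
        return None
    grid: dict[tuple[int, int], str] = {}
    occupied: set[tuple[int, int]] = set()
    n_cols = 0
    for r, tr in enumerate(rows):
        c = 0
        for cell in tr.xpath("./td|./th"):
            while (r, c) in occupied:
                c += 1
            text = _cell_text(cell)
            try:
                rowspan = max(1, int(cell.get("rowspan", "1")))
                colspan = max(1, int(cell.get("colspan", "1")))
            except ValueError:
                rowspan = colspan = 1
            for dr in range(rowspan):
                for dc in range(colspan):
                    grid[(r + dr, c + dc)] = text
                    occupied.add((r + dr, c + dc))
            c += colspan
        n_cols = max(n_cols, c)
    n_rows = max(r for r, _ in grid) + 1 if grid else 0
    n_cols = max(n_cols, (max(c for _, c in grid) + 1) if grid else 0)
    if n_rows == 0 or n_cols == 0:
        return None
    dense = tuple(
        tuple(grid.get((r, c), "") for c in range(n_cols)) for r in range(n_rows)
    )
    caption_el = table_el.xpath(".//caption")
    caption = _cell_text(caption_el[0]) if caption_el else ""
    return RawTable(table_id=table_id, caption=caption, grid=dense)


_HEADING_TAGS = {"h1", "h2", "h3", "h4", "h5", "h6"}


def parse_article(
    html: str,
    journal_hint: Optional[str] = None,
    pmid: Optional[str] = None,
    mesh_terms: Optional[list[str]] = None,
) -> Article:
    """Parse HTML text into an :class:`Article`.

    Section titles come from heading elements (``h1``–``h6``) and from
    paragraphs whose entire content is bold/strong (a common journal
    dialect for inline section heads).  Text before the first heading is
    stored under the empty section title.  Tables that cannot be
    rectangularized are skipped with a logged warning.
    """
    if not html or not html.strip():
        raise ArticleParseError("empty HTML input")
    try:
        doc = lxml.html.fromstring(html)
    except Exception as exc:  # lxml raises several parse error types
        raise ArticleParseError(f"unparseable HTML: {exc}") from exc

    title_el = doc.xpath("//title|//h1")
    title = _cell_text(title_el[0]) if title_el else ""

    if pmid is None:
        meta = doc.xpath('//meta[@name="citation_pmid"]/@content')
        if meta and str(meta[0]).strip().isdigit():
            pmid = str(meta[0]).strip()

    # walk the body linearly, splitting text at headings
    sections: list[tuple[str, str]] = []
    current_title = ""
    current_parts: list[str] = []

    def flush() -> None:
        body = " ".join(p for p in current_parts if p).strip()
        if body or current_title:
            sections.append((current_title, body))

    body = doc.body if doc.body is not None else doc
    for el in body.iter():
        if not isinstance(el.tag, str):
            continue
        tag = el.tag.lower()
        if tag in _HEADING_TAGS or (
            tag == "p"
            and len(el) == 1
            and el[0].tag in ("b", "strong")
            and not (el.text or "").strip()
            and not (el[0].tail or "").strip()
        ):
            flush()
            current_title = _cell_text(el)
            current_parts = []
        elif tag == "p" and not el.xpath("ancestor::table"):
            current_parts.append(_cell_text(el))
    flush()

    tables: list[RawTable] = []
    for i, table_el in enumerate(doc.xpath("//table")):
        try:
            t = _densify_table(table_el, table_id=len(tables))
        except ValueError as exc:
            log.warning("skipping table %d: %s", i, exc)
            continue
        if t is None:
            log.warning("skipping table %d: no cells", i)
            continue
        tables.append(t)

    return Article(
        title=title,
        pmid=pmid,
        journal=journal_hint,
        sections=sections,
        tables=tables,
        mesh_terms=list(mesh_terms or []),
    )


def read_mesh_sidecar(path: str | Path) -> list[str]:
    """Read a MeSH sidecar file: one term per line, blanks ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def parse_article_file(
    path: str | Path, journal_hint: Optional[str] = None
) -> Article:
    """Parse an HTML file, picking up a ``<stem>.mesh.txt`` sidecar if present."""
    path = Path(path)
    mesh_path = path.parent / (path.stem + ".mesh.txt")
    mesh = read_mesh_sidecar(mesh_path) if mesh_path.exists() else None
    return parse_article(
        path.read_text(encoding="utf-8"), journal_hint=journal_hint, mesh_terms=mesh
    )


def extract_methods_section(
    article: Article, tag_filters: tuple[str, ...] = DEFAULT_METHODS_FILTERS
) -> str:
    """Return the text of the first section whose title matches a filter.

    Matching is case-insensitive on the full title or a title that starts
    with the filter phrase; the earliest matching section in document
    order wins.  Returns empty text when nothing matches.
    """
    filters = [f.casefold() for f in tag_filters]
    for sec_title, body in article.sections:
        t = sec_title.casefold().strip()
        # tolerate numbered headings like "2. Materials and methods"
        t = re.sub(r"^[\d.\s]+", "", t)
        if any(t == f or t.startswith(f) for f in filters):
            return body
    return ""
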