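"""Parse JATS/PMC article XML into structured table records and read/write
the JSONL corpus format.

Table-wraps whose only content is a graphic (image-only tables) are skipped.
Cell text is the concatenation of all descendant text with internal whitespace
collapsed to single spaces; ``rowspan``/``colspan`` attributes are expanded so
every body grid is rectangular.
"""
from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .labels import Label, normalize_label

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractedTable",
    "LabeledTable",
    "Corpus",
    "JATSParseError",
    "GridSpanError",
    "CorpusSchemaError",
    "parse_article_tables",
    "normalize_grid",
    "read_corpus",
    "write_corpus",
]

_WS = re.compile(r"\s+")


def _collapse(text: str) -> str:
    return _WS.sub(" ", text).strip()


class JATSParseError(ValueError):
    """Raised on malformed article XML."""


class GridSpanError(ValueError):
    """Raised when rowspan/colspan attributes describe overlapping cells."""


class CorpusSchemaError(ValueError):
    """Raised when a corpus JSONL record violates the table schema."""


@dataclass
class ExtractedTable:
    """A structured table: caption, header rows, rectangular body, footer.

    ``label`` is ``None`` for unlabeled records; a labeled record is what the
    spec calls a ``LabeledTable``.
    """

    table_id: str
    article_id: str = ""
    caption: str = ""
    header_rows: list[list[str]] = field(default_factory=list)
    body: list[list[str]] = field(default_factory=list)
    footer: str = ""
    label: Label | None = None

    def __post_init__(self) -> None:
        widths = {len(row) for row in self.body}
        if len(widths) > 1:
            raise ValueError(
                f"table {self.table_id!r}: body is not rectangular "
                f"(row widths {sorted(widths)})"
            )

    @property
    def n_columns(self) -> int:
        return len(self.body[0]) if self.body else (
            len(self.header_rows[0]) if self.header_rows else 0
        )

    def to_dict(self) -> dict:
        record = {
            "table_id": self.table_id,
            "article_id": self.article_id,
            "caption": self.caption,
            "header_rows": self.header_rows,
            "body": self.body,
            "footer": self.footer,
        }
        if self.label is not None:
            record["label"] = self.label.value
        return record


#: Alias used where a gold label is required.
LabeledTable = ExtractedTable


@dataclass
class Corpus:
    """An ordered collection of tables, optionally labeled."""

    records: list[ExtractedTable] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def is_labeled(self) -> bool:
        return bool(self.records) and all(t.label is not None for t in self.records)

    def labels(self) -> list[Label]:
        if not self.is_labeled:
            raise ValueError("corpus contains unlabeled records")
        return [t.label for t in self.records]  # type: ignore[misc]

    def label_counts(self) -> dict[Label, int]:
        counts: dict[Label, int] = {}
        for lab in self.labels():
            counts[lab] = counts.get(lab, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Grid normalization
# ---------------------------------------------------------------------------

Cell = "str | tuple[str, int, int]"


def normalize_grid(raw_rows: Sequence[Sequence]) -> list[list[str]]:
    """Expand span attributes into a rectangular grid of cell texts.

    Each raw cell is either a plain string (spans 1x1) or a
    ``(text, rowspan, colspan)`` triple. Spanned cells are replicated into
    every covered position; ragged rows are right-padded with empty strings.
    Overlapping spans raise :class:`GridSpanError` naming the position.
    """
    parsed: list[list[tuple[str, int, int]]] = []
    for row in raw_rows:
        cells = []
        for cell in row:
            if isinstance(cell, str):
                cells.append((cell, 1, 1))
            else:
                text, rowspan, colspan = cell
                rowspan, colspan = int(rowspan), int(colspan)
                if rowspan < 1 or colspan < 1:
                    raise GridSpanError(
                        f"rowspan/colspan must be >= 1, got ({rowspan}, {colspan})"
                    )
                cells.append((str(text), rowspan, colspan))
        parsed.append(cells)

    occupied: dict[tuple[int, int], str] = {}
    width = 0
    for r, cells in enumerate(parsed):
        col = 0
        for text, rowspan, colspan in cells:
            while (r, col) in occupied:
                col += 1
            for dr in range(rowspan):
                for dc in range(colspan):
                    pos = (r + dr, col + dc)
                    if pos in occupied:
                        raise GridSpanError(
                            f"overlapping span at row {pos[0]}, column {pos[1]}"
                        )
                    occupied[pos] = text
            col += colspan
            width = max(width, col)

    n_rows = len(parsed)
    if occupied:
        n_rows = max(n_rows, max(r for r, _ in occupied) + 1)
    return [[occupied.get((r, c), "") for c in range(width)] for r in range(n_rows)]


# ---------------------------------------------------------------------------
# JATS parsing
# ---------------------------------------------------------------------------


def _local(tag) -> str:
    """Namespace-agnostic element name."""
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _byte_offset(document: str, line: int, column: int) -> int:
    lines = document.split("\n")
    offset = sum(len(l.encode("utf-8")) + 1 for l in lines[: line - 1])
    return offset + column


def _cell_text(el: ET.Element) -> str:
    return _collapse("".join(el.itertext()))


def _iter_rows(table_el: ET.Element):
    """Yield (is_header, tr_element) in document order."""
    for section in table_el:
        name = _local(section.tag)
        if name == "thead":
            for tr in section.iter():
                if _local(tr.tag) == "tr":
                    yield True, tr
        elif name in ("tbody", "tfoot"):
            for tr in section.iter():
                if _local(tr.tag) == "tr":
                    yield False, tr
        elif name == "tr":
            yield False, section


def _span(cell: ET.Element, attr: str) -> int:
    raw = cell.get(attr, "1")
    try:
        value = int(str(raw).strip() or "1")
    except ValueError:
        value = 1
    return max(value, 1)


def _article_id(root: ET.Element) -> str:
    ids: dict[str, str] = {}
    for el in root.iter():
        if _local(el.tag) == "article-id" and el.text:
            ids[el.get("pub-id-type", "")] = el.text.strip()
    for key in ("pmc", "pmcid", "pmid", "doi"):
        if key in ids:
            return ids[key]
    return next(iter(ids.values()), "")


def parse_article_tables(jats_document: str) -> list[ExtractedTable]:
    """Extract one :class:`ExtractedTable` per machine-readable table-wrap.

    Table-wraps containing only a graphic/image reference are excluded;
    table-wraps with rows but no cells are skipped with a logged warning.
    """
    try:
        root = ET.fromstring(jats_document)
    except ET.ParseError as exc:
        line, column = exc.position
        offset = _byte_offset(jats_document, line, column)
        raise JATSParseError(
            f"malformed XML at byte offset {offset} (line {line}, column {column}): {exc}"
        ) from exc

    article_id = _article_id(root)
    tables: list[ExtractedTable] = []
    for index, wrap in enumerate(el for el in root.iter() if _local(el.tag) == "table-wrap"):
        caption = ""
        footer = ""
        table_el = None
        has_graphic = False
        for el in wrap.iter():
            name = _local(el.tag)
            if name == "caption" and not caption:
                caption = _cell_text(el)
            elif name == "table-wrap-foot" and not footer:
                footer = _cell_text(el)
            elif name == "table" and table_el is None:
                table_el = el
            elif name in ("graphic", "inline-graphic"):
                has_graphic = True

        table_id = wrap.get("id") or f"{article_id or 'article'}-table-{index + 1}"

        raw_header: list[list[tuple[str, int, int]]] = []
        raw_body: list[list[tuple[str, int, int]]] = []
        n_cells = 0
        if table_el is not None:
            for is_header, tr in _iter_rows(table_el):
                row = [
                    (_cell_text(cell), _span(cell, "rowspan"), _span(cell, "colspan"))
                    for cell in tr
                    if _local(cell.tag) in ("td", "th")
                ]
                n_cells += len(row)
                (raw_header if is_header else raw_body).append(row)

        if n_cells == 0:
            if has_graphic:
                logger.debug("table-wrap %s: image-only, excluded", table_id)
            elif raw_header or raw_body:
                logger.warning("table-wrap %s: rows but no cells, skipped", table_id)
            continue

        grid = normalize_grid(raw_header + raw_body)
        n_header = len(raw_header)
        # rowspans may stretch the grid past the declared header rows
        header_rows = grid[:n_header]
        body = grid[n_header:]
        tables.append(
            ExtractedTable(
                table_id=table_id,
                article_id=article_id,
                caption=caption,
                header_rows=header_rows,
                body=body,
                footer=footer,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Corpus JSONL
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("table_id", "caption", "header_rows", "body", "footer")


def _record_from_dict(record: dict, line_no: int) -> ExtractedTable:
    for key in _REQUIRED_KEYS:
        if key not in record:
            raise CorpusSchemaError(f"line {line_no}: record missing field {key!r}")
    label = None
    if record.get("label") is not None:
        try:
            label = normalize_label(record["label"])
        except ValueError as exc:
            raise CorpusSchemaError(f"line {line_no}: {exc}") from exc
    try:
        return ExtractedTable(
            table_id=str(record["table_id"]),
            article_id=str(record.get("article_id", "")),
            caption=str(record["caption"]),
            header_rows=[[str(c) for c in row] for row in record["header_rows"]],
            body=[[str(c) for c in row] for row in record["body"]],
            footer=str(record["footer"]),
            label=label,
        )
    except ValueError as exc:
        raise CorpusSchemaError(f"line {line_no}: {exc}") from exc


def read_corpus(path) -> Corpus:
    """Read a JSONL corpus (one table object per line, UTF-8)."""
    records: list[ExtractedTable] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusSchemaError(f"line {line_no}: invalid JSON ({exc})") from exc
            table = _record_from_dict(payload, line_no)
            if table.table_id in seen:
                raise CorpusSchemaError(
                    f"line {line_no}: duplicate table_id {table.table_id!r}"
                )
            seen.add(table.table_id)
            records.append(table)
    return Corpus(records=records)


def write_corpus(corpus: "Corpus | Iterable[ExtractedTable]", path) -> None:
    """Write a corpus as JSONL; ``write∘read`` is the identity on valid corpora."""
    records = corpus.records if isinstance(corpus, Corpus) else list(corpus)
    with open(path, "w", encoding="utf-8") as handle:
        for table in records:
            handle.write(json.dumps(table.to_dict(), ensure_ascii=False))
            handle.write("\n")
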