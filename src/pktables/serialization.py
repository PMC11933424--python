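"""Markdown serialization of tables and the seven field-selection variants."""
from __future__ import annotations

import re
from enum import Enum

from .table_io import ExtractedTable

__all__ = ["FieldKind", "to_markdown", "select_field"]


class FieldKind(str, Enum):
    """Which part of the table is serialized into classifier input text."""

    CAPTION = "caption"
    HEADER_ROW = "header_row"
    FIRST_COLUMN = "first_column"
    FIRST_FEW_ROWS = "first_few_rows"
    TABLE = "table"
    FOOTER = "footer"
    CAPTION_PLUS_TABLE = "caption_plus_table"


def _escape(cell: str, escape_pipes: bool) -> str:
    return cell.replace("|", "\\|") if escape_pipes else cell


def _pipe_row(cells: list[str], escape_pipes: bool) -> str:
    return "| " + " | ".join(_escape(c, escape_pipes) for c in cells) + " |"


def to_markdown(
    table: ExtractedTable,
    *,
    max_body_rows: int | None = None,
    escape_pipes: bool = True,
) -> str:
    """Serialize a table row by row as pipe-delimited markdown.

    First header row, then a ``| --- |`` separator row, then body rows in
    order. Tables with no header rows emit body rows only (no separator);
    a fully empty table serializes to the empty string.
    """
    lines: list[str] = []
    if table.header_rows:
        header = table.header_rows[0]
        lines.append(_pipe_row(header, escape_pipes))
        lines.append("| " + " | ".join("---" for _ in header) + " |")
    body = table.body if max_body_rows is None else table.body[:max_body_rows]
    lines.extend(_pipe_row(row, escape_pipes) for row in body)
    return "\n".join(lines)


def select_field(
    table: ExtractedTable,
    kind: FieldKind,
    *,
    first_few_rows_k: int = 3,
    escape_pipes: bool = True,
) -> str:
    """Extract one of the seven evaluated table-field texts."""
    kind = FieldKind(kind)
    if kind is FieldKind.CAPTION:
        return table.caption
    if kind is FieldKind.FOOTER:
        return table.footer
    if kind is FieldKind.HEADER_ROW:
        if not table.header_rows:
            return ""
        return _pipe_row(table.header_rows[0], escape_pipes)
    if kind is FieldKind.FIRST_COLUMN:
        cells = [row[0] for row in table.header_rows if row]
        cells += [row[0] for row in table.body if row]
        return re.sub(r"\s+", " ", " ".join(cells)).strip()
    if kind is FieldKind.FIRST_FEW_ROWS:
        return to_markdown(table, max_body_rows=first_few_rows_k, escape_pipes=escape_pipes)
    if kind is FieldKind.TABLE:
        return to_markdown(table, escape_pipes=escape_pipes)
    if kind is FieldKind.CAPTION_PLUS_TABLE:
        return table.caption + "\n" + to_markdown(table, escape_pipes=escape_pipes)
    raise ValueError(f"unknown field kind: {kind!r}")  # pragma: no cover
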