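"""Adapter for ingesting externally released table corpora whose JSON schema
differs from the core JSONL format.

The released corpus archive is an optional external input; its exact schema is
not fixed here, so the adapter exposes a configurable field mapping instead of
a hard-coded one. Never required by tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from .labels import normalize_label
from .table_io import Corpus, CorpusSchemaError, ExtractedTable

__all__ = ["FieldMapping", "load_external_corpus"]


@dataclass(frozen=True)
class FieldMapping:
    """Maps external record keys onto the core table schema."""

    table_id: str = "table_id"
    article_id: str = "article_id"
    caption: str = "caption"
    header_rows: str = "header_rows"
    body: str = "body"
    footer: str = "footer"
    label: str = "label"
    #: External label spellings mapped onto the three-class set.
    label_aliases: dict = field(
        default_factory=lambda: {
            "pk": "PK",
            "pk parameters": "PK",
            "demographics": "DEMOGRAPHICS",
            "other": "OTHER",
        }
    )


def _rectangularize(rows: list) -> list[list[str]]:
    grid = [[str(c) for c in row] for row in rows]
    width = max((len(r) for r in grid), default=0)
    return [row + [""] * (width - len(row)) for row in grid]


def load_external_corpus(path, mapping: FieldMapping | None = None) -> Corpus:
    """Read an external JSONL release through a field mapping, normalizing
    labels and padding ragged grids."""
    mapping = mapping or FieldMapping()
    records: list[ExtractedTable] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            raw = json.loads(line)
            table_id = str(raw.get(mapping.table_id, f"external-{line_no}"))
            if table_id in seen:
                raise CorpusSchemaError(f"line {line_no}: duplicate table_id {table_id!r}")
            seen.add(table_id)
            label = None
            if raw.get(mapping.label) is not None:
                value = str(raw[mapping.label]).strip().lower()
                label = normalize_label(mapping.label_aliases.get(value, value))
            records.append(
                ExtractedTable(
                    table_id=table_id,
                    article_id=str(raw.get(mapping.article_id, "")),
                    caption=str(raw.get(mapping.caption, "")),
                    header_rows=_rectangularize(raw.get(mapping.header_rows, [])),
                    body=_rectangularize(raw.get(mapping.body, [])),
                    footer=str(raw.get(mapping.footer, "")),
                    label=label,
                )
            )
    return Corpus(records=records)
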