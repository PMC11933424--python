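"""Zero-shot chain-of-thought table classification through an abstract LLM
backend, with deterministic mock backends for offline use.

The prompt template is an editable plain-text asset with named slots
({table_id}, {caption}, {table_markdown}, {footer}); its wording is
configuration, not code. Tables are passed without chunking — fallback
backends are assumed to have long contexts.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Protocol, Union, runtime_checkable

from .labels import Label, normalize_label
from .serialization import to_markdown
from .table_io import ExtractedTable

logger = logging.getLogger(__name__)

__all__ = [
    "UNPARSEABLE",
    "PromptTemplate",
    "LLMBackend",
    "StaticBackend",
    "ScriptedBackend",
    "OracleBackend",
    "build_prompt",
    "parse_response",
    "classify_zero_shot",
]


class _Unparseable:
    """Sentinel for model output that carries no recognizable answer."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNPARSEABLE"

    def __bool__(self) -> bool:
        return False


UNPARSEABLE = _Unparseable()

FallbackLabel = Union[Label, _Unparseable]

_SLOTS = ("{table_id}", "{caption}", "{table_markdown}", "{footer}")


@dataclass(frozen=True)
class PromptTemplate:
    """Chain-of-thought prompt text with named slots for the table content."""

    text: str

    def __post_init__(self) -> None:
        missing = [slot for slot in _SLOTS if slot not in self.text]
        if missing:
            raise ValueError(f"prompt template missing slots: {', '.join(missing)}")
        for label in Label:
            if label.value not in self.text:
                raise ValueError(f"prompt template does not mention label {label.value}")
        if "ANSWER:" not in self.text:
            raise ValueError("prompt template missing the final-answer directive")

    @classmethod
    def default(cls) -> "PromptTemplate":
        text = (
            resources.files("pktables.assets")
            .joinpath("prompt_template.txt")
            .read_text(encoding="utf-8")
        )
        return cls(text=text)

    @classmethod
    def from_file(cls, path) -> "PromptTemplate":
        with open(path, encoding="utf-8") as handle:
            return cls(text=handle.read())


@runtime_checkable
class LLMBackend(Protocol):
    """Text-completion contract; identical prompts to a mock yield identical
    responses."""

    name: str

    def complete(self, prompt: str) -> str: ...


class StaticBackend:
    """Returns the same response for every prompt."""

    def __init__(self, response: str, name: str = "static-mock"):
        self.name = name
        self.response = response

    def complete(self, prompt: str) -> str:
        return self.response


_TABLE_ID_RE = re.compile(r"^Table ID:\s*(\S+)\s*$", re.MULTILINE)


class ScriptedBackend:
    """Responds per table id (read back from the prompt's provenance line)."""

    def __init__(self, script: Mapping[str, str], default: str = "", name: str = "scripted-mock"):
        self.name = name
        self.script = dict(script)
        self.default = default

    def complete(self, prompt: str) -> str:
        match = _TABLE_ID_RE.search(prompt)
        if match and match.group(1) in self.script:
            return self.script[match.group(1)]
        return self.default


class OracleBackend:
    """Answers with the gold label for each table id — an upper-bound mock."""

    def __init__(self, gold: Mapping[str, Label], name: str = "oracle-mock"):
        self.name = name
        self.gold = {tid: Label(label) for tid, label in gold.items()}

    def complete(self, prompt: str) -> str:
        match = _TABLE_ID_RE.search(prompt)
        if match and match.group(1) in self.gold:
            return f"The table matches the gold category.\nANSWER: {self.gold[match.group(1)].value}"
        return "I cannot find this table."


def build_prompt(template: PromptTemplate, table: ExtractedTable) -> str:
    """Render the prompt: caption, full markdown table and footer are slotted
    in verbatim. Rendering is deterministic."""
    prompt = template.text
    replacements = {
        "{table_id}": table.table_id,
        "{caption}": table.caption,
        "{table_markdown}": to_markdown(table),
        "{footer}": table.footer,
    }
    for slot, value in replacements.items():
        prompt = prompt.replace(slot, value)
    return prompt


_ANSWER_RE = re.compile(r"answer\s*:\s*([A-Za-z]+)", re.IGNORECASE)


def parse_response(response: str) -> FallbackLabel:
    """Extract the last ``ANSWER:`` directive (case-insensitive) and map it to
    a label; anything else is UNPARSEABLE. Never raises."""
    matches = _ANSWER_RE.findall(response or "")
    if not matches:
        return UNPARSEABLE
    try:
        return normalize_label(matches[-1])
    except ValueError:
        return UNPARSEABLE


def classify_zero_shot(
    backend: LLMBackend,
    template: PromptTemplate,
    table: ExtractedTable,
    max_retries: int = 2,
) -> FallbackLabel:
    """One zero-shot classification call; backend failures degrade to
    UNPARSEABLE after ``max_retries`` retries."""
    prompt = build_prompt(template, table)
    logger.debug(
        "zero-shot call: table_id=%s prompt_chars=%d backend=%s",
        table.table_id,
        len(prompt),
        backend.name,
    )
    response = None
    for attempt in range(max_retries + 1):
        try:
            response = backend.complete(prompt)
            break
        except Exception as exc:
            logger.warning(
                "backend %s failed on table %s (attempt %d/%d): %s",
                backend.name,
                table.table_id,
                attempt + 1,
                max_retries + 1,
                exc,
            )
    if response is None:
        logger.warning("table %s: backend exhausted retries, UNPARSEABLE", table.table_id)
        return UNPARSEABLE
    outcome = parse_response(response)
    logger.debug("table %s: zero-shot outcome %r", table.table_id, outcome)
    return outcome
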