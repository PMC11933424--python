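"""Synthetic labeled tables and JATS documents with a controllable
class-separability dial, so the whole pipeline is testable offline.

Each class draws from a class-exclusive keyword lexicon (at noise 0 the
classes are lexically disjoint on those keywords); the lexical-noise rate is
the probability that a class-typical token is replaced by a keyword from a
different class. The OTHER class includes the hard negative of
concentration-only measurement tables with no derived parameter names.
"""
from __future__ import annotations

import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Sequence

from .evaluation import largest_remainder
from .labels import CLASS_ORDER, Label
from .serialization import to_markdown
from .table_io import Corpus, ExtractedTable

__all__ = [
    "GeneratorConfig",
    "CLASS_KEYWORDS",
    "generate_table",
    "generate_corpus",
    "generate_jats",
]

#: Class-exclusive keyword lexicons (lowercased token forms). Disjoint by
#: construction; everything else in the templates is shared background.
CLASS_KEYWORDS: dict[Label, tuple[str, ...]] = {
    Label.PK: (
        "pharmacokinetic",
        "parameter",
        "parameters",
        "clearance",
        "cl/f",
        "auc",
        "cmax",
        "tmax",
        "vss",
        "ka",
        "half-life",
        "bioavailability",
    ),
    Label.DEMOGRAPHICS: (
        "demographic",
        "characteristics",
        "characteristic",
        "age",
        "weight",
        "height",
        "bmi",
        "sex",
        "male",
        "female",
        "ethnicity",
    ),
    Label.OTHER: (
        "adverse",
        "event",
        "events",
        "incidence",
        "headache",
        "nausea",
        "vomiting",
        "diarrhea",
        "assay",
        "stability",
        "inhibition",
        "viability",
        "plasma",
        "concentration",
        "concentrations",
        "sampling",
        "timepoint",
    ),
}

_DRUGS = (
    "midazolam",
    "rifampicin",
    "metformin",
    "voriconazole",
    "lamotrigine",
    "dexamethasone",
    "tacrolimus",
    "artesunate",
)

_PK_PARAMS = (
    ("CL/F", "L/h"),
    ("AUC", "ng·h/mL"),
    ("Cmax", "ng/mL"),
    ("Tmax", "h"),
    ("Vss", "L"),
    ("ka", "1/h"),
    ("half-life", "h"),
    ("bioavailability", "%"),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus generation settings.

    Default class proportions mirror a realistic imbalanced training split
    (PK : DEMOGRAPHICS : OTHER = 532 : 233 : 819); ``counts`` overrides them
    with exact per-class totals.
    """

    total: int = 600
    proportions: tuple[int, int, int] = (532, 233, 819)
    counts: dict | None = None
    noise_rate: float = 0.0
    long_table_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate <= 1:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if not 0 <= self.long_table_rate <= 1:
            raise ValueError(
                f"long_table_rate must be in [0, 1], got {self.long_table_rate}"
            )

    def class_counts(self) -> dict[Label, int]:
        if self.counts is not None:
            return {Label(k): int(v) for k, v in self.counts.items()}
        weight = sum(self.proportions)
        fractions = [p / weight for p in self.proportions]
        allocated = largest_remainder(self.total, fractions)
        return dict(zip(CLASS_ORDER, allocated))


def _cross_class_keywords(label: Label) -> list[str]:
    pool: list[str] = []
    for other, keywords in CLASS_KEYWORDS.items():
        if other != label:
            pool.extend(keywords)
    return pool


def _apply_noise(text: str, label: Label, noise_rate: float, rng: random.Random) -> str:
    """Replace own-class keyword tokens with cross-class keywords at the
    configured rate."""
    if noise_rate <= 0 or not text:
        return text
    own = set(CLASS_KEYWORDS[label])
    pool = _cross_class_keywords(label)
    tokens = text.split(" ")
    out = []
    for token in tokens:
        if token.lower().strip("().,;:") in own and rng.random() < noise_rate:
            out.append(rng.choice(pool))
        else:
            out.append(token)
    return " ".join(out)


def _value(rng: random.Random, low: float = 0.1, high: float = 99.0) -> str:
    return f"{rng.uniform(low, high):.2f}"


def _pk_template(rng: random.Random) -> tuple[str, list[list[str]], list[list[str]], str]:
    drug = rng.choice(_DRUGS)
    caption = rng.choice(
        (
            f"Pharmacokinetic parameter estimates of {drug} after oral dosing",
            f"Summary of pharmacokinetic parameters for {drug}",
            f"Estimated pharmacokinetic parameters of {drug} in healthy volunteers",
        )
    )
    header = [["Parameter", "Estimate", "Unit"]]
    params = rng.sample(_PK_PARAMS, k=rng.randint(4, len(_PK_PARAMS)))
    body = [[name, f"{_value(rng)} ± {_value(rng, 0.05, 9.0)}", unit] for name, unit in params]
    footer = (
        "CL/F, apparent clearance; AUC, area under the curve; "
        "Cmax, peak level. Values are mean ± SD."
    )
    return caption, header, body, footer


def _demographics_template(
    rng: random.Random,
) -> tuple[str, list[list[str]], list[list[str]], str]:
    caption = rng.choice(
        (
            "Baseline demographic characteristics of the study population",
            "Demographic and baseline characteristics of enrolled participants",
            "Summary of demographic characteristics by treatment group",
        )
    )
    header = [["Characteristic", "Value"]]
    n_male, n_female = rng.randint(5, 40), rng.randint(5, 40)
    body = [
        ["Age (years)", f"{_value(rng, 18, 80)} ± {_value(rng, 1, 12)}"],
        ["Weight (kg)", f"{_value(rng, 45, 110)} ± {_value(rng, 2, 15)}"],
        ["Height (cm)", f"{_value(rng, 150, 195)} ± {_value(rng, 2, 12)}"],
        ["BMI (kg/m2)", f"{_value(rng, 17, 36)} ± {_value(rng, 1, 5)}"],
        ["Sex, Male / Female", f"{n_male} / {n_female}"],
        ["Ethnicity", rng.choice(("Asian", "White", "Black", "Mixed"))],
    ]
    footer = "Data are mean ± SD or counts. BMI, body mass index."
    return caption, header, body, footer


def _other_template(rng: random.Random) -> tuple[str, list[list[str]], list[list[str]], str]:
    variant = rng.randint(0, 2)
    if variant == 0:  # adverse events
        caption = "Summary of adverse events reported during the study"
        header = [["Event", "Incidence"]]
        body = [
            [name, f"{rng.randint(0, 12)} ({rng.randint(0, 30)}%)"]
            for name in rng.sample(("Headache", "Nausea", "Vomiting", "Diarrhea"), k=3)
        ]
        footer = "Adverse events graded per protocol."
    elif variant == 1:  # in vitro assay
        caption = "In vitro stability and inhibition assay results"
        header = [["Assay", "Result"]]
        body = [
            ["Microsomal stability", f"{rng.randint(40, 99)}%"],
            ["Enzyme inhibition", rng.choice(("negative", "weak", "moderate"))],
            ["Cell viability", f"{rng.randint(60, 99)}%"],
        ]
        footer = "Assay results from duplicate runs."
    else:  # concentration-only hard negative: units but no parameter names
        drug = rng.choice(_DRUGS)
        caption = (
            f"Individual plasma concentration measurements of {drug} "
            "at each sampling timepoint"
        )
        header = [["Time (h)", "Concentration (ng/mL)"]]
        times = sorted(rng.sample(range(1, 49), k=rng.randint(4, 8)))
        body = [[f"{t}", _value(rng, 0.5, 500.0)] for t in times]
        footer = "Concentrations below the limit of quantification are omitted."
    return caption, header, body, footer


_TEMPLATES = {
    Label.PK: _pk_template,
    Label.DEMOGRAPHICS: _demographics_template,
    Label.OTHER: _other_template,
}


def _pad_long(table: ExtractedTable, rng: random.Random, min_tokens: int = 512) -> None:
    """Append subject rows until the markdown serialization exceeds
    ``min_tokens`` whitespace tokens."""
    width = table.n_columns
    subject = 1
    while len(to_markdown(table).split()) <= min_tokens:
        row = [f"Subject {subject}"] + [_value(rng) for _ in range(width - 1)]
        table.body.append(row)
        subject += 1


def generate_table(
    label: Label,
    config: GeneratorConfig,
    rng: random.Random,
    table_id: str = "synth-0000",
    long_table: bool = False,
) -> ExtractedTable:
    """Generate one labeled table from the class's template lexicon."""
    label = Label(label)
    caption, header, body, footer = _TEMPLATES[label](rng)
    noise = config.noise_rate
    table = ExtractedTable(
        table_id=table_id,
        article_id="",
        caption=_apply_noise(caption, label, noise, rng),
        header_rows=[[_apply_noise(c, label, noise, rng) for c in row] for row in header],
        body=[[_apply_noise(c, label, noise, rng) for c in row] for row in body],
        footer=_apply_noise(footer, label, noise, rng),
        label=label,
    )
    if long_table:
        _pad_long(table, rng)
    return table


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a labeled corpus: exact class counts, deterministic shuffle,
    long-table rate honored within ±1 table."""
    rng = random.Random(config.seed)
    counts = config.class_counts()
    labels: list[Label] = []
    for label in CLASS_ORDER:
        labels.extend([label] * counts.get(label, 0))
    rng.shuffle(labels)
    total = len(labels)
    n_long = round(config.long_table_rate * total)
    long_indices = set(rng.sample(range(total), n_long)) if n_long else set()
    records = [
        generate_table(
            label,
            config,
            rng,
            table_id=f"synth-{i:04d}",
            long_table=i in long_indices,
        )
        for i, label in enumerate(labels)
    ]
    return Corpus(records=records)


_XLINK = "http://www.w3.org/1999/xlink"


def generate_jats(
    tables: Sequence[ExtractedTable], include_image_only: int = 0
) -> str:
    """Emit a well-formed JATS article wrapping each table in a table-wrap,
    plus ``include_image_only`` graphic-only table-wraps (which a parser must
    exclude)."""
    ET.register_namespace("xlink", _XLINK)
    article = ET.Element("article")
    front = ET.SubElement(article, "front")
    ET.SubElement(front, "article-meta")
    body_el = ET.SubElement(article, "body")
    sec = ET.SubElement(body_el, "sec")

    for i, table in enumerate(tables):
        wrap = ET.SubElement(sec, "table-wrap", {"id": table.table_id})
        label_el = ET.SubElement(wrap, "label")
        label_el.text = f"Table {i + 1}"
        if table.caption:
            caption_el = ET.SubElement(wrap, "caption")
            p = ET.SubElement(caption_el, "p")
            p.text = table.caption
        table_el = ET.SubElement(wrap, "table")
        if table.header_rows:
            thead = ET.SubElement(table_el, "thead")
            for row in table.header_rows:
                tr = ET.SubElement(thead, "tr")
                for cell in row:
                    th = ET.SubElement(tr, "th")
                    th.text = cell
        tbody = ET.SubElement(table_el, "tbody")
        for row in table.body:
            tr = ET.SubElement(tbody, "tr")
            for cell in row:
                td = ET.SubElement(tr, "td")
                td.text = cell
        if table.footer:
            foot = ET.SubElement(wrap, "table-wrap-foot")
            p = ET.SubElement(foot, "p")
            p.text = table.footer

    for i in range(include_image_only):
        wrap = ET.SubElement(sec, "table-wrap", {"id": f"image-only-{i + 1}"})
        caption_el = ET.SubElement(wrap, "caption")
        p = ET.SubElement(caption_el, "p")
        p.text = "Table available as image only"
        ET.SubElement(wrap, "graphic", {f"{{{_XLINK}}}href": f"table-image-{i + 1}.jpg"})

    return ET.tostring(article, encoding="unicode")
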