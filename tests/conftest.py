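import random
import string

import pytest

from pktables.classifier import fit_table_classifier
from pktables.evaluation import stratified_split
from pktables.fixtures import GeneratorConfig, generate_corpus
from pktables.labels import Label
from pktables.table_io import Corpus, ExtractedTable


@pytest.fixture
def simple_table():
    return ExtractedTable(
        table_id="t1",
        article_id="PMC1234",
        caption="Tab",
        header_rows=[["P", "V"]],
        body=[["CL", "5"]],
        footer="CL, clearance",
    )


@pytest.fixture
def two_row_table():
    return ExtractedTable(
        table_id="t2",
        caption="Tab",
        header_rows=[["P", "V"]],
        body=[["CL", "5"], ["AUC", "9"]],
    )


def make_random_table(rng: random.Random, table_id: str) -> ExtractedTable:
    alphabet = string.ascii_letters + string.digits + " |±·-/%(),"
    text = lambda k: "".join(rng.choice(alphabet) for _ in range(rng.randint(0, k)))
    width = rng.randint(1, 5)
    return ExtractedTable(
        table_id=table_id,
        article_id=text(8),
        caption=text(40),
        header_rows=[[text(10) for _ in range(width)] for _ in range(rng.randint(0, 2))],
        body=[[text(10) for _ in range(width)] for _ in range(rng.randint(0, 6))],
        footer=text(30),
        label=rng.choice([None, Label.PK, Label.DEMOGRAPHICS, Label.OTHER]),
    )


def make_random_corpus(n: int, seed: int = 0) -> Corpus:
    rng = random.Random(seed)
    return Corpus(records=[make_random_table(rng, f"rand-{i:05d}") for i in range(n)])


@pytest.fixture(scope="session")
def corpus600():
    """The end-to-end synthetic corpus: 600 tables, imbalanced class
    proportions, lexical noise 0.2, seed 7."""
    return generate_corpus(GeneratorConfig(total=600, noise_rate=0.2, seed=7))


@pytest.fixture(scope="session")
def split600(corpus600):
    return stratified_split(corpus600, fractions=(0.6, 0.2, 0.2), seed=7)


@pytest.fixture(scope="session")
def model600(split600):
    train_corpus, _, _ = split600
    return fit_table_classifier(train_corpus, seed=7)
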