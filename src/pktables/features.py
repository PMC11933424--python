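"""Text featurization: bag-of-words vectors, and a pluggable encoder backend
with 512-token chunking plus mean/max pooling for long tables.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "VocabularyConfig",
    "Vocabulary",
    "FeatureVector",
    "PoolingMode",
    "EncoderBackend",
    "EncoderError",
    "HashingEncoder",
    "fit_vocabulary",
    "bow_encode",
    "chunk_tokens",
    "pool_chunks",
    "encode_long_text",
]


class PoolingMode(str, Enum):
    MEAN = "mean"
    MAX = "max"


@dataclass(frozen=True)
class VocabularyConfig:
    """Tokenization settings for the bag-of-words vocabulary.

    Tokens are maximal runs of alphanumeric characters (digits kept — PK
    tables are number-dense), lowercased by default. ``min_df`` filters on
    document frequency.
    """

    lowercase: bool = True
    token_pattern: str = r"[0-9a-zA-Z]+"
    min_df: int = 1


@dataclass
class Vocabulary:
    """Injective term→index map with 0..|V|-1 contiguous indices."""

    index: dict[str, int]
    config: VocabularyConfig = field(default_factory=VocabularyConfig)

    def __len__(self) -> int:
        return len(self.index)

    def tokenize(self, text: str) -> list[str]:
        return _tokenize(text, self.config)


@dataclass
class FeatureVector:
    """Fixed-length numeric representation of a serialized table."""

    values: np.ndarray
    tag: str

    @property
    def dimension(self) -> int:
        return int(self.values.shape[0])


def _tokenize(text: str, config: VocabularyConfig) -> list[str]:
    if config.lowercase:
        text = text.lower()
    return re.findall(config.token_pattern, text)


def fit_vocabulary(
    texts: Sequence[str], config: VocabularyConfig | None = None
) -> Vocabulary:
    """Build a vocabulary of every token meeting ``min_df``, indexed in
    lexicographic order."""
    if not texts:
        raise ValueError("cannot fit a vocabulary on an empty text list")
    config = config or VocabularyConfig()
    doc_freq: dict[str, int] = {}
    any_tokens = False
    for text in texts:
        tokens = set(_tokenize(text, config))
        any_tokens = any_tokens or bool(tokens)
        for token in tokens:
            doc_freq[token] = doc_freq.get(token, 0) + 1
    if not any_tokens:
        raise ValueError("all texts are empty; no tokens to build a vocabulary from")
    terms = sorted(t for t, df in doc_freq.items() if df >= config.min_df)
    return Vocabulary(index={term: i for i, term in enumerate(terms)}, config=config)


def bow_encode(text: str, vocab: Vocabulary) -> FeatureVector:
    """Count vocabulary terms in ``text``; out-of-vocabulary tokens ignored."""
    values = np.zeros(len(vocab), dtype=np.int64)
    for token in vocab.tokenize(text):
        idx = vocab.index.get(token)
        if idx is not None:
            values[idx] += 1
    return FeatureVector(values=values, tag="bow")


def chunk_tokens(tokens: Sequence, max_len: int = 512) -> list[list]:
    """Split tokens into consecutive non-overlapping chunks of ``max_len``
    (last chunk may be shorter). Empty input yields one empty chunk."""
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    tokens = list(tokens)
    if not tokens:
        return [[]]
    return [tokens[i : i + max_len] for i in range(0, len(tokens), max_len)]


def pool_chunks(chunk_vectors: Sequence[np.ndarray], mode: PoolingMode) -> np.ndarray:
    """Combine chunk vectors elementwise by arithmetic mean or maximum."""
    if not chunk_vectors:
        raise ValueError("pool_chunks requires at least one chunk vector")
    stacked = [np.asarray(v, dtype=float) for v in chunk_vectors]
    dims = {v.shape for v in stacked}
    if len(dims) > 1:
        raise ValueError(f"chunk vectors have mismatched dimensions: {sorted(dims)}")
    matrix = np.stack(stacked)
    mode = PoolingMode(mode)
    if mode is PoolingMode.MEAN:
        return matrix.mean(axis=0)
    return matrix.max(axis=0)


@runtime_checkable
class EncoderBackend(Protocol):
    """Pluggable fixed-dimension text encoder (e.g. a transformer adapter).

    The 512-token limit is a property of the encoder, so chunking uses the
    encoder's own tokenizer and ``max_len``.
    """

    name: str
    dimension: int
    max_len: int

    def tokenize(self, text: str) -> list[str]: ...

    def encode(self, tokens: Sequence[str]) -> np.ndarray: ...


class EncoderError(RuntimeError):
    """An encoder backend failed on a specific chunk."""


class HashingEncoder:
    """Deterministic hash-based encoder used as the test/reference backend.

    No learned weights: each token contributes a stable pseudo-random value to
    one of ``dimension`` buckets (sha1-based, independent of PYTHONHASHSEED).
    """

    def __init__(self, dimension: int = 8, max_len: int = 512, name: str = "hash"):
        self.name = name
        self.dimension = dimension
        self.max_len = max_len

    def tokenize(self, text: str) -> list[str]:
        return text.split()

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        vector = np.zeros(self.dimension, dtype=float)
        for token in tokens:
            digest = hashlib.sha1(str(token).encode("utf-8")).digest()
            bucket = digest[0] % self.dimension
            vector[bucket] += (int.from_bytes(digest[1:5], "big") % 1000) / 1000.0
        return vector


def encode_long_text(
    text: str, encoder: EncoderBackend, mode: PoolingMode
) -> FeatureVector:
    """Encode text of any length: tokenize, chunk to ``encoder.max_len``,
    encode each chunk, pool elementwise."""
    tokens = encoder.tokenize(text)
    chunks = chunk_tokens(tokens, encoder.max_len)
    vectors = []
    for i, chunk in enumerate(chunks):
        try:
            vectors.append(np.asarray(encoder.encode(chunk), dtype=float))
        except Exception as exc:
            raise EncoderError(
                f"encoder {encoder.name!r} failed on chunk {i} of {len(chunks)}: {exc}"
            ) from exc
    pooled = pool_chunks(vectors, mode)
    return FeatureVector(values=pooled, tag=f"{encoder.name}:{PoolingMode(mode).value}")
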