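"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from medembed import (
    ConceptDictionary,
    CooccurrenceMatrix,
    SPPMISVD,
    SyntheticSpec,
    Vocabulary,
    Window,
    chunk_windows,
    count_text_cooccurrences,
    generate_corpus,
    generate_thesaurus,
    normalize_text,
)

# The seven-mapping dictionary behind the worked normalization example.
WORKED_SENTENCE = (
    "Bronchopulmonary Dysplasia was first described by Northway and "
    "colleagues in 1967 as a lung injury in a preterm infant resulting "
    "from oxygen and mechanical ventilation."
)
WORKED_NORMALIZED = (
    "C0006287 was first described by northway and colleagues in 1967 as a "
    "C0024109 C3263722 in a C0021294 C0678226 C0030054 and C0199470"
)
WORKED_MAPPINGS = [
    ("bronchopulmonary dysplasia", "C0006287"),
    ("lung", "C0024109"),
    ("injury", "C3263722"),
    ("preterm infant", "C0021294"),
    ("resulting from", "C0678226"),
    ("oxygen", "C0030054"),
    ("mechanical ventilation", "C0199470"),
]


@pytest.fixture(scope="session")
def worked_dictionary() -> ConceptDictionary:
    return ConceptDictionary.from_pairs(WORKED_MAPPINGS)


@pytest.fixture
def toy_vocab() -> Vocabulary:
    return Vocabulary(("C1", "C2", "C3"))


def windows_of(*window_tokens: tuple[str, ...], length: int = 10) -> list[Window]:
    return [Window(tokens=tuple(toks), length=length) for toks in window_tokens]


def random_symmetric_counts(
    rng: np.random.Generator, n: int, high: int = 6
) -> CooccurrenceMatrix:
    """A random symmetric nonnegative-integer matrix with zero diagonal."""
    upper = np.triu(rng.integers(0, high, size=(n, n)), k=1)
    counts = upper + upper.T
    if counts.sum() == 0:  # ensure at least one nonzero cell
        counts[0, 1] = counts[1, 0] = 1
    vocab = Vocabulary(tuple(f"C{i:04d}" for i in range(n)))
    return CooccurrenceMatrix(counts=sp.csr_matrix(counts), vocab=vocab)


def run_text_pipeline(spec: SyntheticSpec, d: int = 50, svd_seed: int = 7):
    """generate -> normalize -> windows -> counts -> SPPMI -> SVD.

    Returns (embedding, semantic-type map, planted pairs).
    """
    dictionary, types = generate_thesaurus(spec)
    docs, planted = generate_corpus(spec, dictionary)
    windows = []
    for i, doc in enumerate(docs):
        stream = normalize_text(doc, dictionary, doc_id=str(i))
        windows.extend(chunk_windows(stream, spec.neighborhood))
    vocab = Vocabulary.from_concepts(dictionary.entries.values())
    counts = count_text_cooccurrences(windows, vocab)
    emb = SPPMISVD(counts).fit(d=d, seed=svd_seed).embedding
    return emb, types, planted
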