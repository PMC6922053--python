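"""Readers and writers for every interchange format.

* co-occurrence matrices: Matrix Market (``.mtx``) next to a vocabulary
  file (one CUI per line, line number = matrix index);
* embeddings: word2vec text format (header ``count dim`` then one
  ``CUI v1 ... vd`` row per concept) or TSV;
* concept dictionaries, event streams, relationship sets, semantic-type
  maps, human-score sets and benchmark results: plain TSV;
* run configuration: flat ``key = value`` text.

Vocabulary order is canonicalized (sorted CUIs) at matrix write time so
merged artifacts are byte-stable; all writers emit 12 significant digits,
so round-trips are lossless well past 1e-10.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .benchmark import (
    BenchmarkResult,
    HumanSimilaritySet,
    RelationshipSet,
    SemanticTypeMap,
)
from .cooccur import CooccurrenceMatrix, EventStream, Vocabulary, merge_counts
from .normalize import ConceptDictionary
from .spectral import EmbeddingMatrix

__all__ = [
    "read_dictionary", "write_dictionary",
    "read_vocabulary", "write_vocabulary",
    "read_cooccurrence", "write_cooccurrence",
    "read_sppmi_values", "write_sppmi_values",
    "read_embeddings", "write_embeddings",
    "read_events", "write_events",
    "read_relationships", "write_relationships",
    "read_semantic_types", "write_semantic_types",
    "read_human_scores", "write_human_scores",
    "write_results", "read_config", "write_config",
]

_FLOAT_FMT = "%.12g"


def _rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh, delimiter="\t") if row]


def _write_rows(path, rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerows(rows)


# -- dictionaries and vocabularies ------------------------------------------

def read_dictionary(path) -> ConceptDictionary:
    """2-column TSV: space-separated lowercase surface phrase, CUI."""
    return ConceptDictionary.from_pairs((r[0], r[1]) for r in _rows(path))


def write_dictionary(path, dictionary: ConceptDictionary) -> None:
    _write_rows(
        path,
        sorted((" ".join(p), cui) for p, cui in dictionary.entries.items()),
    )


def read_vocabulary(path) -> Vocabulary:
    with open(path) as fh:
        cuis = [line.strip() for line in fh if line.strip()]
    return Vocabulary(tuple(cuis))


def write_vocabulary(path, vocab: Vocabulary) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{cui}\n" for cui in vocab.cuis)


# -- sparse matrices ---------------------------------------------------------

def _vocab_path(matrix_path) -> Path:
    p = Path(matrix_path)
    return p.with_suffix(p.suffix + ".vocab") if p.suffix != ".mtx" \
        else p.with_suffix(".vocab")


def write_cooccurrence(
    path, matrix: CooccurrenceMatrix, canonical: bool = True
) -> None:
    """Matrix Market file plus a ``.vocab`` sidecar.

    With *canonical* (default) the vocabulary is re-sorted before writing
    so identical content always produces identical bytes.
    """
    if canonical and list(matrix.vocab.cuis) != sorted(matrix.vocab.cuis):
        matrix = merge_counts([matrix])
    mmwrite(str(path), matrix.counts, field="integer", symmetry="general")
    write_vocabulary(_vocab_path(path), matrix.vocab)


def read_cooccurrence(path) -> CooccurrenceMatrix:
    counts = sp.csr_matrix(mmread(str(path)))
    vocab = read_vocabulary(_vocab_path(path))
    if counts.shape[0] != len(vocab):
        raise ValueError(
            f"matrix is {counts.shape[0]}x{counts.shape[1]} but the "
            f"vocabulary file lists {len(vocab)} concepts"
        )
    return CooccurrenceMatrix(counts=counts, vocab=vocab)


def write_sppmi_values(path, values: sp.spmatrix, vocab: Vocabulary) -> None:
    mmwrite(str(path), sp.coo_matrix(values), field="real", precision=12)
    write_vocabulary(_vocab_path(path), vocab)


def read_sppmi_values(path) -> tuple[sp.csr_matrix, Vocabulary]:
    values = sp.csr_matrix(mmread(str(path)))
    vocab = read_vocabulary(_vocab_path(path))
    if values.shape[0] != len(vocab):
        raise ValueError("matrix dimension does not match the vocabulary file")
    return values, vocab


# -- embeddings --------------------------------------------------------------

def write_embeddings(path, emb: EmbeddingMatrix, fmt: str = "word2vec") -> None:
    """word2vec text format (``fmt="word2vec"``) or headerless TSV."""
    if fmt not in ("word2vec", "tsv"):
        raise ValueError(f"unknown embedding format {fmt!r}")
    with open(path, "w") as fh:
        if fmt == "word2vec":
            fh.write(f"{len(emb.vocab)} {emb.d}\n")
        sep = " " if fmt == "word2vec" else "\t"
        for cui, row in zip(emb.vocab.cuis, emb.vectors):
            vals = sep.join(_FLOAT_FMT % v for v in row)
            fh.write(f"{cui}{sep}{vals}\n")


def read_embeddings(path, fmt: str = "word2vec") -> EmbeddingMatrix:
    if fmt not in ("word2vec", "tsv"):
        raise ValueError(f"unknown embedding format {fmt!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if fmt == "word2vec":
        header = lines[0].split()
        if len(header) != 2:
            raise ValueError("word2vec header must be 'count dim'")
        n, d = int(header[0]), int(header[1])
        lines = lines[1:]
        if len(lines) != n:
            raise ValueError(
                f"header announces {n} rows but the file holds {len(lines)}"
            )
    cuis, vectors = [], []
    for ln in lines:
        parts = ln.split() if fmt == "word2vec" else ln.split("\t")
        cuis.append(parts[0])
        vectors.append([float(v) for v in parts[1:]])
    arr = np.asarray(vectors, dtype=np.float64)
    if fmt == "word2vec" and arr.shape[1] != d:
        raise ValueError(f"header announces dim {d}, rows have {arr.shape[1]}")
    return EmbeddingMatrix(vectors=arr, vocab=Vocabulary(tuple(cuis)))


# -- events, relationships, types, scores, results ---------------------------

def read_events(path) -> EventStream:
    """3-column TSV: patient_id, cui, day."""
    return EventStream.from_tuples(
        (r[0], r[1], int(r[2])) for r in _rows(path)
    )


def write_events(path, events: EventStream) -> None:
    _write_rows(path, ((r.patient_id, r.cui, r.day) for r in events))


def read_relationships(path, name: str = "relationships") -> RelationshipSet:
    """3-column TSV: cui_x, cui_y, relation."""
    return RelationshipSet(
        tuple((r[0], r[1], r[2] if len(r) > 2 else "related") for r in _rows(path)),
        name=name,
    )


def write_relationships(path, rels: RelationshipSet) -> None:
    _write_rows(path, rels.pairs)


def read_semantic_types(path) -> SemanticTypeMap:
    """2-column TSV: cui, category."""
    return SemanticTypeMap(categories={r[0]: r[1] for r in _rows(path)})


def write_semantic_types(path, types: SemanticTypeMap) -> None:
    _write_rows(path, sorted(types.categories.items()))


def read_human_scores(path) -> HumanSimilaritySet:
    """3-column TSV: cui_x, cui_y, mean human score."""
    return HumanSimilaritySet(
        tuple((r[0], r[1], float(r[2])) for r in _rows(path))
    )


def write_human_scores(path, human: HumanSimilaritySet) -> None:
    _write_rows(
        path, ((x, y, _FLOAT_FMT % s) for x, y, s in human.pairs)
    )


def write_results(path, results: Iterable[BenchmarkResult]) -> None:
    rows = [("benchmark", "metric", "value", "n_evaluable", "n_total")]
    rows += [
        (r.name, r.metric, _FLOAT_FMT % r.value, r.n_evaluable, r.n_total)
        for r in results
    ]
    _write_rows(path, rows)


# -- configuration -----------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` file; blank lines and ``#`` comments ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{k} = {v}\n" for k, v in sorted(config.items()))
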