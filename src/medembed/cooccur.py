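"""Concept-concept co-occurrence counting.

Three counting pathways feed one symmetric master matrix:

* text windows — a pair of distinct concepts co-present in the same
  fixed-length window counts once per window;
* rolling temporal mode (claims-style) — a pair counts once per patient
  if any two of the patient's events carry the two concepts within a
  fixed number of days of each other;
* calendar temporal mode (notes-style) — days are partitioned into fixed
  bins anchored at each patient's first event and a pair counts when both
  concepts fall in a common bin.

Per-source matrices over possibly different vocabularies are merged by
vocabulary union and cell-wise addition.  All matrices are symmetric,
integer, and have an identically zero diagonal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .normalize import Window, is_cui

__all__ = [
    "Vocabulary",
    "CooccurrenceMatrix",
    "EventRecord",
    "EventStream",
    "count_text_cooccurrences",
    "count_temporal_cooccurrences",
    "merge_counts",
]


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between concept IDs and contiguous 0-based indices."""

    cuis: tuple[str, ...]
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        index = {cui: i for i, cui in enumerate(self.cuis)}
        if len(index) != len(self.cuis):
            raise ValueError("duplicate concept IDs in vocabulary")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_concepts(cls, cuis: Iterable[str], sort: bool = True) -> "Vocabulary":
        cuis = list(dict.fromkeys(cuis))
        if sort:
            cuis.sort()
        return cls(tuple(cuis))

    def __len__(self) -> int:
        return len(self.cuis)

    def __contains__(self, cui: str) -> bool:
        return cui in self._index

    def index(self, cui: str) -> int:
        return self._index[cui]

    def get(self, cui: str, default=None):
        return self._index.get(cui, default)


@dataclass
class CooccurrenceMatrix:
    """Symmetric nonnegative integer co-occurrence counts over a vocabulary."""

    counts: sp.csr_matrix
    vocab: Vocabulary
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        self.validate()

    def validate(self) -> None:
        n = len(self.vocab)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match |V|={n}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative co-occurrence count")
        if np.any(self.counts.diagonal() != 0):
            raise ValueError("nonzero diagonal: self co-occurrence is not allowed")
        asym = abs(self.counts - self.counts.T)
        if asym.nnz and asym.max() > 0:
            i, j = np.unravel_index(np.argmax(asym.toarray()), asym.shape)
            raise ValueError(f"asymmetric counts at indices ({i}, {j})")

    @property
    def total_pairs(self) -> int:
        """Total number of counted unordered co-occurrence pairs."""
        return int(self.counts.sum()) // 2

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()


@dataclass(frozen=True)
class EventRecord:
    """A single timestamped code assignment: (patient, concept, day)."""

    patient_id: str
    cui: str
    day: int

    def __post_init__(self) -> None:
        if not is_cui(self.cui):
            raise ValueError(f"{self.cui!r} does not match the CUI pattern")
        if not np.isfinite(self.day):
            raise ValueError("event day must be finite")


@dataclass(frozen=True)
class EventStream:
    """An unordered collection of patient event records."""

    records: tuple[EventRecord, ...]

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple[str, str, int]]
    ) -> "EventStream":
        return cls(tuple(EventRecord(p, c, int(d)) for p, c, d in tuples))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _matrix_from_pairs(
    pair_counts: dict[tuple[int, int], int], vocab: Vocabulary, source_tag: str
) -> CooccurrenceMatrix:
    n = len(vocab)
    if pair_counts:
        rows, cols, vals = [], [], []
        for (i, j), c in pair_counts.items():
            rows += [i, j]
            cols += [j, i]
            vals += [c, c]
        counts = sp.csr_matrix(
            (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(n, n)
        )
    else:
        counts = sp.csr_matrix((n, n), dtype=np.int64)
    return CooccurrenceMatrix(counts=counts, vocab=vocab, source_tag=source_tag)


def count_text_cooccurrences(
    windows: Sequence[Window],
    vocab: Vocabulary,
    concept_only: bool = True,
    multiplicity: str = "presence",
) -> CooccurrenceMatrix:
    """Count concept pairs co-present in the same text window.

    With ``multiplicity="presence"`` (default) each unordered pair of
    distinct concepts co-present in a window increments its cell by 1,
    once per window regardless of how many times either token repeats.
    ``multiplicity="product"`` instead adds the product of the two tokens'
    within-window multiplicities (sensitivity-check variant).

    When *concept_only* is set, only CUI-pattern tokens are counted and
    tokens missing from *vocab* are skipped; otherwise every token is
    counted and an unknown token raises ``KeyError``.
    """
    if multiplicity not in ("presence", "product"):
        raise ValueError(f"unknown multiplicity rule {multiplicity!r}")
    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for window in windows:
        tallies: dict[int, int] = defaultdict(int)
        for tok in window:
            if concept_only:
                if not is_cui(tok):
                    continue
                idx = vocab.get(tok)
                if idx is None:
                    continue
            else:
                idx = vocab.get(tok)
                if idx is None:
                    raise KeyError(f"token {tok!r} is not in the vocabulary")
            tallies[idx] += 1
        for i, j in combinations(sorted(tallies), 2):
            if multiplicity == "presence":
                pair_counts[(i, j)] += 1
            else:
                pair_counts[(i, j)] += tallies[i] * tallies[j]
    return _matrix_from_pairs(pair_counts, vocab, source_tag="text")


def _rolling_patient_pairs(
    events: list[tuple[int, int]], span_days: int, per_episode: bool
) -> dict[tuple[int, int], int]:
    """Pairs co-occurring within ``span_days`` for one patient's events.

    *events* is a (day, concept-index) list.  Returns pair -> count, where
    the count is 1 (default) or the number of disjoint episodes
    (non-overlapping day intervals containing both concepts).
    """
    events = sorted(events)
    by_pair: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    start = 0
    for k, (day, idx) in enumerate(events):
        while events[start][0] < day - span_days:
            start += 1
        for prev_day, prev_idx in events[start:k]:
            if prev_idx != idx:
                pair = (min(prev_idx, idx), max(prev_idx, idx))
                by_pair[pair].append((prev_day, day))
    if not per_episode:
        return {pair: 1 for pair in by_pair}
    out = {}
    for pair, intervals in by_pair.items():
        # greedy non-overlapping interval selection, by earliest end day
        intervals.sort(key=lambda iv: iv[1])
        count, free_from = 0, -np.inf
        for lo, hi in intervals:
            if lo >= free_from:
                count += 1
                free_from = hi + 1
        out[pair] = count
    return out


def count_temporal_cooccurrences(
    events: EventStream,
    vocab: Vocabulary,
    span_days: int = 30,
    mode: str = "rolling",
    per_episode: bool = False,
    per_bin: bool = False,
) -> CooccurrenceMatrix:
    """Count concept pairs co-occurring in time within each patient.

    ``mode="rolling"`` (claims-style): a pair counts once per patient if
    any two of the patient's events carry the two concepts with a day
    difference of at most *span_days*; ``per_episode=True`` instead counts
    disjoint such episodes.  ``mode="calendar"`` (notes-style): days are
    partitioned into bins of *span_days* anchored at the patient's first
    event, and a pair counts once per patient if both concepts share some
    bin (``per_bin=True``: once per bin instead).  Pairs never cross
    patients.
    """
    if span_days < 1:
        raise ValueError(f"span_days must be >= 1, got {span_days}")
    if mode not in ("rolling", "calendar"):
        raise ValueError(f"unknown mode {mode!r}")
    by_patient: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rec in events:
        idx = vocab.get(rec.cui)
        if idx is None:
            raise KeyError(f"concept {rec.cui!r} is not in the vocabulary")
        by_patient[rec.patient_id].append((rec.day, idx))

    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for patient_events in by_patient.values():
        if mode == "rolling":
            for pair, c in _rolling_patient_pairs(
                patient_events, span_days, per_episode
            ).items():
                pair_counts[pair] += c
        else:
            first_day = min(day for day, _ in patient_events)
            bins: dict[int, set[int]] = defaultdict(set)
            for day, idx in patient_events:
                bins[(day - first_day) // span_days].add(idx)
            seen: set[tuple[int, int]] = set()
            for members in bins.values():
                for pair in combinations(sorted(members), 2):
                    if per_bin:
                        pair_counts[pair] += 1
                    else:
                        seen.add(pair)
            for pair in seen:
                pair_counts[pair] += 1
    tag = "claims" if mode == "rolling" else "notes"
    return _matrix_from_pairs(pair_counts, vocab, source_tag=tag)


def merge_counts(matrices: Sequence[CooccurrenceMatrix]) -> CooccurrenceMatrix:
    """Merge per-source matrices into one master matrix.

    The output vocabulary is the sorted union of the input vocabularies;
    each cell is the sum of the aligned input cells.
    """
    if len(matrices) == 0:
        raise ValueError("nothing to merge: empty matrix list")
    merged_vocab = Vocabulary.from_concepts(
        (cui for m in matrices for cui in m.vocab.cuis), sort=True
    )
    n = len(merged_vocab)
    total = sp.csr_matrix((n, n), dtype=np.int64)
    for m in matrices:
        coo = m.counts.tocoo()
        lookup = np.asarray([merged_vocab.index(c) for c in m.vocab.cuis])
        total = total + sp.csr_matrix(
            (coo.data, (lookup[coo.row], lookup[coo.col])), shape=(n, n)
        )
    tags = sorted({m.source_tag for m in matrices if m.source_tag})
    return CooccurrenceMatrix(
        counts=total, vocab=merged_vocab, source_tag="+".join(tags) or "merged"
    )
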