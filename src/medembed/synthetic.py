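"""Synthetic corpora, event streams and benchmark tables with planted signal.

The generator emulates the statistical skeleton of the real inputs:

* a thesaurus of synthetic concepts (CUIs in the C9xxxxxx range) with
  1-3-token surface phrases and a category label per concept, categories
  given by a cluster partition;
* concept-bearing text in which documents lean toward one cluster's
  concepts (topicality) over a Zipf-distributed background vocabulary,
  with *planted related pairs*: whenever the first member of a pair is
  mentioned, the second is inserted into the same 10-token neighborhood
  with probability lambda;
* patient event streams over a two-year horizon with *planted comorbid
  pairs*: a patient carrying the first concept also receives the second
  within 30 days with probability lambda.

Every generator is a pure function of (spec, seed), so all fixtures are
reproducible and no data files need to ship.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

from .benchmark import SemanticTypeMap
from .cooccur import EventRecord, EventStream
from .normalize import ConceptDictionary

__all__ = [
    "SyntheticSpec",
    "generate_thesaurus",
    "generate_corpus",
    "generate_event_stream",
    "planted_relationships",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world.

    ``planted_pairs`` lists (cui_a, cui_b, lambda) triples; when empty,
    ``n_planted_pairs`` same-cluster pairs at ``planted_lambda`` are
    chosen automatically by :func:`planted_relationships`.
    """

    n_concepts: int = 100
    n_clusters: int = 4
    n_documents: int = 1500
    doc_length: int = 100
    n_patients: int = 500
    events_per_patient: int = 10
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    n_planted_pairs: int = 20
    planted_lambda: float = 0.9
    background_vocab: int = 300
    concept_rate: float = 0.25
    topic_strength: float = 0.5
    zipf_exponent: float = 1.1
    neighborhood: int = 10
    event_horizon_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_concepts, self.n_clusters, self.n_documents, self.doc_length,
            self.n_patients, self.background_vocab,
        ) <= 0 or self.events_per_patient < 0:
            raise ValueError("all synthetic sizes must be positive")
        if self.n_clusters > self.n_concepts:
            raise ValueError("more clusters than concepts")
        for _, _, lam in self.planted_pairs:
            if not 0.0 <= lam <= 1.0:
                raise ValueError("mixing strength lambda must be in [0, 1]")
        if not 0.0 <= self.planted_lambda <= 1.0:
            raise ValueError("mixing strength lambda must be in [0, 1]")

    def with_lambda(self, lam: float) -> "SyntheticSpec":
        """Copy of this spec with all planted strengths set to *lam*."""
        pairs = tuple((a, b, lam) for a, b, _ in self.planted_pairs)
        return replace(self, planted_pairs=pairs, planted_lambda=lam)


def _concept_ids(spec: SyntheticSpec) -> list[str]:
    return [f"C9{i:06d}" for i in range(spec.n_concepts)]


def _clusters(spec: SyntheticSpec) -> dict[str, int]:
    """Concepts partitioned into contiguous, near-equal clusters."""
    cuis = _concept_ids(spec)
    bounds = np.linspace(0, spec.n_concepts, spec.n_clusters + 1).astype(int)
    out = {}
    for c in range(spec.n_clusters):
        for i in range(bounds[c], bounds[c + 1]):
            out[cuis[i]] = c
    return out


def _random_word(rng: np.random.Generator, lo: int = 4, hi: int = 8) -> str:
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(list(string.ascii_lowercase), size=length)
    return "".join(letters)


def generate_thesaurus(
    spec: SyntheticSpec,
) -> tuple[ConceptDictionary, SemanticTypeMap]:
    """Synthetic concept dictionary and per-cluster category map.

    Surface phrases have 1-3 tokens; every surface token is used by
    exactly one concept (collisions are redrawn), so greedy longest-match
    recovers the planted concepts exactly.
    """
    rng = np.random.default_rng([spec.seed, 101])
    cuis = _concept_ids(spec)
    clusters = _clusters(spec)
    used_tokens: set[str] = set()
    entries: dict[tuple[str, ...], str] = {}
    for cui in cuis:
        n_tok = int(rng.integers(1, 4))
        phrase = []
        for _ in range(n_tok):
            tok = _random_word(rng)
            while tok in used_tokens:
                tok = _random_word(rng)
            used_tokens.add(tok)
            phrase.append(tok)
        entries[tuple(phrase)] = cui
    categories = SemanticTypeMap(
        categories={cui: f"type_{clusters[cui]}" for cui in cuis}
    )
    return ConceptDictionary(entries=entries), categories


def planted_relationships(spec: SyntheticSpec) -> tuple[tuple[str, str, float], ...]:
    """The spec's planted pairs, or an automatic same-cluster selection.

    Automatic selection draws ``n_planted_pairs`` disjoint pairs whose two
    members share a cluster, at strength ``planted_lambda``.
    """
    if spec.planted_pairs:
        return spec.planted_pairs
    rng = np.random.default_rng([spec.seed, 202])
    clusters = _clusters(spec)
    by_cluster: dict[int, list[str]] = {}
    for cui, c in clusters.items():
        by_cluster.setdefault(c, []).append(cui)
    pairs = []
    taken: set[str] = set()
    cluster_cycle = sorted(by_cluster)
    c_i = 0
    while len(pairs) < spec.n_planted_pairs:
        members = [m for m in by_cluster[cluster_cycle[c_i % len(cluster_cycle)]]
                   if m not in taken]
        c_i += 1
        if len(members) < 2:
            if all(
                len([m for m in ms if m not in taken]) < 2
                for ms in by_cluster.values()
            ):
                raise ValueError("not enough free concepts to plant pairs")
            continue
        a, b = rng.choice(members, size=2, replace=False)
        taken.update((a, b))
        pairs.append((str(a), str(b), spec.planted_lambda))
    return tuple(pairs)


def _background_sampler(spec: SyntheticSpec, rng: np.random.Generator):
    """Bounded Zipf sampler over the background vocabulary."""
    ranks = np.arange(1, spec.background_vocab + 1, dtype=np.float64)
    probs = ranks**-spec.zipf_exponent
    probs /= probs.sum()
    words = [f"w{_random_word(rng, 3, 6)}" for _ in range(spec.background_vocab)]

    def sample(size: int) -> list[str]:
        return [words[i] for i in rng.choice(spec.background_vocab, size=size, p=probs)]

    return sample


def generate_corpus(
    spec: SyntheticSpec, dictionary: ConceptDictionary
) -> tuple[list[str], tuple[tuple[str, str, float], ...]]:
    """Synthetic raw-text documents plus the planted ground truth.

    Each document draws a topic cluster; concept slots (rate
    ``concept_rate``) pick a concept from that cluster with probability
    ``topic_strength``, otherwise uniformly.  Documents are laid out in
    *normalized token units* (one unit per concept mention or background
    word, ``doc_length`` units per document) so planted-pair placement can
    respect the downstream windows: whenever the first member of a planted
    pair is emitted, its partner is placed immediately after it inside the
    same ``neighborhood``-unit block with probability lambda (the pair is
    nudged off a block boundary when needed, so lambda = 1 forces
    co-occurrence in every window).  Units are then rendered as surface
    phrases and Zipf-distributed background words, capitalized and
    period-terminated, so the normalizer has real work to do.
    """
    rng = np.random.default_rng([spec.seed, 303])
    cuis = _concept_ids(spec)
    clusters = _clusters(spec)
    by_cluster: dict[int, list[str]] = {}
    for cui, c in clusters.items():
        by_cluster.setdefault(c, []).append(cui)
    phrase_of = {cui: list(p) for p, cui in dictionary.entries.items()}
    planted = planted_relationships(spec)
    partner = {a: (b, lam) for a, b, lam in planted}
    bg = _background_sampler(spec, rng)
    L = spec.neighborhood
    docs: list[str] = []
    for _ in range(spec.n_documents):
        topic = int(rng.integers(spec.n_clusters))
        units: list[str] = []
        while len(units) < spec.doc_length:
            if rng.random() < spec.concept_rate:
                if rng.random() < spec.topic_strength:
                    cui = str(rng.choice(by_cluster[topic]))
                else:
                    cui = str(rng.choice(cuis))
                pair = partner.get(cui)
                if pair is not None and rng.random() < pair[1]:
                    # keep the pair inside one window: pad off a block
                    # boundary, and drop the mention if the document
                    # cannot hold both members
                    if len(units) % L == L - 1:
                        units.extend(bg(1))
                    if spec.doc_length - len(units) >= 2:
                        units.extend((cui, pair[0]))
                    else:
                        units.extend(bg(1))
                else:
                    units.append(cui)
            else:
                units.extend(bg(1))
        units = units[: spec.doc_length]
        words = [w for u in units for w in phrase_of.get(u, [u])]
        text = " ".join(words)
        docs.append(text[0].upper() + text[1:] + ".")
    return docs, planted


def generate_event_stream(
    spec: SyntheticSpec,
) -> tuple[EventStream, tuple[tuple[str, str, float], ...]]:
    """Synthetic patient event stream plus the planted ground truth.

    Base events get uniform days over the horizon and uniform concepts.
    For each planted pair (a, b, lambda) and each patient with at least
    one event of a, an event of b is added within 30 days of one of the
    a-events with probability lambda.
    """
    rng = np.random.default_rng([spec.seed, 404])
    cuis = _concept_ids(spec)
    planted = planted_relationships(spec)
    records: list[EventRecord] = []
    per_patient: dict[str, dict[str, list[int]]] = {}
    for p in range(spec.n_patients):
        pid = f"P{p:05d}"
        carried: dict[str, list[int]] = {}
        for _ in range(spec.events_per_patient):
            cui = str(rng.choice(cuis))
            day = int(rng.integers(spec.event_horizon_days))
            records.append(EventRecord(patient_id=pid, cui=cui, day=day))
            carried.setdefault(cui, []).append(day)
        per_patient[pid] = carried
    for a, b, lam in planted:
        for pid, carried in per_patient.items():
            if a in carried and rng.random() < lam:
                anchor = int(rng.choice(carried[a]))
                day = anchor + int(rng.integers(0, 31))
                records.append(EventRecord(patient_id=pid, cui=b, day=day))
    return EventStream(records=tuple(records)), planted
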