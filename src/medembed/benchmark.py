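"""Statistical-power benchmarking of concept embeddings.

The benchmark asks: of a set of known related concept pairs, what fraction
can the embedding "discover"?  For a known pair (x, y) the null
distribution of similarity scores is built by drawing 10,000 bootstrap
pairs (x*, y*) where x* shares x's category (semantic type or benchmark
class) and y* shares y's, and recording their cosine similarity.  The
known pair is declared discovered when its cosine strictly exceeds the
95th percentile of that null, a one-sided test at level 0.05.  Power is
the discovered fraction over all evaluable pairs, directly interpretable
as the fraction of true relationships found at a 5% false-positive
tolerance.

Null distributions are cached per unordered category pair (one set of
draws per category pair, not per relationship).  The empirical quantile is
the order statistic at ceiling((1 - level) * n) of the sorted draws, and
the two drawn concepts are required to be distinct (a draw hitting the
same concept twice is redrawn).  The semantic-type benchmark instead uses
a *marginal* null: the two concepts are drawn from two different,
randomly chosen categories.

Agreement with human similarity judgements is summarized as the Spearman
rank correlation between mean human scores and embedding cosines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping
from zlib import crc32

import numpy as np
from scipy import stats

from .spectral import EmbeddingMatrix

__all__ = [
    "SemanticTypeMap",
    "RelationshipSet",
    "HumanSimilaritySet",
    "NullDistribution",
    "BenchmarkResult",
    "cosine_similarity",
    "bootstrap_null",
    "relationship_power",
    "human_similarity_correlation",
]

DEFAULT_N_BOOTSTRAP = 10_000


@dataclass(frozen=True)
class SemanticTypeMap:
    """Concept ID -> single category label."""

    categories: Mapping[str, str]

    def __getitem__(self, cui: str) -> str:
        return self.categories[cui]

    def get(self, cui: str, default=None):
        return self.categories.get(cui, default)

    def members(self, label: str) -> list[str]:
        return [c for c, lab in self.categories.items() if lab == label]

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.categories.values()))


@dataclass(frozen=True)
class RelationshipSet:
    """Known related concept pairs for one benchmark family."""

    pairs: tuple[tuple[str, str, str], ...]
    name: str = "relationships"

    def __post_init__(self) -> None:
        seen = set()
        for x, y, _rel in self.pairs:
            if x == y:
                raise ValueError(f"self-pair ({x}, {y}) is not a relationship")
            if (x, y) in seen:
                raise ValueError(f"duplicate pair ({x}, {y})")
            seen.add((x, y))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], relation: str = "related",
        name: str = "relationships",
    ) -> "RelationshipSet":
        return cls(tuple((x, y, relation) for x, y in pairs), name=name)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class HumanSimilaritySet:
    """Concept pairs with mean human similarity judgements."""

    pairs: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if any(not np.isfinite(s) for _, _, s in self.pairs):
            raise ValueError("human scores must be finite")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap cosine-similarity samples for one category pair."""

    samples: np.ndarray
    category_pair: tuple[str, str]
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.samples) > 1 + 1e-9):
            raise ValueError("cosine samples must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.samples)

    def threshold(self, level: float = 0.05) -> float:
        """Empirical (1 - level) quantile: sorted order statistic at
        ceiling((1 - level) * n)."""
        srt = np.sort(self.samples)
        rank = int(np.ceil((1.0 - level) * self.n))
        return float(srt[rank - 1])


@dataclass(frozen=True)
class BenchmarkResult:
    """A single benchmark metric with its coverage."""

    metric: str
    value: float
    n_evaluable: int
    n_total: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_evaluable > self.n_total:
            raise ValueError("evaluable pairs cannot exceed total pairs")


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two vectors: 1 when identical in
    direction, 0 when orthogonal, -1 when antiparallel."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(v1 @ v2 / (n1 * n2))


def _embedded_members(
    emb: EmbeddingMatrix, categories: SemanticTypeMap
) -> dict[str, np.ndarray]:
    """Category label -> array of embedding row indices with nonzero rows."""
    members: dict[str, list[int]] = {}
    norms = np.linalg.norm(emb.vectors, axis=1)
    for cui, label in categories.categories.items():
        idx = emb.vocab.get(cui)
        if idx is not None and norms[idx] > 0:
            members.setdefault(label, []).append(idx)
    return {lab: np.asarray(ix) for lab, ix in members.items()}


def _draw_pairs(
    rng: np.random.Generator,
    pool_x: np.ndarray,
    pool_y: np.ndarray,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """n draws of (x*, y*) with replacement, redrawing until x* != y*."""
    xs = rng.choice(pool_x, size=n)
    ys = rng.choice(pool_y, size=n)
    clash = xs == ys
    while np.any(clash):
        k = int(clash.sum())
        xs[clash] = rng.choice(pool_x, size=k)
        ys[clash] = rng.choice(pool_y, size=k)
        clash = xs == ys
    return xs, ys


def bootstrap_null(
    emb: EmbeddingMatrix,
    categories: SemanticTypeMap,
    cat_x: str,
    cat_y: str,
    n: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
    mode: str = "matched",
) -> NullDistribution:
    """Bootstrap null distribution of cosines for one category pair.

    ``mode="matched"`` draws x* from *cat_x* and y* from *cat_y*
    (the category-matched null); ``mode="marginal"`` ignores the two
    labels and draws the two concepts from two different, randomly chosen
    categories (the semantic-type benchmark's null).  The two drawn
    concepts are always distinct.
    """
    members = _embedded_members(emb, categories)
    unit = emb.unit_vectors()
    rng = np.random.default_rng(seed)
    if mode == "matched":
        for lab in (cat_x, cat_y):
            if len(members.get(lab, ())) < 2:
                raise ValueError(
                    f"category {lab!r} has fewer than 2 embedded concepts: "
                    "degenerate null"
                )
        xs, ys = _draw_pairs(rng, members[cat_x], members[cat_y], n)
    elif mode == "marginal":
        labels = [lab for lab, ix in members.items() if len(ix) >= 1]
        if len(labels) < 2:
            raise ValueError("marginal null needs at least 2 embedded categories")
        lab_x = rng.choice(labels, size=n)
        lab_y = rng.choice(labels, size=n)
        clash = lab_x == lab_y
        while np.any(clash):
            lab_y[clash] = rng.choice(labels, size=int(clash.sum()))
            clash = lab_x == lab_y
        xs = np.array([rng.choice(members[lab]) for lab in lab_x])
        ys = np.array([rng.choice(members[lab]) for lab in lab_y])
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    samples = np.einsum("ij,ij->i", unit[xs], unit[ys])
    return NullDistribution(
        samples=samples, category_pair=(cat_x, cat_y), seed=seed
    )


def _pair_seed(seed: int, cat_x: str, cat_y: str, mode: str) -> int:
    """Stable per-category-pair child seed (< 2**31)."""
    a, b = sorted((cat_x, cat_y))
    return (seed * 2654435761 + crc32(f"{mode}|{a}|{b}".encode())) % (2**31)


def relationship_power(
    emb: EmbeddingMatrix,
    rels: RelationshipSet,
    categories: SemanticTypeMap,
    n: int = DEFAULT_N_BOOTSTRAP,
    level: float = 0.05,
    seed: int = 0,
    null_mode: str = "matched",
) -> BenchmarkResult:
    """Statistical power of an embedding on a set of known relationships.

    Each evaluable pair (both concepts embedded and categorized) is tested
    against the cached bootstrap null for its category pair; it is
    discovered when its cosine strictly exceeds the null's (1 - level)
    quantile.  Power is discovered / evaluable.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    unit = emb.unit_vectors()
    nulls: dict[tuple[str, str], NullDistribution] = {}
    n_eval = 0
    discovered = 0
    for x, y, _rel in rels.pairs:
        ix, iy = emb.vocab.get(x), emb.vocab.get(y)
        cx, cy = categories.get(x), categories.get(y)
        if ix is None or iy is None or cx is None or cy is None:
            continue
        if not (np.any(unit[ix]) and np.any(unit[iy])):
            continue
        key = tuple(sorted((cx, cy)))
        if key not in nulls:
            nulls[key] = bootstrap_null(
                emb, categories, key[0], key[1], n=n,
                seed=_pair_seed(seed, cx, cy, null_mode), mode=null_mode,
            )
        n_eval += 1
        if float(unit[ix] @ unit[iy]) > nulls[key].threshold(level):
            discovered += 1
    if n_eval == 0:
        raise ValueError(f"benchmark {rels.name!r} has no evaluable pairs")
    return BenchmarkResult(
        metric="power",
        value=discovered / n_eval,
        n_evaluable=n_eval,
        n_total=len(rels),
        name=rels.name,
    )


def human_similarity_correlation(
    emb: EmbeddingMatrix, human: HumanSimilaritySet
) -> BenchmarkResult:
    """Spearman correlation between human scores and embedding cosines.

    Ties receive average ranks.  All human scores being tied makes the
    ranking degenerate and raises.
    """
    scores, cosines = [], []
    for x, y, s in human.pairs:
        if x in emb and y in emb:
            vx, vy = emb.vector(x), emb.vector(y)
            if np.any(vx) and np.any(vy):
                scores.append(s)
                cosines.append(cosine_similarity(vx, vy))
    if len(scores) < 3:
        raise ValueError(
            f"only {len(scores)} evaluable pairs; need at least 3 for a "
            "rank correlation"
        )
    if len(set(scores)) == 1:
        raise ValueError("all human scores are tied: rank correlation undefined")
    rho = stats.spearmanr(scores, cosines).statistic
    return BenchmarkResult(
        metric="spearman_rho",
        value=float(rho),
        n_evaluable=len(scores),
        n_total=len(human),
        name="human_similarity",
    )
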