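"""Cosine similarity, bootstrap nulls, statistical power, human correlation."""

import numpy as np
import pytest

from medembed import (
    EmbeddingMatrix,
    HumanSimilaritySet,
    RelationshipSet,
    SemanticTypeMap,
    Vocabulary,
    bootstrap_null,
    cosine_similarity,
    human_similarity_correlation,
    relationship_power,
)


def isotropic_embedding(n: int, d: int, seed: int) -> EmbeddingMatrix:
    rng = np.random.default_rng(seed)
    vocab = Vocabulary(tuple(f"C{i:05d}" for i in range(n)))
    return EmbeddingMatrix(vectors=rng.standard_normal((n, d)), vocab=vocab)


def four_categories(vocab: Vocabulary) -> SemanticTypeMap:
    return SemanticTypeMap(
        categories={c: f"cat_{i % 4}" for i, c in enumerate(vocab.cuis)}
    )


def random_within_category_pairs(
    types: SemanticTypeMap, n_pairs: int, seed: int
) -> RelationshipSet:
    rng = np.random.default_rng(seed)
    members = {lab: np.array(types.members(lab)) for lab in types.labels}
    labels = sorted(members)
    pairs = set()
    while len(pairs) < n_pairs:
        lab = labels[rng.integers(len(labels))]
        x, y = rng.choice(members[lab], size=2, replace=False)
        pairs.add((str(min(x, y)), str(max(x, y))))
    return RelationshipSet.from_pairs(sorted(pairs), name="random_pairs")


class TestCosine:
    def test_identical_vectors_give_one(self):
        v = np.arange(1.0, 6.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors_give_zero(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0

    def test_antiparallel_vectors_give_minus_one(self):
        assert cosine_similarity(
            np.array([1.0, 0.0]), np.array([-1.0, 0.0])
        ) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.ones(3), np.ones(4))


class TestBootstrapNull:
    def test_sample_count_and_range(self):
        emb = isotropic_embedding(40, 8, seed=0)
        types = four_categories(emb.vocab)
        null = bootstrap_null(emb, types, "cat_0", "cat_1", n=10_000, seed=1)
        assert null.n == 10_000
        assert np.all(np.abs(null.samples) <= 1.0 + 1e-12)

    def test_same_seed_reproduces_samples(self):
        emb = isotropic_embedding(40, 8, seed=0)
        types = four_categories(emb.vocab)
        a = bootstrap_null(emb, types, "cat_0", "cat_0", n=500, seed=7)
        b = bootstrap_null(emb, types, "cat_0", "cat_0", n=500, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_identical_vectors_make_threshold_one(self):
        vocab = Vocabulary(tuple(f"C{i}" for i in range(10)))
        emb = EmbeddingMatrix(vectors=np.tile([1.0, 2.0], (10, 1)), vocab=vocab)
        types = SemanticTypeMap(categories={c: "only" for c in vocab.cuis})
        null = bootstrap_null(emb, types, "only", "only", n=200, seed=0)
        assert np.allclose(null.samples, 1.0)
        assert null.threshold(0.05) == pytest.approx(1.0)

    def test_drawn_concepts_are_distinct(self):
        emb = isotropic_embedding(8, 4, seed=2)
        types = SemanticTypeMap(categories={c: "only" for c in emb.vocab.cuis})
        null = bootstrap_null(emb, types, "only", "only", n=2000, seed=3)
        # identical draws would put exact 1.0 cosines in the samples
        assert not np.any(np.isclose(null.samples, 1.0, atol=1e-12))

    def test_degenerate_category_rejected(self):
        emb = isotropic_embedding(5, 4, seed=0)
        types = SemanticTypeMap(
            categories={**{c: "big" for c in emb.vocab.cuis[:4]},
                        emb.vocab.cuis[4]: "tiny"}
        )
        with pytest.raises(ValueError, match="degenerate"):
            bootstrap_null(emb, types, "tiny", "big", n=100, seed=0)

    def test_marginal_mode_crosses_categories(self):
        emb = isotropic_embedding(40, 8, seed=4)
        types = four_categories(emb.vocab)
        null = bootstrap_null(
            emb, types, "cat_0", "cat_0", n=300, seed=5, mode="marginal"
        )
        assert null.n == 300

    def test_quantile_convention(self):
        from medembed.benchmark import NullDistribution

        null = NullDistribution(
            samples=np.linspace(-1, 1, 100), category_pair=("a", "b"), seed=0
        )
        # ceiling(0.95 * 100) = 95th order statistic of 100 sorted values
        assert null.threshold(0.05) == np.sort(null.samples)[94]


class TestRelationshipPower:
    def test_duplicated_vectors_are_discovered(self):
        """Pairs that share an identical vector have cosine 1, far above a
        random-direction null at d=50."""
        rng = np.random.default_rng(6)
        n, d = 200, 50
        vectors = rng.standard_normal((n, d))
        vocab = Vocabulary(tuple(f"C{i:04d}" for i in range(n)))
        pairs = [(f"C{2*i:04d}", f"C{2*i+1:04d}") for i in range(30)]
        for x, y in pairs:
            vectors[vocab.index(y)] = vectors[vocab.index(x)]
        emb = EmbeddingMatrix(vectors=vectors, vocab=vocab)
        types = SemanticTypeMap(categories={c: "all" for c in vocab.cuis})
        result = relationship_power(
            emb, RelationshipSet.from_pairs(pairs), types, n=2000, seed=7
        )
        assert result.value >= 0.9
        assert result.n_evaluable == 30

    def test_power_monotone_in_planted_effect_size(self):
        """Mixing related vectors toward each other raises power."""
        rng = np.random.default_rng(8)
        n, d = 200, 50
        base = rng.standard_normal((n, d))
        vocab = Vocabulary(tuple(f"C{i:04d}" for i in range(n)))
        types = SemanticTypeMap(categories={c: "all" for c in vocab.cuis})
        pairs = [(f"C{2*i:04d}", f"C{2*i+1:04d}") for i in range(40)]
        powers = {}
        for lam in (0.0, 0.4, 0.8):
            vectors = base.copy()
            for x, y in pairs:
                ix, iy = vocab.index(x), vocab.index(y)
                mean = 0.5 * (base[ix] + base[iy])
                vectors[ix] = (1 - lam) * base[ix] + lam * mean
                vectors[iy] = (1 - lam) * base[iy] + lam * mean
            emb = EmbeddingMatrix(vectors=vectors, vocab=vocab)
            powers[lam] = relationship_power(
                emb, RelationshipSet.from_pairs(pairs), types, n=4000, seed=9
            ).value
        assert powers[0.8] >= powers[0.4] >= powers[0.0]

    def test_pairs_with_missing_concepts_are_excluded(self):
        emb = isotropic_embedding(40, 8, seed=10)
        types = four_categories(emb.vocab)
        rels = RelationshipSet.from_pairs(
            [("C00000", "C00004"), ("C00000", "C99999")]
        )
        result = relationship_power(emb, rels, types, n=500, seed=0)
        assert result.n_evaluable == 1 and result.n_total == 2

    def test_no_evaluable_pairs_rejected(self):
        emb = isotropic_embedding(10, 4, seed=0)
        types = four_categories(emb.vocab)
        rels = RelationshipSet.from_pairs([("C99998", "C99999")])
        with pytest.raises(ValueError, match="evaluable"):
            relationship_power(emb, rels, types, n=100, seed=0)

    def test_empty_relationship_set_rejected(self):
        emb = isotropic_embedding(10, 4, seed=0)
        with pytest.raises(ValueError):
            relationship_power(
                emb, RelationshipSet(pairs=(), name="empty"),
                four_categories(emb.vocab), n=100, seed=0,
            )

    def test_power_reproducible_given_seed(self):
        emb = isotropic_embedding(60, 10, seed=11)
        types = four_categories(emb.vocab)
        rels = random_within_category_pairs(types, 50, seed=12)
        a = relationship_power(emb, rels, types, n=1000, seed=13).value
        b = relationship_power(emb, rels, types, n=1000, seed=13).value
        assert a == b and 0.0 <= a <= 1.0


class TestHumanCorrelation:
    def _embedding_and_pairs(self):
        rng = np.random.default_rng(14)
        emb = isotropic_embedding(30, 10, seed=14)
        pairs = [(f"C{2*i:05d}", f"C{2*i+1:05d}") for i in range(12)]
        cosines = [
            cosine_similarity(emb.vector(x), emb.vector(y)) for x, y in pairs
        ]
        return emb, pairs, cosines

    def test_monotone_transform_of_cosines_gives_rho_one(self):
        emb, pairs, cosines = self._embedding_and_pairs()
        human = HumanSimilaritySet(
            pairs=tuple(
                (x, y, float(np.exp(3 * c))) for (x, y), c in zip(pairs, cosines)
            )
        )
        result = human_similarity_correlation(emb, human)
        assert result.value == pytest.approx(1.0)

    def test_negated_scores_give_rho_minus_one(self):
        emb, pairs, cosines = self._embedding_and_pairs()
        human = HumanSimilaritySet(
            pairs=tuple((x, y, -c) for (x, y), c in zip(pairs, cosines))
        )
        assert human_similarity_correlation(emb, human).value == pytest.approx(-1.0)

    def test_all_tied_scores_rejected(self):
        emb, pairs, _ = self._embedding_and_pairs()
        human = HumanSimilaritySet(pairs=tuple((x, y, 1.0) for x, y in pairs))
        with pytest.raises(ValueError, match="tied"):
            human_similarity_correlation(emb, human)

    def test_too_few_evaluable_pairs_rejected(self):
        emb, pairs, _ = self._embedding_and_pairs()
        human = HumanSimilaritySet(
            pairs=(("C99990", "C99991", 1.0), (pairs[0][0], pairs[0][1], 2.0))
        )
        with pytest.raises(ValueError):
            human_similarity_correlation(emb, human)
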