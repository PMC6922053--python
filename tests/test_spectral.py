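"""PMI/SPPMI transformation and SVD factorization."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from medembed import (
    CooccurrenceMatrix,
    RawCountSVD,
    SPPMIParams,
    SPPMISVD,
    SyntheticSpec,
    Vocabulary,
    count_text_cooccurrences,
    pca_embeddings,
    pmi_matrix,
    sppmi_transform,
    svd_embeddings,
)
from tests.conftest import random_symmetric_counts, run_text_pipeline, windows_of


def brute_force_pmi(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Independent dense PMI oracle: explicit loops, no sparse machinery.

    Joint probabilities over unordered pairs, margins over pair
    participations, margin smoothing by exponent alpha with
    renormalization; NaN where the count is zero.
    """
    n = counts.shape[0]
    grand = counts.sum()
    total_pairs = grand / 2.0
    margins = np.array([counts[i, :].sum() / grand for i in range(n)])
    smoothed = margins**alpha
    smoothed = smoothed / smoothed.sum()
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if counts[i, j] > 0:
                p_ij = counts[i, j] / total_pairs
                out[i, j] = np.log(p_ij / (smoothed[i] * smoothed[j]))
    return out


class TestPMI:
    def test_worked_window_example(self, toy_vocab):
        counts = count_text_cooccurrences(
            windows_of(("C1", "C2"), ("C1", "C2"), ("C1", "C3")), toy_vocab
        )
        pmi = pmi_matrix(counts, alpha=1.0)
        assert pmi[0, 1] == pytest.approx(np.log(4), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_uniform_matrix_closed_form(self, n):
        # all off-diagonal cells equal: every margin is 1/n, every joint is
        # 1/C(n,2), so PMI = log(2n/(n-1)) on every nonzero cell
        vocab = Vocabulary(tuple(f"C{i}" for i in range(n)))
        dense = 3 * (np.ones((n, n), dtype=np.int64) - np.eye(n, dtype=np.int64))
        counts = CooccurrenceMatrix(counts=sp.csr_matrix(dense), vocab=vocab)
        pmi = pmi_matrix(counts, alpha=1.0).toarray()
        expected = np.log(2 * n / (n - 1))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(pmi[off], expected, atol=1e-12)

    def test_alpha_one_equals_unsmoothed_definition(self):
        rng = np.random.default_rng(3)
        m = random_symmetric_counts(rng, 8)
        smoothed = pmi_matrix(m, alpha=1.0).toarray()
        dense = m.toarray().astype(float)
        grand = dense.sum()
        margins = dense.sum(axis=1) / grand
        nz = dense > 0
        ratio = (dense[nz] / (grand / 2)) / np.outer(margins, margins)[nz]
        assert np.allclose(smoothed[nz], np.log(ratio), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_symmetric_counts(rng, 12)
            alpha = rng.uniform(0.3, 1.0)
            got = pmi_matrix(m, alpha=alpha).toarray()
            want = brute_force_pmi(m.toarray().astype(float), alpha)
            nz = m.toarray() > 0
            assert np.max(np.abs(got[nz] - want[nz])) < 1e-10

    def test_joint_probabilities_sum_to_one(self):
        rng = np.random.default_rng(7)
        m = random_symmetric_counts(rng, 10)
        dense = m.toarray()
        assert dense[np.triu_indices(10, 1)].sum() == m.total_pairs

    def test_empty_matrix_rejected(self, toy_vocab):
        empty = CooccurrenceMatrix(
            counts=sp.csr_matrix((3, 3), dtype=np.int64), vocab=toy_vocab
        )
        with pytest.raises(ValueError):
            pmi_matrix(empty)


class TestSPPMI:
    def test_k_one_means_no_shift(self):
        pmi = sp.csr_matrix(np.array([[0.0, 1.5], [1.5, 0.0]]))
        out = sppmi_transform(pmi, k=1.0)
        assert out[0, 1] == pytest.approx(1.5)

    def test_negative_pmi_clipped_to_zero(self):
        pmi = sp.csr_matrix(np.array([[0.0, -0.3], [-0.3, 0.0]]))
        out = sppmi_transform(pmi, k=1.0)
        assert out.nnz == 0

    def test_shift_by_log_k(self):
        pmi = sp.csr_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        out = sppmi_transform(pmi, k=np.e)
        assert out[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            sppmi_transform(sp.csr_matrix((2, 2)), k=0.5)
        with pytest.raises(ValueError):
            SPPMIParams(k=0.9)
        with pytest.raises(ValueError):
            SPPMIParams(alpha=0.0)

    @given(k1=st.floats(1.0, 20.0), k2=st.floats(1.0, 20.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_k(self, k1, k2):
        lo, hi = sorted((k1, k2))
        rng = np.random.default_rng(5)
        m = random_symmetric_counts(rng, 8)
        pmi = pmi_matrix(m)
        a = sppmi_transform(pmi, k=lo).toarray()
        b = sppmi_transform(pmi, k=hi).toarray()
        assert np.all(b <= a + 1e-12)


class TestSVDEmbeddings:
    def test_full_rank_reconstruction_with_symmetric_scaling(self):
        rng = np.random.default_rng(1)
        m = random_symmetric_counts(rng, 30)
        model = SPPMISVD(m)
        res = model.fit(d=30, sigma_power=0.5, seed=0)
        err = np.abs(res.reconstruction() - model.sppmi.toarray()).max()
        assert err < 1e-8

    def test_diagonal_matrix_singular_values(self):
        from medembed.spectral import SPPMIMatrix

        vocab = Vocabulary(("C1", "C2"))
        sm = SPPMIMatrix(
            values=sp.csr_matrix(np.diag([4.0, 1.0])), vocab=vocab,
            params=SPPMIParams(),
        )
        fact, emb = svd_embeddings(sm, d=2)
        assert np.allclose(fact.Sigma_d, [4.0, 1.0])

    def test_embedding_shape_contract(self):
        rng = np.random.default_rng(2)
        m = random_symmetric_counts(rng, 12)
        for d in (1, 5, 12):
            res = SPPMISVD(m).fit(d=d)
            assert res.embedding.vectors.shape == (12, d)

    def test_invalid_rank_rejected(self):
        rng = np.random.default_rng(2)
        m = random_symmetric_counts(rng, 6)
        with pytest.raises(ValueError):
            SPPMISVD(m).fit(d=0)
        with pytest.raises(ValueError):
            SPPMISVD(m).fit(d=7)

    def test_reconstruction_error_nonincreasing_in_rank(self):
        rng = np.random.default_rng(9)
        m = random_symmetric_counts(rng, 20)
        model = SPPMISVD(m)
        target = model.sppmi.toarray()
        errs = [
            np.linalg.norm(model.fit(d=d).reconstruction() - target)
            for d in (2, 5, 10, 20)
        ]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        m = random_symmetric_counts(rng, 15)
        a = SPPMISVD(m).fit(d=6, seed=3).embedding.vectors
        b = SPPMISVD(m).fit(d=6, seed=3).embedding.vectors
        assert np.array_equal(a, b)

    def test_cluster_recovery_on_synthetic_corpus(self):
        """Planted topical clusters separate: within-cluster cosines exceed
        between-cluster cosines on average."""
        spec = SyntheticSpec(
            n_concepts=40, n_clusters=2, n_documents=300, doc_length=80,
            n_planted_pairs=0, topic_strength=0.7, seed=21,
        )
        emb, types, _ = run_text_pipeline(spec, d=10)
        unit = emb.unit_vectors()
        labels = np.array(
            [types[cui] for cui in emb.vocab.cuis]
        )
        sims = unit @ unit.T
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        within = sims[same & off_diag].mean()
        between = sims[~same].mean()
        assert within > between


class TestPCABaseline:
    def test_rank_one_matrix_reconstructed_exactly(self):
        vocab = Vocabulary(("C1", "C2"))
        counts = CooccurrenceMatrix(
            counts=sp.csr_matrix(np.array([[0, 3], [3, 0]])), vocab=vocab
        )
        res = RawCountSVD(counts).fit(d=2)
        rec = res.factorization.word_vectors @ res.factorization.V_d.T
        assert np.abs(rec - counts.toarray()).max() < 1e-10

    def test_diagonal_counts_give_sorted_singular_values(self):
        # an off-diagonal permutation-like matrix has singular values
        # equal to the moved entries, sorted
        vocab = Vocabulary(("C1", "C2", "C3", "C4"))
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 5
        dense[2, 3] = dense[3, 2] = 2
        counts = CooccurrenceMatrix(counts=sp.csr_matrix(dense), vocab=vocab)
        res = RawCountSVD(counts).fit(d=4)
        assert np.allclose(res.singular_values, [5, 5, 2, 2])

    def test_rank_zero_rejected(self):
        rng = np.random.default_rng(2)
        m = random_symmetric_counts(rng, 5)
        with pytest.raises(ValueError):
            pca_embeddings(m, d=0)

    def test_summary_mentions_dimension(self):
        rng = np.random.default_rng(2)
        m = random_symmetric_counts(rng, 8)
        text = RawCountSVD(m).fit(d=3).summary()
        assert "embedding dimension: 3" in text
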