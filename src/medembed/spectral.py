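"""Spectral embeddings: smoothed PMI, SPPMI, and truncated-SVD factorization.

Pointwise mutual information measures how much more often two concepts
co-occur than independence predicts,

    PMI(w, c) = log[ p(w, c) / (p(w)^a p(c)^a) ],

with the joint p(w, c) taken as the pair's count over the total number of
unordered co-occurrence pairs, and the margins p(w) as each concept's pair
participation over the grand total.  Margin smoothing raises both margins
to the exponent ``alpha`` (default 0.75) and renormalizes them to sum to
one; because the co-occurrence matrix is symmetric the word and context
margins coincide and both are smoothed.  Natural logarithms throughout.

Shifting the PMI down by log(k) and clipping at zero gives the shifted
positive PMI (SPPMI) matrix,

    SPPMI(w, c) = max(PMI(w, c) - log k, 0),

whose truncated SVD recovers the implicit objective of skip-gram with
negative sampling with k negative samples.  With the default k = 1 there
is no shift.  Rank-d factors U_d, S_d, V_d give word vectors
W~ = U_d S_d^p, context vectors C~ = V_d S_d^p and the final embedding
W = W~ + C~ (the symmetrically scaled sum, p = 0.5 by default; p = 1
reproduces the plain U_d S_d reading).

A raw-SVD baseline ("PCA") factors the count matrix directly and embeds
each concept as U_d S_d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cooccur import CooccurrenceMatrix, Vocabulary

__all__ = [
    "SPPMIParams",
    "SPPMIMatrix",
    "SVDFactorization",
    "EmbeddingMatrix",
    "SPPMISVD",
    "RawCountSVD",
    "SpectralEmbeddingResults",
    "pmi_matrix",
    "sppmi_transform",
    "svd_embeddings",
    "pca_embeddings",
]

# Dense SVD below this dimension: exact, and faster than iterating.
_DENSE_CUTOFF = 400


@dataclass(frozen=True)
class SPPMIParams:
    """Smoothing exponent and shift for the SPPMI transformation."""

    alpha: float = 0.75
    k: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.k < 1.0:
            raise ValueError(f"shift k must be >= 1, got {self.k}")


@dataclass
class SPPMIMatrix:
    """Sparse symmetric nonnegative SPPMI values over a vocabulary."""

    values: sp.csr_matrix
    vocab: Vocabulary
    params: SPPMIParams

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("SPPMI values must be nonnegative")

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


@dataclass(frozen=True)
class SVDFactorization:
    """Truncated rank-d SVD factors and the derived embedding blocks."""

    U_d: np.ndarray
    Sigma_d: np.ndarray
    V_d: np.ndarray
    sigma_power: float

    def __post_init__(self) -> None:
        if np.any(self.Sigma_d < -1e-12) or np.any(np.diff(self.Sigma_d) > 1e-10):
            raise ValueError("singular values must be nonnegative and nonincreasing")

    @property
    def word_vectors(self) -> np.ndarray:
        """W~ = U_d Sigma_d^p."""
        return self.U_d * self.Sigma_d**self.sigma_power

    @property
    def context_vectors(self) -> np.ndarray:
        """C~ = V_d Sigma_d^p."""
        return self.V_d * self.Sigma_d**self.sigma_power

    @property
    def embedding(self) -> np.ndarray:
        """W = W~ + C~, the symmetrically scaled sum."""
        return self.word_vectors + self.context_vectors


@dataclass
class EmbeddingMatrix:
    """A |V| x d real embedding with its vocabulary."""

    vectors: np.ndarray
    vocab: Vocabulary

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocab):
            raise ValueError(
                f"embedding shape {self.vectors.shape} does not match "
                f"|V|={len(self.vocab)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, cui: str) -> bool:
        return cui in self.vocab

    def vector(self, cui: str) -> np.ndarray:
        return self.vectors[self.vocab.index(cui)]

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy (zero rows are left as zeros)."""
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return self.vectors / norms


def pmi_matrix(counts: CooccurrenceMatrix, alpha: float = 0.75) -> sp.csr_matrix:
    """Smoothed PMI on the nonzero cells of a co-occurrence matrix.

    Margins are raised to *alpha* and renormalized before entering the
    denominator; PMI is only defined (and stored) on nonzero cells.
    Returns a symmetric sparse matrix that may hold negative values.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    coo = counts.counts.tocoo()
    if coo.nnz == 0:
        raise ValueError("co-occurrence matrix has no nonzero cells")
    grand = coo.data.sum()  # = 2 x total unordered pairs
    joint = coo.data / (grand / 2.0)
    margins = np.asarray(counts.counts.sum(axis=1)).ravel() / grand
    assert abs(joint.sum() - 2.0) < 1e-9  # both triangles stored
    smoothed = margins**alpha
    smoothed /= smoothed.sum()
    pmi = np.log(joint) - np.log(smoothed[coo.row]) - np.log(smoothed[coo.col])
    return sp.csr_matrix((pmi, (coo.row, coo.col)), shape=coo.shape)


def sppmi_transform(
    pmi: sp.spmatrix, k: float = 1.0, vocab: Vocabulary | None = None,
    params: SPPMIParams | None = None,
) -> SPPMIMatrix | sp.csr_matrix:
    """Shift PMI down by log(k) and clip at zero; zero cells are dropped.

    If *vocab* is given, the result is wrapped in an :class:`SPPMIMatrix`.
    """
    if k < 1.0:
        raise ValueError(f"shift k must be >= 1, got {k}")
    coo = sp.coo_matrix(pmi)
    shifted = np.maximum(coo.data - np.log(k), 0.0)
    out = sp.csr_matrix((shifted, (coo.row, coo.col)), shape=coo.shape)
    out.eliminate_zeros()
    if vocab is None:
        return out
    return SPPMIMatrix(
        values=out, vocab=vocab, params=params or SPPMIParams(k=k)
    )


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign ambiguity: largest-|.| entry of each U column > 0."""
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def _truncated_svd(
    matrix: sp.spmatrix, d: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-d SVD, descending singular values, deterministic given *seed*.

    Small or nearly full-rank problems use an exact dense SVD; larger ones
    a Lanczos-style sparse solver with a seeded starting vector.
    """
    n, m = matrix.shape
    if d < 1 or d > min(n, m):
        raise ValueError(f"rank d={d} outside 1..{min(n, m)}")
    if min(n, m) <= _DENSE_CUTOFF or d >= min(n, m) - 1:
        U, s, Vt = np.linalg.svd(np.asarray(matrix.todense()), full_matrices=False)
        U, s, V = U[:, :d], s[:d], Vt[:d].T
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n, m))
        U, s, Vt = spla.svds(matrix.astype(np.float64), k=d, v0=v0, tol=1e-8)
        order = np.argsort(s)[::-1]
        U, s, V = U[:, order], s[order], Vt[order].T
    U, V = _fix_signs(U, V)
    return U, s, V


@dataclass
class SpectralEmbeddingResults:
    """Fit results for an SVD-based embedding model.

    Carries the truncated factors, the final embedding, and the spectrum;
    ``summary()`` renders a short fit report.
    """

    model: object
    factorization: SVDFactorization
    embedding: EmbeddingMatrix
    seed: int | None = None

    @property
    def singular_values(self) -> np.ndarray:
        return self.factorization.Sigma_d

    def explained_energy(self) -> np.ndarray:
        """Cumulative share of captured spectral energy (sum of sigma^2)."""
        s2 = self.singular_values**2
        return np.cumsum(s2) / s2.sum()

    def reconstruction(self) -> np.ndarray:
        """W~ C~^T, the rank-d reconstruction of the factorized matrix."""
        f = self.factorization
        return f.word_vectors @ f.context_vectors.T

    def summary(self) -> str:
        f = self.factorization
        n, d = self.embedding.vectors.shape
        lines = [
            f"{type(self.model).__name__} fit",
            "=" * 40,
            f"concepts:            {n}",
            f"embedding dimension: {d}",
            f"sigma power:         {f.sigma_power}",
            f"top singular value:  {f.Sigma_d[0]:.6g}",
            f"smallest kept:       {f.Sigma_d[-1]:.6g}",
            f"energy captured:     {self.explained_energy()[-1]:.4f} "
            "(of kept spectrum)",
        ]
        return "\n".join(lines)


class SPPMISVD:
    """Word2vec-style embedding model: SPPMI matrix factorized by SVD.

    Built either from raw co-occurrence counts (the PMI/SPPMI transform is
    applied with *params*) or from a precomputed :class:`SPPMIMatrix`.

    Parameters
    ----------
    data
        A :class:`CooccurrenceMatrix` or an :class:`SPPMIMatrix`.
    params
        Smoothing exponent alpha and shift k (ignored when *data* is
        already an SPPMI matrix).
    """

    def __init__(
        self,
        data: CooccurrenceMatrix | SPPMIMatrix,
        params: SPPMIParams | None = None,
    ):
        self.params = params or SPPMIParams()
        if isinstance(data, SPPMIMatrix):
            self.sppmi = data
            self.params = data.params
        elif isinstance(data, CooccurrenceMatrix):
            pmi = pmi_matrix(data, alpha=self.params.alpha)
            self.sppmi = sppmi_transform(
                pmi, k=self.params.k, vocab=data.vocab, params=self.params
            )
        else:
            raise TypeError(f"cannot build SPPMISVD from {type(data).__name__}")
        self.vocab = self.sppmi.vocab

    def fit(
        self, d: int = 500, sigma_power: float = 0.5, seed: int | None = 0
    ) -> SpectralEmbeddingResults:
        """Factorize the SPPMI matrix at rank *d*.

        *sigma_power* is the exponent applied to the singular values when
        forming the word and context blocks (0.5 = symmetric scaling).
        """
        U, s, V = _truncated_svd(self.sppmi.values, d, seed)
        fact = SVDFactorization(U_d=U, Sigma_d=s, V_d=V, sigma_power=sigma_power)
        emb = EmbeddingMatrix(vectors=fact.embedding, vocab=self.vocab)
        return SpectralEmbeddingResults(
            model=self, factorization=fact, embedding=emb, seed=seed
        )


class RawCountSVD:
    """PCA-style baseline: truncated SVD of the raw count matrix.

    The embedding is U_d Sigma_d (no context-vector sum)."""

    def __init__(self, counts: CooccurrenceMatrix):
        self.counts = counts
        self.vocab = counts.vocab

    def fit(self, d: int, seed: int | None = 0) -> SpectralEmbeddingResults:
        U, s, V = _truncated_svd(
            self.counts.counts.astype(np.float64), d, seed
        )
        fact = SVDFactorization(U_d=U, Sigma_d=s, V_d=V, sigma_power=1.0)
        emb = EmbeddingMatrix(vectors=fact.word_vectors, vocab=self.vocab)
        return SpectralEmbeddingResults(
            model=self, factorization=fact, embedding=emb, seed=seed
        )


def svd_embeddings(
    sppmi: SPPMIMatrix, d: int, sigma_power: float = 0.5, seed: int | None = 0
) -> tuple[SVDFactorization, EmbeddingMatrix]:
    """Functional form of :meth:`SPPMISVD.fit` on a precomputed SPPMI matrix."""
    res = SPPMISVD(sppmi).fit(d=d, sigma_power=sigma_power, seed=seed)
    return res.factorization, res.embedding


def pca_embeddings(
    counts: CooccurrenceMatrix, d: int, seed: int | None = 0
) -> EmbeddingMatrix:
    """Functional form of :meth:`RawCountSVD.fit`."""
    return RawCountSVD(counts).fit(d=d, seed=seed).embedding
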