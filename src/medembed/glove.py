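"""GloVe-style embeddings by weighted least squares on log co-occurrence.

For every nonzero co-occurrence cell (w, c) with count y the model fits

    f(y) * (w.c + b_w + b_c - log y)^2,

summed over all nonzero cells, where f caps the influence of very
frequent pairs:

    f(y) = (y / y_max)^alpha   for y < y_max,   1 otherwise.

Training is stochastic: nonzero cells are visited in shuffled order and
parameters updated with per-coordinate adaptive (AdaGrad-style) steps,
the standard optimizer for this objective.  On a symmetric matrix each
unordered pair is stored once and visited once per epoch with both
orientations updated, which matches the full both-triangles sum without
double counting.  The final embedding for a concept is the sum of its
word and context vectors.  Runs are bit-reproducible given a seed
(single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .cooccur import CooccurrenceMatrix
from .spectral import EmbeddingMatrix

__all__ = [
    "GloVeParams",
    "GloVe",
    "GloVeResults",
    "glove_weight",
    "glove_loss",
    "train_glove",
]


@dataclass(frozen=True)
class GloVeParams:
    """Training hyperparameters for the weighted least-squares objective."""

    d: int = 100
    y_max: float = 100.0
    alpha_w: float = 0.75
    epochs: int = 25
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.y_max <= 0:
            raise ValueError("y_max must be positive")
        if not 0.0 < self.alpha_w <= 1.0:
            raise ValueError("weighting exponent must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def glove_weight(y, y_max: float = 100.0, alpha_w: float = 0.75):
    """Weighting function f(y): (y/y_max)^alpha below the cap, else 1."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y <= 0):
        raise ValueError("weights are defined only for positive counts")
    return np.where(y < y_max, (y / y_max) ** alpha_w, 1.0)


@dataclass
class GloVeState:
    """Model parameters: word/context vectors and biases."""

    word_vectors: np.ndarray
    context_vectors: np.ndarray
    word_biases: np.ndarray
    context_biases: np.ndarray

    def embedding(self) -> np.ndarray:
        return self.word_vectors + self.context_vectors


def _as_cells(counts) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Nonzero cells (rows, cols, values) of a count matrix, both triangles."""
    mat = counts.counts if isinstance(counts, CooccurrenceMatrix) else counts
    coo = sp.coo_matrix(mat)
    if coo.nnz == 0:
        raise ValueError("count matrix has no nonzero cells: nothing to train on")
    return coo.row, coo.col, coo.data.astype(np.float64), coo.shape[0]


def glove_loss(state: GloVeState, counts, params: GloVeParams) -> float:
    """Weighted least-squares objective over all nonzero cells."""
    rows, cols, vals, n = _as_cells(counts)
    if state.word_vectors.shape[0] != n:
        raise ValueError(
            f"model has {state.word_vectors.shape[0]} rows, matrix has {n}"
        )
    pred = (
        np.einsum(
            "ij,ij->i", state.word_vectors[rows], state.context_vectors[cols]
        )
        + state.word_biases[rows]
        + state.context_biases[cols]
    )
    resid = pred - np.log(vals)
    return float(np.sum(glove_weight(vals, params.y_max, params.alpha_w) * resid**2))


class GloVe:
    """GloVe model over a co-occurrence matrix.

    Accepts a :class:`CooccurrenceMatrix` or any scipy sparse nonnegative
    count matrix.  ``fit()`` runs seeded AdaGrad over shuffled nonzero
    cells and returns a :class:`GloVeResults`.
    """

    def __init__(self, counts, params: GloVeParams | None = None):
        self.counts = counts
        self.params = params or GloVeParams()
        self.vocab = getattr(counts, "vocab", None)
        rows, cols, vals, self.n = _as_cells(counts)
        # keep each unordered pair once; diagonal cells kept as-is
        keep = rows <= cols
        self._rows, self._cols, self._vals = rows[keep], cols[keep], vals[keep]
        self._symmetric = bool(
            (abs(sp.coo_matrix(
                counts.counts if isinstance(counts, CooccurrenceMatrix) else counts
            ) - sp.coo_matrix(
                counts.counts if isinstance(counts, CooccurrenceMatrix) else counts
            ).T)).nnz == 0
        )
        if not self._symmetric:
            # general matrix: train on every stored cell in its orientation
            self._rows, self._cols, self._vals = rows, cols, vals

    def _init_state(self, rng: np.random.Generator) -> GloVeState:
        d, n = self.params.d, self.n
        scale = 0.5 / d
        return GloVeState(
            word_vectors=rng.uniform(-scale, scale, size=(n, d)),
            context_vectors=rng.uniform(-scale, scale, size=(n, d)),
            word_biases=rng.uniform(-scale, scale, size=n),
            context_biases=rng.uniform(-scale, scale, size=n),
        )

    def fit(self) -> "GloVeResults":
        p = self.params
        rng = np.random.default_rng(p.seed)
        state = self._init_state(rng)
        w, c, bw, bc = (
            state.word_vectors,
            state.context_vectors,
            state.word_biases,
            state.context_biases,
        )
        # AdaGrad accumulators, initialized at 1 so the first step is lr-sized
        gw = np.ones_like(w)
        gc = np.ones_like(c)
        gbw = np.ones_like(bw)
        gbc = np.ones_like(bc)
        logy = np.log(self._vals)
        fy = glove_weight(self._vals, p.y_max, p.alpha_w)
        n_cells = len(self._vals)
        initial_loss = glove_loss(state, self.counts, p)
        loss_path = [initial_loss]
        for _ in range(p.epochs):
            order = rng.permutation(n_cells)
            for idx in order:
                i, j = self._rows[idx], self._cols[idx]
                orientations = ((i, j), (j, i)) if (self._symmetric and i != j) else ((i, j),)
                for a, b in orientations:
                    err = fy[idx] * (w[a] @ c[b] + bw[a] + bc[b] - logy[idx])
                    grad_w = err * c[b]
                    grad_c = err * w[a]
                    w[a] -= p.learning_rate * grad_w / np.sqrt(gw[a])
                    c[b] -= p.learning_rate * grad_c / np.sqrt(gc[b])
                    gw[a] += grad_w**2
                    gc[b] += grad_c**2
                    bw[a] -= p.learning_rate * err / np.sqrt(gbw[a])
                    bc[b] -= p.learning_rate * err / np.sqrt(gbc[b])
                    gbw[a] += err**2
                    gbc[b] += err**2
            loss_path.append(glove_loss(state, self.counts, p))
        emb = None
        if self.vocab is not None:
            emb = EmbeddingMatrix(vectors=state.embedding(), vocab=self.vocab)
        return GloVeResults(
            model=self, state=state, embedding=emb, loss_path=np.asarray(loss_path)
        )


@dataclass
class GloVeResults:
    """Fitted GloVe parameters, loss trajectory and the final embedding."""

    model: GloVe
    state: GloVeState
    embedding: EmbeddingMatrix | None
    loss_path: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def initial_loss(self) -> float:
        return float(self.loss_path[0])

    @property
    def final_loss(self) -> float:
        return float(self.loss_path[-1])

    def embedding_array(self) -> np.ndarray:
        return self.state.embedding()

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "GloVe fit",
            "=" * 40,
            f"concepts:            {self.model.n}",
            f"embedding dimension: {p.d}",
            f"nonzero cells:       {len(self.model._vals)}",
            f"epochs:              {p.epochs}",
            f"y_max / alpha:       {p.y_max:g} / {p.alpha_w:g}",
            f"initial loss:        {self.initial_loss:.6g}",
            f"final loss:          {self.final_loss:.6g}",
        ]
        return "\n".join(lines)


def train_glove(counts, params: GloVeParams) -> tuple[GloVeResults, EmbeddingMatrix | None]:
    """Functional form of :meth:`GloVe.fit`."""
    res = GloVe(counts, params).fit()
    return res, res.embedding
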