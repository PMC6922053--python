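# Methods

This note records the statistical model behind `medembed`, the
conventions and defaults the implementation pins down, what the
synthetic-data generator does and does not emulate, and the numerical
choices that affect reproducibility.

## Co-occurrence model

All data sources are reduced to one symmetric nonnegative integer matrix
over a concept vocabulary. The counting rules are presence-based:

- **Text.** Normalized token streams are chunked into non-overlapping
  windows of L = 10 tokens (chunked, not sliding — each token belongs to
  exactly one window). An unordered pair of distinct concepts co-present
  in a window contributes 1, regardless of token multiplicity. A
  `multiplicity="product"` variant (adds the product of within-window
  multiplicities) exists for sensitivity analysis only.
- **Rolling temporal (claims-style).** A pair contributes 1 per patient
  if any two of the patient's events carry the two concepts at most
  `span_days` = 30 days apart — a patient-level statistic ("how many
  patients exhibit this pair"), not an episode count. `per_episode=True`
  counts maximal disjoint episodes instead.
- **Calendar temporal (notes-style).** Days are partitioned into
  30-day bins anchored at each patient's first event (per-patient
  anchoring; a global calendar anchor would make counts depend on an
  arbitrary epoch). By default a pair again contributes once per patient
  when both concepts share some bin, which makes calendar counts a
  cell-wise lower bound of rolling counts (two events in one bin are at
  most 29 days apart); `per_bin=True` switches to once per (patient,
  bin). The patient-level default keeps the two temporal modes ordered
  and comparable; the per-bin variant is closer to a frequency
  weighting.

Self co-occurrence is excluded everywhere (the diagonal is identically
zero): self-similarity carries no information for the downstream
benchmarks. Merging matrices from different sources takes the sorted
union of vocabularies and adds aligned cells.

## PMI, SPPMI and the spectral factorization

Let C be the count matrix, G = ΣᵢⱼCᵢⱼ the grand sum (each unordered pair
is stored in both triangles, so G is twice the number of counted pairs).
The conventions, fixed by the package:

- joint probability of an unordered pair: p(w,c) = C[w,c] / (G/2);
- margins from pair participations: p(w) = (row sum of w) / G. Margins
  are *not* taken from raw corpus token frequencies — after merging
  heterogeneous sources the matrix itself is the only consistent
  definition;
- margin smoothing: both margins are raised to α = 0.75 and renormalized
  to sum to one. Smoothing both (rather than only the context margin) is
  forced by symmetry: word and context frequencies coincide in a
  symmetric matrix;
- PMI is computed on nonzero cells only, with natural logarithms (the
  shift in the SPPMI transform subtracts log k, so the log base must
  match; base e is the convention here);
- SPPMI(w,c) = max(PMI(w,c) − log k, 0) with k = 1 by default (no
  shift). k is the negative-sampling count whose implicit objective the
  factorization recovers. Cells that clip to 0 are dropped from storage;
  0 is also the sparse implicit value, so the factorization is
  unaffected.

The truncated rank-d SVD U_d Σ_d V_dᵀ of the SPPMI matrix gives
W̃ = U_d Σ_d^p, C̃ = V_d Σ_d^p and the final embedding W = W̃ + C̃.
The exponent p defaults to 0.5 — the symmetric scaling that splits the
spectrum evenly between word and context blocks, so that W̃ C̃ᵀ exactly
reconstructs the rank-d SPPMI approximation — and is exposed as
`sigma_power` for the p = 1 variant (then the embedding is U_d Σ_d plus
V_d Σ_d and the word block alone is the classical LSA coordinates). The
"PCA" baseline factors the raw count matrix and embeds concepts as
U_d Σ_d.

Default embedding dimension is d = 500 in the pipeline configuration
(the regime intended for production-scale vocabularies); tests and the
synthetic studies use d = 50, which is full-rank-adjacent for a
200-concept vocabulary.

## GloVe

The weighted least-squares objective over nonzero cells y = C[w,c],

    Σ f(y) (w⃗·c⃗ᵀ + b_w + b_c − log y)²,
    f(y) = (y / y_max)^0.75 for y < y_max, else 1,   y_max = 100,

is minimized by per-coordinate adaptive gradient (AdaGrad) over shuffled
cells — the canonical optimizer for this objective. Parameters are
initialized uniformly in (−0.5/d, 0.5/d) from the run seed. A symmetric
matrix is stored once per unordered pair; each pair is visited once per
epoch with both orientations updated, which matches the full
both-triangles sum without double counting (verified against an
independent dense loss oracle in the tests). Learning rate 0.05 and
epoch counts are package defaults; single-threaded runs are
bit-reproducible given the seed. The final embedding is w⃗ + c⃗.

## Bootstrap power benchmark

For a known pair (x, y) with categories (a, b), the null is the
distribution of cosines of random pairs (x*, y*) with x* drawn uniformly
with replacement from category a and y* from b, the two drawn concepts
required to be distinct (identical draws are redrawn; a self-cosine of 1
would otherwise contaminate the upper tail that the test uses).
Conventions fixed here because quantile dialects differ:

- n = 10,000 draws per null; the threshold is the order statistic at
  ceiling((1 − level)·n) of the sorted samples (level 0.05 → the 9,500th
  of 10,000);
- discovery requires *strictly* exceeding the threshold; ties are
  non-discoveries (conservative);
- nulls are cached per unordered category pair within a run — one set of
  draws per category pair, not per relationship — with a stable child
  seed derived from the run seed and the category labels, so results do
  not depend on relationship order;
- pairs with a missing or zero embedding vector, or an uncategorized
  concept, are excluded and reported as n_total − n_evaluable;
- the semantic-type benchmark uses a *marginal* null mode that draws the
  two concepts from two different, randomly chosen categories.

With 1,000 signal-free pairs the measured discovery rate has a binomial
99% band of roughly [0.035, 0.065] around the nominal 0.05; the shared
cached nulls add a small correlated error across pairs, so rates near
the band edges occur at moderate category counts. Human-assessment
agreement is Spearman's ρ with average ranks for ties; an all-tied score
vector is rejected as degenerate rather than returned as NaN.

## Synthetic data: what it emulates, what it does not

The generator produces a thesaurus (CUIs in the C9xxxxxx range, 1–3-token
surface phrases, every surface token owned by exactly one concept so the
greedy longest-match normalizer recovers mentions exactly), topical
documents, and patient event streams. Defaults, chosen once as the
package's standard study conditions:

| parameter | default | role |
|---|---|---|
| n_concepts / n_clusters | 200 / 4 | vocabulary and category structure |
| n_documents × doc_length | 1,500 × 100 units | ≈ 15,000 windows, ≈ 190 mentions/concept |
| concept_rate | 0.25 | concept mentions per token slot |
| topic_strength | 0.5 | share of mentions drawn from the document's cluster |
| background vocabulary | 300 words, Zipf(1.1) | mimics natural-text margins |
| planted pairs | 20, same-cluster, λ = 0.9 | recoverable ground truth |
| n_patients × events | 500 × 10, 730-day horizon | event-stream pathway |

Documents are laid out in normalized token units aligned with the
10-token windows, so a planted pair inserted at strength λ = 1 lands in
the same window with certainty (the pair is nudged off a window boundary
when needed). The 200-concept default keeps the 20 planted pairs below
half a percent of the same-category pair population; a materially larger
planted fraction contaminates the bootstrap null's upper tail and
visibly deflates the measured false-positive rate, which would
confound calibration checks.

What the generator does **not** emulate: real UMLS semantic-type
taxonomy depth, abbreviations/negation/sense ambiguity in clinical
prose, ICD-9 coding semantics, seasonality or care-episode structure in
event timing, and the heavy-tailed concept frequency distribution of
real corpora (concepts are uniform within topics). Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct and calibrated, not that any particular real corpus would yield
embeddings of a given quality.

## Numerical choices

- SVD: exact dense LAPACK SVD for matrices up to 400 rows or when the
  requested rank is within 1 of full; otherwise a Lanczos-style sparse
  solver (`svds`, tolerance 1e−8) with a seeded starting vector. Sign
  ambiguity is resolved by forcing the largest-magnitude entry of each
  left singular vector positive, making factors deterministic.
- All random draws flow through `numpy.random.Generator` seeded from
  explicit arguments; the pipeline derives per-stage child seeds (kept
  below 2³¹) from its single top-level seed and records them in the run
  manifest.
- Embedding writers print 12 significant digits; round-trips are exact
  to < 1e−10, and matrices are written with a canonical (sorted)
  vocabulary so identical content gives identical bytes.
- Degenerate inputs are rejected loudly: empty count matrices, zero
  vectors in cosines, categories with fewer than two embedded members,
  all-tied human scores, windows shorter than 2 tokens.

## Known limitations

- Greedy longest-match linking is a transparent stand-in for a full
  clinical concept normalizer; it has no disambiguation and will link
  any surface form in the dictionary regardless of context.
- The GloVe trainer is single-threaded by design (bit-reproducibility);
  it is not intended for vocabularies beyond ~10⁵ nonzero cells per
  second-scale budgets.
- Calendar binning anchored at the first event makes a patient's bins
  depend on their earliest record; a late-arriving earlier event shifts
  all bins.
- The power benchmark's cached nulls trade per-pair exactness for a
  10,000-fold cost reduction; with very few categories the shared
  threshold error is the dominant noise term in measured power.
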