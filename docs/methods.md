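# Methods

## Problem setting

Given a sparse binary catalogue of disease–miRNA associations, the task is
to score every unobserved pair so that true-but-unrecorded associations
rank high. The predictor is unsupervised and purely topological/similarity
driven: no negative labels exist (absence of a record is not evidence of
absence), which is why evaluation ranks held-out positives against all
unknown pairs rather than against a sampled negative class.

## Pipeline

`nbmda_scores(A_train, fs, ss, params)` is the whole model, in order:

1. **Gaussian interaction-profile kernels.** `KM` over the columns of the
   training matrix, `KD` over the rows, bandwidth `γ = γ′ / mean‖IP‖²`
   with `γ′ = 1` on both sides. Normalising by the mean squared profile
   norm makes the kernel invariant to uniformly duplicating the catalogue
   (doubling every profile's mass leaves the kernel unchanged entrywise —
   tested). Individual all-zero profiles are allowed: their kernel row is
   `exp(−γ‖IP_j‖²)`, well defined as long as the network has any edge at
   all; a fully empty matrix raises a degenerate-kernel error.
2. **Semantic similarity.** Contributions are evaluated by memoised
   recursion restricted to the ancestor closure `T(D)`; children outside
   `T(D)` lie on no path from `D` and are ignored. With multiple parents
   the maximum over paths is taken (`D_D(t) = max_paths Δ^len`), verified
   against explicit path enumeration. Association labels that do not map
   into the ontology get a zero semantic row (unit diagonal), so the
   kernel becomes their only disease-similarity source.
3. **Integration.** `S = K` where the primary similarity is zero, else
   `(primary + K)/2`. "Zero" is `|x| ≤ 1e−12` because the primary matrix
   typically arrives from a file of printed floats.
4. **KNN augmentation.** Each disease's `K = 3` most similar other
   diseases (self excluded; similarity ties at the cut broken toward the
   smaller index so runs are deterministic) vote per miRNA; an edge needs
   a strict majority, `⌊K/2⌋ + 1` votes, by default. The vote threshold is
   exposed because "most neighbors agree" admits readings from 1 to K.
   `SDA`/`SMA` are the union of recommendations with the original edges:
   the construction exists to densify a sparse network, and replacing the
   original edges would discard known evidence. Raising the threshold can
   only remove recommended edges (monotonicity is property-tested).
5. **Scoring.** Per network, the seed edge is removed first and degrees
   are taken after removal, so a known pair and an unknown pair embedded
   in the same surrounding topology receive identical scores — this is
   what lets the full-data network score its own known edges without
   trivial self-confirmation. Because the seed entry is zeroed, degenerate
   "paths" through an endpoint (`d_l = d_i` or `m_k = m_j`) drop out of
   the common-neighbor sets automatically. `LCL` counts every edge whose
   two endpoints are both common neighbors, whether or not that edge lies
   on a quadrangle through the seed pair. In a bipartite graph the two
   endpoint neighborhoods are disjoint, so the denominator
   `|N(d_i) ∪ N(m_j)|` is exactly `deg(d_i) + deg(m_j)` (asserted in a
   test). `CJC = 0` when both endpoints are isolated (0/0 guard). The
   final score is the geometric mean over the three networks, so any
   network without a linked quadrangle for the pair annihilates the score.

The dense implementation computes all pairs at once: common-neighbor
counts are boolean matrix products, and the `LCL` matrix is the four-index
contraction `Σ_{l,k} [C(i,l)>0]·X(l,j)·X(l,k)·X(i,k)·[B(k,j)>0]`
(`B = XᵀX`, `C = XXᵀ`), valid wherever the seed entry is already zero;
pairs that are edges of `X` are recomputed individually with the edge
removed. Exact integer agreement with a brute-force enumerator of all
length-3 paths is part of the test suite (200 random graphs up to 10×10).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `k` | KNN neighbor count | 3 | sweeps of 1–5 are conventional; any `k < N_d` (resp. `N_m`) accepted |
| `vote_threshold` | neighbors that must agree | `⌊k/2⌋+1` | 1 = any neighbor suffices, `k` = unanimity |
| `delta` | semantic decay per ontology level | 0.5 | in (0, 1] |
| `gamma_prime_m`, `gamma_prime_d` | kernel bandwidth bases | 1.0 | larger = narrower kernel |
| `folds`, `repeats` | CV shape | 5, 100 | repeats tamed to 5 in the shipped study conditions (below) |
| `similarity_mode` | `dynamic` / `static` | `dynamic` | see below |

All are settable via a flat YAML config (`knn.k`, `knn.vote_threshold`,
`semantic.delta`, `kernel.gamma_prime_{m,d}`, `cv.*`); precedence is
defaults < file < CLI flags, and the resolved config is embedded in every
report so a run reproduces from its own output.

## Cross-validation design

**Negative pool.** For both LOOCV and k-fold, positives are ranked against
every pair with no known evidence in the *full* catalogue. Using the full
matrix to define pool membership (not values) keeps the pool identical
across iterations and matches the standard protocol in this literature.

**Normalised-rank ROC.** Because each iteration rescoring moves the
negatives' scores too, each positive is compared against its own
iteration's negative pool: `u_p = (#neg above + ½·#ties)/#neg`, AUC
`= 1 − mean(u_p)`, and the ROC is the step curve `TPR(f) = frac(u_p ≤ f)`
over `FPR = f`, emitted with both corner points per jump so the
trapezoidal area equals the rank-sum AUC exactly (asserted to 1e−9). A
constant scorer lands on AUC 0.5 exactly via mid-ranks; the standalone
`roc_auc` for a shared pool additionally cross-checks the Mann–Whitney
statistic against scikit-learn's threshold-swept curve.

**Dynamic vs static similarity.** `dynamic` recomputes kernels,
integrated similarities and the augmented networks from each iteration's
training matrix, so no stage can see a held-out edge (the leakage test
tampers with the full matrix at the held-out cell and requires bitwise
identical kernels, networks and scores). `static` computes everything
once from the full matrix and leans on the seed-removal convention alone;
it is far cheaper and is what several peer models appear to have done,
which is why it is offered, but it does let held-out edges shape the
kernels and augmentation. The mode is recorded in the result's settings.

**Random streams.** Repeat `r` of k-fold uses `default_rng(seed + r)`;
fold sizes differ by at most one. LOOCV is deterministic.

## Synthetic study conditions

The generator emulates the gross shape of real catalogues — sparse,
bipartite, with groups of related miRNAs attached to groups of related
diseases — as an aligned planted-block model: 30 diseases × 30 miRNAs in
3 blocks, within-block edge probability 0.5, cross-block 0.02 (≈ 160
edges, ≈ 18% density overall). The functional-similarity fixture echoes
the block assignment (0.8 within, 0.1 across, Gaussian noise sd 0.05,
clipped and symmetrised); the ontology fixture is a random rooted DAG
over the disease labels (uniform parent among lower indices, extra-edge
probability 0.1), deliberately uninformative about the blocks so the
semantic branch is exercised without trivially encoding the answer. These
scales keep the brute-force scoring oracle (O(N_d²·N_m²)) and dynamic
LOOCV comfortable on one CPU; CV runs in the shipped conditions use 5
repeats rather than 100 since the per-repeat spread at this size is
already ~0.01. What passing shows: the pipeline recovers planted
block structure from edge topology plus block-consistent similarity
(5-fold AUC ≈ 0.84 vs ≈ 0.50 on a permuted null). What it does not show:
performance under real catalogues' heavy-tailed degree distributions,
annotation bias, or ontology-correlated block structure, none of which
are modelled.

## Numerical choices and degenerate inputs

- Similarity files must be symmetric to 1e−8 and inside [0, 1] up to
  1e−8 (clipped); worse violations are format errors, not warnings.
- Matrix axes follow first-appearance order of labels; everything
  downstream joins by label, so ordering is cosmetic.
- Label matching strips surrounding whitespace and is case-sensitive by
  default (`--normalize-case` lowercases for merging messy sources).
- Ranked outputs break score ties by ascending miRNA index (stable sort)
  and print scores with 6 significant digits.
- Scores are not probabilities: `CJC` is unbounded above (it grows with
  community size and internal connectivity); only the ordering is used.

## Known limitations

- Dynamic LOOCV is O(P) full pipeline evaluations; at real-catalogue
  scale (≈ 5000 edges, 383×495) static mode or k-fold is the practical
  choice.
- The miRNA functional-similarity matrix is an input, not recomputed from
  disease term overlap; diseases missing from the ontology silently fall
  back to kernel-only similarity (with a warning).
- No higher-order closures (hexagonal paths), weighted networks, or
  alternative local-community indices are implemented.
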