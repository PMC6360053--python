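# nbmda

Neighborhood-based prediction of miRNA–disease associations.

Experimentally confirmed miRNA–disease associations are rare: catalogues
cover only a few percent of all possible pairs, and many diseases (or
miRNAs) have just one or two known partners. `nbmda` is a network-based
predictor for prioritising unobserved pairs from such a sparse bipartite
catalogue, aimed at computational biologists who want a ranked candidate
list per disease before committing to wet-lab validation.

## Model

Let `A` be the binary `N_d × N_m` adjacency matrix of known associations,
with row `i` the interaction profile `IP(d_i)` of disease `d_i` and column
`j` the profile `IP(m_j)` of miRNA `m_j`. The predictor combines three
ingredients:

1. **Similarity fusion.** Disease semantic similarity `SS` comes from the
   disease-ontology DAG: a term contributes `Δ^depth` (best path, `Δ = 0.5`)
   to each descendant's semantic value `DV(D) = Σ_{t∈T(D)} D_D(t)`, and

   `SS(d_i, d_j) = Σ_{t ∈ T(d_i)∩T(d_j)} (D_{d_i}(t) + D_{d_j}(t)) / (DV(d_i) + DV(d_j))`.

   Gaussian interaction-profile kernels supply a topology-driven
   counterpart, `KD(d_i,d_j) = exp(−γ_d ‖IP(d_i) − IP(d_j)‖²)` with
   `γ_d = γ′_d / mean_i ‖IP(d_i)‖²` (and `KM` likewise over columns).
   The integrated similarities use the kernel where the primary similarity
   is zero and the arithmetic mean elsewhere:
   `S_d = KD` if `SS = 0` else `(SS + KD)/2`, and analogously
   `S_m` from the miRNA functional similarity `FS` and `KM`.

2. **KNN densification.** For every disease, its `K = 3` most similar
   other diseases (by `S_d`) vote: a miRNA carried by a strict majority of
   them is recommended, giving the augmented network `SDA` (union with the
   original edges). The mirror construction over `S_m` gives `SMA`.

3. **Quadrangular local-community scoring.** In each network
   `X ∈ {MDA, SDA, SMA}` (seed edge `(d_i, m_j)` removed first), the common
   neighbors `CN` are the interior nodes of length-3 paths
   `d_i – m_k – d_l – m_j`, `LCL` counts the edges internal to that
   community, and

   `CJC_X(i,j) = CN · LCL / (deg(d_i) + deg(m_j))`,
   `score(i,j) = (CJC_MDA · CJC_SDA · CJC_SMA)^{1/3}`.

Evaluation follows the field's convention: global LOOCV (each known pair
held out and ranked against all pairs with no known evidence) and repeated
5-fold CV, with Mann–Whitney/trapezoidal AUC and mid-rank tie handling.

## Worked example

Simulate a small planted-block catalogue (three groups of diseases and
miRNAs, dense within-group edges), rank candidates for one disease, and
cross-validate:

```sh
nbmda simulate --n-diseases 15 --n-mirnas 15 --n-blocks 3 --seed 2 --out-dir demo
nbmda rank --assoc demo/associations.tsv --fs demo/fs.tsv --dag demo/dag.tsv \
      --disease disease_000 --top-n 5 --out demo/rank.tsv
nbmda kfold --assoc demo/associations.tsv --fs demo/fs.tsv --dag demo/dag.tsv \
      --seed 1 --repeats 5 --out demo/kfold.json
```

`demo/rank.tsv` lists the strongest unobserved candidates for
`disease_000`:

```
rank	mirna	score
1	mirna_004	8.70659
2	mirna_002	3.40851
3	mirna_005	0
```

`mirna_004` and `mirna_002` close many quadrangles with internal links
around `disease_000` in all three networks — these are the pairs the model
would send to validation first; a score of 0 means at least one network
contains no linked quadrangle for the pair. The CV report prints
`kfold AUC = 0.6441` (per-repeat AUCs 0.6685, 0.6696, 0.6318, 0.5392,
0.7113): on this tiny 43-edge toy the model ranks held-out true pairs above
unknown pairs well over half the time; on the default 30×30 fixture the
AUC is ≈ 0.84 against a permuted-matrix null of ≈ 0.50.

The same functionality is available as a library: `read_associations`,
`disease_semantic_similarity`, `mirna_kernel`/`disease_kernel`,
`integrate`, `knn_augment_by_disease`/`_by_mirna`, `score_all`,
`run_loocv`/`run_kfold` (see `docs/methods.md`).

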