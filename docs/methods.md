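# Methods

## Model and assumptions

`netscreen` treats disease-gene discovery as semi-supervised node
classification on a weighted, undirected PPI network. The working
assumptions are those of guilt-by-association: genes causing the same
disease tend to interact (directly or through short weighted paths), and a
validated seed set S is a representative, if incomplete, sample of the true
disease module. Edge weights are STRING-style integer confidence scores in
1–999; all screening mathematics uses the normalized score
Q(g,g′) = score/1000, so the published-style thresholds (0.9 for the
interaction screen, 0.95 for enrichment similarity) read directly on the
confidence scale.

### Scorer

Each gene is a feature row of a representation matrix:

* **adjacency** — the normalized weighted adjacency, zero diagonal;
* **influence** (default) — the random-walk-with-restart kernel
  K = α (I − (1−α) W)⁻¹, where W is the column-normalized weighted
  adjacency. Columns of K are probability distributions (the stationary
  visiting profile of walks restarting at that node); an isolated node's
  column is the unit vector on itself. Computed by dense inversion, which
  is exact and fast at the network sizes this package targets (10²–10³
  nodes); networks of STRING scale would need an iterative solver.
* **embedding** — the d eigenpairs of the weighted adjacency with largest
  |eigenvalue|, each eigenvector scaled by √|λ| with the sign fixed so its
  first nonzero entry is positive. A deterministic spectral construction is
  used instead of stochastic random-walk embeddings so that repeated runs
  are bit-identical without walk-count bookkeeping.

Training sets: positives = mapped seeds; genes belonging to any annotation
term with Jaccard similarity to S above `jaccard_max` (default 0.1) are
excluded from both classes; everything else is a negative. The classifier
is scikit-learn logistic regression (lbfgs, unpenalized intercept) with
inverse-frequency class weights, so tens of positives are not swamped by
hundreds or thousands of negatives. Features are standardized over genes
and constant columns dropped before fitting.

**Self-visit exclusion.** For influence mode the classifier works on a copy
of K with the diagonal zeroed. The kernel diagonal (≈ α) is a near-one-hot
identity feature per gene; with as many features as genes, the model can
use it to memorize which genes carried which training label rather than
learn network proximity. Empirically this inflates null cross-validation
AUROC from ≈ 0.5 to ≈ 0.95. The representation matrix itself keeps the
exact kernel (columns sum to one); only the classifier's working copy is
modified.

The fitted probability is reported for every gene, including positives and
excluded genes. Note that the probability of a gene present in the
*negative* training class is a fitted training value and is actively pushed
down by the optimizer; consequently the scorer is **not** a monotone
propagation operator — adding a high-confidence edge between a background
gene and every seed increases the influence mass that gene receives (a
property the test suite asserts) but may still lower its fitted
probability, because the whole model is refit on re-standardized features
of a different graph.

### Screens

1. **Permutation test.** R random node sets of seed-set size are drawn
   uniformly from the network (seeds are eligible by default; a flag
   excludes them) and scored with the identical configuration. For each
   non-seed gene, p = N/R with N the count of random runs whose probability
   meets or exceeds the observed one. p = N/R is used exactly, staying
   faithful to the defining ratio; the optional add-one smoothing
   p = (N+1)/(R+1) is off by default. Keep p < 0.05 (strict inequality).
2. **Interaction screen.** MIS(g) = max over seeds of Q(g, seed); zero when
   no seed edge exists. Keep MIS ≥ 0.9.
3. **Enrichment screen.** For term F with M members in a universe of
   N genes (N defaults to the network node count), a gene with n network
   neighbours (any positive score by default; a minimum-score option
   exists; the gene itself never counts) of which m are annotated by F gets
   ES = −log₁₀ P(X ≥ m) under the hypergeometric law, computed with
   `scipy.stats.hypergeom.sf`; tails below 1e-300 are clamped before the
   logarithm. Cosine similarity between ES vectors is defined as zero when
   either vector is all-zero. Keep MES ≥ 0.95.

Stages run in order; MIS is computed for permutation survivors and MES for
interaction survivors (genes removed earlier carry NaN). Survivor sets are
nested by construction, and tie-breaking at thresholds is strict `<` for p,
`≥` for MIS and MES.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.85 | RWR restart probability; larger keeps influence local |
| d | 32 | embedding dimension (embedding mode only) |
| λ | 1.0 | L2 strength; the sklearn C is 1/λ |
| jaccard_max | 0.1 | term-similarity cutoff for negative exclusion |
| R (`n_random_sets`) | 1000 | permutation replicates; 100 in the synthetic benchmark for runtime |
| p_cut / mis_cut / mes_cut | 0.05 / 0.9 / 0.95 | cascade thresholds |
| conf_cut | 0.9 | confidence threshold of the connection report |

α, d and λ are package defaults chosen from common practice in network
propagation (no authoritative values exist for this pipeline); all are
exposed in `PipelineConfig` and the CLI.

## Synthetic benchmark

`synthetic_data` generates an Erdős–Rényi background (q_bg = 0.02, scores
uniform on 150–700) of 200 nodes with a planted 30-gene module wired at
q_mod = 0.5 with scores uniform on 850–999, 50 annotation terms of which
30% draw ~70% of their members from the module, and a uniform 50/50 split
of the module into revealed seeds and held-out genes. The disjoint score
bands make interaction-screen behaviour fully controllable: background
genes cannot reach MIS ≥ 0.9, so final-list precision against planted
truth is a sharp readout. What the generator does **not** emulate:
scale-free degree distributions, STRING's evidence-channel score
composition, annotation hierarchies (GO DAG structure), or literature
bias. Passing the recovery tests therefore demonstrates the machinery is
correct and well-calibrated under the stated generative model, not that
real-data gene lists will reach any particular precision.

A separate homogeneous background generator (no planted module) serves as
the null instrument for permutation-calibration checks: under a planted
module, the module genes' p-values move coherently with each random seed
draw — a real dependence, not a bug — which inflates the
Kolmogorov–Smirnov statistic even when every marginal is uniform.

## Numerical and design choices

* Duplicate/reversed edge rows collapse to one undirected edge keeping the
  maximum score; self-loop rows are dropped with a warning.
* Identifier matching is exact and case-sensitive; gzip input is accepted
  transparently.
* Every stochastic step draws from a named `numpy` SeedSequence substream
  of one master seed (stable across processes; label streams are tagged by
  CRC32 of the label), so full runs are bit-reproducible and independent
  disease labels do not share streams.
* Score tables render floats with 12 significant digits, which round-trips
  through the reader to within 1e-9.
* The permutation stage refuses jobs whose R × node-count product exceeds
  a budget cap (default 2×10⁷) rather than grinding for hours.
* Problem sizes in tests and the acceptance script (200–300 nodes, R =
  100–200, 5–10 master seeds) were chosen so a full validation pass
  completes in well under a minute per component while keeping every
  statistical check adequately powered.

## Known limitations

* Dense linear algebra bounds practical network size to ~10⁴ nodes.
* The permutation p-value is granular at 1/R; with R = 100 the smallest
  nonzero p is 0.01, so p_cut below that degenerates to "never exceeded".
* Negative selection treats every non-seed, non-similar gene as a negative
  although some are undiscovered positives; this biases probabilities
  downward for true disease genes (the permutation screen is rank-based
  and largely insensitive to it).
* The cross-validation AUROC shares negatives between training and
  evaluation, as is standard for this design; it measures ranking of
  held-out positives, not generalization to unseen negatives.
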