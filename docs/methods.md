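# Methods

## Model and learning procedure

The prioritizer treats known disease-gene associations as positive examples
and every other (disease, gene) pair as unlabeled.  Scoring is done by a
bagging biased SVM over a precomputed kernel:

1. **Gene kernels.** A feature table Φ (genes × features) yields the linear
   kernel K = ΦΦᵀ.  An interaction graph yields the heat-diffusion kernel
   K = exp(−βL) with L = D − A the combinatorial Laplacian, computed by
   eigendecomposition (β defaults to 1).  We use the combinatorial rather
   than the normalized Laplacian: it is the classical heat-kernel
   construction and guarantees positive semidefiniteness; the choice is a
   convention of this package, and either convention yields a valid kernel.
2. **Normalization and fusion.** Every source kernel is rescaled to unit
   diagonal, K̃_ij = K_ij/√(K_ii K_jj), *before* averaging — averaging
   heterogeneous kernels is only meaningful once their self-similarities
   agree.  The mean of unit-diagonal PSD kernels is again unit-diagonal and
   PSD, so the fused kernel needs no re-normalization.  Weighted (MKL-style)
   fusion is deliberately not implemented; uniform averaging is the
   supported strategy.
3. **PU engine.** For b = 1..B the engine draws a subsample U_b of the
   unlabeled set (default size |P|: balanced base problems train fast and
   weight positives strongly), trains a soft-margin SVM with labels +1 on P
   and −1 on U_b at equal cost C on both classes, and aggregates.  An
   item's score is the mean decision value over the rounds in which it was
   **out of bag**; rounds that used the item as a training negative
   systematically depress its decision value and are excluded.  An item in
   every bag (possible only when the subsample is the whole of U) falls
   back to the mean over all rounds.  Defaults B = 30, C = 1.
4. **Multitask sharing.** Pairs are compared with
   K_pair = K_disease · K_gene.  The four disease kernels: Dirac (identity;
   variant 1), 1 + Dirac (variant 2), a phenotype-similarity kernel
   (variant 3), and phenotype + Dirac (variant 4).  Training positives are
   all known pairs; the unlabeled pool contains every pair (D_j, G) with
   D_j a training disease or the query and G not a known gene of D_j, and
   each bootstrap round subsamples as many pool pairs as there are positive
   pairs.

## The SVM has no intercept

The dual of the intercept-free SVM is a box-constrained QP without the
equality constraint Σαᵢyᵢ = 0.  This matters: under the Dirac disease
kernel the pair Gram matrix is block-diagonal by disease, and without the
coupling constraint the optimization decomposes exactly into independent
per-disease problems — "no sharing" holds at the optimization level, not
just in intuition.  The implementation exploits this by assembling only the
query disease's block for variant 1, which is mathematically equivalent and
makes variant 1 bit-identical to running the PU engine directly on the gene
kernel.  The QP is solved with L-BFGS-B on the analytic dual
(ftol 1e-14, gtol 1e-10); tests cross-check it against exhaustive KKT
active-set enumeration on small problems.

## Orphan diseases and the variant-3/4 equivalence

For a query disease with no known genes, the phenotype+Dirac kernel's Dirac
component cannot contribute to the scoring function — no training pair
involves the query, so K_Dirac(D_query, ·) vanishes on every training item.
Variants 3 and 4 are therefore the same method in this setting, and the
implementation makes the equivalence exact by using the phenotype kernel
alone whenever the query is orphan under variant 4.  (Strictly, a naive
variant-4 training Gram would still differ on entries between training
pairs sharing a non-query disease; collapsing to variant 3 implements the
method as defined rather than that incidental perturbation.)

## Reproducibility and randomness

All stochastic steps flow from one integer seed.  Each bootstrap round
derives its randomness from (seed, round index), so enlarging B never
changes earlier rounds.  Within a round, the subsample is drawn by hashing
each unlabeled item's *identity* and keeping the smallest hashed
priorities; consequently results are invariant to the storage order of the
inputs, and consistently relabeling genes/diseases permutes the outputs
identically.  Ranks use mid-rank tie handling by default, which makes the
rank-AUC identity rank = (|U|+1)(1−AUC) agree with the ½-credit-for-ties
AUC; a worst-rank rule is available for conservative reporting.  Percent
recall thresholds ("top 5%") are resolved per association against its own
candidate-list size.  In the Wilcoxon signed-rank test zero differences are
dropped, the null is enumerated exactly up to 25 pairs and approximated
normally (with continuity correction) above.

## Synthetic benchmark

The generator plants, for each disease and each of L sources, a unit
centroid direction; the disease's genes are drawn at
signal_strength · noise · centroid + noise · N(0, I), background genes at
noise · N(0, I).  Disease centroids mix a shared 4-dimensional latent
factor with weight ρ = `phenotype_informativeness` against independent
noise, and the phenotype matrix is the correlation of the concatenated
centroids plus symmetric noise (sd 0.05, unit diagonal): at ρ = 0 the
phenotype matrix is uninformative about which diseases share gene
neighborhoods; at ρ = 1 it is maximally informative.  An interaction graph
draws each edge with probability increasing linearly in feature cosine
similarity (1% to 30%).  Orphan benchmarks use disjoint gene sets per
disease so an orphan's genes are genuinely unseen; otherwise genes may
belong to several diseases (pleiotropy).

Defaults (chosen once as a realistic desk-scale regime): 200 genes, 10
diseases × 5 genes, 2 sources of dimension 10, signal_strength 3, source
noise 1, ρ = 0.7.  The variant-comparison benchmark uses 300 genes and 20
diseases × 10 genes, with fully informative phenotypes (ρ = 1), so that
comparisons rest on 200 held-out associations.

A consequence of this design worth knowing: because the generated phenotype
matrix is the correlation of the *actual* disease centroids (plus small
noise), it is truthful by construction.  The phenotype+Dirac variant was
motivated by incomplete or misleading phenotype descriptions — two diseases
with near-identical descriptions but different genes — and that failure
mode cannot arise here.  On these benchmarks the pure phenotype variant is
therefore already near-optimal, and the +Dirac variant performs on par with
it (typically within ~1 mean-rank unit, between the phenotype variant and
the no-sharing variant) rather than ahead of it.
What the generator does **not** emulate: the heavy-tailed and block
structure of real annotation/expression kernels, scale (tens of thousands
of genes), incomplete and biased association tables, and phenotype
similarities estimated from text.  Passing the planted-recovery tests shows
the machinery is correct and that sharing helps when its assumptions hold —
not that any particular recall level will transfer to real data.

## Problem sizes and numerical choices

Test and acceptance runs use the sizes above (50-200 LOOCV splits,
pair pools up to ~6000, SVMs up to ~400 dual variables); these are the
package's chosen desk-scale study conditions.  Kernel symmetry is enforced
to 1e-8; PSD is accepted down to −1e-6 · max diagonal for gene kernels
(solvers tolerate near-PSD Grams), while the phenotype matrix — the one
input routinely indefinite in practice — is repaired by clipping negative
eigenvalues at zero and re-normalizing to unit diagonal, so the Dirac
addition in variant 4 always has relative weight 1.  Diseases missing from
a user phenotype matrix are an error in strict use; the lenient path gives
them a Dirac row.

## Known limitations

- The unlabeled pool construction for variants 2-4 (all training diseases
  plus the query) is one reasonable choice among several; pool design can
  affect absolute ranks.
- Scores are SVM decision values: comparable within one ranking, not
  calibrated probabilities across diseases or runs.
- No model serialization; rankings are recomputed per query.
- MKL weight optimization, one-class baselines and label-propagation
  baselines are out of scope.
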