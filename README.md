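# prodige

Disease-gene prioritization by **positive-unlabeled (PU) learning** with
multitask sharing across diseases.

## The problem

Given a set of genes 𝒢 = {G₁,…,G_N}, a set of diseases 𝒟 = {D₁,…,D_M},
and a table of known disease-gene associations, rank the candidate genes
U_i = 𝒢 \ P_i of each disease D_i so that its still-unknown causal genes
land near the top.  Known disease genes are *positive* examples; every other
gene is *unlabeled* — it may be an undiscovered disease gene, so treating it
as a negative is wrong.  This package is for computational biologists and
statistical-genetics methodologists who need a prioritizer that (a) learns
from positives *and* the distribution of unlabeled genes, (b) fuses
heterogeneous gene-similarity sources, and (c) can borrow known genes from
phenotypically similar diseases — including for **orphan diseases** with no
known gene at all.

## The method

- **Gene kernels.** Each data source gives a kernel K(G,G′) = Φ(G)ᵀΦ(G′)
  (inner products of feature vectors, or a heat-diffusion kernel
  exp(−βL) on an interaction graph).  Sources are normalized to unit
  diagonal, K̃_ij = K_ij/√(K_ii K_jj), and fused by averaging,
  K_int = (1/L) Σ_ℓ K_ℓ.
- **PU engine.** A *bagging biased SVM*: for b = 1..B (default 30), draw a
  random subsample U_b ⊂ U (default size |P|), train a soft-margin SVM
  (precomputed kernel, cost C = 1, no intercept) labeling P positive and
  U_b negative, and score each unlabeled gene by its mean decision value
  over the rounds in which it was out of bag.
- **Multitask sharing.** Pairs (D,G) are scored with the tensor-product
  kernel K_pair((D,G),(D′,G′)) = K_disease(D,D′)·K_gene(G,G′).  Four
  disease kernels define four variants: (1) Dirac/identity — no sharing;
  (2) 1 + Dirac — uniform sharing; (3) a phenotype-similarity kernel;
  (4) phenotype + Dirac.  Variants 2-4 can rank genes for orphan diseases.
- **Evaluation.** Leave-one-out cross-validation over associations; the
  held-out gene's rank relates to ROC AUC by rank = (|U|+1)(1−AUC); recall
  at k / rank CDF curves; paired Wilcoxon signed-rank comparisons between
  variants; hypergeometric enrichment of top-k lists.
- **Synthetic benchmarks.** A generator plants disease-specific gene
  clusters in multiple feature sources, with disease centroids correlated
  according to a controllable phenotype informativeness, so every claim is
  testable without any external data.

## Worked example

```python
from prodige import (SyntheticConfig, generate, linear_kernel, loocv,
                     recall_curve, RunConfig)

bench = generate(SyntheticConfig(n_genes=200, n_diseases=10,
                                 genes_per_disease=5, signal_strength=3.0,
                                 seed=7))
kernels = [linear_kernel(t) for t in bench.feature_tables]
res = loocv(1, bench.genes, kernels, bench.associations, bench.phenotype,
            RunConfig(variant=1, B=30, seed=7))
print(len(res), res.median_rank, res.mean_rank)
print(recall_curve(res, [1, 10, "1%", "5%", "10%"]).as_dict())
```

prints

```
50 5.5 14.6
{'1': 0.2, '10': 0.62, '1%': 0.2, '5%': 0.62, '10%': 0.78}
```

i.e. across the 50 leave-one-out splits of the planted benchmark the
held-out causal gene has median rank 5.5 among ~196 candidates (a uniform
random ranker would give ~98), is ranked first 20% of the time and within
the top 10% of candidates 78% of the time.

The same pipeline is scriptable from the shell:

```bash
prodige simulate --out bench --seed 7
prodige rank --variant 3 --associations bench/associations.tsv \
    --gene-kernels bench/kernel_source0.tsv,bench/kernel_source1.tsv \
    --phenotype bench/phenotype.tsv --disease d000 --out ranks.tsv
prodige loocv --variant 1 --associations bench/associations.tsv \
    --gene-kernels bench/kernel_source0.tsv,bench/kernel_source1.tsv \
    --out loocv.tsv
prodige eval --ranks loocv.tsv --at 1,10,1%,5%,10%
```

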