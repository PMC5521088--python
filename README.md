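# nogoa

Predict **noisy Gene Ontology annotations** — gene–term associations that
appear in one GOA release but are removed from a later one — so they can be
flagged or stripped before enrichment analysis, semantic-similarity
computation or function prediction.

Most quality-control work on GO annotations replenishes *missing*
annotations; this package addresses the converse, rarely studied problem of
identifying *incorrect* ones. It fuses two independent signals:

1. **Sparse-representation similarity votes.** With `A ∈ {0,1}^{N×|T|}` the
   true-path-propagated gene–term matrix, each gene's row is reconstructed
   as a sparse nonnegative combination of the other genes' rows,

   ```
   γ̂ᵢ = argmin_{γ ≥ 0}  ½‖A(i,·) − γᵀ Ā^i‖₂² + λ‖γ‖₁
   ```

   and the coefficients, symmetrised into `S = (S + Sᵀ)/2` with a zero
   diagonal, act as a semantic similarity that is robust to the noisy
   entries it is trying to find. Aggregated votes
   `V_SR(i,t) = Σⱼ S(i,j)·A(j,t)` behave like a weighted kNN: an annotated
   term rarely carried by the gene's neighbours gets a low vote.

2. **Evidence-code reliability weights.** Comparing successive archived GOA
   releases, the fraction of direct annotations tagged with evidence code
   `c` that disappeared estimates its noise ratio `r(c) = N̄(c)/N(c)`.
   Ratios averaged over `l` prior release pairs are thresholded at their
   mean τ: unstable codes (`r̃ ≥ τ`) are down-weighted to `θ < 1`. Weights
   attach to direct annotations (max over a pair's codes) and propagate to
   ancestors with the max rule, giving `A_ec`.

The fused score `V(i,t) = α·V_SR(i,t) + (1−α)·A_ec(i,t)` ranks each gene's
annotated terms; the lowest-scoring ones (per-gene `q` lowest, or everything
below a cut, 0.45 by default) are flagged noisy, together with their
annotated descendants — by the true path rule an annotation cannot survive
the removal of its ancestor. `α = 0` reduces to the evidence-only ranking
(EC), `α = 1` to the similarity-only ranking (SR). Defaults: `α = 0.2`,
`θ = 0.5`, `λ = 0.5`.

## Worked example

Everything is testable without downloads through the synthetic generator,
which emulates the archived-release setting: a layered DAG, cluster-
structured gene annotations with 10% off-profile "true noise" tagged with a
noisier evidence-code mix, and a recent release derived by per-code removal
(elevated for off-profile records).

```python
from nogoa import SimConfig, benchmark_seed

run = benchmark_seed(7, cfg=SimConfig(n_terms=120, n_genes=60,
                                      n_clusters=4, directs_per_gene=5))
print(run.weights.table.loc[["IEA", "IDA", "TAS"]][["n", "n_noisy", "r_tilde", "w"]])
print("tau =", round(run.weights.tau, 4))
for method, res in sorted(run.results.items()):
    print(f"{method:7s} P={res.precision:.3f} R={res.recall:.3f} F1={res.f1:.3f}")
```

prints

```
        n  n_noisy   r_tilde    w
code
IEA   104       44  0.423077  0.5
IDA   109        9  0.082569  1.0
TAS    87       16  0.183908  1.0
tau = 0.2299
EC      P=0.430 R=0.719 F1=0.519
LF      P=0.308 R=0.308 F1=0.308
NoGOA   P=0.579 R=0.587 F1=0.582
Random  P=0.288 R=0.670 F1=0.395
SR      P=0.366 R=0.378 F1=0.372
```

Reading it: the estimation release pair shows IEA annotations vanishing at
42% against a mean of 23%, so IEA is down-weighted to θ = 0.5. With the
per-gene oracle `q` (the true number of removed annotations), the fused
detector (`NoGOA`) recovers the injected noise with F1 = 0.58, ahead of the
evidence-only (EC), similarity-only (SR), lowest-frequency (LF) and random
baselines — the evidence signal knows *which codes* are unreliable, the
similarity signal knows *which terms* don't fit the gene's neighbourhood,
and the fusion needs both.

Real data goes through the CLI (two GO releases, two or more GAF releases):

```bash
nogoa predict --obo-old go_may.obo --obo-new go_sep.obo \
      --gaf-old goa_may.gaf --gaf-new goa_sep.gaf \
      --gaf-history goa_jan.gaf --branch BP --mode threshold \
      --out noisy_annotations.tsv
nogoa simulate --out-dir demo/          # synthetic OBO + GAF dataset
```

There is also an estimator-style API
(`nogoa.NoisyAnnotationDetector(alpha=0.2).fit_predict(A)`) that follows
scikit-learn conventions.

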