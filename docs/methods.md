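# Methods

## Problem and model

GO annotations associate genes with ontology terms; a sizeable fraction of
them — particularly electronically inferred ones — are later retracted. We
operationalise "noisy annotation" as *present in a historical GOA release,
absent from a recent one*, an observable proxy that also provides labels for
evaluation. Annotation matrices live in propagated (true-path) space: a gene
annotated with a term is annotated with every ancestor of it along is_a and
part_of paths, and branch roots are excluded (every annotated gene trivially
reaches its root, which therefore carries no information and can never be a
meaningful noisy annotation).

Detection fuses two scores computed on the historical release:

* **Similarity votes.** Each propagated row is sparse-coded against the
  other genes' rows under a nonnegative l1 penalty; the coefficients,
  symmetrised with a zero diagonal, act as a semantic similarity and the
  matrix product `V_SR = S·A` gives per-entry neighbourhood support. Sparse
  coding (rather than cosine or count-based measures) is chosen because the
  association matrix is itself sparse with noisy entries, the very setting
  sparse representation handles well. A gene with no semantically similar
  genes receives a near-zero similarity row and hence uniformly low votes;
  the selection protocol mitigates this by ranking only within the gene's
  own annotated terms.
* **Evidence weights.** Per branch, the fraction of direct annotations with
  evidence code c that disappear across a release pair estimates the code's
  noise ratio; ratios are averaged over `l` prior pairs, thresholded at
  their own mean, and unstable codes are down-weighted. Weights attach to
  direct annotations and propagate to ancestors by maximum, so an
  ancestor — which is easier to verify and supported by every descendant —
  is never weighted below a descendant.

The fused score is the affine combination `V = α·V_SR + (1−α)·A_ec`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ | 0.5 | l1 weight of the sparse coder; performance is stable over [0.1, 1] and the default is the midpoint of that range |
| α | 0.2 | fusion weight; 0 = evidence-only (EC), 1 = votes-only (SR); values in [0.1, 0.3] behave similarly |
| θ | 0.5 | down-weight applied to unstable evidence codes |
| τ | data-driven | mean of averaged ratios over codes observed in the estimation window |
| l | 1 | number of prior release pairs averaged for the ratios |
| v_cut | 0.45 | threshold-mode score cut; with α=0.2, θ=0.5 it flags exactly the entries at the gene's lowest evidence weight whose votes fall below 0.25 |

## Numerical choices

* The sparse coder minimises `½‖A(i,·) − γᵀĀ^i‖² + λ‖γ‖₁` with `γ ≥ 0`
  (the standard squared-loss lasso; an unsquared residual would change the
  meaning of λ). The solver is scikit-learn's nonnegative coordinate
  descent followed by exact coordinate-descent polishing; the contract is
  the KKT condition (residual ≤ 1e−4, polished to 1e−6), not a named
  algorithm, and tests verify objective agreement (≤ 1e−6) with an
  independent projected-gradient solver. Coefficients below 1e−10 are
  reported as exact zeros.
* Noisiness in ratio estimation is decided on direct (gene, term) pairs
  only, and pair presence in the newer release is code-agnostic: an
  annotation that merely changed evidence code during re-curation is not
  counted as noise.
* Codes with no annotations in the estimation window keep weight 1 (with a
  warning) and are excluded from the τ mean; ties `r̃ = τ` fall on the
  down-weighted side (codes at or above the average are unstable).
* Ranking ties in q-selection break lexicographically by term id, making
  selections deterministic and order-independent; the Random and LF
  baselines draw from a seeded generator.
* Per-gene F1 is defined 0 when precision + recall = 0; genes with no noise
  label are excluded from the averages (the evaluation protocol sets q from
  the true noisy count, so those genes make no predictions and their
  precision would be undefined).
* Degenerate (never-annotated) terms are dropped from per-term averages in
  the function-prediction metrics; Fmax/Smin use a 0.01-spaced threshold
  grid and information content −log(term frequency in the truth matrix).

## Synthetic data: what it emulates and what it does not

The generator produces a layered random is_a DAG (geometric layer growth,
1–2 parents per term), genes partitioned into functional clusters that own
disjoint pools of leaf terms, and per-gene direct annotations drawn from the
cluster pool. With probability `profile_noise` (default 0.1) a draw is
swapped for another cluster's term — the injected "true noise" — and tagged
from a noisier evidence-code mix (70% IEA) than on-profile annotations
(40% IDA / 30% TAS / 30% IEA). The recent release removes each record
independently: base rates {IEA 0.2, IDA 0.05, TAS 0.1}, elevated to 0.9 for
off-profile records, coupling injected noise with disappearance the way
archived GOA pairs couple instability with retraction. Ratio estimation
uses an independent replicate release pair (different sub-seed), standing in
for the earlier-in-the-year archives, so estimation never sees the
evaluation pair.

This emulation gives the two signals exactly the structure the method
assumes: cluster-mates make sparse-representation votes informative, and the
code-skewed noise makes evidence ratios informative. Real GOA data differs
in ways the simulation does not model: GO's heavy-tailed term depth and
information-content distributions, annotation biases toward well-studied
genes, evidence codes whose reliability varies by branch, and noise that is
correlated across genes (e.g. a retracted high-throughput experiment).
Passing the synthetic benchmark therefore shows the machinery implements the
model correctly and that fusion helps when both signals carry information —
not that the specific F1 levels transfer to any particular species.

Default study size is 300 genes × 400 terms × 10 clusters with 8 direct
annotations per gene; the benchmark averages 20 seeds in the test suite and
10 in the acceptance script. These sizes give stable method orderings while
keeping a full run in the tens of seconds.

## Design choices

* is_a and part_of are both treated as containment (propagating) relations;
  regulates-type relations are not. The relation set is a parameter of
  `parse_obo` so part_of can be excluded.
* NOT-qualified and ND-evidence GAF records are dropped by default (negative
  annotations are not annotations in the matrix sense; ND annotates roots
  only); both filters are switchable.
* Duplicate gene–term pairs collapse to one entry with the union of their
  evidence codes; weighting then takes the maximum code weight, since
  independent supporting evidence should raise, not lower, confidence.
* Gene identity is GAF column 2 (DB Object ID); alt_id term aliases resolve
  to their primary id; obsolete terms are recorded but excluded from all
  matrices.
* q-mode (per-gene q lowest scores, q from the labels) is the evaluation
  protocol; threshold mode (V < 0.45) is the production protocol used when
  no labels exist. Descendant-expanded selections are flagged `inherited`
  and counted like direct ones in evaluation — both live in propagated
  space.
* The estimator layer (`NoisyAnnotationDetector`) is transductive, like
  scikit-learn's `LocalOutlierFactor`: `fit` scores the matrix it was given
  and `fit_predict` returns the flagged-entry mask.

## Known limitations

* A noisy annotation that persists across releases and is common among a
  gene's neighbours is invisible to both signals by construction.
* The removal-based labels conflate genuine error correction with other
  curation churn; this is inherent to the operational definition.
* On the synthetic benchmark the downstream majority-vote demo shows only
  marginal, mixed effects of threshold-mode cleanup (Smin improves slightly,
  term-averaged AUROC does not): false flags remove genuinely stable
  annotations and offset the benefit of removing injected noise. The demo
  is reported as computed.
* The dense N×N similarity and per-gene lasso solves scale to thousands of
  genes comfortably but not to whole-proteome matrices without blocking or
  sparsification.
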