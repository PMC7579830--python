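# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not demonstrate.

## Similarity kernels

**GIP kernel.** For miRNAs, `GM(rᵢ,rⱼ) = exp(−α_r ‖IV(rᵢ) − IV(rⱼ)‖²)` on
rows of the association matrix, with `α_r = α_{r0} / meanᵢ ‖IV(rᵢ)‖²` and
initial bandwidth `α_{r0} = 1`. The disease-side kernel mirrors this on
columns with `α_{d0} = 1`. An all-zero profile set makes the bandwidth
undefined and raises a degenerate-input error naming the offending side.

**Wang semantic similarity.** Within a disease's ancestor DAG, the disease
contributes 1 and each ancestor contributes
`max{Δ · contribution(child)}` over its children in the DAG, so an ancestor
at shortest downward distance k contributes `Δᵏ`. Δ (the semantic
contribution delay factor) defaults to **0.5**, the standard value in this
similarity family; it is configurable (`delta`). Similarity of two diseases
is the sum of both contributions over shared terms divided by the sum of
both semantic values. Cyclic DAGs and terms with no downward path to the
disease are rejected.

**Xuan semantic similarity.** A term appearing in k of the n disease DAGs
contributes `−log(k/n)` (information content, independent of the target
disease); a disease's semantic value is the sum over its DAG terms, and the
similarity formula mirrors the decay-based one. The logarithm base is
natural by default; the similarity is provably base-invariant (a common
factor cancels), which the tests verify, so this choice is cosmetic.

**Integration.** MiRna similarity uses functional similarity where *both*
miRNAs appear in the FS data (self-similarity forced to 1) and the GIP
kernel elsewhere; disease similarity uses the average of the two semantic
measures where both diseases have a DAG, GIP elsewhere. Integration is a
pure elementwise case split and is idempotent for a fixed mask.

## Network and meta-paths

The heterogeneous network has miRNA and disease nodes and three undirected
edge classes: M–D where `A = 1`, and M–M / D–D where the off-diagonal
integrated similarity is ≥ `sim_threshold` (default **0.5**). The threshold
discretizes the dense similarity matrices; without it, instance enumeration
grows combinatorially. Similarity values are used only for thresholding —
edges are unweighted.

Meta-path types are all node-class sequences of length 1..`max_length`
(`Σ 2^{l+1}` of them; 28 at the default `max_length = 3`). Instances are
enumerated exhaustively by vectorized frontier expansion over a CSR
adjacency; **simple paths only** by default (a repeated node adds only
information already present in shorter paths). Instances are extracted from
*every* node — both miRNAs and diseases are embedding targets; the
miRNA-to-disease direction enters at scoring time. Enumeration order is
deterministic given the input ordering, and the test suite checks exact
agreement with a recursive DFS oracle on random networks.

With the default synthetic data the exhaustive length-3 instance set runs to
~4·10⁵ instances. Training (not extraction) optionally subsamples each
(target, type) group to at most `max_instances_per_group` instances with a
seeded draw; the evaluation profile uses 8. This bounds per-node encoder
work while keeping every type represented.

## Encoder and loss

Raw node features are the rows of the integrated similarity matrices (a
miRNA's feature has dimension m, a disease's n); separate learnable matrices
project both into a shared z-dimensional space, z = **64** by default. The
per-instance mean encoder includes the target and the neighbour. Instance
attention computes `ReLU(att_P · [h_u ‖ h_u^p])`, softmax-normalized with
max-subtraction over the type's instances, and squashes the weighted sum
with a sigmoid. One instance-attention vector is learned **per meta-path
type** and shared by all its instances: per-instance parameters could not be
shared or learned across targets, so the per-type vector is the standard
heterogeneous-attention reading. Type fusion scores each per-type vector
with `ReLU(att'_P · h_u^P)` and combines with the **normalized** softmax
weights (the unnormalized scores would make the normalization step dead
code). No sigmoid is applied after type fusion. Targets with no instances
of any type fall back to their transformed feature vector, which keeps
isolated and deliberately zeroed (new-disease) nodes scoreable.

The loss is `Σ_pos log σ(dist) − Σ_neg log σ(dist)` with Manhattan distance;
minimizing drives positive-pair distances toward 0 (term → log ½) and
negative-pair distances up (term → 0). Positives are all edges of the
heterogeneous network (associations plus thresholded similarity pairs);
negatives are unknown miRNA–disease pairs sampled uniformly at a 1:1 ratio
to positives, re-sampled every epoch from the run seed. The "low
similarity" qualifier for negatives has no stated cutoff, so the uniform
unknown-pair sampler is used as the simplest admissible reading.

### Numerical choices

* Softmax always uses max-subtraction; `ReLU` outputs 0 at exactly 0 and its
  derivative is taken as 0 there. The Manhattan-distance subgradient uses
  `sign`, which is 0 at ties (measure-zero under continuous initialization).
* All gradients are hand-derived and computed with NumPy segment operations
  (`reduceat` over contiguous (target, type) groups); the test suite checks
  every parameter block against central finite differences at 1e-4 relative
  tolerance on a 6-node toy network.
* Optimization is Adam (β₁ = 0.9, β₂ = 0.999). Initialization is seeded
  uniform, scaled by 1/√fan-in.
* The monitored loss (all positives plus one fixed reference negative
  sample) is evaluated after each epoch, and the returned state is the one
  minimizing it, so the reported final loss never exceeds the initial loss.
* Training aborts with a diagnostic if the loss becomes non-finite; the
  returned state is checked finite.

### Default hyperparameters

`TrainConfig` defaults: z = 64, learning rate 0.005, 100 epochs, batch 64,
negative ratio 1.0, no instance cap — suitable for small inputs and
unambiguous semantics. The evaluation profile (`default_cv_config`) is
sized so that a full train plus fivefold cross-validation runs in minutes on
one CPU: 40 epochs, batch 256, Adam learning rate 0.02, instance cap 8.
The epoch count matters for the attention comparison: with too few epochs
the attention parameters are still underfit and the attention model can
trail the mean-encoder ablation, so the profile is sized for both variants
to converge.

## Evaluation protocols

* **k-fold CV** partitions the verified associations (only) into k
  near-equal groups by seeded shuffling; for each fold, held-out positives
  are zeroed in `A`, and *every* stage — GIP kernels, integrated similarity,
  network, meta-path instances, training — is recomputed from the training
  matrix, so held-out pairs cannot leak. Held-out positives are scored
  against all pairs unverified in the full data set. Repeats are averaged;
  the default is 1 repeat in the evaluation profile and configurable
  (`--repeats`) up to the conventional 100.
* **Global LOOCV** retrains per held-out pair and ranks it among the
  unverified pairs of the same disease, pooling into one AUC. This is the
  faithful-but-slow default; `max_folds` caps the number of held-out pairs
  for smoke runs, and `reuse_similarity` reproduces the cheaper variant that
  computes similarities once from the full matrix (leaky; comparison only).
* **Case study (new disease).** All associations of one disease are zeroed,
  the model is retrained, and all miRNAs are ranked for that disease;
  the default candidate list is the top 50.
* **AUC** is the Mann–Whitney statistic with midranks (scikit-learn),
  verified exactly against an O(n²) pair-counting oracle including ties.
* **Ablation** replaces both attention stages with unweighted means (the
  instance stage keeps its sigmoid); the result is independent of the
  attention parameters.

## Synthetic benchmark: what it shows and what it cannot

The generator plants the method's own premise — functionally related miRNAs
associate with similar diseases — as a two-sided block model: 40 miRNAs and
30 diseases in 2 blocks; associations Bernoulli(0.3) within and
Bernoulli(0.02) across blocks; functional similarity = block indicator +
truncated Gaussian noise (sd 0.1, clipped to [0,1], unit diagonal); disease
DAGs share a per-block ancestor chain of depth 3. Everything is reproducible
from one seed.

Passing the pipeline tests on this data shows that the implementation
recovers planted community structure through the full similarity → network →
meta-path → attention-embedding → CV chain, deterministically and without
fold leakage. It does **not** show real-data performance: the generator has
no degree heterogeneity, no miRNA families, no MeSH-like deep ontology, and
its noise model is far simpler than curation noise in HMDD.

One structural property deserves emphasis: given block membership, planted
associations are *independent* Bernoulli draws, so no method can distinguish
a held-out positive from a within-block unverified pair. An oracle scoring
pairs by perfect block membership attains mean fivefold AUC ≈ 0.755 over
seeds 1–5 (≈42% of unknown-pair negatives are within-block and
information-theoretically indistinguishable from held-out positives). The
trained model's mean fivefold AUC of ≈ 0.746 therefore sits essentially at
the Bayes-optimal ceiling of this generator — useful to keep in mind when
interpreting absolute AUC values on the benchmark. With deeper semantic
structure (DAG depth 3, Δ = 0.5) the disease–disease semantic similarity of
two distinct diseases is bounded above by 0.5, so at the default threshold
the synthetic network typically has no D–D edges; block signal flows through
M–M and M–D edges.

### Problem sizes used

Tests and the acceptance script run the synthetic defaults (40×30, ~190
positives, ~4·10⁵ exhaustive instances capped at 8 per group for training)
over seeds 1–5: full fivefold CV for the headline number and single-fold
runs for the ablation and length comparisons. These sizes complete the whole
suite in a couple of minutes on one CPU while keeping every pipeline stage —
including per-fold recomputation — fully exercised.

## Known limitations

* Attention parameters are per meta-path type, not per instance; this is a
  deliberate reading (see above) and matches how such attention is usually
  shared, but it is not the only possible one.
* The LOOCV negative pool (same-disease unverified pairs) and the k-fold
  pool (all unverified pairs) are documented choices; no canonical
  definition exists.
* CPU-only, single-process; exhaustive enumeration at real-data scale
  (length 3 on an HMDD-sized network) is a multi-day computation.
* The miRNA functional-similarity matrix is consumed, never recomputed.
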