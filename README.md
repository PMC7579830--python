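# m2gmda

Multiple meta-paths fusion graph embedding for miRNA–disease association
prediction.

MicroRNAs regulate protein-coding genes and are implicated in a wide range of
human diseases, but confirming an individual miRNA–disease association
experimentally is slow and expensive. `m2gmda` predicts unverified
associations computationally: it embeds miRNAs and diseases into a shared
latent space using the structure of a heterogeneous network built from
verified associations and similarity data, then ranks candidate pairs by
embedding distance. It is aimed at computational biologists who work with
association databases such as HMDD and want a self-contained, testable
implementation of meta-path attention embedding — including a synthetic
benchmark that exercises every stage without any download.

## The model

**Inputs.** A binary association matrix `A ∈ {0,1}^{m×n}` (rows miRNAs,
columns diseases), a miRNA functional-similarity matrix `FS`, and per-disease
MeSH-like ancestor DAGs.

**Similarity integration.** Where `FS` is undefined, miRNA similarity falls
back to the Gaussian interaction profile (GIP) kernel on rows of `A`:

    GM(rᵢ, rⱼ) = exp(−α‖IV(rᵢ) − IV(rⱼ)‖²),   α = α₀ / meanᵢ‖IV(rᵢ)‖²,  α₀ = 1.

Disease similarity averages two DAG-based semantic measures — decayed
ancestor contributions (contribution 1 at the disease, factor Δ = 0.5 per
level up) and information content (−log of the fraction of disease DAGs
containing a term) — with the GIP kernel on columns of `A` as fallback.

**Heterogeneous network and meta-paths.** Nodes are miRNAs (M) and diseases
(D); edges are verified associations (M–D) plus similarity pairs at or above
a threshold (M–M, D–D; default 0.5). A *meta-path type* is a node-class
sequence such as M→D→M→D; a *meta-path instance* is a concrete simple path
following it. All instances up to length 3 (default) are enumerated
exhaustively from every node.

**Encoder.** Raw features (rows of the integrated similarity matrices) are
linearly mapped to a z = 64 dimensional space (`h = Wx`). Each instance is
summarized by the mean of its node vectors; instances of one type are fused
by graph attention, `h_u^P = σ(Σₚ wₚ h_u^p)` with
`wₚ = softmax(ReLU(att_P · [h_u ‖ h_u^p]))`; types are fused by a second
attention over `ReLU(att'_P · h_u^P)`. Nodes with no meta-path instances
keep their transformed features, so new diseases remain scoreable.

**Training and scoring.** Parameters minimize the contrastive loss

    Loss = Σ_{(u,v)∈𝒫} log σ(dist(u,v)) − Σ_{(u,v)∈𝒩} log σ(dist(u,v)),

with `dist` the Manhattan distance, 𝒫 the connected pairs of the network and
𝒩 uniformly re-sampled unknown miRNA–disease pairs. Gradients are analytic
(NumPy), verified against finite differences in the test suite; optimization
is seeded mini-batch Adam. A pair's association score is the negated
Manhattan distance between final embeddings.

## Worked example

```python
from m2gmda import SyntheticConfig, generate, CVScheme, run_cv, case_study
from m2gmda.evaluation import default_cv_config

A, fs, dags = generate(SyntheticConfig(seed=1))   # planted two-block data
result = run_cv(A, fs, dags, CVScheme(kind="kfold", k=5, repeats=1, seed=1),
                default_cv_config(seed=1))
print(f"fivefold CV AUC: {result.auc:.4f}")
top = case_study(A, fs, dags, "disease-003", default_cv_config(seed=1), top_k=5)
print(top.to_string(index=False))
```

prints

```
fivefold CV AUC: 0.7654
 rank     miRNA     disease      score
    1 mirna-014 disease-003 -35.568157
    2 mirna-016 disease-003 -35.572420
    3 mirna-012 disease-003 -35.575215
    4 mirna-006 disease-003 -35.575717
    5 mirna-015 disease-003 -35.575951
```

The synthetic data set plants 174 associations between 40 miRNAs and 30
diseases in two blocks. The fivefold AUC of 0.77 means held-out verified
pairs rank well above the average unverified pair — close to the theoretical
optimum for this generator, whose only recoverable signal is block
membership (a perfect block oracle scores ≈ 0.755 on these seeds; see
`docs/methods.md`). The case-study rows are the top candidate miRNAs for a
disease whose known associations were zeroed before retraining, emulating a
disease with no verified miRNAs; higher (less negative) scores mean closer
embeddings.

The same pipeline runs from the shell:

```sh
m2gmda synth --out-assoc assoc.tsv --out-fs fs.csv \
       --out-dag-edges dags.tsv --out-dag-manifest diseases.txt --seed 1
m2gmda cv --assoc assoc.tsv --fs fs.csv --dag-edges dags.tsv \
       --dag-manifest diseases.txt --out metrics.json --seed 1
```

See `m2gmda --help` for the other verbs (`similarity`, `build-net`, `paths`,
`train`, `predict`, `case-study`).

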