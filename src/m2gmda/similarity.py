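"""Similarity kernels for miRNAs and diseases.

Three ingredients feed the heterogeneous network:

* **Gaussian interaction profile (GIP) kernel** similarity, computed on the
  rows (miRNAs) or columns (diseases) of the binary association matrix with a
  data-normalized bandwidth,

      GM(r_i, r_j) = exp(-alpha * ||IV(r_i) - IV(r_j)||^2),
      alpha = alpha0 / mean_i ||IV(r_i)||^2,   alpha0 = 1 by default.

* **Wang semantic similarity** between diseases, from decayed contributions of
  shared ancestors in per-disease DAGs: the disease itself contributes 1 and
  each ancestor contributes ``max(delta * contribution(child))`` over its
  children inside the DAG.

* **Xuan semantic similarity**, the information-content variant: a term's
  contribution is -log(fraction of disease DAGs containing it), so rare,
  specific ancestors weigh more.

The integrated miRNA similarity SM uses functional similarity where defined
and the GIP kernel elsewhere; the integrated disease similarity SD uses the
average of the two semantic measures where both diseases have a DAG and the
GIP kernel elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import DataError, DegenerateInputError, InvalidDAGError

DEFAULT_ALPHA0 = 1.0
DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class KernelBandwidth:
    """GIP kernel bandwidth: the initial value and its profile-normalized form."""

    alpha0: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0):
            raise DataError("alpha0 must be positive")
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise DataError("normalized bandwidth must be finite and positive")


def gip_bandwidth(
    profiles: np.ndarray, alpha0: float = DEFAULT_ALPHA0, name: str = "profiles"
) -> KernelBandwidth:
    """Normalize the initial bandwidth by the mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise DataError("profiles must be a nonempty 2-d array")
    mean_sq = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq == 0.0:
        raise DegenerateInputError(
            f"all interaction profiles of {name} are zero; "
            "GIP bandwidth is undefined"
        )
    return KernelBandwidth(alpha0=float(alpha0), alpha=float(alpha0) / mean_sq)


def gip_similarity(
    A: AssociationMatrix, axis: str = "mirna", alpha0: float = DEFAULT_ALPHA0
) -> SimilarityMatrix:
    """GIP kernel similarity over rows (miRNAs) or columns (diseases) of A."""
    if axis == "mirna":
        profiles, labels = A.values.astype(float), A.mirna_names
    elif axis == "disease":
        profiles, labels = A.values.T.astype(float), A.disease_names
    else:
        raise DataError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    bw = gip_bandwidth(profiles, alpha0, name=f"{axis} side of association matrix")
    sq_norms = (profiles**2).sum(axis=1)
    # ||x_i - x_j||^2 = ||x_i||^2 + ||x_j||^2 - 2 x_i.x_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-bw.alpha * d2)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(labels)).validate()


def _check_acyclic(dag: DiseaseDAG) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise InvalidDAGError(f"DAG for {dag.disease!r} contains a cycle")


def wang_contributions(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> DiseaseDAG:
    """Decay-based ancestor contributions and the resulting semantic value.

    The disease itself contributes 1; every ancestor contributes the maximum
    of ``delta`` times its children's contributions, i.e. ``delta**k`` for an
    ancestor whose closest descending path to the disease has k edges.
    """
    if not (0 < delta <= 1):
        raise DataError(f"delta must be in (0, 1], got {delta}")
    _check_acyclic(dag)
    contrib: dict[str, float] = {}

    def value(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term == dag.disease:
            contrib[term] = 1.0
            return 1.0
        kids = dag.children(term)
        vals = [delta * value(c) for c in kids]
        vals = [v for v in vals if v > 0.0]
        if not vals:
            raise InvalidDAGError(
                f"term {term!r} in DAG for {dag.disease!r} has no path to the disease"
            )
        contrib[term] = max(vals)
        return contrib[term]

    # Descendants of D inside an ancestor DAG would be anomalous; every node
    # must reach D going downwards.
    for term in sorted(dag.nodes):
        value(term)
    return DiseaseDAG(
        disease=dag.disease,
        nodes=dag.nodes,
        edges=dag.edges,
        contributions1=contrib,
        contributions2=dict(dag.contributions2),
        semantic_value1=float(sum(contrib.values())),
        semantic_value2=dag.semantic_value2,
    )


def wang_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Shared-ancestor similarity from the decay-based contributions."""
    if not dag_i.contributions1 or not dag_j.contributions1:
        raise DataError("wang_contributions must be computed on both DAGs")
    shared = dag_i.nodes & dag_j.nodes
    num = sum(dag_i.contributions1[d] + dag_j.contributions1[d] for d in shared)
    den = dag_i.semantic_value1 + dag_j.semantic_value1
    if den <= 0:
        raise DataError("empty DAGs: zero total semantic value")
    return num / den


def xuan_contributions(
    dags: list[DiseaseDAG], base: float = math.e
) -> list[DiseaseDAG]:
    """Information-content contributions over a full DAG corpus.

    A term appearing in ``k`` of the ``n`` disease DAGs contributes
    ``-log(k / n)``.  The corpus must be the complete collection for the
    disease set, since ``n`` is the number of diseases.
    """
    if not dags:
        raise DataError("empty DAG corpus")
    n = len(dags)
    counts: dict[str, int] = {}
    for dag in dags:
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    log_base = math.log(base)
    out = []
    for dag in dags:
        contrib = {}
        for term in dag.nodes:
            k = counts.get(term, 0)
            if k == 0:
                raise DataError(f"term {term!r} appears in no DAG of the corpus")
            contrib[term] = -math.log(k / n) / log_base
        out.append(
            DiseaseDAG(
                disease=dag.disease,
                nodes=dag.nodes,
                edges=dag.edges,
                contributions1=dict(dag.contributions1),
                contributions2=contrib,
                semantic_value1=dag.semantic_value1,
                semantic_value2=float(sum(contrib.values())),
            )
        )
    return out


def xuan_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Shared-ancestor similarity from the information-content contributions."""
    if not dag_i.contributions2 or not dag_j.contributions2:
        raise DataError("xuan_contributions must be computed on both DAGs")
    den = dag_i.semantic_value2 + dag_j.semantic_value2
    if den == 0:
        raise DegenerateInputError(
            "both diseases have zero information content; similarity undefined"
        )
    shared = dag_i.nodes & dag_j.nodes
    num = sum(dag_i.contributions2[d] + dag_j.contributions2[d] for d in shared)
    return num / den


def _pairwise_matrix(dags: list[DiseaseDAG], fn) -> SimilarityMatrix:
    k = len(dags)
    values = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = fn(dags[i], dags[j])
    return SimilarityMatrix(values, [d.disease for d in dags]).validate()


def wang_matrix(dags: list[DiseaseDAG], delta: float = DEFAULT_DELTA) -> SimilarityMatrix:
    dags = [wang_contributions(d, delta) for d in dags]
    return _pairwise_matrix(dags, wang_similarity)


def xuan_matrix(dags: list[DiseaseDAG], base: float = math.e) -> SimilarityMatrix:
    dags = xuan_contributions(dags, base)
    return _pairwise_matrix(dags, xuan_similarity)


def combined_semantic(ss1: SimilarityMatrix, ss2: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of the two semantic similarity matrices."""
    if ss1.labels != ss2.labels:
        raise DataError("semantic similarity matrices have mismatched labels")
    return SimilarityMatrix(0.5 * (ss1.values + ss2.values), list(ss1.labels))


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Case-split integration: primary where defined, fallback elsewhere.

    ``primary.mask`` marks the defined entries; the output diagonal is forced
    to 1 (self-similarity).
    """
    if primary.labels != fallback.labels:
        raise DataError("integrated similarity inputs have mismatched labels")
    mask = (
        primary.mask
        if primary.mask is not None
        else np.ones_like(primary.values, dtype=bool)
    )
    values = np.where(mask, primary.values, fallback.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(primary.labels)).validate()


def _expand(
    sub: SimilarityMatrix, labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Embed a sub-matrix into the full label set; returns (values, mask)."""
    k = len(labels)
    values = np.zeros((k, k))
    mask = np.zeros((k, k), dtype=bool)
    pos = {lab: i for i, lab in enumerate(labels)}
    idx = np.array([pos[lab] for lab in sub.labels if lab in pos], dtype=int)
    keep = np.array([lab in pos for lab in sub.labels], dtype=bool)
    if idx.size:
        block = sub.values[np.ix_(keep, keep)]
        values[np.ix_(idx, idx)] = block
        mask[np.ix_(idx, idx)] = True
    return values, mask


def mirna_similarity(
    A: AssociationMatrix,
    fs: SimilarityMatrix | None,
    alpha0: float = DEFAULT_ALPHA0,
) -> SimilarityMatrix:
    """Integrated miRNA similarity SM: functional similarity where both
    miRNAs are covered by the FS data, GIP kernel similarity elsewhere."""
    gm = gip_similarity(A, axis="mirna", alpha0=alpha0)
    if fs is None:
        return gm
    values, mask = _expand(fs, A.mirna_names)
    primary = SimilarityMatrix(values, list(A.mirna_names), mask=mask)
    return integrate_similarity(primary, gm)


def disease_similarity(
    A: AssociationMatrix,
    dags: list[DiseaseDAG] | None,
    delta: float = DEFAULT_DELTA,
    alpha0: float = DEFAULT_ALPHA0,
) -> SimilarityMatrix:
    """Integrated disease similarity SD: averaged semantic similarity where
    both diseases have a DAG, GIP kernel similarity elsewhere."""
    gd = gip_similarity(A, axis="disease", alpha0=alpha0)
    if not dags:
        return gd
    dags = [d for d in dags if d.disease in set(A.disease_names)]
    if not dags:
        return gd
    ss = combined_semantic(wang_matrix(dags, delta), xuan_matrix(dags))
    values, mask = _expand(ss, A.disease_names)
    primary = SimilarityMatrix(values, list(A.disease_names), mask=mask)
    return integrate_similarity(primary, gd)
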