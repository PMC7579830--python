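"""The meta-path fusion graph-embedding model.

Encoder stack, for a target node u:

1. *Linear transform*: every node's raw feature (its row of the integrated
   similarity matrix SM or SD) is mapped into a shared z-dimensional latent
   space, ``h = W x``, with separate learnable matrices for miRNAs and
   diseases.
2. *Mean encoder*: each meta-path instance p starting at u is summarized as
   the arithmetic mean of the transformed vectors of all its nodes
   (target and neighbour included).
3. *Instance attention*: within one meta-path type P, instance scores
   ``e_p = ReLU(att_P . [h_u || h_u^p])`` are softmax-normalized over the
   type's instances and the weighted sum is squashed,
   ``h_u^P = sigmoid(sum_p w_p h_u^p)``.
4. *Type fusion*: per-type vectors are combined with a second attention,
   ``c_P = ReLU(att'_P . h_u^P)``, softmax over the types present for u,
   ``h_u = sum_P omega_P h_u^P``.  Targets with no instances fall back to
   their transformed feature vector so isolated/new nodes stay scoreable.

Training minimizes the contrastive objective

    Loss = sum_{(u,v) in Pos} log sigmoid(dist(u,v))
         - sum_{(u,v) in Neg} log sigmoid(dist(u,v)),

where ``dist`` is the Manhattan distance between final embeddings, Pos are
connected pairs of the heterogeneous network and Neg are uniformly sampled
unknown miRNA-disease pairs (re-sampled each epoch).  All gradients are
derived analytically and verified against finite differences in the test
suite; optimization is Adam with seeded mini-batches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import SimilarityMatrix
from .errors import ConfigError, DataError
from .network import (
    HeteroNetwork,
    MetaPathInstances,
    MetaPathType,
    enumerate_types,
)

DEFAULT_EMBED_DIM = 64


@dataclass
class FeatureSpace:
    """Raw node features: rows of SM for miRNAs, rows of SD for diseases."""

    mirna_features: np.ndarray
    disease_features: np.ndarray
    embed_dim: int = DEFAULT_EMBED_DIM

    def __post_init__(self) -> None:
        self.mirna_features = np.asarray(self.mirna_features, dtype=float)
        self.disease_features = np.asarray(self.disease_features, dtype=float)
        if self.embed_dim <= 0:
            raise ConfigError("embed_dim must be positive")

    @classmethod
    def from_similarity(
        cls, SM: SimilarityMatrix, SD: SimilarityMatrix, embed_dim: int = DEFAULT_EMBED_DIM
    ) -> "FeatureSpace":
        return cls(SM.values, SD.values, embed_dim)

    @property
    def n_mirnas(self) -> int:
        return self.mirna_features.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.mirna_features.shape[0] + self.disease_features.shape[0]


@dataclass
class TrainConfig:
    """Hyperparameters of the embedding model and its optimizer."""

    embed_dim: int = DEFAULT_EMBED_DIM
    learning_rate: float = 0.005
    epochs: int = 100
    batch_size: int = 64
    negative_ratio: float = 1.0
    max_instances_per_group: int | None = None
    attention: bool = True
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if self.negative_ratio < 0:
            raise ConfigError("negative_ratio must be >= 0")
        if not (self.learning_rate > 0):
            raise ConfigError("learning_rate must be positive")


class ModelState:
    """All learnable parameters, keyed layout:

    ``W_R`` (z, d_r), ``W_D`` (z, d_d), one instance-attention vector of
    length 2z per enumerated meta-path type and one type-attention vector of
    length z per type.
    """

    def __init__(
        self,
        W_R: np.ndarray,
        W_D: np.ndarray,
        att_instance: dict[MetaPathType, np.ndarray],
        att_type: dict[MetaPathType, np.ndarray],
        config: TrainConfig,
    ):
        self.W_R = np.asarray(W_R, dtype=float)
        self.W_D = np.asarray(W_D, dtype=float)
        self.att_instance = {t: np.asarray(v, dtype=float) for t, v in att_instance.items()}
        self.att_type = {t: np.asarray(v, dtype=float) for t, v in att_type.items()}
        self.config = config

    @classmethod
    def initialize(
        cls,
        features: FeatureSpace,
        types: list[MetaPathType],
        config: TrainConfig,
    ) -> "ModelState":
        rng = np.random.default_rng(config.seed)
        z = config.embed_dim
        d_r = features.mirna_features.shape[1]
        d_d = features.disease_features.shape[1]
        s = config.init_scale

        def unif(*shape, fan):
            return rng.uniform(-s, s, size=shape) / np.sqrt(fan)

        W_R = unif(z, d_r, fan=d_r)
        W_D = unif(z, d_d, fan=d_d)
        att_instance = {t: unif(2 * z, fan=2 * z).ravel() for t in types}
        att_type = {t: unif(z, fan=z).ravel() for t in types}
        return cls(W_R, W_D, att_instance, att_type, config)

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"W_R": self.W_R, "W_D": self.W_D}
        for t, v in self.att_instance.items():
            params[f"att_instance/{t}"] = v
        for t, v in self.att_type.items():
            params[f"att_type/{t}"] = v
        return params

    def copy(self) -> "ModelState":
        return ModelState(
            self.W_R.copy(),
            self.W_D.copy(),
            {t: v.copy() for t, v in self.att_instance.items()},
            {t: v.copy() for t, v in self.att_type.items()},
            copy.deepcopy(self.config),
        )

    def check_finite(self) -> None:
        for name, p in self.parameters().items():
            if not np.all(np.isfinite(p)):
                raise DataError(f"non-finite parameter block {name}")

    # --- JSON checkpointing -------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path) -> None:
        """Write a JSON checkpoint with version tag, seed and hyperparameters."""
        import dataclasses
        import json

        payload = {
            "format_version": self.CHECKPOINT_VERSION,
            "seed": self.config.seed,
            "hyperparameters": dataclasses.asdict(self.config),
            "W_R": self.W_R.tolist(),
            "W_D": self.W_D.tolist(),
            "att_instance": {
                "->".join(t.node_classes): v.tolist()
                for t, v in self.att_instance.items()
            },
            "att_type": {
                "->".join(t.node_classes): v.tolist()
                for t, v in self.att_type.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelState":
        import json

        from .network import MetaPathType

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != cls.CHECKPOINT_VERSION:
            raise DataError(
                f"unsupported checkpoint version {payload.get('format_version')!r}"
            )

        def key(s: str) -> MetaPathType:
            return MetaPathType(tuple(s.split("->")))

        return cls(
            np.array(payload["W_R"]),
            np.array(payload["W_D"]),
            {key(k): np.array(v) for k, v in payload["att_instance"].items()},
            {key(k): np.array(v) for k, v in payload["att_type"].items()},
            TrainConfig(**payload["hyperparameters"]),
        )


@dataclass
class EmbeddingSet:
    """Node embeddings at the two ends of the encoder stack."""

    transformed: np.ndarray  # h_u, (n_nodes, z)
    final: np.ndarray  # fused representation, (n_nodes, z)
    n_mirnas: int

    def mirna(self, i: int) -> np.ndarray:
        return self.final[i]

    def disease(self, j: int) -> np.ndarray:
        return self.final[self.n_mirnas + j]


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def transform(features: FeatureSpace, state: ModelState) -> np.ndarray:
    """Project all raw node features into the latent space; (n_nodes, z)."""
    if state.W_R.shape[1] != features.mirna_features.shape[1]:
        raise DataError("W_R width does not match miRNA feature dimension")
    if state.W_D.shape[1] != features.disease_features.shape[1]:
        raise DataError("W_D width does not match disease feature dimension")
    H_m = features.mirna_features @ state.W_R.T
    H_d = features.disease_features @ state.W_D.T
    return np.concatenate([H_m, H_d], axis=0)


def mean_encode(instance_nodes, transformed: np.ndarray) -> np.ndarray:
    """Mean of the transformed vectors of all nodes along one instance."""
    idx = np.asarray(instance_nodes, dtype=int)
    if idx.size == 0:
        raise DataError("empty meta-path instance")
    return transformed[idx].mean(axis=0)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _segment_softmax(e: np.ndarray, starts: np.ndarray, seg_id: np.ndarray) -> np.ndarray:
    """Softmax within contiguous segments, computed with max-subtraction."""
    emax = np.maximum.reduceat(e, starts)
    ex = np.exp(e - emax[seg_id])
    denom = np.add.reduceat(ex, starts)
    return ex / denom[seg_id]


def instance_attention(
    h_target: np.ndarray, instance_vecs: np.ndarray, att: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Attention aggregation of one (target, type) group.

    Returns (h^P, weights).  Reference implementation used by tests and by
    ablation comparisons; the training path computes the same quantities for
    all groups at once.
    """
    V = np.atleast_2d(np.asarray(instance_vecs, dtype=float))
    if V.shape[0] == 0:
        raise DataError("instance_attention needs at least one instance vector")
    pre = V @ att[len(h_target):] + h_target @ att[: len(h_target)]
    e = _relu(pre)
    starts = np.array([0])
    seg = np.zeros(V.shape[0], dtype=int)
    w = _segment_softmax(e, starts, seg)
    return expit(w @ V), w


def type_fusion(
    per_type_vecs: dict[MetaPathType, np.ndarray],
    att_type: dict[MetaPathType, np.ndarray],
) -> tuple[np.ndarray, dict[MetaPathType, float]]:
    """Attention fusion across meta-path types; returns (h, weights)."""
    if not per_type_vecs:
        raise DataError("type_fusion needs at least one meta-path type")
    types = sorted(per_type_vecs, key=lambda t: (t.length, t.node_classes))
    V = np.stack([per_type_vecs[t] for t in types])
    c = _relu(np.array([att_type[t] @ per_type_vecs[t] for t in types]))
    w = _segment_softmax(c, np.array([0]), np.zeros(len(types), dtype=int))
    return w @ V, dict(zip(types, w))


def manhattan(u: np.ndarray, v: np.ndarray) -> float:
    """L1 distance between two embedding vectors."""
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError("manhattan distance needs equal-length vectors")
    return float(np.abs(u - v).sum())


def _log_sigmoid(d: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -d)


def loss(pos_pairs, neg_pairs, embeddings: dict | np.ndarray) -> float:
    """Contrastive loss over positive and negative node pairs.

    ``embeddings`` maps node -> vector (dict or array indexed by node id).
    """
    if len(pos_pairs) == 0 and len(neg_pairs) > 0:
        raise DataError("positive pair set must be nonempty")

    def dists(pairs):
        return np.array([manhattan(embeddings[u], embeddings[v]) for u, v in pairs])

    total = 0.0
    if len(pos_pairs):
        total += float(_log_sigmoid(dists(pos_pairs)).sum())
    if len(neg_pairs):
        total -= float(_log_sigmoid(dists(neg_pairs)).sum())
    return total


# ---------------------------------------------------------------------------
# vectorized encoder over the whole instance set
# ---------------------------------------------------------------------------

class EncoderGraph:
    """Frozen segment layout of the instance set, shared by forward/backward."""

    def __init__(self, instances: MetaPathInstances):
        self.net = instances.net
        self.n_nodes = instances.net.n_nodes
        self.types: list[MetaPathType] = []
        self.paths: list[np.ndarray] = []
        self.seg_nodes: list[np.ndarray] = []
        self.seg_starts: list[np.ndarray] = []
        self.seg_id: list[np.ndarray] = []
        for mptype, paths in instances.by_type.items():
            if paths.shape[0] == 0:
                continue
            indptr = instances.indptr_by_type[mptype]
            counts = np.diff(indptr)
            nodes = np.flatnonzero(counts)
            nz = counts[nodes]
            starts = np.concatenate([[0], np.cumsum(nz)[:-1]])
            self.types.append(mptype)
            self.paths.append(paths)
            self.seg_nodes.append(nodes)
            self.seg_starts.append(starts.astype(np.int64))
            self.seg_id.append(np.repeat(np.arange(len(nodes)), nz))


def _scatter_add_rows(out: np.ndarray, idx: np.ndarray, rows: np.ndarray) -> None:
    """out[idx] += rows with duplicate indices, via sort + reduceat."""
    if idx.size == 0:
        return
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    rows_s = rows[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(idx_s)) + 1])
    sums = np.add.reduceat(rows_s, starts, axis=0)
    out[idx_s[starts]] += sums


def encode_all(
    state: ModelState,
    graph: EncoderGraph,
    H: np.ndarray,
    attention: bool = True,
) -> tuple[np.ndarray, dict]:
    """Forward pass of stages 2-4 for every node; returns (final, cache)."""
    z = H.shape[1]
    cache: dict = {"type": [], "attention": attention}
    entry_nodes, entry_type, entry_hP, entry_cpre = [], [], [], []
    for ti, mptype in enumerate(graph.types):
        P = graph.paths[ti]
        starts = graph.seg_starts[ti]
        seg_id = graph.seg_id[ti]
        M = H[P].mean(axis=1)
        if attention:
            a = state.att_instance[mptype]
            pre = H[P[:, 0]] @ a[:z] + M @ a[z:]
            e = _relu(pre)
            w = _segment_softmax(e, starts, seg_id)
        else:
            pre = e = None
            counts = np.diff(np.concatenate([starts, [P.shape[0]]]))
            w = 1.0 / counts[seg_id]
        s = np.add.reduceat(w[:, None] * M, starts, axis=0)
        hP = expit(s)
        cpre = hP @ state.att_type[mptype] if attention else np.zeros(hP.shape[0])
        cache["type"].append(
            {"M": M, "pre": pre, "w": w, "hP": hP, "slice_len": hP.shape[0]}
        )
        entry_nodes.append(graph.seg_nodes[ti])
        entry_type.append(np.full(len(graph.seg_nodes[ti]), ti, dtype=np.int64))
        entry_hP.append(hP)
        entry_cpre.append(cpre)

    final = H.copy()  # fallback for nodes with no instances
    if entry_nodes:
        nodes = np.concatenate(entry_nodes)
        tps = np.concatenate(entry_type)
        HP = np.concatenate(entry_hP, axis=0)
        cpre = np.concatenate(entry_cpre)
        order = np.argsort(nodes, kind="stable")
        nodes_s, tps_s, HP_s, cpre_s = nodes[order], tps[order], HP[order], cpre[order]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(nodes_s)) + 1])
        counts = np.diff(np.concatenate([starts, [len(nodes_s)]]))
        seg_id = np.repeat(np.arange(len(starts)), counts)
        if attention:
            c = _relu(cpre_s)
            om = _segment_softmax(c, starts, seg_id)
        else:
            om = 1.0 / counts[seg_id]
        fused = np.add.reduceat(om[:, None] * HP_s, starts, axis=0)
        uniq_nodes = nodes_s[starts]
        final[uniq_nodes] = fused
        cache["entries"] = {
            "order": order,
            "nodes_s": nodes_s,
            "tps_s": tps_s,
            "HP_s": HP_s,
            "cpre_s": cpre_s,
            "om": om,
            "starts": starts,
            "seg_id": seg_id,
            "uniq_nodes": uniq_nodes,
        }
    else:
        cache["entries"] = None
    return final, cache


def backward_all(
    state: ModelState,
    graph: EncoderGraph,
    H: np.ndarray,
    grad_final: np.ndarray,
    cache: dict,
) -> tuple[np.ndarray, dict[MetaPathType, np.ndarray], dict[MetaPathType, np.ndarray]]:
    """Backpropagate d Loss / d final into (gH, g_att_instance, g_att_type)."""
    attention = cache["attention"]
    z = H.shape[1]
    gH = np.zeros_like(H)
    g_att_inst = {t: np.zeros(2 * z) for t in state.att_instance}
    g_att_type = {t: np.zeros(z) for t in state.att_type}

    ent = cache["entries"]
    if ent is None:
        gH += grad_final
        return gH, g_att_inst, g_att_type

    # fallback nodes (no instances) pass the gradient straight through
    has_entries = np.zeros(graph.n_nodes, dtype=bool)
    has_entries[ent["uniq_nodes"]] = True
    gH[~has_entries] += grad_final[~has_entries]

    g_up = grad_final[ent["nodes_s"]]  # (E, z)
    om, starts, seg_id = ent["om"], ent["starts"], ent["seg_id"]
    gHP_s = om[:, None] * g_up
    if attention:
        t_e = (g_up * ent["HP_s"]).sum(axis=1)
        sdot = np.add.reduceat(om * t_e, starts)
        dc = om * (t_e - sdot[seg_id])
        dpre_c = dc * (ent["cpre_s"] > 0)
        AT = np.stack([state.att_type[t] for t in graph.types])
        gHP_s += dpre_c[:, None] * AT[ent["tps_s"]]
        gAT = np.zeros_like(AT)
        np.add.at(gAT, ent["tps_s"], dpre_c[:, None] * ent["HP_s"])
        for ti, mptype in enumerate(graph.types):
            g_att_type[mptype] += gAT[ti]

    # undo the node sort, split per type
    gHP = np.empty_like(gHP_s)
    gHP[ent["order"]] = gHP_s
    offset = 0
    for ti, mptype in enumerate(graph.types):
        tc = cache["type"][ti]
        k = tc["slice_len"]
        gHP_t = gHP[offset : offset + k]
        offset += k
        P = graph.paths[ti]
        starts_t = graph.seg_starts[ti]
        seg_t = graph.seg_id[ti]
        M, w, hP = tc["M"], tc["w"], tc["hP"]
        gs = gHP_t * hP * (1.0 - hP)
        gs_rows = gs[seg_t]
        gM = w[:, None] * gs_rows
        if attention:
            a = state.att_instance[mptype]
            t_p = (gs_rows * M).sum(axis=1)
            sdot = np.add.reduceat(w * t_p, starts_t)
            de = w * (t_p - sdot[seg_t])
            dpre = de * (tc["pre"] > 0)
            g_att_inst[mptype][:z] += dpre @ H[P[:, 0]]
            g_att_inst[mptype][z:] += dpre @ M
            _scatter_add_rows(gH, P[:, 0], dpre[:, None] * a[:z])
            gM = gM + dpre[:, None] * a[z:]
        # mean-encoder backward: spread to every node of every instance
        L1 = P.shape[1]
        _scatter_add_rows(gH, P.ravel(), np.repeat(gM / L1, L1, axis=0))
    return gH, g_att_inst, g_att_type


# ---------------------------------------------------------------------------
# loss with gradients, training loop
# ---------------------------------------------------------------------------

def _pair_loss_grad(
    emb: np.ndarray, pos: np.ndarray, neg: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss value and d Loss / d emb for index-array pair sets."""
    grad = np.zeros_like(emb)
    total = 0.0
    for pairs, sgn in ((pos, 1.0), (neg, -1.0)):
        if len(pairs) == 0:
            continue
        u, v = pairs[:, 0], pairs[:, 1]
        diff = emb[u] - emb[v]
        d = np.abs(diff).sum(axis=1)
        total += sgn * float(_log_sigmoid(d).sum())
        coef = sgn * expit(-d)
        signed = coef[:, None] * np.sign(diff)
        _scatter_add_rows(grad, u, signed)
        _scatter_add_rows(grad, v, -signed)
    return total, grad


def loss_and_gradients(
    state: ModelState,
    graph: EncoderGraph,
    features: FeatureSpace,
    pos: np.ndarray,
    neg: np.ndarray,
    attention: bool = True,
) -> tuple[float, dict[str, np.ndarray]]:
    """Full-stack loss and analytic gradients for every parameter block."""
    H = transform(features, state)
    emb, cache = encode_all(state, graph, H, attention=attention)
    value, grad_final = _pair_loss_grad(emb, np.asarray(pos), np.asarray(neg))
    gH, g_ai, g_at = backward_all(state, graph, H, grad_final, cache)
    m = features.n_mirnas
    grads = {
        "W_R": gH[:m].T @ features.mirna_features,
        "W_D": gH[m:].T @ features.disease_features,
    }
    for t, g in g_ai.items():
        grads[f"att_instance/{t}"] = g
    for t, g in g_at.items():
        grads[f"att_type/{t}"] = g
    return value, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainResult:
    state: ModelState
    embeddings: EmbeddingSet
    loss_history: list[float] = field(default_factory=list)
    initial_loss: float = 0.0
    final_loss: float = 0.0


def _positive_pairs(net: HeteroNetwork) -> np.ndarray:
    return net.edge_array.copy()


def _unknown_md_pairs(net: HeteroNetwork) -> np.ndarray:
    """All miRNA-disease pairs without an edge in the network."""
    m, n = net.n_mirnas, net.n_diseases
    known = np.zeros((m, n), dtype=bool)
    e = net.edge_array
    md = e[(e[:, 0] < m) & (e[:, 1] >= m)]
    known[md[:, 0], md[:, 1] - m] = True
    unk = np.argwhere(~known)
    unk[:, 1] += m
    return unk


def train(
    net: HeteroNetwork,
    instances: MetaPathInstances,
    features: FeatureSpace,
    config: TrainConfig,
) -> TrainResult:
    """Mini-batch contrastive training; returns the best-loss state.

    Deterministic given ``config.seed``: initialization, negative sampling and
    batch shuffling all draw from one seeded generator.  The monitored loss
    (positives plus a fixed reference negative sample) is evaluated after
    every epoch and the returned state is the one minimizing it, so the final
    loss never exceeds the initial one.
    """
    rng = np.random.default_rng(config.seed)
    if config.max_instances_per_group is not None:
        instances = instances.subsample(
            config.max_instances_per_group, seed=int(rng.integers(2**31 - 1))
        )
    graph = EncoderGraph(instances)
    types = enumerate_types(instances.max_length)
    cfg = copy.deepcopy(config)
    cfg.embed_dim = features.embed_dim
    state = ModelState.initialize(features, types, cfg)
    pos = _positive_pairs(net)
    if len(pos) == 0:
        raise DataError("network has no edges; nothing to train on")
    unknown = _unknown_md_pairs(net)
    n_neg = int(round(config.negative_ratio * len(pos)))

    def sample_neg(gen) -> np.ndarray:
        if n_neg == 0 or len(unknown) == 0:
            return np.empty((0, 2), dtype=np.int64)
        idx = gen.choice(len(unknown), size=min(n_neg, len(unknown)), replace=False)
        return unknown[np.sort(idx)]

    ref_neg = sample_neg(rng)

    def monitored_loss(st: ModelState) -> float:
        H = transform(features, st)
        emb, _ = encode_all(st, graph, H, attention=config.attention)
        val, _ = _pair_loss_grad(emb, pos, ref_neg)
        return val

    initial = monitored_loss(state)
    best_state, best_loss = state.copy(), initial
    params = state.parameters()
    opt = _Adam(params, config.learning_rate)
    history = [initial]
    for _ in range(config.epochs):
        neg = sample_neg(rng)
        pairs = np.concatenate([pos, neg]) if len(neg) else pos
        labels = np.concatenate(
            [np.ones(len(pos), dtype=bool), np.zeros(len(neg), dtype=bool)]
        )
        perm = rng.permutation(len(pairs))
        pairs, labels = pairs[perm], labels[perm]
        for lo in range(0, len(pairs), config.batch_size):
            bp = pairs[lo : lo + config.batch_size]
            bl = labels[lo : lo + config.batch_size]
            value, grads = loss_and_gradients(
                state, graph, features, bp[bl], bp[~bl], attention=config.attention
            )
            if not np.isfinite(value):
                raise DataError("non-finite training loss; aborting")
            opt.step(params, grads)
        ep_loss = monitored_loss(state)
        history.append(ep_loss)
        if ep_loss < best_loss:
            best_loss = ep_loss
            best_state = state.copy()
    best_state.check_finite()
    H = transform(features, best_state)
    final, _ = encode_all(best_state, graph, H, attention=config.attention)
    emb = EmbeddingSet(transformed=H, final=final, n_mirnas=features.n_mirnas)
    return TrainResult(
        state=best_state,
        embeddings=emb,
        loss_history=history,
        initial_loss=initial,
        final_loss=best_loss,
    )


def score_pair(r: int, d: int, embeddings: EmbeddingSet) -> float:
    """Association score: negated Manhattan distance (higher = more likely)."""
    return -manhattan(embeddings.mirna(r), embeddings.disease(d))


def score_matrix(embeddings: EmbeddingSet) -> np.ndarray:
    """Scores for every miRNA-disease pair; (m, n)."""
    m = embeddings.n_mirnas
    E_m = embeddings.final[:m]
    E_d = embeddings.final[m:]
    return -np.abs(E_m[:, None, :] - E_d[None, :, :]).sum(axis=2)


def rank_pairs(scores: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Order candidate (i, j) pairs by score, ties broken on (i, j)."""
    cand = np.asarray(candidates)
    s = scores[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -s))
    return cand[order]
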