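"""Cross-validated evaluation: global LOOCV, repeated fivefold CV, ROC/AUC,
per-disease candidate ranking and the zeroed-disease (new disease) protocol.

Every fold recomputes the GIP similarities, the heterogeneous network, the
meta-path instances and the trained model from the *training* associations
only, so held-out positives cannot leak into any stage.  Held-out positives
are then scored against the pairs that are unverified in the full data set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .data import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import ConfigError, DataError
from .model import (
    FeatureSpace,
    TrainConfig,
    TrainResult,
    score_matrix,
    train,
)
from .network import build_network, extract_instances, DEFAULT_SIM_THRESHOLD
from .similarity import DEFAULT_DELTA, disease_similarity, mirna_similarity


@dataclass
class CVScheme:
    """Cross-validation protocol: LOOCV or repeated k-fold over positives."""

    kind: str = "kfold"
    k: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ConfigError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ConfigError("k must be >= 2 for k-fold CV")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    fold_aucs: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "seed": self.seed,
        }


def auc(scores, labels) -> float:
    """Ranking AUC (Mann-Whitney statistic with midranks for ties)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DataError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class PipelineConfig:
    """End-to-end settings: similarity, network, meta-paths and training."""

    train: TrainConfig = field(default_factory=TrainConfig)
    sim_threshold: float = DEFAULT_SIM_THRESHOLD
    max_length: int = 3
    delta: float = DEFAULT_DELTA
    alpha0_mirna: float = 1.0
    alpha0_disease: float = 1.0
    simple_only: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_cv_config(seed: int = 0) -> PipelineConfig:
    """Profile sized so a full train + fivefold CV runs in minutes on one CPU.

    Meta-path enumeration stays exhaustive; training subsamples instances per
    (target, type) group and uses larger, fewer mini-batches.  See the
    methods note for the rationale behind each value.
    """
    return PipelineConfig(
        train=TrainConfig(
            embed_dim=64,
            learning_rate=0.02,
            epochs=40,
            batch_size=256,
            max_instances_per_group=8,
            seed=seed,
        )
    )


def fit_predict(
    A: AssociationMatrix,
    fs: SimilarityMatrix | None,
    dags: list[DiseaseDAG] | None,
    config: PipelineConfig,
    similarities: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
) -> tuple[np.ndarray, TrainResult]:
    """Run the full pipeline on ``A`` and return (score matrix, TrainResult).

    ``similarities`` optionally injects precomputed (SM, SD); otherwise both
    are recomputed from ``A``.
    """
    if similarities is not None:
        SM, SD = similarities
    else:
        SM = mirna_similarity(A, fs, alpha0=config.alpha0_mirna)
        SD = disease_similarity(
            A, dags, delta=config.delta, alpha0=config.alpha0_disease
        )
    net = build_network(A, SM, SD, sim_threshold=config.sim_threshold)
    instances = extract_instances(net, config.max_length, config.simple_only)
    features = FeatureSpace.from_similarity(SM, SD, embed_dim=config.train.embed_dim)
    result = train(net, instances, features, config.train)
    return score_matrix(result.embeddings), result


def fold_assignments(
    pairs: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Seeded partition of positive pairs into k groups of near-equal size."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    return [perm[f::k] for f in range(k)]


def _mask_positives(A: AssociationMatrix, held_out: np.ndarray) -> AssociationMatrix:
    A_train = A.copy()
    A_train.values[held_out[:, 0], held_out[:, 1]] = 0
    return A_train


def run_cv(
    A: AssociationMatrix,
    fs: SimilarityMatrix | None,
    dags: list[DiseaseDAG] | None,
    scheme: CVScheme,
    config: PipelineConfig,
    max_folds: int | None = None,
    reuse_similarity: bool = False,
) -> RocResult:
    """Cross-validated AUC with per-fold recomputation of every stage.

    ``max_folds`` limits how many folds (per repeat) or held-out pairs are
    evaluated; useful for quick single-fold comparisons and LOOCV smoke runs.

    ``reuse_similarity=True`` reproduces the cheaper alternative that computes
    SM/SD once from the *full* association matrix and reuses them across
    folds; this leaks the held-out positives into the GIP kernels and exists
    only for comparison.
    """
    sims = None
    if reuse_similarity:
        sims = (
            mirna_similarity(A, fs, alpha0=config.alpha0_mirna),
            disease_similarity(
                A, dags, delta=config.delta, alpha0=config.alpha0_disease
            ),
        )
    positives = A.pairs()
    if len(positives) == 0:
        raise DataError("no positive associations to cross-validate")
    negatives = np.argwhere(A.values == 0)
    fold_aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    if scheme.kind == "kfold":
        for rep in range(scheme.repeats):
            folds = fold_assignments(positives, scheme.k, scheme.seed + rep)
            if max_folds is not None:
                folds = folds[:max_folds]
            for fold_idx in folds:
                held = positives[fold_idx]
                if len(held) == 0:
                    raise DataError("fold with zero positives")
                scores, _ = fit_predict(
                    _mask_positives(A, held), fs, dags, config, similarities=sims
                )
                s_pos = scores[held[:, 0], held[:, 1]]
                s_neg = scores[negatives[:, 0], negatives[:, 1]]
                y = np.concatenate([np.ones(len(s_pos)), np.zeros(len(s_neg))])
                s = np.concatenate([s_pos, s_neg])
                fold_aucs.append(auc(s, y))
                if rep == 0:
                    pooled_scores.append(s)
                    pooled_labels.append(y)
    else:  # global LOOCV: retrain per held-out pair, rank among same-disease unknowns
        order = positives
        if max_folds is not None:
            order = positives[:max_folds]
        for pair in order:
            held = pair[None, :]
            scores, _ = fit_predict(
                _mask_positives(A, held), fs, dags, config, similarities=sims
            )
            i, j = int(pair[0]), int(pair[1])
            cand = np.flatnonzero(A.values[:, j] == 0)
            s = np.concatenate([[scores[i, j]], scores[cand, j]])
            y = np.concatenate([[1.0], np.zeros(len(cand))])
            pooled_scores.append(s)
            pooled_labels.append(y)
        fold_aucs = [auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))]

    all_s = np.concatenate(pooled_scores)
    all_y = np.concatenate(pooled_labels)
    fpr, tpr, thr = roc_curve(all_y, all_s)
    return RocResult(
        auc=float(np.mean(fold_aucs)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        fold_aucs=fold_aucs,
        seed=scheme.seed,
    )


def case_study(
    A: AssociationMatrix,
    fs: SimilarityMatrix | None,
    dags: list[DiseaseDAG] | None,
    disease: str,
    config: PipelineConfig,
    top_k: int = 50,
) -> pd.DataFrame:
    """New-disease protocol: zero every association of ``disease``, retrain,
    rank all miRNAs for it by score; returns the top_k as a DataFrame."""
    if disease not in A.disease_names:
        raise DataError(f"unknown disease {disease!r}")
    j = A.disease_names.index(disease)
    A_zero = A.copy()
    A_zero.values[:, j] = 0
    scores, _ = fit_predict(A_zero, fs, dags, config)
    col = scores[:, j]
    order = np.lexsort((np.arange(len(col)), -col))[:top_k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "miRNA": [A.mirna_names[i] for i in order],
            "disease": disease,
            "score": col[order],
        }
    )


def ablation_run(
    A: AssociationMatrix,
    fs: SimilarityMatrix | None,
    dags: list[DiseaseDAG] | None,
    mode: str,
    scheme: CVScheme,
    config: PipelineConfig,
    max_folds: int | None = None,
) -> RocResult:
    """CV with the attention stages optionally replaced by unweighted means."""
    if mode not in ("attention", "no_attention"):
        raise ConfigError(f"mode must be 'attention' or 'no_attention', got {mode!r}")
    import copy as _copy

    cfg = _copy.deepcopy(config)
    cfg.train.attention = mode == "attention"
    return run_cv(A, fs, dags, scheme, cfg, max_folds=max_folds)
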