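"""Readers and writers for the interchange formats, plus run configuration.

Formats (all plain text):

* associations — two-column TSV ``miRNA<TAB>disease``, optional header;
* similarity — labeled CSV (header row, first-column labels, decimal reals);
* disease DAGs — TSV edge list ``child<TAB>parent`` over all terms, plus a
  manifest listing one target disease per line; each disease's DAG is its
  ancestor closure in the global parent graph;
* network — typed edge list TSV ``node1<TAB>node2<TAB>edge_class``;
* predictions — TSV ``rank<TAB>miRNA<TAB>disease<TAB>score``;
* metrics — JSON.

Every reader/writer pair round-trips losslessly on valid data.  Label
matching across inputs is exact-string and case-sensitive.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import ConfigError, DataError
from .evaluation import CVScheme, PipelineConfig, RocResult
from .model import TrainConfig
from .network import HeteroNetwork

logger = logging.getLogger("m2gmda")

_ASSOC_HEADERS = {"mirna", "mir", "disease"}


def read_associations(path) -> AssociationMatrix:
    """Read a two-column miRNA/disease pair list into a binary matrix.

    Duplicate pairs are counted once (and logged); labels are sorted unique.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a.lower() in _ASSOC_HEADERS:
                continue  # header row
            if not a or not b:
                raise DataError(f"{path}:{lineno}: empty field")
            pairs.append((a, b))
    if not pairs:
        raise DataError(f"{path}: no association pairs found")
    uniq = sorted(set(pairs))
    if len(uniq) < len(pairs):
        logger.info("%s: %d duplicate pairs collapsed", path, len(pairs) - len(uniq))
    mirnas = sorted({p[0] for p in uniq})
    diseases = sorted({p[1] for p in uniq})
    mi = {x: i for i, x in enumerate(mirnas)}
    di = {x: i for i, x in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for a, b in uniq:
        values[mi[a], di[b]] = 1
    return AssociationMatrix(values, mirnas, diseases)


def write_associations(path, A: AssociationMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("miRNA\tdisease\n")
        for i, j in A.pairs():
            fh.write(f"{A.mirna_names[i]}\t{A.disease_names[j]}\n")


def read_similarity(path, tol: float = 1e-9) -> SimilarityMatrix:
    """Read a labeled CSV similarity matrix; rejects asymmetry and bad ranges."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise DataError(f"{path}: row and column labels differ")
    sim = SimilarityMatrix(df.to_numpy(dtype=float), labels)
    try:
        sim.validate(tol=tol)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc
    return sim


def write_similarity(path, sim: SimilarityMatrix) -> None:
    pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels).to_csv(path)


def read_dags(edges_path, manifest_path) -> list[DiseaseDAG]:
    """Build one ancestor-closure DAG per manifest disease from a global
    ``child<TAB>parent`` edge list."""
    parents: dict[str, set[str]] = {}
    with open(edges_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(
                    f"{edges_path}:{lineno}: expected 'child<TAB>parent'"
                )
            child, parent = fields[0].strip(), fields[1].strip()
            parents.setdefault(child, set()).add(parent)
    diseases = [
        line.strip() for line in open(manifest_path) if line.strip()
    ]
    if not diseases:
        raise DataError(f"{manifest_path}: empty disease manifest")
    dags = []
    for disease in diseases:
        nodes = {disease}
        stack = [disease]
        while stack:
            term = stack.pop()
            for p in parents.get(term, ()):  # ancestor closure
                if p not in nodes:
                    nodes.add(p)
                    stack.append(p)
        edges = {
            (p, c) for c in nodes for p in parents.get(c, ()) if p in nodes
        }
        dags.append(DiseaseDAG(disease=disease, nodes=nodes, edges=edges))
    return dags


def write_dags(edges_path, manifest_path, dags: list[DiseaseDAG]) -> None:
    all_edges = sorted({e for dag in dags for e in dag.edges})
    with open(edges_path, "w") as fh:
        for parent, child in all_edges:
            fh.write(f"{child}\t{parent}\n")
    with open(manifest_path, "w") as fh:
        for dag in dags:
            fh.write(dag.disease + "\n")


def write_network(path, net: HeteroNetwork) -> None:
    with open(path, "w") as fh:
        for u, v in net.edge_array:
            fh.write(
                f"{net.node_name(int(u))}\t{net.node_name(int(v))}\t"
                f"{net.edge_class(int(u), int(v))}\n"
            )


def write_predictions(path, ranked: pd.DataFrame) -> None:
    ranked.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metrics(path, result: RocResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")


def write_roc_points(path, result: RocResult) -> None:
    pd.DataFrame(
        {"fpr": result.fpr, "tpr": result.tpr, "threshold": result.thresholds}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TRAIN_KEYS = {f.name for f in dataclasses.fields(TrainConfig)}
_PIPE_KEYS = {
    "sim_threshold",
    "max_length",
    "delta",
    "alpha0_mirna",
    "alpha0_disease",
    "simple_only",
}
_CV_KEYS = {"kind", "k", "repeats", "seed"}
_TOP_KEYS = {"train", "pipeline", "cv", "paths", "mode"}


def load_config(path) -> tuple[PipelineConfig, CVScheme, dict]:
    """Load a YAML run config; unknown keys are rejected with their location."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")

    def section(name, allowed):
        sec = raw.get(name, {}) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"{path}: section {name!r} must be a mapping")
        bad = set(sec) - allowed
        if bad:
            raise ConfigError(
                f"{path}: unknown keys {sorted(bad)} in section {name!r}; "
                f"allowed: {sorted(allowed)}"
            )
        return sec

    try:
        train_cfg = TrainConfig(**section("train", _TRAIN_KEYS))
        pipe = PipelineConfig(train=train_cfg, **section("pipeline", _PIPE_KEYS))
        cv = CVScheme(**section("cv", _CV_KEYS))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    extra = {"paths": raw.get("paths", {}), "mode": raw.get("mode", "attention")}
    if extra["mode"] not in ("attention", "no_attention"):
        raise ConfigError(f"{path}: mode must be 'attention' or 'no_attention'")
    return pipe, cv, extra
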