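"""Core data containers: association matrix, similarity matrix, disease DAG.

These are thin, validated wrappers around NumPy arrays plus ordered label
lists.  All downstream stages (similarity kernels, network construction,
embedding) consume these types rather than raw arrays, so validation happens
once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

SYMMETRY_TOL = 1e-9


@dataclass
class AssociationMatrix:
    """Binary miRNA-disease association matrix.

    Rows are miRNAs, columns are diseases; ``values[i, j] == 1`` means the
    pair is a verified association.
    """

    values: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DataError("association matrix must be 2-dimensional")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise DataError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        m, n = self.values.shape
        if len(self.mirna_names) != m or len(self.disease_names) != n:
            raise DataError("label lists do not match matrix dimensions")
        if len(set(self.mirna_names)) != m or len(set(self.disease_names)) != n:
            raise DataError("duplicate labels in association matrix")

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_names), list(self.disease_names)
        )

    def pairs(self) -> np.ndarray:
        """Return the (i, j) indices of all verified associations."""
        return np.argwhere(self.values == 1)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix in [0, 1] with ordered labels.

    ``mask`` optionally marks which entries are *defined* (e.g. functional
    similarity is only available for miRNAs present in the downloaded file);
    undefined entries are filled from a fallback kernel at integration time.
    """

    values: np.ndarray
    labels: list[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise DataError("similarity matrix shape does not match labels")
        if len(set(self.labels)) != k:
            raise DataError("duplicate labels in similarity matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError("mask shape does not match similarity matrix")

    def validate(self, tol: float = SYMMETRY_TOL) -> "SimilarityMatrix":
        """Check symmetry and value range; return self for chaining."""
        if not np.allclose(self.values, self.values.T, atol=tol, rtol=0):
            raise DataError(f"similarity matrix asymmetric beyond {tol}")
        vals = self.values[self.mask] if self.mask is not None else self.values
        if vals.size and (np.nanmin(vals) < -tol or np.nanmax(vals) > 1 + tol):
            raise DataError("similarity values outside [0, 1]")
        return self

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class DiseaseDAG:
    """Per-disease ancestor DAG with semantic contribution weights.

    ``nodes`` contains the disease term itself plus all its ancestors;
    ``edges`` are (parent, child) pairs restricted to ``nodes``.  The two
    contribution maps hold the decay-based weights (Wang) and the
    information-content weights (Xuan) once computed.
    """

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    contributions1: dict[str, float] = field(default_factory=dict)
    contributions2: dict[str, float] = field(default_factory=dict)
    semantic_value1: float | None = None
    semantic_value2: float | None = None

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset(self.edges)
        if self.disease not in self.nodes:
            raise DataError(f"DAG for {self.disease!r} does not contain the disease")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise DataError(f"edge ({p!r}, {c!r}) leaves the DAG node set")

    def children(self, term: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == term)

    def parents(self, term: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == term)
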