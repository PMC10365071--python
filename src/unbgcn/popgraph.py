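"""Phenotype-similarity population graph and its propagation operators.

Subjects are nodes; the edge weight between two subjects counts how many
phenotypes (gender, age, APOE e4 allele count, ...) agree:

    W(m, n) = sum_l alpha_l(m, n)

with alpha the Kronecker delta for categorical phenotypes and a unit step
|difference| < theta for numeric ones.  Spectral graph convolution on this
graph uses the symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2};
the network layers use the first-order renormalized propagation operator
S = Dt^{-1/2} (W + I) Dt^{-1/2}, the standard single-hop realization of the
spectral filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THETA = 2.0  # numeric-phenotype similarity threshold


@dataclass
class PhenotypeSpec:
    """One phenotype used for edge construction."""

    name: str
    kind: str  # "categorical" | "numeric"
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "numeric" and self.theta <= 0:
            raise ValueError("theta must be positive for numeric phenotypes")


@dataclass
class EdgeSpec:
    """Ordered list of phenotypes entering the adjacency sum."""

    phenotypes: list[PhenotypeSpec]

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValueError("EdgeSpec needs at least one phenotype")

    @classmethod
    def default(cls, theta: float = DEFAULT_THETA) -> "EdgeSpec":
        """Gender (categorical), age and APOE e4 count (numeric, same theta)."""
        return cls(
            [
                PhenotypeSpec("gender", "categorical"),
                PhenotypeSpec("age", "numeric", theta),
                PhenotypeSpec("apoe4_count", "numeric", theta),
            ]
        )


@dataclass
class PopulationGraph:
    """Node features, phenotype-similarity adjacency, labels and split masks."""

    X: np.ndarray
    W: np.ndarray
    labels: np.ndarray  # integer class codes; -1 = unlabeled
    train_mask: np.ndarray
    test_mask: np.ndarray
    phenotypes: pd.DataFrame | None = None
    feature_names: list[str] | None = None
    class_names: list[str] | None = None
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        self.test_mask = np.asarray(self.test_mask, dtype=bool)
        n = self.X.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("adjacency shape does not match feature rows")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.W < 0):
            raise ValueError("adjacency must be nonnegative")
        for m in (self.labels, self.train_mask, self.test_mask):
            if m.shape != (n,):
                raise ValueError("labels/masks must have one entry per node")
        if np.any(self.train_mask & self.test_mask):
            raise ValueError("train and test masks must be disjoint")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def phenotype_similarity(a, b, kind: str, theta: float = DEFAULT_THETA) -> int:
    """0/1 similarity of one phenotype between two subjects.

    Categorical: Kronecker delta (1 iff equal).  Numeric: unit step,
    1 iff |a - b| < theta (strict; a difference of exactly theta scores 0).
    """
    if kind == "categorical":
        return int(a == b)
    if kind == "numeric":
        if theta <= 0:
            raise ValueError("theta must be positive")
        return int(abs(float(a) - float(b)) < theta)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def build_adjacency(phenotypes: pd.DataFrame, spec: EdgeSpec) -> np.ndarray:
    """Sum the per-phenotype 0/1 similarities over all subject pairs.

    Entries are integers in [0, P] where P = number of phenotypes; the
    diagonal is set to 0 (no self edges; self loops are added later by the
    renormalized propagation operator).
    """
    n = len(phenotypes)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    for ps in spec.phenotypes:
        if ps.name not in phenotypes.columns:
            raise ValueError(f"phenotype column {ps.name!r} missing")
        if phenotypes[ps.name].isna().any():
            bad = phenotypes.index[phenotypes[ps.name].isna()].tolist()
            raise ValueError(f"missing {ps.name!r} for subjects {bad}")
    W = np.zeros((n, n))
    for ps in spec.phenotypes:
        col = phenotypes[ps.name].to_numpy()
        if ps.kind == "categorical":
            sim = (col[:, None] == col[None, :]).astype(float)
        else:
            vals = col.astype(float)
            sim = (np.abs(vals[:, None] - vals[None, :]) < ps.theta).astype(float)
        W += sim
    np.fill_diagonal(W, 0.0)
    return W


def _check_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency must be nonnegative")
    return W


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2}.

    Isolated nodes (zero degree) get L row/column = identity, the 0/0 -> 0
    limit of the normalization.
    """
    W = _check_adjacency(W)
    d = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(len(W)) - dinv[:, None] * W * dinv[None, :]
    return (L + L.T) / 2.0


def renormalized_propagation(W: np.ndarray) -> np.ndarray:
    """First-order propagation operator S = Dt^{-1/2} (W + I) Dt^{-1/2}.

    Self loops are added before normalization, so every degree is positive
    and the spectral radius of S is at most 1.
    """
    W = _check_adjacency(W)
    Wt = W + np.eye(len(W))
    dinv = 1.0 / np.sqrt(Wt.sum(axis=1))
    S = dinv[:, None] * Wt * dinv[None, :]
    return (S + S.T) / 2.0


def spectral_filter(W: np.ndarray, x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Reference full-spectrum graph convolution g * x = U((U^T g) . (U^T x)).

    Eigendecomposition of the normalized Laplacian; used as an oracle for the
    first-order propagation, not in the training path.
    """
    L = normalized_laplacian(W)
    _, U = np.linalg.eigh(L)
    return U @ ((U.T @ np.asarray(g, dtype=float)) * (U.T @ np.asarray(x, dtype=float)))
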