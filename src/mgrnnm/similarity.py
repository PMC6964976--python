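"""Similarity fusion and graph construction.

Four similarity measures are derived from the binary interaction matrix
(cosine, Pearson correlation, Hamming, Jaccard), combined with the standard
chemical/sequence similarity by a weighted sum, sparsified to a p-nearest
neighbor graph, and turned into a (normalized) combined graph Laplacian.

Degenerate interaction profiles (all-zero rows for novel drugs, constant
vectors) map to similarity 0: absence of evidence defers entirely to the
standard similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_WEIGHTS",
    "SIMILARITY_KINDS",
    "SimilarityBundle",
    "GraphOperator",
    "interaction_similarity",
    "interaction_bundle",
    "combine_similarities",
    "sparsify_pnn",
    "build_graph",
]

SIMILARITY_KINDS = ("cosine", "correlation", "hamming", "jaccard")

#: Cosine, correlation and jaccard carry four times the weight of hamming;
#: the standard chemical/sequence similarity keeps unit weight.
DEFAULT_WEIGHTS = {
    "standard": 1.0,
    "cosine": 4.0,
    "correlation": 4.0,
    "hamming": 1.0,
    "jaccard": 4.0,
}


def _profiles(X: np.ndarray, side: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("interaction matrix must be binary")
    if side == "drug":
        return X
    if side == "target":
        return X.T
    raise ValueError(f"side must be 'drug' or 'target', got {side!r}")


def interaction_similarity(X: np.ndarray, side: str, kind: str) -> np.ndarray:
    """Pairwise similarity of interaction profiles (rows for drugs, columns
    for targets).

    kind:
      cosine       inner product over the product of norms, in [-1, 1]
                   (here >= 0 since profiles are binary); 0 for zero vectors.
      correlation  Pearson's r, in [-1, 1]; 0 when either profile is constant.
      hamming      1 minus the fraction of differing positions, in [0, 1].
      jaccard      matching nonzero positions over union support, in [0, 1];
                   0 for an empty union.
    """
    P = _profiles(X, side)
    k, d = P.shape

    if kind == "cosine":
        norms = np.linalg.norm(P, axis=1)
        denom = np.outer(norms, norms)
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(denom > 0, (P @ P.T) / np.where(denom > 0, denom, 1.0), 0.0)
    elif kind == "correlation":
        C = P - P.mean(axis=1, keepdims=True)
        sd = np.linalg.norm(C, axis=1)
        denom = np.outer(sd, sd)
        S = np.where(denom > 0, (C @ C.T) / np.where(denom > 0, denom, 1.0), 0.0)
    elif kind == "hamming":
        # profiles binary: number of differing positions via the cross products
        ones = P.sum(axis=1)
        agree11 = P @ P.T
        differ = ones[:, None] + ones[None, :] - 2 * agree11
        S = 1.0 - differ / d
    elif kind == "jaccard":
        ones = P.sum(axis=1)
        agree11 = P @ P.T
        union = ones[:, None] + ones[None, :] - agree11
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(union > 0, agree11 / np.where(union > 0, union, 1.0), 0.0)
    else:
        raise ValueError(f"unknown similarity kind {kind!r}")

    S = (S + S.T) / 2.0
    # non-degenerate profiles are perfectly self-similar under every measure
    if kind == "cosine":
        np.fill_diagonal(S, np.where(np.linalg.norm(P, axis=1) > 0, 1.0, 0.0))
    elif kind == "correlation":
        sd = P.std(axis=1)
        np.fill_diagonal(S, np.where(sd > 0, 1.0, 0.0))
    elif kind == "hamming":
        np.fill_diagonal(S, 1.0)
    elif kind == "jaccard":
        np.fill_diagonal(S, np.where(P.sum(axis=1) > 0, 1.0, 0.0))
    return S


@dataclass(frozen=True)
class SimilarityBundle:
    """Named per-side similarity matrices with their combination weights."""

    side: str
    matrices: dict[str, np.ndarray]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.side not in ("drug", "target"):
            raise ValueError(f"side must be 'drug' or 'target', got {self.side!r}")
        if set(self.matrices) != set(self.weights):
            raise ValueError(
                f"matrix keys {sorted(self.matrices)} do not match weight keys "
                f"{sorted(self.weights)}"
            )
        shapes = {np.asarray(S).shape for S in self.matrices.values()}
        if len(shapes) != 1:
            raise ValueError(f"similarity matrices have mixed shapes {shapes}")
        for name, S in self.matrices.items():
            S = np.asarray(S, dtype=float)
            if not np.allclose(S, S.T, atol=1e-10, rtol=0):
                raise ValueError(f"{name} similarity matrix is not symmetric")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")


def interaction_bundle(
    X: np.ndarray,
    standard: np.ndarray,
    side: str,
    weights: dict[str, float] | None = None,
) -> SimilarityBundle:
    """Assemble the five-similarity bundle for one side from the interaction
    matrix and the standard (chemical or sequence) similarity."""
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    matrices: dict[str, np.ndarray] = {"standard": np.asarray(standard, dtype=float)}
    for kind in SIMILARITY_KINDS:
        matrices[kind] = interaction_similarity(X, side, kind)
    return SimilarityBundle(side=side, matrices=matrices, weights=weights)


def combine_similarities(bundle: SimilarityBundle) -> np.ndarray:
    """Weighted sum of the bundle's similarity matrices (the combined
    similarity S^COM)."""
    out = None
    for name in sorted(bundle.matrices):
        term = bundle.weights[name] * np.asarray(bundle.matrices[name], dtype=float)
        out = term if out is None else out + term
    return out


def sparsify_pnn(S: np.ndarray, p: int) -> np.ndarray:
    """Restrict a similarity matrix to its p-nearest-neighbor graph.

    The mask N is 1 where the two nodes are mutually among each other's p
    nearest neighbors (by similarity, self excluded, ties broken by
    ascending index), 0 where neither is, and 0.5 otherwise; the diagonal is
    kept with factor 1.  The result is S * N elementwise.
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or not np.allclose(S, S.T, atol=1e-10, rtol=0):
        raise ValueError("S must be a symmetric square matrix")
    if not 1 <= p <= k - 1:
        raise ValueError(f"p must lie in [1, {k - 1}], got {p}")

    # rank neighbors of each node: descending similarity, self excluded,
    # ties by ascending index (lexsort is stable on the secondary key)
    member = np.zeros((k, k), dtype=bool)   # member[i, j]: j in Np(i)
    idx = np.arange(k)
    for i in range(k):
        others = idx[idx != i]
        order = others[np.lexsort((others, -S[i, others]))]
        member[i, order[:p]] = True

    N = (member & member.T) * 1.0 + (member ^ member.T) * 0.5
    np.fill_diagonal(N, 1.0)
    return S * N


@dataclass(frozen=True)
class GraphOperator:
    """Combined similarity with its degree vector and graph Laplacian."""

    combined_similarity: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    normalized: bool
    p_used: int | None = None

    @property
    def n(self) -> int:
        return self.laplacian.shape[0]


def build_graph(
    S_combined: np.ndarray,
    normalized: bool = True,
    p_used: int | None = None,
) -> GraphOperator:
    """Build the (normalized) combined graph Laplacian from a combined
    similarity matrix.

    degree_i = sum_j S_ij, L = D - S; the normalized variant is
    D^(-1/2) L D^(-1/2) with zero-degree nodes given D^(-1/2) entry 0.
    Negative entries are rejected: combined similarities must be clipped
    to be valid Laplacian weights.
    """
    S = np.asarray(S_combined, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10, rtol=0):
        raise ValueError("combined similarity must be symmetric")
    if (S < 0).any():
        raise ValueError(
            "combined similarity has negative entries; clip before building "
            "the graph Laplacian"
        )
    degree = S.sum(axis=1)
    L = np.diag(degree) - S
    if normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(degree > 0, 1.0 / np.sqrt(np.where(degree > 0, degree, 1.0)), 0.0)
        L = dinv[:, None] * L * dinv[None, :]
        L = (L + L.T) / 2.0
    return GraphOperator(
        combined_similarity=S,
        degree=degree,
        laplacian=L,
        normalized=normalized,
        p_used=p_used,
    )


def combined_graph(
    X: np.ndarray,
    standard: np.ndarray,
    side: str,
    weights: dict[str, float] | None = None,
    p: int | None = 5,
    normalized: bool = True,
) -> GraphOperator:
    """Full preprocessing pipeline for one side: interaction-derived
    similarities -> weighted combination -> clip negatives -> p-NN
    sparsification -> (normalized) Laplacian."""
    bundle = interaction_bundle(X, standard, side, weights)
    S = np.maximum(combine_similarities(bundle), 0.0)
    if p is not None:
        S = sparsify_pnn(S, p)
    return build_graph(S, normalized=normalized, p_used=p)
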