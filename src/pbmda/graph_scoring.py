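"""Heterogeneous-graph construction and path-based association scoring.

The graph has three layers: miRNA-miRNA and disease-disease similarity
edges (kept only at weight >= T, self-loops removed) and binary
miRNA-disease association edges. The score of a pair (m, d) sums, over all
simple paths p from m to d of at most L edges,

    (product of edge weights along p) ** (alpha * len(p))

so a direct association contributes exactly 1 and longer / weaker paths
are exponentially discounted (alpha = 2.26 by default).

Two engines compute the full score matrix: ``dfs`` enumerates the simple
paths explicitly (any L), and ``matrix`` evaluates the same sum for L <= 3
with per-length elementwise-powered weight matrices combined over the path
shapes, plus walk-revisit corrections so that only simple paths are
counted. The dfs engine is the reference; the matrix engine must agree
with it elementwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix

DEFAULT_THRESHOLD = 0.5
DEFAULT_MAX_LENGTH = 3
DEFAULT_ALPHA = 2.26


@dataclass(frozen=True)
class PBMDAParams:
    """Scoring parameters: similarity cutoff T, path-length cap L, decay alpha."""

    threshold: float = DEFAULT_THRESHOLD
    max_length: int = DEFAULT_MAX_LENGTH
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold T must lie in [0, 1]")
        if not (isinstance(self.max_length, (int, np.integer)) and self.max_length >= 1):
            raise ValueError("max path length L must be an integer >= 1")
        if self.alpha <= 0:
            raise ValueError("decay factor alpha must be positive")


@dataclass
class HeterogeneousGraph:
    """Thresholded three-layer graph over typed miRNA/disease nodes."""

    W_mm: np.ndarray
    W_dd: np.ndarray
    W_md: np.ndarray
    mirna_labels: list[str]
    disease_labels: list[str]

    def __post_init__(self) -> None:
        nm, nd = len(self.mirna_labels), len(self.disease_labels)
        if self.W_mm.shape != (nm, nm) or self.W_dd.shape != (nd, nd) or self.W_md.shape != (nm, nd):
            raise ValueError("graph layer shapes inconsistent with labels")
        if np.abs(np.diag(self.W_mm)).max(initial=0) > 0 or np.abs(np.diag(self.W_dd)).max(initial=0) > 0:
            raise ValueError("similarity layers must have zero diagonal")


@dataclass(frozen=True)
class Path:
    """A simple path from a miRNA to a disease through the graph.

    ``nodes`` are (type, label) pairs with type "m" or "d"; ``length`` is
    the edge count and ``weight_product`` the product of traversed weights.
    """

    nodes: tuple[tuple[str, str], ...]
    weight_product: float

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


def build_graph(
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    Y: AssociationMatrix,
    params: PBMDAParams = PBMDAParams(),
) -> HeterogeneousGraph:
    """Threshold the similarity layers at T and assemble the graph.

    Similarity entries strictly below T are dropped (a weight equal to T
    survives); diagonals are zeroed so no traversal can sit still. The
    bipartite layer is the binary Y, never thresholded.
    """
    if Sm.labels != Y.mirna_labels:
        raise ValueError("miRNA labels of Sm and Y differ")
    if Sd.labels != Y.disease_labels:
        raise ValueError("disease labels of Sd and Y differ")
    W_mm = np.where(Sm.values >= params.threshold, Sm.values, 0.0)
    W_dd = np.where(Sd.values >= params.threshold, Sd.values, 0.0)
    np.fill_diagonal(W_mm, 0.0)
    np.fill_diagonal(W_dd, 0.0)
    return HeterogeneousGraph(W_mm, W_dd, Y.values.copy(), list(Y.mirna_labels), list(Y.disease_labels))


def _neighbors(graph: HeterogeneousGraph, node: tuple[str, int]):
    """Typed neighbors of a node, in deterministic (type, label) order."""
    kind, idx = node
    out: list[tuple[tuple[str, int], float]] = []
    if kind == "m":
        for j in np.flatnonzero(graph.W_md[idx]):
            out.append((("d", int(j)), 1.0))
        for j in np.flatnonzero(graph.W_mm[idx]):
            out.append((("m", int(j)), float(graph.W_mm[idx, j])))
    else:
        for j in np.flatnonzero(graph.W_dd[idx]):
            out.append((("d", int(j)), float(graph.W_dd[idx, j])))
        for i in np.flatnonzero(graph.W_md[:, idx]):
            out.append((("m", int(i)), 1.0))
    labels = {"m": graph.mirna_labels, "d": graph.disease_labels}
    out.sort(key=lambda t: (t[0][0], labels[t[0][0]][t[0][1]]))
    return out


def enumerate_paths(
    graph: HeterogeneousGraph, mirna: str, disease: str, max_length: int = DEFAULT_MAX_LENGTH
) -> list[Path]:
    """All simple paths from a miRNA to a disease with at most L edges.

    Iterative depth-first search with an explicit stack and a per-branch
    visited set; the returned list is sorted lexicographically by node
    sequence.
    """
    mi = graph.mirna_labels.index(mirna)
    di = graph.disease_labels.index(disease)
    start, target = ("m", mi), ("d", di)
    paths: list[Path] = []
    # stack frames: (node, path-so-far, weight product)
    stack: list[tuple[tuple[str, int], tuple[tuple[str, int], ...], float]] = [(start, (start,), 1.0)]
    while stack:
        node, trail, wprod = stack.pop()
        if node == target:
            labeled = tuple(
                (k, graph.mirna_labels[i] if k == "m" else graph.disease_labels[i]) for k, i in trail
            )
            paths.append(Path(labeled, wprod))
            continue
        if len(trail) - 1 >= max_length:
            continue
        for nbr, w in reversed(_neighbors(graph, node)):
            if nbr not in trail:
                stack.append((nbr, trail + (nbr,), wprod * w))
    paths.sort(key=lambda p: p.nodes)
    return paths


def decay_exponent(path: Path, alpha: float = DEFAULT_ALPHA) -> float:
    """Exponent applied to a path's weight product: alpha times its length."""
    return alpha * path.length


def path_contribution(path: Path, alpha: float = DEFAULT_ALPHA) -> float:
    return float(path.weight_product ** decay_exponent(path, alpha))


def score_pair(
    graph: HeterogeneousGraph, mirna: str, disease: str, params: PBMDAParams = PBMDAParams()
) -> float:
    """Path score of one miRNA-disease pair (0 if disconnected within L)."""
    paths = enumerate_paths(graph, mirna, disease, params.max_length)
    return float(sum(path_contribution(p, params.alpha) for p in paths))


def _score_all_dfs(graph: HeterogeneousGraph, params: PBMDAParams) -> np.ndarray:
    S = np.zeros((len(graph.mirna_labels), len(graph.disease_labels)))
    for i, m in enumerate(graph.mirna_labels):
        for j, d in enumerate(graph.disease_labels):
            S[i, j] = score_pair(graph, m, d, params)
    return S


def _score_all_matrix(graph: HeterogeneousGraph, params: PBMDAParams) -> np.ndarray:
    """Closed-form simple-path score for L <= 3.

    Each path length uses its own elementwise-powered weight matrices
    (every edge on a length-l path is raised to alpha*l). Per shape:

      l=1  m-d                        : Y
      l=2  m-m'-d  /  m-d'-d          : M2 Y  /  Y D2
      l=3  m-m-m-d                    : M3 M3 Y  minus walks returning to m
           m-m-d-d                    : M3 Y D3 (zero diagonals already
                                        exclude revisits)
           m-d-d-d                    : Y D3 D3 minus walks leaving through d
           m-d-m-d                    : Y Y' Y  minus walks through the start
                                        miRNA or the terminal disease
                                        (inclusion-exclusion adds the doubly
                                        degenerate walks back)
    """
    if params.max_length > 3:
        raise ValueError("matrix engine supports L <= 3; fall back to engine='dfs'")
    a = params.alpha
    Y = graph.W_md
    S = Y.copy()
    if params.max_length >= 2:
        M2 = graph.W_mm**(2 * a)
        D2 = graph.W_dd**(2 * a)
        S += M2 @ Y + Y @ D2
    if params.max_length >= 3:
        M3 = graph.W_mm**(3 * a)
        D3 = graph.W_dd**(3 * a)
        S += M3 @ M3 @ Y - np.diag(M3 @ M3)[:, None] * Y
        S += M3 @ Y @ D3
        S += Y @ D3 @ D3 - Y * np.diag(D3 @ D3)[None, :]
        row_deg = Y.sum(axis=1)
        col_deg = Y.sum(axis=0)
        S += Y @ Y.T @ Y - row_deg[:, None] * Y - Y * col_deg[None, :] + Y
    return S


def score_all(
    graph: HeterogeneousGraph,
    params: PBMDAParams = PBMDAParams(),
    engine: str = "matrix",
) -> ScoreMatrix:
    """Score every miRNA-disease pair.

    ``engine="matrix"`` (default, L <= 3) and ``engine="dfs"`` (any L)
    produce identical results; dfs is the reference implementation.
    """
    if engine == "dfs":
        S = _score_all_dfs(graph, params)
    elif engine == "matrix":
        S = _score_all_matrix(graph, params)
    else:
        raise ValueError(f"unknown engine {engine!r}; choose 'dfs' or 'matrix'")
    return ScoreMatrix(S, list(graph.mirna_labels), list(graph.disease_labels))


def explain_pair(
    graph: HeterogeneousGraph, mirna: str, disease: str, params: PBMDAParams = PBMDAParams()
) -> list[dict]:
    """Per-path audit of one pair's score: nodes, weight product, exponent,
    contribution."""
    rows = []
    for p in enumerate_paths(graph, mirna, disease, params.max_length):
        rows.append(
            {
                "path": " <-> ".join(label for _, label in p.nodes),
                "length": p.length,
                "weight_product": p.weight_product,
                "exponent": decay_exponent(p, params.alpha),
                "contribution": path_contribution(p, params.alpha),
            }
        )
    return rows
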