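import networkx as nx
import numpy as np
import pytest

from pbmda.containers import AssociationMatrix, SimilarityMatrix
from pbmda.graph_scoring import HeterogeneousGraph, PBMDAParams, build_graph
from pbmda.io_tabular import build_Y
from pbmda.synthetic import fig1_fixture


@pytest.fixture
def fig1_graph() -> HeterogeneousGraph:
    assoc, Sm, Sd = fig1_fixture()
    Y = build_Y(assoc, Sm.labels, Sd.labels)
    return build_graph(Sm, Sd, Y, PBMDAParams())


def random_graph(rng: np.random.Generator, nm: int, nd: int, density: float = 0.5) -> HeterogeneousGraph:
    """A random thresholded heterogeneous graph (weights already >= 0.5)."""
    W_mm = np.where(rng.random((nm, nm)) < density, rng.uniform(0.5, 1.0, (nm, nm)), 0.0)
    W_mm = np.triu(W_mm, 1)
    W_mm = W_mm + W_mm.T
    W_dd = np.where(rng.random((nd, nd)) < density, rng.uniform(0.5, 1.0, (nd, nd)), 0.0)
    W_dd = np.triu(W_dd, 1)
    W_dd = W_dd + W_dd.T
    Y = (rng.random((nm, nd)) < density).astype(float)
    return HeterogeneousGraph(
        W_mm, W_dd, Y, [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)]
    )


def nx_simple_paths(graph: HeterogeneousGraph, mirna: str, disease: str, max_length: int):
    """Independent simple-path oracle built on networkx.

    Returns a sorted list of (node-sequence, weight-product) pairs.
    """
    G = nx.Graph()
    nm, nd = len(graph.mirna_labels), len(graph.disease_labels)
    for i in range(nm):
        for j in range(i + 1, nm):
            if graph.W_mm[i, j] > 0:
                G.add_edge(("m", graph.mirna_labels[i]), ("m", graph.mirna_labels[j]),
                           weight=graph.W_mm[i, j])
    for i in range(nd):
        for j in range(i + 1, nd):
            if graph.W_dd[i, j] > 0:
                G.add_edge(("d", graph.disease_labels[i]), ("d", graph.disease_labels[j]),
                           weight=graph.W_dd[i, j])
    for i in range(nm):
        for j in range(nd):
            if graph.W_md[i, j] > 0:
                G.add_edge(("m", graph.mirna_labels[i]), ("d", graph.disease_labels[j]), weight=1.0)
    src, tgt = ("m", mirna), ("d", disease)
    out = []
    if src in G and tgt in G:
        for p in nx.all_simple_paths(G, src, tgt, cutoff=max_length):
            w = 1.0
            for a, b in zip(p, p[1:]):
                w *= G[a][b]["weight"]
            out.append((tuple(p), w))
    return sorted(out)


def nx_score(graph: HeterogeneousGraph, mirna: str, disease: str, params: PBMDAParams) -> float:
    return sum(
        w ** (params.alpha * (len(p) - 1))
        for p, w in nx_simple_paths(graph, mirna, disease, params.max_length)
    )


def pairwise_auc(scores, labels) -> float:
    """Brute-force AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
    return float(wins / (len(pos) * len(neg)))


def toy_similarity(values: np.ndarray, labels, role: str, coverage=None) -> SimilarityMatrix:
    return SimilarityMatrix(np.asarray(values, dtype=float), list(labels), role, coverage)
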