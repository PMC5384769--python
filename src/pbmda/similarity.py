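"""Disease semantic similarity, Gaussian interaction-profile kernels, and
their integration into the final miRNA/disease similarity matrices.

Semantic similarity follows the MeSH-DAG construction: each disease D is a
DAG of itself plus its ancestor terms; an ancestor at graph distance k
contributes delta**k (delta in (0, 1), default 0.5), and two diseases are
similar in proportion to the contributions of the DAG terms they share.

Where that primary knowledge is missing (a miRNA pair outside the
functional-similarity matrix, a disease without a DAG), the Gaussian
interaction-profile kernel computed from the known association matrix Y
fills the gap:

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2),
    gamma   = gamma' / mean(||IP||^2)

with IP(i) the binary association profile (a row of Y for miRNAs, a column
for diseases) and gamma' = 1 by default.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG, SemanticProfile, SimilarityMatrix

DEFAULT_DECAY = 0.5
DEFAULT_GAMMA_PRIME = 1.0


def semantic_contributions(dag: DiseaseDAG, delta: float = DEFAULT_DECAY) -> SemanticProfile:
    """Decayed contribution of every DAG term to its disease's semantic value.

    The disease term itself contributes 1; any other term t contributes
    delta * max over t's children within the DAG. A term reachable through
    several paths takes its max-path value (dynamic programming over the
    DAG, memoized child-ward recursion).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"decay factor must lie in (0, 1), got {delta}")
    contrib: dict[str, float] = {dag.disease: 1.0}
    in_progress: set[str] = set()

    def value(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term in in_progress:  # acyclicity is checked at load time; belt and braces
            raise ValueError(f"cycle through term {term!r} in DAG of {dag.disease!r}")
        in_progress.add(term)
        child_vals = [value(c) for c in dag.children_of(term)]
        in_progress.discard(term)
        if not child_vals:
            raise ValueError(
                f"term {term!r} in DAG of {dag.disease!r} has no path to the disease term"
            )
        contrib[term] = delta * max(child_vals)
        return contrib[term]

    for term in sorted(dag.terms):
        value(term)
    return SemanticProfile(dag.disease, contrib, delta)


def disease_semantic_similarity(profile_i: SemanticProfile, profile_j: SemanticProfile) -> float:
    """Similarity of two diseases from their shared DAG terms.

    SS = sum over shared terms of (D_i(t) + D_j(t)), normalized by the sum
    of the two semantic values; 1 for identical DAGs, 0 for disjoint ones.
    """
    if profile_i.decay != profile_j.decay:
        raise ValueError("semantic profiles built with different decay factors")
    shared = profile_i.contributions.keys() & profile_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(profile_i.contributions[t] + profile_j.contributions[t] for t in shared)
    return float(num / (profile_i.semantic_value + profile_j.semantic_value))


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    delta: float = DEFAULT_DECAY,
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a disease universe.

    ``labels`` may extend beyond the diseases that have DAGs; a pair is
    covered only when both diseases have one, leaving the rest to the
    kernel fallback.
    """
    if labels is None:
        labels = sorted(dags)
    labels = list(labels)
    if not labels:
        raise ValueError("no diseases supplied")
    profiles = {d: semantic_contributions(dags[d], delta) for d in labels if d in dags}
    n = len(labels)
    values = np.zeros((n, n))
    coverage = np.zeros((n, n), dtype=bool)
    for i, di in enumerate(labels):
        values[i, i] = 1.0
        if di not in profiles:
            continue
        coverage[i, i] = True
        for j in range(i + 1, n):
            dj = labels[j]
            if dj not in profiles:
                continue
            values[i, j] = values[j, i] = disease_semantic_similarity(profiles[di], profiles[dj])
            coverage[i, j] = coverage[j, i] = True
    return SimilarityMatrix(values, labels, "SS", coverage)


def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "miRNAs":
        return Y.values
    if axis == "diseases":
        return Y.values.T
    raise ValueError(f"axis must be 'miRNAs' or 'diseases', got {axis!r}")


def gaussian_kernel_bandwidth(
    Y: AssociationMatrix, axis: str, gamma_prime: float = DEFAULT_GAMMA_PRIME
) -> float:
    """Effective kernel bandwidth: gamma' over the mean squared profile norm.

    Since Y is binary the squared norm of a profile is its association
    count. An all-zero Y leaves the bandwidth undefined and is an error.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    profiles = _profiles(Y, axis)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("association matrix has no associations; kernel bandwidth undefined")
    return gamma_prime / mean_sq


def gaussian_kernel_matrix(
    Y: AssociationMatrix, axis: str, gamma_prime: float = DEFAULT_GAMMA_PRIME
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity between all entities
    on one side of the bipartite association matrix."""
    gamma = gaussian_kernel_bandwidth(Y, axis, gamma_prime)
    profiles = _profiles(Y, axis)
    sq_norms = (profiles**2).sum(axis=1)
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    K = np.exp(-gamma * sq_dist)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    role = "KM" if axis == "miRNAs" else "KD"
    labels = Y.mirna_labels if axis == "miRNAs" else Y.disease_labels
    return SimilarityMatrix(K, list(labels), role)


def integrate_similarity(
    primary: SimilarityMatrix,
    kernel: SimilarityMatrix,
    coverage_from_nonzero: bool = False,
) -> SimilarityMatrix:
    """Fuse primary similarity (FS or SS) with the kernel fallback.

    Each cell takes the primary value where the pair is covered by primary
    knowledge and the kernel value otherwise. With
    ``coverage_from_nonzero`` the covered set is instead the nonzero cells
    of the primary matrix (an alternative reading in which an explicit 0
    also falls back to the kernel).
    """
    if primary.labels != kernel.labels:
        raise ValueError("primary and kernel similarity label sets differ")
    mask = (primary.values != 0) if coverage_from_nonzero else primary.coverage
    values = np.where(mask, primary.values, kernel.values)
    role = "Sm" if kernel.role == "KM" else "Sd"
    return SimilarityMatrix(values, list(primary.labels), role)
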