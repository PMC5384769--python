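"""Synthetic heterogeneous networks with planted block structure.

The generator emulates the statistical structure the path-based model
assumes: functionally similar miRNAs (same planted block) associate with
similar diseases (the matching disease block). Associations are Bernoulli
draws whose probability depends on block co-membership; similarities are
clipped-normal draws with a higher mean within blocks; a configurable
fraction of miRNA pairs is left uncovered by the primary similarity to
exercise the kernel fallback.

The worked-example fixture (three miRNAs, four diseases) is also built
here; its score for the pair (m1, d1) under default parameters is the
package's primary correctness gate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, AssociationTable, DiseaseDAG, SimilarityMatrix

#: mean similarity drawn for cross-block pairs (below the default edge
#: threshold of 0.5, so cross-block similarity edges rarely survive)
BETWEEN_BLOCK_SIM = 0.15


@dataclass(frozen=True)
class SyntheticSpec:
    nm: int = 60
    nd: int = 40
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.3
    between_block_assoc_prob: float = 0.02
    sim_signal: float = 0.8
    sim_noise: float = 0.1
    fs_coverage_frac: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (
            self.within_block_assoc_prob,
            self.between_block_assoc_prob,
            self.fs_coverage_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.sim_signal <= 1.0:
            raise ValueError("sim_signal must lie in [0, 1]")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be non-negative")
        if self.nm < 1 or self.nd < 1 or self.n_blocks < 1:
            raise ValueError("entity and block counts must be positive")


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def _block_similarity(
    blocks: np.ndarray, signal: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric clipped-normal similarity with block-dependent means."""
    n = len(blocks)
    means = np.where(blocks[:, None] == blocks[None, :], signal, BETWEEN_BLOCK_SIM)
    draw = rng.normal(means, noise) if noise > 0 else means.astype(float)
    sym = np.clip((draw + draw.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return sym


def generate(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[AssociationTable, SimilarityMatrix, SimilarityMatrix]:
    """Draw (associations, FS with partial coverage, SS) from a planted-block spec.

    Fully reproducible from ``spec.seed``. miRNA block b is preferentially
    associated with disease block b.
    """
    rng = np.random.default_rng(spec.seed)
    m_labels = _labels("m", spec.nm)
    d_labels = _labels("d", spec.nd)
    mb = _blocks(spec.nm, spec.n_blocks)
    db = _blocks(spec.nd, spec.n_blocks)

    probs = np.where(
        mb[:, None] == db[None, :], spec.within_block_assoc_prob, spec.between_block_assoc_prob
    )
    Y = (rng.random((spec.nm, spec.nd)) < probs).astype(float)
    if Y.sum() == 0:  # degenerate draw: the kernels need at least one association
        Y[0, 0] = 1.0
    pairs = [(m_labels[i], d_labels[j]) for i, j in zip(*np.nonzero(Y))]
    assoc = AssociationTable.from_pairs(pairs)

    fs_values = _block_similarity(mb, spec.sim_signal, spec.sim_noise, rng)
    cov_draw = rng.random((spec.nm, spec.nm)) < spec.fs_coverage_frac
    coverage = np.triu(cov_draw, 1)
    coverage = coverage | coverage.T
    np.fill_diagonal(coverage, True)
    FS = SimilarityMatrix(np.where(coverage, fs_values, 0.0), m_labels, "FS", coverage)

    ss_values = _block_similarity(db, spec.sim_signal, spec.sim_noise, rng)
    SS = SimilarityMatrix(ss_values, d_labels, "SS")
    return assoc, FS, SS


def block_dags(spec: SyntheticSpec = SyntheticSpec()) -> dict[str, DiseaseDAG]:
    """Ontology DAGs whose semantic similarity echoes the planted blocks.

    Every disease in block b hangs under two block-shared ancestors, both
    children of a common root, so same-block pairs share most of their
    semantic value and cross-block pairs share only the root.
    """
    d_labels = _labels("d", spec.nd)
    db = _blocks(spec.nd, spec.n_blocks)
    root = "ROOT"
    dags = {}
    for d, b in zip(d_labels, db):
        a1, a2 = f"ANC{b + 1}a", f"ANC{b + 1}b"
        edges = frozenset({(root, a1), (root, a2), (a1, d), (a2, d)})
        dags[d] = DiseaseDAG(d, frozenset({d, a1, a2, root}), edges)
    return dags


def permute_labels(assoc: AssociationTable, seed: int) -> AssociationTable:
    """Null model: randomly permute the miRNA column of the association list."""
    if assoc.n_associations == 0:
        raise ValueError("cannot permute an empty association table")
    rng = np.random.default_rng(seed)
    mirnas = assoc.pairs["mirna"].to_numpy()
    permuted = mirnas[rng.permutation(len(mirnas))]
    return AssociationTable.from_pairs(list(zip(permuted, assoc.pairs["disease"])))


def fig1_fixture() -> tuple[AssociationTable, SimilarityMatrix, SimilarityMatrix]:
    """The three-miRNA, four-disease worked-example network.

    Associations m1-d1, m1-d2, m3-d1, m2-d3; miRNA similarities
    m1-m3 = 0.8 and m1-m2 = 0.7; disease similarities d1-d2 = 0.7,
    d1-d3 = 0.9 and d1-d4 = 0.3 (the last deliberately below the default
    edge threshold of 0.5; its exact value is otherwise arbitrary).
    """
    assoc = AssociationTable.from_pairs([("m1", "d1"), ("m1", "d2"), ("m3", "d1"), ("m2", "d3")])
    Sm = np.eye(3)
    Sm[0, 2] = Sm[2, 0] = 0.8
    Sm[0, 1] = Sm[1, 0] = 0.7
    Sd = np.eye(4)
    Sd[0, 1] = Sd[1, 0] = 0.7
    Sd[0, 2] = Sd[2, 0] = 0.9
    Sd[0, 3] = Sd[3, 0] = 0.3
    return (
        assoc,
        SimilarityMatrix(Sm, ["m1", "m2", "m3"], "Sm"),
        SimilarityMatrix(Sd, ["d1", "d2", "d3", "d4"], "Sd"),
    )
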