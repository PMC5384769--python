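"""Core in-memory containers shared across the pipeline.

Labels are plain strings, kept exactly as read (case-sensitive, no
normalization): silent label merges would corrupt the association matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SIMILARITY_ROLES = ("FS", "SS", "KD", "KM", "Sm", "Sd")
#: roles whose diagonal is a self-similarity and must equal 1
_UNIT_DIAG_ROLES = ("SS", "KD", "KM", "Sm", "Sd")

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated list of known miRNA-disease associations."""

    pairs: pd.DataFrame  # columns: mirna, disease

    def __post_init__(self) -> None:
        df = self.pairs
        if list(df.columns) != ["mirna", "disease"]:
            raise ValueError("association table must have columns (mirna, disease)")
        if df.duplicated().any():
            raise ValueError("association table contains duplicate pairs")
        if (df["mirna"].str.len() == 0).any() or (df["disease"].str.len() == 0).any():
            raise ValueError("association labels must be non-empty")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "AssociationTable":
        df = pd.DataFrame(pairs, columns=["mirna", "disease"], dtype=str)
        return cls(df.drop_duplicates(ignore_index=True))

    @property
    def n_associations(self) -> int:
        return len(self.pairs)

    @property
    def mirnas(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["mirna"]))

    @property
    def diseases(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["disease"]))


@dataclass
class AssociationMatrix:
    """Binary adjacency matrix Y (miRNAs x diseases).

    Row i is the interaction profile of miRNA i; column j is the
    interaction profile of disease j.
    """

    values: np.ndarray
    mirna_labels: list[str]
    disease_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_labels), len(self.disease_labels)):
            raise ValueError("Y shape does not match label counts")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("Y entries must be binary")
        for labels, kind in ((self.mirna_labels, "miRNA"), (self.disease_labels, "disease")):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {kind} labels")

    @property
    def nm(self) -> int:
        return len(self.mirna_labels)

    @property
    def nd(self) -> int:
        return len(self.disease_labels)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), list(self.mirna_labels), list(self.disease_labels))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with a coverage mask.

    ``coverage[i, j]`` is True where the value comes from actual knowledge
    (a pair present in the source file / both diseases having an ontology
    DAG); an uncovered cell is *unknown*, which is distinct from an
    explicit similarity of 0.
    """

    values: np.ndarray
    labels: list[str]
    role: str
    coverage: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if self.coverage is None:
            self.coverage = np.ones((n, n), dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.coverage.shape != (n, n):
            raise ValueError("coverage mask shape does not match labels")
        vals = self.values[self.coverage]
        if vals.size and (not np.isfinite(vals).all() or vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError(f"{self.role} similarity values must be finite and in [0, 1]")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > _SYM_TOL:
            raise ValueError(f"{self.role} similarity matrix asymmetric (max |S - S'| = {asym:.3g})")
        if self.role in _UNIT_DIAG_ROLES:
            diag = np.diag(self.values)[np.diag(self.coverage)]
            if diag.size and np.abs(diag - 1.0).max() > 1e-8:
                raise ValueError(f"{self.role} diagonal must equal 1 (self-similarity)")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's MeSH-style DAG: the disease term plus its ancestors.

    ``edges`` are (parent, child) links; both endpoints belong to ``terms``.
    """

    disease: str
    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.disease not in self.terms:
            raise ValueError(f"disease {self.disease!r} missing from its own term set")
        for parent, child in self.edges:
            if parent not in self.terms or child not in self.terms:
                raise ValueError(f"edge ({parent!r}, {child!r}) endpoint outside term set")

    def children_of(self, term: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == term)


@dataclass(frozen=True)
class SemanticProfile:
    """Decayed semantic contributions of a disease's DAG terms."""

    disease: str
    contributions: dict[str, float]
    decay: float

    @property
    def semantic_value(self) -> float:
        return float(sum(self.contributions.values()))


@dataclass
class ScoreMatrix:
    """Real-valued association-confidence scores (miRNAs x diseases)."""

    values: np.ndarray
    mirna_labels: list[str]
    disease_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_labels), len(self.disease_labels)):
            raise ValueError("score matrix shape does not match label counts")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("scores must be finite and non-negative")

    def score(self, mirna: str, disease: str) -> float:
        return float(
            self.values[self.mirna_labels.index(mirna), self.disease_labels.index(disease)]
        )
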