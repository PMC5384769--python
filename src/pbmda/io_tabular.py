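"""Readers and writers for every on-disk artifact.

All tabular inputs are TSV or CSV; the delimiter is sniffed from the first
line (a tab wins over a comma), since supplementary spreadsheets arrive in
unknown export dialects. Labels are matched exactly and case-sensitively.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AssociationMatrix, AssociationTable, DiseaseDAG, ScoreMatrix, SimilarityMatrix

_HEADER_TOKENS = {
    "mirna", "mir", "mirna_name", "mir_name", "name",
    "disease", "disease_name", "child", "child_term", "parent", "parent_term",
}


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ParseError(f"{path}: empty file")
    return "\t" if "\t" in first else ","


def _is_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_associations(path: str | Path) -> AssociationTable:
    """Read a two-column miRNA/disease edge list, deduplicating rows.

    The first row is treated as a header when it contains recognizable
    column names (e.g. "miRNA", "disease"); otherwise it is data.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            if lineno == 1 and _is_header(fields):
                continue
            if not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: empty label")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ParseError(f"{path}: no association rows found")
    return AssociationTable.from_pairs(pairs)


def build_Y(
    assoc: AssociationTable,
    mirna_order: Iterable[str],
    disease_order: Iterable[str],
) -> AssociationMatrix:
    """Build the binary adjacency matrix Y from an association table.

    Y[i, j] = 1 iff miRNA i is known to be associated with disease j.
    """
    mirna_order = list(mirna_order)
    disease_order = list(disease_order)
    mi = {m: i for i, m in enumerate(mirna_order)}
    di = {d: j for j, d in enumerate(disease_order)}
    Y = np.zeros((len(mirna_order), len(disease_order)))
    for m, d in assoc.pairs.itertuples(index=False):
        if m not in mi:
            raise KeyError(f"miRNA label {m!r} not in supplied miRNA order")
        if d not in di:
            raise KeyError(f"disease label {d!r} not in supplied disease order")
        Y[mi[m], di[d]] = 1.0
    return AssociationMatrix(Y, mirna_order, disease_order)


def read_similarity(path: str | Path, role: str) -> SimilarityMatrix:
    """Read a labeled square similarity table.

    Missing cells (empty fields) are recorded as *not covered* in the
    coverage mask -- distinct from an explicit 0. Mild asymmetry (beyond
    1e-8) is symmetrized by averaging with a warning.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ParseError(f"{path}: similarity table must be square with matching row/column labels")
    values = df.to_numpy(dtype=float)
    coverage = np.isfinite(values)
    # a pair is covered if either triangle carries it; take the mean of what is there
    coverage = coverage | coverage.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sym = np.nanmean(np.stack([values, values.T]), axis=0)
    filled = np.where(coverage, sym, 0.0)
    if (filled < -1e-9).any() or (filled > 1 + 1e-9).any():
        bad = filled[coverage]
        raise ParseError(
            f"{path}: similarity values outside [0, 1] (min {bad.min():.4g}, max {bad.max():.4g})"
        )
    both = np.isfinite(values) & np.isfinite(values.T)
    asym = np.abs(values - values.T)[both].max(initial=0.0)
    if asym > 1e-8:
        warnings.warn(f"{path}: asymmetric similarity table (max deviation {asym:.3g}); symmetrized by averaging")
    return SimilarityMatrix(np.clip(filled, 0.0, 1.0), list(df.index), role, coverage)


def write_matrix(matrix: SimilarityMatrix | ScoreMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV (first row/column are labels)."""
    if isinstance(matrix, ScoreMatrix):
        df = pd.DataFrame(matrix.values, index=matrix.mirna_labels, columns=matrix.disease_labels)
    else:
        vals = matrix.values.astype(object)
        vals[~matrix.coverage] = np.nan
        df = pd.DataFrame(vals, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t")


def read_scores(path: str | Path) -> ScoreMatrix:
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ScoreMatrix(df.to_numpy(dtype=float), [str(x) for x in df.index], [str(x) for x in df.columns])


def read_dags(path: str | Path) -> dict[str, DiseaseDAG]:
    """Read a flat per-disease DAG edge list.

    Format: three columns (disease, child_term, parent_term), one row per
    edge. A disease whose term is a root (no ancestors) appears with a
    single self row (disease, disease, disease). Cycles are rejected.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns (disease, child, parent)")
            if lineno == 1 and _is_header(fields):
                continue
            rows.append((fields[0], fields[1], fields[2]))
    if not rows:
        raise ParseError(f"{path}: no DAG rows found")
    dags: dict[str, DiseaseDAG] = {}
    by_disease: dict[str, list[tuple[str, str]]] = {}
    for disease, child, parent in rows:
        by_disease.setdefault(disease, []).append((parent, child))
    for disease, edges in by_disease.items():
        real_edges = frozenset((p, c) for p, c in edges if p != c)
        terms = {disease} | {t for e in real_edges for t in e}
        g = nx.DiGraph(real_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ParseError(f"{path}: cycle detected in DAG of disease {disease!r}")
        dags[disease] = DiseaseDAG(disease, frozenset(terms), real_edges)
    return dags


def write_dags(dags: Mapping[str, DiseaseDAG], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tchild_term\tparent_term\n")
        for disease in sorted(dags):
            dag = dags[disease]
            if not dag.edges:
                fh.write(f"{disease}\t{disease}\t{disease}\n")
            for parent, child in sorted(dag.edges):
                fh.write(f"{disease}\t{child}\t{parent}\n")


def write_associations(assoc: AssociationTable, path: str | Path) -> None:
    assoc.pairs.to_csv(path, sep="\t", index=False, header=["mirna", "disease"])


def rank_candidates(
    scores: ScoreMatrix,
    disease: str,
    exclude_known: AssociationMatrix,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank candidate miRNAs for one disease by descending score.

    miRNAs already known to be associated with the disease are excluded;
    ties are broken by miRNA label ascending.
    """
    if disease not in scores.disease_labels:
        raise KeyError(f"disease label {disease!r} not in score matrix")
    j = scores.disease_labels.index(disease)
    jk = exclude_known.disease_labels.index(disease)
    rows = []
    for i, m in enumerate(scores.mirna_labels):
        ik = exclude_known.mirna_labels.index(m)
        if exclude_known.values[ik, jk] == 0:
            rows.append((m, float(scores.values[i, j])))
    rows.sort(key=lambda r: (-r[1], r[0]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "miRNA": [r[0] for r in rows],
            "score": [r[1] for r in rows],
            "evidence_flag": "unknown",
        }
    )


def write_ranked_list(
    scores: ScoreMatrix,
    disease: str,
    exclude_known: AssociationMatrix,
    top_n: int | None,
    path: str | Path,
) -> pd.DataFrame:
    ranked = rank_candidates(scores, disease, exclude_known, top_n)
    ranked.to_csv(path, sep="\t", index=False)
    return ranked
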