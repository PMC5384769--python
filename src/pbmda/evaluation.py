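"""Cross-validation frameworks and ROC/AUC machinery.

Three evaluation modes over the known-association list:

* **global LOOCV** — each known association is held out in turn, the model
  is retrained (kernels recomputed from the reduced Y), and the held-out
  pair is ranked against every pair with no known association.
* **local LOOCV** — identical, except the held-out pair is ranked only
  against the unknown miRNAs of its own disease.
* **repeated k-fold CV** — the associations are randomly split into k
  folds; each fold is held out in turn and its pairs ranked globally; one
  AUC per random division, repeated ``repeats`` times.

Each held-out positive contributes its normalized rank u = fraction of
candidate (negative) pairs scoring above it, with ties given half weight.
Pooling the u values across test samples yields a single ROC whose area is
mean(1 - u) — the pairwise-comparison AUC where every positive is compared
against its own iteration's candidate pool. This makes diseases (or
iterations) with different candidate counts commensurable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn import metrics as _skm

from .containers import AssociationMatrix, AssociationTable, DiseaseDAG, SimilarityMatrix
from .graph_scoring import PBMDAParams, build_graph, score_all
from .io_tabular import build_Y
from .similarity import (
    DEFAULT_DECAY,
    DEFAULT_GAMMA_PRIME,
    gaussian_kernel_matrix,
    integrate_similarity,
    semantic_similarity_matrix,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    mode: str = "global_loocv"  # global_loocv | local_loocv | kfold
    k: int = 5
    repeats: int = 100
    seed: int = 0
    params: PBMDAParams = field(default_factory=PBMDAParams)
    recompute_kernels: bool = True
    engine: str = "matrix"
    delta: float = DEFAULT_DECAY
    gamma_prime: float = DEFAULT_GAMMA_PRIME
    #: local LOOCV only: average per-disease AUCs instead of pooling ranks
    average_per_disease: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("global_loocv", "local_loocv", "kfold"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for k-fold CV")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class RocCurve:
    """An ROC polyline from (0, 0) to (1, 1) and its trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CVResult:
    per_repeat_auc: list[float]
    mean_auc: float
    sd_auc: float
    roc: RocCurve
    config: CVConfig
    n_skipped: int = 0

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "mode": cfg.mode,
            "k": cfg.k,
            "repeats": cfg.repeats,
            "seed": cfg.seed,
            "threshold": cfg.params.threshold,
            "max_length": cfg.params.max_length,
            "alpha": cfg.params.alpha,
            "delta": cfg.delta,
            "gamma_prime": cfg.gamma_prime,
            "recompute_kernels": cfg.recompute_kernels,
            "engine": cfg.engine,
            "per_repeat_auc": [float(a) for a in self.per_repeat_auc],
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "n_skipped": self.n_skipped,
        }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and AUC from raw scores and binary labels.

    The threshold sweep runs over the distinct score values; with ties the
    area equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc needs at least one positive and one negative label")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return RocCurve(fpr, tpr, float(_skm.auc(fpr, tpr)))


def _rank_roc(u: np.ndarray) -> RocCurve:
    """Pooled ROC from per-positive normalized ranks.

    Sweeping a rank threshold x in [0, 1]: TPR(x) = fraction of positives
    with u <= x, FPR(x) = x. The staircase area equals mean(1 - u).
    """
    u = np.sort(np.asarray(u, dtype=float))
    xs = [0.0]
    ys = [0.0]
    n = len(u)
    vals, counts = np.unique(u, return_counts=True)
    cum = np.cumsum(counts) / n
    prev = 0.0
    for v, f in zip(vals, cum):
        xs.extend([v, v])
        ys.extend([prev, f])
        prev = f
    xs.append(1.0)
    ys.append(1.0)
    return RocCurve(np.asarray(xs), np.asarray(ys), float(np.mean(1.0 - u)))


def _normalized_rank(pos: float, neg: np.ndarray) -> float:
    above = np.count_nonzero(neg > pos)
    ties = np.count_nonzero(neg == pos)
    return (above + 0.5 * ties) / len(neg)


def _resolve_semantic(
    SS_or_dags: SimilarityMatrix | Mapping[str, DiseaseDAG],
    assoc: AssociationTable,
    delta: float,
) -> SimilarityMatrix:
    if isinstance(SS_or_dags, SimilarityMatrix):
        return SS_or_dags
    labels = sorted(set(assoc.diseases) | set(SS_or_dags))
    return semantic_similarity_matrix(SS_or_dags, delta, labels)


class _Trainer:
    """Rebuilds similarities and scores from one training Y."""

    def __init__(self, Y_full: AssociationMatrix, FS: SimilarityMatrix, SS: SimilarityMatrix, config: CVConfig):
        self.FS, self.SS, self.config = FS, SS, config
        self.mirnas = Y_full.mirna_labels
        self.diseases = Y_full.disease_labels
        if not config.recompute_kernels:
            self._KM = gaussian_kernel_matrix(Y_full, "miRNAs", config.gamma_prime)
            self._KD = gaussian_kernel_matrix(Y_full, "diseases", config.gamma_prime)

    def scores(self, Y_train_values: np.ndarray) -> np.ndarray:
        Y = AssociationMatrix(Y_train_values, self.mirnas, self.diseases)
        if self.config.recompute_kernels:
            KM = gaussian_kernel_matrix(Y, "miRNAs", self.config.gamma_prime)
            KD = gaussian_kernel_matrix(Y, "diseases", self.config.gamma_prime)
        else:
            KM, KD = self._KM, self._KD
        Sm = integrate_similarity(self.FS, KM)
        Sd = integrate_similarity(self.SS, KD)
        graph = build_graph(Sm, Sd, Y, self.config.params)
        engine = self.config.engine
        if engine == "matrix" and self.config.params.max_length > 3:
            engine = "dfs"
        return score_all(graph, self.config.params, engine).values


def _prepare(assoc, FS, SS_or_dags, config):
    if assoc.n_associations == 0:
        raise ValueError("empty association set")
    SS = _resolve_semantic(SS_or_dags, assoc, config.delta)
    Y_full = build_Y(assoc, FS.labels, SS.labels)
    trainer = _Trainer(Y_full, FS, SS, config)
    pairs = [
        (FS.labels.index(m), SS.labels.index(d))
        for m, d in assoc.pairs.itertuples(index=False)
    ]
    return Y_full, trainer, pairs


def global_loocv(
    assoc: AssociationTable,
    FS: SimilarityMatrix,
    SS_or_dags: SimilarityMatrix | Mapping[str, DiseaseDAG],
    config: CVConfig | None = None,
) -> CVResult:
    """Leave each association out and rank it against all unknown pairs."""
    config = config or CVConfig(mode="global_loocv")
    Y_full, trainer, pairs = _prepare(assoc, FS, SS_or_dags, config)
    neg_mask = Y_full.values == 0
    u = []
    for i, j in pairs:
        Y_train = Y_full.values.copy()
        Y_train[i, j] = 0.0
        assert Y_train[i, j] == 0.0  # no test-edge leakage into the scored graph
        S = trainer.scores(Y_train)
        u.append(_normalized_rank(S[i, j], S[neg_mask]))
    roc = _rank_roc(np.asarray(u))
    return CVResult([roc.auc], roc.auc, 0.0, roc, config)


def local_loocv(
    assoc: AssociationTable,
    FS: SimilarityMatrix,
    SS_or_dags: SimilarityMatrix | Mapping[str, DiseaseDAG],
    config: CVConfig | None = None,
) -> CVResult:
    """Leave each association out and rank it within its own disease."""
    config = config or CVConfig(mode="local_loocv")
    Y_full, trainer, pairs = _prepare(assoc, FS, SS_or_dags, config)
    neg_mask = Y_full.values == 0
    u, dis, skipped = [], [], 0
    for i, j in pairs:
        cand = neg_mask[:, j]
        if not cand.any():
            logger.warning(
                "disease %s has no candidate miRNAs; test sample skipped", Y_full.disease_labels[j]
            )
            skipped += 1
            continue
        Y_train = Y_full.values.copy()
        Y_train[i, j] = 0.0
        S = trainer.scores(Y_train)
        u.append(_normalized_rank(S[i, j], S[cand, j]))
        dis.append(j)
    if not u:
        raise ValueError("no rankable test samples in local LOOCV")
    u = np.asarray(u)
    roc = _rank_roc(u)
    if config.average_per_disease:
        per = [np.mean(1.0 - u[np.asarray(dis) == j]) for j in sorted(set(dis))]
        auc = float(np.mean(per))
    else:
        auc = roc.auc
    return CVResult([auc], auc, 0.0, roc, config, n_skipped=skipped)


def kfold_cv(
    assoc: AssociationTable,
    FS: SimilarityMatrix,
    SS_or_dags: SimilarityMatrix | Mapping[str, DiseaseDAG],
    config: CVConfig | None = None,
) -> CVResult:
    """Repeated random k-fold CV with globally ranked test folds.

    Each repeat draws an independent random division of the associations
    from a counter-based substream of the master seed, so repeats are
    order-insensitive. One AUC per repeat; the reported sd is over the
    repeat-level AUCs.
    """
    config = config or CVConfig(mode="kfold")
    Y_full, trainer, pairs = _prepare(assoc, FS, SS_or_dags, config)
    if config.k > len(pairs):
        raise ValueError(f"k={config.k} exceeds the association count {len(pairs)}")
    neg_mask = Y_full.values == 0
    per_repeat = []
    all_u = []
    for r in range(config.repeats):
        rng = np.random.default_rng([config.seed, r])
        order = rng.permutation(len(pairs))
        u = []
        for fold in np.array_split(order, config.k):
            Y_train = Y_full.values.copy()
            for t in fold:
                Y_train[pairs[t]] = 0.0
            S = trainer.scores(Y_train)
            neg = S[neg_mask]
            for t in fold:
                u.append(_normalized_rank(S[pairs[t]], neg))
        per_repeat.append(float(np.mean(1.0 - np.asarray(u))))
        all_u.extend(u)
    roc = _rank_roc(np.asarray(all_u))
    return CVResult(
        per_repeat,
        float(np.mean(per_repeat)),
        float(np.std(per_repeat)),
        roc,
        config,
    )


def run_cv(assoc, FS, SS_or_dags, config: CVConfig) -> CVResult:
    if config.mode == "global_loocv":
        return global_loocv(assoc, FS, SS_or_dags, config)
    if config.mode == "local_loocv":
        return local_loocv(assoc, FS, SS_or_dags, config)
    return kfold_cv(assoc, FS, SS_or_dags, config)
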