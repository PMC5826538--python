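"""Conformity scoring, pooled ROC/AUC, and threshold/weight optimization.

A threshold (or weight triple) is judged by how well the resulting per-family
score vectors discriminate families from one another.  Every sequence in the
dataset is conformity-scored against every FOI: the sum of the FOI's score
vector over the columns where the sequence's residue belongs to the FOI's
retained residue repertoire.  Pooling over all FOIs, scores of sequences that
belong to the FOI (``family_scores``, positives) should exceed those of
sequences that do not (``nonfamily_scores``, negatives); the pooled AUC
quantifies this and is the objective of every sweep.

AUC is computed as the midrank Mann–Whitney statistic, which equals the
trapezoidal area under the empirical ROC curve exactly and is threshold-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .alignment_io import DEFAULT_MIN_FREQ, FamilyAssignment, MasterAlignment
from .measures import Thresholds
from .scoring import ScoringEngine, Weights

#: default sweep grids per measure
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "pc": np.arange(0, 11, 1),
    "ent": np.arange(0.0, 2.5 + 1e-9, 0.125),
    "prob": np.arange(0.0, 0.9 + 1e-9, 0.02),
    "prob_with_replacement": np.arange(0.0, 0.9 + 1e-9, 0.02),
}


@dataclass
class ROCResult:
    auc: float
    curve: np.ndarray  # (k, 2) columns: 1 - specificity, sensitivity


@dataclass
class SweepResult:
    grid: list
    aucs: np.ndarray
    best_value: object
    best_auc: float


def conformity_score(
    seq_row: str,
    score_vector: np.ndarray,
    distinct_sets: list[frozenset[str]] | tuple[frozenset[str], ...],
) -> float:
    """Sum of the FOI's scores at columns where the sequence conforms.

    A sequence conforms to the FOI at column p when its symbol at p is one of
    the FOI's retained symbols at p.
    """
    score_vector = np.asarray(score_vector)
    if len(seq_row) != len(score_vector) or len(seq_row) != len(distinct_sets):
        raise ValueError("sequence, score vector and profile sets must align")
    return float(
        sum(
            s
            for a, s, dset in zip(seq_row, score_vector, distinct_sets)
            if a in dset
        )
    )


def conformity_matrix(
    engine: ScoringEngine, scores: np.ndarray, prefilter: bool = False
) -> np.ndarray:
    """(n_seqs, F) conformity scores of every sequence against every FOI.

    ``scores`` is the (F, N) per-measure (or integrated) score matrix.
    Membership is tested against the post-filter distinct sets by default.
    """
    masks = engine.masks_prefilter if prefilter else engine.masks  # (F, N)
    bits = (np.int64(1) << engine.matrix.astype(np.int64))  # (n_seqs, N)
    out = np.empty((engine.matrix.shape[0], engine.F))
    for f in range(engine.F):
        conform = (bits & masks[f][None, :]) != 0
        out[:, f] = conform @ scores[f]
    return out


def conformity_pool(
    engine: ScoringEngine, scores: np.ndarray, prefilter: bool = False
) -> pd.DataFrame:
    """Pooled (sequence, FOI) conformity entries with positive/negative labels."""
    C = conformity_matrix(engine, scores, prefilter=prefilter)
    fam_of_seq = np.array(
        [
            engine.family_ids.index(engine.families.seq_to_family[sid])
            if sid in engine.families.seq_to_family
            else -1
            for sid in engine.alignment.ids
        ]
    )
    n_seqs, F = C.shape
    seq_idx, foi_idx = np.meshgrid(np.arange(n_seqs), np.arange(F), indexing="ij")
    df = pd.DataFrame(
        {
            "seq_id": np.asarray(engine.alignment.ids)[seq_idx.ravel()],
            "foi": np.asarray(engine.family_ids)[foi_idx.ravel()],
            "score": C.ravel(),
            "label": (fam_of_seq[seq_idx.ravel()] == foi_idx.ravel()),
        }
    )
    return df[fam_of_seq[seq_idx.ravel()] >= 0].reset_index(drop=True)


def _auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pooled_roc_auc(
    scores: np.ndarray | pd.DataFrame, labels: np.ndarray | None = None
) -> ROCResult:
    """Midrank AUC and empirical ROC curve for pooled conformity scores.

    Accepts either a pool frame with ``score``/``label`` columns or parallel
    score and boolean label arrays.  Ties contribute half wins (midranks),
    so the AUC equals the trapezoidal area under the returned curve.
    """
    if isinstance(scores, pd.DataFrame):
        labels = scores["label"].to_numpy(dtype=bool)
        scores = scores["score"].to_numpy(dtype=float)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pool must contain at least one positive and one negative")

    auc = _auc_from_ranks(scores, labels)

    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(~l)
    boundary = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    curve = np.column_stack(
        [np.r_[0.0, fp[boundary] / n_neg], np.r_[0.0, tp[boundary] / n_pos]]
    )
    return ROCResult(auc=auc, curve=curve)


def sweep_threshold(
    alignment: MasterAlignment | None = None,
    families: FamilyAssignment | None = None,
    measure: str = "pc",
    grid: np.ndarray | list | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    engine: ScoringEngine | None = None,
    base_thresholds: Thresholds | None = None,
    prefilter_membership: bool = False,
) -> SweepResult:
    """Pooled AUC for each candidate threshold of one measure; argmax returned.

    Ties in the maximum AUC are broken toward the smallest threshold.
    """
    if engine is None:
        engine = ScoringEngine(alignment, families, min_freq=min_freq)
    if grid is None:
        grid = DEFAULT_GRIDS[measure]
    grid = list(np.asarray(grid).tolist())
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    base = base_thresholds or Thresholds()

    fam_labels = _pool_labels(engine)
    aucs = np.empty(len(grid))
    for gi, t in enumerate(grid):
        thr = _with_threshold(base, measure, t)
        scores = engine.measure_scores(measure, thr)
        C = conformity_matrix(engine, scores, prefilter=prefilter_membership)
        aucs[gi] = _auc_from_ranks(C.ravel()[fam_labels >= 0],
                                   (fam_labels[fam_labels >= 0] == 1))
    best_i = int(np.argmax(aucs))  # argmax returns the first (smallest) maximizer
    return SweepResult(
        grid=grid, aucs=aucs, best_value=grid[best_i], best_auc=float(aucs[best_i])
    )


def _with_threshold(base: Thresholds, measure: str, value) -> Thresholds:
    if measure == "pc":
        return Thresholds(t_p=int(value), t_e=base.t_e, t_s=base.t_s)
    if measure == "ent":
        return Thresholds(t_p=base.t_p, t_e=float(value), t_s=base.t_s)
    if measure in ("prob", "prob_with_replacement"):
        return Thresholds(t_p=base.t_p, t_e=base.t_e, t_s=float(value))
    raise ValueError(f"unknown measure {measure!r}")


def _pool_labels(engine: ScoringEngine) -> np.ndarray:
    """Flattened (n_seqs × F) labels: 1 positive, 0 negative, -1 unmapped."""
    fam_of_seq = np.array(
        [
            engine.family_ids.index(engine.families.seq_to_family[sid])
            if sid in engine.families.seq_to_family
            else -1
            for sid in engine.alignment.ids
        ]
    )
    n_seqs = engine.matrix.shape[0]
    labels = np.full((n_seqs, engine.F), -1, dtype=np.int8)
    mapped = fam_of_seq >= 0
    labels[mapped, :] = 0
    labels[np.nonzero(mapped)[0], fam_of_seq[mapped]] = 1
    return labels.ravel()


def simplex_weight_grid(step: float = 0.005) -> list[tuple[float, float, float]]:
    """All weight triples on the unit simplex with the given step, in
    lexicographically ascending (pc_wt, ent_wt, prob_wt) order."""
    n = int(round(1.0 / step))
    grid = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            grid.append((i * step, j * step, k * step))
    return grid


def sweep_weights(
    alignment: MasterAlignment | None = None,
    families: FamilyAssignment | None = None,
    thresholds: Thresholds | None = None,
    step: float = 0.005,
    grid: list[tuple[float, float, float]] | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    engine: ScoringEngine | None = None,
    prefilter_membership: bool = False,
) -> SweepResult:
    """Pooled AUC for each weight triple combining the three measure scores.

    Conformity scores are linear in the score vector, so the per-measure
    conformity components are computed once and recombined per triple.  By
    default the search runs on the unit simplex (pc+ent+prob = 1), which
    loses nothing since AUC is invariant under positive scaling of the
    weights; pass an explicit ``grid`` of triples for other designs.
    All-zero triples are skipped.  Ties are broken toward the
    lexicographically smallest triple.
    """
    if engine is None:
        engine = ScoringEngine(alignment, families, min_freq=min_freq)
    thresholds = thresholds or Thresholds()
    if grid is None:
        grid = simplex_weight_grid(step)
    grid = [tuple(w) for w in grid if sum(w) > 0]
    if not grid:
        raise ValueError("weight grid must contain a non-zero triple")

    comps = np.stack(
        [
            conformity_matrix(
                engine,
                engine.measure_scores(m, thresholds),
                prefilter=prefilter_membership,
            ).ravel()
            for m in ("pc", "ent", "prob")
        ],
        axis=1,
    )  # (n_seqs*F, 3)
    fam_labels = _pool_labels(engine)
    keep = fam_labels >= 0
    comps = comps[keep]
    labels = fam_labels[keep] == 1

    aucs = np.empty(len(grid))
    for gi, w in enumerate(grid):
        aucs[gi] = _auc_from_ranks(comps @ np.asarray(w), labels)
    best_i = int(np.argmax(aucs))  # first maximizer = lexicographically smallest
    return SweepResult(
        grid=grid, aucs=aucs, best_value=grid[best_i], best_auc=float(aucs[best_i])
    )
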