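"""The full scoring pipeline: pairwise family comparison → decision matrices →
per-measure scores → integrated ID_score.

For a family of interest (FOI), every alignment column is compared against the
corresponding column of every family in the dataset (the nFOIs, the FOI
itself included).  Each comparison yields a binary decision per measure;
averaging the F decisions per column gives the per-measure score in [0, 1]
(the fraction of pairwise comparisons in which the column is differentially
conserved).  A weighted linear combination of the three per-measure scores is
the integrated discriminatory score (ID_score).

The :class:`ScoringEngine` vectorizes the whole computation: per-family column
count tensors are built once and shared by all FOIs, and per-FOI pairwise
statistics (pooled property counts, pooled entropies, draw probabilities) are
cached so that threshold sweeps only re-apply cheap comparisons.  Results are
contractually identical to the naive per-(FOI, nFOI, column) recomputation via
:func:`idscore.alignment_io.column_profile` and the scalar measure functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alignment_io import (
    DEFAULT_MIN_FREQ,
    FamilyAssignment,
    MasterAlignment,
)
from .alphabet import GAP_INDEX, N_SYMBOLS
from .measures import Thresholds, pc_of_masks

MEASURES = ("pc", "ent", "prob", "prob_with_replacement")


@dataclass(frozen=True)
class Weights:
    """Nonnegative weights of the linear score integration.

    The defaults keep only the physicochemical and entropy measures, in the
    proportion that maximizes family discriminability; the probability measure
    is optimally weighted at zero.
    """

    pc_wt: float = 0.615
    ent_wt: float = 0.385
    prob_wt: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pc_wt, self.ent_wt, self.prob_wt) < 0:
            raise ValueError("weights must be nonnegative")
        if self.pc_wt + self.ent_wt + self.prob_wt <= 0:
            raise ValueError("weights must not all be zero")

    def as_array(self) -> np.ndarray:
        return np.array([self.pc_wt, self.ent_wt, self.prob_wt])


@dataclass
class DecisionMatrix:
    """F × N binary matrix of one measure's decisions for a single FOI."""

    foi: str
    measure: str
    family_ids: tuple[str, ...]
    values: np.ndarray  # (F, N) uint8


@dataclass
class ScoreTable:
    """Per-family score vectors over all alignment columns (values in [0, 1])."""

    family_ids: tuple[str, ...]
    pc_score: np.ndarray  # (F, N)
    ent_score: np.ndarray
    prob_score: np.ndarray
    id_score: np.ndarray
    thresholds: Thresholds = field(default_factory=Thresholds)
    weights: Weights = field(default_factory=Weights)

    @property
    def n_cols(self) -> int:
        return self.pc_score.shape[1]

    def family_index(self, family_id: str) -> int:
        try:
            return self.family_ids.index(family_id)
        except ValueError:
            raise KeyError(f"unknown family: {family_id!r}") from None

    def scores_for(self, family_id: str) -> dict[str, np.ndarray]:
        i = self.family_index(family_id)
        return {
            "pc_score": self.pc_score[i],
            "ent_score": self.ent_score[i],
            "prob_score": self.prob_score[i],
            "id_score": self.id_score[i],
        }

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (family, position)."""
        frames = []
        pos = np.arange(1, self.n_cols + 1)
        for i, fid in enumerate(self.family_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "family": fid,
                        "position": pos,
                        "pc_score": self.pc_score[i],
                        "ent_score": self.ent_score[i],
                        "prob_score": self.prob_score[i],
                        "id_score": self.id_score[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_wide_frame(self, measure: str = "id_score", ndigits: int = 4) -> pd.DataFrame:
        """Wide format: one row per family, columns ``pos_1 … pos_N``."""
        arr = getattr(self, measure)
        cols = [f"pos_{p}" for p in range(1, self.n_cols + 1)]
        df = pd.DataFrame(np.round(arr, ndigits), columns=cols)
        df.insert(0, "family", list(self.family_ids))
        return df


def _entropy_of_counts(counts: np.ndarray) -> np.ndarray:
    """Entropy (nats) along the last (symbol) axis; 0 where the total is 0."""
    totals = counts.sum(axis=-1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[..., None]
        term = np.where(p > 0, p * np.log(p), 0.0)
    ent = -term.sum(axis=-1)
    return np.where(totals > 0, ent, 0.0)


class ScoringEngine:
    """Vectorized pipeline state for one (alignment, family map, filter) triple.

    Parameters
    ----------
    empty_profile_policy:
        ``"zero"`` (default): every decision involving an empty post-filter
        profile is 0 — an empty category is uninformative, and vacuous
        conservation of ten absent properties would be an artifact.
        ``"literal"``: empty profiles take their face-value measures
        (pc = 10, entropy = 0, draw probability 1 for an empty FOI).
    mask_gap_columns:
        if True, zero all decisions of an FOI at columns where its retained
        profile is 100% gaps (by the literal rules a gap-only column counts
        as perfectly property-conserved, since gaps carry no properties).
    """

    def __init__(
        self,
        alignment: MasterAlignment,
        families: FamilyAssignment,
        min_freq: float = DEFAULT_MIN_FREQ,
        empty_profile_policy: str = "zero",
        mask_gap_columns: bool = False,
    ) -> None:
        if empty_profile_policy not in ("zero", "literal"):
            raise ValueError("empty_profile_policy must be 'zero' or 'literal'")
        self.alignment = alignment
        self.families = families
        self.min_freq = float(min_freq)
        self.empty_profile_policy = empty_profile_policy
        self.mask_gap_columns = mask_gap_columns

        # deterministic family order: lexicographic by family_id
        self.family_ids: tuple[str, ...] = families.family_ids
        self.F = len(self.family_ids)
        self.N = alignment.n_cols
        if self.F == 0:
            raise ValueError("no families to score")

        M = alignment.matrix()
        self.matrix = M
        self.family_sizes = np.zeros(self.F, dtype=np.int64)
        raw = np.zeros((self.F, self.N, N_SYMBOLS), dtype=np.int32)
        for i, fid in enumerate(self.family_ids):
            idx = [alignment.index(sid) for sid in families.members(fid)]
            sub = M[idx]
            offsets = sub.astype(np.int64) + N_SYMBOLS * np.arange(self.N)
            raw[i] = np.bincount(
                offsets.ravel(), minlength=N_SYMBOLS * self.N
            ).reshape(self.N, N_SYMBOLS)
            self.family_sizes[i] = len(idx)

        self.raw_counts = raw
        keep = raw >= (self.family_sizes[:, None, None] * self.min_freq - 1e-9)
        self.counts = np.where(keep, raw, 0).astype(np.int32)
        self.totals = self.counts.sum(axis=-1)
        self.empty = self.totals == 0
        self.gap_only = (self.totals > 0) & (
            self.counts[..., GAP_INDEX] == self.totals
        )

        bits = (1 << np.arange(N_SYMBOLS, dtype=np.int64))
        self.masks = ((self.counts > 0) * bits).sum(axis=-1)
        self.masks_prefilter = ((raw > 0) * bits).sum(axis=-1)
        self.pc = pc_of_masks(self.masks)  # (F, N) int8
        self.ent = _entropy_of_counts(self.counts)  # (F, N)

        self._pair_cache: dict[tuple[int, str], np.ndarray] = {}

    # -- pairwise statistics (threshold-independent, cached per FOI) --------

    def pair_stats(self, foi_index: int, name: str) -> np.ndarray:
        key = (foi_index, name)
        if key in self._pair_cache:
            return self._pair_cache[key]
        if name == "pc_both":
            v = pc_of_masks(self.masks[foi_index][None, :] | self.masks)
        elif name == "ent_both":
            merged = self.counts[foi_index][None, ...] + self.counts
            v = _entropy_of_counts(merged)
        elif name == "prob":
            v = self._prob_without_replacement(foi_index)
        elif name == "prob_with_replacement":
            v = self._prob_with_replacement(foi_index)
        else:
            raise ValueError(f"unknown pairwise statistic {name!r}")
        self._pair_cache[key] = v
        return v

    def _prob_without_replacement(self, i: int) -> np.ndarray:
        nf = self.counts[i]  # (N, 22)
        ng = self.counts  # (F, N, 22)
        invalid = (nf[None, ...] > ng).any(axis=-1)
        kk = np.minimum(nf[None, ...], ng)
        lognum = (gammaln(ng + 1) - gammaln(kk + 1) - gammaln(ng - kk + 1)).sum(axis=-1)
        tf = self.totals[i][None, :]
        tg = self.totals
        td = np.where(tg >= tf, tg - tf, 0)
        logden = gammaln(tg + 1) - gammaln(tf + 1) - gammaln(td + 1)
        prob = np.exp(lognum - logden)
        prob[invalid] = 0.0
        return np.clip(prob, 0.0, 1.0)

    def _prob_with_replacement(self, i: int) -> np.ndarray:
        nf = self.counts[i].astype(np.float64)  # (N, 22)
        ng = self.counts.astype(np.float64)  # (F, N, 22)
        tg = self.totals.astype(np.float64)  # (F, N)
        invalid = ((ng == 0) & (nf[None, ...] > 0)).any(axis=-1)
        logcoef = gammaln(self.totals[i] + 1) - gammaln(nf + 1).sum(axis=-1)  # (N,)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = nf[None, ...] * (np.log(ng) - np.log(tg)[..., None])
        term = np.where(nf[None, ...] > 0, term, 0.0)
        prob = np.exp(logcoef[None, :] + term.sum(axis=-1))
        prob[invalid] = 0.0
        return np.clip(np.nan_to_num(prob, nan=0.0), 0.0, 1.0)

    # -- decisions and scores ----------------------------------------------

    def family_index(self, family_id: str) -> int:
        try:
            return self.family_ids.index(family_id)
        except ValueError:
            raise KeyError(f"unknown family: {family_id!r}") from None

    def decisions(
        self, foi: str | int, measure: str, thresholds: Thresholds
    ) -> np.ndarray:
        """(F, N) uint8 decision matrix of ``measure`` for the given FOI."""
        i = foi if isinstance(foi, int) else self.family_index(foi)
        if measure == "pc":
            pcf = self.pc[i][None, :]
            pcn = self.pc
            pcb = self.pair_stats(i, "pc_both")
            t = thresholds.t_p
            d = (pcf >= t) & ((pcn < t) | ((pcn >= t) & (pcb < t)))
        elif measure == "ent":
            entf = self.ent[i][None, :]
            entn = self.ent
            entb = self.pair_stats(i, "ent_both")
            t = thresholds.t_e
            d = (entf <= t) & ((entn > t) | ((entn <= t) & (entb > t)))
        elif measure in ("prob", "prob_with_replacement"):
            prob = self.pair_stats(i, measure)
            d = prob <= thresholds.t_s
        else:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        if self.empty_profile_policy == "zero":
            d = d & ~(self.empty[i][None, :] | self.empty)
        if self.mask_gap_columns:
            d = d & ~self.gap_only[i][None, :]
        return d.astype(np.uint8)

    def measure_scores(self, measure: str, thresholds: Thresholds) -> np.ndarray:
        """(F, N) matrix of per-measure scores: row i is FOI i's score vector."""
        out = np.empty((self.F, self.N))
        for i in range(self.F):
            out[i] = self.decisions(i, measure, thresholds).mean(axis=0)
        return out


# ---------------------------------------------------------------------------
# public operations


def decision_matrix(
    alignment: MasterAlignment,
    families: FamilyAssignment,
    foi: str,
    measure: str,
    thresholds: Thresholds | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    engine: ScoringEngine | None = None,
) -> DecisionMatrix:
    """Binary decisions of one measure for one FOI against every family."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if engine is None:
        engine = ScoringEngine(alignment, families, min_freq=min_freq)
    thresholds = thresholds or Thresholds()
    values = engine.decisions(foi, measure, thresholds)
    return DecisionMatrix(
        foi=foi, measure=measure, family_ids=engine.family_ids, values=values
    )


def measure_score(dm: DecisionMatrix) -> np.ndarray:
    """Column means of the decision matrix (self-comparison row included in
    the denominator, so the maximum attainable score is (F-1)/F)."""
    return dm.values.mean(axis=0)


def id_score(
    pc: np.ndarray, ent: np.ndarray, prob: np.ndarray, weights: Weights | None = None
) -> np.ndarray:
    """Elementwise weighted combination of the three per-measure score vectors."""
    weights = weights or Weights()
    pc, ent, prob = np.asarray(pc), np.asarray(ent), np.asarray(prob)
    if not (pc.shape == ent.shape == prob.shape):
        raise ValueError("score vectors must have equal lengths")
    return weights.pc_wt * pc + weights.ent_wt * ent + weights.prob_wt * prob


def score_all_families(
    alignment: MasterAlignment,
    families: FamilyAssignment,
    thresholds: Thresholds | None = None,
    weights: Weights | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    empty_profile_policy: str = "zero",
    mask_gap_columns: bool = False,
    engine: ScoringEngine | None = None,
    prob_variant: str = "prob",
) -> ScoreTable:
    """Run the complete pipeline with every family as the FOI."""
    thresholds = thresholds or Thresholds()
    weights = weights or Weights()
    if engine is None:
        engine = ScoringEngine(
            alignment,
            families,
            min_freq=min_freq,
            empty_profile_policy=empty_profile_policy,
            mask_gap_columns=mask_gap_columns,
        )
    pc = engine.measure_scores("pc", thresholds)
    ent = engine.measure_scores("ent", thresholds)
    prob = engine.measure_scores(prob_variant, thresholds)
    ids = id_score(pc, ent, prob, weights)
    return ScoreTable(
        family_ids=engine.family_ids,
        pc_score=pc,
        ent_score=ent,
        prob_score=prob,
        id_score=ids,
        thresholds=thresholds,
        weights=weights,
    )
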