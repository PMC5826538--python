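"""Per-column pairwise conservation measures and their binary uniqueness rules.

For a pair (FOI, nFOI) of families at one alignment column, three measures
quantify whether the column is differentially conserved in the family of
interest:

``pc``
    conservation of physicochemical properties: the number of the 10 classic
    residue property classes (hydrophobic, polar, small, proline, tiny,
    aliphatic, aromatic, positive, negative, charged) that are either
    uniformly present or uniformly absent across the retained residues.
``ent``
    Shannon entropy (nats) of the retained residue frequencies over the
    22-symbol alphabet, each symbol counted individually.
``prob``
    probability of drawing the FOI's exact residue multiset, without
    replacement, from the nFOI's residue pool (a multivariate hypergeometric
    point mass); a with-replacement (multinomial) variant is also provided.

Each measure turns into a 0/1 decision by comparison against a threshold
(``t_p``, ``t_e``, ``t_s``): a column is flagged either when the FOI is
conserved and the nFOI is not, or when both are conserved but conserve
*different* residues/properties (detected on the pooled FOI+nFOI profile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import ColumnProfile
from .alphabet import ALPHABET, MAX_ENTROPY, SYMBOL_INDEX, symbol_bitmask

# ---------------------------------------------------------------------------
# physicochemical property table

PROPERTY_ORDER: tuple[str, ...] = (
    "hydrophobic",
    "polar",
    "small",
    "proline",
    "tiny",
    "aliphatic",
    "aromatic",
    "positive",
    "negative",
    "charged",
)

PROPERTY_SETS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("CYWHKREQDNST"),
    "small": frozenset("VCAGDNSTP"),
    "proline": frozenset("P"),
    "tiny": frozenset("CAGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("HKR"),
    "negative": frozenset("ED"),
    "charged": frozenset("HKRED"),
}

# gap '-' and unknown 'X' belong to none of the 10 properties
PROPERTY_MASKS: np.ndarray = np.array(
    [symbol_bitmask(PROPERTY_SETS[name]) for name in PROPERTY_ORDER], dtype=np.int64
)


def property_bits(symbol: str) -> np.ndarray:
    """10-bit presence vector of ``symbol`` in the fixed property order."""
    try:
        bit = 1 << SYMBOL_INDEX[symbol]
    except KeyError:
        raise ValueError(f"symbol {symbol!r} outside the 22-symbol alphabet") from None
    return ((PROPERTY_MASKS & bit) != 0).astype(np.uint8)


def pc_of_masks(masks: np.ndarray | int) -> np.ndarray | int:
    """Conserved-property count for 22-bit distinct-set masks (vectorized).

    A property is conserved iff it is uniformly present (every symbol in the
    mask carries it) or uniformly absent (no symbol carries it).
    """
    m = np.asarray(masks, dtype=np.int64)
    hit = m[..., None] & PROPERTY_MASKS  # broadcast over the 10 properties
    conserved = (hit == 0) | (hit == m[..., None])
    out = conserved.sum(axis=-1).astype(np.int8)
    return int(out) if np.isscalar(masks) or np.ndim(masks) == 0 else out


def count_conserved_properties(profile: ColumnProfile) -> int:
    """Number of the 10 properties uniform across the profile's distinct symbols."""
    if profile.total < 1:
        raise ValueError("empty profile; empty-profile policy is handled by callers")
    return int(pc_of_masks(profile.mask))


# ---------------------------------------------------------------------------
# thresholds and per-pair measure bundle


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the three measures.

    ``t_p`` (conserved property count, integer 0–10), ``t_e`` (entropy in
    nats, 0–ln 22) and ``t_s`` (draw probability, 0–1).  Defaults are the
    discriminability-optimal values for a large superfamily alignment.
    """

    t_p: int = 4
    t_e: float = 1.375
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.t_p <= 10:
            raise ValueError("t_p must lie in [0, 10]")
        if not 0.0 <= self.t_e <= MAX_ENTROPY + 1e-12:
            raise ValueError("t_e must lie in [0, ln 22]")
        if not 0.0 <= self.t_s <= 1.0:
            raise ValueError("t_s must lie in [0, 1]")


@dataclass(frozen=True)
class PairMeasures:
    """All category measures for one (FOI, nFOI, column) comparison."""

    pc_foi: int
    pc_nfoi: int
    pc_both: int
    ent_foi: float
    ent_nfoi: float
    ent_both: float
    prob_foi: float


def pair_measures(foi: ColumnProfile, nfoi: ColumnProfile) -> PairMeasures:
    """Compute pc/ent/prob category measures for a pair of non-empty profiles.

    The pooled FOI+nFOI category is formed by adding the two post-filter
    count multisets without re-filtering.
    """
    both = foi.merge(nfoi)
    return PairMeasures(
        pc_foi=count_conserved_properties(foi),
        pc_nfoi=count_conserved_properties(nfoi),
        pc_both=count_conserved_properties(both),
        ent_foi=shannon_entropy(foi),
        ent_nfoi=shannon_entropy(nfoi),
        ent_both=shannon_entropy(both),
        prob_foi=prob_foi_without_replacement(foi, nfoi),
    )


# ---------------------------------------------------------------------------
# the three measures


def shannon_entropy(profile: ColumnProfile) -> float:
    """Entropy (nats) of the renormalized retained frequencies; 0 if empty."""
    if profile.total == 0:
        return 0.0
    f = np.array(list(profile.freqs.values()))
    return float(-(f * np.log(f)).sum())


def prob_foi_without_replacement(foi: ColumnProfile, nfoi: ColumnProfile) -> float:
    """P(draw exactly the FOI multiset from the nFOI pool without replacement).

    ``∏_a C(count_nfoi(a), count_foi(a)) / C(|nFOI|, |FOI|)`` with
    ``C(n, k) = 0`` whenever ``k > n``; computed with exact integer binomials.
    """
    if foi.total == 0 or nfoi.total == 0:
        raise ValueError("profiles must be non-empty")
    if foi.total > nfoi.total:
        return 0.0
    num = 1
    for a, k in foi.counts.items():
        n = nfoi.counts.get(a, 0)
        if k > n:
            return 0.0
        num *= math.comb(n, k)
    return num / math.comb(nfoi.total, foi.total)


def prob_foi_with_replacement(foi: ColumnProfile, nfoi: ColumnProfile) -> float:
    """Multinomial variant: FOI multiset drawn with replacement from nFOI.

    ``(|FOI|! / ∏_a count_foi(a)!) · ∏_a (count_nfoi(a) / |nFOI|)^count_foi(a)``;
    0 if any FOI symbol is absent from nFOI.
    """
    if foi.total == 0 or nfoi.total == 0:
        raise ValueError("profiles must be non-empty")
    logp = math.lgamma(foi.total + 1)
    for a, k in foi.counts.items():
        n = nfoi.counts.get(a, 0)
        if n == 0:
            return 0.0
        logp += k * (math.log(n) - math.log(nfoi.total)) - math.lgamma(k + 1)
    return math.exp(logp)


# ---------------------------------------------------------------------------
# binary decisions


def pc_decision(m: PairMeasures, t_p: int) -> int:
    """1 iff properties are conserved in FOI but not nFOI, or conserved
    differently in the two (pooled conservation collapses)."""
    if m.pc_foi >= t_p and m.pc_nfoi < t_p:
        return 1
    if m.pc_foi >= t_p and m.pc_nfoi >= t_p and m.pc_both < t_p:
        return 1
    return 0


def ent_decision(m: PairMeasures, t_e: float) -> int:
    """1 iff randomness is low in FOI but not nFOI, or low in both while the
    pooled distribution is random (different residues conserved)."""
    if m.ent_foi <= t_e and m.ent_nfoi > t_e:
        return 1
    if m.ent_foi <= t_e and m.ent_nfoi <= t_e and m.ent_both > t_e:
        return 1
    return 0


def prob_decision(prob_foi: float, t_s: float) -> int:
    """1 iff the FOI composition is sufficiently improbable under the nFOI pool."""
    if not 0.0 <= prob_foi <= 1.0 + 1e-12:
        raise ValueError("prob_foi must lie in [0, 1]")
    return 1 if prob_foi <= t_s else 0


def dump_property_table() -> "pd.DataFrame":  # noqa: F821 - lazy import
    """Property membership as a 22-row × 10-column 0/1 table (for inspection)."""
    import pandas as pd

    data = {
        name: [1 if s in PROPERTY_SETS[name] else 0 for s in ALPHABET]
        for name in PROPERTY_ORDER
    }
    return pd.DataFrame(data, index=list(ALPHABET))
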