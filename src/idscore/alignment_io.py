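"""Master-alignment and family-map input, plus filtered per-family column profiles.

The master alignment is a single gapped multiple sequence alignment covering an
entire protein superfamily; a separate TSV maps each sequence to its family
(and optionally to a coarser group).  All conservation measures operate on
:class:`ColumnProfile` objects: the multiset of symbols a family presents at
one alignment column after low-frequency symbols (alignment-noise correction)
have been removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, SYMBOL_INDEX, encode_rows, sanitize, symbol_bitmask

log = logging.getLogger(__name__)

#: default minimum within-family symbol frequency retained at a column.
#: Symbols rarer than this in a family are treated as alignment noise.
DEFAULT_MIN_FREQ = 0.085


def passes_frequency_filter(count: int, family_size: int, min_freq: float) -> bool:
    """Strict low-frequency filter: drop iff ``count / family_size < min_freq``.

    The comparison carries a small absolute tolerance so that frequencies that
    equal the threshold up to float rounding (e.g. 17/200 vs 0.085) are
    retained, matching the intended "strictly less than" rule.
    """
    return count >= family_size * min_freq - 1e-9


@dataclass(eq=False)
class MasterAlignment:
    """Equal-length gapped sequences with stable unique identifiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValueError("alignment must contain at least one record")
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dups = sorted({i for i in self.ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate sequence identifiers: {dups}")
        n = len(self.rows[0])
        bad = [sid for sid, row in zip(self.ids, self.rows) if len(row) != n]
        if bad:
            raise ValueError(
                f"alignment rows have unequal lengths; offending ids: {bad}"
            )
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "MasterAlignment":
        """Build from ``(seq_id, row)`` pairs, applying the remap policy."""
        ids, rows = [], []
        n_remapped = 0
        for sid, row in records:
            clean, n = sanitize(row)
            n_remapped += n
            ids.append(sid)
            rows.append(clean)
        if n_remapped:
            log.warning("remapped %d out-of-alphabet characters to X/-", n_remapped)
        return cls(ids=tuple(ids), rows=tuple(rows))

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def index(self, seq_id: str) -> int:
        return self._index[seq_id]

    def matrix(self) -> np.ndarray:
        """(n_seqs, n_cols) int8 matrix of symbol indices (cached)."""
        if self._matrix is None:
            self._matrix = encode_rows(self.rows)
        return self._matrix


@dataclass
class FamilyAssignment:
    """Sequence→family (and optional family→group) labels.

    Defines the FOI/nFOI partitions: the family of interest (FOI) being scored
    and every family it is pairwise-compared against.
    """

    seq_to_family: dict[str, str]
    family_to_group: dict[str, str] = field(default_factory=dict)
    unmapped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        members: dict[str, list[str]] = {}
        for sid, fid in self.seq_to_family.items():
            members.setdefault(fid, []).append(sid)
        self._members = {fid: tuple(sids) for fid, sids in members.items()}

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._members))

    @property
    def n_families(self) -> int:
        return len(self._members)

    def members(self, family_id: str) -> tuple[str, ...]:
        try:
            return self._members[family_id]
        except KeyError:
            raise KeyError(f"unknown family: {family_id!r}") from None


@dataclass(frozen=True)
class ColumnProfile:
    """Post-filter residue multiset of one family at one (1-based) column."""

    family_id: str
    position: int
    counts: dict[str, int]
    total: int
    distinct: frozenset[str]
    freqs: dict[str, float]

    @classmethod
    def from_counts(
        cls, family_id: str, position: int, counts: dict[str, int]
    ) -> "ColumnProfile":
        counts = {a: int(c) for a, c in counts.items() if c > 0}
        total = sum(counts.values())
        freqs = {a: c / total for a, c in counts.items()} if total else {}
        return cls(
            family_id=family_id,
            position=position,
            counts=counts,
            total=total,
            distinct=frozenset(counts),
            freqs=freqs,
        )

    def merge(self, other: "ColumnProfile") -> "ColumnProfile":
        """Pooled FOI+nFOI profile: post-filter counts added, no re-filtering."""
        if self.position != other.position:
            raise ValueError("cannot merge profiles from different columns")
        merged = dict(self.counts)
        for a, c in other.counts.items():
            merged[a] = merged.get(a, 0) + c
        return ColumnProfile.from_counts(
            f"{self.family_id}+{other.family_id}", self.position, merged
        )

    @property
    def mask(self) -> int:
        """22-bit presence mask over the distinct retained symbols."""
        return symbol_bitmask(self.distinct)


def read_alignment(path: str | Path) -> MasterAlignment:
    """Read and validate an aligned FASTA file.

    Rows are uppercased; out-of-alphabet symbols are remapped (``B Z J U O *``
    → ``X``, ``.`` → ``-``) with a logged count.  Unequal row lengths raise a
    format error naming the offending identifiers.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return MasterAlignment.from_records(records)


def write_alignment(alignment: MasterAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_family_map(
    path: str | Path,
    alignment: MasterAlignment,
    min_members: int = 2,
) -> FamilyAssignment:
    """Read a ``seq_id<TAB>family[<TAB>group]`` table restricted to the alignment.

    Alignment identifiers absent from the table are reported in
    ``FamilyAssignment.unmapped``.  A sequence mapped to two different families
    is an error (ambiguous association).  Families with fewer than
    ``min_members`` sequences present in the alignment are dropped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seq_id", "family"}
    if not required.issubset(df.columns):
        raise ValueError(f"family map must have columns {sorted(required)}")
    df = df.dropna(subset=["seq_id", "family"])

    seq_to_family: dict[str, str] = {}
    for sid, fid in zip(df["seq_id"], df["family"]):
        prev = seq_to_family.get(sid)
        if prev is not None and prev != fid:
            raise ValueError(
                f"sequence {sid!r} ambiguously mapped to families {prev!r} and {fid!r}"
            )
        seq_to_family[sid] = fid

    aligned_ids = set(alignment.ids)
    restricted = {s: f for s, f in seq_to_family.items() if s in aligned_ids}
    unmapped = tuple(sid for sid in alignment.ids if sid not in restricted)
    if unmapped:
        log.warning("%d alignment sequences have no family mapping", len(unmapped))

    counts: dict[str, int] = {}
    for fid in restricted.values():
        counts[fid] = counts.get(fid, 0) + 1
    small = {fid for fid, c in counts.items() if c < min_members}
    if small:
        log.warning(
            "dropping %d families with fewer than %d aligned members: %s",
            len(small), min_members, sorted(small),
        )
        restricted = {s: f for s, f in restricted.items() if f not in small}
        unmapped = tuple(sid for sid in alignment.ids if sid not in restricted)

    family_to_group: dict[str, str] = {}
    if "group" in df.columns:
        sub = df.dropna(subset=["group"])
        for fid, gid in zip(sub["family"], sub["group"]):
            prev = family_to_group.get(fid)
            if prev is not None and prev != gid:
                raise ValueError(
                    f"family {fid!r} ambiguously mapped to groups {prev!r} and {gid!r}"
                )
            family_to_group[fid] = gid
        family_to_group = {
            f: g for f, g in family_to_group.items() if f in set(restricted.values())
        }

    return FamilyAssignment(
        seq_to_family=restricted,
        family_to_group=family_to_group,
        unmapped=unmapped,
    )


def write_family_map(families: FamilyAssignment, path: str | Path) -> None:
    rows = [
        {
            "seq_id": sid,
            "family": fid,
            "group": families.family_to_group.get(fid, ""),
        }
        for sid, fid in sorted(families.seq_to_family.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def column_profile(
    alignment: MasterAlignment,
    families: FamilyAssignment,
    family_id: str,
    position: int,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> ColumnProfile:
    """Filtered residue profile of one family at one 1-based column.

    Symbols (gaps and X included) whose within-family frequency is strictly
    below ``min_freq`` are disregarded; frequencies of the retained symbols
    are renormalized to sum to 1.  The profile may be empty (``total == 0``)
    if every symbol falls below the filter.
    """
    if not 1 <= position <= alignment.n_cols:
        raise ValueError(f"position {position} outside 1..{alignment.n_cols}")
    members = families.members(family_id)
    size = len(members)
    raw: dict[str, int] = {}
    for sid in members:
        a = alignment.row(sid)[position - 1]
        raw[a] = raw.get(a, 0) + 1
    kept = {
        a: c for a, c in raw.items() if passes_frequency_filter(c, size, min_freq)
    }
    return ColumnProfile.from_counts(family_id, position, kept)
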