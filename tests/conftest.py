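"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the vectorized engine: they recompute
decisions via per-column profiles and the scalar measure functions
(`naive_score_tables`) or by exhaustive enumeration (`enumerate_draw_prob`),
so that equivalence tests pit two independent routes against each other.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from idscore import (
    FamilyAssignment,
    MasterAlignment,
    SyntheticConfig,
    Thresholds,
    column_profile,
    pair_measures,
    simulate_alignment,
)
from idscore.measures import ent_decision, pc_decision, prob_decision


def make_alignment(rows_by_family: dict[str, list[str]]) -> tuple[MasterAlignment, FamilyAssignment]:
    """Build an alignment + family map from {family: [row, ...]}."""
    ids, rows, s2f = [], [], {}
    for fid in sorted(rows_by_family):
        for i, row in enumerate(rows_by_family[fid]):
            sid = f"{fid}_{i}"
            ids.append(sid)
            rows.append(row)
            s2f[sid] = fid
    return (
        MasterAlignment.from_records(list(zip(ids, rows))),
        FamilyAssignment(seq_to_family=s2f),
    )


def random_alignment(
    rng: np.random.Generator,
    n_families: int = 5,
    seqs_per_family: int = 6,
    n_cols: int = 25,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWYX-",
) -> tuple[MasterAlignment, FamilyAssignment]:
    letters = np.array(list(alphabet))
    rows_by_family = {
        f"fam{f}": [
            "".join(rng.choice(letters, size=n_cols)) for _ in range(seqs_per_family)
        ]
        for f in range(n_families)
    }
    return make_alignment(rows_by_family)


def naive_score_tables(
    alignment: MasterAlignment,
    families: FamilyAssignment,
    thresholds: Thresholds,
    min_freq: float = 0.085,
) -> dict[str, np.ndarray]:
    """Brute-force per-(FOI, nFOI, column) recomputation of all three scores."""
    fids = families.family_ids
    F, N = len(fids), alignment.n_cols
    profs = {
        (f, p): column_profile(alignment, families, f, p, min_freq)
        for f in fids
        for p in range(1, N + 1)
    }
    out = {m: np.zeros((F, N)) for m in ("pc", "ent", "prob")}
    for i, foi in enumerate(fids):
        for p in range(1, N + 1):
            fp = profs[(foi, p)]
            for g in fids:
                gp = profs[(g, p)]
                if fp.total == 0 or gp.total == 0:
                    continue  # empty-profile policy: decisions are 0
                m = pair_measures(fp, gp)
                out["pc"][i, p - 1] += pc_decision(m, thresholds.t_p)
                out["ent"][i, p - 1] += ent_decision(m, thresholds.t_e)
                out["prob"][i, p - 1] += prob_decision(m.prob_foi, thresholds.t_s)
    for k in out:
        out[k] /= F
    return out


def enumerate_draw_prob(foi_counts: dict[str, int], nfoi_counts: dict[str, int]) -> float:
    """Exhaustive oracle for the without-replacement draw probability.

    Enumerates every unordered index-subset of the nFOI pool of size |FOI|
    and counts those whose symbol multiset equals the FOI's.
    """
    pool = [a for a, c in sorted(nfoi_counts.items()) for _ in range(c)]
    k = sum(foi_counts.values())
    if k > len(pool):
        return 0.0
    target = dict(foi_counts)
    hits = 0
    total = 0
    for comb in combinations(range(len(pool)), k):
        total += 1
        drawn: dict[str, int] = {}
        for i in comb:
            drawn[pool[i]] = drawn.get(pool[i], 0) + 1
        hits += drawn == target
    return hits / total


@pytest.fixture(scope="session")
def noise_free_sim():
    """Noise-free, gap-free synthetic dataset with planted specific columns."""
    cfg = SyntheticConfig(seed=11, within_family_noise=0.0, gap_rate=0.0)
    return cfg, *simulate_alignment(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Small noisy dataset used where full defaults would be slow."""
    cfg = SyntheticConfig(
        n_families=4,
        seqs_per_family=30,
        n_cols=60,
        n_specific_cols=2,
        n_global_cols=6,
        seed=5,
    )
    return cfg, *simulate_alignment(cfg)
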