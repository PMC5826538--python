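"""Conformity scoring, pooled ROC/AUC and the optimization sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idscore import (
    Thresholds,
    conformity_pool,
    conformity_score,
    pooled_roc_auc,
    sweep_threshold,
    sweep_weights,
)
from idscore.discrimination import simplex_weight_grid
from idscore.scoring import ScoringEngine, score_all_families
from conftest import make_alignment


class TestConformity:
    def test_worked_example(self):
        sets = [frozenset("ALIM"), frozenset("K")]
        v = np.array([0.4, 0.2])
        assert conformity_score("IK", v, sets) == pytest.approx(0.6)
        assert conformity_score("VK", v, sets) == pytest.approx(0.2)

    def test_all_gap_sequence_scores_zero(self):
        sets = [frozenset("AL"), frozenset("K")]
        assert conformity_score("--", np.array([0.4, 0.2]), sets) == 0.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            conformity_score("AKL", np.array([0.4, 0.2]), [frozenset("A")] * 2)

    def test_pool_has_one_entry_per_sequence_family_pair(self, small_sim):
        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        scores = engine.measure_scores("pc", Thresholds())
        pool = conformity_pool(engine, scores)
        assert len(pool) == aln.n_seqs * len(fam.family_ids)
        assert pool["label"].sum() == aln.n_seqs  # each sequence positive once

    def test_pool_matches_scalar_conformity(self, small_sim):
        from idscore import column_profile

        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        scores = engine.measure_scores("ent", Thresholds())
        pool = conformity_pool(engine, scores)
        foi = fam.family_ids[1]
        sets = [
            column_profile(aln, fam, foi, p).distinct
            for p in range(1, aln.n_cols + 1)
        ]
        sid = aln.ids[0]
        expected = conformity_score(
            aln.row(sid), scores[engine.family_index(foi)], sets
        )
        got = pool.query("seq_id == @sid and foi == @foi")["score"].iloc[0]
        assert got == pytest.approx(expected)


class TestPooledROC:
    def test_perfect_separation(self):
        r = pooled_roc_auc(np.array([3.0, 4.0, 1.0, 2.0]), np.array([1, 1, 0, 0], bool))
        assert r.auc == 1.0

    def test_identical_pools_are_chance(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        assert pooled_roc_auc(scores, labels).auc == 0.5

    def test_tie_counts_half(self):
        r = pooled_roc_auc(np.array([2.0, 3.0, 1.0, 3.0]), np.array([1, 1, 0, 0], bool))
        assert r.auc == pytest.approx(0.625)

    def test_single_class_pool_is_an_error(self):
        with pytest.raises(ValueError):
            pooled_roc_auc(np.array([1.0, 2.0]), np.array([1, 1], bool))

    def test_trapezoid_equals_midrank_statistic(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            r = pooled_roc_auc(scores, labels)
            trap = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
            assert abs(trap - r.auc) < 1e-12

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        scores=st.lists(
            # keep values on a coarse lattice so the transforms below remain
            # strictly monotone in float arithmetic (no underflow collapse)
            st.floats(-5, 5).map(lambda x: round(x, 3)),
            min_size=4,
            max_size=30,
        ),
        cut=st.integers(1, 3),
    )
    def test_invariant_under_monotone_transforms(self, scores, cut):
        scores = np.asarray(scores)
        labels = np.zeros(len(scores), bool)
        labels[:cut] = True
        if labels.all():
            return
        base = pooled_roc_auc(scores, labels).auc
        for f in (lambda x: 3 * x + 2, np.exp, lambda x: x**3):
            assert pooled_roc_auc(f(scores), labels).auc == pytest.approx(base)


class TestThresholdSweep:
    def test_single_element_grid(self, small_sim):
        _, aln, fam, _ = small_sim
        res = sweep_threshold(aln, fam, measure="pc", grid=[4])
        assert res.best_value == 4 and len(res.aucs) == 1

    def test_auc_varies_across_the_grid(self, small_sim):
        """With planted family structure the threshold genuinely matters."""
        _, aln, fam, _ = small_sim
        res = sweep_threshold(aln, fam, measure="pc")
        assert np.ptp(res.aucs) > 0
        assert res.best_auc == max(res.aucs)

    def test_informative_thresholds_beat_degenerate_ones(self, noise_free_sim):
        """At the permissive end of each grid no column is ever flagged
        (t_p = 0: every count passes; t_e = 2.5 ~ saturation: nothing is
        "random"), so discrimination collapses to chance there."""
        _, aln, fam, _ = noise_free_sim
        engine = ScoringEngine(aln, fam)
        pc = sweep_threshold(engine=engine, measure="pc")
        by_tp = dict(zip(pc.grid, pc.aucs))
        assert by_tp[4] > by_tp[0]
        ent = sweep_threshold(engine=engine, measure="ent")
        by_te = dict(zip(ent.grid, ent.aucs))
        assert by_te[1.375] > by_te[2.5]

    def test_empty_grid_is_an_error(self, small_sim):
        _, aln, fam, _ = small_sim
        with pytest.raises(ValueError):
            sweep_threshold(aln, fam, measure="ent", grid=[])


class TestWeightSweep:
    def test_simplex_grid_covers_corners(self):
        grid = simplex_weight_grid(0.25)
        assert (1.0, 0.0, 0.0) in grid and (0.0, 0.0, 1.0) in grid
        assert all(abs(sum(w) - 1) < 1e-9 for w in grid)

    def test_pc_corner_matches_pc_only_auc(self, small_sim):
        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        res = sweep_weights(engine=engine, grid=[(1.0, 0.0, 0.0)])
        ref = sweep_threshold(engine=engine, measure="pc", grid=[4])
        assert res.best_auc == pytest.approx(ref.best_auc, abs=1e-12)

    def test_scaling_a_triple_leaves_auc_unchanged(self, small_sim):
        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        res = sweep_weights(
            engine=engine, grid=[(0.3, 0.2, 0.1), (0.6, 0.4, 0.2)]
        )
        assert res.aucs[0] == pytest.approx(res.aucs[1], abs=1e-12)

    def test_zero_triples_are_skipped(self, small_sim):
        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        res = sweep_weights(engine=engine, grid=[(0, 0, 0), (0.5, 0.5, 0)])
        assert res.grid == [(0.5, 0.5, 0)]

    def test_best_weights_discriminate_on_synthetic_data(self, small_sim):
        _, aln, fam, _ = small_sim
        engine = ScoringEngine(aln, fam)
        res = sweep_weights(engine=engine, step=0.25)
        assert res.best_auc > 0.9
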