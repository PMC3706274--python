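"""Consensus DE calling: pair enumeration, the default caller, tallying
against a brute-force oracle, and monotonicity in the cut-off."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_expression_matrix
from xyloseq.consensus import (
    CallerConfig,
    calls_to_frame,
    consensus,
    default_pair_caller,
    enumerate_pairs,
    run_consensus_de,
    selected_genes,
)
from xyloseq.errors import ConfigError, DesignError
from xyloseq.io import ExpressionMatrix, PairwiseDETable
from xyloseq.simulate import SimConfig, simulate_expression


def brute_force_tally(matrix, ctl_cond, exp_cond, min_abs_lfc=1.0, eps=1.0):
    """Independent oracle: plain-Python loop over every replicate pair."""
    ctl = [s for s in matrix.sample_ids if matrix.condition_of[s] == ctl_cond]
    exp = [s for s in matrix.sample_ids if matrix.condition_of[s] == exp_cond]
    tally = {f: [0, 0] for f in matrix.feature_ids}
    for c in ctl:
        for e in exp:
            for f in matrix.feature_ids:
                vc = matrix.values.loc[f, c]
                ve = matrix.values.loc[f, e]
                lfc = math.log2((ve + eps) / (vc + eps))
                if abs(lfc) >= min_abs_lfc:
                    tally[f][0 if lfc > 0 else 1] += 1
    return tally


class TestEnumeratePairs:
    @pytest.mark.parametrize("r_ctl,r_exp,expected", [(3, 3, 9), (1, 1, 1), (2, 3, 6)])
    def test_cartesian_product_counts(self, r_ctl, r_exp, expected):
        m = random_expression_matrix(np.random.default_rng(0), 2, r_ctl, r_exp)
        pairs = enumerate_pairs(m, "ctl", "exp")
        assert len(pairs) == expected
        assert len(set(pairs)) == expected
        # control-major deterministic order
        assert pairs == [(c, e) for c in m.samples_of("ctl") for e in m.samples_of("exp")]

    def test_unknown_condition(self, tiny_matrix):
        with pytest.raises(DesignError):
            enumerate_pairs(tiny_matrix, "ctl", "nope")


class TestDefaultPairCaller:
    def test_shrunken_fold_change_arithmetic(self, tiny_matrix):
        """v_ctl=1, v_exp=7, eps=1 -> log2(8/2)=2 -> significant, up."""
        table = default_pair_caller(tiny_matrix, ("c_r1", "e_r1"), CallerConfig())
        rec = table.records.set_index("feature_id")
        assert rec.loc["gA", "log2_fold_change"] == pytest.approx(2.0)
        assert rec.loc["gA", "significant"]
        assert rec.loc["gA", "direction"] == "up"

    def test_identical_values_give_no_calls(self):
        vals = pd.DataFrame({"c1": [3.0, 8.0], "e1": [3.0, 8.0]}, index=["f1", "f2"])
        m = ExpressionMatrix(values=vals, condition_of={"c1": "ctl", "e1": "exp"})
        table = default_pair_caller(m, ("c1", "e1"), CallerConfig())
        assert not table.records["significant"].any()

    def test_infinite_threshold_gives_no_calls(self, tiny_matrix):
        cfg = CallerConfig(min_abs_log2fc=float("inf"))
        table = default_pair_caller(tiny_matrix, ("c_r1", "e_r1"), cfg)
        assert not table.records["significant"].any()


def _table(pair, feats, directions):
    rows = []
    for f, d in zip(feats, directions):
        sig = d != "none"
        rows.append((f, 1.0, 2.0, 1.0 if d == "up" else -1.0 if d == "down" else 0.0,
                     0.0 if sig else 1.0, np.nan, sig, d))
    return PairwiseDETable(
        pair_label=pair,
        records=pd.DataFrame(
            rows,
            columns=["feature_id", "value_control", "value_experiment",
                     "log2_fold_change", "p_value", "q_value", "significant", "direction"],
        ),
    )


class TestConsensus:
    def test_unanimous_up_selected_at_full_support(self):
        tables = [_table((f"c{i}", f"e{i}"), ["G"], ["up"]) for i in range(9)]
        (call,) = consensus(tables, cutoff_n=9)
        assert call.support == 9 and call.selected and call.consensus_direction == "up"

    def test_split_direction_not_selected(self):
        """Support 9 split 5 up / 4 down is not consistent behavior."""
        dirs = ["up"] * 5 + ["down"] * 4
        tables = [_table((f"c{i}", f"e{i}"), ["G"], [d]) for i, d in enumerate(dirs)]
        (call,) = consensus(tables, cutoff_n=9)
        assert call.n_up == 5 and call.n_down == 4
        assert not call.selected and call.consensus_direction == "none"

    def test_minority_disagreement_blocks_selection(self):
        dirs = ["up"] * 5 + ["down"]
        tables = [_table((f"c{i}", f"e{i}"), ["G"], [d]) for i, d in enumerate(dirs)]
        (call,) = consensus(tables, cutoff_n=4)
        assert not call.selected
        relaxed = consensus(tables, cutoff_n=4, require_consistent_direction=False)
        assert relaxed[0].selected and relaxed[0].consensus_direction == "up"

    def test_cutoff_bounds(self):
        tables = [_table(("c", "e"), ["G"], ["up"])]
        with pytest.raises(ConfigError):
            consensus(tables, cutoff_n=2)
        with pytest.raises(ConfigError):
            consensus(tables, cutoff_n=0)

    def test_mismatched_universe_rejected(self):
        t1 = _table(("c1", "e1"), ["G1"], ["up"])
        t2 = _table(("c2", "e2"), ["G2"], ["up"])
        with pytest.raises(DesignError):
            consensus([t1, t2], cutoff_n=1)

    def test_output_sorted_by_support_then_id(self):
        tables = [
            _table(("c1", "e1"), ["a", "b", "c"], ["up", "up", "none"]),
            _table(("c2", "e2"), ["a", "b", "c"], ["none", "up", "none"]),
        ]
        calls = consensus(tables, cutoff_n=1)
        assert [c.feature_id for c in calls] == ["b", "a", "c"]


class TestOracleEquivalence:
    def test_brute_force_tally_matches(self):
        """Randomized small instances: package tallies equal a plain-Python
        enumeration of every replicate pair."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n_f = int(rng.integers(1, 6))
            r_c = int(rng.integers(1, 4))
            r_e = int(rng.integers(1, 4))
            m = random_expression_matrix(rng, n_f, r_c, r_e)
            calls = run_consensus_de(m, "ctl", "exp", cutoff_n=1)
            expected = brute_force_tally(m, "ctl", "exp")
            for c in calls:
                assert (c.n_up, c.n_down) == tuple(expected[c.feature_id])

    def test_hand_enumerated_2x2_instance(self):
        """4 features, 2x2 replicates, hand-checkable values."""
        vals = pd.DataFrame(
            {
                "c1": [1.0, 10.0, 1.0, 5.0],
                "c2": [1.0, 10.0, 9.0, 5.0],
                "e1": [7.0, 3.0, 1.0, 5.0],
                "e2": [7.0, 3.0, 9.0, 5.0],
            },
            index=["up_all", "down_all", "mixed", "flat"],
        )
        m = ExpressionMatrix(
            values=vals, condition_of={"c1": "ctl", "c2": "ctl", "e1": "exp", "e2": "exp"}
        )
        calls = {c.feature_id: c for c in run_consensus_de(m, "ctl", "exp", cutoff_n=4)}
        # up_all: log2(8/2)=2 in all four pairs
        assert calls["up_all"].n_up == 4 and calls["up_all"].selected
        # down_all: log2(4/11) ~ -1.46 in all four pairs
        assert calls["down_all"].n_down == 4 and calls["down_all"].selected
        # mixed: c1->e2 up (log2(10/2)), c2->e1 down (log2(2/10)), others flat
        assert (calls["mixed"].n_up, calls["mixed"].n_down) == (1, 1)
        assert not calls["mixed"].selected
        assert calls["flat"].support == 0


class TestMonotonicityAndRecovery:
    def test_selected_set_shrinks_with_cutoff(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            m = random_expression_matrix(rng, int(rng.integers(2, 8)), 3, 3)
            prev = None
            for n in range(1, 10):
                sel = set(selected_genes(run_consensus_de(m, "ctl", "exp", n)))
                if prev is not None:
                    assert sel <= prev
                prev = sel

    def test_identical_conditions_select_nothing(self):
        vals = pd.DataFrame(
            np.tile(np.array([[4.0], [9.0]]), (1, 6)),
            index=["f1", "f2"],
            columns=[f"s{i}" for i in range(6)],
        )
        cond = {f"s{i}": ("ctl" if i < 3 else "exp") for i in range(6)}
        m = ExpressionMatrix(values=vals, condition_of=cond)
        assert selected_genes(run_consensus_de(m, "ctl", "exp", 9)) == []

    def test_planted_direction_recovered(self):
        """On a small simulated matrix nearly all selected features carry the
        planted direction."""
        m, truth = simulate_expression(SimConfig(n_genes=800, n_de=30, seed=42))
        calls = run_consensus_de(m, "control", "experiment", cutoff_n=9)
        selected = [c for c in calls if c.selected]
        assert selected
        agree = sum(
            truth.de_genes.get(c.feature_id) == c.consensus_direction for c in selected
        )
        assert agree / len(selected) >= 0.95

    def test_label_permutation_within_condition_preserves_tallies(self):
        m, _ = simulate_expression(SimConfig(n_genes=100, n_de=5, seed=8))
        calls = run_consensus_de(m, "control", "experiment", cutoff_n=9)
        shuffled = m.values[
            ["control_r2", "control_r3", "control_r1",
             "experiment_r3", "experiment_r1", "experiment_r2"]
        ].copy()
        shuffled.columns = m.sample_ids  # relabel replicates within conditions
        m2 = ExpressionMatrix(values=shuffled, condition_of=m.condition_of)
        calls2 = run_consensus_de(m2, "control", "experiment", cutoff_n=9)
        frame = calls_to_frame(calls).set_index("feature_id").sort_index()
        frame2 = calls_to_frame(calls2).set_index("feature_id").sort_index()
        pd.testing.assert_frame_equal(frame, frame2)
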