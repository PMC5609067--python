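"""Two-control regulon calling, intersections, unique fractions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pcwdn.regulons import (
    ExpressionMatrix,
    RegulonSet,
    Thresholds,
    call_regulon,
    exclusive_intersections,
    expression_from_long,
    fallback_differential,
    unique_fraction,
)
from pcwdn.simulate import SimulationConfig, simulate_expression, simulate_network


def _de(rows, test="Avicel", control="NoC"):
    return pd.DataFrame(
        [{"gene_id": g, "test_condition": test, "control_condition": control,
          "log2fc": lfc, "p_raw": np.nan, "p_adj": p} for g, lfc, p in rows]
    )


class TestFallbackDifferential:
    def test_identical_replicates_give_null_result(self):
        expr = ExpressionMatrix(
            genes=["NCU00001"],
            values={"Avicel": np.full((1, 3), 10.0), "NoC": np.full((1, 3), 10.0)},
        )
        de = fallback_differential(expr, "Avicel", "NoC")
        assert de["log2fc"].iloc[0] == 0.0
        assert de["p_adj"].iloc[0] == 1.0

    def test_bh_step_up_hand_example(self):
        """Raw p (0.01, 0.02, 0.03, 0.04) over 4 genes adjusts to 0.04 each."""
        # exercise the same BH routine the fallback uses, via the raw-p path
        # of a table without p_adj
        df = pd.DataFrame(
            {"gene_id": [f"NCU0000{i}" for i in range(1, 5)],
             "test_condition": "Avicel", "control_condition": "NoC",
             "log2fc": [2.0] * 4, "p_raw": [0.01, 0.02, 0.03, 0.04]}
        )
        from pcwdn.regulons import _prepare_de

        adj = _prepare_de(df)["p_adj"].tolist()
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_replicate_directs_to_precomputed_tables(self):
        expr = ExpressionMatrix(
            genes=["NCU00001"], values={"Avicel": [[8.0]], "NoC": [[1.0]]}
        )
        with pytest.raises(ValueError, match="precomputed"):
            fallback_differential(expr, "Avicel", "NoC")

    def test_planted_induction_detected_at_low_noise(self):
        """Strong planted induction (8-fold, sd 0.1) is found in >=95% of seeds."""
        cfg = SimulationConfig(
            n_genes=100, n_network_genes=50, replicate_noise_sd=0.1, induction_log2fc=3.0
        )
        net, _ = simulate_network(cfg, 0)
        hits = trials = 0
        for seed in range(100):
            expr, truth = simulate_expression(cfg, net, seed)
            de = fallback_differential(expr, "Avicel", "NoC")
            de = de.set_index("gene_id")
            for g in truth.planted_regulons["Avicel"]:
                trials += 1
                hits += de.loc[g, "p_adj"] < 0.05 and de.loc[g, "log2fc"] >= 1
        assert trials > 0
        assert hits / trials >= 0.95
        # and the fold estimate is near the planted effect
        assert de.loc[sorted(truth.planted_regulons["Avicel"])[0], "log2fc"] == pytest.approx(3, abs=0.7)


class TestCallRegulon:
    def test_membership_requires_both_controls(self):
        noc = _de([("NCU00001", 3.0, 0.001), ("NCU00002", 3.0, 0.001), ("NCU00003", 0.5, 0.001)])
        suc = _de([("NCU00001", 2.5, 0.01), ("NCU00002", 3.0, 0.5), ("NCU00003", 3.0, 0.001)],
                  control="sucrose")
        reg = call_regulon(noc, suc, "up")
        assert reg.members == {"NCU00001"}

    def test_twofold_threshold_inclusive(self):
        noc = _de([("NCU00001", 1.0, 0.001)])
        suc = _de([("NCU00001", 1.0, 0.001)], control="sucrose")
        assert call_regulon(noc, suc, "up").members == {"NCU00001"}

    def test_down_direction_uses_negative_fold(self):
        noc = _de([("NCU00001", -2.0, 0.001), ("NCU00002", 2.0, 0.001)])
        suc = _de([("NCU00001", -1.5, 0.001), ("NCU00002", 2.0, 0.001)], control="sucrose")
        down = call_regulon(noc, suc, "down")
        up = call_regulon(noc, suc, "up")
        assert down.members == {"NCU00001"}
        assert not down.members & up.members

    def test_empty_tables_give_empty_regulon(self):
        reg = call_regulon(_de([]), _de([], control="sucrose"), "up")
        assert reg.members == frozenset()

    def test_mismatched_test_conditions_rejected(self):
        noc = _de([("NCU00001", 3.0, 0.001)], test="Avicel")
        suc = _de([("NCU00001", 3.0, 0.001)], test="xylan", control="sucrose")
        with pytest.raises(ValueError, match="mismatched"):
            call_regulon(noc, suc)

    def test_two_control_rule_restricts_single_control_set(self, small_bundle):
        _, expr, _, _, _ = small_bundle
        th = Thresholds()
        de_noc = fallback_differential(expr, "Avicel", "NoC", th)
        de_suc = fallback_differential(expr, "Avicel", "sucrose", th)
        reg = call_regulon(de_noc, de_suc, "up", th)
        vs_noc_only = set(
            de_noc.loc[(de_noc.p_adj < th.alpha) & (de_noc.log2fc >= 1), "gene_id"]
        )
        assert set(reg.members) <= vs_noc_only


class TestExclusiveIntersections:
    def _brute_force(self, sets):
        """Enumerate all non-empty membership patterns directly."""
        names = list(sets)
        out = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(sets[c] for c in combo))
                outside = set.union(*(sets[c] for c in names if c not in combo), set())
                exact = inside - outside
                if exact:
                    out[tuple(c for c in names if c in combo)] = frozenset(exact)
        return out

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"NCU{i:05d}" for i in range(1, 11)]
        sets = {c: set(rng.choice(genes, size=6, replace=False)) for c in "ABC"}
        regs = [RegulonSet(c, "up", frozenset(sets[c])) for c in "ABC"]
        got = exclusive_intersections(regs, min_size=1)
        assert got == self._brute_force(sets)

    def test_partitions_the_union(self):
        rng = np.random.default_rng(6)
        genes = [f"NCU{i:05d}" for i in range(1, 40)]
        regs = [
            RegulonSet(c, "up", frozenset(rng.choice(genes, size=15, replace=False)))
            for c in "ABCD"
        ]
        got = exclusive_intersections(regs, min_size=1)
        union = set().union(*(r.members for r in regs))
        pieces = list(got.values())
        assert sum(len(p) for p in pieces) == len(union)
        for a, b in combinations(pieces, 2):
            assert not a & b

    def test_disjoint_sets_yield_singleton_patterns(self):
        regs = [
            RegulonSet("A", "up", frozenset({"NCU00001"})),
            RegulonSet("B", "up", frozenset({"NCU00002"})),
        ]
        got = exclusive_intersections(regs)
        assert set(got) == {("A",), ("B",)}

    def test_min_size_filter(self):
        regs = [
            RegulonSet("A", "up", frozenset({"NCU00001", "NCU00002"})),
            RegulonSet("B", "up", frozenset({"NCU00003"})),
        ]
        assert set(exclusive_intersections(regs, min_size=2)) == {("A",)}

    def test_mixed_directions_rejected(self):
        regs = [RegulonSet("A", "up", frozenset()), RegulonSet("B", "down", frozenset())]
        with pytest.raises(ValueError, match="direction"):
            exclusive_intersections(regs)


class TestUniqueFraction:
    def test_matches_set_arithmetic(self):
        target = RegulonSet("starch", "up", frozenset({"a", "b", "c", "d"}))
        others = [RegulonSet("x", "up", frozenset({"c", "e"})),
                  RegulonSet("y", "up", frozenset({"d"}))]
        count, frac = unique_fraction(target, others)
        assert (count, frac) == (2, 0.5)

    def test_disjoint_target_fully_unique(self):
        target = RegulonSet("A", "up", frozenset({"a"}))
        count, frac = unique_fraction(target, [RegulonSet("B", "up", frozenset({"b"}))])
        assert (count, frac) == (1, 1.0)

    def test_empty_target_fraction_absent(self):
        count, frac = unique_fraction(RegulonSet("A", "up", frozenset()), [])
        assert count == 0 and frac is None


def test_long_form_round_trip():
    df = pd.DataFrame(
        {"gene_id": ["NCU00001"] * 4, "condition": ["NoC", "NoC", "Avicel", "Avicel"],
         "replicate": [1, 2, 1, 2], "fpkm": [1.0, 2.0, 30.0, 40.0]}
    )
    expr = expression_from_long(df)
    assert expr.values["Avicel"].tolist() == [[30.0, 40.0]]
    assert expr.condition_means().loc["NCU00001", "NoC"] == 1.5
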