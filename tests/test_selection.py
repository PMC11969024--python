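"""Point-mutation ranking, pool selection and combinatorial CM grouping."""

import random

import numpy as np
import pandas as pd
import pytest

from mutascan import (
    Mutation,
    MutationEffect,
    SelectionConfig,
    apply_mutations,
    rank_combinatorial,
    select_improving_mutations,
    summarize_mutation_effects,
)


def enrichment_frame(delta_by_variant_target):
    rows = [
        {"variant": v, "target": t, "log2E": x, "delta_log2E": x,
         "input_imputed": False, "output_imputed": False}
        for (v, t), x in delta_by_variant_target.items()
    ]
    return pd.DataFrame(rows)


def single(parent, pos, to_aa):
    return apply_mutations(parent, {Mutation(pos, parent[pos - 1], to_aa)})


class TestSummarizeEffects:
    def test_single_target_mean_equals_peak(self, parent, panel):
        v = single(parent, 5, "W")
        tbl = enrichment_frame({(v, "CCL2"): 2.5})
        (eff,) = summarize_mutation_effects(tbl, panel, parent, "CC")
        assert eff.mean_delta == eff.peak_delta == 2.5
        assert eff.mutation == Mutation(5, "Y", "W")

    def test_mean_and_peak_over_two_targets(self, parent, panel):
        v = single(parent, 6, "D")
        tbl = enrichment_frame({(v, "CCL2"): 1.0, (v, "CCL5"): 3.0})
        (eff,) = summarize_mutation_effects(tbl, panel, parent, "CC")
        assert eff.mean_delta == pytest.approx(2.0)
        assert eff.peak_delta == pytest.approx(3.0)

    def test_matches_per_row_mean_max_oracle(self, parent, panel):
        rng = random.Random(0)
        targets = panel.names("ALL")
        data = {}
        variants = {}
        for i in range(10):
            pos = i + 1
            to_aa = "W" if parent[pos - 1] != "W" else "F"
            v = single(parent, pos, to_aa)
            variants[v] = [rng.uniform(-3, 6) for _ in targets]
            for t, x in zip(targets, variants[v]):
                data[(v, t)] = x
        effects = summarize_mutation_effects(
            enrichment_frame(data), panel, parent, "ALL"
        )
        by_mut = {str(e.mutation): e for e in effects}
        for v, deltas in variants.items():
            mut = next(iter(
                {str(m) for m in
                 __import__("mutascan").mutations_from_sequence(parent, v)}))
            assert by_mut[mut].mean_delta == pytest.approx(np.mean(deltas))
            assert by_mut[mut].peak_delta == pytest.approx(np.max(deltas))

    def test_multi_mutant_variant_errors(self, parent, panel):
        v = apply_mutations(parent, {Mutation(5, "Y", "W"), Mutation(6, "T", "D")})
        with pytest.raises(ValueError, match="single mutant"):
            summarize_mutation_effects(
                enrichment_frame({(v, "CCL2"): 1.0}), panel, parent, "CC"
            )

    def test_parent_row_skipped(self, parent, panel):
        tbl = enrichment_frame({(parent, "CCL2"): 0.0})
        assert summarize_mutation_effects(tbl, panel, parent, "CC") == []


def effect(pos, from_aa, to_aa, mean, peak, scope="CC"):
    return MutationEffect(Mutation(pos, from_aa, to_aa), scope, mean, peak, 3)


class TestSelectImproving:
    def test_single_passing_candidate_selected(self):
        pools = select_improving_mutations(
            [effect(5, "Y", "W", 1.0, 6.0)], [], SelectionConfig()
        )
        assert pools == {Mutation(5, "Y", "W"): {"CC"}}

    def test_below_both_thresholds_excluded(self):
        pools = select_improving_mutations(
            [effect(5, "Y", "W", 0.5, 4.9)], [], SelectionConfig()
        )
        assert pools == {}

    def test_either_threshold_suffices(self):
        by_peak = select_improving_mutations(
            [effect(5, "Y", "W", 0.1, 5.0)], [], SelectionConfig())
        by_mean = select_improving_mutations(
            [effect(5, "Y", "W", 0.55, 1.0)], [], SelectionConfig())
        assert len(by_peak) == 1 and len(by_mean) == 1

    def test_union_of_class_pools_with_shared_members(self, parent):
        # 10 CC mutations at positions 1-10; CXnC shares the first 6 and adds
        # 6 more at positions 11-16: union must be 10 + 12 - 6 = 16.
        def mk(pos, scope, mean):
            to_aa = "W" if parent[pos - 1] != "W" else "F"
            return effect(pos, parent[pos - 1], to_aa, mean, mean + 1, scope)

        cc = [mk(p, "CC", 5.0 - 0.1 * p) for p in range(1, 11)]
        cxnc = [mk(p, "CXnC", 5.0 - 0.1 * p) for p in range(1, 7)]
        cxnc += [mk(p, "CXnC", 4.0 - 0.1 * p) for p in range(11, 17)]
        pools = select_improving_mutations(cc, cxnc, SelectionConfig())
        assert len(pools) == 16
        both = [m for m, lbls in pools.items() if lbls == {"CC", "CXnC"}]
        assert len(both) == 6

    def test_truncation_to_top_n_by_mean_then_peak(self):
        effects = [effect(p, "A", "W", 3.0 - 0.1 * p, 10.0) for p in range(1, 6)]
        pools = select_improving_mutations(
            effects, [], SelectionConfig(top_n_cc=3))
        assert {m.position for m in pools} == {1, 2, 3}

    def test_fewer_candidates_than_top_n_warns(self):
        with pytest.warns(UserWarning, match="returning all"):
            pools = select_improving_mutations(
                [effect(1, "A", "W", 2.0, 8.0)], [], SelectionConfig(top_n_cc=10))
        assert len(pools) == 1


class TestRankCombinatorial:
    def test_median_of_three_targets(self, parent, panel):
        variants = {f"V{i}" + "A" * 13: None for i in range(5)}
        data = {}
        for i, v in enumerate(variants):
            for j, t in enumerate(["CCL2", "CCL5", "CCL8"]):
                data[(v, t)] = float(j + i)
        ranking = rank_combinatorial(enrichment_frame(data), panel, group_size=2)
        row = ranking.table.set_index("variant")
        first = next(iter(variants))
        assert row.loc[first, "median_delta_all"] == pytest.approx(1.0)

    def test_parent_medians_are_zero(self, parent, panel):
        data = {(parent, t): 0.0 for t in panel.names("ALL")}
        for i in range(4):
            for t in panel.names("ALL"):
                data[(f"V{i}" + "B" * 13, t)] = 1.0 + i
        ranking = rank_combinatorial(enrichment_frame(data), panel, group_size=2)
        row = ranking.table.set_index("variant").loc[parent]
        assert row["median_delta_all"] == 0.0
        assert row["median_delta_cc"] == 0.0

    def test_groups_match_full_sort_oracle(self, panel):
        rng = random.Random(9)
        targets = panel.names("ALL")
        data = {}
        medians = {}
        for i in range(30):
            v = f"V{i:02d}" + "C" * 12
            vals = [rng.uniform(-4, 8) for _ in targets]
            for t, x in zip(targets, vals):
                data[(v, t)] = x
            medians[v] = np.median(vals)
        ranking = rank_combinatorial(enrichment_frame(data), panel, group_size=5)
        by_desc = sorted(medians, key=lambda v: (-medians[v], v))
        assert ranking.groups["CM-max"] == by_desc[:5]
        by_asc = sorted(medians, key=lambda v: (medians[v], v))
        assert ranking.groups["CM-min"] == by_asc[:5]
        assert set(ranking.groups["CM-max"]).isdisjoint(ranking.groups["CM-min"])

    def test_row_order_irrelevant(self, panel):
        rng = random.Random(10)
        data = {
            (f"V{i}" + "D" * 14, t): rng.uniform(-2, 2)
            for i in range(8)
            for t in panel.names("ALL")
        }
        frame = enrichment_frame(data)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = rank_combinatorial(frame, panel, group_size=3)
        r2 = rank_combinatorial(shuffled, panel, group_size=3)
        assert r1.groups == r2.groups

    def test_shift_invariance_of_ordering(self, panel):
        rng = random.Random(11)
        data = {
            (f"V{i}" + "E" * 14, t): rng.uniform(-2, 2)
            for i in range(8)
            for t in panel.names("ALL")
        }
        shifted = {k: v + 2.5 for k, v in data.items()}
        r1 = rank_combinatorial(enrichment_frame(data), panel, group_size=3)
        r2 = rank_combinatorial(enrichment_frame(shifted), panel, group_size=3)
        assert r1.groups == r2.groups
        assert np.allclose(
            r1.table["median_delta_all"] + 2.5, r2.table["median_delta_all"]
        )

    def test_library_smaller_than_group_errors(self, panel):
        data = {("VAAA", "CCL2"): 1.0}
        with pytest.raises(ValueError, match="group_size"):
            rank_combinatorial(enrichment_frame(data), panel, group_size=5)
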