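"""Concordance scoring, consensus, classification and tier compilation."""

from __future__ import annotations

import numpy as np
import pytest

from mutbench.curation import (
    CurationConfig,
    GoldMutation,
    classify_candidate,
    compile_tiers,
    consensus_partition,
    snape_score,
    snape_score_mc,
    tier_sizes_from_counts,
)
from mutbench.variants import CallSet, MutationCall


class TestSnapeScore:
    def test_symmetric_counts_give_half(self):
        assert snape_score(0, 50, 0, 50) == pytest.approx(0.5, abs=1e-9)
        assert snape_score(10, 20, 10, 20) == pytest.approx(0.5, abs=1e-9)

    def test_matches_monte_carlo_oracle(self):
        val = snape_score(10, 20, 0, 30)
        mc, se = snape_score_mc(10, 20, 0, 30, n_draws=10**6, seed=42)
        assert abs(val - mc) < 3 * se

    def test_monotone_in_alt_support(self):
        assert snape_score(11, 19, 0, 30) > snape_score(10, 20, 0, 30)

    def test_swap_symmetry(self):
        a = snape_score(7, 13, 2, 40)
        b = snape_score(2, 40, 7, 13)
        assert a + b == pytest.approx(1.0, abs=1e-8)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            snape_score(0, 0, 1, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_configs_match_mc(self, seed):
        rng = np.random.default_rng(seed)
        t_alt = int(rng.integers(0, 60))
        t_ref = int(rng.integers(1, 300))
        n_alt = int(rng.integers(0, 10))
        n_ref = int(rng.integers(1, 300))
        val = snape_score(t_alt, t_ref, n_alt, n_ref)
        mc, se = snape_score_mc(t_alt, t_ref, n_alt, n_ref, n_draws=200_000,
                                seed=seed)
        assert abs(val - mc) <= 4 * max(se, 1e-4)


def _sets(support_pattern):
    """Call sets where site ('1', i) appears in the first k sets per k."""
    sets = []
    for s in range(6):
        calls = [
            MutationCall("1", i, "A", "T")
            for i, k in enumerate(support_pattern)
            if s < k
        ]
        sets.append(CallSet(f"s{s}", calls, normalized=True))
    return sets


class TestConsensus:
    def test_partition_rules(self):
        auto, review = consensus_partition(_sets([4, 3, 6, 1]))
        assert ("1", 0, "A", "T") in auto and ("1", 2, "A", "T") in auto
        assert ("1", 1, "A", "T") in review and ("1", 3, "A", "T") in review

    def test_duplicates_from_one_source_count_once(self):
        cs = CallSet("dup", [MutationCall("1", 5, "A", "T")] * 3, normalized=True)
        others = [CallSet(f"o{i}", [], normalized=True) for i in range(3)]
        auto, review = consensus_partition([cs] + others)
        assert not auto and review == {("1", 5, "A", "T")}

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition([CallSet("x", [], normalized=False)])


def _ev(t_alt, t_ref, n_alt=0, n_ref=100, score=0.99, map100=1.0,
        segdup=False, ambiguous=False):
    return {
        "t_alt": t_alt, "t_ref": t_ref, "n_alt": n_alt, "n_ref": n_ref,
        "score": score, "map100": map100, "segdup": segdup,
        "ambiguous": ambiguous,
    }


class TestClassification:
    cfg = CurationConfig()

    @pytest.mark.parametrize("t_alt,t_ref,expected", [
        (25, 75, 1),   # MAF 0.25
        (7, 93, 2),    # MAF 0.07
        (3, 97, 3),    # MAF 0.03
        (1, 99, 0),    # MAF below the 2% reliability floor
    ])
    def test_clean_candidates_classified_by_maf(self, t_alt, t_ref, expected):
        assert classify_candidate(_ev(t_alt, t_ref), self.cfg) == expected

    def test_ambiguous_alignment_is_class4(self):
        ev = _ev(25, 75, score=0.95, map100=0.8, ambiguous=True)
        assert classify_candidate(ev, self.cfg) == 4

    def test_depth_outlier_is_class5(self):
        ev = _ev(250, 550, score=0.95)  # depth 800 vs bounds (50, 200)
        assert classify_candidate(ev, self.cfg, depth_bounds=(50, 200)) == 5

    def test_low_score_rejected(self):
        assert classify_candidate(_ev(25, 75, score=0.85), self.cfg) == 0

    def test_consensus_skips_score_gate_only_when_clean(self):
        ev = _ev(25, 75, score=0.6)
        assert classify_candidate(ev, self.cfg, auto_accepted=True) == 1
        dirty = _ev(25, 75, score=0.6, segdup=True)
        assert classify_candidate(dirty, self.cfg, auto_accepted=True) == 0

    def test_insufficient_depth_blocks_auto_class(self):
        ev = _ev(5, 10)  # depth 15 < 20
        assert classify_candidate(ev, self.cfg) == 0

    def test_unscored_evidence_rejected(self):
        with pytest.raises(ValueError):
            classify_candidate(_ev(25, 75, score=float("nan")), self.cfg)


def _gold_mutations(class_counts, mut_class="SSM"):
    muts, pos = [], 0
    for cls, n in class_counts.items():
        for _ in range(n):
            pos += 10
            ref, alt = ("A", "T") if mut_class == "SSM" else ("AT", "A")
            muts.append(GoldMutation(
                MutationCall("1", pos, ref, alt), maf=0.3, class_label=cls,
            ))
    return muts


class TestTierCompilation:
    def test_ssm_tier_sizes_cumulative(self):
        counts = {1: 962, 2: 139, 3: 154, 4: 8, 5: 29}
        gold = compile_tiers(_gold_mutations(counts), "SSM")
        assert gold.tier_sizes == {1: 962, 2: 1101, 3: 1255, 4: 1263, 5: 1292}
        assert tier_sizes_from_counts(counts) == gold.tier_sizes

    def test_sim_tiers_use_classes_1_and_4(self):
        gold = compile_tiers(_gold_mutations({1: 337, 4: 10}, "SIM"), "SIM")
        assert gold.tier_sizes == {1: 337, 4: 347}
        # classes 2/3/5 are rejected for indels
        gold2 = compile_tiers(_gold_mutations({1: 5, 2: 3, 5: 2}, "SIM"), "SIM")
        assert gold2.tier_sizes == {1: 5, 4: 5}

    def test_all_class0_gives_empty_tiers(self):
        gold = compile_tiers(_gold_mutations({0: 10}), "SSM")
        assert all(v == 0 for v in gold.tier_sizes.values())

    def test_tier_nesting_invariant(self, small_gold):
        for gold in small_gold.values():
            tiers = [gold.tier(k) for k in gold.class_order]
            for lo, hi in zip(tiers, tiers[1:]):
                assert lo <= hi
            sizes = gold.tier_sizes
            assert sizes == tier_sizes_from_counts(gold.class_counts, gold.mut_class)


class TestEndToEndCuration:
    def test_clean_clonal_recovered_as_class1(self, small_cohort, small_gold):
        truth = small_cohort["truth"]
        clonal = truth[truth["planted_class"] == 1]
        keys = {(r.chrom, int(r.pos), r.ref, r.alt) for r in clonal.itertuples()}
        class1 = {
            m.call.key()
            for g in small_gold.values()
            for m in g.mutations
            if m.class_label == 1
        }
        recovered = len(keys & class1) / len(keys)
        assert recovered >= 0.98

    def test_subclonal_strata_populate_lower_tiers(self, small_gold):
        sizes = small_gold["SSM"].tier_sizes
        assert sizes[1] < sizes[2] < sizes[3]
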