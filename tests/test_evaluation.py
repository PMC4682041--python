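"""Tiered accuracy evaluation against gold sets."""

from __future__ import annotations

import math

import pytest

from mutbench.curation import GoldMutation, compile_tiers
from mutbench.data import published_accuracy_table
from mutbench.evaluation import (
    ConfusionCounts,
    accuracy,
    call_status,
    evaluate_cohort,
    evaluate_submission,
    match_calls,
)
from mutbench.variants import CallSet, MutationCall


class TestAccuracy:
    def test_balanced_counts_give_equal_p_r_f1(self):
        rep = accuracy(ConfusionCounts(tp=50, tp_extra=0, fp=50, fn=50))
        assert rep.precision == rep.recall == rep.f1 == pytest.approx(0.5)

    def test_empty_submission_convention(self):
        rep = accuracy(ConfusionCounts(tp=0, tp_extra=0, fp=0, fn=10))
        assert math.isnan(rep.precision)
        assert rep.f1 == 0.0
        assert rep.notes

    def test_f1_uses_unrounded_precision_recall(self):
        # P = 0.8749..., R = 0.695...: rounding first would change F1
        rep = accuracy(ConfusionCounts(tp=879, tp_extra=7, fp=129, fn=376))
        assert rep.rounded() == (0.87, 0.70, 0.78)

    @pytest.mark.parametrize("mut_class", ["SSM", "SIM"])
    def test_published_counts_yield_selfconsistent_metrics(self, mut_class):
        """P/R/F1 recomputed from every published confusion row are valid
        probabilities with F1 between min and max of P and R."""
        for row in published_accuracy_table(mut_class).itertuples(index=False):
            rep = accuracy(ConfusionCounts(row.tp, row.tp_extra, row.fp, row.fn))
            assert 0 <= rep.precision <= 1 and 0 <= rep.recall <= 1
            assert min(rep.precision, rep.recall) - 1e-12 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12


def _make_gold(n1=6, n2=3, n3=2, n4=2):
    muts, pos = [], 100
    for cls, n in ((1, n1), (2, n2), (3, n3), (4, n4)):
        for _ in range(n):
            pos += 10
            muts.append(GoldMutation(MutationCall("1", pos, "A", "T"),
                                     maf=0.3, class_label=cls))
    return compile_tiers(muts, "SSM")


class TestMatching:
    def test_exact_tier3_submission(self):
        gold = _make_gold()
        calls = [MutationCall(k[0], k[1], k[2], k[3]) for k in gold.tier(3)]
        sub = CallSet("exact", calls, normalized=True)
        c = match_calls(sub, gold)
        assert (c.tp, c.tp_extra, c.fp, c.fn) == (len(gold.tier(3)), 0, 0, 0)

    def test_empty_submission(self):
        gold = _make_gold()
        c = match_calls(CallSet("empty", [], normalized=True), gold)
        assert c.tp == 0 and c.fn == len(gold.tier(3))

    def test_tier4_matches_counted_separately(self):
        gold = _make_gold()
        tier4_only = gold.tier(4) - gold.tier(3)
        calls = [MutationCall(k[0], k[1], k[2], k[3]) for k in tier4_only]
        sub = CallSet("amb", calls, normalized=True)
        c = match_calls(sub, gold)
        assert c.tp == 0 and c.tp_extra == len(tier4_only) and c.fp == 0

    def test_precision_grows_with_precision_tier(self):
        """Enlarging the precision tier can only convert FP to TP."""
        gold = _make_gold()
        calls = [MutationCall(k[0], k[1], k[2], k[3]) for k in gold.tier(4)]
        sub = CallSet("all", calls, normalized=True)
        p3 = accuracy(match_calls(sub, gold, precision_tier=3)).precision
        p4 = accuracy(match_calls(sub, gold, precision_tier=4)).precision
        assert p4 >= p3

    def test_recall_invariant_to_fp_injection(self):
        gold = _make_gold()
        hits = [MutationCall(k[0], k[1], k[2], k[3]) for k in gold.tier(3)][:4]
        fps = [MutationCall("1", 5000 + i, "C", "G") for i in range(20)]
        r_clean = accuracy(match_calls(CallSet("a", hits, normalized=True), gold)).recall
        r_noisy = accuracy(
            match_calls(CallSet("b", hits + fps, normalized=True), gold)
        ).recall
        assert r_clean == r_noisy

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            match_calls(CallSet("x", []), _make_gold())

    def test_counts_match_generator_ledger(self, small_cohort, small_gold):
        """TP/FP bookkeeping agrees with the generator's planted truth."""
        gold = small_gold["SSM"]
        tier4 = gold.tier(4)
        for sub in small_cohort["subs"]:
            c = match_calls(sub, gold)
            ssm = sub.filter_class("SSM")
            ledger_fp = {k for k in sub.ledger["fp"] if k in ssm.keys()}
            # planted FPs that did not sneak into the gold set are counted FPs
            expected_fp = len(ledger_fp - tier4)
            truth_missed = {k for k in ssm.keys() if k not in ledger_fp}
            assert c.fp == expected_fp + len(truth_missed - tier4)
            assert c.tp + c.tp_extra + c.fp == len(ssm)


class TestCohortTable:
    def test_perfect_submission_row(self, small_gold):
        gold = small_gold["SSM"]
        calls = [MutationCall(*k) for k in gold.tier(3)]
        sub = CallSet("perfect", calls, normalized=True)
        table = evaluate_cohort([sub], gold_ssm=gold)
        row = table.iloc[0]
        assert row["P"] == 1.0 and row["R3"] == 1.0 and row["F1"] == 1.0

    def test_rows_sorted_by_source(self, small_cohort, small_gold):
        subs = list(reversed(small_cohort["subs"]))
        table = evaluate_cohort(subs, small_gold["SSM"], small_gold["SIM"])
        assert list(table["source"]) == sorted(table["source"])
        assert set(table["class"]) == {"SSM", "SIM"}

    def test_af_stratified_caller_recall_matches_expectation(
        self, small_cohort, small_gold
    ):
        """A caller with stratified sensitivity (1.0 / 0.5 / 0.0 across AF
        strata) shows near-perfect tier-1 recall and a tier-3 recall near
        the sensitivity-weighted mean over gold mutations."""
        from mutbench.simulate import CallerProfile, simulate_submission
        from mutbench.variants import normalize_callset

        sg, truth = small_cohort["sg"], small_cohort["truth"]
        prof = CallerProfile("strat", (1.0, 0.5, 0.0), fp_rate_per_mb=0.0, seed=5)
        sub = normalize_callset(simulate_submission(sg, truth, prof), sg.genome)
        gold = small_gold["SSM"]
        rep = evaluate_submission(sub, gold)
        af_by_key = {
            (r.chrom, int(r.pos), r.ref, r.alt): r.af_tumour
            for r in truth.itertuples(index=False)
        }
        sens = [
            float(prof.sensitivity(af_by_key[k]))
            for k in gold.tier(3) if k in af_by_key
        ]
        expected = sum(sens) / len(gold.tier(3))
        sd = (sum(s * (1 - s) for s in sens)) ** 0.5 / len(gold.tier(3))
        assert rep.recall_by_tier[1] > 0.9
        assert abs(rep.recall_by_tier[3] - expected) <= max(4 * sd, 0.02)
        assert rep.recall_by_tier[1] >= rep.recall_by_tier[3]


def test_call_status_partitions_submission(small_cohort, small_gold):
    sub = small_cohort["subs"][0]
    st = call_status(sub, small_gold["SSM"])
    keys = sub.filter_class("SSM").keys()
    assert st["tp"] | st["tp_extra"] | st["fp"] == keys
    assert not st["tp"] & st["fp"]
    assert st["fn"] <= set(small_gold["SSM"].tier(3))
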