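"""Scoring submissions against a tiered gold set.

Recall is computed against a cumulative tier of the gold set (Tier 3 for
substitutions, Tier 1 for indels by default); precision is always
computed against Tier 4, which additionally contains alignment-ambiguous
mutations, so that hard-to-align but convincing calls are not penalised.
Matches between the recall tier and Tier 4 are the parenthetical
"additional Tier 4 calls" of a benchmark report table.  F1 is computed
from the unrounded precision and recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .curation import GoldSet
from .variants import CallSet


@dataclass(frozen=True)
class ConfusionCounts:
    """TP within the recall tier, extra TP only in the precision tier,
    FP in neither, FN = recall-tier mutations not called."""

    tp: int
    tp_extra: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tp_extra, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_calls(self) -> int:
        return self.tp + self.tp_extra + self.fp


@dataclass
class AccuracyReport:
    precision: float  # NaN when the submission is empty
    recall: float
    f1: float
    recall_by_tier: dict[int, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Display rounding (the underlying F1 uses unrounded P and R)."""
        r = lambda x: float("nan") if math.isnan(x) else round(x, ndigits)
        return r(self.precision), r(self.recall), r(self.f1)


def accuracy(c: ConfusionCounts) -> AccuracyReport:
    """Precision, recall and F1 = 2PR/(P+R) from confusion counts.

    Zero denominators follow the documented convention: an empty
    submission has undefined precision (reported as NaN) and F1 = 0; an
    empty recall tier gives recall NaN and F1 = 0.  Both cases are flagged
    in ``notes`` instead of raising, so batch evaluation never crashes.
    """
    notes = []
    n_calls = c.tp + c.tp_extra + c.fp
    if n_calls == 0:
        precision = float("nan")
        notes.append("empty submission: precision undefined")
    else:
        precision = (c.tp + c.tp_extra) / n_calls
    if c.tp + c.fn == 0:
        recall = float("nan")
        notes.append("empty recall tier: recall undefined")
    else:
        recall = c.tp / (c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = 0.0
        if not notes:
            notes.append("P + R = 0: F1 set to 0 by convention")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return AccuracyReport(precision=precision, recall=recall, f1=f1, notes=notes)


def match_calls(
    sub: CallSet,
    gold: GoldSet,
    recall_tier: int | None = None,
    precision_tier: int = 4,
    position_only: bool = False,
) -> ConfusionCounts:
    """Confusion counts of a normalised submission against a gold set.

    Identity is position + exact alleles by default; ``position_only``
    matches on site alone (an option for indel call sets whose allele
    representations differ).  Only calls of the gold set's mutation class
    are considered.
    """
    if not sub.normalized:
        raise ValueError(f"submission {sub.source!r} is not normalized")
    if recall_tier is None:
        recall_tier = 3 if gold.mut_class == "SSM" else 1
    if recall_tier not in gold.tiers or precision_tier not in gold.tiers:
        raise KeyError(
            f"tier {recall_tier}/{precision_tier} undefined for "
            f"{gold.mut_class} gold set"
        )
    sub_keys = sub.filter_class(gold.mut_class).keys(position_only)
    recall_set = gold.tier(recall_tier)
    prec_set = gold.tier(precision_tier)
    if position_only:
        recall_set = frozenset((k[0], k[1]) for k in recall_set)
        prec_set = frozenset((k[0], k[1]) for k in prec_set)
    tp = len(sub_keys & recall_set)
    tp_extra = len(sub_keys & (prec_set - recall_set))
    fp = len(sub_keys) - tp - tp_extra
    fn = len(recall_set) - tp
    return ConfusionCounts(tp=tp, tp_extra=tp_extra, fp=fp, fn=fn)


def evaluate_submission(
    sub: CallSet, gold: GoldSet, position_only: bool = False
) -> AccuracyReport:
    """Accuracy report with per-tier recall (tiers up to the recall tier)."""
    counts = match_calls(sub, gold, position_only=position_only)
    report = accuracy(counts)
    recall_tiers = (1, 2, 3) if gold.mut_class == "SSM" else (1,)
    sub_keys = sub.filter_class(gold.mut_class).keys(position_only)
    for k in recall_tiers:
        tier = gold.tier(k)
        if position_only:
            tier = frozenset((x[0], x[1]) for x in tier)
        report.recall_by_tier[k] = (
            len(sub_keys & tier) / len(tier) if tier else float("nan")
        )
    return report


def call_status(
    sub: CallSet, gold: GoldSet,
    recall_tier: int | None = None, precision_tier: int = 4,
    position_only: bool = False,
) -> dict[str, set]:
    """Key sets behind the confusion counts: tp, tp_extra, fp and fn.

    ``fn`` contains the recall-tier gold mutations absent from the
    submission (the set rainfall and feature diagnostics consume).
    """
    if recall_tier is None:
        recall_tier = 3 if gold.mut_class == "SSM" else 1
    sub_keys = sub.filter_class(gold.mut_class).keys(position_only)
    recall_set = set(gold.tier(recall_tier))
    prec_set = set(gold.tier(precision_tier))
    if position_only:
        recall_set = {(k[0], k[1]) for k in recall_set}
        prec_set = {(k[0], k[1]) for k in prec_set}
    tp = sub_keys & recall_set
    tp_extra = sub_keys & (prec_set - recall_set)
    return {
        "tp": tp,
        "tp_extra": tp_extra,
        "fp": sub_keys - tp - tp_extra,
        "fn": recall_set - sub_keys,
    }


def evaluate_cohort(
    subs: list[CallSet],
    gold_ssm: GoldSet | None = None,
    gold_sim: GoldSet | None = None,
    position_only_sim: bool = False,
) -> pd.DataFrame:
    """Benchmark report table: one row per (submission, mutation class).

    Columns: source, class, TP, TP4 (extra precision-tier matches), FP,
    FN, P, R1..R3, F1.  Rows are sorted by source identifier then class,
    independent of input order.
    """
    rows = []
    for cs in sorted(subs, key=lambda s: s.source):
        for gold in (gold_ssm, gold_sim):
            if gold is None:
                continue
            pos_only = position_only_sim and gold.mut_class == "SIM"
            counts = match_calls(cs, gold, position_only=pos_only)
            report = evaluate_submission(cs, gold, position_only=pos_only)
            rows.append({
                "source": cs.source,
                "class": gold.mut_class,
                "TP": counts.tp,
                "TP4": counts.tp_extra,
                "FP": counts.fp,
                "FN": counts.fn,
                "P": report.precision,
                "R1": report.recall_by_tier.get(1, float("nan")),
                "R2": report.recall_by_tier.get(2, float("nan")),
                "R3": report.recall_by_tier.get(3, float("nan")),
                "F1": report.f1,
            })
    return pd.DataFrame(rows)
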