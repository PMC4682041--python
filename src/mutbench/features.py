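"""Genomic and alignment feature annotation, enrichment diagnostics and
rainfall records.

Each call is annotated with the Boolean flags and scores used to explain
caller errors: tandem-repeat context from a bounded period scan (period
1-6, at least six copies, in the 201-bp window centred on the call),
homopolymer runs longer than six bases, interval-track membership
(simple/nested repeats, segmental duplications, centromere and blacklist
regions), window mappability complements (mult100/mult150), the sameAF
transform of the tumour/normal concordance score, the mutant AF observed
in the normal, and depth-outlier flags in the normal.

Enrichment matrices contrast FP (or FN) feature frequencies with the gold
set, weighted by the FP (or FN) rate; rainfall records give each call's
distance to the previous mutation on its chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .simulate import SyntheticGenome

BOOL_FEATURES = [
    "inTR", "adjTR", "sRep", "msat", "hp", "nestRep", "dups", "centr",
    "DacBL", "DukeBL", "DPNhi", "DPNlo", "AFTlo",
]
SCORE_FEATURES = ["same_af", "mult100", "mult150", "AFN"]


def scan_tandem_repeats(
    seq: str, max_period: int = 6, min_copies: int = 6
) -> list[tuple[int, int, int]]:
    """Find tandem repeats in ``seq``: (start, end, period) per maximal run.

    A repeat of period p is a maximal run where seq[i] == seq[i-p]; with
    run length L (matches) the repeat spans L + p bases, i.e. (L + p) / p
    copies.  Runs with at least ``min_copies`` copies are reported.
    """
    n = len(seq)
    hits = []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for p in range(1, max_period + 1):
        if n <= p:
            break
        match = arr[p:] == arr[:-p]
        i = 0
        m = len(match)
        while i < m:
            if match[i]:
                j = i
                while j < m and match[j]:
                    j += 1
                span = (j - i) + p
                if span / p >= min_copies:
                    hits.append((i, i + span, p))
                i = j
            else:
                i += 1
    return hits


def _repeat_context(
    seq_window: str, rel_start: int, rel_end: int
) -> tuple[bool, bool, bool, bool]:
    """(inTR, adjTR, hp, msat) for footprint [rel_start, rel_end) in window."""
    in_tr = adj_tr = hp = msat = False
    for s, e, p in scan_tandem_repeats(seq_window):
        overlaps = s < rel_end and e > rel_start
        adjacent = (rel_start - 1 <= e <= rel_start + 1) or (
            rel_end - 1 <= s <= rel_end + 1
        )
        if overlaps:
            in_tr = True
        elif adjacent:
            adj_tr = True
        if (overlaps or adjacent) and p == 1 and (e - s) > 6:
            hp = True
        if overlaps and 2 <= p <= 6:
            msat = True
    return in_tr, adj_tr, hp, msat


def annotate_features(
    evidence: pd.DataFrame,
    sg: SyntheticGenome,
    maf_lo: float = 0.10,
    depth_outlier_mults: tuple[float, float] = (0.5, 2.0),
    window_flank: int = 100,
) -> pd.DataFrame:
    """FeatureVector table for every scored evidence row.

    ``evidence`` must carry counts, ``score``, ``maf``, ``map100`` and
    ``map150``; the result is indexed by (chrom, pos, ref, alt).  Raises
    if a call lies outside the genome.
    """
    if "score" not in evidence.columns:
        raise ValueError("evidence must be scored (run curation.score_evidence)")
    depth_n = (evidence["n_alt"] + evidence["n_ref"]).to_numpy(dtype=float)
    med_n = np.median(depth_n)
    rows = []
    for row in evidence.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        if chrom not in sg.genome or not 0 <= pos < sg.genome.length(chrom):
            raise ValueError(f"call {chrom}:{pos + 1} outside genome bounds")
        win_start = max(0, pos - window_flank)
        window = sg.genome.fetch(chrom, win_start, pos + window_flank + 1)
        rel_start = pos - win_start
        rel_end = rel_start + len(row.ref)
        in_tr, adj_tr, hp, msat = _repeat_context(window, rel_start, rel_end)
        repeat_labels = set(sg.repeat_track.labels_at(chrom, pos, pos + len(row.ref)))
        black_labels = set(sg.blacklist_track.labels_at(chrom, pos, pos + len(row.ref)))
        dn = row.n_alt + row.n_ref
        score = float(row.score)
        rows.append({
            "inTR": in_tr,
            "adjTR": adj_tr,
            "sRep": "simple_repeat" in repeat_labels,
            "msat": msat or "microsatellite" in repeat_labels,
            "hp": hp,
            "nestRep": "nested_repeat" in repeat_labels,
            "dups": sg.segdup_track.overlaps(chrom, pos, pos + len(row.ref)),
            "centr": "centromere" in black_labels,
            "DacBL": "dac" in black_labels,
            "DukeBL": "duke" in black_labels,
            "DPNhi": dn > depth_outlier_mults[1] * med_n,
            "DPNlo": dn < depth_outlier_mults[0] * med_n,
            "AFTlo": float(row.maf) < maf_lo,
            "same_af": 1.0 - 2.0 * (score - 0.5) if score >= 0.5 else 0.0,
            "mult100": 1.0 - float(row.map100),
            "mult150": 1.0 - float(row.map150),
            "AFN": row.n_alt / dn if dn else 0.0,
        })
    idx = pd.MultiIndex.from_arrays(
        [evidence["chrom"], evidence["pos"], evidence["ref"], evidence["alt"]],
        names=["chrom", "pos", "ref", "alt"],
    )
    out = pd.DataFrame(rows, index=idx)
    out[BOOL_FEATURES] = out[BOOL_FEATURES].astype(bool)
    return out


@dataclass
class EnrichmentMatrix:
    matrix: pd.DataFrame  # submissions x features
    mode: str  # "FP" or "FN"
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # submissions with empty error sets


def enrichment_matrix(
    features: pd.DataFrame,
    per_sub_status: Mapping[str, Mapping[str, set]],
    gold_keys: set,
    mode: str = "FP",
) -> EnrichmentMatrix:
    """Weighted feature-frequency differences of FPs (or FNs) vs gold.

    Entry (submission, feature) = (mean feature value over the FP or FN
    calls − mean over the gold set) × (FP rate or FN rate), where
    FP rate = FP/(TP+TP4+FP) and FN rate = FN/(TP+FN) from the same
    evaluation run.  Submissions with an empty error set get a zero row
    and are listed in ``flagged``.
    """
    if mode not in ("FP", "FN"):
        raise ValueError("mode must be 'FP' or 'FN'")
    gold_idx = [k for k in gold_keys if k in features.index]
    gold_mean = features.loc[gold_idx].astype(float).mean()
    rows = {}
    flagged = []
    for source in sorted(per_sub_status):
        st = per_sub_status[source]
        tp, extra, fp, fn = (len(st["tp"]), len(st.get("tp_extra", ())),
                             len(st["fp"]), len(st["fn"]))
        if mode == "FP":
            keys = st["fp"]
            rate = fp / (tp + extra + fp) if tp + extra + fp else 0.0
        else:
            keys = st["fn"]
            rate = fn / (tp + fn) if tp + fn else 0.0
        keys = [k for k in keys if k in features.index]
        if not keys:
            rows[source] = pd.Series(0.0, index=features.columns)
            flagged.append(source)
            continue
        err_mean = features.loc[keys].astype(float).mean()
        rows[source] = (err_mean - gold_mean) * rate
    mat = pd.DataFrame(rows).T
    row_order = list(mat.index)
    col_order = list(mat.columns)
    if len(mat) >= 2:
        z = hierarchy.average(hierarchy.distance.pdist(mat.to_numpy()))
        row_order = [mat.index[i] for i in hierarchy.leaves_list(z)]
    if mat.shape[1] >= 2:
        z = hierarchy.average(hierarchy.distance.pdist(mat.to_numpy().T))
        col_order = [mat.columns[i] for i in hierarchy.leaves_list(z)]
    return EnrichmentMatrix(matrix=mat, mode=mode, row_order=row_order,
                            col_order=col_order, flagged=flagged)


def rainfall(calls_with_status: pd.DataFrame) -> pd.DataFrame:
    """Distance of each mutation to the previous one on its chromosome.

    Input columns: chrom, pos, status (TP/FP/FN).  The first mutation on
    each chromosome carries no distance and is omitted, so the output has
    (total calls − chromosomes bearing calls) rows.
    """
    df = calls_with_status.sort_values(["chrom", "pos"]).reset_index(drop=True)
    df["distance"] = df.groupby("chrom")["pos"].diff()
    out = df.dropna(subset=["distance"]).copy()
    out["distance"] = out["distance"].astype(int)
    return out[["chrom", "pos", "distance", "status"]]


def rainfall_input(status: Mapping[str, set]) -> pd.DataFrame:
    """Assemble the rainfall table from evaluation key sets.

    TP and FP positions come from the submission; FN positions are the
    gold mutations the submission missed.
    """
    rows = []
    for label, key_name in (("TP", "tp"), ("TP", "tp_extra"), ("FP", "fp"), ("FN", "fn")):
        for k in status.get(key_name, ()):
            rows.append({"chrom": k[0], "pos": k[1], "status": label})
    return pd.DataFrame(rows, columns=["chrom", "pos", "status"])
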