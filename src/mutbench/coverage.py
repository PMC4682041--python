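"""Coverage evenness diagnostics: GC-bias windows, cumulative coverage
curves and low-coverage fractions in regions of interest.

Depth is consumed as a BEDGRAPH-style table (chrom, start, end, depth),
per-base or windowed; nothing here touches alignments.  GC bias is
assessed on fixed windows (10 kb by default): each window's coverage is
divided by the mean over all retained windows, windows with more than 100
'N' bases are excluded, and a flat normalised-coverage-vs-GC relation
indicates an unbiased (e.g. PCR-free) library.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import Genome, IntervalTrack


def read_depth_track(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"], comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_depth_track(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", "depth"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def _per_window_depth(depth: pd.DataFrame, chrom: str, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
    """Mean depth per window, weighting depth bins by overlap length."""
    sub = depth[depth["chrom"] == chrom]
    out = np.zeros(len(starts))
    if not len(sub):
        return out
    b_start = sub["start"].to_numpy()
    b_end = sub["end"].to_numpy()
    b_depth = sub["depth"].to_numpy(dtype=float)
    for i, (ws, we) in enumerate(zip(starts, ends)):
        lo = np.searchsorted(b_end, ws, side="right")
        hi = np.searchsorted(b_start, we, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(b_end[lo:hi], we) - np.maximum(b_start[lo:hi], ws)
        ov = np.maximum(ov, 0)
        total = ov.sum()
        if total > 0:
            out[i] = float((b_depth[lo:hi] * ov).sum() / (we - ws))
    return out


def gc_bias(
    depth: pd.DataFrame, genome: Genome, window: int = 10_000,
    max_n_bases: int = 100,
) -> pd.DataFrame:
    """Per-window GC fraction and normalised coverage.

    Windows with more than ``max_n_bases`` 'N' bases are flagged
    ``excluded`` and ignored when computing the normalising mean, so the
    mean normalised coverage over included windows is 1 by construction.
    """
    if window < 1000:
        raise ValueError("window must be at least 1 kb")
    rows = []
    for chrom, seq in genome.items():
        length = len(seq)
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = (arr == ord("N")) | (arr == ord("n"))
        cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
        cum_n = np.concatenate([[0], np.cumsum(is_n)])
        raw = _per_window_depth(depth, chrom, starts, ends)
        for s, e, r in zip(starts, ends, raw):
            n_count = int(cum_n[e] - cum_n[s])
            non_n = (e - s) - n_count
            gc = float((cum_gc[e] - cum_gc[s]) / non_n) if non_n else np.nan
            rows.append({
                "chrom": chrom, "start": int(s), "end": int(e),
                "gc": gc, "n_count": n_count, "raw": float(r),
                "excluded": n_count > max_n_bases,
            })
    out = pd.DataFrame(rows)
    included = ~out["excluded"]
    mean_cov = out.loc[included, "raw"].mean()
    out["normalized"] = np.where(included & (mean_cov > 0),
                                 out["raw"] / mean_cov, np.nan)
    return out


def cumulative_coverage(
    depth: pd.DataFrame, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Fraction of bases covered at or above each depth threshold.

    A non-increasing step curve with fraction 1 at t = 0; bases are
    weighted by bin length.
    """
    lengths = (depth["end"] - depth["start"]).to_numpy(dtype=float)
    depths = depth["depth"].to_numpy(dtype=float)
    total = lengths.sum()
    if thresholds is None:
        thresholds = np.arange(0, int(depths.max()) + 2)
    fracs = [float(lengths[depths >= t].sum() / total) for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction": fracs})


def low_coverage_fraction(
    depth: pd.DataFrame, regions: IntervalTrack, threshold: int = 10,
) -> pd.Series:
    """Fraction of region bases covered by fewer than ``threshold`` reads,
    per region class (strict '<'; the threshold is configurable).

    Region classes with no bases in the depth track get NaN.
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in depth.groupby("chrom")
    }
    for chrom, r_start, r_end, label in regions:
        sub = by_chrom.get(str(chrom))
        den.setdefault(label, 0.0)
        num.setdefault(label, 0.0)
        if sub is None:
            continue
        b_start = sub["start"].to_numpy()
        b_end = sub["end"].to_numpy()
        b_depth = sub["depth"].to_numpy(dtype=float)
        lo = np.searchsorted(b_end, r_start, side="right")
        hi = np.searchsorted(b_start, r_end, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(b_end[lo:hi], r_end) - np.maximum(b_start[lo:hi], r_start)
        ov = np.maximum(ov, 0).astype(float)
        den[label] += ov.sum()
        num[label] += ov[b_depth[lo:hi] < threshold].sum()
    out = {}
    for label in den:
        out[label] = num[label] / den[label] if den[label] > 0 else np.nan
    return pd.Series(out).sort_index()
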