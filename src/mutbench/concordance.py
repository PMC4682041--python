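"""Agreement among submissions: concordance levels, Jaccard clustering
and correspondence analysis.

The concordance-level table records, for every called site, how many
distinct submissions support it; the Jaccard matrix (|A∩B|/|A∪B|) is
clustered with average linkage on 1−J; correspondence analysis decomposes
a sites × attributes Boolean table (submission membership plus genomic
feature flags) via the SVD of the standardised residuals of the
correspondence matrix, placing submissions and features in a joint
low-dimensional space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .curation import GoldSet
from .variants import CallSet, require_normalized


def concordance_levels(
    callsets: list[CallSet], gold: GoldSet | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-site support table and per-level histogram.

    Returns (table, histogram): the table has one row per called site with
    its support count, the supporting sources, and (when a gold set is
    given) whether the site is gold; the histogram counts sites at each
    support level k = 1..N and sums to the size of the union.
    """
    require_normalized(callsets)
    supporters: dict[tuple, set[str]] = {}
    for cs in callsets:
        for key in cs.keys():
            supporters.setdefault(key, set()).add(cs.source)
    gold_keys = gold.tier(max(gold.tiers)) if gold is not None else frozenset()
    rows = [
        {
            "chrom": k[0],
            "pos": k[1],
            "ref": k[2],
            "alt": k[3],
            "support": len(srcs),
            "sources": ",".join(sorted(srcs)),
            "in_gold": k in gold_keys,
        }
        for k, srcs in sorted(supporters.items())
    ]
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "support", "sources", "in_gold"]
    )
    hist = (
        table["support"].value_counts().reindex(
            range(1, len(callsets) + 1), fill_value=0
        ).sort_index()
        if len(table)
        else pd.Series(dtype=int)
    )
    return table, hist


@dataclass
class JaccardMatrix:
    sources: list[str]
    matrix: pd.DataFrame  # symmetric, NaN where a set is empty
    linkage: np.ndarray | None = None
    order: list[str] = field(default_factory=list)


def jaccard_cluster(callsets: list[CallSet]) -> JaccardMatrix:
    """Pairwise Jaccard indices with average-linkage clustering on 1−J.

    Empty call sets yield NaN rows/columns (J undefined) and are excluded
    from the clustering; ties are broken deterministically by sorting
    sources by name first.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    require_normalized(callsets)
    callsets = sorted(callsets, key=lambda c: c.source)
    sources = [cs.source for cs in callsets]
    keysets = {cs.source: cs.keys() for cs in callsets}
    n = len(sources)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            a, b = keysets[sources[i]], keysets[sources[j]]
            if not a or not b:
                continue
            union = len(a | b)
            mat[i, j] = mat[j, i] = len(a & b) / union
    df = pd.DataFrame(mat, index=sources, columns=sources)
    valid = [s for s in sources if keysets[s]]
    linkage = None
    order = valid
    if len(valid) >= 2:
        sub = df.loc[valid, valid].to_numpy()
        dist = squareform(1.0 - sub, checks=False)
        linkage = hierarchy.average(dist)
        order = [valid[i] for i in hierarchy.leaves_list(linkage)]
    return JaccardMatrix(sources=sources, matrix=df, linkage=linkage, order=order)


@dataclass
class CAResult:
    row_coords: pd.DataFrame  # principal coordinates
    col_coords: pd.DataFrame
    inertia: np.ndarray  # per-axis principal inertias (squared singular values)
    total_inertia: float

    @property
    def inertia_shares(self) -> np.ndarray:
        return self.inertia / self.inertia.sum() if self.inertia.sum() else self.inertia


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """Simple correspondence analysis of a non-negative table.

    Standard construction: with correspondence matrix P = X / n and margin
    vectors r, c, the standardised residuals S = D_r^{-1/2} (P - r c^T)
    D_c^{-1/2} are decomposed by SVD; principal coordinates are
    F = D_r^{-1/2} U Σ and G = D_c^{-1/2} V Σ, and the total inertia is
    χ²/n = Σ σ_k².  All-zero rows or columns are rejected.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis needs a non-negative table")
    if X.sum() == 0:
        raise ValueError("degenerate table: total is zero")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column; filter before analysis")
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((s > 1e-12).sum())
    if rank == 0:
        raise ValueError("rank-0 table: no association to decompose")
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    F = (U * s) / np.sqrt(r)[:, None]
    G = (Vt.T * s) / np.sqrt(c)[:, None]
    axes = [f"dim{i + 1}" for i in range(rank)]
    return CAResult(
        row_coords=pd.DataFrame(F, index=table.index, columns=axes),
        col_coords=pd.DataFrame(G, index=table.columns, columns=axes),
        inertia=s**2,
        total_inertia=float((s**2).sum()),
    )


def build_ca_table(
    callsets: list[CallSet], annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sites × (submissions + Boolean features) table for CA.

    One row per genomic site called by any submission; columns are 0/1
    membership per submission, optionally extended with Boolean feature
    annotations indexed the same way.
    """
    require_normalized(callsets)
    table, _hist = concordance_levels(callsets)
    idx = pd.MultiIndex.from_arrays(
        [table["chrom"], table["pos"], table["ref"], table["alt"]]
    )
    out = pd.DataFrame(index=idx)
    for cs in sorted(callsets, key=lambda c: c.source):
        keys = cs.keys()
        out[cs.source] = [int(k in keys) for k in idx]
    if annotations is not None:
        bool_cols = [c for c in annotations.columns if annotations[c].dtype == bool]
        ann = annotations[bool_cols].astype(int)
        ann = ann.reindex(idx, fill_value=0)
        out = pd.concat([out, ann], axis=1)
    return out
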