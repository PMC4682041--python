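"""Tiered gold-set curation from multi-caller evidence.

The curation recipe mirrors how a deep-coverage (~300x tumour / ~270x
normal) verification set is built: candidate sites supported by more than
three of the verification pipelines are accepted automatically (subject to
evidence gates), the rest are reviewed; every candidate gets a
beta-posterior concordance score comparing tumour and normal allele
counts; candidates with sufficient depth, a near-certain score, perfect
window mappability and no segmental-duplication overlap are classified by
mutant allele fraction (class 1: MAF >= 0.10, class 2: 0.05 <= MAF < 0.10,
class 3: 0.02 <= MAF < 0.05); alignment-ambiguous candidates become class
4 and depth outliers class 5; everything else is rejected (class 0).
Tiers are cumulative unions of classes (Tier 1 = class 1 ... Tier 5 = all);
indel gold sets use only classes 1 and 4 (Tiers 1 and 4).

Manual review of ambiguous alignments and aberrant depth is replaced by
deterministic proxies: planted ambiguity flags and configurable depth
quantile bounds.  This keeps curation machine-decidable; see the methods
note for what this does and does not emulate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special

from .variants import CallSet, MutationCall, require_normalized

SSM_CLASS_ORDER = (1, 2, 3, 4, 5)
SIM_CLASS_ORDER = (1, 4)


@dataclass
class CurationConfig:
    """Thresholds of the curation recipe (printed inequality directions
    are used exactly: >= 0.1, >= 0.05, >= 20, >= 0.98, > 0.9, > 3
    submitters)."""

    consensus_min_submitters: int = 4  # "more than three"
    min_depth: int = 20
    auto_score: float = 0.98
    review_score: float = 0.9
    maf_class1: float = 0.10
    maf_class2: float = 0.05
    af_floor: float = 0.02
    base_quality_min: int = 13  # documentation only: pileup extraction setting
    mapping_quality_min: int = 20  # documentation only
    depth_outlier_quantiles: tuple[float, float] = (0.5, 2.0)  # x median
    beta_prior: tuple[float, float] = (0.5, 0.5)  # Jeffreys

    def __post_init__(self):
        if not 0 < self.maf_class2 < self.maf_class1 < 1:
            raise ValueError("need 0 < maf_class2 < maf_class1 < 1")
        if not self.review_score < self.auto_score:
            raise ValueError("review_score must be below auto_score")


def snape_score(
    t_alt: int, t_ref: int, n_alt: int, n_ref: int,
    prior: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Probability that the tumour allele fraction exceeds the normal one.

    Independent beta posteriors are placed on the two allele fractions,
    Beta(alt + a, ref + b) with prior (a, b), and the score is
    P(p_tumour > p_normal) computed by numerical integration of
    f_T(x) * F_N(x) over [0, 1] to absolute tolerance 1e-6.  A score near
    1 is confident somatic evidence; identical count pairs score 0.5.
    """
    if min(t_alt, t_ref, n_alt, n_ref) < 0:
        raise ValueError("negative allele count")
    if t_alt + t_ref == 0 or n_alt + n_ref == 0:
        raise ValueError("zero total depth in tumour or normal")
    a, b = prior
    at, bt = t_alt + a, t_ref + b
    an, bn = n_alt + a, n_ref + b
    log_norm = special.betaln(at, bt)

    def integrand(x):
        x = np.clip(x, 1e-300, 1.0 - 1e-16)
        pdf_t = np.exp((at - 1) * np.log(x) + (bt - 1) * np.log1p(-x) - log_norm)
        return pdf_t * special.betainc(an, bn, x)

    # break the integration at both posterior means so adaptive quadrature
    # cannot step over a concentrated density
    pts = sorted({at / (at + bt), an / (an + bn)})
    val, _err = integrate.quad(
        integrand, 0.0, 1.0, points=pts, epsabs=1e-9, epsrel=1e-9, limit=200,
    )
    return float(min(1.0, max(0.0, val)))


def snape_score_mc(
    t_alt: int, t_ref: int, n_alt: int, n_ref: int,
    prior: tuple[float, float] = (0.5, 0.5),
    n_draws: int = 10**6, seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo oracle for :func:`snape_score`: (estimate, std. error)."""
    rng = np.random.default_rng(seed)
    a, b = prior
    pt = rng.beta(t_alt + a, t_ref + b, size=n_draws)
    pn = rng.beta(n_alt + a, n_ref + b, size=n_draws)
    hits = pt > pn
    p = hits.mean()
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))
    return float(p), se


def score_evidence(
    evidence: pd.DataFrame, prior: tuple[float, float] = (0.5, 0.5)
) -> pd.DataFrame:
    """Add the concordance ``score`` and observed ``maf`` columns."""
    out = evidence.copy()
    out["score"] = [
        snape_score(ta, tr, na, nr, prior)
        for ta, tr, na, nr in zip(
            out["t_alt"], out["t_ref"], out["n_alt"], out["n_ref"]
        )
    ]
    depth = (out["t_alt"] + out["t_ref"]).to_numpy()
    out["maf"] = out["t_alt"].to_numpy() / np.maximum(depth, 1)
    return out


def consensus_partition(
    callsets: Sequence[CallSet], cfg: CurationConfig | None = None
) -> tuple[set[tuple], set[tuple]]:
    """Split candidate sites into auto-accept and review sets.

    Support is counted by distinct sources; sites backed by at least
    ``consensus_min_submitters`` go to auto-accept, any other supported
    site goes to review.
    """
    cfg = cfg or CurationConfig()
    if not callsets:
        raise ValueError("need at least one call set")
    require_normalized(callsets)
    support: Counter = Counter()
    for cs in callsets:
        for key in cs.keys():
            support[key] += 1
    auto = {k for k, n in support.items() if n >= cfg.consensus_min_submitters}
    review = {k for k, n in support.items() if 0 < n < cfg.consensus_min_submitters}
    return auto, review


def _maf_class(maf: float, cfg: CurationConfig) -> int:
    if maf >= cfg.maf_class1:
        return 1
    if maf >= cfg.maf_class2:
        return 2
    if maf >= cfg.af_floor:
        return 3
    return 0


def classify_candidate(
    ev: Mapping, cfg: CurationConfig,
    depth_bounds: tuple[float, float] | None = None,
    auto_accepted: bool = False,
) -> int:
    """Assign the gold-set class (0-5) to one scored candidate.

    ``ev`` needs fields t_alt/t_ref/n_alt/n_ref, score, map100, segdup,
    ambiguous.  ``depth_bounds`` are the absolute (low, high) tumour-depth
    outlier limits; ``auto_accepted`` lets consensus calls skip the score
    gate (never the depth/mappability gates).
    """
    if "score" not in ev or ev["score"] is None or np.isnan(ev["score"]):
        raise ValueError("candidate has not been scored")
    depth_t = ev["t_alt"] + ev["t_ref"]
    depth_n = ev["n_alt"] + ev["n_ref"]
    maf = ev["t_alt"] / depth_t if depth_t else 0.0
    clean = (
        depth_t >= cfg.min_depth
        and depth_n >= cfg.min_depth
        and ev["map100"] == 1.0
        and not ev["segdup"]
    )
    if clean and (ev["score"] >= cfg.auto_score or auto_accepted):
        return _maf_class(maf, cfg)
    if ev["score"] > cfg.review_score:
        if ev.get("ambiguous", False):
            return 4
        if depth_bounds is not None and not (depth_bounds[0] <= depth_t <= depth_bounds[1]):
            return 5
        if clean:
            return _maf_class(maf, cfg)
        return 0
    return 0


@dataclass(frozen=True)
class GoldMutation:
    call: MutationCall
    maf: float
    class_label: int
    evidence_index: int = -1


class GoldSet:
    """Tier-indexed curated truth for one mutation class (SSM or SIM)."""

    def __init__(self, mutations: Iterable[GoldMutation], mut_class: str = "SSM"):
        if mut_class not in ("SSM", "SIM"):
            raise ValueError("mut_class must be 'SSM' or 'SIM'")
        self.mut_class = mut_class
        self.mutations = [m for m in mutations if m.class_label != 0]
        order = SSM_CLASS_ORDER if mut_class == "SSM" else SIM_CLASS_ORDER
        self.class_order = order
        self.tiers: dict[int, frozenset] = {}
        cum: set[tuple] = set()
        for cls in order:
            cum |= {m.call.key() for m in self.mutations if m.class_label == cls}
            self.tiers[cls] = frozenset(cum)

    def tier(self, k: int) -> frozenset:
        if k not in self.tiers:
            raise KeyError(f"tier {k} undefined for {self.mut_class} gold set")
        return self.tiers[k]

    @property
    def tier_sizes(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.tiers.items()}

    @property
    def class_counts(self) -> dict[int, int]:
        c = Counter(m.class_label for m in self.mutations)
        return {k: c.get(k, 0) for k in self.class_order}

    def __len__(self) -> int:
        return len(self.mutations)

    def to_ledger(self) -> pd.DataFrame:
        """TSV-ready ledger: one row per curated mutation."""
        return pd.DataFrame(
            {
                "chrom": [m.call.chrom for m in self.mutations],
                "pos": [m.call.pos + 1 for m in self.mutations],
                "ref": [m.call.ref for m in self.mutations],
                "alt": [m.call.alt for m in self.mutations],
                "maf": [m.maf for m in self.mutations],
                "class": [m.class_label for m in self.mutations],
            }
        )

    def write_vcf(self, path, genome=None) -> None:
        from .variants import write_callset

        cs = CallSet("GOLD", [m.call for m in self.mutations], normalized=True)
        info = {}
        for m in self.mutations:
            tiers = ",".join(
                str(k) for k in self.class_order if m.call.key() in self.tiers[k]
            )
            info[m.call.key()] = {"CLASS": m.class_label, "TIERS": tiers}
        write_callset(cs, path, genome=genome, info=info)


def tier_sizes_from_counts(
    class_counts: Mapping[int, int], mut_class: str = "SSM"
) -> dict[int, int]:
    """Cumulative tier sizes implied by per-class counts."""
    order = SSM_CLASS_ORDER if mut_class == "SSM" else SIM_CLASS_ORDER
    sizes = {}
    total = 0
    for cls in order:
        total += int(class_counts.get(cls, 0))
        sizes[cls] = total
    return sizes


def compile_tiers(
    classified: Iterable[GoldMutation], mut_class: str = "SSM"
) -> GoldSet:
    """Build the cumulative-tier gold set from classified mutations.

    Class 0 never enters any tier; for SIMs only classes 1 and 4 are used
    (candidates labelled 2, 3 or 5 are rejected, matching the coarser
    indel classification).
    """
    muts = list(classified)
    if mut_class == "SIM":
        muts = [m for m in muts if m.class_label in SIM_CLASS_ORDER]
    return GoldSet(muts, mut_class=mut_class)


def depth_bounds_from_evidence(
    evidence: pd.DataFrame, quantile_mults: tuple[float, float] = (0.5, 2.0)
) -> tuple[float, float]:
    """Absolute tumour-depth outlier bounds: multiples of the median depth."""
    med = float(np.median((evidence["t_alt"] + evidence["t_ref"]).to_numpy()))
    return quantile_mults[0] * med, quantile_mults[1] * med


def curate(
    callsets: Sequence[CallSet],
    evidence: pd.DataFrame,
    cfg: CurationConfig | None = None,
) -> dict[str, GoldSet]:
    """Full curation: consensus, scoring, classification, tier compilation.

    ``evidence`` must cover every candidate site in the union of the call
    sets (rows are matched on chrom/pos/ref/alt); candidate calls without
    evidence are rejected.  Returns {'SSM': GoldSet, 'SIM': GoldSet}.
    """
    cfg = cfg or CurationConfig()
    auto, review = consensus_partition(callsets, cfg)
    candidates = auto | review

    ev = evidence
    if "score" not in ev.columns:
        ev = score_evidence(ev, cfg.beta_prior)
    ev = ev.reset_index(drop=True)
    index = {
        (c, p, r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(ev["chrom"], ev["pos"], ev["ref"], ev["alt"])
        )
    }
    bounds = depth_bounds_from_evidence(ev, cfg.depth_outlier_quantiles)

    per_class: dict[str, list[GoldMutation]] = {"SSM": [], "SIM": []}
    for key in sorted(candidates):
        i = index.get(key)
        if i is None:
            continue
        row = ev.iloc[i]
        label = classify_candidate(
            row, cfg, depth_bounds=bounds, auto_accepted=key in auto
        )
        call = MutationCall(str(row["chrom"]), int(row["pos"]),
                            str(row["ref"]), str(row["alt"]), source="GOLD")
        per_class[call.mut_class].append(
            GoldMutation(call, maf=float(row["maf"]), class_label=label,
                         evidence_index=i)
        )
    return {
        "SSM": compile_tiers(per_class["SSM"], "SSM"),
        "SIM": compile_tiers(per_class["SIM"], "SIM"),
    }
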