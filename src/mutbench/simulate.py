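"""Synthetic tumour-normal benchmark cohort.

Generates, from a seed alone, everything the benchmarking analysis
consumes: a small genome with annotated repeat/segdup/blacklist/ROI
tracks, a planted somatic-mutation truth table for a high-purity, largely
tetraploid tumour (clonal and subclonal allele-fraction strata), allele
counts at candidate sites under a negative-binomial depth / binomial
error model, per-caller submissions with configurable sensitivity and
feature-biased false positives, and windowed depth tracks.

Counts, not reads, are the unit of evidence: every downstream computation
(concordance scoring, curation, evaluation, saturation modelling) works on
tumour/normal allele counts and intervals, so no BAM-level simulation is
performed.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, IntervalTrack
from .mappability import KmerMappability
from .variants import CallSet, MutationCall, left_align

TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "mut_class", "planted_class",
    "af_tumour", "af_normal", "clone", "copy_number", "mutated_copies",
    "clone_fraction", "ambiguous", "depth_mult", "in_tr",
]

EVIDENCE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "mut_class", "t_alt", "t_ref",
    "n_alt", "n_ref", "depth_t", "depth_n", "map100", "map150",
    "segdup", "blacklist", "ambiguous", "af_true",
]


@dataclass
class CohortConfig:
    """Generator settings for one synthetic cohort.

    Defaults emulate the deep-coverage verification setting: a 5-Mb
    two-contig genome standing in for a largely tetraploid tumour (one
    contig at copy number 2), ~300x tumour / ~270x normal coverage,
    purity 0.98, per-base error 1e-3 and a PCR-free (flat-GC) coverage
    profile.  Class weights follow the curated-set proportions
    (~74/11/12/0.6/2.2% for classes 1-5); most indels are planted inside
    tandem repeats or homopolymers.
    """

    contig_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 3_000_000, "2": 2_000_000}
    )
    contig_copy_number: Mapping[str, int] = field(
        default_factory=lambda: {"1": 4, "2": 2}
    )
    purity: float = 0.98
    gc_window: int = 10_000
    gc_mean: float = 0.41
    gc_sd: float = 0.06
    mutation_rate_per_mb: float = 100.0
    sim_fraction: float = 0.2
    ssm_class_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.745, 2: 0.108, 3: 0.119, 4: 0.006, 5: 0.022}
    )
    sim_class_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.971, 4: 0.029}
    )
    sim_tr_fraction: float = 0.83
    class2_af_range: tuple[float, float] = (0.055, 0.095)
    class3_af_range: tuple[float, float] = (0.022, 0.048)
    depth_outlier_mults: tuple[float, float] = (0.3, 3.0)
    # feature planting densities (per Mb unless stated)
    homopolymers_per_mb: float = 60.0
    microsats_per_mb: float = 40.0
    simple_reps_per_mb: float = 20.0
    nested_reps_per_mb: float = 5.0
    segdups_per_mb: float = 1.0
    segdup_length: int = 2_000
    centromere_length: int = 50_000
    blacklist_per_genome: int = 6
    blacklist_length: int = 2_000
    exons_per_mb: float = 25.0
    exon_length: int = 200
    enhancers_per_mb: float = 10.0
    enhancer_length: int = 500
    # sequencing model
    mean_depth_tumour: float = 300.0
    mean_depth_normal: float = 270.0
    error_rate: float = 1e-3
    nb_dispersion: float = 10.0
    gc_slope: float = 0.0

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.ssm_class_weights = {int(k): float(v) for k, v in cfg.ssm_class_weights.items()}
        cfg.sim_class_weights = {int(k): float(v) for k, v in cfg.sim_class_weights.items()}
        return cfg


@dataclass
class SyntheticGenome:
    """Genome plus the annotation context the feature analysis relies on."""

    genome: Genome
    repeat_track: IntervalTrack
    segdup_track: IntervalTrack
    blacklist_track: IntervalTrack
    roi_track: IntervalTrack
    gc_profile: pd.DataFrame  # chrom, start, end, gc
    _mapp: dict = field(default_factory=dict, repr=False)

    def mappability(self, k: int) -> KmerMappability:
        if k not in self._mapp:
            self._mapp[k] = KmerMappability(self.genome, k)
        return self._mapp[k]

    def window_mappability(self, chrom, pos, k: int) -> np.ndarray:
        rel = (-90, -10) if k == 100 else (-(k - 10), -10)
        return self.mappability(k).window_means(
            np.asarray(chrom, dtype=object), np.asarray(pos), rel[0], rel[1]
        )

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.genome.to_fasta(os.path.join(outdir, "genome.fa"))
        self.repeat_track.to_bed(os.path.join(outdir, "repeats.bed"))
        self.segdup_track.to_bed(os.path.join(outdir, "segdups.bed"))
        self.blacklist_track.to_bed(os.path.join(outdir, "blacklist.bed"))
        self.roi_track.to_bed(os.path.join(outdir, "roi.bed"))
        self.gc_profile.to_csv(os.path.join(outdir, "gc_profile.tsv"), sep="\t", index=False)


_BASES = np.array(list("ACGT"))


def _random_sequence(length: int, gc_window: int, gc_mean: float, gc_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Random sequence with per-window GC targets (char numpy array)."""
    n_win = max(1, int(np.ceil(length / gc_window)))
    gc = np.clip(rng.normal(gc_mean, gc_sd, size=n_win), 0.25, 0.65)
    per_base_gc = np.repeat(gc, gc_window)[:length]
    is_gc = rng.random(length) < per_base_gc
    second = rng.random(length) < 0.5
    codes = np.where(is_gc, np.where(second, 1, 2), np.where(second, 0, 3))
    return _BASES[codes].copy()


def _place_intervals(rng, occupied: list[tuple[int, int]], contig_len: int,
                     n: int, length_fn, margin: int = 10, max_tries: int = 50):
    """Sample n non-overlapping intervals, rejecting clashes with `occupied`."""
    placed = []
    for _ in range(n):
        for _try in range(max_tries):
            ln = int(length_fn())
            start = int(rng.integers(margin, max(margin + 1, contig_len - ln - margin)))
            if all(start + ln + margin <= s or start >= e + margin for s, e in occupied):
                occupied.append((start, start + ln))
                placed.append((start, ln))
                break
    return placed


def simulate_genome(config: CohortConfig, seed: int) -> SyntheticGenome:
    """Generate the synthetic genome and its annotation tracks."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    repeat = IntervalTrack("repeats")
    segdup = IntervalTrack("segdups")
    blacklist = IntervalTrack("blacklist")
    roi = IntervalTrack("roi")

    for chrom, length in config.contig_lengths.items():
        seq = _random_sequence(length, config.gc_window, config.gc_mean,
                               config.gc_sd, rng)
        mb = length / 1e6
        occupied: list[tuple[int, int]] = []

        # centromere: tandemly tiled satellite unit in the contig middle
        cen_len = min(config.centromere_length, length // 10)
        cen_start = (length - cen_len) // 2
        unit = _BASES[rng.integers(0, 4, size=171)]
        tiled = np.tile(unit, cen_len // len(unit) + 1)[:cen_len]
        seq[cen_start : cen_start + cen_len] = tiled
        occupied.append((cen_start, cen_start + cen_len))
        blacklist.add(chrom, cen_start, cen_start + cen_len, "centromere")

        # homopolymers: runs of 8-15 of one base
        for start, ln in _place_intervals(
            rng, occupied, length, rng.poisson(config.homopolymers_per_mb * mb),
            lambda: rng.integers(8, 16),
        ):
            seq[start : start + ln] = _BASES[rng.integers(0, 4)]
            repeat.add(chrom, start, start + ln, "homopolymer")

        # microsatellites: unit 2-6 bp, 6-12 copies
        n_ms = rng.poisson(config.microsats_per_mb * mb)
        for _ in range(n_ms):
            u = int(rng.integers(2, 7))
            copies = int(rng.integers(6, 13))
            ln = u * copies
            got = _place_intervals(rng, occupied, length, 1, lambda: ln)
            if not got:
                continue
            start, _ = got[0]
            unit_seq = _BASES[rng.integers(0, 4, size=u)]
            seq[start : start + ln] = np.tile(unit_seq, copies)
            repeat.add(chrom, start, start + ln, "microsatellite")

        # simple repeats: unit 7-20 bp, 4-8 copies (period above the TR-scan range)
        n_sr = rng.poisson(config.simple_reps_per_mb * mb)
        for _ in range(n_sr):
            u = int(rng.integers(7, 21))
            copies = int(rng.integers(4, 9))
            ln = u * copies
            got = _place_intervals(rng, occupied, length, 1, lambda: ln)
            if not got:
                continue
            start, _ = got[0]
            unit_seq = _BASES[rng.integers(0, 4, size=u)]
            seq[start : start + ln] = np.tile(unit_seq, copies)
            repeat.add(chrom, start, start + ln, "simple_repeat")

        # nested repeats: a microsatellite embedded inside a simple repeat
        n_nr = rng.poisson(config.nested_reps_per_mb * mb)
        for _ in range(n_nr):
            ln = 240
            got = _place_intervals(rng, occupied, length, 1, lambda: ln)
            if not got:
                continue
            start, _ = got[0]
            outer = _BASES[rng.integers(0, 4, size=40)]
            block = np.tile(outer, 6)[:ln]
            inner_unit = _BASES[rng.integers(0, 4, size=3)]
            block[60:120] = np.tile(inner_unit, 20)
            seq[start : start + ln] = block
            repeat.add(chrom, start, start + ln, "nested_repeat")

        # regions of interest
        for start, ln in _place_intervals(
            rng, occupied, length, rng.poisson(config.exons_per_mb * mb),
            lambda: config.exon_length,
        ):
            roi.add(chrom, start, start + ln, "exon")
        for start, ln in _place_intervals(
            rng, occupied, length, rng.poisson(config.enhancers_per_mb * mb),
            lambda: config.enhancer_length,
        ):
            roi.add(chrom, start, start + ln, "enhancer")

        seqs[chrom] = seq

    # segmental duplications: copy 2-kb blocks verbatim to a second locus
    for chrom, length in config.contig_lengths.items():
        seq = seqs[chrom]
        n_sd = rng.poisson(config.segdups_per_mb * length / 1e6)
        for _ in range(n_sd):
            ln = config.segdup_length
            src = int(rng.integers(1000, length - 2 * ln - 2000))
            dst = int(rng.integers(src + ln + 1000, length - ln - 500))
            seq[dst : dst + ln] = seq[src : src + ln]
            segdup.add(chrom, src, src + ln, "segdup")
            segdup.add(chrom, dst, dst + ln, "segdup")

    # additional blacklist intervals (DAC / Duke style)
    chroms = list(config.contig_lengths)
    for i in range(config.blacklist_per_genome):
        chrom = chroms[i % len(chroms)]
        length = config.contig_lengths[chrom]
        start = int(rng.integers(1000, length - config.blacklist_length - 1000))
        label = "dac" if i % 2 == 0 else "duke"
        blacklist.add(chrom, start, start + config.blacklist_length, label)

    genome = Genome({c: "".join(s) for c, s in seqs.items()})
    gc_profile = compute_gc_profile(genome, config.gc_window)
    return SyntheticGenome(genome, repeat, segdup, blacklist, roi, gc_profile)


def compute_gc_profile(genome: Genome, window: int) -> pd.DataFrame:
    rows = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            rows.append((chrom, start, end, float(is_gc[start:end].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def _forbidden_mask_positions(sg: SyntheticGenome, chrom: str, pos: np.ndarray,
                              margin: int = 150) -> np.ndarray:
    """True where a position is too close to segdup/blacklist/contig edge."""
    length = sg.genome.length(chrom)
    bad = (pos < margin) | (pos > length - margin)
    for track in (sg.segdup_track, sg.blacklist_track):
        for c, s, e, _lab in track:
            if c == chrom:
                bad |= (pos >= s - margin) & (pos < e + margin)
    return bad


def simulate_truth(config: CohortConfig, seed: int) -> tuple[SyntheticGenome, pd.DataFrame]:
    """Plant the somatic truth set on a freshly generated genome.

    Returns the annotated genome and the truth table (one row per planted
    mutation) with allele fractions consistent with the per-contig copy
    number, clone fraction and tumour purity:
    ``af = purity * mutated_copies * clone_fraction / copy_number``.
    """
    sg = simulate_genome(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    total_mb = sum(config.contig_lengths.values()) / 1e6
    n_total = rng.poisson(config.mutation_rate_per_mb * total_mb)
    if n_total == 0:
        raise ValueError("config yields zero mutations; increase mutation_rate_per_mb")
    n_sim = int(round(n_total * config.sim_fraction))
    n_ssm = n_total - n_sim

    contigs = list(config.contig_lengths)
    weights = np.array([config.contig_lengths[c] for c in contigs], dtype=float)
    weights /= weights.sum()

    rows: list[dict] = []
    used_positions: set[tuple[str, int]] = set()

    def _sample_clean_position() -> tuple[str, int] | None:
        for _ in range(100):
            chrom = str(rng.choice(contigs, p=weights))
            pos = int(rng.integers(150, config.contig_lengths[chrom] - 150))
            if _forbidden_mask_positions(sg, chrom, np.array([pos]))[0]:
                continue
            if any((chrom, p) in used_positions for p in range(pos - 25, pos + 26)):
                continue
            return chrom, pos
        return None

    def _sample_track_position(ivs: list) -> tuple[str, int] | None:
        if not ivs:
            return None
        for _ in range(100):
            chrom, s, e, _lab = ivs[int(rng.integers(0, len(ivs)))]
            pos = int(rng.integers(s + 120, e - 20))
            if any((chrom, p) in used_positions for p in range(pos - 25, pos + 26)):
                continue
            return chrom, pos
        return None

    def _assign_af(chrom: str, planted_class: int) -> dict:
        cn = int(config.contig_copy_number.get(chrom, 4))
        if planted_class in (1, 4, 5):
            # clonal: whole-tumour mutations on 1..cn copies
            m = int(rng.choice([1, 2], p=[0.7, 0.3])) if cn >= 4 else 1
            if rng.random() < 0.1:
                m = cn // 2 + 1
            frac = 1.0
            clone = "clonal"
        else:
            lo, hi = (config.class2_af_range if planted_class == 2
                      else config.class3_af_range)
            target = float(rng.uniform(lo, hi))
            m = 1
            frac = min(1.0, target * cn / (config.purity * m))
            clone = "sub1" if planted_class == 2 else "sub2"
        af = config.purity * m * frac / cn
        return dict(af_tumour=af, clone=clone, copy_number=cn,
                    mutated_copies=m, clone_fraction=frac)

    ssm_classes = list(config.ssm_class_weights)
    ssm_p = np.array([config.ssm_class_weights[k] for k in ssm_classes], dtype=float)
    ssm_p /= ssm_p.sum()
    sim_classes = list(config.sim_class_weights)
    sim_p = np.array([config.sim_class_weights[k] for k in sim_classes], dtype=float)
    sim_p /= sim_p.sum()

    tr_intervals = [
        iv for iv in sg.repeat_track
        if iv[3] in ("homopolymer", "microsatellite")
        and not _forbidden_mask_positions(sg, iv[0], np.array([iv[1]]))[0]
    ]
    tr_weights = np.array([e - s for _, s, e, _l in tr_intervals], dtype=float)
    if len(tr_intervals):
        tr_weights /= tr_weights.sum()

    def _emit(mut_class: str, planted_class: int) -> None:
        ambiguous = planted_class == 4
        depth_mult = 1.0
        in_tr = False
        if ambiguous:
            spot = _sample_track_position(sg.segdup_track.intervals)
        elif planted_class == 5:
            # aberrant-depth mutations sit in repetitive (low-mappability)
            # context, as large CNV/satellite regions do in real tumours
            depth_mult = float(rng.choice(config.depth_outlier_mults))
            spot = _sample_track_position([
                iv for iv in sg.blacklist_track if iv[3] == "centromere"
            ])
        elif (mut_class == "SIM" and len(tr_intervals)
              and rng.random() < config.sim_tr_fraction):
            idx = int(rng.choice(len(tr_intervals), p=tr_weights))
            chrom, s, e, lab = tr_intervals[idx]
            pos = int(rng.integers(s, max(s + 1, e - 8)))
            spot = None if (chrom, pos) in used_positions else (chrom, pos)
            in_tr = spot is not None
        else:
            spot = _sample_clean_position()
        if spot is None:
            return
        chrom, pos = spot
        seq = sg.genome[chrom]
        if mut_class == "SSM":
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            if rng.random() < 0.6 and pos + 4 < sg.genome.length(chrom):
                dlen = int(rng.integers(1, 4))
                ref = seq[pos : pos + 1 + dlen]
                alt = ref[0]
            else:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                ref = seq[pos]
                alt = ref + ins
            call = left_align(MutationCall(chrom, pos, ref, alt), sg.genome)
            chrom, pos, ref, alt = call.chrom, call.pos, call.ref, call.alt
            if (chrom, pos) in used_positions:
                return
        for p in range(pos - 25, pos + 26):
            used_positions.add((chrom, p))
        rows.append(dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, mut_class=mut_class,
            planted_class=planted_class, af_normal=0.0,
            ambiguous=ambiguous, depth_mult=depth_mult, in_tr=in_tr,
            **_assign_af(chrom, planted_class),
        ))

    for _ in range(n_ssm):
        _emit("SSM", int(rng.choice(ssm_classes, p=ssm_p)))
    for _ in range(n_sim):
        _emit("SIM", int(rng.choice(sim_classes, p=sim_p)))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return sg, truth


def _gc_factor(sg: SyntheticGenome, chrom: np.ndarray, pos: np.ndarray,
               gc_slope: float) -> np.ndarray:
    """Multiplicative GC response of coverage, from the genome's GC profile."""
    if gc_slope == 0.0:
        return np.ones(len(pos))
    prof = sg.gc_profile
    out = np.ones(len(pos))
    mean_gc = prof["gc"].mean()
    for c in np.unique(np.asarray(chrom, dtype=object)):
        sub = prof[prof["chrom"] == c]
        window = int(sub["end"].iloc[0] - sub["start"].iloc[0])
        sel = np.asarray(chrom, dtype=object) == c
        idx = np.minimum(np.asarray(pos)[sel] // window, len(sub) - 1)
        out[sel] = 1.0 + gc_slope * (sub["gc"].to_numpy()[idx] - mean_gc)
    return np.clip(out, 0.05, None)


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(
    sg: SyntheticGenome,
    truth: pd.DataFrame,
    extra_sites: pd.DataFrame | None = None,
    *,
    mean_depth_t: float = 300.0,
    mean_depth_n: float = 270.0,
    error_rate: float = 1e-3,
    contamination: float = 0.0,
    gc_slope: float = 0.0,
    dispersion: float = 10.0,
    seed: int = 0,
    with_mappability: bool = True,
) -> pd.DataFrame:
    """Tumour/normal allele counts at truth sites plus any extra candidates.

    Per-site depth is negative binomial around the (GC-modulated) mean;
    the tumour alternate count is Binomial(depth, af*(1-contamination) +
    error_rate) and the normal alternate count Binomial(depth, af_normal +
    error_rate).  Extra (non-mutated) candidate sites emit error-only
    counts.  Deterministic given seed.
    """
    if mean_depth_t <= 0 or mean_depth_n <= 0:
        raise ValueError("mean depths must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate outside [0, 0.05]")
    if not 0 <= contamination < 1:
        raise ValueError("contamination outside [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    frames = [truth[["chrom", "pos", "ref", "alt", "mut_class"]].assign(
        af_true=truth["af_tumour"].to_numpy(),
        af_normal=truth["af_normal"].to_numpy(),
        ambiguous=truth["ambiguous"].to_numpy(),
        depth_mult=truth["depth_mult"].to_numpy(),
    )]
    if extra_sites is not None and len(extra_sites):
        ex = extra_sites[["chrom", "pos", "ref", "alt"]].copy()
        ex["mut_class"] = [
            "SSM" if len(r) == 1 and len(a) == 1 else "SIM"
            for r, a in zip(ex["ref"], ex["alt"])
        ]
        ex["af_true"] = 0.0
        ex["af_normal"] = 0.0
        ex["ambiguous"] = False
        ex["depth_mult"] = 1.0
        frames.append(ex)
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], keep="first")
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    chrom = sites["chrom"].to_numpy(dtype=object)
    pos = sites["pos"].to_numpy(dtype=np.int64)
    gcf = _gc_factor(sg, chrom, pos, gc_slope)
    mult = sites["depth_mult"].to_numpy(dtype=float)

    depth_t = _nbinom(rng, mean_depth_t * gcf * mult, dispersion)
    depth_n = _nbinom(rng, mean_depth_n * gcf, dispersion)
    depth_t = np.maximum(depth_t, 1)
    depth_n = np.maximum(depth_n, 1)

    af = sites["af_true"].to_numpy(dtype=float)
    p_t = np.clip(af * (1.0 - contamination) + error_rate, 0.0, 1.0)
    p_n = np.clip(sites["af_normal"].to_numpy(dtype=float) + error_rate, 0.0, 1.0)
    t_alt = rng.binomial(depth_t, p_t)
    n_alt = rng.binomial(depth_n, p_n)

    ev = sites[["chrom", "pos", "ref", "alt", "mut_class", "af_true"]].copy()
    ev["t_alt"] = t_alt
    ev["t_ref"] = depth_t - t_alt
    ev["n_alt"] = n_alt
    ev["n_ref"] = depth_n - n_alt
    ev["depth_t"] = depth_t
    ev["depth_n"] = depth_n
    if with_mappability:
        ev["map100"] = sg.window_mappability(chrom, pos, 100)
        ev["map150"] = sg.window_mappability(chrom, pos, 150)
    else:
        ev["map100"] = 1.0
        ev["map150"] = 1.0
    ev["segdup"] = sg.segdup_track.overlap_mask(chrom, pos)
    ev["blacklist"] = sg.blacklist_track.overlap_mask(chrom, pos)
    ev["ambiguous"] = sites["ambiguous"].to_numpy(dtype=bool)
    return ev[EVIDENCE_COLUMNS]


@dataclass
class CallerProfile:
    """Stylised somatic-calling pipeline: AF-stratified sensitivity plus
    feature-biased false positives.

    ``sensitivity_by_af`` holds detection probabilities for the three AF
    strata (af >= 0.10, 0.05 <= af < 0.10, af < 0.05); false positives are
    placed uniformly at ``fp_rate_per_mb``, with per-feature multipliers
    (e.g. ``{"blacklist": 10.0}``) concentrating extra FPs inside flagged
    intervals.
    """

    name: str
    sensitivity_by_af: tuple[float, float, float] = (0.95, 0.6, 0.2)
    fp_rate_per_mb: float = 5.0
    fp_feature_bias: Mapping[str, float] = field(default_factory=dict)
    mut_classes: tuple[str, ...] = ("SSM", "SIM")
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 <= s <= 1.0 for s in self.sensitivity_by_af):
            raise ValueError("sensitivities must lie in [0, 1]")
        if self.fp_rate_per_mb < 0 or any(m < 0 for m in self.fp_feature_bias.values()):
            raise ValueError("FP rates and bias multipliers must be >= 0")

    def sensitivity(self, af: float | np.ndarray) -> np.ndarray:
        af = np.asarray(af, dtype=float)
        hi, mid, lo = self.sensitivity_by_af
        return np.where(af >= 0.10, hi, np.where(af >= 0.05, mid, lo))


def simulate_submission(
    sg: SyntheticGenome, truth: pd.DataFrame, profile: CallerProfile
) -> CallSet:
    """One caller's submission: thinned truth plus feature-biased FPs.

    The returned CallSet carries a ``ledger`` attribute recording exactly
    which truth rows were emitted and which calls are planted FPs, so
    evaluation results can be checked against generator bookkeeping.
    """
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 3]))
    calls: list[MutationCall] = []
    detected: set[tuple] = set()
    sub_truth = truth[truth["mut_class"].isin(profile.mut_classes)]
    keep = rng.random(len(sub_truth)) < profile.sensitivity(
        sub_truth["af_tumour"].to_numpy()
    )
    for row in sub_truth[keep].itertuples(index=False):
        call = MutationCall(row.chrom, int(row.pos), row.ref, row.alt,
                            source=profile.name)
        calls.append(call)
        detected.add(call.key())

    fp_keys: set[tuple] = set()

    def _emit_fp(chrom: str, pos: int) -> None:
        seq = sg.genome[chrom]
        if pos >= len(seq) - 5 or pos < 1:
            return
        want_sim = "SIM" in profile.mut_classes and (
            "SSM" not in profile.mut_classes or rng.random() < 0.2
        )
        if want_sim:
            if rng.random() < 0.5:
                ref = seq[pos : pos + 2]
                alt = ref[0]
            else:
                ref = seq[pos]
                alt = ref + str(rng.choice(list("ACGT")))
            if ref == alt:
                return
            call = left_align(MutationCall(chrom, pos, ref, alt,
                                           source=profile.name), sg.genome)
        else:
            ref = seq[pos]
            if ref not in "ACGT":
                return
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            call = MutationCall(chrom, pos, ref, alt, source=profile.name)
        if call.key() in detected or call.key() in fp_keys:
            return
        calls.append(call)
        fp_keys.add(call.key())

    # background FPs across the genome
    for chrom, length in ((c, sg.genome.length(c)) for c in sg.genome.contigs):
        n_bg = rng.poisson(profile.fp_rate_per_mb * length / 1e6)
        for pos in rng.integers(5, length - 5, size=n_bg):
            _emit_fp(chrom, int(pos))
    # feature-concentrated FPs
    track_map = {
        "blacklist": sg.blacklist_track,
        "segdup": sg.segdup_track,
        "repeat": sg.repeat_track,
    }
    for feature, mult in profile.fp_feature_bias.items():
        track = track_map.get(feature)
        if track is None or mult <= 1.0:
            continue
        for chrom, s, e, _lab in track:
            extra = rng.poisson(profile.fp_rate_per_mb * (mult - 1.0) * (e - s) / 1e6)
            for pos in rng.integers(s, e, size=extra):
                _emit_fp(chrom, int(pos))

    cs = CallSet(profile.name, calls)
    cs.ledger = {"detected": detected, "fp": fp_keys}  # type: ignore[attr-defined]
    return cs


def thin_and_mix(
    evidence: pd.DataFrame,
    fraction: float,
    contamination: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially thin counts to a coverage fraction and mix in normal reads.

    Each tumour read is kept with probability ``fraction*(1-contamination)``;
    the removed tumour fraction is replaced by reads drawn with the normal
    sample's empirical alternate-allele rate, so the expected total tumour
    depth scales by ``fraction`` while the expected mutant AF scales by
    ``(1-contamination)``.  Normal counts are thinned by ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not 0 <= contamination < 1:
        raise ValueError("contamination must lie in [0, 1)")
    if fraction == 1.0 and contamination == 0.0:
        return evidence.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    out = evidence.copy()
    keep = fraction * (1.0 - contamination)
    t_alt = rng.binomial(evidence["t_alt"].to_numpy(), keep)
    t_ref = rng.binomial(evidence["t_ref"].to_numpy(), keep)
    if contamination > 0:
        depth = evidence["depth_t"].to_numpy()
        n_added = rng.binomial(depth, fraction * contamination)
        p_n = evidence["n_alt"].to_numpy() / np.maximum(
            evidence["depth_n"].to_numpy(), 1
        )
        added_alt = rng.binomial(n_added, p_n)
        t_alt = t_alt + added_alt
        t_ref = t_ref + (n_added - added_alt)
    n_alt = rng.binomial(evidence["n_alt"].to_numpy(), fraction)
    n_ref = rng.binomial(evidence["n_ref"].to_numpy(), fraction)
    out["t_alt"], out["t_ref"] = t_alt, t_ref
    out["n_alt"], out["n_ref"] = n_alt, n_ref
    out["depth_t"] = t_alt + t_ref
    out["depth_n"] = n_alt + n_ref
    return out


def random_error_sites(
    sg: SyntheticGenome, truth: pd.DataFrame, n: int, seed: int = 0
) -> pd.DataFrame:
    """Non-mutated candidate sites (for FP/error-rate experiments)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    taken = set(zip(truth["chrom"], truth["pos"]))
    contigs = sg.genome.contigs
    weights = np.array([sg.genome.length(c) for c in contigs], dtype=float)
    weights /= weights.sum()
    rows = []
    while len(rows) < n:
        chrom = str(rng.choice(contigs, p=weights))
        pos = int(rng.integers(150, sg.genome.length(chrom) - 150))
        if (chrom, pos) in taken:
            continue
        ref = sg.genome.base(chrom, pos)
        if ref not in "ACGT":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rows.append((chrom, pos, ref, alt))
        taken.add((chrom, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def simulate_depth_track(
    sg: SyntheticGenome,
    mean_depth: float = 30.0,
    window: int = 1_000,
    dispersion: float = 10.0,
    gc_slope: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed depth track (BEDGRAPH-style) with the cohort coverage model."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    rows = []
    for chrom in sg.genome.contigs:
        length = sg.genome.length(chrom)
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        mids = (starts + ends) // 2
        gcf = _gc_factor(sg, np.full(len(starts), chrom, dtype=object), mids, gc_slope)
        depth = _nbinom(rng, mean_depth * gcf, dispersion)
        for s, e, d in zip(starts, ends, depth):
            rows.append((chrom, int(s), int(e), int(d)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


def curation_caller_profiles(n: int = 6, seed: int = 0) -> list[CallerProfile]:
    """Deep-coverage verification pipelines used to build the candidate pool."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    profiles = []
    for i in range(n):
        profiles.append(CallerProfile(
            name=f"deep{chr(65 + i)}",
            sensitivity_by_af=(
                float(rng.uniform(0.97, 0.995)),
                float(rng.uniform(0.85, 0.95)),
                float(rng.uniform(0.55, 0.8)),
            ),
            fp_rate_per_mb=float(rng.uniform(2.0, 8.0)),
            fp_feature_bias={"blacklist": float(rng.uniform(2.0, 6.0))},
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return profiles


def benchmark_caller_profiles(seed: int = 0) -> list[CallerProfile]:
    """A spread of 40x-style submissions: balanced, conservative, overcalling
    and feature-biased pipelines, echoing the diversity of a community
    benchmark."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))

    def s(lo, hi):
        return float(rng.uniform(lo, hi))

    return [
        CallerProfile("subA", (s(0.85, 0.92), s(0.4, 0.6), 0.05),
                      fp_rate_per_mb=3.0, seed=int(rng.integers(2**31))),
        CallerProfile("subB", (s(0.9, 0.95), s(0.5, 0.7), 0.1),
                      fp_rate_per_mb=1.0, seed=int(rng.integers(2**31))),
        CallerProfile("subC", (s(0.8, 0.9), s(0.3, 0.5), 0.05),
                      fp_rate_per_mb=30.0,
                      fp_feature_bias={"blacklist": 20.0},
                      seed=int(rng.integers(2**31))),
        CallerProfile("subD", (s(0.9, 0.97), s(0.6, 0.8), 0.2),
                      fp_rate_per_mb=60.0,
                      fp_feature_bias={"repeat": 5.0},
                      seed=int(rng.integers(2**31))),
        CallerProfile("subE", (s(0.5, 0.6), s(0.1, 0.3), 0.0),
                      fp_rate_per_mb=0.5, seed=int(rng.integers(2**31))),
        CallerProfile("subF", (s(0.88, 0.94), s(0.45, 0.65), 0.1),
                      fp_rate_per_mb=8.0,
                      fp_feature_bias={"segdup": 10.0},
                      seed=int(rng.integers(2**31))),
    ]


def write_evidence(evidence: pd.DataFrame, path: str | os.PathLike) -> None:
    out = evidence.copy()
    out["pos"] = out["pos"] + 1  # 1-based at the file boundary
    out.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | os.PathLike) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    ev["chrom"] = ev["chrom"].astype(str)
    ev["pos"] = ev["pos"] - 1
    return ev
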