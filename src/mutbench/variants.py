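"""Mutation calls, call sets and VCF I/O.

Somatic calls are held as :class:`MutationCall` (SSM = single-base
substitution, SIM = insertion/deletion) inside a :class:`CallSet` per
submission.  Positions are 0-based internally; the 1-based convention of
VCF applies only at the file boundary.  Normalisation mirrors what a
benchmark evaluation server does before comparing submissions: restrict to
chromosomes 1-22/X/Y, left-align indels against the reference, sort and
collapse exact duplicates.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .genome import Genome

CANONICAL_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_VALID_BASES = frozenset("ACGTN")


class MalformedRecordError(ValueError):
    """A VCF record that cannot be interpreted as a point mutation or indel."""


class ReferenceMismatchError(ValueError):
    """Stated REF allele disagrees with the reference sequence (corrupt input)."""


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix; 'chrM'/'MT' style contigs are left untouched."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class MutationCall:
    """A single somatic mutation call.

    ``pos`` is 0-based.  SSMs have single-base ref and alt; SIMs follow the
    VCF anchored convention (ref and alt share their first base and differ
    in length).  ``source`` identifies the submission and is excluded from
    identity comparisons.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = field(default="", compare=False)

    def __post_init__(self):
        if self.ref == self.alt:
            raise MalformedRecordError(f"ref == alt at {self.chrom}:{self.pos + 1}")
        if not self.ref or not self.alt:
            raise MalformedRecordError(
                f"empty allele at {self.chrom}:{self.pos + 1} (un-anchored indel?)"
            )
        for allele in (self.ref, self.alt):
            if not set(allele.upper()) <= _VALID_BASES:
                raise MalformedRecordError(
                    f"non-nucleotide allele {allele!r} at {self.chrom}:{self.pos + 1}"
                )

    @property
    def mut_class(self) -> str:
        """'SSM' for single-base substitutions, 'SIM' for indels."""
        return "SSM" if len(self.ref) == 1 and len(self.alt) == 1 else "SIM"

    @property
    def is_ssm(self) -> bool:
        return self.mut_class == "SSM"

    @property
    def end(self) -> int:
        """0-based half-open end of the reference footprint."""
        return self.pos + len(self.ref)

    def key(self, position_only: bool = False) -> tuple:
        """Identity for matching: exact alleles by default, site-only optionally."""
        if position_only:
            return (self.chrom, self.pos)
        return (self.chrom, self.pos, self.ref, self.alt)


class CallSet:
    """An ordered collection of calls from one submission."""

    def __init__(
        self,
        source: str,
        calls: Iterable[MutationCall] = (),
        normalized: bool = False,
    ):
        self.source = source
        self.calls: list[MutationCall] = list(calls)
        self.normalized = normalized

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[MutationCall]:
        return iter(self.calls)

    def __repr__(self) -> str:
        return f"CallSet({self.source!r}, n={len(self)}, normalized={self.normalized})"

    def keys(self, position_only: bool = False) -> set[tuple]:
        return {c.key(position_only) for c in self.calls}

    def filter_class(self, mut_class: str) -> "CallSet":
        """Sub-set to 'SSM' or 'SIM' calls, keeping normalisation status."""
        return CallSet(
            self.source,
            [c for c in self.calls if c.mut_class == mut_class],
            normalized=self.normalized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.calls],
                "pos": [c.pos for c in self.calls],
                "ref": [c.ref for c in self.calls],
                "alt": [c.alt for c in self.calls],
                "class": [c.mut_class for c in self.calls],
                "source": self.source,
            }
        )


def read_callset(path: str | os.PathLike, source: str | None = None) -> CallSet:
    """Read a VCF 4.x file into a CallSet (one call per record/ALT pair).

    Multi-allelic records are split.  Symbolic, breakend or missing ALT
    alleles cannot be interpreted as point mutations; they are reported via
    a warning rather than silently dropped.
    """
    src = source if source is not None else os.path.basename(str(path)).split(".")[0]
    calls: list[MutationCall] = []
    skipped: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if not alts:
                skipped.append(f"{rec.chrom}:{rec.pos} has no ALT")
                continue
            for alt in alts:
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt:
                    skipped.append(f"{rec.chrom}:{rec.pos} symbolic ALT {alt!r}")
                    continue
                if alt == "*":
                    skipped.append(f"{rec.chrom}:{rec.pos} spanning-deletion ALT")
                    continue
                try:
                    calls.append(
                        MutationCall(
                            chrom=str(rec.chrom),
                            pos=rec.start,
                            ref=str(rec.ref).upper(),
                            alt=str(alt).upper(),
                            source=src,
                        )
                    )
                except MalformedRecordError as exc:
                    raise MalformedRecordError(f"{path}: {exc}") from exc
    if skipped:
        warnings.warn(
            f"{path}: skipped {len(skipped)} non-point-mutation allele(s): "
            + "; ".join(skipped[:5]),
            stacklevel=2,
        )
    return CallSet(src, calls)


def write_callset(
    cs: CallSet,
    path: str | os.PathLike,
    genome: Genome | None = None,
    info: dict[tuple, dict] | None = None,
) -> None:
    """Write a CallSet as uncompressed VCF 4.2.

    ``info`` optionally maps call keys to INFO fields (e.g. gold-set CLASS
    and TIERS annotations); keys present in any entry are declared in the
    header.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", f"mutbench:{cs.source}")
    contigs = sorted({c.chrom for c in cs.calls}, key=_chrom_sort_key)
    if genome is not None:
        contigs = [c for c in genome.contigs]
    for contig in contigs:
        if genome is not None and contig in genome:
            header.contigs.add(contig, length=genome.length(contig))
        else:
            header.contigs.add(contig)
    info_keys: list[str] = []
    if info:
        for d in info.values():
            for k in d:
                if k not in info_keys:
                    info_keys.append(k)
        for k in info_keys:
            header.info.add(k, 1, "String", f"mutbench annotation {k}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(cs.calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.end,
                alleles=(call.ref, call.alt),
            )
            if info:
                for k, v in info.get(call.key(), {}).items():
                    rec.info[k] = str(v)
            out.write(rec)


def callset_to_tsv(cs: CallSet, path: str | os.PathLike) -> None:
    """Export a normalised call table (1-based positions, as in VCF)."""
    df = cs.to_dataframe()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False)


def _chrom_sort_key(chrom: str):
    c = normalize_chrom(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


def left_align(call: MutationCall, genome: Genome) -> MutationCall:
    """Return the minimal, left-most representation of an indel.

    Applying the original and the returned variant to the reference yields
    byte-identical alternate haplotypes.  SSMs are returned unchanged.
    Raises :class:`ReferenceMismatchError` if the stated REF allele does not
    match the reference sequence.
    """
    seq = genome[call.chrom]
    if seq[call.pos : call.pos + len(call.ref)].upper() != call.ref.upper():
        raise ReferenceMismatchError(
            f"REF {call.ref!r} does not match reference at {call.chrom}:{call.pos + 1}"
        )
    if call.is_ssm:
        return call
    ref, alt, pos = call.ref.upper(), call.alt.upper(), call.pos
    changed = True
    while changed:
        changed = False
        # trim a shared rightmost base; re-anchor leftwards if an allele empties
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 0:
                pass  # cannot re-anchor past the contig start
            else:
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    pos -= 1
                    base = seq[pos].upper()
                    ref, alt = base + ref, base + alt
                changed = True
        # trim a shared leftmost base while both alleles stay non-empty
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
    return MutationCall(call.chrom, pos, ref, alt, source=call.source)


def apply_variant(call: MutationCall, seq: str) -> str:
    """Alternate haplotype produced by applying ``call`` to contig sequence."""
    return seq[: call.pos] + call.alt + seq[call.pos + len(call.ref) :]


def normalize_callset(cs: CallSet, genome: Genome) -> CallSet:
    """Evaluation-server normalisation of a submission.

    Restricts calls to chromosomes 1-22/X/Y (accepting 'chr' prefixes),
    left-aligns SIMs, coordinate-sorts and collapses exact duplicates.
    Idempotent.
    """
    out: list[MutationCall] = []
    for call in cs.calls:
        chrom = normalize_chrom(call.chrom)
        if chrom not in CANONICAL_CHROMS:
            continue
        call = MutationCall(chrom, call.pos, call.ref.upper(), call.alt.upper(), source=cs.source)
        if not call.is_ssm:
            if chrom not in genome:
                raise ReferenceMismatchError(
                    f"contig {chrom} absent from reference; cannot left-align "
                    f"{call.ref}>{call.alt} at {chrom}:{call.pos + 1}"
                )
            call = left_align(call, genome)
        out.append(call)
    seen: set[tuple] = set()
    unique: list[MutationCall] = []
    for call in sorted(out, key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.ref, c.alt)):
        k = call.key()
        if k not in seen:
            seen.add(k)
            unique.append(call)
    return CallSet(cs.source, unique, normalized=True)


def require_normalized(callsets: Sequence[CallSet]) -> None:
    for cs in callsets:
        if not cs.normalized:
            raise ValueError(f"call set {cs.source!r} is not normalized")
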