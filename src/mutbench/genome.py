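"""Reference sequences and labelled interval tracks.

A :class:`Genome` is an in-memory mapping of contig name to nucleotide
string, read and written as plain (indexable) FASTA.  Interval annotations
(repeats, segmental duplications, blacklists, regions of interest) are
:class:`IntervalTrack` objects backed by BED files; all coordinates are
0-based half-open, converted only at the file boundary (BED is already
0-based half-open, VCF is 1-based).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import pysam


class Genome:
    """In-memory genome: contig name -> upper-case sequence string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(c): str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        with pysam.FastaFile(str(path)) as fa:
            return cls({name: fa.fetch(name) for name in fa.references})

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        # index so pysam/pyfaidx consumers can random-access the output
        try:
            pysam.faidx(str(path))
        except pysam.SamtoolsError:  # pragma: no cover - non-indexable path
            pass

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clamped to contig bounds."""
        seq = self._seqs[chrom]
        return seq[max(0, start) : min(len(seq), end)]

    def base(self, chrom: str, pos: int) -> str:
        return self._seqs[chrom][pos]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())


@dataclass
class IntervalTrack:
    """Labelled genomic intervals (0-based half-open), BED-backed.

    Intervals within a track may overlap; queries are by position or range.
    """

    name: str
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def add(self, chrom: str, start: int, end: int, label: str = ".") -> None:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.intervals.append((str(chrom), int(start), int(end), str(label)))
        self._index = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    _index: dict | None = None

    def _build_index(self) -> dict:
        if self._index is None:
            idx: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
            by_chrom: dict[str, list] = {}
            for chrom, s, e, lab in self.intervals:
                by_chrom.setdefault(chrom, []).append((s, e, lab))
            for chrom, ivs in by_chrom.items():
                ivs.sort()
                starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
                ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
                labels = [lab for _, _, lab in ivs]
                idx[chrom] = (starts, ends, labels)
            self._index = idx
        return self._index

    def labels_at(self, chrom: str, start: int, end: int | None = None) -> list[str]:
        """Labels of intervals overlapping [start, end) (point if end is None)."""
        if end is None:
            end = start + 1
        idx = self._build_index()
        if chrom not in idx:
            return []
        starts, ends, labels = idx[chrom]
        # candidate intervals cannot start at/after `end`
        hi = int(np.searchsorted(starts, end, side="left"))
        return [labels[i] for i in range(hi) if ends[i] > start]

    def overlaps(self, chrom: str, start: int, end: int | None = None) -> bool:
        return bool(self.labels_at(chrom, start, end))

    def overlap_mask(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorised point-overlap test for parallel chrom/pos arrays."""
        out = np.zeros(len(pos), dtype=bool)
        idx = self._build_index()
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        for c, (starts, ends, _labels) in idx.items():
            sel = chrom == c
            if not sel.any():
                continue
            p = pos[sel]
            hit = np.zeros(len(p), dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (p >= s) & (p < e)
            out[sel] = hit
        return out

    def to_bed(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "name"])
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | os.PathLike, name: str | None = None) -> "IntervalTrack":
        track = cls(name=name or os.path.basename(str(path)))
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs at least 3 columns")
        for row in df.itertuples(index=False):
            label = str(row[3]) if df.shape[1] > 3 else "."
            track.add(str(row[0]), int(row[1]), int(row[2]), label)
        return track

    def total_span(self, label: str | None = None) -> int:
        """Sum of interval lengths (not merged), optionally for one label."""
        return sum(
            e - s for _, s, e, lab in self.intervals if label is None or lab == label
        )
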