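"""Exact k-mer mappability of a reference genome.

Mappability of a k-mer starting at position i is 1/m where m is the number
of occurrences of that exact k-mer on the forward strand of the genome
(m >= 1).  Unique k-mers therefore score 1; a position inside a two-copy
segmental duplication scores 0.5.  Window scores used for calls average
the k-mer scores over the standard upstream window (-90..-10 for 100-mers,
-140..-10 for 150-mers, relative to the call position), so that every
averaged k-mer covers the call site.

Occurrence counting uses two independent 31-bit polynomial rolling hashes
combined into one 64-bit key; for genomes up to tens of megabases the
collision probability is negligible, and a brute-force oracle in the test
suite pins down exactness on small genomes.
"""

from __future__ import annotations

import numpy as np

from .genome import Genome

_BASE_CODE = np.full(256, 0, dtype=np.uint64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

# two independent (modulus, multiplier) pairs; moduli < 2^31 keep products in uint64
_HASHES = ((2147483647, 1009), (2147483629, 10007))


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rolling_hash(codes: np.ndarray, k: int, mod: int, mult: int) -> np.ndarray:
    """Hash of every k-window of ``codes`` (length n-k+1), vectorised."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n - k + 1, dtype=np.uint64)
    mod_u = np.uint64(mod)
    mult_u = np.uint64(mult)
    for j in range(k):
        h = (h * mult_u + codes[j : j + n - k + 1]) % mod_u
    return h


class KmerMappability:
    """Per-position k-mer occurrence counts for one k over a genome."""

    def __init__(self, genome: Genome, k: int):
        self.k = int(k)
        keys: list[np.ndarray] = []
        offsets: dict[str, tuple[int, int]] = {}
        cursor = 0
        for chrom, seq in genome.items():
            codes = _encode(seq)
            h1 = _rolling_hash(codes, self.k, *_HASHES[0])
            h2 = _rolling_hash(codes, self.k, *_HASHES[1])
            key = h1 * np.uint64(2147483629) + h2
            keys.append(key)
            offsets[chrom] = (cursor, cursor + len(key))
            cursor += len(key)
        allkeys = np.concatenate(keys) if keys else np.empty(0, dtype=np.uint64)
        _, inverse, counts = np.unique(allkeys, return_inverse=True, return_counts=True)
        occ = counts[inverse].astype(np.int32)
        self._counts = {c: occ[s:e] for c, (s, e) in offsets.items()}

    def counts(self, chrom: str) -> np.ndarray:
        """Occurrence count of the k-mer starting at each position."""
        return self._counts[chrom]

    def score(self, chrom: str, start: int) -> float:
        """Mappability (1/occurrences) of the k-mer starting at ``start``."""
        c = self._counts[chrom]
        if not 0 <= start < len(c):
            raise IndexError(f"k-mer start {start} out of range for {chrom}")
        return 1.0 / float(c[start])

    def window_mean(self, chrom: str, pos: int, rel_start: int, rel_end: int) -> float:
        """Mean k-mer mappability for k-mer starts in pos+[rel_start, rel_end].

        The window is clamped to valid k-mer start positions; an empty
        window (contig edge) falls back to the single k-mer covering pos.
        """
        c = self._counts[chrom]
        lo = max(0, pos + rel_start)
        hi = min(len(c) - 1, pos + rel_end)
        if hi < lo:
            lo = hi = min(max(pos, 0), len(c) - 1)
        return float(np.mean(1.0 / c[lo : hi + 1]))

    def window_means(self, chrom: np.ndarray, pos: np.ndarray, rel_start: int, rel_end: int) -> np.ndarray:
        """Vectorised :meth:`window_mean` over parallel chrom/pos arrays."""
        out = np.empty(len(pos), dtype=float)
        chrom = np.asarray(chrom, dtype=object)
        for c in np.unique(chrom):
            counts = self._counts[str(c)]
            inv = 1.0 / counts
            csum = np.concatenate([[0.0], np.cumsum(inv)])
            sel = np.where(chrom == c)[0]
            p = np.asarray(pos, dtype=np.int64)[sel]
            lo = np.clip(p + rel_start, 0, len(counts) - 1)
            hi = np.clip(p + rel_end, 0, len(counts) - 1)
            bad = hi < lo
            lo[bad] = hi[bad] = np.clip(p[bad], 0, len(counts) - 1)
            out[sel] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
        return out


def window_mappability(
    genome: Genome, chrom: np.ndarray, pos: np.ndarray, k: int
) -> np.ndarray:
    """Mean k-mer mappability upstream of each call position.

    Uses the window -90..-10 for k=100 and -140..-10 for k=150 (k-mer start
    offsets relative to the call), the convention for flagging
    alignment-ambiguous context.
    """
    rel = (-90, -10) if k == 100 else (-(k - 10), -10)
    km = KmerMappability(genome, k)
    return km.window_means(chrom, pos, rel[0], rel[1])
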