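"""96-type mutational catalogues and signature-exposure fitting.

Single-base substitutions are binned by the pyrimidine representation of
the substituted base and its 5'/3' neighbours: purine-reference mutations
are reverse-complemented (allele and context) first, leaving six
substitution types x 16 trinucleotide contexts = 96 bins in the canonical
substitution-major, then 5' base, then 3' base alphabetical order (the
COSMIC convention, so published signature matrices drop in directly).

Exposures are estimated per sample by non-negative least squares, the
quadratic program  min ||S e - m||^2  s.t.  e >= 0, with no sum
constraint; signatures whose exposure falls below a reporting threshold
(default 5% of the catalogue total) are suppressed from the reported set.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genome import Genome
from .variants import MutationCall

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: canonical 96-bin labels, e.g. "A[C>A]A"
SBS96_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_substitution(ref: str, alt: str, five: str, three: str) -> str:
    """96-bin label for one substitution with its flanking bases."""
    if ref in "GA":
        ref, alt = _revcomp(ref), _revcomp(alt)
        five, three = _revcomp(three), _revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def build_catalogue(ssms: list[MutationCall], genome: Genome) -> pd.Series:
    """Count the 96 mutation types over a set of SSMs.

    The reference base at each site must match the stated REF allele;
    sites at contig edges (no flanking base) are excluded with a warning,
    so the catalogue total equals the SSM count minus edge exclusions.
    """
    counts = pd.Series(0, index=list(SBS96_LABELS), dtype=int)
    excluded = 0
    for call in ssms:
        if call.mut_class != "SSM":
            raise ValueError(f"non-SSM call in catalogue input: {call}")
        seq = genome[call.chrom]
        if genome.base(call.chrom, call.pos).upper() != call.ref.upper():
            raise ValueError(
                f"reference mismatch at {call.chrom}:{call.pos + 1}: "
                f"expected {call.ref}"
            )
        if call.pos == 0 or call.pos >= len(seq) - 1:
            excluded += 1
            continue
        label = classify_substitution(
            call.ref.upper(), call.alt.upper(),
            seq[call.pos - 1].upper(), seq[call.pos + 1].upper(),
        )
        counts[label] += 1
    if excluded:
        warnings.warn(f"excluded {excluded} contig-edge SSM(s) without flanks",
                      stacklevel=2)
    return counts


@dataclass
class ExposureVector:
    """Signature exposures on the mutation-count scale."""

    exposures: pd.Series  # all signatures, >= 0
    reported: pd.Series  # subset with exposure/total >= threshold
    residual: float  # ||S e - m||
    threshold: float = 0.05
    catalogue_total: float = field(default=0.0)


def check_signature_matrix(signatures: pd.DataFrame, atol: float = 1e-6) -> None:
    """Reject matrices whose columns are not probability vectors."""
    if signatures.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 rows, got {signatures.shape[0]}")
    arr = signatures.to_numpy(dtype=float)
    if (arr < -atol).any():
        raise ValueError("signature matrix has negative entries")
    sums = arr.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError(f"signature columns must each sum to 1 (got {sums})")


def fit_exposures(
    catalogue: pd.Series,
    signatures: pd.DataFrame,
    threshold: float = 0.05,
) -> ExposureVector:
    """Non-negative least-squares exposures of known signatures.

    ``catalogue`` is a 96-vector of counts (any consistent bin order
    shared with ``signatures``' rows); the reporting threshold is applied
    as exposure / catalogue-total.
    """
    check_signature_matrix(signatures)
    if len(catalogue) != 96:
        raise ValueError("catalogue must have 96 bins")
    if not catalogue.index.equals(signatures.index):
        signatures = signatures.reindex(catalogue.index)
        if signatures.isna().any().any():
            raise ValueError("signature rows do not match catalogue bins")
    m = catalogue.to_numpy(dtype=float)
    S = signatures.to_numpy(dtype=float)
    e, resid = nnls(S, m)
    exposures = pd.Series(e, index=signatures.columns)
    total = float(m.sum())
    if total > 0:
        reported = exposures[exposures / total >= threshold]
    else:
        reported = exposures.iloc[0:0]
    return ExposureVector(
        exposures=exposures, reported=reported, residual=float(resid),
        threshold=threshold, catalogue_total=total,
    )


def read_signature_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a COSMIC-style 96 x K TSV (first column = bin label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df.reindex(list(SBS96_LABELS))


def write_signature_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="type")


def write_catalogue(catalogue: pd.Series, path: str | os.PathLike) -> None:
    catalogue.rename("count").to_csv(path, sep="\t", index_label="type")


def read_catalogue(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["count"].reindex(list(SBS96_LABELS)).fillna(0).astype(int)


def random_signatures(k: int, seed: int = 0, concentration: float = 0.5) -> pd.DataFrame:
    """Synthetic signature matrix (Dirichlet columns) for simulations."""
    rng = np.random.default_rng(seed)
    cols = {
        f"SBS_syn{i + 1}": rng.dirichlet(np.full(96, concentration))
        for i in range(k)
    }
    return pd.DataFrame(cols, index=list(SBS96_LABELS))


def sample_catalogue(
    signatures: pd.DataFrame, exposures: np.ndarray, seed: int = 0
) -> pd.Series:
    """Poisson-sample a catalogue from signature mixture intensities."""
    rng = np.random.default_rng(seed)
    mean = signatures.to_numpy(dtype=float) @ np.asarray(exposures, dtype=float)
    return pd.Series(rng.poisson(mean), index=signatures.index)
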