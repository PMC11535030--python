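"""Reference genomes and phased SNP sets.

Sequences are plain Python strings over ``ACGTN``; coordinates are 0-based,
half-open everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """An ordered collection of named chromosome sequences."""

    sequences: dict[str, str]

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class VariantSet:
    """Phased SNPs for a single haplotype, reference-stranded.

    ``snps`` maps chromosome name to a pair of parallel arrays:
    0-based positions (sorted, unique) and single-character alternate bases.
    Alternate bases always differ from the reference base at that position.
    """

    snps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def count(self) -> int:
        return sum(len(pos) for pos, _ in self.snps.values())

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self.snps:
            return np.empty(0, dtype=np.int64)
        return self.snps[chrom][0]

    def apply(self, chrom: str, seq: str) -> str:
        """Substitute this haplotype's alternate alleles into ``seq``.

        ``seq`` must be the full reference sequence of ``chrom``; SNPs whose
        position falls outside the sequence are ignored.
        """
        if chrom not in self.snps:
            return seq
        pos, alt = self.snps[chrom]
        buf = bytearray(seq, "ascii")
        for p, a in zip(pos.tolist(), alt.tolist()):
            if 0 <= p < len(buf):
                buf[p] = ord(a)
        return buf.decode("ascii")
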