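"""SV contigs: oriented reference segments, CSCN encoding and the ref() mapping.

A *contig* is an assembled derivative-chromosome sequence written as an
ordered list of oriented reference segments joined at SV breakpoints, with a
haplotype label and an integer copy number ``mu``.  Its sequence is realized
by substituting the haplotype's phased SNPs into the reference (in reference
orientation), slicing each segment and reverse-complementing the ``-`` ones.

CSCN (contig-specific copy number) encoding is one-hot base encoding scaled
by ``mu``: column ``j`` holds ``mu`` in the row of base ``j`` (row order
A, C, G, T) and zero elsewhere; ambiguous bases give all-zero columns.

The ``ref()`` projection maps a contig bin pair onto the reference bin pair
of maximum base overlap — for example a 40-kb contig bin containing 30 kb of
one reference bin and 10 kb of another maps to the first — or to nothing when
a bin has no reference overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ReferenceGenome, VariantSet, reverse_complement
from .hic import Binning

_ROW = np.full(256, -1, dtype=np.int8)
for _k, _b in enumerate("ACGT"):
    _ROW[ord(_b)] = _k
    _ROW[ord(_b.lower())] = _k


@dataclass(frozen=True)
class Segment:
    """Oriented reference interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    orientation: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed segment [{self.start}, {self.end})")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    """Ordered, oriented reference segments with haplotype id and copy number."""

    id: str
    segments: list[Segment]
    haplotype: int = 1
    mu: int = 1

    def __post_init__(self):
        if self.mu < 1:
            raise ValueError("contig copy number mu must be >= 1")
        if self.haplotype not in (1, 2):
            raise ValueError("haplotype must be 1 or 2")
        if not self.segments:
            raise ValueError("contig needs at least one segment")

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)

    def junctions(self) -> list[int]:
        """Contig base offsets of segment joins (the SV breakpoints)."""
        out, off = [], 0
        for seg in self.segments[:-1]:
            off += len(seg)
            out.append(off)
        return out

    def junction_bins(self, resolution: int) -> list[int]:
        """Bin boundary indices crossed by segment joins at ``resolution``."""
        return sorted({-(-j // resolution) for j in self.junctions()})

    def flipped(self) -> "Contig":
        segs = [
            Segment(s.chrom, s.start, s.end, "+" if s.orientation == "-" else "-")
            for s in reversed(self.segments)
        ]
        return Contig(self.id + "_flip", segs, self.haplotype, self.mu)


def contig_sequence(
    contig: Contig, ref: ReferenceGenome, variants: VariantSet | None = None
) -> str:
    """Realize the DNA sequence of a contig.

    Haplotype SNPs are substituted in reference orientation first, then each
    segment is sliced and ``-`` segments contribute their reverse complement,
    concatenated in segment order.
    """
    edited: dict[str, str] = {}
    parts: list[str] = []
    for seg in contig.segments:
        if seg.chrom not in ref:
            raise KeyError(f"segment chromosome {seg.chrom!r} not in reference")
        if seg.end > len(ref[seg.chrom]):
            raise ValueError(f"segment {seg} outside chromosome bounds")
        if seg.chrom not in edited:
            chrom_seq = ref[seg.chrom]
            if variants is not None:
                chrom_seq = variants.apply(seg.chrom, chrom_seq)
            edited[seg.chrom] = chrom_seq
        piece = edited[seg.chrom][seg.start : seg.end]
        if seg.orientation == "-":
            piece = reverse_complement(piece)
        parts.append(piece)
    return "".join(parts)


def encode_cscn(seq: str, mu: int = 1) -> np.ndarray:
    """CSCN-encode a sequence: a 4 x len(seq) integer matrix.

    ``h[row(base), j] = mu`` and all other rows are zero; bases outside
    A/C/G/T give all-zero columns.  With ``mu = 1`` this is one-hot encoding.
    """
    if mu < 1:
        raise ValueError("mu must be >= 1")
    codes = _ROW[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    h = np.zeros((4, len(seq)), dtype=np.int32)
    valid = codes >= 0
    h[codes[valid], np.nonzero(valid)[0]] = mu
    return h


@dataclass
class BinMap:
    """Maximum-overlap mapping of contig bins to global reference bins.

    ``entries[b]`` is the global reference bin contributing the most bases to
    contig bin ``b`` (ties break to the lower reference bin index), or -1 for
    a bin with no reference overlap.
    """

    resolution: int
    entries: np.ndarray
    binning: Binning

    def __len__(self) -> int:
        return len(self.entries)


def build_bin_map(contig: Contig, resolution: int, binning: Binning) -> BinMap:
    """Assign each contig bin to the reference bin of maximum base overlap.

    Only full bins are mapped: a trailing partial bin of the contig is
    dropped, mirroring how the contact matrices are binned.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution != binning.resolution:
        raise ValueError("bin map resolution must match the reference binning")
    length = len(contig)
    n_bins = length // resolution
    entries = np.full(n_bins, -1, dtype=np.int64)

    # segment spans in contig coordinates
    spans = []
    off = 0
    for seg in contig.segments:
        spans.append((off, off + len(seg), seg))
        off += len(seg)

    for b in range(n_bins):
        lo, hi = b * resolution, (b + 1) * resolution
        overlap: dict[int, int] = {}
        for s_lo, s_hi, seg in spans:
            a, z = max(lo, s_lo), min(hi, s_hi)
            if a >= z:
                continue
            # reference interval of this contig slice
            if seg.orientation == "+":
                r_lo = seg.start + (a - s_lo)
                r_hi = seg.start + (z - s_lo)
            else:
                r_hi = seg.end - (a - s_lo)
                r_lo = seg.end - (z - s_lo)
            first = r_lo // resolution
            last = (r_hi - 1) // resolution
            for rb in range(first, last + 1):
                cov = min(r_hi, (rb + 1) * resolution) - max(r_lo, rb * resolution)
                g = binning.offset(seg.chrom) + rb
                overlap[g] = overlap.get(g, 0) + cov
        if overlap:
            best = max(overlap.items(), key=lambda kv: (kv[1], -kv[0]))
            entries[b] = best[0]
    return BinMap(resolution, entries, binning)


def ref_project(
    i: int, j: int, value: float, bin_map: BinMap
) -> tuple[int, int, float] | None:
    """Project a contig bin pair onto reference bins, or None if unmapped.

    The result is canonicalized so the smaller global reference bin comes
    first; distinct contig pairs may project to the same reference pair (e.g.
    across a duplication) and are summed downstream.
    """
    if not (0 <= i < len(bin_map) and 0 <= j < len(bin_map)):
        return None
    x, y = bin_map.entries[i], bin_map.entries[j]
    if x < 0 or y < 0:
        return None
    if x > y:
        x, y = y, x
    return int(x), int(y), value
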