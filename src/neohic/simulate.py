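"""Synthetic diploid genomes, SV contigs and ground-truth Hi-C.

The generator produces everything the prediction pipeline consumes: a random
reference genome, two phased SNP sets, SV contigs of the canonical classes
(DEL, DUP, INV, TRA, COMPLEX) and raw contact matrices with known
statistical structure, so that every downstream stage can be exercised and
parameter recovery can be measured against a known truth.

Contact counts follow a Poisson distance-decay + TAD-block model: for contig
bins ``i != j``,

    lambda(i, j) = mu * depth * |i - j|**(-decay_alpha)
                   * tad_enrichment**[i, j in the same TAD block]

and observed counts are Poisson(lambda), sampled on the upper triangle and
mirrored.  Self-interaction bins get ``10 * mu * depth``, mimicking the high
self-ligation diagonal of raw Hi-C that the pole extraction excludes.

TAD structure is tied to sequence: the reference generator plants a fixed
boundary motif (a 12-bp G run, standing in for a CTCF-site proxy) at random
positions with mean spacing ``tad_mean_size``, and the TAD blocks of *any*
contig are the motif occurrences found in that contig's own realized
sequence, on either strand.  Rearrangements therefore reshape domains in
contig coordinates — duplications and translocations create junction-spanning
"neo" blocks — and, crucially, contact structure is a learnable function of
the input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contigs import Contig, Segment, build_bin_map
from .genome import ReferenceGenome, VariantSet
from .hic import Binning, ContactMatrix

BOUNDARY_MOTIF = "G" * 12

_SV_KINDS = ("DEL", "DUP", "INV", "TRA", "COMPLEX")


@dataclass(frozen=True)
class SV:
    """A structural variant on one haplotype.

    DEL/DUP/INV/COMPLEX act on ``[start, end)`` of ``chrom``; a reciprocal TRA
    joins ``chrom`` at ``start`` with ``chrom2`` at ``pos2``.
    """

    kind: str
    haplotype: int
    chrom: str
    start: int
    end: int = 0
    chrom2: str | None = None
    pos2: int = 0

    def __post_init__(self):
        if self.kind not in _SV_KINDS:
            raise ValueError(f"unknown SV class {self.kind!r}")
        if self.kind == "TRA":
            if self.chrom2 is None:
                raise ValueError("TRA needs a partner chromosome")
        elif not (0 <= self.start < self.end):
            raise ValueError("SV needs 0 <= start < end")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and Hi-C generator.

    Defaults describe the desk-scale diploid study: a 4-Mb genome split over
    two chromosomes at 4-kb matrix resolution, SNP heterozygosity 1e-3/bp,
    unit distance-decay exponent, 60-kb mean TAD size with 4-fold
    within-domain contact enrichment, and 100 expected reads per bin pair at
    one-bin distance.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    resolution: int = 4_000
    snp_rate: float = 1e-3
    sv_spec: list[SV] = field(default_factory=list)
    decay_alpha: float = 1.0
    tad_mean_size: int = 60_000
    tad_enrichment: float = 4.0
    depth: float = 100.0
    boundary_motif: str = BOUNDARY_MOTIF

    def __post_init__(self):
        if self.chrom_length <= 0 or self.n_chrom <= 0:
            raise ValueError("chromosome count and length must be positive")
        if not (0.0 <= self.snp_rate <= 1.0):
            raise ValueError("snp_rate must be a probability")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be positive")
        if self.tad_enrichment < 1:
            raise ValueError("tad_enrichment must be >= 1")
        for sv in self.sv_spec:
            if sv.end - sv.start >= self.chrom_length:
                raise ValueError("SV size must be smaller than the chromosome")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent seeded stream, e.g. ``cfg.rng(3, k)`` for contig k."""
        return np.random.default_rng([self.seed, *stream])


# ---------------------------------------------------------------------------
# genome and haplotypes

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_reference(cfg: SimConfig) -> ReferenceGenome:
    """Random reference genome with planted TAD-boundary motifs.

    Deterministic for a fixed seed.  Boundary motif positions are drawn per
    chromosome with exponential spacing of mean ``tad_mean_size`` (at least
    three bins apart, so domains stay callable).
    """
    rng = cfg.rng(0)
    motif = cfg.boundary_motif
    min_gap = max(3 * cfg.resolution, 4 * len(motif))
    seqs: dict[str, str] = {}
    for c in range(cfg.n_chrom):
        codes = rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8)
        buf = bytearray(_BASE_LUT[codes].tobytes())
        pos = 0
        while True:
            gap = rng.exponential(cfg.tad_mean_size)
            pos += int(max(gap, min_gap))
            if pos + len(motif) >= cfg.chrom_length:
                break
            buf[pos : pos + len(motif)] = motif.encode("ascii")
        seqs[f"chr{c + 1}"] = buf.decode("ascii")
    return ReferenceGenome(seqs)


def generate_haplotypes(ref: ReferenceGenome, cfg: SimConfig) -> tuple[VariantSet, VariantSet]:
    """Two phased SNP sets; per-haplotype SNP counts are Binomial(L, snp_rate)."""
    if not (0.0 <= cfg.snp_rate <= 1.0):
        raise ValueError("snp_rate must be in [0, 1]")
    out = []
    for hap in (1, 2):
        rng = cfg.rng(hap)
        snps = {}
        for chrom, seq in ref.sequences.items():
            hit = np.nonzero(rng.random(len(seq)) < cfg.snp_rate)[0]
            if len(hit) == 0:
                continue
            ref_codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[hit]
            ref_idx = np.searchsorted(_BASE_LUT, ref_codes)  # A<C<G<T is sorted
            alt_idx = (ref_idx + rng.integers(1, 4, len(hit))) % 4
            alt = np.array([chr(b) for b in _BASE_LUT[alt_idx]], dtype="<U1")
            snps[chrom] = (hit.astype(np.int64), alt)
        out.append(VariantSet(snps))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# contigs from SV specs


def sv_breakpoints(sv_spec: list[SV]) -> dict[str, list[int]]:
    """Reference breakpoint positions per chromosome, over both haplotypes."""
    bps: dict[str, set[int]] = {}
    for sv in sv_spec:
        if sv.kind == "TRA":
            bps.setdefault(sv.chrom, set()).add(sv.start)
            bps.setdefault(sv.chrom2, set()).add(sv.pos2)
        elif sv.kind == "COMPLEX":
            third = (sv.end - sv.start) // 3
            pts = {sv.start, sv.start + third, sv.start + 2 * third, sv.end}
            bps.setdefault(sv.chrom, set()).update(pts)
        else:
            bps.setdefault(sv.chrom, set()).update((sv.start, sv.end))
    return {c: sorted(v) for c, v in bps.items()}


def _linear_segments(chrom: str, length: int, svs: list[SV]) -> list[Segment]:
    """Segment pattern of one rearranged chromosome (no translocations)."""
    segs: list[Segment] = []
    pos = 0
    for sv in sorted(svs, key=lambda s: s.start):
        if sv.start < pos:
            raise ValueError("overlapping SVs on one haplotype are not supported")
        if sv.end > length:
            raise ValueError("SV coordinates outside chromosome")
        if sv.kind == "DEL":
            if sv.start > pos:
                segs.append(Segment(chrom, pos, sv.start))
        elif sv.kind == "DUP":
            segs.append(Segment(chrom, pos, sv.end))
            segs.append(Segment(chrom, sv.start, sv.end))
        elif sv.kind == "INV":
            if sv.start > pos:
                segs.append(Segment(chrom, pos, sv.start))
            segs.append(Segment(chrom, sv.start, sv.end, "-"))
        elif sv.kind == "COMPLEX":
            # clustered rearrangement of [start, end): thirds A, B, C become
            # A, C-, B, A (a duplication, an inversion and a reordering)
            third = (sv.end - sv.start) // 3
            a = Segment(chrom, sv.start, sv.start + third)
            b = Segment(chrom, sv.start + third, sv.start + 2 * third)
            c_inv = Segment(chrom, sv.start + 2 * third, sv.end, "-")
            if sv.start > pos:
                segs.append(Segment(chrom, pos, sv.start))
            segs.extend([a, c_inv, b, Segment(a.chrom, a.start, a.end)])
        else:
            raise ValueError(f"unsupported linear SV {sv.kind}")
        pos = sv.end
    if pos < length:
        segs.append(Segment(chrom, pos, length))
    return segs


def build_contigs(
    ref: ReferenceGenome,
    sv_spec: list[SV],
    copy_numbers: dict[str, int] | None = None,
) -> list[Contig]:
    """Derive haplotype contigs from an SV specification.

    Each haplotype contributes one contig per (derivative) chromosome;
    unrearranged chromosomes become single-segment contigs.  A chromosome
    involved in a reciprocal translocation cannot carry further SVs on that
    haplotype.  ``copy_numbers`` maps contig ids to integer copy number
    (default 1).
    """
    copy_numbers = copy_numbers or {}
    contigs: list[Contig] = []
    for hap in (1, 2):
        svs = [s for s in sv_spec if s.haplotype == hap]
        tras = [s for s in svs if s.kind == "TRA"]
        linear: dict[str, list[SV]] = {}
        for s in svs:
            if s.kind != "TRA":
                linear.setdefault(s.chrom, []).append(s)
        tra_chroms = set()
        for t in tras:
            tra_chroms.update((t.chrom, t.chrom2))
        if tra_chroms & set(linear):
            raise ValueError("a translocated chromosome cannot carry further SVs on that haplotype")
        done = set()
        for t in tras:
            la, lb = len(ref[t.chrom]), len(ref[t.chrom2])
            if not (0 < t.start < la and 0 < t.pos2 < lb):
                raise ValueError("TRA breakpoints outside chromosomes")
            der1 = f"h{hap}_t({t.chrom};{t.chrom2})"
            der2 = f"h{hap}_t({t.chrom2};{t.chrom})"
            contigs.append(
                Contig(der1, [Segment(t.chrom, 0, t.start), Segment(t.chrom2, t.pos2, lb)],
                       haplotype=hap, mu=copy_numbers.get(der1, 1))
            )
            contigs.append(
                Contig(der2, [Segment(t.chrom2, 0, t.pos2), Segment(t.chrom, t.start, la)],
                       haplotype=hap, mu=copy_numbers.get(der2, 1))
            )
            done.update((t.chrom, t.chrom2))
        for chrom in ref.chroms:
            if chrom in done:
                continue
            cid = f"h{hap}_{chrom}"
            segs = _linear_segments(chrom, len(ref[chrom]), linear.get(chrom, []))
            contigs.append(Contig(cid, segs, haplotype=hap, mu=copy_numbers.get(cid, 1)))
    return contigs


# ---------------------------------------------------------------------------
# Hi-C simulation


def tad_boundary_positions(seq: str, motif: str = BOUNDARY_MOTIF) -> list[int]:
    """Start positions of boundary-motif occurrences on either strand."""
    from .genome import reverse_complement

    hits = set()
    for pat in {motif, reverse_complement(motif)}:
        k = seq.find(pat)
        while k != -1:
            hits.add(k)
            k = seq.find(pat, k + 1)
    return sorted(hits)


def tad_blocks(seq: str, resolution: int, motif: str = BOUNDARY_MOTIF) -> np.ndarray:
    """Block label per bin, boundaries at the nearest bin edge to each motif."""
    n = len(seq) // resolution
    edges = sorted({int(round(p / resolution)) for p in tad_boundary_positions(seq, motif)})
    edges = [e for e in edges if 0 < e < n]
    return np.searchsorted(np.asarray(edges), np.arange(n), side="right")


def contact_intensity(
    n_bins: int,
    block: np.ndarray,
    mu: int,
    depth: float,
    decay_alpha: float,
    tad_enrichment: float,
) -> np.ndarray:
    """Expected count matrix of the Poisson distance-decay + block model."""
    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        lam = mu * depth * np.where(d > 0, d, 1.0) ** (-decay_alpha)
    same = block[:, None] == block[None, :]
    lam = lam * np.where(same, tad_enrichment, 1.0)
    np.fill_diagonal(lam, 10.0 * mu * depth)
    return lam


def simulate_contig_hic(
    contig: Contig,
    cfg: SimConfig,
    seq: str,
    rng: np.random.Generator | None = None,
) -> ContactMatrix:
    """Raw contig-space contact matrix sampled from the generative model.

    ``seq`` is the contig's realized sequence (SNPs applied); TAD blocks are
    read off its motif occurrences.  Counts are sampled on the upper triangle
    and mirrored, so the result is exactly symmetric.
    """
    n = len(seq) // cfg.resolution
    if n < 2:
        raise ValueError("contig must span at least 2 bins")
    rng = rng if rng is not None else cfg.rng(3)
    block = tad_blocks(seq, cfg.resolution, cfg.boundary_motif)
    lam = contact_intensity(n, block, contig.mu, cfg.depth, cfg.decay_alpha, cfg.tad_enrichment)
    iu = np.triu_indices(n)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu] = rng.poisson(lam[iu])
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(counts.astype(float), cfg.resolution, space="contig", name=contig.id)


def simulate_total_hic(
    contigs: list[Contig],
    cfg: SimConfig,
    ref: ReferenceGenome,
    haplotypes: tuple[VariantSet, VariantSet],
    return_parts: bool = False,
):
    """Total Hi-C in reference coordinates as the sum of projected contig Hi-C.

    Every contig is simulated independently (seeded per contig) and its upper
    triangle is pushed through the maximum-match bin map; counts landing on
    the same reference pair accumulate.  The grand total over the upper
    triangle is conserved exactly.
    """
    from .contigs import contig_sequence

    binning = Binning.from_lengths(ref.lengths, cfg.resolution)
    n = binning.n_bins
    upper = np.zeros((n, n))
    parts: dict[str, ContactMatrix] = {}
    maps = {}
    seqs = {}
    for k, contig in enumerate(contigs):
        variants = haplotypes[contig.haplotype - 1]
        seq = contig_sequence(contig, ref, variants)
        cm = simulate_contig_hic(contig, cfg, seq, rng=cfg.rng(3, k))
        bmap = build_bin_map(contig, cfg.resolution, binning)
        nb = len(bmap)
        iu = np.triu_indices(nb)
        vals = cm.matrix[: nb, : nb][iu]
        e = bmap.entries
        gi, gj = e[iu[0]], e[iu[1]]
        ok = (gi >= 0) & (gj >= 0) & (vals != 0)
        x = np.minimum(gi[ok], gj[ok])
        y = np.maximum(gi[ok], gj[ok])
        np.add.at(upper, (x, y), vals[ok])
        parts[contig.id] = cm
        maps[contig.id] = bmap
        seqs[contig.id] = seq
    total = np.triu(upper) + np.triu(upper, 1).T
    tm = ContactMatrix(total, cfg.resolution, space="reference", binning=binning)
    if return_parts:
        return tm, parts, maps, seqs
    return tm


# ---------------------------------------------------------------------------
# random SV genomes (round-trip / conservation checks)


def random_sv_spec(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n_sv: int = 2,
    sv_size: int = 40_000,
) -> list[SV]:
    """Draw a valid random SV specification (one SV class per draw)."""
    chroms = list(chrom_lengths)
    spec: list[SV] = []
    used: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for _ in range(n_sv):
        kind = _SV_KINDS[rng.integers(0, len(_SV_KINDS))]
        hap = int(rng.integers(1, 3))
        if kind == "TRA" and len(chroms) >= 2:
            c1, c2 = rng.choice(len(chroms), 2, replace=False)
            c1, c2 = chroms[c1], chroms[c2]
            if any(k == (hap, c) for k in used for c in (c1, c2)):
                continue
            p = int(rng.integers(sv_size, chrom_lengths[c1] - sv_size))
            q = int(rng.integers(sv_size, chrom_lengths[c2] - sv_size))
            spec.append(SV("TRA", hap, c1, p, chrom2=c2, pos2=q))
            used[(hap, c1)] = [(0, chrom_lengths[c1])]
            used[(hap, c2)] = [(0, chrom_lengths[c2])]
        elif kind != "TRA":
            chrom = chroms[rng.integers(0, len(chroms))]
            size = max(3 * 3, sv_size)
            lo = int(rng.integers(0, chrom_lengths[chrom] - size))
            iv = (lo, lo + size)
            taken = used.get((hap, chrom), [])
            if any(iv[0] < e and s < iv[1] for s, e in taken):
                continue
            spec.append(SV(kind, hap, chrom, iv[0], iv[1]))
            used.setdefault((hap, chrom), []).append(iv)
    return spec
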