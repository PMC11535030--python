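"""Contig-to-total Hi-C conversion and SV-window delineation.

Per-contig contact matrices (predicted or simulated) are projected through
their maximum-match bin maps and summed in reference coordinates — first into
the two haplotype matrices, then into the total.  A provenance ledger of
which contig pair contributed to which reference pair is retained; it is what
makes SV windows (contact signal that exists only because a rearrangement
juxtaposes two loci) identifiable, and what the overlapping-TAD counting
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contigs import BinMap
from .hic import Binning, ContactMatrix


@dataclass
class TotalAssembly:
    """Total and per-haplotype reference matrices plus contribution ledger."""

    total: ContactMatrix
    per_haplotype: dict[int, ContactMatrix]
    contributions: dict[tuple[int, int], list[tuple[str, tuple[int, int], float]]]

    def contributed_pairs(self, contig_id: str) -> set[tuple[int, int]]:
        return {
            pair
            for pair, entries in self.contributions.items()
            if any(cid == contig_id for cid, _, _ in entries)
        }


def merge_to_total(
    contig_matrices: dict[str, ContactMatrix | np.ndarray],
    bin_maps: dict[str, BinMap],
    haplotype_of: dict[str, int],
    binning: Binning,
) -> TotalAssembly:
    """Sum per-contig matrices into haplotype and total reference matrices.

    NaN entries (outside a predicted band) contribute nothing.  All inputs
    must share the binning resolution.  Merging is exact: the upper-triangle
    grand total equals the sum of mapped contig entries, and the haplotype
    matrices sum to the total.
    """
    n = binning.n_bins
    upper = np.zeros((n, n))
    upper_hap = {1: np.zeros((n, n)), 2: np.zeros((n, n))}
    ledger: dict[tuple[int, int], list[tuple[str, tuple[int, int], float]]] = {}

    for cid, cm in contig_matrices.items():
        mat = cm.matrix if isinstance(cm, ContactMatrix) else np.asarray(cm)
        if isinstance(cm, ContactMatrix) and cm.resolution != binning.resolution:
            raise ValueError(f"resolution mismatch for contig {cid}")
        bmap = bin_maps[cid]
        if bmap.resolution != binning.resolution:
            raise ValueError(f"bin map resolution mismatch for contig {cid}")
        hap = haplotype_of[cid]
        nb = min(len(bmap), mat.shape[0])
        iu = np.triu_indices(nb)
        vals = mat[:nb, :nb][iu]
        ok = ~np.isnan(vals) & (vals != 0)
        e = bmap.entries
        gi, gj = e[iu[0][ok]], e[iu[1][ok]]
        vv = vals[ok]
        mapped = (gi >= 0) & (gj >= 0)
        x = np.minimum(gi[mapped], gj[mapped])
        y = np.maximum(gi[mapped], gj[mapped])
        vv = vv[mapped]
        ci, cj = iu[0][ok][mapped], iu[1][ok][mapped]
        np.add.at(upper, (x, y), vv)
        np.add.at(upper_hap[hap], (x, y), vv)
        for a, b, i, j, v in zip(x.tolist(), y.tolist(), ci.tolist(), cj.tolist(), vv.tolist()):
            ledger.setdefault((a, b), []).append((cid, (i, j), v))

    def _sym(u):
        return np.triu(u) + np.triu(u, 1).T

    res = binning.resolution
    total = ContactMatrix(_sym(upper), res, space="reference", binning=binning)
    per_hap = {
        h: ContactMatrix(_sym(u), res, space="reference", binning=binning)
        for h, u in upper_hap.items()
    }
    return TotalAssembly(total, per_hap, ledger)


@dataclass
class SVWindows:
    """Reference bin pairs carrying SV-derived (novel) contact signal."""

    pairs: set[tuple[int, int]]
    by_contig: dict[str, set[tuple[int, int]]] = field(default_factory=dict)

    def outlines(self) -> list[tuple[str, int, int, int, int]]:
        """Rectangular (contig, x0, x1, y0, y1) outlines of each contig's pairs."""
        out = []
        for cid, pairs in self.by_contig.items():
            if not pairs:
                continue
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            out.append((cid, min(xs), max(xs) + 1, min(ys), max(ys) + 1))
        return out


def extract_sv_windows(
    assembly: TotalAssembly,
    junction_bins: dict[str, list[int]],
    binning: Binning,
) -> SVWindows:
    """Identify reference pairs whose signal is SV-derived.

    A contribution flags its reference pair when the contig bin pair straddles
    a segment junction (``i < t <= j``) *and* the reference relationship
    differs from the contig one — the bins land on different chromosomes or at
    a different reference distance than their contig distance.  Contacts that
    are merely copy-number-scaled at reference adjacency are not SV windows.
    Pairs folding onto the reference diagonal are dropped: self-interaction
    bins are excluded from contact modelling throughout (their raw signal is
    dominated by self-ligation), so they carry no comparable prediction.
    """
    chrom_of = {}
    off = 0
    for c, _ in binning.chrom_lengths:
        nb = binning.chrom_bins(c)
        for k in range(nb):
            chrom_of[off + k] = c
        off += nb

    pairs: set[tuple[int, int]] = set()
    by_contig: dict[str, set[tuple[int, int]]] = {}
    for (x, y), entries in assembly.contributions.items():
        if x == y:
            continue
        for cid, (i, j), _v in entries:
            ts = junction_bins.get(cid, [])
            if not any(i < t <= j for t in ts):
                continue
            if chrom_of[x] != chrom_of[y] or (y - x) != (j - i):
                pairs.add((x, y))
                by_contig.setdefault(cid, set()).add((x, y))
    return SVWindows(pairs, by_contig)
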