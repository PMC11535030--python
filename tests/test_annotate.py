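"""TAD calling, neo-TAD identification and enhancer-hijacking rules."""

import numpy as np
import pandas as pd
import pytest

from neohic.annotate import (
    NeoTAD,
    TAD,
    call_hijacking,
    call_tads,
    count_overlapping_tads,
    find_neo_tads,
    tad_footprint,
)
from neohic.contigs import BinMap, Contig, Segment, build_bin_map
from neohic.hic import Binning, ContactMatrix
from neohic.merge import SVWindows, merge_to_total
from neohic.normalize import ice_normalize


def _block_matrix(boundaries, n, enrichment=4.0, depth=100.0, alpha=1.0):
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx)).astype(float)
    lam = depth * np.where(d > 0, d, 1.0) ** (-alpha)
    block = np.searchsorted(np.asarray(boundaries), idx, side="right")
    lam = lam * np.where(block[:, None] == block[None, :], enrichment, 1.0)
    np.fill_diagonal(lam, 0.0)
    return lam


class TestCallTads:
    def test_three_planted_blocks_recovered(self):
        m = _block_matrix([10, 22], 30)
        norm = ice_normalize(m).normalized.matrix
        primary = [t for t in call_tads(norm) if t.level == 1]
        starts = sorted(t.start for t in primary)
        assert len(primary) == 3
        assert abs(starts[1] - 10) <= 1 and abs(starts[2] - 22) <= 1

    def test_uniform_matrix_single_domain(self):
        u = np.ones((20, 20))
        np.fill_diagonal(u, 0)
        tads = call_tads(u)
        assert [(t.level, t.start, t.end) for t in tads] == [(1, 0, 20)]

    def test_nesting_invariant(self, rng):
        m = _block_matrix([8, 15, 24], 32) + rng.uniform(0, 5, (32, 32))
        m = (m + m.T) / 2
        tads = call_tads(m)
        by_level = {lv: [t for t in tads if t.level == lv] for lv in (1, 2, 3)}
        for lv in (2, 3):
            for child in by_level[lv]:
                assert any(
                    parent.start <= child.start and child.end <= parent.end
                    for parent in by_level[lv - 1]
                )

    def test_minimum_domain_size(self):
        m = _block_matrix([5, 20], 28)
        tads = call_tads(m, min_size=3)
        assert all(len(t) >= 3 for t in tads)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            call_tads(np.ones((5, 5)))


class TestNeoTads:
    def _identity_setup(self):
        binning = Binning((("chr1", 300_000),), 10_000)
        c = Contig("c", [Segment("chr1", 0, 300_000)])
        return binning, build_bin_map(c, 10_000, binning)

    def test_identity_contig_yields_no_neo_tads(self):
        _, bmap = self._identity_setup()
        tads = [TAD("contig", 0, 10, 1), TAD("contig", 10, 30, 1)]
        ref = [TAD("reference", 0, 10, 1), TAD("reference", 10, 30, 1)]
        assert find_neo_tads(tads, ref, bmap, junction_bins=[]) == []

    def test_junction_crossing_tad_is_neo(self):
        _, bmap = self._identity_setup()
        tads = [TAD("contig", 5, 20, 1)]
        ref = [TAD("reference", 5, 20, 1)]
        neo = find_neo_tads(tads, ref, bmap, junction_bins=[12])
        assert len(neo) == 1 and neo[0].crosses_breakpoint

    def test_unreproduced_projection_is_neo(self):
        # a merged block that no reference TAD matches at 0.9 reciprocal overlap
        _, bmap = self._identity_setup()
        tads = [TAD("contig", 0, 20, 1)]
        ref = [TAD("reference", 0, 10, 1), TAD("reference", 10, 20, 1)]
        neo = find_neo_tads(tads, ref, bmap, junction_bins=[])
        assert len(neo) == 1 and not neo[0].crosses_breakpoint

    def test_planted_duplication_merge_is_flagged(self):
        # duplication junction fuses two blocks into one contig TAD
        binning = Binning((("chr1", 200_000),), 10_000)
        dup = Contig("dup", [
            Segment("chr1", 0, 120_000), Segment("chr1", 60_000, 120_000), Segment("chr1", 120_000, 200_000),
        ])
        bmap = build_bin_map(dup, 10_000, binning)
        t = dup.junction_bins(10_000)[0]
        contig_tads = [TAD("contig", t - 4, t + 4, 1)]
        ref_tads = [TAD("reference", 0, 20, 1)]
        neo = find_neo_tads(contig_tads, ref_tads, bmap, junction_bins=[t], contig_id="dup")
        assert len(neo) == 1


class TestOverlapCounting:
    def _assembly(self, rng):
        binning = Binning((("chr1", 200_000),), 10_000)
        dup = Contig("dup", [Segment("chr1", 0, 120_000), Segment("chr1", 60_000, 120_000)])
        plain = Contig("plain", [Segment("chr1", 0, 200_000)], haplotype=2)
        maps = {
            "dup": build_bin_map(dup, 10_000, binning),
            "plain": build_bin_map(plain, 10_000, binning),
        }
        mats = {}
        for cid, bm in maps.items():
            n = len(bm)
            m = rng.poisson(5, (n, n)).astype(float) + 1
            mats[cid] = ContactMatrix(np.triu(m) + np.triu(m, 1).T, 10_000, space="contig")
        asm = merge_to_total(mats, maps, {"dup": 1, "plain": 2}, binning)
        return asm, maps

    def test_single_contig_counts_zero(self, rng):
        binning = Binning((("chr1", 200_000),), 10_000)
        c = Contig("only", [Segment("chr1", 0, 200_000)])
        bmap = build_bin_map(c, 10_000, binning)
        n = len(bmap)
        m = np.ones((n, n))
        asm = merge_to_total({"only": m}, {"only": bmap}, {"only": 1}, binning)
        nt = NeoTAD(TAD("contig", 2, 8, 1), "only", True, frozenset(range(2, 8)))
        assert count_overlapping_tads(nt, asm, {"only": [nt.tad]}) == 0

    def test_shared_duplicated_region_counts(self, rng):
        asm, maps = self._assembly(rng)
        # the duplicated second copy occupies contig bins [12, 18) of "dup"
        neo = NeoTAD(TAD("contig", 12, 18, 1), "dup", True,
                     frozenset(int(g) for g in maps["dup"].entries[12:18]))
        others = {"plain": [TAD("contig", 6, 12, 1)]}  # reference bins 6..12
        count = count_overlapping_tads(neo, asm, others, overlap_cutoff=0.10)
        # oracle: footprints intersect in the duplicated reference region
        own = tad_footprint(neo.tad, "dup", asm)
        other = tad_footprint(others["plain"][0], "plain", asm)
        expected = int(len(own & other) > 0.10 * len(own))
        assert count == expected == 1

    def test_cutoff_one_requires_identical_footprint(self, rng):
        asm, maps = self._assembly(rng)
        neo = NeoTAD(TAD("contig", 12, 18, 1), "dup", True, frozenset())
        others = {"plain": [TAD("contig", 6, 12, 1)]}
        assert count_overlapping_tads(neo, asm, others, overlap_cutoff=1.0) == 0


class TestHijacking:
    def _setup(self):
        # chr1 occupies global bins 0..39, chr2 bins 40..79
        binning = Binning((("chr1", 400_000), ("chr2", 400_000)), 10_000)
        res = 10_000
        # neo-TAD projecting to chr1 bins 20..28 and chr2 global bins 50..58
        proj = frozenset(range(20, 28)) | frozenset(range(50, 58))
        neo = [NeoTAD(TAD("contig", 0, 16, 1), "der", True, proj)]
        ref_tads = [TAD("reference", 16, 30, 1), TAD("reference", 46, 59, 1)]
        genes = pd.DataFrame(
            [("chr1", 220_000, 230_000, "ONC")], columns=["chrom", "start", "end", "name"]
        )
        enhancers = pd.DataFrame(
            [
                ("chr2", 120_000, 130_000, "SE", "SE1"),   # global bin 52
                ("chr1", 250_000, 260_000, "TE", "TE1"),   # same reference TAD as ONC
            ],
            columns=["chrom", "start", "end", "class", "name"],
        )
        pairs = {(22, 52)}
        svw = SVWindows(pairs, {"der": pairs})
        mat = np.zeros((binning.n_bins, binning.n_bins))
        mat[22, 52] = mat[52, 22] = 7.0
        pred = ContactMatrix(mat, res, binning=binning)
        return binning, neo, ref_tads, genes, enhancers, svw, pred

    def test_translocated_se_event_called(self):
        binning, neo, ref_tads, genes, enhancers, svw, pred = self._setup()
        events = call_hijacking(neo, ref_tads, genes, enhancers, svw, pred, binning)
        assert len(events) == 1
        ev = events[0]
        assert ev.gene == "ONC" and ev.enhancer_class == "SE"

    def test_same_reference_tad_pair_suppressed(self):
        binning, neo, ref_tads, genes, enhancers, svw, pred = self._setup()
        # TE1 sits in ONC's reference TAD; even with contact it must not fire
        svw.pairs.add((22, 25))
        pred.matrix[22, 25] = pred.matrix[25, 22] = 9.0
        events = call_hijacking(neo, ref_tads, genes, enhancers, svw, pred, binning)
        assert all(e.enhancer != "TE1" for e in events)

    def test_offset_expansion_suppresses_near_boundary_enhancer(self):
        binning, neo, ref_tads, genes, enhancers, svw, pred = self._setup()
        # enhancer 2 bins outside the gene's reference TAD: suppressed at 40 kb
        enhancers2 = pd.DataFrame(
            [("chr1", 140_000, 150_000, "SE", "NEAR")],
            columns=["chrom", "start", "end", "class", "name"],
        )
        neo2 = [NeoTAD(TAD("contig", 0, 16, 1), "der", True,
                       frozenset(range(14, 28)))]
        svw.pairs.add((14, 22))
        pred.matrix[14, 22] = pred.matrix[22, 14] = 3.0
        with_offset = call_hijacking(neo2, ref_tads, genes, enhancers2, svw, pred, binning, offset=40_000)
        without = call_hijacking(neo2, ref_tads, genes, enhancers2, svw, pred, binning, offset=0)
        assert with_offset == []
        assert len(without) == 1

    def test_offset_monotonicity(self):
        binning, neo, ref_tads, genes, enhancers, svw, pred = self._setup()
        counts = []
        for off in (0, 20_000, 40_000, 100_000):
            counts.append(len(call_hijacking(neo, ref_tads, genes, enhancers, svw, pred, binning, offset=off)))
        assert counts == sorted(counts, reverse=True)

    def test_no_sv_window_no_event(self):
        binning, neo, ref_tads, genes, enhancers, _svw, pred = self._setup()
        empty = SVWindows(set(), {})
        assert call_hijacking(neo, ref_tads, genes, enhancers, empty, pred, binning) == []

    def test_events_subset_of_neo_projection_pairs(self):
        binning, neo, ref_tads, genes, enhancers, svw, pred = self._setup()
        events = call_hijacking(neo, ref_tads, genes, enhancers, svw, pred, binning)
        for ev in events:
            gbin = binning.bin_index(ev.gene_interval[0], (ev.gene_interval[1] + ev.gene_interval[2]) // 2)
            ebin = binning.bin_index(ev.enhancer_interval[0], (ev.enhancer_interval[1] + ev.enhancer_interval[2]) // 2)
            assert gbin in ev.neo_tad.ref_bins and ebin in ev.neo_tad.ref_bins
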