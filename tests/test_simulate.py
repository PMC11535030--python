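"""Generator: determinism, variant statistics, SV segment patterns, Hi-C model."""

import numpy as np
import pytest

from neohic.contigs import contig_sequence
from neohic.genome import reverse_complement
from neohic.simulate import (
    SV,
    SimConfig,
    build_contigs,
    contact_intensity,
    generate_haplotypes,
    generate_reference,
    simulate_contig_hic,
    simulate_total_hic,
    sv_breakpoints,
    tad_blocks,
)


class TestReference:
    def test_deterministic_by_seed(self):
        cfg = SimConfig(seed=1, n_chrom=1, chrom_length=100_000, resolution=5_000)
        a = generate_reference(cfg)
        b = generate_reference(cfg)
        assert a.sequences == b.sequences
        assert len(a["chr1"]) == 100_000

    def test_seed_sensitivity(self):
        mk = lambda s: generate_reference(
            SimConfig(seed=s, n_chrom=1, chrom_length=50_000, resolution=5_000)
        )
        assert mk(1).sequences != mk(2).sequences

    def test_base_frequencies_binomial(self):
        # each base ~ Binomial(L, 1/4); allow 3 sigma plus the planted motifs
        L = 4_000_000
        cfg = SimConfig(seed=2, n_chrom=1, chrom_length=L, resolution=10_000,
                        tad_mean_size=400_000)
        seq = generate_reference(cfg)["chr1"]
        sigma = np.sqrt(L * 0.25 * 0.75)
        motif_allowance = (L // cfg.tad_mean_size + 2) * len(cfg.boundary_motif)
        for base in "ACGT":
            assert abs(seq.count(base) - L / 4) < 3 * sigma + motif_allowance

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, chrom_length=0)


class TestHaplotypes:
    def test_zero_rate_empty(self, small_ref, small_cfg):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length=50_000, resolution=5_000, snp_rate=0.0)
        ref = generate_reference(cfg)
        h1, h2 = generate_haplotypes(ref, cfg)
        assert h1.count() == 0 and h2.count() == 0

    def test_count_binomial(self):
        cfg = SimConfig(seed=6, n_chrom=1, chrom_length=1_000_000, resolution=10_000, snp_rate=1e-3)
        ref = generate_reference(cfg)
        h1, _ = generate_haplotypes(ref, cfg)
        sigma = np.sqrt(1_000_000 * 1e-3)
        assert abs(h1.count() - 1000) < 3 * sigma

    def test_alt_differs_from_ref(self, small_ref, small_haps):
        for vs in small_haps:
            for chrom, (pos, alt) in vs.snps.items():
                seq = small_ref[chrom]
                for p, a in zip(pos, alt):
                    assert seq[p] != a

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, snp_rate=1.5)


class TestContigPatterns:
    def test_tandem_dup_segments(self, small_ref):
        L = len(small_ref["chr1"])
        svs = [SV("DUP", 1, "chr1", 50_000, 80_000)]
        contigs = {c.id: c for c in build_contigs(small_ref, svs)}
        segs = contigs["h1_chr1"].segments
        assert [(s.start, s.end, s.orientation) for s in segs] == [
            (0, 80_000, "+"), (50_000, 80_000, "+"), (80_000, L, "+"),
        ]

    def test_inversion_orientation(self, small_ref):
        svs = [SV("INV", 2, "chr1", 50_000, 80_000)]
        contigs = {c.id: c for c in build_contigs(small_ref, svs)}
        assert [s.orientation for s in contigs["h2_chr1"].segments] == ["+", "-", "+"]

    def test_deletion_gap(self, small_ref):
        L = len(small_ref["chr1"])
        svs = [SV("DEL", 1, "chr1", 50_000, 80_000)]
        contigs = {c.id: c for c in build_contigs(small_ref, svs)}
        assert len(contigs["h1_chr1"]) == L - 30_000

    def test_reciprocal_tra_arm_accounting(self, small_ref):
        # every base of chr1 and chr2 appears exactly once across both derivatives
        svs = [SV("TRA", 1, "chr1", 120_000, chrom2="chr2", pos2=200_000)]
        contigs = [c for c in build_contigs(small_ref, svs) if c.haplotype == 1 and "t(" in c.id]
        coverage = {c: np.zeros(len(small_ref[c]), dtype=int) for c in ("chr1", "chr2")}
        for contig in contigs:
            for seg in contig.segments:
                coverage[seg.chrom][seg.start : seg.end] += 1
        for arr in coverage.values():
            assert (arr == 1).all()

    def test_sv_outside_chromosome_rejected(self, small_ref):
        with pytest.raises(ValueError):
            build_contigs(small_ref, [SV("DEL", 1, "chr1", 250_000, 400_000)])

    def test_breakpoint_table(self):
        bps = sv_breakpoints([SV("DUP", 1, "chr1", 10, 20), SV("TRA", 2, "chr1", 50, chrom2="chr2", pos2=7)])
        assert bps == {"chr1": [10, 20, 50], "chr2": [7]}


class TestContigHiC:
    def _contig(self, ref, cfg):
        contigs = build_contigs(ref, [])
        c = contigs[0]
        seq = contig_sequence(c, ref, None)
        return c, seq

    def test_zero_depth_gives_zero_matrix(self, small_ref, small_cfg):
        cfg = SimConfig(seed=3, n_chrom=2, chrom_length=300_000, resolution=5_000, depth=0.0)
        c, seq = self._contig(small_ref, cfg)
        m = simulate_contig_hic(c, cfg, seq)
        assert not m.matrix.any()

    def test_symmetry(self, small_ref, small_cfg):
        c, seq = self._contig(small_ref, small_cfg)
        m = simulate_contig_hic(c, seq=seq, cfg=small_cfg)
        assert np.array_equal(m.matrix, m.matrix.T)
        assert (m.matrix >= 0).all() and np.array_equal(m.matrix, np.floor(m.matrix))

    def test_decay_exponent_recovery(self):
        # log-log regression of between-block mean counts on distance recovers
        # -decay_alpha within 0.1 on a 4-Mb chromosome at depth 100
        cfg = SimConfig(seed=11, n_chrom=1, chrom_length=4_000_000, resolution=10_000,
                        snp_rate=0.0, decay_alpha=1.0, depth=100.0, tad_mean_size=100_000)
        ref = generate_reference(cfg)
        contig = build_contigs(ref, [])[0]
        seq = contig_sequence(contig, ref, None)
        m = simulate_contig_hic(contig, cfg, seq)
        block = tad_blocks(seq, cfg.resolution, cfg.boundary_motif)
        n = m.n_bins
        xs, ys = [], []
        for d in range(1, 60):
            vals = np.diagonal(m.matrix, offset=d)
            cross = block[:-d] != block[d:]
            if cross.sum() < 30:
                continue
            mean = vals[cross].mean()
            if mean > 0:
                xs.append(np.log(d))
                ys.append(np.log(mean))
        slope = np.polyfit(xs, ys, 1)[0]
        assert abs(slope + cfg.decay_alpha) < 0.1

    def test_self_interaction_scaling(self, small_ref, small_cfg):
        c, seq = self._contig(small_ref, small_cfg)
        block = tad_blocks(seq, small_cfg.resolution)
        lam = contact_intensity(len(block), block, 1, small_cfg.depth,
                                small_cfg.decay_alpha, small_cfg.tad_enrichment)
        assert np.allclose(np.diag(lam), 10 * small_cfg.depth)


class TestTotalHiC:
    def test_identity_contig_total_equals_part(self):
        cfg = SimConfig(seed=9, n_chrom=1, chrom_length=100_000, resolution=5_000)
        ref = generate_reference(cfg)
        haps = generate_haplotypes(ref, cfg)
        contigs = [c for c in build_contigs(ref, []) if c.haplotype == 1]
        total, parts, _, _ = simulate_total_hic(contigs, cfg, ref, haps, return_parts=True)
        assert np.array_equal(total.matrix, parts["h1_chr1"].matrix)

    def test_conservation_exact(self, small_ref, small_cfg, small_haps):
        svs = [SV("DUP", 1, "chr1", 100_000, 150_000),
               SV("TRA", 2, "chr1", 200_000, chrom2="chr2", pos2=120_000)]
        contigs = build_contigs(small_ref, svs)
        total, parts, _, _ = simulate_total_hic(contigs, small_cfg, small_ref, small_haps, return_parts=True)
        assert total.upper_sum() == sum(p.upper_sum() for p in parts.values())

    def test_poisson_additivity_of_copies(self):
        # two mu=1 copies of a contig match one mu=2 contig in expectation
        base = dict(n_chrom=1, chrom_length=60_000, resolution=5_000, snp_rate=0.0)
        sums1, sums2 = [], []
        for seed in range(100):
            cfg = SimConfig(seed=seed, **base)
            ref = generate_reference(cfg)
            haps = generate_haplotypes(ref, cfg)
            c1 = [c for c in build_contigs(ref, []) if c.haplotype == 1][0]
            t1 = simulate_total_hic([c1, c1], cfg, ref, haps)
            c2 = [c for c in build_contigs(ref, [], {"h1_chr1": 2}) if c.haplotype == 1][0]
            t2 = simulate_total_hic([c2], cfg, ref, haps)
            sums1.append(t1.upper_sum())
            sums2.append(t2.upper_sum())
        m1, m2 = np.mean(sums1), np.mean(sums2)
        assert abs(m1 - m2) / m2 < 0.05
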