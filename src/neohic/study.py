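"""Desk-scale end-to-end parameter-recovery study.

This module wires the whole pipeline together on a simulated 4-Mb diploid
genome (two 2-Mb chromosomes, 4-kb resolution, sequencing depth 100): a
tandem duplication is planted on haplotype 1 of chr1 and a reciprocal
translocation t(chr1;chr2) on haplotype 2, SV-free 200-kb windows are split
80/10/10, the scaled-down predictor (104-kb windows, units divided by 10) is
trained on summed-haplotype raw totals, and recovery is measured as

* distance-stratified correlation on held-out test-1 windows,
* Pearson correlation on SV-window pairs (the novel contacts the SVs create),
* recovery of the duplication's junction-crossing neo-TAD, and
* recovery of the translocation's planted SE-hijacking event.

SV breakpoints and the planted gene/enhancer are placed in the interior of
TAD blocks (between boundary motifs), the way a positive control would be
constructed, so the expected outcome is unambiguous.  Problem sizes (window
stride, epoch count) are chosen so the full study runs in minutes on one
CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import TAD, call_hijacking, call_tads, find_neo_tads
from .contigs import Contig, build_bin_map, contig_sequence, encode_cscn
from .genome import ReferenceGenome, VariantSet
from .hic import Binning, ContactMatrix, WindowSplit, ZigzagPole, extract_pole, make_splits, pole_to_matrix
from .merge import extract_sv_windows, merge_to_total
from .metrics import cn_expression_fit, cooks_outliers, distance_stratified_correlation, window_pearson
from .predictor import (
    PredictorConfig,
    PredictorState,
    TrainHyper,
    TrainSample,
    build_predictor,
    predict_contig_matrix,
    train_total,
)
from .simulate import SV, SimConfig, build_contigs, generate_haplotypes, generate_reference, simulate_total_hic, sv_breakpoints, tad_boundary_positions


def _gap_midpoints(boundaries: list[int], length: int, min_width: int) -> list[int]:
    """Midpoints of inter-motif gaps at least ``min_width`` wide, sorted."""
    edges = [0] + list(boundaries) + [length]
    mids = [(a + b) // 2 for a, b in zip(edges[:-1], edges[1:]) if b - a >= min_width]
    if not mids:
        raise RuntimeError("no inter-motif gap wide enough for SV placement")
    return mids


@dataclass
class StudyGenome:
    cfg: SimConfig
    ref: ReferenceGenome
    haplotypes: tuple[VariantSet, VariantSet]
    svs: list[SV]
    contigs: list[Contig]
    binning: Binning
    total: ContactMatrix
    parts: dict[str, ContactMatrix]
    maps: dict
    seqs: dict[str, str]
    breakpoints: dict[str, list[int]]
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    dup: SV
    tra: SV

    @property
    def resolution(self) -> int:
        return self.cfg.resolution

    def hap_chrom_seq(self, hap: int, chrom: str) -> str:
        return self.haplotypes[hap - 1].apply(chrom, self.ref[chrom])

    def contig_by_id(self, cid: str) -> Contig:
        return next(c for c in self.contigs if c.id == cid)


def build_study_genome(seed: int, cfg: SimConfig | None = None) -> StudyGenome:
    """Simulate the diploid study genome with planted DUP, TRA and annotations."""
    cfg = cfg or SimConfig(seed=seed)
    ref = generate_reference(cfg)
    haps = generate_haplotypes(ref, cfg)
    L = cfg.chrom_length
    b1 = tad_boundary_positions(ref["chr1"], cfg.boundary_motif)
    b2 = tad_boundary_positions(ref["chr2"], cfg.boundary_motif)
    min_w = 50_000
    mids1 = _gap_midpoints(b1, L, min_w)
    mids2 = _gap_midpoints(b2, L, min_w)
    dup_s = min(mids1, key=lambda m: abs(m - int(0.40 * L)))
    later = [m for m in mids1 if m >= dup_s + 60_000]
    dup_e = later[0] if later else dup_s + 80_000
    tra_cands = [m for m in mids1 if m >= dup_e + 200_000 and m <= L - 100_000] or [mids1[-1]]
    tra_p = min(tra_cands, key=lambda m: abs(m - int(0.72 * L)))
    tra_q = min(
        [m for m in mids2 if 100_000 <= m <= L - 100_000] or [mids2[len(mids2) // 2]],
        key=lambda m: abs(m - int(0.30 * L)),
    )
    dup = SV("DUP", 1, "chr1", dup_s, dup_e)
    tra = SV("TRA", 2, "chr1", tra_p, chrom2="chr2", pos2=tra_q)
    svs = [dup, tra]
    contigs = build_contigs(ref, svs)
    total, parts, maps, seqs = simulate_total_hic(contigs, cfg, ref, haps, return_parts=True)
    binning = Binning.from_lengths(ref.lengths, cfg.resolution)

    genes = pd.DataFrame(
        [
            ("chr1", tra_p - 22_000, tra_p - 14_000, "GENE1"),
            ("chr2", int(0.80 * L), int(0.80 * L) + 8_000, "GENE2"),
        ],
        columns=["chrom", "start", "end", "name"],
    )
    enhancers = pd.DataFrame(
        [
            ("chr1", tra_p - 12_000, tra_p - 8_000, "TE"),   # shares GENE1's reference TAD
            ("chr2", tra_q + 14_000, tra_q + 22_000, "SE"),  # hijacked by the translocation
            ("chr2", int(0.85 * L), int(0.85 * L) + 6_000, "TE"),
        ],
        columns=["chrom", "start", "end", "class"],
    )
    enhancers["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(enhancers.chrom, enhancers.start, enhancers.end)]
    return StudyGenome(
        cfg, ref, haps, svs, contigs, binning, total, parts, maps, seqs,
        sv_breakpoints(svs), genes, enhancers, dup, tra,
    )


# ---------------------------------------------------------------------------
# training data


def make_training_samples(
    study: StudyGenome,
    windows: list[tuple[str, int, int]],
    window_bins: int,
    stride: int = 2,
    reverse_complement_augment: bool = False,
) -> list[TrainSample]:
    """Summed-haplotype training samples from SV-free reference windows.

    Inside SV-free windows the haplotype contigs coincide with the SNP-edited
    reference, so the sample is simply (hap1 crop, hap2 crop, observed total
    pole).  Pole windows are placed fully inside each split window.  With
    ``reverse_complement_augment`` each window is also emitted on the reverse
    strand with the mirrored pole, doubling the set.
    """
    from .hic import reverse_sample

    res = study.resolution
    samples = []
    hap_seq: dict[tuple[int, str], str] = {}
    for chrom, start, end in windows:
        for hap in (1, 2):
            if (hap, chrom) not in hap_seq:
                hap_seq[(hap, chrom)] = study.hap_chrom_seq(hap, chrom)
        b0, b1 = start // res, end // res
        off = study.binning.offset(chrom)
        for b in range(b0, b1 - window_bins + 1, stride):
            pole = extract_pole(study.total.matrix, off + b, window_bins)
            crops = tuple(
                hap_seq[(hap, chrom)][b * res : (b + window_bins) * res] for hap in (1, 2)
            )
            samples.append(TrainSample(crops, (1, 1), pole.values))
            if reverse_complement_augment:
                flipped = [reverse_sample(c, pole) for c in crops]
                samples.append(
                    TrainSample(
                        tuple(seq for seq, _ in flipped), (1, 1), flipped[0][1].values
                    )
                )
    return samples


def train_study_model(
    study: StudyGenome,
    split: WindowSplit,
    epochs: int = 10,
    stride: int = 2,
    seed: int = 0,
    pretrain_steps: int = 3000,
    reverse_complement_augment: bool = False,
) -> PredictorState:
    """Pretrain the convolution stack, transfer, then fit the contact model.

    Mirrors the full-scale protocol: the chromatin-feature stack is first
    trained on a sequence-feature task (here, boundary-motif occupancy of
    4-kb tiles, the synthetic world's only chromatin feature), its weights
    are transferred, and the whole network is then trained on summed-
    haplotype contact poles for at most ``epochs`` epochs (optionally
    reverse-complement augmented).
    """
    from .predictor import motif_occupancy_tiles, pretrain_conv_stack

    cfg = PredictorConfig.scaled_down()
    if cfg.resolution != study.resolution:
        raise ValueError("study and predictor resolutions disagree")
    pretrained = None
    if pretrain_steps:
        seqs = [study.hap_chrom_seq(h, c) for h in (1, 2) for c in study.ref.chroms]
        tiles = motif_occupancy_tiles(
            seqs, study.cfg.boundary_motif, n_tiles=2000, tile_bp=4_000,
            pool_factor=cfg.pool_factor, seed=seed,
        )
        pretrained = pretrain_conv_stack(cfg, tiles, steps=pretrain_steps, seed=seed)
    train = make_training_samples(
        study, split.train, cfg.window_bins, stride=stride,
        reverse_complement_augment=reverse_complement_augment,
    )
    val = make_training_samples(study, split.val, cfg.window_bins, stride=1)
    state = build_predictor(cfg, pretrained=pretrained, seed=seed)
    hyper = TrainHyper(max_epochs=epochs, seed=seed)
    return train_total(
        state, train, hyper, val_samples=val,
        train_conv_stack=pretrained is None,
    )


# ---------------------------------------------------------------------------
# evaluation: reference windows (test 1)


def predict_reference_windows(
    state: PredictorState,
    study: StudyGenome,
    windows: list[tuple[str, int, int]],
    strand_average: bool = True,
) -> np.ndarray:
    """Summed-haplotype predicted total over the given reference windows.

    Returns a global reference matrix, NaN outside the predicted band.
    """
    from .predictor import predict_pole

    cfg = state.cfg
    res = study.resolution
    nb = cfg.window_bins
    poles = []
    hap_seq: dict[tuple[int, str], str] = {}
    for chrom, start, end in windows:
        for hap in (1, 2):
            if (hap, chrom) not in hap_seq:
                hap_seq[(hap, chrom)] = study.hap_chrom_seq(hap, chrom)
        b0, b1 = start // res, end // res
        off = study.binning.offset(chrom)
        for b in range(b0, b1 - nb + 1):
            vals = np.zeros(cfg.pole_length)
            for hap in (1, 2):
                crop = hap_seq[(hap, chrom)][b * res : (b + nb) * res]
                vals += predict_pole(state, encode_cscn(crop, 1), strand_average=strand_average)
            poles.append(ZigzagPole(off + b, nb, vals))
    return pole_to_matrix(poles, study.binning.n_bins)


def evaluate_test1(state: PredictorState, study: StudyGenome, split: WindowSplit) -> float:
    pred = predict_reference_windows(state, study, split.test1)
    report = distance_stratified_correlation(pred, study.total.matrix, state.cfg.pole_length)
    return report.dsc


# ---------------------------------------------------------------------------
# evaluation: SV windows, neo-TADs, hijacking


def _junction_centers(junctions: list[int], n_bins: int, window_bins: int, pad: int = 6) -> list[int]:
    centers = set()
    for t in junctions:
        for w0 in range(t - window_bins - pad + 1, t + pad):
            if 0 <= w0 and w0 + window_bins <= n_bins:
                centers.add(w0)
    return sorted(centers)


def _region_centers(lo: int, hi: int, n_bins: int, window_bins: int) -> list[int]:
    return [w0 for w0 in range(lo - window_bins, hi + 1) if 0 <= w0 and w0 + window_bins <= n_bins]


@dataclass
class SVEvaluation:
    sv_window_pearson: float
    neo_tad_recovered: bool
    se_hijacking_recovered: bool
    n_sv_pairs: int
    hijack_events: list = field(default_factory=list)


def evaluate_sv_recovery(state: PredictorState, study: StudyGenome) -> SVEvaluation:
    """Predict around every SV junction, merge, and score SV-derived signal.

    TAD calling here runs on the raw predicted bands: model predictions carry
    no per-bin experimental bias, and balancing a narrow, block-dominated
    band absorbs domain signal into the bias estimate and distorts the map
    (ICE keeps its role for observed count matrices).
    """
    cfg = state.cfg
    res = study.resolution
    nb = cfg.window_bins
    dup_cid = "h1_chr1"
    der1_cid, der2_cid = "h2_t(chr1;chr2)", "h2_t(chr2;chr1)"

    dup_contig = study.contig_by_id(dup_cid)
    der1 = study.contig_by_id(der1_cid)
    der2 = study.contig_by_id(der2_cid)

    s_bin, e_bin = study.dup.start // res, study.dup.end // res

    centers = {
        dup_cid: _junction_centers(dup_contig.junction_bins(res), len(study.seqs[dup_cid]) // res, nb),
        der1_cid: sorted(
            set(_junction_centers(der1.junction_bins(res), len(study.seqs[der1_cid]) // res, nb))
            | set(_region_centers(s_bin, e_bin, len(study.seqs[der1_cid]) // res, nb))
        ),
        der2_cid: _junction_centers(der2.junction_bins(res), len(study.seqs[der2_cid]) // res, nb),
    }

    pred_mats = {}
    for cid, cs in centers.items():
        pred_mats[cid] = predict_contig_matrix(
            state, study.seqs[cid], mu=study.contig_by_id(cid).mu, centers=cs
        )

    hap_of = {cid: study.contig_by_id(cid).haplotype for cid in pred_mats}
    bmaps = {cid: study.maps[cid] for cid in pred_mats}
    assembly = merge_to_total(pred_mats, bmaps, hap_of, study.binning)

    junctions = {cid: study.contig_by_id(cid).junction_bins(res) for cid in pred_mats}
    svwin = extract_sv_windows(assembly, junctions, study.binning)
    pearson = window_pearson(assembly.total.matrix, study.total.matrix, svwin.pairs)

    # --- neo-TAD recovery at the duplication ------------------------------
    t1, t2 = dup_contig.junction_bins(res)
    lo_c, hi_c = t1 - 28, t2 + 28
    sub = pred_mats[dup_cid].matrix[lo_c:hi_c, lo_c:hi_c]
    contig_tads = [
        TAD("contig", tad.start + lo_c, tad.end + lo_c, tad.level)
        for tad in call_tads(ContactMatrix(sub, res, space="contig"))
    ]

    ref_chr1 = study.ref["chr1"]
    off1 = study.binning.offset("chr1")
    lo_r, hi_r = s_bin - 28, e_bin + 28
    ref_pred = predict_contig_matrix(
        state, ref_chr1, centers=_region_centers(lo_r, hi_r, len(ref_chr1) // res, nb)
    )
    sub_r = ref_pred.matrix[lo_r:hi_r, lo_r:hi_r]
    ref_tads_dup = [
        TAD("reference", tad.start + lo_r + off1, tad.end + lo_r + off1, tad.level)
        for tad in call_tads(ContactMatrix(sub_r, res, space="reference"))
    ]
    neo_dup = find_neo_tads(
        contig_tads, ref_tads_dup, study.maps[dup_cid], [t1, t2], contig_id=dup_cid
    )
    neo_recovered = any(
        nt.tad.start < t < nt.tad.end for nt in neo_dup for t in (t1, t2)
    )

    # --- SE hijacking at the translocation --------------------------------
    p_bin = study.tra.start // res
    q_bin = study.tra.pos2 // res
    tj = der1.junction_bins(res)[0]
    lo_j, hi_j = tj - 28, tj + 28
    sub_j = pred_mats[der1_cid].matrix[lo_j:hi_j, lo_j:hi_j]
    der1_tads = [
        TAD("contig", tad.start + lo_j, tad.end + lo_j, tad.level)
        for tad in call_tads(ContactMatrix(sub_j, res, space="contig"))
    ]

    # reference TADs around both translocation partners (for rule 1)
    off2 = study.binning.offset("chr2")
    lo_p, hi_p = p_bin - 40, p_bin + 10
    ref_pred_p = predict_contig_matrix(
        state, ref_chr1, centers=_region_centers(lo_p, hi_p, len(ref_chr1) // res, nb)
    )
    sub_p = ref_pred_p.matrix[lo_p:hi_p, lo_p:hi_p]
    ref_tads_p = [
        TAD("reference", t.start + lo_p + off1, t.end + lo_p + off1, t.level)
        for t in call_tads(ContactMatrix(sub_p, res, space="reference"))
    ]
    ref_chr2 = study.ref["chr2"]
    lo_q, hi_q = q_bin - 10, q_bin + 40
    ref_pred_q = predict_contig_matrix(
        state, ref_chr2, centers=_region_centers(lo_q, hi_q, len(ref_chr2) // res, nb)
    )
    sub_q = ref_pred_q.matrix[lo_q:hi_q, lo_q:hi_q]
    ref_tads_q = [
        TAD("reference", t.start + lo_q + off2, t.end + lo_q + off2, t.level)
        for t in call_tads(ContactMatrix(sub_q, res, space="reference"))
    ]
    ref_tads_all = ref_tads_dup + ref_tads_p + ref_tads_q

    neo_der1 = find_neo_tads(
        der1_tads, ref_tads_all, study.maps[der1_cid], [tj], contig_id=der1_cid
    )
    events = call_hijacking(
        neo_der1, ref_tads_all, study.genes, study.enhancers, svwin,
        assembly.total, study.binning, offset=40_000,
    )
    se_recovered = any(ev.gene == "GENE1" and ev.enhancer_class == "SE" for ev in events)

    return SVEvaluation(pearson, neo_recovered, se_recovered, len(svwin.pairs), events)


# ---------------------------------------------------------------------------
# the Cook's-distance overexpression stage on planted fixtures


def cooks_recovery(seed: int, n: int = 90, n_neo: int = 8, effect_sd: float = 5.0) -> dict:
    """Planted overexpression recovery with the Cook's distance rule.

    Simulates ``n`` samples with integer copy numbers, expression linear in
    CN with unit-variance noise, plants a ``effect_sd``-standard-deviation
    expression boost in ``n_neo`` neo-TAD samples, and measures the
    sensitivity of the D > 4/n & positive-residual rule.
    """
    rng = np.random.default_rng([seed, 7])
    cn = rng.integers(1, 7, n).astype(float)
    expr = 2.0 * cn + 1.0 + rng.normal(0.0, 1.0, n)
    neo_idx = rng.choice(n, n_neo, replace=False)
    expr[neo_idx] += effect_sd * 1.0
    mask = np.ones(n, dtype=bool)
    mask[neo_idx] = False
    fit = cn_expression_fit(expr, cn, mask)
    calls = cooks_outliers(fit, expr[neo_idx], cn[neo_idx], n=n, samples=neo_idx.tolist())
    sensitivity = float(np.mean([c.called for c in calls]))
    return {
        "fit": fit,
        "calls": calls,
        "sensitivity": sensitivity,
        "expr": expr,
        "cn": cn,
        "neo_idx": neo_idx,
    }


# ---------------------------------------------------------------------------
# full study


def run_recovery_study(seed: int, epochs: int = 10, stride: int = 2) -> dict:
    """Run the full desk-scale study and return its headline metrics."""
    study = build_study_genome(seed)
    split = make_splits(study.ref.lengths, study.breakpoints, window_bp=200_000, seed=seed)
    state = train_study_model(study, split, epochs=epochs, stride=stride, seed=seed)
    dsc = evaluate_test1(state, study, split)
    sv = evaluate_sv_recovery(state, study)
    return {
        "study": study,
        "split": split,
        "state": state,
        "test1_dsc": dsc,
        "sv_window_pearson": sv.sv_window_pearson,
        "neo_tad_recovered": sv.neo_tad_recovered,
        "se_hijacking_recovered": sv.se_hijacking_recovered,
        "n_sv_pairs": sv.n_sv_pairs,
    }
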