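"""File formats: FASTA, phased VCF, contig tables, contact files, BED/BEDPE.

Contact data travels either as single-resolution COOL files (the standard
HDF5 layout with ``chroms``, ``bins``, ``pixels`` and ``indexes`` groups) or
as a whitespace triplet text dialect:

    chrom  bin_i  bin_j  count                (intra-chromosomal)
    chrom1 bin_i  chrom2 bin_j  count         (inter-chromosomal)

with chromosome-local bin indices and the upper triangle sufficient.

The contig table is a TSV with one segment per row:
``contig_id  haplotype  mu  order  chrom  start  end  orientation``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contigs import Contig, Segment
from .genome import ReferenceGenome, VariantSet
from .hic import Binning, ContactMatrix

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_fasta(path) -> ReferenceGenome:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# phased VCF (one sample, GT 1|0 / 0|1 / 1|1)


def write_phased_vcf(path, ref: ReferenceGenome, hap1: VariantSet, hap2: VariantSet) -> None:
    """Write the two haplotype SNP sets as a single-sample phased VCF."""
    records: dict[tuple[str, int], list] = {}
    for hap_idx, vs in ((0, hap1), (1, hap2)):
        for chrom, (pos, alt) in vs.snps.items():
            for p, a in zip(pos.tolist(), alt.tolist()):
                key = (chrom, int(p))
                rec = records.setdefault(key, [ref[chrom][p], [None, None]])
                rec[1][hap_idx] = a
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in ref.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for chrom in ref.chroms:
            keys = sorted(k for k in records if k[0] == chrom)
            for key in keys:
                refbase, (a1, a2) = records[key]
                alts = []
                for a in (a1, a2):
                    if a is not None and a not in alts:
                        alts.append(a)
                gt1 = str(alts.index(a1) + 1) if a1 is not None else "0"
                gt2 = str(alts.index(a2) + 1) if a2 is not None else "0"
                fh.write(
                    f"{key[0]}\t{key[1] + 1}\t.\t{refbase}\t{','.join(alts)}\t.\t.\t.\tGT\t{gt1}|{gt2}\n"
                )


def read_phased_vcf(path) -> tuple[VariantSet, VariantSet]:
    """Read a single-sample phased VCF back into two haplotype SNP sets."""
    import pysam

    per_hap: list[dict[str, tuple[list, list]]] = [{}, {}]
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            alleles = rec.alleles
            gt = rec.samples[sample]["GT"]
            for hap_idx, allele_idx in enumerate(gt[:2]):
                if allele_idx in (None, 0):
                    continue
                alt = alleles[allele_idx]
                pos_list, alt_list = per_hap[hap_idx].setdefault(rec.chrom, ([], []))
                pos_list.append(rec.pos - 1)
                alt_list.append(alt)
    out = []
    for hap in per_hap:
        snps = {
            chrom: (np.asarray(p, dtype=np.int64), np.asarray(a, dtype="<U1"))
            for chrom, (p, a) in hap.items()
        }
        out.append(VariantSet(snps))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# contig tables


def write_contigs(path, contigs: list[Contig]) -> None:
    rows = []
    for c in contigs:
        for order, seg in enumerate(c.segments):
            rows.append((c.id, c.haplotype, c.mu, order, seg.chrom, seg.start, seg.end, seg.orientation))
    pd.DataFrame(
        rows,
        columns=["contig_id", "haplotype", "mu", "order", "chrom", "start", "end", "orientation"],
    ).to_csv(path, sep="\t", index=False)


def read_contigs(path) -> list[Contig]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    contigs = []
    for cid, grp in df.groupby("contig_id", sort=False):
        grp = grp.sort_values("order")
        segs = [
            Segment(r.chrom, int(r.start), int(r.end), str(r.orientation))
            for r in grp.itertuples()
        ]
        contigs.append(
            Contig(str(cid), segs, haplotype=int(grp.haplotype.iloc[0]), mu=int(grp.mu.iloc[0]))
        )
    return contigs


# ---------------------------------------------------------------------------
# triplet text contacts


def write_triplet(path, m: ContactMatrix) -> None:
    """Write the upper triangle of a contact matrix as triplet text."""
    if m.space == "reference" and m.binning is None:
        raise ValueError("reference-space matrix needs a binning to write")
    with open(path, "w") as fh:
        iu = np.nonzero(np.triu(~np.isnan(m.matrix) & (m.matrix != 0)))
        for i, j in zip(*iu):
            v = m.matrix[i, j]
            v_str = f"{int(v)}" if float(v).is_integer() else f"{v:.10g}"
            if m.space == "contig":
                fh.write(f"{m.name or 'contig'} {i} {j} {v_str}\n")
            else:
                c1, b1 = m.binning.locate(int(i))
                c2, b2 = m.binning.locate(int(j))
                if c1 == c2:
                    fh.write(f"{c1} {b1} {b2} {v_str}\n")
                else:
                    fh.write(f"{c1} {b1} {c2} {b2} {v_str}\n")


def read_triplet(path, binning: Binning, space: str = "reference", name: str | None = None) -> ContactMatrix:
    """Load triplet text into a symmetric dense matrix.

    Conflicting duplicate entries for mirrored pairs raise; negative counts
    raise.
    """
    n = binning.n_bins
    mat = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    chroms = set(binning.chroms)
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                c1, b1, b2, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                c2 = c1
            elif len(parts) == 5:
                c1, b1, c2, b2, v = parts[0], int(parts[1]), parts[2], int(parts[3]), float(parts[4])
            else:
                raise ValueError(f"malformed triplet line: {line!r}")
            if c1 not in chroms or c2 not in chroms:
                raise ValueError(f"unknown chromosome in triplet line: {line!r}")
            if v < 0:
                raise ValueError("negative contact count")
            i = binning.offset(c1) + b1
            j = binning.offset(c2) + b2
            if i > j:
                i, j = j, i
            if seen[i, j] and mat[i, j] != v:
                raise ValueError(f"conflicting asymmetric entries for pair ({i},{j})")
            mat[i, j] = v
            seen[i, j] = True
    mat = np.triu(mat) + np.triu(mat, 1).T
    return ContactMatrix(mat, binning.resolution, space=space, binning=binning, name=name)


# ---------------------------------------------------------------------------
# minimal single-resolution COOL


def write_cool(path, m: ContactMatrix) -> None:
    """Write a contact matrix as a single-resolution COOL (HDF5) file."""
    import h5py

    if m.binning is None:
        binning = Binning((((m.name or "contig"), m.n_bins * m.resolution),), m.resolution)
    else:
        binning = m.binning
    bins = binning.bins_table()
    chrom_names = binning.chroms
    chrom_id = {c: k for k, c in enumerate(chrom_names)}
    iu = np.triu_indices(m.n_bins)
    vals = m.matrix[iu]
    keep = ~np.isnan(vals) & (vals != 0)
    b1, b2, v = iu[0][keep], iu[1][keep], vals[keep]
    order = np.lexsort((b2, b1))
    b1, b2, v = b1[order], b2[order], v[order]

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = m.resolution
        f.attrs["nbins"] = m.n_bins
        f.attrs["nnz"] = len(v)
        f.attrs["nchroms"] = len(chrom_names)
        f.attrs["storage-mode"] = "symmetric-upper"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(chrom_names, dtype="S32"))
        g.create_dataset("length", data=np.array([dict(binning.chrom_lengths)[c] for c in chrom_names], dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=bins["chrom"].map(chrom_id).to_numpy(np.int32))
        g.create_dataset("start", data=bins["start"].to_numpy(np.int64))
        g.create_dataset("end", data=bins["end"].to_numpy(np.int64))
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=b1.astype(np.int64))
        g.create_dataset("bin2_id", data=b2.astype(np.int64))
        if np.all(v == np.floor(v)):
            g.create_dataset("count", data=v.astype(np.int64))
        else:
            g.create_dataset("count", data=v.astype(np.float64))
        g = f.create_group("indexes")
        chrom_offset = np.zeros(len(chrom_names) + 1, dtype=np.int64)
        for k, c in enumerate(chrom_names):
            chrom_offset[k + 1] = chrom_offset[k] + binning.chrom_bins(c)
        g.create_dataset("chrom_offset", data=chrom_offset)
        bin1_offset = np.searchsorted(b1, np.arange(m.n_bins + 1))
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def read_cool(path, space: str = "reference", name: str | None = None) -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        res = int(f.attrs["bin-size"])
        chrom_names = [c.decode() if isinstance(c, bytes) else str(c) for c in f["chroms/name"][:]]
        lengths = f["chroms/length"][:]
        binning = Binning(tuple(zip(chrom_names, (int(x) for x in lengths))), res)
        n = binning.n_bins
        mat = np.zeros((n, n))
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        v = f["pixels/count"][:].astype(float)
        mat[b1, b2] = v
        mat = np.triu(mat) + np.triu(mat, 1).T
    return ContactMatrix(mat, res, space=space, binning=binning, name=name)


def load_contacts(path, format: str | None = None, binning: Binning | None = None, **kw) -> ContactMatrix:
    """Load a contact matrix from a COOL or triplet-text file.

    The format is sniffed from the extension when not given; triplet text
    requires an explicit ``binning``.
    """
    fmt = format
    if fmt is None:
        fmt = "cool" if str(path).endswith((".cool", ".mcool", ".h5")) else "triplet"
    if fmt == "cool":
        return read_cool(path, **kw)
    if fmt == "triplet":
        if binning is None:
            raise ValueError("triplet text requires a binning")
        return read_triplet(path, binning, **kw)
    raise ValueError(f"unknown contact format {fmt!r}")


# ---------------------------------------------------------------------------
# BED / BEDPE


def read_bed(path, class_column: bool = False) -> pd.DataFrame:
    """Read a BED file of intervals (optionally with a TE/SE class column).

    Columns: chrom, start, end, then ``name`` or, with ``class_column=True``,
    the enhancer class (TE or SE) as the 4th column.  Rows must be sorted
    within each chromosome and well-formed (start < end).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    cols = ["chrom", "start", "end"]
    if df.shape[1] >= 4:
        cols.append("class" if class_column else "name")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if (df["start"] >= df["end"]).any():
        raise ValueError("malformed BED interval (start >= end)")
    for _, grp in df.groupby("chrom"):
        if not grp["start"].is_monotonic_increasing:
            raise ValueError("BED rows must be sorted by start within each chromosome")
    if class_column:
        bad = ~df["class"].isin(["TE", "SE"])
        if bad.any():
            raise ValueError("enhancer class column must be TE or SE")
        df["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    elif "name" not in df:
        df["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return df


def write_bedpe(path, rows: list[tuple]) -> None:
    """Write pair regions (chrom1, s1, e1, chrom2, s2, e2, name) as BEDPE."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    df = df.iloc[:, :7]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"][: df.shape[1]]
    return df
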