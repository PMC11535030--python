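"""Binned contact matrices, zigzag-pole targets, window splits and augmentations.

A contact matrix lives either in *reference* space (one global bin index over
all chromosomes, so interchromosomal contacts are first-class) or in *contig*
space (bins along one assembled derivative sequence).  Raw matrices hold
integer counts; normalized matrices hold non-negative reals.  Band-limited
predicted matrices use NaN for entries that no prediction window targeted.

The *zigzag pole* is the training/prediction target of the sequence model: for
a window of ``n`` bins it is the vector of ``n - 1`` contact values, one per
genomic distance ``d = 1 .. n-1``, where for each distance the bin pair whose
midpoint is closest to the window centre is selected.  Self-interaction
(``d = 0``) is excluded because raw Hi-C diagonals are dominated by
self-ligation signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import reverse_complement

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class Binning:
    """Fixed-resolution binning over an ordered set of chromosomes.

    Bin ``b`` of a chromosome covers ``[b*resolution, (b+1)*resolution)``;
    global bin indices concatenate chromosomes in order.
    """

    chrom_lengths: tuple[tuple[str, int], ...]
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(
            self, "chrom_lengths", tuple((str(c), int(l)) for c, l in self.chrom_lengths)
        )

    @classmethod
    def from_lengths(cls, lengths: dict[str, int], resolution: int) -> "Binning":
        return cls(tuple(lengths.items()), resolution)

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_lengths]

    def chrom_bins(self, chrom: str) -> int:
        for c, l in self.chrom_lengths:
            if c == chrom:
                return -(-l // self.resolution)
        raise KeyError(chrom)

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_bins(c) for c in self.chroms)

    def offset(self, chrom: str) -> int:
        off = 0
        for c, _ in self.chrom_lengths:
            if c == chrom:
                return off
            off += self.chrom_bins(c)
        raise KeyError(chrom)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of base position ``pos`` on ``chrom``."""
        return self.offset(chrom) + pos // self.resolution

    def locate(self, gbin: int) -> tuple[str, int]:
        """Inverse of :meth:`bin_index`: global bin -> (chrom, local bin)."""
        off = 0
        for c, _ in self.chrom_lengths:
            n = self.chrom_bins(c)
            if gbin < off + n:
                return c, gbin - off
            off += n
        raise IndexError(gbin)

    def bins_table(self):
        import pandas as pd

        rows = []
        for c, l in self.chrom_lengths:
            for b in range(self.chrom_bins(c)):
                rows.append((c, b * self.resolution, min((b + 1) * self.resolution, l)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix in reference or contig space."""

    matrix: np.ndarray
    resolution: int
    space: str = "reference"  # 'reference' | 'contig'
    binning: Binning | None = None
    name: str | None = None
    normalized: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.space not in ("reference", "contig"):
            raise ValueError(f"unknown space {self.space!r}")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def is_symmetric(self, tol: float = 0.0) -> bool:
        m = self.matrix
        either_nan = np.isnan(m) | np.isnan(m.T)
        nan_match = np.isnan(m) == np.isnan(m.T)
        with np.errstate(invalid="ignore"):
            close = np.abs(m - m.T) <= tol
        return bool(np.all(np.where(either_nan, nan_match, close)))

    def upper_sum(self) -> float:
        """Sum over the upper triangle including the diagonal, NaN-aware."""
        iu = np.triu_indices(self.n_bins)
        vals = self.matrix[iu]
        return float(np.nansum(vals))


# ---------------------------------------------------------------------------
# zigzag poles


def pole_pairs(window_start: int, n_bins: int, tie: str = "low") -> tuple[np.ndarray, np.ndarray]:
    """Bin pairs targeted by the pole of the window starting at ``window_start``.

    For distance ``d`` the pair ``(i, i+d)`` with midpoint closest to the
    window centre ``window_start + (n_bins-1)/2`` is chosen.  When two pairs
    are equidistant from the centre (``n_bins - d`` even) the tie breaks to the
    smaller ``i`` (``tie='low'``) or to its mirror image (``tie='high'``).
    """
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    d = np.arange(1, n_bins)
    base = n_bins - 1 - d
    off = base // 2 if tie == "low" else (base + 1) // 2
    i = window_start + off
    return i, i + d


@dataclass
class ZigzagPole:
    """Per-distance contact targets of one prediction window.

    ``values`` uses the canonical (low) tie-break; ``values_mirror`` holds the
    values the mirrored window would select, needed for exact
    reverse-complement augmentation.
    """

    window_start: int
    n_bins: int
    values: np.ndarray
    values_mirror: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_bins - 1:
            raise ValueError("pole length must be n_bins - 1")
        if self.values_mirror is None:
            self.values_mirror = self.values.copy()
        else:
            self.values_mirror = np.asarray(self.values_mirror, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def extract_pole(m: ContactMatrix | np.ndarray, window_start: int, n_bins: int) -> ZigzagPole:
    """Extract the zigzag pole of the ``n_bins``-wide window at ``window_start``.

    The window must fit inside the matrix; there is no padding.
    """
    mat = m.matrix if isinstance(m, ContactMatrix) else np.asarray(m)
    if n_bins < 2:
        raise ValueError("window must span at least 2 bins")
    if window_start < 0 or window_start + n_bins > mat.shape[0]:
        raise ValueError("window extends beyond the matrix; no padding is applied")
    i_lo, j_lo = pole_pairs(window_start, n_bins, tie="low")
    i_hi, j_hi = pole_pairs(window_start, n_bins, tie="high")
    return ZigzagPole(window_start, n_bins, mat[i_lo, j_lo], mat[i_hi, j_hi])


def pole_to_matrix(poles, size: int) -> np.ndarray:
    """Assemble sliding-window poles into a band-limited symmetric matrix.

    Entries targeted by several windows are averaged; entries no pole targeted
    (including everything with ``|i-j| > n_bins-1`` and the diagonal) are NaN.
    """
    sums = np.zeros((size, size))
    cnt = np.zeros((size, size))
    for p in poles:
        i, j = pole_pairs(p.window_start, p.n_bins, tie="low")
        np.add.at(sums, (i, j), p.values)
        np.add.at(cnt, (i, j), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, sums / np.where(cnt > 0, cnt, 1.0), np.nan)
    # mirror
    upper = ~np.isnan(out)
    out_t = out.T.copy()
    merged = np.where(upper, out, out_t)
    return merged


# ---------------------------------------------------------------------------
# window splits with breakpoint removal


@dataclass
class WindowSplit:
    """Disjoint train/validation/test1 genomic windows plus SV windows (test2).

    Windows intersecting any SV breakpoint form ``test2``; the SV-free
    remainder is randomly partitioned by ``fractions`` under ``seed``.
    """

    train: list[tuple[str, int, int]]
    val: list[tuple[str, int, int]]
    test1: list[tuple[str, int, int]]
    test2: list[tuple[str, int, int]]
    window_bp: int
    seed: int


def make_splits(
    chrom_lengths: dict[str, int],
    breakpoints: dict[str, list[int]] | None,
    window_bp: int = 4_000_000,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> WindowSplit:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    breakpoints = breakpoints or {}
    free: list[tuple[str, int, int]] = []
    test2: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        n_win = length // window_bp
        if n_win == 0:
            logger.warning("chromosome %s shorter than one %d-bp window; skipped", chrom, window_bp)
            continue
        bps = sorted(breakpoints.get(chrom, []))
        for k in range(n_win):
            start, end = k * window_bp, (k + 1) * window_bp
            if any(start <= b < end for b in bps):
                test2.append((chrom, start, end))
            else:
                free.append((chrom, start, end))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(free))
    n = len(free)
    n_tr = int(n * fractions[0])
    n_val = int(n * (fractions[0] + fractions[1])) - n_tr
    shuffled = [free[k] for k in order]
    return WindowSplit(
        train=shuffled[:n_tr],
        val=shuffled[n_tr : n_tr + n_val],
        test1=shuffled[n_tr + n_val :],
        test2=test2,
        window_bp=window_bp,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# augmentations


def bin_read_pairs(
    pos1: np.ndarray, pos2: np.ndarray, resolution: int, n_bins: int, offset: int = 0
) -> np.ndarray:
    """Bin raw intra-chromosomal read-pair positions on a (possibly shifted) grid.

    A read at base position ``p`` lands in bin ``floor((p - offset)/resolution)``;
    reads before ``offset`` fall outside the shifted grid and are dropped.
    """
    p1 = np.asarray(pos1, dtype=np.int64)
    p2 = np.asarray(pos2, dtype=np.int64)
    keep = (p1 >= offset) & (p2 >= offset)
    b1 = (p1[keep] - offset) // resolution
    b2 = (p2[keep] - offset) // resolution
    keep2 = (b1 < n_bins) & (b2 < n_bins)
    b1, b2 = b1[keep2], b2[keep2]
    m = np.zeros((n_bins, n_bins), dtype=np.int64)
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    np.add.at(m, (lo, hi), 1)
    m = m + np.triu(m, 1).T
    return m


def shift_augment(
    pos1: np.ndarray, pos2: np.ndarray, resolution: int, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Double the training data by re-binning reads on a half-bin-shifted grid.

    Returns the matrices of the original grid and of the grid shifted by
    ``resolution/2`` (e.g. 40-kb bins re-mapped to 20-60-kb boundaries).
    """
    if resolution % 2 != 0:
        raise ValueError("resolution must be even to shift by half a bin")
    offset = resolution // 2
    n0 = length // resolution
    n1 = (length - offset) // resolution
    m0 = bin_read_pairs(pos1, pos2, resolution, n0, offset=0)
    m1 = bin_read_pairs(pos1, pos2, resolution, n1, offset=offset)
    return m0, m1


def reverse_sample(seq: str, pole: ZigzagPole) -> tuple[str, ZigzagPole]:
    """Reverse-complement augmentation of one (sequence window, pole) sample.

    The sequence is reverse complemented; pole values keep their distance
    indexing but tie-broken pair choices are mirrored, so applying the
    transform twice returns the original sample exactly.
    """
    flipped = ZigzagPole(
        pole.window_start, pole.n_bins, pole.values_mirror.copy(), pole.values.copy()
    )
    return reverse_complement(seq), flipped
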