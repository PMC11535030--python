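"""Contig-specific ICE normalization.

Balancing is applied per contig matrix rather than to the total Hi-C: the
per-contig matrices are already free of copy-number and SV biases (copy
number enters the model multiplicatively and rearranged contacts live in
their own contig's coordinates), so iterative correction here removes only
the residual per-bin multiplicative bias.  The observed matrix factorizes as

    c(i', j') = b_{i'} * b_{j'} * t(i', j')

with the balanced matrix ``t`` satisfying, for every non-empty row,

    sum over |i' - j'| > 1 of t(i', j') = 1.

The diagonal and first off-diagonal are masked from the balancing
constraint (self-interaction and adjacent-bin signal dominate raw counts);
rows that are entirely zero under the mask are dropped from balancing and
reported with an undefined (NaN) bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hic import ContactMatrix

logger = logging.getLogger(__name__)


@dataclass
class IceResult:
    normalized: ContactMatrix
    biases: np.ndarray
    iterations: int
    converged: bool


def ice_normalize(
    m: ContactMatrix | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 300,
    mask_width: int = 1,
) -> IceResult:
    """Iteratively balance a symmetric non-negative contig matrix.

    ``mask_width = 1`` excludes ``|i-j| <= 1`` from the marginal constraint.
    NaN entries mark unobserved pairs (e.g. outside a prediction band): they
    are excluded from balancing, rows equalize the *mean* of their observed
    masked entries instead of the sum (so truncated rows are comparable),
    and the NaNs are restored in the output.  Convergence is declared when
    the masked row marginals are equal within ``tol`` (max relative
    deviation); hitting ``max_iter`` first returns the partial result with
    ``converged=False`` and a warning.
    """
    if isinstance(m, ContactMatrix):
        mat = np.asarray(m.matrix, dtype=float)
        meta = m
    else:
        mat = np.asarray(m, dtype=float)
        meta = None
    n = mat.shape[0]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    valid = ~np.isnan(mat)
    if not np.array_equal(valid, valid.T):
        raise ValueError("matrix must be symmetric")
    banded = not valid.all()
    mat = np.where(valid, mat, 0.0)
    if not np.allclose(mat, mat.T):
        raise ValueError("matrix must be symmetric")
    if (mat < 0).any():
        raise ValueError("matrix must be non-negative")
    if not mat.any():
        raise ValueError("all-zero matrix cannot be balanced")

    keep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > mask_width
    # band-limited input: missing entries are excluded and rows balance on
    # the *mean* of their observed masked entries, so rows with truncated
    # bands are comparable to full ones
    counted = keep & valid
    cnt = counted.sum(axis=1)
    t = mat.copy()
    bias = np.ones(n)
    active = (mat * counted).sum(axis=1) > 0
    if not active.any():
        raise ValueError("no off-diagonal signal to balance")

    def _marginal(x):
        s = (x * counted).sum(axis=1)
        if banded:
            return np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
        return s

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = _marginal(t)
        mean_s = s[active].mean()
        d = np.where(active, s / mean_s, 1.0)
        # guard rows that lost all mass numerically
        d[d <= 0] = 1.0
        t = t / np.outer(d, d)
        bias = bias * d
        if np.max(np.abs(d[active] - 1.0)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("ICE did not converge in %d iterations", max_iter)

    # scale so masked row marginals (sums, or means when band-limited)
    # equal 1 on active rows
    s = _marginal(t)
    scale = s[active].mean()
    t = t / scale
    bias = bias * np.sqrt(scale)
    t[~active, :] = 0.0
    t[:, ~active] = 0.0
    biases = np.where(active, bias, np.nan)
    if banded:
        t = np.where(valid, t, np.nan)

    if meta is not None:
        norm = ContactMatrix(
            t, meta.resolution, space=meta.space, binning=meta.binning,
            name=meta.name, normalized=True,
        )
    else:
        norm = ContactMatrix(t, resolution=1, space="contig", normalized=True)
    return IceResult(norm, biases, it, converged)
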