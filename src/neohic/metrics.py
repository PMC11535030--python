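"""Evaluation metrics and the copy-number-aware overexpression analysis.

Two agreement metrics for predicted vs observed contact maps:

* **DSC** (distance-stratified correlation): the Pearson correlation between
  prediction and observation is computed separately at every genomic
  distance, and the DSC is the unweighted mean over distances.  Stratifying
  by distance removes the trivially shared distance decay, so the DSC
  rewards position-specific structure only.
* **window Pearson**: plain Pearson correlation over the bin pairs of a
  window or of an SV-window pair set (the measure used on SV-derived
  contacts, where a distance stratification is not meaningful).

The expression stage regresses expression on integer gene copy number in
*reference* samples (those without a neo-TAD over the gene), scores each
neo-TAD sample's influence on that line with Cook's distance, and calls
overexpression when the distance exceeds 4/n with a positive residual.
Recurrent genes must have both a majority of called neo-TAD samples and a
minimum number of SE-hijacking samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .hic import ContactMatrix

logger = logging.getLogger(__name__)


def _as_array(m) -> np.ndarray:
    return m.matrix if isinstance(m, ContactMatrix) else np.asarray(m, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class DscReport:
    per_distance_r: dict[int, float]
    dsc: float
    max_distance: int


def distance_stratified_correlation(
    pred, obs, max_distance: int | None = None, min_pairs: int = 3
) -> DscReport:
    """Mean per-distance Pearson correlation between two matrices.

    Pairs where either matrix is NaN are skipped; strata with fewer than
    ``min_pairs`` valid pairs or with zero variance on either side are
    excluded from the mean (and logged), never NaN-propagated.
    """
    p, o = _as_array(pred), _as_array(obs)
    if p.shape != o.shape:
        raise ValueError("matrices must share a grid")
    n = p.shape[0]
    dmax = max_distance if max_distance is not None else n - 1
    per: dict[int, float] = {}
    for d in range(1, dmax + 1):
        pv = np.diagonal(p, offset=d)
        ov = np.diagonal(o, offset=d)
        ok = ~np.isnan(pv) & ~np.isnan(ov)
        if ok.sum() < min_pairs:
            continue
        pv, ov = pv[ok], ov[ok]
        if pv.std() == 0 or ov.std() == 0:
            logger.debug("distance %d has a zero-variance stratum; excluded", d)
            continue
        per[d] = _pearson(pv, ov)
    dsc = float(np.mean(list(per.values()))) if per else math.nan
    return DscReport(per, dsc, dmax)


def window_pearson(pred, obs, pairs) -> float:
    """Pearson correlation over an explicit set of bin pairs.

    ``pairs`` is an iterable of (i, j) matrix indices (e.g. SV-window pairs);
    at least three valid pairs are required.
    """
    p, o = _as_array(pred), _as_array(obs)
    pv, ov = [], []
    for i, j in pairs:
        a, b = p[i, j], o[i, j]
        if np.isnan(a) or np.isnan(b):
            continue
        pv.append(a)
        ov.append(b)
    if len(pv) < 3:
        raise ValueError("need at least 3 valid pairs for a correlation")
    return _pearson(np.asarray(pv), np.asarray(ov))


# ---------------------------------------------------------------------------
# CN ~ expression regression and Cook's distance


@dataclass
class CnExpressionFit:
    slope: float
    intercept: float
    residuals: np.ndarray  # reference-sample residuals
    cn: np.ndarray  # reference CNs
    expr: np.ndarray
    slope_defined: bool

    def predict(self, cn) -> np.ndarray:
        return self.slope * np.asarray(cn, dtype=float) + self.intercept


def cn_expression_fit(expr, cn, reference_mask) -> CnExpressionFit:
    """OLS of expression on integer copy number over reference samples only.

    With constant CN among references the slope is undefined and an
    intercept-only fit (the mean) is returned, flagged via ``slope_defined``.
    """
    expr = np.asarray(expr, dtype=float)
    cn = np.asarray(cn, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    x, y = cn[mask], expr[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 reference samples")
    if np.ptp(x) == 0:
        fit = CnExpressionFit(0.0, float(y.mean()), y - y.mean(), x, y, False)
        return fit
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return CnExpressionFit(float(slope), float(intercept), resid, x, y, True)


@dataclass
class OverexpressionCall:
    sample: object
    cooks_d: float
    residual: float
    called: bool


def cooks_outliers(
    fit: CnExpressionFit, query_expr, query_cn, n: int, samples=None
) -> list[OverexpressionCall]:
    """Cook's distance of each query sample against the reference regression.

    Each query is scored by augmenting the reference samples with that single
    point, computing its Cook's distance in the augmented fit (the standard
    leverage/residual formula with p = 2 parameters; deleting the query
    recovers the reference fit exactly).  A sample is called overexpressed
    when D > 4/n and its residual from the reference line is positive.
    """
    query_expr = np.atleast_1d(np.asarray(query_expr, dtype=float))
    query_cn = np.atleast_1d(np.asarray(query_cn, dtype=float))
    if samples is None:
        samples = list(range(len(query_expr)))
    thr = 4.0 / n
    p = 2
    out = []
    for s, ye, xc in zip(samples, query_expr, query_cn):
        x = np.append(fit.cn, xc)
        y = np.append(fit.expr, ye)
        if np.ptp(x) == 0:
            X = np.ones((len(x), 1))
            p_eff = 1
        else:
            X = np.column_stack([np.ones(len(x)), x])
            p_eff = p
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(x) - p_eff
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        h = float(H[-1, -1])
        e = float(resid[-1])
        if s2 <= 0:
            d = 0.0
        else:
            d = (e * e / (p_eff * s2)) * (h / (1.0 - h) ** 2)
        ref_resid = float(ye - fit.predict(xc))
        out.append(OverexpressionCall(s, float(d), ref_resid, bool(d > thr and ref_resid > 0)))
    return out


@dataclass
class RecurrentGene:
    gene: str
    called_fraction: float
    se_hijack_samples: int
    overexpression_threshold: float


def recurrent_genes(
    calls_by_gene: dict[str, list[OverexpressionCall]],
    se_hijack_counts: dict[str, int],
    expr_by_gene: dict[str, np.ndarray] | None = None,
    min_called_fraction: float = 0.5,
    min_se_samples: int = 4,
) -> list[RecurrentGene]:
    """Select recurrently overexpressed neo-TAD genes.

    A gene qualifies when (1) more than ``min_called_fraction`` of its
    neo-TAD samples are called by the Cook's-distance rule and (2) it has at
    least ``min_se_samples`` SE-hijacking samples.  The per-gene
    overexpression threshold is the minimum expression among called samples.
    """
    out = []
    for gene, calls in calls_by_gene.items():
        if not calls:
            continue
        frac = sum(c.called for c in calls) / len(calls)
        se = se_hijack_counts.get(gene, 0)
        if frac <= min_called_fraction or se < min_se_samples:
            continue
        if expr_by_gene is not None and gene in expr_by_gene:
            expr = np.asarray(expr_by_gene[gene], dtype=float)
            called_idx = [k for k, c in enumerate(calls) if c.called]
            threshold = float(expr[called_idx].min()) if called_idx else math.nan
        else:
            threshold = math.nan
        out.append(RecurrentGene(gene, frac, se, threshold))
    return out
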