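"""Correlation-based lncRNA–mRNA pairing and cis-candidate ranking.

Pearson correlation between each lncRNA and each protein-coding gene is
computed on log2(FPKM+1) across the shared samples (by default all 18
pooled samples). A pair is retained when the *signed* coefficient exceeds
``r_min`` (default 0.80, strict) and the two-sided t-based p-value is below
``p_max`` (default 0.05, strict); an absolute-value variant and optional BH
correction are available by flag. Retained pairs that also lie within the
cis window are joined with their signed genomic distance and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression_stats import ExpressionMatrix, benjamini_hochberg


@dataclass(frozen=True)
class CorrelatedPair:
    lncrna_id: str
    gene_id: str
    r: float
    p_value: float
    n: int
    signed_distance: int | None = None
    is_cis: bool = False

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("correlation out of range")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the exact t reference
    distribution: t = r * sqrt((n-2)/(1-r^2)) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r and p matrices between rows of a (k × n) and rows of b (m × n)."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)  # |r| = 1 -> p -> 0
    return r, p


def correlated_pairs(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    r_min: float = 0.80,
    p_max: float = 0.05,
    use_absolute_r: bool = False,
    adjust_fdr: bool = False,
) -> list[CorrelatedPair]:
    """All lncRNA–gene pairs passing both strict thresholds.

    ``use_absolute_r`` switches the r threshold to |r| > r_min;
    ``adjust_fdr`` applies BH across all pairs and thresholds the q-value
    instead of the raw p. Constant feature vectors never form pairs.
    """
    if list(lnc_expr.sample_ids) != list(gene_expr.sample_ids):
        raise ValueError("lncRNA and gene matrices must share ordered samples")
    a = lnc_expr.log2().to_numpy()
    b = gene_expr.log2().to_numpy()
    n = a.shape[1]
    r, p = _pairwise_pearson(a, b)
    const_a = np.ptp(a, axis=1) == 0
    const_b = np.ptp(b, axis=1) == 0
    invalid = np.outer(const_a, np.ones(len(b), bool)) | np.outer(
        np.ones(len(a), bool), const_b
    )
    r = np.where(invalid, np.nan, r)
    crit_p = p.copy()
    if adjust_fdr:
        flat = p[~invalid]
        adj = benjamini_hochberg(flat)
        crit_p[~invalid] = adj
    stat = np.abs(r) if use_absolute_r else r
    with np.errstate(invalid="ignore"):
        mask = (stat > r_min) & (crit_p < p_max) & ~invalid
    lnc_ids = lnc_expr.feature_ids
    gene_ids = gene_expr.feature_ids
    out = []
    for i, j in zip(*np.nonzero(mask)):
        out.append(
            CorrelatedPair(
                lncrna_id=lnc_ids[i],
                gene_id=gene_ids[j],
                r=float(r[i, j]),
                p_value=float(p[i, j]),
                n=n,
            )
        )
    return sorted(out, key=lambda c: (-c.r, c.lncrna_id, c.gene_id))


def join_cis(
    pairs: list[CorrelatedPair],
    cis: list[tuple[str, str, int]],
    top_n: int = 10,
) -> list[CorrelatedPair]:
    """Intersect correlated pairs with cis-proximal pairs and rank.

    Ranking: descending r, ties by smaller |distance|, then lexicographic
    (lncRNA id, gene id). Returns at most ``top_n`` records with
    ``is_cis=True`` and the signed distance attached.
    """
    distances = {(l, g): d for l, g, d in cis}
    joined = [
        CorrelatedPair(
            lncrna_id=p.lncrna_id,
            gene_id=p.gene_id,
            r=p.r,
            p_value=p.p_value,
            n=p.n,
            signed_distance=distances[(p.lncrna_id, p.gene_id)],
            is_cis=True,
        )
        for p in pairs
        if (p.lncrna_id, p.gene_id) in distances
    ]
    joined.sort(
        key=lambda c: (-c.r, abs(c.signed_distance), c.lncrna_id, c.gene_id)
    )
    return joined[:top_n]
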