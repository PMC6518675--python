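"""Expression thresholding, differential expression, correlation and PVCA.

The expression unit is FPKM-like (non-negative, length/depth normalised);
all statistics operate on ``log2(FPKM + 1)``. Differential expression
between the high-intake and control groups within one tissue uses a Welch
t-test per feature with Benjamini–Hochberg FDR control — a deliberately
transparent two-group test standing in for read-level count models, since
the downstream pipeline logic depends only on the DE calls.

PVCA (principal variance component analysis) attributes expression variance
to the experimental factors: PCA on the sample-sample covariance of
standardised features, a balanced two-way ANOVA method-of-moments variance
decomposition of each retained PC's scores (tissue, treatment, their
interaction, residual), negative component estimates truncated to zero,
per-PC normalisation, then an eigenvalue-weighted average across the PCs
explaining at least ``min_var_explained`` of total variance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lncflux")

TREATMENTS = ("control", "high_intake")


@dataclass
class ExpressionMatrix:
    """Features × samples FPKM-like values with per-sample design metadata.

    ``values``: DataFrame indexed by feature id, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``tissue``, ``treatment`` (control / high_intake) and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample metadata does not match matrix columns")
        missing = {"tissue", "treatment", "replicate"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["tissue"]))

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.sample_meta)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)

    def write(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="feature_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, expr_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(values, meta)


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    mean_control: float
    mean_treated: float
    fold_change: float
    log2fc: float
    p_value: float
    q_value: float
    is_de: bool


@dataclass(frozen=True)
class PvcaResult:
    factor_names: tuple[str, ...]
    weighted_proportions: dict[str, float]
    n_pcs_used: int = 0

    def __post_init__(self) -> None:
        total = sum(self.weighted_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"PVCA proportions sum to {total}, not 1")


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))


def filter_expressed(
    m: ExpressionMatrix, threshold: float = 0.1, agg: str = "max"
) -> tuple[ExpressionMatrix, int]:
    """Keep features whose max (or mean) FPKM strictly exceeds threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if m.values.empty:
        raise ValueError("empty expression matrix")
    if agg == "max":
        stat = m.values.max(axis=1)
    elif agg == "mean":
        stat = m.values.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    keep = stat > threshold
    kept = ExpressionMatrix(m.values.loc[keep], m.sample_meta)
    return kept, int(keep.sum())


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone over ranked p-values)."""
    q = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
    return q


def differential_expression(
    m: ExpressionMatrix, tissue: str, alpha: float = 0.05, epsilon: float = 1e-6
) -> list[DEResult]:
    """Welch t-test on log2(FPKM+1), treated vs control, within one tissue.

    Features with both groups constant and equal get p = 1. Fold change is
    on the raw FPKM scale with an ``epsilon`` pseudo-abundance.
    """
    meta = m.sample_meta
    in_tissue = meta["tissue"] == tissue
    ctrl_ids = meta.index[in_tissue & (meta["treatment"] == "control")]
    trt_ids = meta.index[in_tissue & (meta["treatment"] == "high_intake")]
    if len(ctrl_ids) < 2 or len(trt_ids) < 2:
        raise ValueError(
            f"tissue {tissue!r} needs >=2 replicates in both treatment groups"
        )
    log = m.log2()
    a = log[trt_ids].to_numpy()
    b = log[ctrl_ids].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # zero variance in both groups: identical means -> p=1, else p -> 0
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        pvals[degenerate & equal_means] = 1.0
        pvals[degenerate & ~equal_means] = 0.0
    qvals = benjamini_hochberg(pvals)
    mean_trt = m.values[trt_ids].mean(axis=1).to_numpy()
    mean_ctrl = m.values[ctrl_ids].mean(axis=1).to_numpy()
    fc = (mean_trt + epsilon) / (mean_ctrl + epsilon)
    results = []
    for i, fid in enumerate(m.feature_ids):
        results.append(
            DEResult(
                feature_id=fid,
                mean_control=float(mean_ctrl[i]),
                mean_treated=float(mean_trt[i]),
                fold_change=float(fc[i]),
                log2fc=float(np.log2(fc[i])),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                is_de=bool(qvals[i] < alpha),
            )
        )
    return results


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("feature_id")


def percent_de(n_de: int, n_expressed: int) -> float:
    """Percentage of expressed features called DE, half-up to 2 decimals."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    if not 0 <= n_de <= n_expressed:
        raise ValueError("n_de must lie in [0, n_expressed]")
    return round_half_up(100.0 * n_de / n_expressed, 2)


def de_overlap_counts(de_sets: dict[str, set]) -> dict[str, int]:
    """Disjoint Venn region counts for k sets; keys like ``"liver&fat"``.

    Region membership is exact: an element counts in the region naming
    precisely the sets that contain it. Counts sum to the union size.
    """
    if len(de_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(de_sets)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(de_sets[n] for n in combo))
            outside = set.union(
                *(de_sets[n] for n in names if n not in combo), set()
            )
            counts["&".join(combo)] = len(inside - outside)
    return counts


def correlation_overview(
    m: ExpressionMatrix,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], float]]:
    """Sample-sample Pearson matrix on log2(FPKM+1) and within-group
    cross-tissue mean correlations.

    Returns the full matrix and a map
    ``(treatment, tissue_a, tissue_b) -> mean r`` over all sample pairs of
    the two tissues within that treatment group. Constant sample vectors
    yield NaN correlations which are excluded from the means (logged).
    """
    if len(m.sample_ids) < 2:
        raise ValueError("need at least two samples")
    log = m.log2()
    constant = log.std(axis=0, ddof=0) == 0
    if constant.any():
        logger.warning(
            "constant sample vectors excluded from correlation means: %s",
            list(log.columns[constant]),
        )
    corr = log.corr(method="pearson")  # pandas leaves NaN for constant columns
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    meta = m.sample_meta
    means: dict[tuple[str, str, str], float] = {}
    tissues = m.tissues
    for treatment in dict.fromkeys(meta["treatment"]):
        for ta, tb in itertools.combinations(tissues, 2):
            ids_a = meta.index[(meta["treatment"] == treatment) & (meta["tissue"] == ta)]
            ids_b = meta.index[(meta["treatment"] == treatment) & (meta["tissue"] == tb)]
            block = corr.loc[ids_a, ids_b].to_numpy(dtype=float)
            if np.isnan(block).all():
                continue
            means[(treatment, ta, tb)] = float(np.nanmean(block))
    return corr, means


# ---------------------------------------------------------------------------
# PVCA
# ---------------------------------------------------------------------------

PVCA_FACTORS = ("tissue", "treatment", "tissue:treatment", "residual")


def _anova_components(scores: np.ndarray, tissue: np.ndarray, treatment: np.ndarray,
                      balanced: bool, pool_alpha: float = 0.001) -> np.ndarray:
    """Method-of-moments variance components for one PC's scores.

    Balanced two-way crossed random-effects layout with ``n`` replicates
    per (tissue, treatment) cell:
    sigma2_e = MSE; sigma2_ab = (MSAB - MSE)/n;
    sigma2_a = (MSA - MSAB)/(b*n); sigma2_b = (MSB - MSAB)/(a*n).
    Negative estimates are truncated to zero, and a factor is pooled into
    the residual unless its mean square significantly exceeds the error
    mean square (F-test at ``pool_alpha``), so chance-level mean-square
    excesses do not masquerade as factor variance; the caller corrects
    ``pool_alpha`` for the number of PCs tested. The unbalanced fallback uses the
    same mean-based sums with the average cell size (a coarser means-based
    estimator).
    """
    t_levels = sorted(set(tissue))
    g_levels = sorted(set(treatment))
    a, b = len(t_levels), len(g_levels)
    cells = {}
    for tl in t_levels:
        for gl in g_levels:
            mask = (tissue == tl) & (treatment == gl)
            cells[(tl, gl)] = scores[mask]
    sizes = {k: len(v) for k, v in cells.items()}
    if balanced:
        n = next(iter(sizes.values()))
    else:
        n = float(np.mean(list(sizes.values())))
    grand = scores.mean()
    mean_t = {tl: scores[tissue == tl].mean() for tl in t_levels}
    mean_g = {gl: scores[treatment == gl].mean() for gl in g_levels}
    mean_cell = {k: v.mean() for k, v in cells.items()}
    ssa = b * n * sum((mean_t[tl] - grand) ** 2 for tl in t_levels)
    ssb = a * n * sum((mean_g[gl] - grand) ** 2 for gl in g_levels)
    ssab = n * sum(
        (mean_cell[(tl, gl)] - mean_t[tl] - mean_g[gl] + grand) ** 2
        for tl in t_levels
        for gl in g_levels
    )
    sse = sum(
        float(((v - mean_cell[k]) ** 2).sum()) for k, v in cells.items()
    )
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_e = sum(sizes.values()) - a * b
    msa = ssa / df_a if df_a else 0.0
    msb = ssb / df_b if df_b else 0.0
    msab = ssab / df_ab if df_ab else 0.0
    mse = sse / df_e if df_e else 0.0
    sigma_e = mse
    sigma_ab = (msab - mse) / n
    sigma_a = (msa - msab) / (b * n)
    sigma_b = (msb - msab) / (a * n)

    def significant(ms_num: float, df_num: int) -> bool:
        # screen against the error mean square: "is there any non-error
        # signal on this margin?"; the MoM subtraction above attributes it
        if df_num <= 0 or df_e <= 0 or mse == 0:
            return ms_num > 0
        return stats.f.sf(ms_num / mse, df_num, df_e) < pool_alpha

    if not significant(msab, df_ab):
        sigma_ab = 0.0
    if not significant(msa, df_a):
        sigma_a = 0.0
    if not significant(msb, df_b):
        sigma_b = 0.0
    comps = np.array([sigma_a, sigma_b, sigma_ab, sigma_e], dtype=float)
    comps[comps < 0] = 0.0
    return comps


def pvca(
    m: ExpressionMatrix,
    n_pcs: int | None = None,
    min_var_explained: float = 0.6,
    method: str = "anova",
    pool_alpha: float = 0.001,
) -> PvcaResult:
    """Weighted variance-component proportions for tissue, treatment,
    interaction and residual.

    ``method="anova"`` requires a balanced design (equal replicate counts in
    every tissue × treatment cell) and uses the exact balanced
    method-of-moments decomposition; ``method="means"`` is the means-based
    fallback for unbalanced designs.
    """
    meta = m.sample_meta
    tissue = meta["tissue"].to_numpy()
    treatment = meta["treatment"].to_numpy()
    cell_sizes = meta.groupby(["tissue", "treatment"]).size()
    balanced = cell_sizes.nunique() == 1
    if method == "anova" and not balanced:
        raise ValueError(
            "unbalanced design: use method='means' (means-based fallback estimator)"
        )
    log = m.log2().to_numpy()
    sd = log.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features constant; PVCA undefined")
    z = (log[keep] - log[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    n_samples = z.shape[1]
    cov = (z.T @ z) / z.shape[0]  # sample-sample covariance of standardized features
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise ValueError("degenerate covariance; PVCA undefined")
    explained = eigval / total
    if n_pcs is None:
        cum = np.cumsum(explained)
        n_pcs = int(np.searchsorted(cum, min_var_explained) + 1)
        n_pcs = min(n_pcs, n_samples)
    n_pcs = max(1, min(n_pcs, n_samples))
    weights = eigval[:n_pcs] / eigval[:n_pcs].sum()
    averaged = np.zeros(4)
    for i in range(n_pcs):
        scores = eigvec[:, i] * np.sqrt(max(eigval[i], 0.0))
        comps = _anova_components(
            scores, tissue, treatment, balanced=balanced,
            pool_alpha=pool_alpha / n_pcs,  # Bonferroni over retained PCs
        )
        total_comp = comps.sum()
        if total_comp <= 0:
            # a PC with no variance at all contributes its weight to residual
            comps = np.array([0.0, 0.0, 0.0, 1.0])
        else:
            comps = comps / total_comp
        averaged += weights[i] * comps
    averaged = averaged / averaged.sum()
    return PvcaResult(
        factor_names=PVCA_FACTORS,
        weighted_proportions=dict(zip(PVCA_FACTORS, map(float, averaged))),
        n_pcs_used=n_pcs,
    )
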