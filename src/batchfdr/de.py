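"""Per-gene differential expression p-values for two-group count matrices.

Two engines are provided:

``welch``
    Welch's unequal-variance t-test per gene on log-CPM values
    (Satterthwaite degrees of freedom).  Fast and assumption-light.

``voom_lite``
    A precision-weighted moderated t-test: a lowess trend of sqrt(residual
    standard deviation) against average log-count supplies per-observation
    inverse-variance weights (predicted^-4), and residual variances are
    shrunk towards a common prior by empirical-Bayes moment matching
    before forming the group-difference t-statistic with moderated
    degrees of freedom d0 + df.

Genes with zero within-group variability on the log-CPM scale get p = 1
and a ``degenerate`` flag rather than NaN, keeping the number of tested
hypotheses fixed for the downstream FDR ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["DEResult", "log_cpm", "shrink_variances", "de_test", "mean_count_filter"]

_WEIGHT_CLIP = (1e-6, 1e6)


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-group DE summary, in input gene order."""

    gene_ids: list[str]
    log2_fold_change: np.ndarray
    t_statistic: np.ndarray
    df_total: np.ndarray
    p_value: np.ndarray
    engine: str
    degenerate: np.ndarray  # True where p was forced to 1 (no variability)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2FC": self.log2_fold_change,
                "statistic": self.t_statistic,
                "p_value": self.p_value,
            }
        )


def log_cpm(counts: np.ndarray, lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """Offset log2 counts-per-million: log2((c + 0.5) / (L + 1) * 1e6)."""
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    return np.log2((counts + 0.5) / (lib_sizes[None, :] + 1.0) * 1e6)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def shrink_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    Models s2_i ~ s0^2 * F(df, d0) and estimates the prior (d0, s0^2) by
    moment matching on log s2 (digamma/trigamma closed forms).  Returns
    posterior variances (d0*s0^2 + df*s2_i)/(d0 + df), d0 and s0^2.
    d0 = inf means total shrinkage to the common value; genes with
    s2_i = 0 still receive the prior component.
    """
    s2 = np.asarray(s2, dtype=float)
    if df < 1:
        raise ValueError("residual df must be >= 1")
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 10:
        raise ValueError("need at least 10 positive sample variances to fit the prior")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        s2_post = np.full_like(s2, s0_sq)
        return s2_post, d0, s0_sq
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    s2_post = (d0 * s0_sq + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return s2_post, float(d0), s0_sq


def mean_count_filter(counts: np.ndarray, min_mean: float) -> np.ndarray:
    """Boolean keep-mask for genes whose mean raw count is >= ``min_mean``."""
    return np.asarray(counts, dtype=float).mean(axis=1) >= min_mean


def _group_masks(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = pd.unique(np.asarray(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got levels {levels!r}")
    g1 = np.asarray(groups) == levels[0]
    g2 = ~g1
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return g1, g2


def _welch(y: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    n1, n2 = g1.sum(), g2.sum()
    m1, m2 = y[:, g1].mean(axis=1), y[:, g2].mean(axis=1)
    v1, v2 = y[:, g1].var(axis=1, ddof=1), y[:, g2].var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, n1 + n2 - 2.0, df)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return m2 - m1, t, df, p, degenerate


def _voom_lite(y: np.ndarray, g1, g2, lib_sizes: np.ndarray, span: float):
    n = y.shape[1]
    df_resid = n - 2
    fitted = np.empty_like(y)
    fitted[:, g1] = y[:, g1].mean(axis=1, keepdims=True)
    fitted[:, g2] = y[:, g2].mean(axis=1, keepdims=True)
    resid = y - fitted
    s2 = (resid**2).sum(axis=1) / df_resid

    # mean-variance trend: sqrt(sd) against average log2 count
    offset = np.log2(lib_sizes + 1.0) - np.log2(1e6)
    mean_logcount = y.mean(axis=1) + offset.mean()
    sqrt_sd = np.sqrt(np.sqrt(s2))
    trend = lowess(
        sqrt_sd, mean_logcount, frac=span, it=3,
        delta=0.01 * np.ptp(mean_logcount), return_sorted=True,
    )
    # predicted sqrt-sd at each observation's fitted log-count
    fitted_logcount = fitted + offset[None, :]
    pred = np.interp(fitted_logcount, trend[:, 0], trend[:, 1])
    pred = np.clip(pred, 1e-6, None)
    w = np.clip(pred**-4.0, *_WEIGHT_CLIP)

    w1, w2 = w[:, g1].sum(axis=1), w[:, g2].sum(axis=1)
    m1 = (w[:, g1] * y[:, g1]).sum(axis=1) / w1
    m2 = (w[:, g2] * y[:, g2]).sum(axis=1) / w2
    wfit = np.empty_like(y)
    wfit[:, g1] = m1[:, None]
    wfit[:, g2] = m2[:, None]
    ss = (w * (y - wfit) ** 2).sum(axis=1)
    s2w = ss / df_resid

    s2_post, d0, _ = shrink_variances(s2w, df_resid)
    df_total = np.full(y.shape[0], min(d0 + df_resid, 1e9))
    se2 = s2_post * (1.0 / w1 + 1.0 / w2)
    degenerate = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df_total))
    return m2 - m1, t, df_total, p, degenerate


def de_test(
    counts: np.ndarray,
    groups: np.ndarray,
    engine: str = "voom_lite",
    gene_ids: list[str] | None = None,
    lib_sizes: np.ndarray | None = None,
    span: float = 0.5,
) -> DEResult:
    """Two-group differential expression test per gene.

    Parameters
    ----------
    counts : (genes, samples) non-negative integer matrix
    groups : length-samples factor with exactly two levels; the reported
        log2 fold change is level2 minus level1 in order of appearance
    engine : "welch" or "voom_lite"
    span : lowess span for the voom_lite mean-variance trend
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    g1, g2 = _group_masks(np.asarray(groups))
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    y = log_cpm(counts, lib_sizes)
    if engine == "welch":
        lfc, t, df, p, degen = _welch(y, g1, g2)
    elif engine == "voom_lite":
        lfc, t, df, p, degen = _voom_lite(y, g1, g2, np.asarray(lib_sizes, float), span)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    p = np.clip(p, 0.0, 1.0)
    return DEResult(
        gene_ids=list(gene_ids),
        log2_fold_change=lfc,
        t_statistic=t,
        df_total=np.asarray(df, dtype=float),
        p_value=p,
        engine=engine,
        degenerate=degen,
    )
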