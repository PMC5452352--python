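"""Differential expression stand-in, set overlaps, and term enrichment.

Differential-expression calling here is a deliberately simple, fully
documented stand-in for a negative-binomial GLM pipeline: median-of-ratios
size factors, per-gene moderated t-tests on log2(normalized + 1) with
empirical-Bayes variance shrinkage across genes (the information sharing
that makes small-replicate designs workable), and Benjamini-Hochberg
correction.  A gene is a DEG when |log2 fold change| >= 1 and BH-adjusted
p < 0.05 (defaults).  Term overrepresentation uses the upper-tail
hypergeometric test with BH correction; a term is reported when adjusted
p < alpha and at least ``min_genes`` study genes hit it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegRecord", "EnrichmentResult", "size_factors", "call_deg", "bh_adjust",
    "overlap_sets", "hypergeom_enrichment",
]


@dataclass
class DegRecord:
    gene_id: str
    base_mean: float
    log2fc: float
    p_value: float
    p_adj: float
    is_deg: bool


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # study hits
    K: int  # population hits
    n: int  # study size
    N: int  # population size
    p_value: float
    p_adj: float
    reported: bool


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    Computed over genes with strictly positive counts in every sample, as
    median_g(count_gj / geometric_mean_g).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    logs = np.log(mat[positive])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def _moderated_variance(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior to the observed residual
    variances by the method of moments on log variances, and returns the
    posterior (moderated) variances plus the prior degrees of freedom.
    """
    s2 = np.maximum(s2, 0.0)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = ev - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e))) if e.size else 1e-8
        return np.full_like(s2, s0_sq), d0
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(np.mean(e) - special.digamma(d0 / 2.0)
                         + np.log(d0 / 2.0)))
    s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_mod, d0


def call_deg(counts: pd.DataFrame, groups: dict[str, str], group_a: str,
             group_b: str, lfc_threshold: float = 1.0,
             alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    ``groups`` maps sample (column) names to group labels.  log2fc is
    group_b minus group_a on the log2(normalized + 1) scale.  The test is a
    moderated t: pooled within-group variances are shrunk across genes
    toward an empirical prior, and the t statistic uses the augmented
    degrees of freedom.  Genes with zero spread everywhere get p = 1.
    Returns a DataFrame with the DegRecord columns.
    """
    cols_a = [c for c in counts.columns if groups.get(c) == group_a]
    cols_b = [c for c in counts.columns if groups.get(c) == group_b]
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    factors = size_factors(counts[cols_a + cols_b])
    norm = counts[cols_a + cols_b] / factors
    logn = np.log2(norm + 1.0)
    xa = logn[cols_a].to_numpy()
    xb = logn[cols_b].to_numpy()
    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    df_resid = na + nb - 2
    s2 = (xa.var(axis=1, ddof=1) * (na - 1)
          + xb.var(axis=1, ddof=1) * (nb - 1)) / df_resid
    s2_mod, d0 = _moderated_variance(s2, df_resid)
    df_total = df_resid + d0 if np.isfinite(d0) else np.inf
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = log2fc / se
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    pvals = np.where(np.isnan(pvals) | (se == 0), 1.0, pvals)
    padj = bh_adjust(pvals)
    base_mean = norm.mean(axis=1).to_numpy()
    is_deg = (np.abs(log2fc) >= lfc_threshold) & (padj < alpha)
    return pd.DataFrame({
        "gene_id": counts.index,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "p_value": pvals,
        "p_adj": padj,
        "is_deg": is_deg,
    }).reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (standard cumulative
    minimum handling of ties)."""
    _, padj, _, _ = multipletests(np.asarray(pvals, dtype=float),
                                  method="fdr_bh")
    return padj


def overlap_sets(dis_genes, deg_genes) -> tuple[int, int, int]:
    """Venn counts (dis-only, deg-only, both) between two gene sets."""
    a, b = set(dis_genes), set(deg_genes)
    return len(a - b), len(b - a), len(a & b)


def hypergeom_enrichment(study_set, population, term_map: dict[str, set],
                         alpha: float = 0.05,
                         min_genes: int = 5) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation of terms in a study set.

    p = P(X >= k) with N population genes, K term members, n study genes and
    k study hits; BH correction across the tested terms.
    """
    population = set(population)
    study = set(study_set)
    stray = sorted(study - population)
    if stray:
        raise ValueError(f"study gene(s) absent from population: {stray[:5]}")
    N, n = len(population), len(study)
    rows = []
    for term_id in sorted(term_map):
        members = set(term_map[term_id]) & population
        if not members:
            continue
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    padj = bh_adjust([p for *_, p in rows])
    return [
        EnrichmentResult(term_id, k, K, n, N, p, float(q),
                         bool(q < alpha and k >= min_genes))
        for (term_id, k, K, p), q in zip(rows, padj)
    ]
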