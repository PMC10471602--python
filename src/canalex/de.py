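"""Differential mean expression between cross-types.

A deliberately simple, fully specified negative-binomial GLM Wald test:
per-gene method-of-moments dispersion shrunk toward a fitted mean–dispersion
trend, a log-link GLM with group (and optional batch) design and log
size-factor offsets, a Wald z statistic on the group contrast, and
Benjamini–Hochberg adjustment across genes at an adjusted-P threshold of 0.1.
Log2 fold changes are unshrunk.  Proportion comparisons between contrasts use
the Yates-corrected 2×2 chi-squared with Bonferroni family control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, norm
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, SampleTable, ValidationError
from .lcv import size_factors

logger = logging.getLogger("canalex")

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8


def filter_low_counts(counts: CountMatrix, min_total: int = 10
                      ) -> tuple[CountMatrix, int]:
    """Drop genes with fewer than ``min_total`` reads summed over all samples.

    Returns the filtered matrix and the number of genes removed.  An empty
    result is an error: nothing downstream can run on it.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    removed = int((~keep).sum())
    if not keep.any():
        raise ValidationError(
            f"all {counts.n_genes} genes fall below {min_total} total reads"
        )
    kept_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    out = CountMatrix(kept_ids, list(counts.sample_ids), counts.counts[keep, :])
    if removed:
        logger.info("filtered %d genes below %d total reads", removed, min_total)
    return out, removed


def estimate_dispersion(counts: CountMatrix, meta: SampleTable,
                        n0: float = 5.0) -> pd.Series:
    """Per-gene NB dispersion: pooled method of moments, shrunk to a trend.

    On size-factor-normalized values, the within-group variance (pooled across
    groups after removing group means) gives the raw estimate
    φ̂ = max(0, (s² − m̄)/m̄²).  Raw estimates are shrunk toward a fitted
    φ(μ) = a0/μ + a1 trend with weight n/(n + n0) on the data, floored at
    1e-8.  Genes with zero mean get the floor and a warning.
    """
    groups = meta.groups()
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"group {g} has < 2 replicates")
    factors = size_factors(counts)
    normed = counts.counts / factors[None, :]
    col_idx = {s: i for i, s in enumerate(counts.sample_ids)}

    n_total = 0
    ss = np.zeros(counts.n_genes)
    for g, ids in groups.items():
        cols = [col_idx[s] for s in ids]
        sub = normed[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_total += len(cols)
    pooled_var = ss / (n_total - len(groups))
    overall_mean = normed.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - overall_mean) / overall_mean**2
    raw = np.where(overall_mean > 0, np.maximum(raw, 0.0), 0.0)

    # trend fit: least squares of raw phi on (1/mu, 1), coefficients clipped >= 0
    ok = overall_mean > 0
    X = np.column_stack([1.0 / overall_mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    trend = np.where(ok, a0 / np.maximum(overall_mean, 1e-12) + a1, DISPERSION_FLOOR)

    w = n_total / (n_total + n0)
    shrunk = np.maximum(w * raw + (1 - w) * trend, DISPERSION_FLOOR)
    shrunk = np.where(ok, shrunk, DISPERSION_FLOOR)
    if (~ok).any():
        logger.warning("%d genes with zero mean set to floor dispersion", int((~ok).sum()))
    return pd.Series(shrunk, index=counts.gene_ids, name="dispersion")


@dataclass
class ContrastResult:
    """Per-gene Wald-test results for one group-pair contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # gene-indexed: log2fc, se, wald, pvalue, padj, mean_a, mean_b, dispersion, converged
    padj_threshold: float

    @property
    def significant(self) -> pd.Series:
        return (self.table["padj"] < self.padj_threshold) & self.table["converged"]

    def n_significant(self) -> int:
        return int(self.significant.sum())


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_wald_test(counts: CountMatrix, meta: SampleTable, contrast: tuple[str, str],
                 batch: bool = False, padj_threshold: float = 0.1,
                 dispersions: pd.Series | None = None,
                 all_factors: np.ndarray | None = None) -> ContrastResult:
    """NB GLM Wald test for one cross-type contrast within a sample subset.

    ``contrast`` names two values of the metadata ``cross_type`` column; the
    test runs on their samples only, with log size-factor offsets (size
    factors may be supplied from the full matrix via ``all_factors``),
    per-gene fixed dispersion and an optional batch fixed effect.  The Wald
    statistic is log2FC/SE with a standard-normal reference; adjusted
    p-values are BH across converged genes only.
    """
    a, b = contrast
    sub_meta = meta.frame[meta.frame["cross_type"].isin([a, b])]
    if sub_meta.empty or set(sub_meta["cross_type"]) != {a, b}:
        raise ValidationError(f"both contrast groups {contrast} must be present")
    sample_ids = list(sub_meta["sample_id"])
    sub = counts.subset_samples(sample_ids)

    if all_factors is not None:
        lookup = dict(zip(counts.sample_ids, np.asarray(all_factors, dtype=float)))
        factors = np.array([lookup[s] for s in sample_ids])
    else:
        factors = size_factors(sub)
    offset = np.log(factors)

    if dispersions is None:
        dispersions = estimate_dispersion(sub, meta.subset(sample_ids))
    phi = dispersions.reindex(sub.gene_ids).to_numpy()

    is_b = (sub_meta["cross_type"] == b).to_numpy().astype(float)
    design_cols = [np.ones(len(sample_ids)), is_b]
    if batch:
        batches = sub_meta["batch"].astype(str).to_numpy()
        levels = sorted(pd.unique(batches))
        for lev in levels[1:]:
            design_cols.append((batches == lev).astype(float))
    X = np.column_stack(design_cols)

    rows = []
    for gi, gene in enumerate(sub.gene_ids):
        y = sub.counts[gi, :]
        alpha = max(float(phi[gi]), DISPERSION_FLOOR)
        try:
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit(maxiter=100)
            converged = bool(fit.converged) and np.isfinite(fit.bse[1]) and fit.bse[1] > 0
        except Exception:  # noqa: BLE001 - any fit failure flags the gene
            fit, converged = None, False
        if converged:
            log2fc = float(fit.params[1]) / LN2
            se = float(fit.bse[1]) / LN2
            wald = log2fc / se
            pval = float(2 * norm.sf(abs(wald)))
            mu_a = float(np.exp(fit.params[0]))
            mu_b = float(np.exp(fit.params[0] + fit.params[1]))
        else:
            log2fc = se = wald = pval = np.nan
            mu_a = mu_b = np.nan
        rows.append(
            dict(
                gene_id=gene, log2fc=log2fc, se=se, wald=wald, pvalue=pval,
                mean_a=mu_a, mean_b=mu_b, dispersion=alpha, converged=converged,
            )
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    # BH across converged genes only: non-converged fits are excluded from m
    padj = np.full(len(table), np.nan)
    conv = table["converged"].to_numpy()
    if conv.any():
        padj[conv] = bh_adjust(table.loc[conv, "pvalue"].to_numpy())
    table["padj"] = padj
    n_failed = int((~conv).sum())
    if n_failed:
        logger.warning("%d gene fits did not converge for contrast %s", n_failed, contrast)
    return ContrastResult(contrast=(a, b), table=table, padj_threshold=padj_threshold)


def pairwise_contrasts(counts: CountMatrix, meta: SampleTable, time_point: int,
                       batch: bool = False, padj_threshold: float = 0.1
                       ) -> dict[frozenset, ContrastResult]:
    """All six cross-type contrasts at one time point, shared dispersions.

    Size factors and dispersions are estimated once on the time point's full
    sample set, matching the shared-gene-set convention of the proportion
    tests downstream.
    """
    sub_meta = meta.frame[meta.frame["time_point"] == time_point]
    if sub_meta.empty:
        raise ValidationError(f"no samples at time point {time_point}")
    sub = counts.subset_samples(list(sub_meta["sample_id"]))
    meta_t = meta.subset(sub.sample_ids)
    factors = size_factors(sub)
    disps = estimate_dispersion(sub, meta_t)
    crosses = sorted(pd.unique(sub_meta["cross_type"]))
    out: dict[frozenset, ContrastResult] = {}
    for i, a in enumerate(crosses):
        for b in crosses[i + 1:]:
            res = de_wald_test(
                sub, meta_t, (a, b), batch=batch, padj_threshold=padj_threshold,
                dispersions=disps, all_factors=factors,
            )
            out[frozenset((a, b))] = res
    return out


def proportion_chi2(count1: int, n1: int, count2: int, n2: int) -> tuple[float, float]:
    """Yates-corrected 2×2 chi-squared comparing two DE-gene proportions."""
    for c, n in ((count1, n1), (count2, n2)):
        if n <= 0 or not 0 <= c <= n:
            raise ValidationError("counts must satisfy 0 <= count <= n, n > 0")
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-squared undefined with a zero margin")
    chi2, p, _, _ = chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni per-test threshold alpha/m, exact and rounded to 3 decimals.

    Rounding is half away from zero, so 0.05/4 = 0.0125 reports as 0.013.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    exact = alpha / m
    rounded = float(np.floor(exact * 1000 + 0.5) / 1000)
    return exact, rounded
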