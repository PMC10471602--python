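"""Local Coefficient of Variation (LCV): expression-level-controlled variability.

Raw CVs confound variability with expression level (low counts are noisier),
so each gene's CV is ranked only against genes of similar average expression.
Per analysis group, genes are ordered by mean normalized expression and, for
each focal gene, a window of ``window_size`` genes centred on its rank
(clamped at the ends so every window has the same size) supplies the
competitors.  The focal CV's rank within the window, rescaled to [0, 100],
is the LCV score: 0 = least variable among peers, 100 = most variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata

from .datamodel import CountMatrix, SampleTable, ValidationError

logger = logging.getLogger("canalex")


@dataclass
class NormalizedMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray


@dataclass
class GroupStats:
    """Per gene × group replicate count, mean, sample SD and CV.

    CV is undefined (NaN) where the group mean is zero.
    """

    gene_ids: list[str]
    group_names: list[str]
    n: pd.DataFrame
    mean: pd.DataFrame
    sd: pd.DataFrame
    cv: pd.DataFrame


@dataclass
class LCVMatrix:
    """Gene × group LCV percentile scores in [0, 100]; NaN where CV undefined."""

    scores: pd.DataFrame  # genes × groups
    window_size: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def group_names(self) -> list[str]:
        return list(self.scores.columns)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median across reference genes of count/geometric
    mean.  Falls back to mean library-size scaling when no reference gene
    exists.
    """
    mat = counts.counts
    if mat.shape[1] < 2:
        raise ValidationError("size factors need >= 2 samples")
    if not mat.any():
        raise ValidationError("all-zero count matrix")
    ref = (mat > 0).all(axis=1)
    if ref.any():
        sub = mat[ref, :].astype(float)
        g = gmean(sub, axis=1)
        factors = np.median(sub / g[:, None], axis=0)
    else:
        logger.warning("no gene observed in all samples; using library-size fallback")
        lib = mat.sum(axis=0).astype(float)
        factors = lib / lib.mean()
    if (factors <= 0).any():
        raise ValidationError("non-positive size factor encountered")
    return factors


def normalize(counts: CountMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValidationError(
            f"expected {counts.n_samples} size factors, got {factors.shape}"
        )
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    values = counts.counts / factors[None, :]
    return NormalizedMatrix(
        list(counts.gene_ids), list(counts.sample_ids), values, factors
    )


def group_cv(norm: NormalizedMatrix, meta: SampleTable) -> GroupStats:
    """Replicate mean, SD (n−1 denominator) and CV per gene × group.

    Groups are cross_type × time_point with family replicates pooled.  Every
    group needs at least two replicates for a sample SD.
    """
    groups = meta.groups()
    col_idx = {s: i for i, s in enumerate(norm.sample_ids)}
    names, ns, means, sds = [], [], [], []
    for grp, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"group {grp} has {len(ids)} replicate(s); need >= 2")
        cols = [col_idx[s] for s in ids]
        sub = norm.values[:, cols]
        names.append(grp)
        ns.append(np.full(sub.shape[0], len(cols)))
        means.append(sub.mean(axis=1))
        sds.append(sub.std(axis=1, ddof=1))
    mean = pd.DataFrame(np.column_stack(means), index=norm.gene_ids, columns=names)
    sd = pd.DataFrame(np.column_stack(sds), index=norm.gene_ids, columns=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(mean > 0)  # zero-mean genes: CV undefined
    n = pd.DataFrame(np.column_stack(ns), index=norm.gene_ids, columns=names)
    return GroupStats(list(norm.gene_ids), names, n, mean, sd, cv)


def _window_bounds(rank: int, n: int, window: int) -> tuple[int, int]:
    """Clamped centred window of exactly ``window`` genes around ``rank``."""
    half = window // 2
    start = min(max(rank - half, 0), n - window)
    return start, start + window


def _lcv_one_group(mean: np.ndarray, cv: np.ndarray, gene_ids: list[str],
                   window_size: int) -> np.ndarray:
    defined = ~np.isnan(cv) & ~np.isnan(mean)
    out = np.full(mean.shape, np.nan)
    idx = np.flatnonzero(defined)
    n_def = idx.size
    if n_def < 2:
        raise ValidationError("fewer than 2 genes with defined CV in a group")
    window = window_size
    if n_def < window:
        logger.warning(
            "only %d defined genes; shrinking LCV window from %d", n_def, window
        )
        window = n_def
    # order by mean ascending, ties broken lexicographically by gene id
    ids = np.array(gene_ids, dtype=object)[idx]
    order = np.lexsort((ids, mean[idx]))
    ordered = idx[order]
    cvs = cv[ordered]
    for pos in range(n_def):
        lo, hi = _window_bounds(pos, n_def, window)
        ranks = rankdata(cvs[lo:hi], method="average")
        r = ranks[pos - lo]
        out[ordered[pos]] = 100.0 * (r - 1.0) / (window - 1.0)
    return out


def lcv_scores(stats: GroupStats, window_size: int) -> LCVMatrix:
    """Sliding-window CV percentile per gene × group.

    Within each group independently, the focal gene's CV is ranked (ascending,
    mean tied ranks) among the ``window_size`` genes nearest in mean
    expression, and rescaled as 100·(rank−1)/(window_size−1).  Genes with
    undefined CV are excluded from that group's ordering and scored NaN.
    """
    if window_size < 2:
        raise ValidationError("window_size must be >= 2")
    scores = {}
    for grp in stats.group_names:
        scores[grp] = _lcv_one_group(
            stats.mean[grp].to_numpy(),
            stats.cv[grp].to_numpy(),
            stats.gene_ids,
            window_size,
        )
    frame = pd.DataFrame(scores, index=stats.gene_ids)[stats.group_names]
    return LCVMatrix(scores=frame, window_size=window_size)


def lcv_pipeline(counts: CountMatrix, meta: SampleTable, window_size: int = 500
                 ) -> tuple[GroupStats, LCVMatrix]:
    """Normalize, compute group CVs, and score LCVs in one call."""
    factors = size_factors(counts)
    norm = normalize(counts, factors)
    stats = group_cv(norm, meta)
    return stats, lcv_scores(stats, window_size)
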