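"""Core data containers for the variability pipeline.

The pipeline analyses a reciprocal-cross design: two morphs (PL, planktivorous/
limnetic; SB, small benthic) crossed in all four maternal × paternal
combinations, sampled at two developmental time points (150 and 200 tau-somite
units).  A *group* throughout the pipeline is one cross-type at one time point,
giving eight groups in the full design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MORPHS = ("PL", "SB")
TIME_POINTS = (150, 200)
#: canonical cross-type order: maternal morph listed first
CROSS_TYPES = ("PLxPL", "PLxSB", "SBxPL", "SBxSB")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


def cross_type(maternal: str, paternal: str) -> str:
    return f"{maternal}x{paternal}"


def maternal_morph_of(cross: str) -> str:
    return cross.split("x")[0]


def group_label(cross: str, time_point: int) -> str:
    return f"{cross}-{time_point}"


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(self.counts != np.floor(self.counts))
                if bad.size:
                    g, s = bad[0]
                    raise ValidationError(
                        f"non-integer count at gene {self.gene_ids[g]!r}, "
                        f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
                    )
                raise ValidationError("counts are not integral")
            self.counts = as_int
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return CountMatrix(list(keep), list(self.sample_ids), self.counts[rows, :])

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return CountMatrix(list(self.gene_ids), list(keep), self.counts[:, cols])


@dataclass
class SampleTable:
    """Per-sample design metadata.

    Wraps a DataFrame with columns sample_id, maternal_morph, paternal_morph,
    time_point, family_id and optional batch; derives cross_type and the
    cross_type × time_point group label.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "maternal_morph", "paternal_morph", "time_point", "family_id")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
        for col in ("maternal_morph", "paternal_morph"):
            bad = set(df[col].astype(str)) - set(MORPHS)
            if bad:
                raise ValidationError(f"unknown morph code(s) in {col}: {sorted(bad)}")
            df[col] = df[col].astype(str)
        df["time_point"] = pd.to_numeric(df["time_point"], errors="coerce")
        if df["time_point"].isna().any() or not set(df["time_point"]) <= set(TIME_POINTS):
            bad = sorted(set(df["time_point"].dropna()) - set(TIME_POINTS))
            raise ValidationError(f"unknown time point(s): {bad or 'non-numeric'}")
        df["time_point"] = df["time_point"].astype(int)
        df["family_id"] = df["family_id"].astype(str)
        if "batch" not in df.columns:
            df["batch"] = pd.NA
        df["cross_type"] = [
            cross_type(m, p) for m, p in zip(df["maternal_morph"], df["paternal_morph"])
        ]
        df["group"] = [
            group_label(c, t) for c, t in zip(df["cross_type"], df["time_point"])
        ]
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> dict[str, list[str]]:
        """Sample ids per cross_type × time_point group, in canonical order."""
        out: dict[str, list[str]] = {}
        for t in TIME_POINTS:
            for c in CROSS_TYPES:
                lbl = group_label(c, t)
                ids = list(
                    self.frame.loc[self.frame["group"] == lbl, "sample_id"]
                )
                if ids:
                    out[lbl] = ids
        return out

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep)


@dataclass
class DesignSummary:
    """Replicate bookkeeping for the cross-type × time-point design."""

    group_sizes: dict[str, int]
    flagged: list[str]
    min_replicates: int

    @property
    def ok(self) -> bool:
        return not self.flagged


def validate_design(
    counts: CountMatrix,
    meta: SampleTable,
    min_replicates: int = 3,
    strict: bool = False,
) -> DesignSummary:
    """Check counts/metadata agreement and per-group replication.

    Every sample in the count matrix must have exactly one metadata row and
    vice versa (hard error).  Groups below ``min_replicates`` are flagged;
    with ``strict=True`` a flagged group is a hard error.  Any cross-type ×
    time-point combination absent from the design is an error: downstream
    inheritance classification needs all four cross-types.
    """
    count_samples = set(counts.sample_ids)
    meta_samples = set(meta.sample_ids)
    only_counts = sorted(count_samples - meta_samples)
    only_meta = sorted(meta_samples - count_samples)
    if only_counts or only_meta:
        raise ValidationError(
            f"sample/metadata mismatch: {only_counts} lack metadata, "
            f"{only_meta} lack counts"
        )
    groups = meta.groups()
    present_crosses = set(meta.frame["cross_type"])
    missing = [c for c in CROSS_TYPES if c not in present_crosses]
    if missing:
        raise ValidationError(f"design is missing cross-type group(s): {missing}")
    sizes = {g: len(ids) for g, ids in groups.items()}
    flagged = [g for g, n in sizes.items() if n < min_replicates]
    if strict and flagged:
        raise ValidationError(
            f"under-replicated group(s) below {min_replicates}: {flagged}"
        )
    return DesignSummary(group_sizes=sizes, flagged=flagged, min_replicates=min_replicates)


@dataclass
class MCMCSettings:
    """Gibbs-sampler run lengths and priors for the per-cluster linear model.

    Defaults follow the weakly informative residual-variance prior
    (inverse-gamma with V=1, nu=0.002) and an effectively flat Normal prior on
    the group means.  13,000 iterations with burn-in 3,000 and thinning 10
    retain exactly 1,000 draws.
    """

    iterations: int = 13_000
    thinning: int = 10
    burnin: int = 3_000
    prior_V: float = 1.0
    prior_nu: float = 0.002
    coef_prior_variance: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValidationError("burnin must be smaller than iterations")
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")
        if self.prior_V <= 0 or self.prior_nu <= 0 or self.coef_prior_variance <= 0:
            raise ValidationError("priors must be positive")
        if self.retained < 100:
            raise ValidationError(
                f"settings retain only {self.retained} draws; need >= 100"
            )

    @property
    def retained(self) -> int:
        return (self.iterations - self.burnin) // self.thinning


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings shared by the CLI and the library entry points."""

    window_size: int = 500
    n_clusters: int = 10
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    alpha: float = 0.05
    de_padj_threshold: float = 0.1
    min_total_reads: int = 10
    min_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValidationError("window_size must be >= 2")
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.de_padj_threshold < 1:
            raise ValidationError("de_padj_threshold must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisConfig":
        data = dict(data)
        mcmc = data.pop("mcmc", None)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        if mcmc is not None:
            cfg.mcmc = MCMCSettings(**mcmc)
        return cfg
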