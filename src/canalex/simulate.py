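"""Synthetic reciprocal-cross RNA-seq experiments with planted inheritance patterns.

The generator emulates the study design the pipeline targets: two pure-morph
crosses (PL×PL, SB×SB) and their reciprocal hybrids (PL×SB, SB×PL), sampled at
two developmental time points with nine replicates per cross-type per time
point (three families × three embryos), i.e. 72 samples.

Counts are negative binomial with variance mean + φ·mean², log-normal baseline
gene means and a decreasing dispersion–mean trend φ(μ) = a0/μ + a1.  Two
independent kinds of effects are planted per gene:

* **mean patterns** shift group means by a log2 fold change δ following the
  inheritance taxonomy (intermediate, maternal, morph-biased,
  over-/underdominant hybrids);
* **variability patterns** scale group dispersions by a ratio ρ following the
  same taxonomy, leaving means untouched — so the local-CV statistic, which
  controls for expression level, is the statistic that should detect them.

Each planted pattern comes in mirror-image variants (which morph carries the
high value; for transgressive variability, which hybrid and which direction).
Variants are recorded in the truth table so that recovery tests can form
parameter-homogeneous gene sets, and they balance the planted effects across
groups so no cross-type is systematically more variable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    CROSS_TYPES,
    TIME_POINTS,
    CountMatrix,
    SampleTable,
    ValidationError,
    group_label,
)

MEAN_PATTERNS = (
    "conserved",
    "maternal",
    "pl_biased",
    "sb_biased",
    "intermediate",
    "overdominant",
    "underdominant",
)
VAR_PATTERNS = ("conserved", "maternal", "pl_biased", "sb_biased", "transgressive")


def theoretical_cv(mu: float, phi: float) -> float:
    """Coefficient of variation of a negative binomial: sqrt(1/μ + φ).

    The Poisson term 1/μ vanishes at high expression, leaving sqrt(φ); at
    φ = 0 it reduces to the Poisson CV 1/sqrt(μ).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return float(np.sqrt(1.0 / mu + phi))


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters for the generator.

    Defaults are the conditions the pipeline is exercised under: 2,000 genes,
    the full 4 cross-types × 2 time points × 9 replicates design, planted
    log2 fold change δ = 2 and dispersion ratio ρ = 4, a log-normal baseline
    (natural-log mean 5 ≈ median 148 counts, SD 1) and trend φ = 3/μ + 0.05.
    """

    n_genes: int = 2000
    replicates_per_group: int = 9
    n_families: int = 3
    baseline_log_mean: tuple[float, float] = (5.0, 1.0)  # natural-log loc, scale
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.05
    delta: float = 2.0  # planted log2 fold change for mean patterns
    rho: float = 4.0  # planted dispersion ratio for variability patterns
    mean_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "maternal": 0.05,
            "pl_biased": 0.025,
            "sb_biased": 0.025,
            "intermediate": 0.05,
            "overdominant": 0.01,
            "underdominant": 0.01,
        }
    )
    var_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "maternal": 0.05,
            "pl_biased": 0.025,
            "sb_biased": 0.025,
            "transgressive": 0.05,
        }
    )
    library_size_spread: tuple[float, float] = (0.7, 1.4)
    time_effect_fraction: float = 0.3
    time_effect_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_group < 2:
            raise ValidationError("need >=1 gene and >=2 replicates per group")
        for name, frac in {**self.mean_fractions, **self.var_fractions}.items():
            if frac < 0:
                raise ValidationError(f"negative fraction for pattern {name!r}")
        if sum(self.mean_fractions.values()) > 1 or sum(self.var_fractions.values()) > 1:
            raise ValidationError("pattern fractions must sum to <= 1")
        unknown = set(self.mean_fractions) - set(MEAN_PATTERNS)
        unknown |= set(self.var_fractions) - set(VAR_PATTERNS)
        if unknown:
            raise ValidationError(f"unknown pattern name(s): {sorted(unknown)}")
        if self.rho <= 0:
            raise ValidationError("rho must be positive")
        if not np.isfinite(self.delta):
            raise ValidationError("delta must be finite")
        lo, hi = self.library_size_spread
        if not 0 < lo <= hi:
            raise ValidationError("library_size_spread must be positive and ordered")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValidationError("dispersion trend parameters must be non-negative")

    def dispersion_trend(self, mu: np.ndarray) -> np.ndarray:
        return self.dispersion_a0 / mu + self.dispersion_a1


@dataclass
class SimulationTruth:
    """Planted per-gene labels and per-group expected NB parameters.

    ``table`` has one row per gene with the planted mean pattern (+ its
    mirror-image ``mean_variant``), the planted variability pattern (+
    ``var_variant``), the signed effect sizes, and expected mean ``mu_<group>``
    and dispersion ``phi_<group>`` for each cross-type × time-point group.
    """

    table: pd.DataFrame
    group_names: list[str]

    def genes(self, var_pattern: str | None = None, mean_pattern: str | None = None,
              var_variant: str | None = None) -> list[str]:
        df = self.table
        if var_pattern is not None:
            df = df[df["var_pattern"] == var_pattern]
        if var_variant is not None:
            df = df[df["var_variant"] == var_variant]
        if mean_pattern is not None:
            df = df[df["mean_pattern"] == mean_pattern]
        return list(df["gene_id"])

    def expected_mu(self, gene: str, group: str) -> float:
        row = self.table.set_index("gene_id").loc[gene]
        return float(row[f"mu_{group}"])

    def expected_phi(self, gene: str, group: str) -> float:
        row = self.table.set_index("gene_id").loc[gene]
        return float(row[f"phi_{group}"])

    def var_variants(self) -> dict[str, list[str]]:
        """Gene sets per planted variability variant (evaluation clusters)."""
        out: dict[str, list[str]] = {}
        for variant, sub in self.table.groupby("var_variant", sort=True):
            out[str(variant)] = list(sub["gene_id"])
        return out


def _assign_patterns(rng: np.random.Generator, n_genes: int,
                     fractions: dict[str, float]) -> np.ndarray:
    """Assign one pattern label per gene by contiguous blocks of a permutation."""
    labels = np.array(["conserved"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    start = 0
    for name in sorted(fractions):
        k = int(round(fractions[name] * n_genes))
        labels[order[start:start + k]] = name
        start += k
    return labels


def _mean_multipliers(pattern: str, sign: int, delta: float) -> dict[str, float]:
    """Per-cross-type multiplicative shift of the baseline mean.

    ``sign``=+1 puts the high value on the SB pure cross (and mirrored for
    -1); hybrids follow the taxonomy.  Over/underdominance shifts both
    hybrids off equal pure-cross means.
    """
    half = 2.0 ** (sign * delta / 2.0)
    lo, hi = 1.0 / half, half  # PLxPL, SBxSB when sign=+1
    mult = {"PLxPL": lo, "SBxSB": hi}
    if pattern == "conserved":
        return {c: 1.0 for c in CROSS_TYPES}
    if pattern == "maternal":
        mult.update({"PLxSB": lo, "SBxPL": hi})
    elif pattern == "pl_biased":
        mult.update({"PLxSB": lo, "SBxPL": lo})
    elif pattern == "sb_biased":
        mult.update({"PLxSB": hi, "SBxPL": hi})
    elif pattern == "intermediate":
        mult.update({"PLxSB": 1.0, "SBxPL": 1.0})
    elif pattern == "overdominant":
        up = 2.0 ** abs(delta)
        mult = {"PLxPL": 1.0, "SBxSB": 1.0, "PLxSB": up, "SBxPL": up}
    elif pattern == "underdominant":
        down = 2.0 ** (-abs(delta))
        mult = {"PLxPL": 1.0, "SBxSB": 1.0, "PLxSB": down, "SBxPL": down}
    else:
        raise ValidationError(f"unknown mean pattern {pattern!r}")
    return mult


def _var_multipliers(pattern: str, variant_code: int, rho: float) -> tuple[dict[str, float], str]:
    """Per-cross-type dispersion scaling and the variant name recorded in truth.

    ``variant_code`` selects the mirror image: which morph carries the high
    dispersion, or (transgressive) which hybrid deviates and in which
    direction.
    """
    ones = {c: 1.0 for c in CROSS_TYPES}
    if pattern == "conserved":
        return ones, "conserved"
    if pattern == "maternal":
        if variant_code % 2 == 0:
            return {**ones, "SBxSB": rho, "SBxPL": rho}, "maternal_SBhigh"
        return {**ones, "PLxPL": rho, "PLxSB": rho}, "maternal_PLhigh"
    if pattern == "pl_biased":
        # hybrids share the PL pure cross's dispersion; the SB side deviates
        if variant_code % 2 == 0:
            return {**ones, "SBxSB": rho}, "pl_biased_SBhigh"
        return {c: rho for c in CROSS_TYPES} | {"SBxSB": 1.0}, "pl_biased_PLhigh"
    if pattern == "sb_biased":
        if variant_code % 2 == 0:
            return {**ones, "PLxPL": rho}, "sb_biased_PLhigh"
        return {c: rho for c in CROSS_TYPES} | {"PLxPL": 1.0}, "sb_biased_SBhigh"
    if pattern == "transgressive":
        hybrid = "PLxSB" if variant_code % 2 == 0 else "SBxPL"
        up = (variant_code // 2) % 2 == 0
        scale = rho if up else 1.0 / rho
        return {**ones, hybrid: scale}, f"transgressive_{hybrid}_{'up' if up else 'down'}"
    raise ValidationError(f"unknown variability pattern {pattern!r}")


EXPECTED_VARIABILITY_CALL = {
    "conserved": "CONSERVED",
    "maternal_SBhigh": "MATERNAL",
    "maternal_PLhigh": "MATERNAL",
    "pl_biased_SBhigh": "PL_BIASED",
    "pl_biased_PLhigh": "PL_BIASED",
    "sb_biased_PLhigh": "SB_BIASED",
    "sb_biased_SBhigh": "SB_BIASED",
    "transgressive_PLxSB_up": "TRANSGRESSIVE_VARIABILITY",
    "transgressive_PLxSB_down": "TRANSGRESSIVE_VARIABILITY",
    "transgressive_SBxPL_up": "TRANSGRESSIVE_VARIABILITY",
    "transgressive_SBxPL_down": "TRANSGRESSIVE_VARIABILITY",
}


def simulate_experiment(config: SimulationConfig) -> tuple[CountMatrix, SampleTable, SimulationTruth]:
    """Draw a full synthetic experiment and its ground truth.

    Counts for sample j in group k are NB with mean s_j · μ_gk and dispersion
    φ_gk, where s_j is a log-uniform library-size factor.  The truth table
    records exactly the parameters the draws used.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{str(i + 1).zfill(len(str(n)))}" for i in range(n)]

    loc, scale = config.baseline_log_mean
    base_mu = np.exp(rng.normal(loc, scale, size=n))

    mean_labels = _assign_patterns(rng, n, config.mean_fractions)
    var_labels = _assign_patterns(rng, n, config.var_fractions)
    mean_signs = rng.choice([-1, 1], size=n)
    var_codes = rng.integers(0, 4, size=n)

    # time-point effect: a global multiplicative shift of a gene fraction at 200
    time_shift = np.ones(n)
    affected = rng.random(n) < config.time_effect_fraction
    shift_sign = rng.choice([-1.0, 1.0], size=n)
    time_shift[affected] = 2.0 ** (shift_sign[affected] * config.time_effect_log2)

    groups = [group_label(c, t) for t in TIME_POINTS for c in CROSS_TYPES]
    mu = np.zeros((n, len(groups)))
    phi = np.zeros((n, len(groups)))
    var_variants = np.empty(n, dtype=object)
    for g in range(n):
        mmult = _mean_multipliers(mean_labels[g], int(mean_signs[g]), config.delta)
        vmult, variant = _var_multipliers(var_labels[g], int(var_codes[g]), config.rho)
        var_variants[g] = variant
        for j, grp in enumerate(groups):
            cross, t = grp.rsplit("-", 1)
            m = base_mu[g] * mmult[cross] * (time_shift[g] if int(t) == 200 else 1.0)
            mu[g, j] = m
            phi[g, j] = config.dispersion_trend(np.array([m]))[0] * vmult[cross]
    if not np.all(mu > 0) or not np.all(phi > 0):
        raise ValidationError("infeasible config: non-positive mean or dispersion")

    # sample layout: per group, replicates split evenly over families
    rows = []
    for t in TIME_POINTS:
        for cross in CROSS_TYPES:
            for r in range(config.replicates_per_group):
                fam = r % config.n_families + 1
                rows.append(
                    dict(
                        sample_id=f"{cross}_{t}_f{fam}_r{r + 1}",
                        maternal_morph=cross[:2],
                        paternal_morph=cross[3:],
                        time_point=t,
                        family_id=f"{cross}_fam{fam}",
                        batch="b1",
                    )
                )
    meta = SampleTable(pd.DataFrame(rows))
    n_samples = len(rows)

    lo, hi = config.library_size_spread
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    counts = np.zeros((n, n_samples), dtype=np.int64)
    group_of_sample = list(meta.frame["group"])
    for j, grp in enumerate(group_of_sample):
        k = groups.index(grp)
        m = mu[:, k] * size_factors[j]
        r_param = 1.0 / phi[:, k]
        p = r_param / (r_param + m)
        counts[:, j] = rng.negative_binomial(r_param, p)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_pattern": mean_labels,
            "mean_variant": [
                f"{lab}_{'SBhigh' if s > 0 else 'PLhigh'}" if lab not in
                ("conserved", "overdominant", "underdominant") else lab
                for lab, s in zip(mean_labels, mean_signs)
            ],
            "delta_log2": np.where(
                np.isin(mean_labels, ["conserved"]), 0.0, mean_signs * config.delta
            ),
            "var_pattern": var_labels,
            "var_variant": var_variants,
            "rho": np.where(np.isin(var_labels, ["conserved"]), 1.0, config.rho),
        }
    )
    for j, grp in enumerate(groups):
        truth[f"mu_{grp}"] = mu[:, j]
        truth[f"phi_{grp}"] = phi[:, j]

    counts_mat = CountMatrix(gene_ids, meta.sample_ids, counts)
    return counts_mat, meta, SimulationTruth(table=truth, group_names=groups)
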