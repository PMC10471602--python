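"""End-to-end convenience runs over the synthetic study design.

These helpers chain the pipeline stages the way an analysis would: simulate a
reciprocal-cross experiment, test differential expression and classify mean
inheritance, score LCVs, infer per-cluster posteriors and classify variability
inheritance, and summarize how well the planted patterns are recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import column_split, kmeans_cluster, order_for_heatmap
from .datamodel import MCMCSettings, maternal_morph_of
from .de import filter_low_counts, pairwise_contrasts
from .inference import infer_clusters
from .inheritance import calls_to_frame, classify_mean_inheritance, classify_variability_inheritance
from .lcv import lcv_pipeline
from .simulate import EXPECTED_VARIABILITY_CALL, SimulationConfig, simulate_experiment


@dataclass
class RecoveryReport:
    """Recovery of planted patterns on one synthetic experiment."""

    n_genes: int
    de_significant: dict[str, int]
    n_tested: int
    maternal_mean_recovery: float
    conserved_mean_recovery: float
    variability_cluster_accuracy: float
    variability_calls: dict[str, tuple[str, str]]  # variant -> (expected, observed)
    maternal_column_pairing: bool
    column_order: list[str] = field(default_factory=list)


def maternal_pairing_ok(split: dict[str, int]) -> bool:
    """True when a two-way column cut separates groups by maternal morph."""
    by_label: dict[int, set[str]] = {}
    for col, lab in split.items():
        cross = col.rsplit("-", 1)[0]
        by_label.setdefault(lab, set()).add(maternal_morph_of(cross))
    return len(by_label) == 2 and all(len(m) == 1 for m in by_label.values())


def run_recovery(config: SimulationConfig, time_point: int = 200,
                 window_size: int = 500, mcmc_seed: int = 1,
                 kmeans_k: int = 10) -> RecoveryReport:
    """Simulate, analyse, and compare calls against the planted truth.

    Mean-expression inheritance is classified per gene from the six pairwise
    Wald contrasts at ``time_point``.  Variability inheritance is classified
    per planted-pattern gene set (the truth table's clusters) from the Gibbs
    posteriors of their LCV scores across the four cross-types at
    ``time_point``; this isolates the inference-and-classification chain from
    k-means, which is exercised separately.  The heatmap column dendrogram is
    cut in two to check the maternal-morph pairing of the eight groups.
    """
    counts, meta, truth = simulate_experiment(config)
    filtered, _ = filter_low_counts(counts)
    results = pairwise_contrasts(filtered, meta, time_point)
    calls = calls_to_frame(classify_mean_inheritance(results)).set_index("target_id")
    tbl = truth.table.set_index("gene_id").loc[calls.index]

    def recovery(pattern: str, call: str) -> float:
        planted = tbl.index[tbl["mean_pattern"] == pattern]
        if not len(planted):
            return float("nan")
        return float((calls.loc[planted, "pattern"] == call).mean())

    de_sig = {
        "/".join(sorted(res.contrast)): res.n_significant()
        for res in results.values()
    }

    stats, scores = lcv_pipeline(counts, meta, window_size=window_size)
    frame = scores.scores[
        [c for c in scores.scores.columns if c.endswith(f"-{time_point}")]
    ].copy()
    frame.columns = [c.rsplit("-", 1)[0] for c in frame.columns]

    settings = MCMCSettings(seed=mcmc_seed)
    variability_calls: dict[str, tuple[str, str]] = {}
    correct = 0
    variants = truth.var_variants()
    for variant in sorted(variants):
        labels = {g: 1 for g in variants[variant]}
        summary, overlap = infer_clusters(frame, labels, settings)[1]
        observed = classify_variability_inheritance(summary, overlap).pattern
        expected = EXPECTED_VARIABILITY_CALL[variant]
        variability_calls[variant] = (expected, observed)
        correct += observed == expected

    assignment = kmeans_cluster(scores, k=kmeans_k, seed=config.seed)
    order = order_for_heatmap(scores, assignment)
    pairing = maternal_pairing_ok(column_split(order, 2))

    return RecoveryReport(
        n_genes=counts.n_genes,
        de_significant=de_sig,
        n_tested=len(calls),
        maternal_mean_recovery=recovery("maternal", "MATERNAL"),
        conserved_mean_recovery=recovery("conserved", "CONSERVED"),
        variability_cluster_accuracy=correct / len(variants),
        variability_calls=variability_calls,
        maternal_column_pairing=pairing,
        column_order=order.column_order,
    )
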