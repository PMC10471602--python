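"""Inheritance-pattern classification for mean expression and variability.

Reciprocal hybrids let maternal effects be separated from additive genetics:
PL×SB and SB×PL (maternal morph first) share nuclear genetics but differ in
maternal origin.  A gene's (or cluster's) value across the four cross-types is
classified by a deterministic rule cascade:

OVERDOMINANT / UNDERDOMINANT
    each hybrid significantly above (below) both pure crosses;
MATERNAL
    each hybrid indistinguishable from its maternal pure cross and distinct
    from the other pure cross, with the pure crosses distinct;
PL_BIASED / SB_BIASED
    both hybrids indistinguishable from one pure cross and distinct from the
    other, pure crosses distinct;
TRANSGRESSIVE_VARIABILITY (variability level only)
    a hybrid's credible interval disjoint from and entirely outside the span
    of both pure crosses' intervals, in either direction;
INTERMEDIATE
    pure crosses distinct, each hybrid distinct from both with its value
    strictly between them;
CONSERVED
    no significant pairwise difference at all;
AMBIGUOUS
    anything else.

For mean expression "significant" means a BH-adjusted Wald P below threshold;
for variability it means non-overlapping 95% HPD intervals.  The evidence
(flags, values) is returned with every call so the pattern can be re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .datamodel import ValidationError
from .de import ContrastResult
from .inference import PosteriorSummary

PURE_PL, PURE_SB = "PLxPL", "SBxSB"
HYB_PL, HYB_SB = "PLxSB", "SBxPL"  # maternal morph first
CROSSES = (PURE_PL, HYB_PL, HYB_SB, PURE_SB)

PATTERNS = (
    "INTERMEDIATE",
    "MATERNAL",
    "PL_BIASED",
    "SB_BIASED",
    "OVERDOMINANT",
    "UNDERDOMINANT",
    "TRANSGRESSIVE_VARIABILITY",
    "CONSERVED",
    "AMBIGUOUS",
)


@dataclass
class InheritanceCall:
    target_id: str
    level: str  # "mean_expression" or "variability"
    pattern: str
    evidence: dict = field(default_factory=dict)


def _pair(a: str, b: str) -> frozenset:
    return frozenset((a, b))


def classify_from_flags(sig: Mapping[frozenset, bool], value: Mapping[str, float],
                        transgressive: Mapping[str, bool] | None = None) -> str:
    """Apply the rule cascade to significance flags and point values.

    ``sig`` maps each unordered cross-type pair to a significance flag;
    ``value`` gives the per-cross-type point value (fitted mean or posterior
    mode); ``transgressive`` optionally flags hybrids whose interval lies
    outside the pure crosses' span (variability level only).
    """
    missing = [
        (a, b) for i, a in enumerate(CROSSES) for b in CROSSES[i + 1:]
        if _pair(a, b) not in sig
    ]
    if missing:
        raise ValidationError(f"missing contrast(s): {missing}")

    def s(a: str, b: str) -> bool:
        return bool(sig[_pair(a, b)])

    pures_distinct = s(PURE_PL, PURE_SB)
    lo = min(value[PURE_PL], value[PURE_SB])
    hi = max(value[PURE_PL], value[PURE_SB])

    def above(h: str) -> bool:
        return s(h, PURE_PL) and s(h, PURE_SB) and value[h] > hi

    def below(h: str) -> bool:
        return s(h, PURE_PL) and s(h, PURE_SB) and value[h] < lo

    if transgressive is None:  # over/underdominance only at the mean level
        if above(HYB_PL) and above(HYB_SB):
            return "OVERDOMINANT"
        if below(HYB_PL) and below(HYB_SB):
            return "UNDERDOMINANT"
    if (
        pures_distinct
        and not s(HYB_PL, PURE_PL) and s(HYB_PL, PURE_SB)
        and not s(HYB_SB, PURE_SB) and s(HYB_SB, PURE_PL)
    ):
        return "MATERNAL"
    if (
        pures_distinct
        and not s(HYB_PL, PURE_PL) and s(HYB_PL, PURE_SB)
        and not s(HYB_SB, PURE_PL) and s(HYB_SB, PURE_SB)
    ):
        return "PL_BIASED"
    if (
        pures_distinct
        and not s(HYB_PL, PURE_SB) and s(HYB_PL, PURE_PL)
        and not s(HYB_SB, PURE_SB) and s(HYB_SB, PURE_PL)
    ):
        return "SB_BIASED"
    if transgressive is not None and (
        transgressive.get(HYB_PL, False) or transgressive.get(HYB_SB, False)
    ):
        return "TRANSGRESSIVE_VARIABILITY"
    if (
        pures_distinct
        and s(HYB_PL, PURE_PL) and s(HYB_PL, PURE_SB) and lo < value[HYB_PL] < hi
        and s(HYB_SB, PURE_PL) and s(HYB_SB, PURE_SB) and lo < value[HYB_SB] < hi
    ):
        return "INTERMEDIATE"
    if not any(s(a, b) for i, a in enumerate(CROSSES) for b in CROSSES[i + 1:]):
        return "CONSERVED"
    return "AMBIGUOUS"


def classify_mean_inheritance(results: Mapping[frozenset, ContrastResult]
                              ) -> list[InheritanceCall]:
    """Classify each gene's mean-expression inheritance from the six contrasts.

    All six pairwise cross-type contrasts at one time point must be supplied.
    A gene is classified on its BH significance flags and fitted group means;
    genes with any non-converged contrast are AMBIGUOUS with the failure
    recorded as evidence.
    """
    needed = [
        _pair(a, b) for i, a in enumerate(CROSSES) for b in CROSSES[i + 1:]
    ]
    missing = [sorted(p) for p in needed if p not in results]
    if missing:
        raise ValidationError(f"missing contrast result(s): {missing}")
    genes = results[needed[0]].table.index
    for p in needed:
        if not results[p].table.index.equals(genes):
            raise ValidationError("contrast results cover different gene sets")

    calls: list[InheritanceCall] = []
    sig_frames = {p: results[p].significant for p in needed}
    conv_frames = {p: results[p].table["converged"] for p in needed}
    # fitted means per cross: average over the contrasts involving that cross
    fitted: dict[str, pd.Series] = {}
    for cross in CROSSES:
        acc = []
        for p, res in results.items():
            a, b = res.contrast
            if a == cross:
                acc.append(res.table["mean_a"])
            elif b == cross:
                acc.append(res.table["mean_b"])
        fitted[cross] = sum(acc) / len(acc)

    for gene in genes:
        if not all(conv_frames[p].loc[gene] for p in needed):
            calls.append(
                InheritanceCall(gene, "mean_expression", "AMBIGUOUS",
                                {"non_converged": True})
            )
            continue
        sig = {p: bool(sig_frames[p].loc[gene]) for p in needed}
        value = {c: float(fitted[c].loc[gene]) for c in CROSSES}
        pattern = classify_from_flags(sig, value)
        calls.append(
            InheritanceCall(
                gene, "mean_expression", pattern,
                {"sig": {"/".join(sorted(p)): v for p, v in sig.items()},
                 "fitted_means": value},
            )
        )
    return calls


def classify_variability_inheritance(summary: PosteriorSummary,
                                     overlaps: pd.DataFrame) -> InheritanceCall:
    """Classify one cluster's variability inheritance from HPD overlaps.

    Significance = non-overlapping 95% HPD intervals; point values are the
    posterior modes.  Transgressive hybrids are those whose interval is
    disjoint from, and entirely outside the span of, both pure crosses'.
    """
    have = set(summary.group_names)
    if not set(CROSSES) <= have:
        raise ValidationError(
            f"summary must cover all four cross-types; has {sorted(have)}"
        )
    sig = {}
    for i, a in enumerate(CROSSES):
        for b in CROSSES[i + 1:]:
            sig[_pair(a, b)] = not bool(overlaps.loc[a, b])
    value = {c: summary.mode(c) for c in CROSSES}
    span_lo = min(summary.interval(PURE_PL)[0], summary.interval(PURE_SB)[0])
    span_hi = max(summary.interval(PURE_PL)[1], summary.interval(PURE_SB)[1])
    transgressive = {}
    for h in (HYB_PL, HYB_SB):
        lo, hi = summary.interval(h)
        transgressive[h] = bool(lo > span_hi or hi < span_lo)
    pattern = classify_from_flags(sig, value, transgressive)
    return InheritanceCall(
        str(summary.cluster_id), "variability", pattern,
        {"modes": value,
         "intervals": {c: summary.interval(c) for c in CROSSES},
         "transgressive": transgressive},
    )


def calls_to_frame(calls: list[InheritanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(target_id=c.target_id, level=c.level, pattern=c.pattern) for c in calls]
    )
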