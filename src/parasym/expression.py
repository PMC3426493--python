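"""Spatio-temporal expression-divergence scoring between duplicate copies.

Per developmental stage shared by both copies, the overlap of their
anatomical expression domains is the Jaccard index of the two term sets;
stages where either gene is annotated to the whole organism (ubiquitous
expression) are excluded. Asymmetrically evolving pairs are compared to
non-asymmetric pairs by a one-sided rank-sum test on stage-level overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .seqio import ExpressionProfile, ParasymError

DEFAULT_UBIQUITOUS_TERM = "whole organism"


@dataclass(frozen=True)
class StageOverlap:
    pair_id: str
    stage: str
    jaccard: float


def stage_overlap(
    p1: ExpressionProfile,
    p2: ExpressionProfile,
    pair_id: str | None = None,
    ubiquitous_term: str = DEFAULT_UBIQUITOUS_TERM,
) -> list[StageOverlap]:
    """Jaccard overlap of anatomy-term sets for every developmental stage
    annotated in both profiles, excluding stages where either gene shows
    ubiquitous (whole-organism) expression."""
    if not p1.stages or not p2.stages:
        raise ParasymError("profiles must be non-empty")
    pid = pair_id or f"{p1.gene_id}~{p2.gene_id}"
    out = []
    for stage in sorted(set(p1.stages) & set(p2.stages)):
        t1, t2 = p1.stages[stage], p2.stages[stage]
        if ubiquitous_term in t1 or ubiquitous_term in t2:
            continue
        out.append(StageOverlap(pid, stage, len(t1 & t2) / len(t1 | t2)))
    if not out:
        warnings.warn(f"{pid}: no shared non-ubiquitous stages", stacklevel=2)
    return out


def divergence_compare(
    asym_overlaps: list[StageOverlap] | list[float],
    nonasym_overlaps: list[StageOverlap] | list[float],
) -> tuple[float, float]:
    """One-sided rank-sum test: do asymmetrically evolving pairs show
    lower stage-level expression overlap than non-asymmetric pairs?
    Returns (U statistic, p)."""

    def values(group):
        return [o.jaccard if isinstance(o, StageOverlap) else float(o) for o in group]

    a, b = values(asym_overlaps), values(nonasym_overlaps)
    if not a or not b:
        raise ParasymError("both groups must be non-empty")
    method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
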