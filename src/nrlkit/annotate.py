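"""Interval intersection utilities: TAD overlap classification, quintile-wise
feature enrichment, and strand-oriented flank read counting.

All overlap predicates use 0-based half-open coordinates and require at least
1 bp of intersection (touching intervals do not overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicInterval
from .motif import AnchorSite

logger = logging.getLogger("nrlkit")

COMMON_THRESHOLD = 0.90
LOST_GAINED_THRESHOLD = 0.80


@dataclass
class TadClassification:
    """A TAD labelled by its fractional coverage in the other cell type's TAD
    set: common (> 0.90), lost/gained (< 0.80, direction-dependent) or other
    (the [0.80, 0.90] gap the thresholds leave open)."""

    tad: GenomicInterval
    overlap_rate: float
    label: str


def _tree_per_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_rate(
    tad: GenomicInterval, others: Sequence[GenomicInterval]
) -> float:
    """Fraction of the TAD covered by the union of the other intervals.

    The numerator is union-based, so abutting or overlapping pieces are never
    double counted; the denominator is the query TAD's own length.
    """
    pieces = sorted(
        (max(tad.start, iv.start), min(tad.end, iv.end))
        for iv in others
        if iv.chrom == tad.chrom and iv.start < tad.end and iv.end > tad.start
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in pieces:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / len(tad)


def _classify_one(
    tad: GenomicInterval,
    trees: dict[str, IntervalTree],
    low_label: str,
) -> TadClassification:
    tree = trees.get(tad.chrom)
    hits = (
        [iv.data for iv in tree.overlap(tad.start, tad.end)] if tree else []
    )
    rate = overlap_rate(tad, hits)
    if rate > COMMON_THRESHOLD:
        label = "common"
    elif rate < LOST_GAINED_THRESHOLD:
        label = low_label
    else:
        label = "other"
    return TadClassification(tad=tad, overlap_rate=rate, label=label)


def classify_tads(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> tuple[list[TadClassification], list[TadClassification]]:
    """Classify two TAD sets against each other (e.g. before and after
    differentiation).

    A TAD of ``set_a`` is common when its coverage by ``set_b`` exceeds 0.90
    and lost when it is below 0.80; a TAD of ``set_b`` is common or gained by
    the mirrored rule; coverage in [0.80, 0.90] is labelled other.  Returns
    (classifications of A, classifications of B).
    """
    trees_a = _tree_per_chrom(set_a)
    trees_b = _tree_per_chrom(set_b)
    a_out = [_classify_one(tad, trees_b, "lost") for tad in set_a]
    b_out = [_classify_one(tad, trees_a, "gained") for tad in set_b]
    return a_out, b_out


def quintile_enrichment(
    sites: Sequence[AnchorSite],
    feature: Sequence[GenomicInterval],
    n_groups: int = 5,
) -> dict[int, float | None]:
    """Per-quintile fraction of sites overlapping the feature by >= 1 bp.

    All sites must carry quintile labels; an empty quintile reports None.
    The overlap predicate uses the full site interval, not just its centre.
    """
    for s in sites:
        if s.quintile is None:
            raise ValueError("all sites must carry quintile labels")
    trees = _tree_per_chrom(feature)
    totals = {q: 0 for q in range(1, n_groups + 1)}
    hits = {q: 0 for q in range(1, n_groups + 1)}
    for s in sites:
        totals[s.quintile] += 1
        tree = trees.get(s.chrom)
        if tree and tree.overlap(s.interval.start, s.interval.end):
            hits[s.quintile] += 1
    return {
        q: (hits[q] / totals[q] if totals[q] else None)
        for q in range(1, n_groups + 1)
    }


def count_reads_flanks(
    reads: Sequence[GenomicInterval],
    anchors: Sequence[AnchorSite],
    up_window: tuple[int, int] = (-1000, 0),
    down_window: tuple[int, int] = (0, 1000),
) -> list[tuple[int, int]]:
    """Per-anchor read counts in the strand-oriented up- and downstream
    flanks.

    A read counts in a flank iff it overlaps the oriented window by at least
    1 bp (half-open semantics: a read ending exactly at the window start does
    not count); reads straddling the anchor may count in both flanks.
    """
    trees = _tree_per_chrom(reads)
    out = []
    for anchor in anchors:
        tree = trees.get(anchor.chrom)
        counts = []
        for rel in (up_window, down_window):
            if anchor.strand == "-":
                lo, hi = anchor.centre - rel[1], anchor.centre - rel[0]
            else:
                lo, hi = anchor.centre + rel[0], anchor.centre + rel[1]
            counts.append(len(tree.overlap(lo, hi)) if tree else 0)
        out.append((counts[0], counts[1]))
    return out
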