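"""Count non-coding elements overlapping a block set.

An element counts when it shares at least ``min_overlap_bp`` base pairs
(default 1) with at least one block — partial and total overlaps alike.  An
element overlapping several blocks counts once, and duplicate annotations of
the same element (same class, id and coordinates from different source
studies) are removed before counting.  Counts are per element class across
the whole block set, matching the genome-wide totals of the report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import ELEMENT_CLASSES, AnnotationElement
from .ld_blocks import LdBlock

__all__ = ["OverlapResult", "dedupe_elements", "overlap_blocks",
           "count_table"]


@dataclass
class OverlapResult:
    """Observed overlap statistic: per-class counts and element lists."""

    counts: dict[str, int]
    elements: dict[str, list[AnnotationElement]]
    blocks_evaluated: int
    total_block_length_bp: int

    @property
    def mean_block_length_bp(self) -> float | None:
        if self.blocks_evaluated == 0:
            return None
        return self.total_block_length_bp / self.blocks_evaluated


def dedupe_elements(elements) -> list[AnnotationElement]:
    """Drop redundant annotations (same redundancy key), keeping first seen."""
    seen = set()
    out = []
    for e in elements:
        if e.key not in seen:
            seen.add(e.key)
            out.append(e)
    return out


def overlap_blocks(blocks: list[LdBlock], elements,
                   min_overlap_bp: int = 1) -> OverlapResult:
    """Count deduplicated elements overlapping any block by >= min_overlap_bp."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for b in blocks:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end)
    counts = {c: 0 for c in ELEMENT_CLASSES}
    hits: dict[str, list[AnnotationElement]] = {c: [] for c in ELEMENT_CLASSES}
    for e in dedupe_elements(elements):
        tree = trees.get(e.chrom)
        if tree is None:
            continue
        best = 0
        for iv in tree.overlap(e.start, e.end):
            best = max(best, min(iv.end, e.end) - max(iv.begin, e.start))
            if best >= min_overlap_bp:
                break
        if best >= min_overlap_bp:
            counts[e.element_class] = counts.get(e.element_class, 0) + 1
            hits.setdefault(e.element_class, []).append(e)
    return OverlapResult(
        counts=counts,
        elements=hits,
        blocks_evaluated=len(blocks),
        total_block_length_bp=sum(b.length_bp for b in blocks))


def count_table(result: OverlapResult) -> pd.Series:
    """One report row: block stats plus per-class element counts."""
    mean_kb = result.mean_block_length_bp
    return pd.Series({
        "n_blocks": result.blocks_evaluated,
        "mean_block_kb": (None if mean_kb is None else mean_kb / 1e3),
        "total_mb": result.total_block_length_bp / 1e6,
        "n_lncRNA": result.counts.get("lncRNA", 0),
        "n_circRNA": result.counts.get("circRNA", 0),
        "n_miRNA": result.counts.get("miRNA", 0),
        "n_SE": result.counts.get("SE", 0),
    })
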