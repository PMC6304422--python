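"""Assign disease-associated SNPs to LD blocks and extract the block set.

A SNP is inside a block iff ``block.start <= pos0 < block.end`` on the same
chromosome, where ``pos0`` is the SNP's 0-based position.  Because blocks
store ``end = most-3'-member-position + 1``, both border SNPs of a block
count as inside.  Two disease SNPs landing in the same block collapse to a
single block in the analysis set (with a warning), so downstream overlap
counts never double-count a block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import SnpRecord, chrom_sort_key
from .ld_blocks import LdBlock

__all__ = ["SnpBlockAssignment", "assign_snps_to_blocks", "unique_block_set"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpBlockAssignment:
    snp_id: str
    block: LdBlock | None
    status: str  # "assigned" | "unassigned"


class _BlockIndex:
    """Binary-searchable per-chromosome index over non-overlapping blocks."""

    def __init__(self, blocks):
        self.blocks = list(blocks)
        per_chrom: dict[str, list[int]] = {}
        for i, b in enumerate(self.blocks):
            per_chrom.setdefault(b.chrom, []).append(i)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, idxs in per_chrom.items():
            idxs.sort(key=lambda i: self.blocks[i].start)
            starts = np.array([self.blocks[i].start for i in idxs])
            ends = np.array([self.blocks[i].end for i in idxs])
            if np.any(ends[:-1] > starts[1:]):
                j = int(np.argmax(ends[:-1] > starts[1:]))
                a, b = self.blocks[idxs[j]], self.blocks[idxs[j + 1]]
                raise ValueError(
                    f"overlapping blocks on chr{chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})")
            self._index[chrom] = (starts, ends, np.array(idxs))

    def lookup(self, chrom: str, pos0: int) -> int:
        """Index of the containing block, or -1."""
        entry = self._index.get(chrom)
        if entry is None:
            return -1
        starts, ends, idxs = entry
        j = int(np.searchsorted(starts, pos0, side="right")) - 1
        if j >= 0 and pos0 < ends[j]:
            return int(idxs[j])
        return -1


def assign_snps_to_blocks(snps: list[SnpRecord],
                          blocks: list[LdBlock]) -> list[SnpBlockAssignment]:
    """Map each SNP to the (unique) block containing its position.

    ``blocks`` must be non-overlapping within each chromosome (the
    block-calling contract); overlap raises ``ValueError``.  SNPs covered by
    no block are returned with status ``unassigned``.
    """
    index = _BlockIndex(blocks)
    out = []
    for s in snps:
        i = index.lookup(s.chrom, s.pos0)
        if i < 0:
            out.append(SnpBlockAssignment(s.snp_id, None, "unassigned"))
        else:
            out.append(SnpBlockAssignment(s.snp_id, index.blocks[i],
                                          "assigned"))
    return out


def unique_block_set(assignments: list[SnpBlockAssignment]) -> list[LdBlock]:
    """Deduplicated blocks carrying at least one assigned SNP.

    Order follows the first occurrence; a block harboring more than one
    SNP is logged as a warning and kept once.
    """
    seen: dict[tuple, int] = {}
    out: list[LdBlock] = []
    for a in assignments:
        if a.block is None:
            continue
        key = (a.block.chrom, a.block.start, a.block.end)
        if key in seen:
            seen[key] += 1
            logger.warning(
                "block chr%s:%d-%d harbors %d disease SNPs; counted once",
                a.block.chrom, a.block.start, a.block.end, seen[key])
        else:
            seen[key] = 1
            out.append(a.block)
    return out
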