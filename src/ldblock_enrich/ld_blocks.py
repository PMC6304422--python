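"""Pairwise LD from unphased genotypes and Gabriel-style haplotype blocks.

The estimation chain is the one behind Haploview's (and Plink's
``--blocks``) default block definition:

1. For every SNP pair within a window (default 200 kb), the four two-locus
   haplotype frequencies are estimated from unphased diploid dosages by EM
   over the double-heterozygote phase ambiguity.
2. Lewontin's D' = |D| / D_max summarizes the pair, and a 90% confidence
   interval on |D'| is obtained by profiling the multinomial genotype
   likelihood over a D' grid (marginal allele frequencies held at their
   MLEs) and trimming 5% of posterior-style mass from each tail.
3. Pairs are classified as "strong LD" (CI lower bound >= 0.70 and upper
   bound >= 0.98) or "strong evidence of recombination" (upper bound
   < 0.90); a candidate block [i..j] whose endpoint pair is in strong LD is
   accepted when strong-LD pairs make up >= 95% of the classified pairs it
   spans.  Overlapping candidates are resolved greedily, largest span first.

Everything here is deterministic: no randomness enters the module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io_formats import SnpRecord, chrom_sort_key, normalize_chrom

__all__ = [
    "MISSING",
    "UninformativePairError",
    "PairwiseLd",
    "LdBlock",
    "BlockCallingParams",
    "GenotypeMatrix",
    "pair_counts",
    "em_haplotype_freqs",
    "dprime",
    "dprime_ci",
    "pairwise_ld",
    "call_blocks",
    "block_summary",
    "BlockSummary",
]

#: sentinel for a missing genotype call
MISSING = -1


class UninformativePairError(ValueError):
    """A locus pair carries no LD information (monomorphic, low MAF, ...)."""


@dataclass(frozen=True)
class PairwiseLd:
    """Two-locus haplotype frequencies with D, D' and (optionally) its CI.

    ``A``/``B`` denote the dosage-coded allele at the first/second locus, so
    ``p_AB`` is the frequency of the haplotype carrying both coded alleles.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    D: float
    Dprime: float
    n_obs: int
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def freqs(self) -> tuple[float, float, float, float]:
        return (self.p_AB, self.p_Ab, self.p_aB, self.p_ab)


@dataclass(frozen=True)
class LdBlock:
    """A haplotype block: member SNPs plus the genomic interval they span.

    The interval is 0-based half-open with ``start`` at the most-5' member
    SNP and ``end`` one past the most-3' member SNP, so both border SNPs lie
    inside the block under half-open containment.
    """

    chrom: str
    snp_ids: tuple[str, ...]
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if len(self.snp_ids) == 1:
            raise ValueError("a block needs >= 2 member SNPs "
                             "(or none, for externally supplied intervals)")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid block interval {self.chrom}:"
                             f"{self.start}-{self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class BlockCallingParams:
    """Gabriel/Haploview block-calling thresholds (Haploview defaults)."""

    max_window_bp: int = 200_000
    strong_ld_ci_low: float = 0.70
    strong_ld_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    inform_frac: float = 0.95
    min_maf: float = 0.05
    ci_grid_step: float = 0.01
    ci_mass_tail: float = 0.05

    def __post_init__(self):
        for name in ("strong_ld_ci_low", "strong_ld_ci_high",
                     "recomb_ci_high", "inform_frac", "min_maf"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_window_bp <= 0:
            raise ValueError("max_window_bp must be positive")


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Unphased diploid genotypes as coded-allele dosages in {0, 1, 2, -1}.

    ``calls`` is an ``(n_samples, n_snps)`` int8 array, ``-1`` marking a
    missing call.  SNPs must be grouped by chromosome and strictly
    position-sorted within each chromosome.
    """

    def __init__(self, samples: Sequence[str], snps: Sequence[SnpRecord],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(snps)):
            raise ValueError(f"calls shape {calls.shape} does not match "
                             f"{len(samples)} samples x {len(snps)} SNPs")
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2} or -1 "
                             "for missing")
        seen: set[str] = set()
        prev_chrom, prev_pos = None, None
        for s in snps:
            if s.chrom != prev_chrom:
                if s.chrom in seen:
                    raise ValueError("SNPs must be grouped by chromosome")
                seen.add(s.chrom)
                prev_chrom, prev_pos = s.chrom, s.pos
            else:
                if s.pos <= prev_pos:
                    raise ValueError(
                        f"SNP positions must be strictly increasing within "
                        f"a chromosome (chr{s.chrom}:{s.pos})")
                prev_pos = s.pos
        self.samples = list(samples)
        self.snps = list(snps)
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @classmethod
    def from_vcf(cls, path, autosomes_only: bool = True) -> "GenotypeMatrix":
        """Load dosages from a VCF; multi-allelic sites are skipped."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        lut = np.array([0, 1, MISSING, 2], dtype=np.int8)
        entries = []
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            chrom = normalize_chrom(v.CHROM)
            if autosomes_only and not chrom.isdigit():
                continue
            snp_id = v.ID or f"{chrom}:{v.POS}"
            entries.append((SnpRecord(snp_id, chrom, v.POS),
                            lut[np.asarray(v.gt_types)]))
        vcf.close()
        entries.sort(key=lambda e: (chrom_sort_key(e[0].chrom), e[0].pos))
        snps = [e[0] for e in entries]
        calls = (np.stack([e[1] for e in entries], axis=1) if entries
                 else np.empty((len(samples), 0), dtype=np.int8))
        return cls(samples, snps, calls)

    @classmethod
    def from_dosage_table(cls, path) -> "GenotypeMatrix":
        """Read the tab-text dosage dialect written by :meth:`to_dosage_table`.

        Header ``snp_id  chrom  pos  <sample...>``; one row per SNP; values
        0/1/2 or NA.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.columns.size < 4:
            raise ValueError(f"{path}: dosage table needs snp_id/chrom/pos "
                             "plus at least one sample column")
        samples = list(df.columns[3:])
        rows = []
        for r in df.itertuples(index=False):
            snp = SnpRecord(str(r[0]), str(r[1]), int(r[2]))
            vals = np.array([MISSING if v in ("NA", ".", "", None) else int(v)
                             for v in r[3:]], dtype=np.int8)
            rows.append((snp, vals))
        rows.sort(key=lambda e: (chrom_sort_key(e[0].chrom), e[0].pos))
        snps = [e[0] for e in rows]
        calls = (np.stack([e[1] for e in rows], axis=1) if rows
                 else np.empty((len(samples), 0), dtype=np.int8))
        return cls(samples, snps, calls)

    def to_dosage_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_id\tchrom\tpos\t" + "\t".join(self.samples) + "\n")
            for j, s in enumerate(self.snps):
                vals = ["NA" if v == MISSING else str(int(v))
                        for v in self.calls[:, j]]
                fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t" +
                         "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------

def pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype table over samples complete at both loci."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    ok = (g1 >= 0) & (g2 >= 0)
    return np.bincount(g1[ok] * 3 + g2[ok],
                       minlength=9).reshape(3, 3).astype(np.int64)


def _marginals(counts: np.ndarray):
    n = counts.sum()
    if n == 0:
        raise UninformativePairError("no samples complete at both loci")
    i = np.arange(3)
    pA = float((counts.sum(axis=1) * i).sum()) / (2 * n)
    pB = float((counts.sum(axis=0) * i).sum()) / (2 * n)
    return n, pA, pB


def _em_from_counts(counts: np.ndarray, tol: float = 1e-9,
                    max_iter: int = 1000):
    """EM for (p_ab, p_aB, p_Ab, p_AB) indexed [00, 01, 10, 11]."""
    n, pA, pB = _marginals(counts)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise UninformativePairError("monomorphic locus")
    N = counts
    base00 = 2 * N[0, 0] + N[0, 1] + N[1, 0]
    base01 = 2 * N[0, 2] + N[0, 1] + N[1, 2]
    base10 = 2 * N[2, 0] + N[1, 0] + N[2, 1]
    base11 = 2 * N[2, 2] + N[2, 1] + N[1, 2]
    ndh = N[1, 1]
    # start from linkage equilibrium
    p00, p01, p10, p11 = ((1 - pA) * (1 - pB), (1 - pA) * pB,
                          pA * (1 - pB), pA * pB)
    for _ in range(max_iter):
        denom = p11 * p00 + p10 * p01
        w = 0.5 if denom <= 0 else p11 * p00 / denom
        q00 = (base00 + ndh * w) / (2 * n)
        q01 = (base01 + ndh * (1 - w)) / (2 * n)
        q10 = (base10 + ndh * (1 - w)) / (2 * n)
        q11 = (base11 + ndh * w) / (2 * n)
        delta = max(abs(q00 - p00), abs(q01 - p01),
                    abs(q10 - p10), abs(q11 - p11))
        p00, p01, p10, p11 = q00, q01, q10, q11
        if delta < tol:
            break
    return (p00, p01, p10, p11), n


def em_haplotype_freqs(g1, g2, tol: float = 1e-9,
                       max_iter: int = 1000) -> PairwiseLd:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Samples missing at either locus are excluded pairwise.  Raises
    :class:`UninformativePairError` for monomorphic loci.
    """
    (p00, p01, p10, p11), n = _em_from_counts(pair_counts(g1, g2),
                                              tol=tol, max_iter=max_iter)
    D, dp = _d_and_dprime(p00, p01, p10, p11)
    return PairwiseLd(p_AB=p11, p_Ab=p10, p_aB=p01, p_ab=p00,
                      D=D, Dprime=dp, n_obs=int(n))


def _d_and_dprime(p00, p01, p10, p11):
    pA = p10 + p11
    pB = p01 + p11
    D = p11 - pA * pB
    if D == 0:
        return 0.0, 0.0
    if min(pA, 1 - pA) <= 0 or min(pB, 1 - pB) <= 0:
        raise UninformativePairError("degenerate marginal allele frequency")
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return float(D), float(min(abs(D) / dmax, 1.0))


def dprime(freqs) -> float:
    """Lewontin's D' = |D| / D_max for a haplotype-frequency quadruple.

    ``freqs`` is a :class:`PairwiseLd` or an ``(p_AB, p_Ab, p_aB, p_ab)``
    tuple.
    """
    if isinstance(freqs, PairwiseLd):
        p11, p10, p01, p00 = freqs.freqs
    else:
        p11, p10, p01, p00 = freqs
    return _d_and_dprime(p00, p01, p10, p11)[1]


# mapping from ordered haplotype pairs to genotype cells; haplotype k has
# allele (k >> 1) at locus 1 and (k & 1) at locus 2
_H_A = np.array([0, 0, 1, 1])
_H_B = np.array([0, 1, 0, 1])


def _genotype_probs(p: np.ndarray) -> np.ndarray:
    """(G, 4) haplotype freqs [p00, p01, p10, p11] -> (G, 3, 3) genotype probs."""
    P = np.zeros(p.shape[:-1] + (3, 3))
    for h in range(4):
        for k in range(4):
            i = _H_A[h] + _H_A[k]
            j = _H_B[h] + _H_B[k]
            P[..., i, j] += p[..., h] * p[..., k]
    return P


def dprime_ci(counts, grid_step: float = 0.01,
              mass_tail: float = 0.05) -> tuple[float, float]:
    """90% (by default) likelihood-based confidence bounds on |D'|.

    The multinomial genotype likelihood is profiled over
    ``D' in {0, grid_step, ..., 1}`` with haplotype frequencies
    parameterized by D' (sign taken from the MLE, marginals fixed at their
    MLEs), normalized to unit mass; the bounds trim ``mass_tail`` from each
    end, following the approach of the software the block definition comes
    from.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n, pA, pB = _marginals(counts)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise UninformativePairError("monomorphic locus")
    (p00, p01, p10, p11), _ = _em_from_counts(counts)
    Dhat = p11 - pA * pB
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    if Dhat >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        D = grid * dmax
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        D = -grid * dmax
    hap = np.stack([(1 - pA) * (1 - pB) + D,
                    (1 - pA) * pB - D,
                    pA * (1 - pB) - D,
                    pA * pB + D], axis=-1)
    hap = np.clip(hap, 0.0, 1.0)
    P = _genotype_probs(hap)  # (G, 3, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), -np.inf)
        # cells with zero counts contribute nothing (avoid 0 * -inf)
        contrib = np.where(counts[None, :, :] > 0,
                           counts[None, :, :] * logP, 0.0)
    ll = contrib.sum(axis=(1, 2))
    finite = np.isfinite(ll)
    if not finite.any():
        raise UninformativePairError("likelihood vanishes on the whole grid")
    ll = np.where(finite, ll, -np.inf)
    w = np.exp(ll - ll.max())
    mass = w / w.sum()
    cdf = np.cumsum(mass)
    eps = 1e-12
    lo_idx = int(np.argmax(cdf >= mass_tail - eps))
    upper = 1.0 - cdf + mass  # upper-tail mass including the grid point
    hi_idx = len(grid) - 1 - int(np.argmax((upper >= mass_tail - eps)[::-1]))
    return float(grid[lo_idx]), float(grid[hi_idx])


def pairwise_ld(g1, g2, grid_step: float = 0.01,
                mass_tail: float = 0.05) -> PairwiseLd:
    """Full pairwise-LD record: EM frequencies, D, D' and the |D'| CI."""
    counts = pair_counts(g1, g2)
    (p00, p01, p10, p11), n = _em_from_counts(counts)
    D, dp = _d_and_dprime(p00, p01, p10, p11)
    lo, hi = dprime_ci(counts, grid_step=grid_step, mass_tail=mass_tail)
    return PairwiseLd(p_AB=p11, p_Ab=p10, p_aB=p01, p_ab=p00, D=D,
                      Dprime=dp, n_obs=int(n), ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# Block calling
# ---------------------------------------------------------------------------

def _informative_mask(calls: np.ndarray, min_maf: float) -> np.ndarray:
    mask = np.zeros(calls.shape[1], dtype=bool)
    for j in range(calls.shape[1]):
        col = calls[:, j]
        ok = col >= 0
        n = int(ok.sum())
        if n == 0:
            continue
        p = float(col[ok].sum()) / (2 * n)
        if min(p, 1 - p) >= min_maf and 0 < p < 1:
            mask[j] = True
    return mask


def call_blocks(matrix: GenotypeMatrix,
                params: BlockCallingParams | None = None) -> list[LdBlock]:
    """Call haplotype blocks with the confidence-interval (Gabriel) criteria.

    Returns non-overlapping blocks sorted by chromosome and position; no
    block spans more than ``params.max_window_bp``.
    """
    params = params or BlockCallingParams()
    blocks: list[LdBlock] = []
    # chromosome runs (matrix validated them contiguous)
    runs: list[tuple[str, int, int]] = []
    for j, s in enumerate(matrix.snps):
        if runs and runs[-1][0] == s.chrom:
            runs[-1] = (s.chrom, runs[-1][1], j + 1)
        else:
            runs.append((s.chrom, j, j + 1))
    for chrom, lo, hi in runs:
        calls = matrix.calls[:, lo:hi]
        snps = matrix.snps[lo:hi]
        m = hi - lo
        if m < 2:
            continue
        pos = np.array([s.pos for s in snps], dtype=np.int64)
        inform = _informative_mask(calls, params.min_maf)
        strong = np.zeros((m, m), dtype=bool)
        classified = np.zeros((m, m), dtype=bool)
        for a in range(m):
            if not inform[a]:
                continue
            for b in range(a + 1, m):
                if pos[b] - pos[a] > params.max_window_bp:
                    break
                if not inform[b]:
                    continue
                counts = pair_counts(calls[:, a], calls[:, b])
                try:
                    lo_ci, hi_ci = dprime_ci(counts,
                                             grid_step=params.ci_grid_step,
                                             mass_tail=params.ci_mass_tail)
                except UninformativePairError:
                    continue
                if (lo_ci >= params.strong_ld_ci_low
                        and hi_ci >= params.strong_ld_ci_high):
                    strong[a, b] = True
                    classified[a, b] = True
                elif hi_ci < params.recomb_ci_high:
                    classified[a, b] = True
        # candidate spans: endpoint pair in strong LD
        cand = []
        for a, b in zip(*np.nonzero(strong)):
            s_cnt = int(strong[a:b + 1, a:b + 1].sum())
            c_cnt = int(classified[a:b + 1, a:b + 1].sum())
            if c_cnt and s_cnt / c_cnt >= params.inform_frac:
                cand.append((int(pos[b] - pos[a]), int(a), int(b)))
        cand.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, dtype=bool)
        for span, a, b in cand:
            if used[a:b + 1].any():
                continue
            used[a:b + 1] = True
            blocks.append(LdBlock(
                chrom=chrom,
                snp_ids=tuple(s.snp_id for s in snps[a:b + 1]),
                start=int(pos[a]) - 1,
                end=int(pos[b])))
    blocks.sort(key=lambda blk: (chrom_sort_key(blk.chrom), blk.start))
    return blocks


class BlockSummary(NamedTuple):
    count: int
    mean_bp: float | None
    min_bp: int | None
    max_bp: int | None


def block_summary(blocks: Iterable[LdBlock]) -> BlockSummary:
    """Count and span statistics (bp) over a block set; lengths are end-start."""
    lengths = [b.length_bp for b in blocks]
    if not lengths:
        return BlockSummary(0, None, None, None)
    return BlockSummary(len(lengths), float(np.mean(lengths)),
                        int(min(lengths)), int(max(lengths)))
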