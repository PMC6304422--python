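"""Matched bootstrap enrichment test with Davison–Hinkley empirical p-values.

The question: do the LD blocks harboring disease-associated GWAS top hits
contain more non-coding elements (lncRNAs, circRNAs, miRNAs,
super-enhancers) than expected by chance?  The null is built by resampling:
random SNPs are drawn from the genotyping-array manifest — stratified so the
intronic fraction mirrors the disease list, avoiding the HLA region and
chromosome X — mapped to their LD blocks, and the per-class element counts
over those blocks recorded.  Two matching modes exist:

* ``match_snp_count`` (Random set I): draw a fixed number of SNPs per
  iteration, yielding a similar number of blocks;
* ``match_total_length`` (Random set II): keep drawing SNPs until the unique
  block territory reaches the disease set's total length.

With ``r`` the number of iterations whose null count meets or exceeds the
observed count (ties count against enrichment) out of ``n`` iterations, the
empirical p-value is the Davison–Hinkley estimator ``(r + 1) / (n + 1)``,
bounded below by ``1 / (n + 1)``.  P-values are reported per class,
unadjusted, exactly as the report tables print them.

The public surface follows the statsmodels idiom: build an
:class:`EnrichmentModel` from data, call :meth:`~EnrichmentModel.fit`, and
read estimates off the returned :class:`EnrichmentResults` (or print
``results.summary()``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation_overlap import OverlapResult, dedupe_elements, overlap_blocks
from .block_mapping import _BlockIndex, assign_snps_to_blocks, unique_block_set
from .io_formats import ELEMENT_CLASSES, GenomicInterval, SnpRecord
from .ld_blocks import LdBlock

__all__ = [
    "NullConstraints",
    "StratumExhaustedError",
    "EnrichmentModel",
    "EnrichmentResults",
    "empirical_pvalue",
    "sample_random_snps",
    "build_null_iteration",
    "run_enrichment",
    "iteration_rng",
    "DEFAULT_HLA_REGION",
]

#: hg19-convention HLA exclusion interval (chromosome 6 MHC cluster)
DEFAULT_HLA_REGION = GenomicInterval("6", 25_000_000, 35_000_000)

MODES = ("match_snp_count", "match_total_length")


class StratumExhaustedError(RuntimeError):
    """A stratified draw asked for more SNPs than the stratum holds."""


@dataclass(frozen=True)
class NullConstraints:
    """Constraints shaping the matched null SNP draws.

    Exactly one of ``n_snps`` (mode ``match_snp_count``) or
    ``target_length_bp`` (mode ``match_total_length``) must be set.
    ``length_tolerance_bp`` (mode II only) defaults to 5% of the target:
    drawing stops at the first SNP whose block pushes the cumulative unique
    block length past ``target - tolerance``.
    """

    mode: str
    n_snps: int | None = None
    target_length_bp: int | None = None
    intronic_fraction: float = 0.5
    excluded_regions: tuple[GenomicInterval, ...] = (DEFAULT_HLA_REGION,)
    excluded_chroms: frozenset[str] = frozenset({"X"})
    length_tolerance_bp: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "match_snp_count":
            if self.n_snps is None or self.target_length_bp is not None:
                raise ValueError("mode match_snp_count requires n_snps "
                                 "(and no target_length_bp)")
            if self.n_snps < 1:
                raise ValueError("n_snps must be >= 1")
        else:
            if self.target_length_bp is None or self.n_snps is not None:
                raise ValueError("mode match_total_length requires "
                                 "target_length_bp (and no n_snps)")
            if self.target_length_bp < 1:
                raise ValueError("target_length_bp must be >= 1")
        if not (0 <= self.intronic_fraction <= 1):
            raise ValueError("intronic_fraction must be in [0, 1]")
        object.__setattr__(self, "excluded_regions",
                           tuple(self.excluded_regions))
        object.__setattr__(self, "excluded_chroms",
                           frozenset(self.excluded_chroms))

    @property
    def tolerance_bp(self) -> int:
        if self.mode != "match_total_length":
            return 0
        if self.length_tolerance_bp is not None:
            return self.length_tolerance_bp
        return int(round(0.05 * self.target_length_bp))


def empirical_pvalue(r: int, n: int) -> float:
    """Davison–Hinkley empirical p-value ``(r + 1) / (n + 1)``.

    ``r`` is the number of resamples whose statistic equals or exceeds the
    observed value out of ``n`` resamples.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    if not (0 <= r <= n):
        raise ValueError(f"exceedance count r={r} outside [0, n={n}]")
    return (r + 1) / (n + 1)


def iteration_rng(seed: int, i: int) -> np.random.Generator:
    """Deterministic per-iteration RNG substream (order-independent)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(i),)))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class _NullSampler:
    """Stratified, exclusion-aware sampler over manifest SNP indices."""

    def __init__(self, manifest: Sequence[SnpRecord],
                 constraints: NullConstraints):
        self.manifest = list(manifest)
        excl_by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in constraints.excluded_regions:
            excl_by_chrom.setdefault(r.chrom, []).append(r)
        intronic, extragenic = [], []
        for i, s in enumerate(self.manifest):
            if s.chrom in constraints.excluded_chroms:
                continue
            if any(iv.contains_pos(s.pos0)
                   for iv in excl_by_chrom.get(s.chrom, ())):
                continue
            if s.category == "intronic":
                intronic.append(i)
            elif s.category == "extragenic":
                extragenic.append(i)
        self.intronic = np.array(intronic, dtype=np.int64)
        self.extragenic = np.array(extragenic, dtype=np.int64)
        self.fraction = constraints.intronic_fraction
        if self.intronic.size + self.extragenic.size == 0:
            raise StratumExhaustedError(
                "no eligible manifest SNPs outside the excluded regions")

    def draw_fixed(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """k manifest indices: round(fraction*k) intronic, rest extragenic."""
        n_int = int(round(self.fraction * k))
        n_ext = k - n_int
        if n_int > self.intronic.size:
            raise StratumExhaustedError(
                f"intronic stratum exhausted (need {n_int}, "
                f"have {self.intronic.size})")
        if n_ext > self.extragenic.size:
            raise StratumExhaustedError(
                f"extragenic stratum exhausted (need {n_ext}, "
                f"have {self.extragenic.size})")
        return np.concatenate([
            rng.choice(self.intronic, size=n_int, replace=False),
            rng.choice(self.extragenic, size=n_ext, replace=False)])

    def draw_stream(self, rng: np.random.Generator):
        """Yield indices one at a time, keeping the running intronic share
        as close as possible to the target fraction; stops when both strata
        are exhausted."""
        pool_int = rng.permutation(self.intronic)
        pool_ext = rng.permutation(self.extragenic)
        i = e = 0
        t = 0
        while i < pool_int.size or e < pool_ext.size:
            want_int = i < round(self.fraction * (t + 1))
            if (want_int and i < pool_int.size) or e >= pool_ext.size:
                yield int(pool_int[i])
                i += 1
            else:
                yield int(pool_ext[e])
                e += 1
            t += 1


def sample_random_snps(manifest: Sequence[SnpRecord],
                       constraints: NullConstraints,
                       rng, k: int | None = None) -> list[SnpRecord]:
    """One stratified uniform draw (without replacement) of random SNPs.

    ``rng`` is a seed or Generator; ``k`` defaults to ``constraints.n_snps``.
    SNPs inside excluded regions or on excluded chromosomes are never drawn.
    """
    rng = _as_rng(rng)
    if k is None:
        if constraints.n_snps is None:
            raise ValueError("k is required when constraints carry no n_snps")
        k = constraints.n_snps
    sampler = _NullSampler(manifest, constraints)
    idx = sampler.draw_fixed(k, rng)
    return [sampler.manifest[i] for i in idx]


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class EnrichmentModel:
    """Annotation-enrichment model for a disease SNP set over LD blocks.

    Parameters
    ----------
    disease_snps
        GWAS top hits (1-based positions).  May be omitted when ``observed``
        is supplied directly or only :meth:`calibrate` is needed.
    manifest
        Array manifest SNPs (the null sampling universe), each carrying an
        intronic/extragenic category.
    blocks
        Genome-wide LD blocks (non-overlapping per chromosome).
    tracks
        Mapping element class -> annotation elements.
    constraints
        Null-matching constraints; when ``None``, mode I with
        ``n_snps = len(disease_snps)`` and the intronic fraction observed in
        the disease list.
    observed
        Pre-computed :class:`~.annotation_overlap.OverlapResult` for the
        disease block set (skips the internal mapping/overlap pass).
    """

    def __init__(self, disease_snps=None, *, manifest, blocks, tracks,
                 constraints: NullConstraints | None = None,
                 observed: OverlapResult | None = None,
                 min_overlap_bp: int = 1):
        self.manifest = list(manifest)
        self.blocks = list(blocks)
        self.tracks = {c: dedupe_elements(v) for c, v in tracks.items()}
        self.classes = [c for c in ELEMENT_CLASSES if c in self.tracks]
        self.min_overlap_bp = min_overlap_bp
        self.disease_snps = None if disease_snps is None else list(disease_snps)

        self._block_index = _BlockIndex(self.blocks)  # validates non-overlap

        # observed statistic
        self.assignments = None
        self.disease_blocks = None
        if observed is not None:
            self.observed_result = observed
        elif self.disease_snps is not None:
            self.assignments = assign_snps_to_blocks(self.disease_snps,
                                                     self.blocks)
            self.disease_blocks = unique_block_set(self.assignments)
            all_elements = [e for c in self.classes for e in self.tracks[c]]
            self.observed_result = overlap_blocks(
                self.disease_blocks, all_elements,
                min_overlap_bp=min_overlap_bp)
        else:
            self.observed_result = None

        if constraints is None:
            if self.disease_snps is None:
                raise ValueError("constraints are required when no disease "
                                 "SNP list is supplied")
            constraints = NullConstraints(
                mode="match_snp_count",
                n_snps=len(self.disease_snps),
                intronic_fraction=_intronic_fraction(self.disease_snps))
        self.constraints = constraints
        self.sampler = _NullSampler(self.manifest, constraints)

        # --- fast-path precomputation -----------------------------------
        # manifest SNP -> block id
        self._snp2block = np.array(
            [self._block_index.lookup(s.chrom, s.pos0) for s in self.manifest],
            dtype=np.int64)
        self._block_len = np.array([b.length_bp for b in self.blocks],
                                   dtype=np.int64)
        # per block, per class: indices of overlapping elements (CSR layout)
        from intervaltree import IntervalTree
        self._elem_csr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in self.classes:
            tree: dict[str, IntervalTree] = {}
            for j, e in enumerate(self.tracks[c]):
                tree.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end,
                                                              j)
            indptr = np.zeros(len(self.blocks) + 1, dtype=np.int64)
            chunks = []
            for i, b in enumerate(self.blocks):
                t = tree.get(b.chrom)
                if t is None:
                    hit = ()
                else:
                    hit = sorted(
                        iv.data for iv in t.overlap(b.start, b.end)
                        if min(iv.end, b.end) - max(iv.begin, b.start)
                        >= min_overlap_bp)
                chunks.append(np.asarray(hit, dtype=np.int64))
                indptr[i + 1] = indptr[i] + len(hit)
            data = (np.concatenate(chunks) if chunks
                    else np.empty(0, dtype=np.int64))
            self._elem_csr[c] = (indptr, data)

    # -- null machinery ---------------------------------------------------

    def _null_block_ids(self, rng: np.random.Generator) -> np.ndarray:
        c = self.constraints
        if c.mode == "match_snp_count":
            idx = self.sampler.draw_fixed(c.n_snps, rng)
            b = self._snp2block[idx]
            return np.unique(b[b >= 0])
        # match_total_length: stratified stream until territory is reached
        target = c.target_length_bp - c.tolerance_bp
        seen = set()
        total = 0
        for i in self.sampler.draw_stream(rng):
            b = int(self._snp2block[i])
            if b < 0 or b in seen:
                continue
            seen.add(b)
            total += int(self._block_len[b])
            if total >= target:
                return np.fromiter(seen, dtype=np.int64, count=len(seen))
        raise StratumExhaustedError(
            f"manifest exhausted at {total} bp of unique block length; "
            f"cannot reach target {c.target_length_bp} bp")

    def _counts_for_blocks(self, block_ids: np.ndarray) -> dict[str, int]:
        out = {}
        for c in self.classes:
            indptr, data = self._elem_csr[c]
            if block_ids.size == 0:
                out[c] = 0
                continue
            parts = [data[indptr[b]:indptr[b + 1]] for b in block_ids]
            merged = np.concatenate(parts) if parts else data[:0]
            out[c] = int(np.unique(merged).size)
        return out

    def null_iteration(self, rng) -> dict[str, int]:
        """One null draw -> per-class element counts (fast path)."""
        rng = _as_rng(rng)
        return self._counts_for_blocks(self._null_block_ids(rng))

    # -- fitting ----------------------------------------------------------

    def fit(self, n_iterations: int = 1000, seed: int | None = None,
            progress=None) -> "EnrichmentResults":
        """Run the bootstrap and return an :class:`EnrichmentResults`.

        Fully reproducible from ``seed``: iteration ``i`` uses the
        deterministic substream ``iteration_rng(seed, i)``, so results do
        not depend on execution order.
        """
        if self.observed_result is None:
            raise ValueError("model has no observed statistic; supply "
                             "disease_snps or observed at construction")
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2 ** 31))
        observed = {c: self.observed_result.counts.get(c, 0)
                    for c in self.classes}
        null_counts = {c: np.empty(n_iterations, dtype=np.int64)
                       for c in self.classes}
        null_n_blocks = np.empty(n_iterations, dtype=np.int64)
        null_total_bp = np.empty(n_iterations, dtype=np.int64)
        for i in range(n_iterations):
            rng = iteration_rng(seed, i)
            bids = self._null_block_ids(rng)
            counts = self._counts_for_blocks(bids)
            for c in self.classes:
                null_counts[c][i] = counts[c]
            null_n_blocks[i] = bids.size
            null_total_bp[i] = int(self._block_len[bids].sum())
            if progress is not None and (i + 1) % 100 == 0:
                progress(i + 1, n_iterations)
        r = {c: int((null_counts[c] >= observed[c]).sum())
             for c in self.classes}
        obs_res = self.observed_result
        return EnrichmentResults(
            classes=list(self.classes),
            observed=observed,
            null_counts=null_counts,
            r=r,
            n_iterations=n_iterations,
            exceed_pct={c: 100.0 * r[c] / n_iterations for c in self.classes},
            p_value={c: empirical_pvalue(r[c], n_iterations)
                     for c in self.classes},
            null_mean={c: float(null_counts[c].mean()) for c in self.classes},
            null_sd={c: float(null_counts[c].std(ddof=1))
                     if n_iterations > 1 else 0.0 for c in self.classes},
            seed=int(seed),
            observed_n_blocks=obs_res.blocks_evaluated,
            observed_total_bp=obs_res.total_block_length_bp,
            null_n_blocks=null_n_blocks,
            null_total_bp=null_total_bp,
        )

    # -- diagnostics ------------------------------------------------------

    def calibrate(self, n_replicates: int, n_iterations: int,
                  seed: int) -> dict[str, np.ndarray]:
        """Type-I calibration: p-values for pseudo-observed sets drawn from
        the null itself.

        For each replicate a pseudo disease set is drawn with the same
        matched sampler, its per-class counts taken as "observed", and a
        fresh ``n_iterations``-draw null compared against it.  With no real
        enrichment the returned p-values should be (sub)uniform.
        """
        ps = {c: np.empty(n_replicates) for c in self.classes}
        for rep in range(n_replicates):
            obs_rng = np.random.default_rng(np.random.SeedSequence(
                entropy=int(seed), spawn_key=(1, rep, 0)))
            observed = self._counts_for_blocks(self._null_block_ids(obs_rng))
            r = {c: 0 for c in self.classes}
            for i in range(n_iterations):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=int(seed), spawn_key=(1, rep, i + 1)))
                counts = self._counts_for_blocks(self._null_block_ids(rng))
                for c in self.classes:
                    if counts[c] >= observed[c]:
                        r[c] += 1
            for c in self.classes:
                ps[c][rep] = empirical_pvalue(r[c], n_iterations)
        return ps


def _intronic_fraction(snps: Iterable[SnpRecord]) -> float:
    n_int = sum(1 for s in snps if s.category == "intronic")
    n_ext = sum(1 for s in snps if s.category == "extragenic")
    if n_int + n_ext == 0:
        return 0.5
    return n_int / (n_int + n_ext)


@dataclass
class EnrichmentResults:
    """Estimates, null distribution and diagnostics from a bootstrap run."""

    classes: list[str]
    observed: dict[str, int]
    null_counts: dict[str, np.ndarray]
    r: dict[str, int]
    n_iterations: int
    exceed_pct: dict[str, float]
    p_value: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    seed: int
    observed_n_blocks: int
    observed_total_bp: int
    null_n_blocks: np.ndarray
    null_total_bp: np.ndarray

    def summary(self) -> str:
        """Report-table-shaped text summary (one column per element class)."""
        import pandas as pd

        def fmt_p(p):
            return f"{p:.1e}" if p < 0.001 else f"{p:.3f}"

        nb = self.null_n_blocks
        tb = self.null_total_bp / 1e6
        mean_kb = np.where(nb > 0, self.null_total_bp / np.maximum(nb, 1)
                           / 1e3, 0.0)
        obs_mean_kb = (self.observed_total_bp / self.observed_n_blocks / 1e3
                       if self.observed_n_blocks else 0.0)
        cols = ["n_blocks", "block_kb", "dna_mb"] + self.classes
        rows = {
            "observed": [self.observed_n_blocks, f"{obs_mean_kb:.1f}",
                         f"{self.observed_total_bp / 1e6:.1f}"] +
                        [self.observed[c] for c in self.classes],
            "null_mean": [f"{nb.mean():.1f}", f"{mean_kb.mean():.1f}",
                          f"{tb.mean():.1f}"] +
                         [f"{self.null_mean[c]:.1f}" for c in self.classes],
            "null_sd": [f"{nb.std(ddof=1):.1f}", f"{mean_kb.std(ddof=1):.1f}",
                        f"{tb.std(ddof=1):.1f}"] +
                       [f"{self.null_sd[c]:.1f}" for c in self.classes],
            "exceed_pct": ["-", "-", "-"] +
                          [f"{self.exceed_pct[c]:.1f}" for c in self.classes],
            "p_value": ["-", "-", "-"] +
                       [fmt_p(self.p_value[c]) for c in self.classes],
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        header = (f"Enrichment bootstrap: {self.n_iterations} iterations, "
                  f"seed {self.seed}\n")
        return header + df.to_string()

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "observed": self.observed,
            "null_counts": {c: self.null_counts[c].tolist()
                            for c in self.classes},
            "r": self.r,
            "n_iterations": self.n_iterations,
            "exceed_pct": self.exceed_pct,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
            "observed_n_blocks": self.observed_n_blocks,
            "observed_total_bp": self.observed_total_bp,
            "null_n_blocks": self.null_n_blocks.tolist(),
            "null_total_bp": self.null_total_bp.tolist(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    def plot_null(self, element_class: str, ax=None, bins: int = 30):
        """Histogram of the null counts with the observed count marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_counts[element_class], bins=bins, color="steelblue",
                alpha=0.8)
        ax.axvline(self.observed[element_class], color="firebrick",
                   label=f"observed = {self.observed[element_class]}")
        ax.set_xlabel(f"{element_class} count per null iteration")
        ax.set_ylabel("iterations")
        ax.legend()
        return ax


def build_null_iteration(manifest, blocks_all, tracks,
                         constraints: NullConstraints,
                         rng) -> dict[str, int]:
    """One null iteration through the reference (slow) path.

    Draws random SNPs, maps them to blocks via
    :func:`~.block_mapping.assign_snps_to_blocks`, deduplicates, overlaps
    with every track and returns per-class counts.  Uses the same draw
    sequence as :meth:`EnrichmentModel.null_iteration`, so the two paths can
    be cross-checked against each other.
    """
    rng = _as_rng(rng)
    sampler = _NullSampler(manifest, constraints)
    classes = [c for c in ELEMENT_CLASSES if c in tracks]
    if constraints.mode == "match_snp_count":
        idx = sampler.draw_fixed(constraints.n_snps, rng)
        snps = [sampler.manifest[i] for i in idx]
        blocks = unique_block_set(assign_snps_to_blocks(snps, blocks_all))
    else:
        index = _BlockIndex(blocks_all)
        target = constraints.target_length_bp - constraints.tolerance_bp
        seen: dict[tuple, LdBlock] = {}
        total = 0
        for i in sampler.draw_stream(rng):
            s = sampler.manifest[i]
            b = index.lookup(s.chrom, s.pos0)
            if b < 0:
                continue
            blk = index.blocks[b]
            key = (blk.chrom, blk.start, blk.end)
            if key in seen:
                continue
            seen[key] = blk
            total += blk.length_bp
            if total >= target:
                break
        else:
            raise StratumExhaustedError(
                f"manifest exhausted at {total} bp; cannot reach "
                f"{constraints.target_length_bp} bp")
        blocks = list(seen.values())
    out = {}
    for c in classes:
        res = overlap_blocks(blocks, tracks[c])
        out[c] = res.counts.get(c, 0)
    return out


def run_enrichment(observed_result: OverlapResult, manifest, blocks_all,
                   tracks, constraints: NullConstraints,
                   n_iterations: int = 1000,
                   seed: int | None = None) -> EnrichmentResults:
    """Functional entry point: bootstrap against a pre-computed observed
    statistic (thin wrapper over :class:`EnrichmentModel`)."""
    model = EnrichmentModel(manifest=manifest, blocks=blocks_all,
                            tracks=tracks, constraints=constraints,
                            observed=observed_result)
    return model.fit(n_iterations=n_iterations, seed=seed)
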