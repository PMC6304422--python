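"""Readers and writers for every external format the pipeline touches.

This module is the single home for coordinate-convention normalization.
Internally every interval is **0-based half-open** ``[start, end)`` and every
SNP position is **1-based** (as printed in array manifests and GWAS tables).
Conversion happens only at the I/O boundary:

========================  =========================  =======================
format                    file convention            normalization
========================  =========================  =======================
BED3/BED4                 0-based half-open          none
GTF (GENCODE dialect)     1-based inclusive          ``start - 1``
GFF3 (miRBase dialect)    1-based inclusive          ``start - 1``
circbase_tab              0-based half-open          none
SNP manifest / SNP lists  1-based positions          kept 1-based
========================  =========================  =======================

Chromosome labels are normalized by stripping a leading ``chr`` prefix
(``chr17`` and ``17`` are the same chromosome); only autosomes 1-22 survive
manifest reading, mirroring the exclusion of chromosome X from the LD
analysis.

The ``circbase_tab`` dialect is fixed here as tab-separated columns
``chrom  start(0-based)  end  circRNA_id  gene_symbol  [source]``, with an
optional header line.  circBase exports vary between studies; any other
layout should be converted to this one (a one-line ``awk`` reshuffle).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AUTOSOMES",
    "ELEMENT_CLASSES",
    "FormatError",
    "SnpRecord",
    "AnnotationElement",
    "GenomicInterval",
    "normalize_chrom",
    "chrom_sort_key",
    "read_snp_manifest",
    "read_annotation_track",
    "read_blocks_bed",
    "write_bed",
    "write_blocks_details",
    "write_snp_manifest",
    "write_gtf",
    "write_gff3",
    "write_circbase_tab",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: canonical element classes, in report-column order
ELEMENT_CLASSES = ("lncRNA", "circRNA", "miRNA", "SE")

_CATEGORIES = ("intronic", "extragenic", "other")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def normalize_chrom(label: object) -> str:
    """Return the canonical chromosome label (no ``chr`` prefix).

    ``chr17`` -> ``17``; ``chrX`` -> ``X``; labels are stripped of
    surrounding whitespace but otherwise preserved.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise FormatError("empty chromosome label")
    return s


def chrom_sort_key(label: str):
    """Sort numerically for autosomes, lexically afterwards (X, Y, MT...)."""
    c = normalize_chrom(label)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class SnpRecord:
    """One array/GWAS SNP: identifier, 1-based position and manifest category."""

    snp_id: str
    chrom: str
    pos: int
    category: str = "other"

    def __post_init__(self):
        if not self.snp_id:
            raise FormatError("snp_id must be non-empty")
        if self.pos < 1:
            raise FormatError(f"SNP {self.snp_id}: position must be >= 1 "
                              f"(1-based coordinates), got {self.pos}")
        if self.category not in _CATEGORIES:
            raise FormatError(f"SNP {self.snp_id}: unknown category "
                              f"{self.category!r}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def pos0(self) -> int:
        """0-based position (internal interval convention)."""
        return self.pos - 1


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class AnnotationElement:
    """One non-coding element (lncRNA gene, miRNA precursor, circRNA or SE).

    ``(element_class, element_id, chrom, start, end)`` is the redundancy
    key: multiple source studies annotating the same element collapse to a
    single record, while distinct ids sharing coordinates stay distinct.
    """

    element_class: str
    element_id: str
    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.element_class not in ELEMENT_CLASSES:
            raise FormatError(f"unknown element class {self.element_class!r}")
        if not self.element_id:
            raise FormatError("element_id must be non-empty")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"{self.element_class} {self.element_id}: invalid interval "
                f"{self.chrom}:{self.start}-{self.end}")

    @property
    def key(self):
        return (self.element_class, self.element_id, self.chrom,
                self.start, self.end)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# SNP manifest / SNP lists
# ---------------------------------------------------------------------------

_ID_COLS = ("snp_id", "id", "probe_set_id", "snp", "rsid", "name")
_CHROM_COLS = ("chrom", "chr", "chromosome")
_POS_COLS = ("pos", "position", "bp", "physical_position")
_CAT_COLS = ("category", "annotation", "location")
_TYPE_COLS = ("type", "probe_type")

_CNV_TOKENS = {"cnv", "cn", "copynumber", "copy_number", "copy number variant"}


def _find_col(columns, names, required, what, path):
    for n in names:
        for c in columns:
            if c.strip().lower() == n:
                return c
    if required:
        raise FormatError(f"{path}: manifest header lacks a {what} column "
                          f"(looked for {'/'.join(names)})")
    return None


def _normalize_category(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "other"
    v = str(value).strip().lower()
    if v.startswith("intron"):
        return "intronic"
    if v in ("extragenic", "intergenic") or v.startswith("extragen"):
        return "extragenic"
    return "other"


def read_snp_manifest(path) -> list[SnpRecord]:
    """Read a tab-text SNP manifest (or disease SNP list) into records.

    The header must name id, chromosome and position columns (several common
    spellings are accepted); a category column is optional and defaults to
    ``other``.  Rows on non-autosomal chromosomes and rows flagged as
    copy-number variants (a ``type`` column saying CNV, or a probe id
    starting with ``CN_``) are dropped.  File order is preserved.
    """
    path = str(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise FormatError(f"{path}: cannot parse as tab-text ({exc})") from exc
    if df.columns.size < 3:
        raise FormatError(f"{path}: manifest needs at least id/chrom/pos "
                          "tab-separated columns")
    id_col = _find_col(df.columns, _ID_COLS, True, "SNP id", path)
    chrom_col = _find_col(df.columns, _CHROM_COLS, True, "chromosome", path)
    pos_col = _find_col(df.columns, _POS_COLS, True, "position", path)
    cat_col = _find_col(df.columns, _CAT_COLS, False, "category", path)
    type_col = _find_col(df.columns, _TYPE_COLS, False, "type", path)

    records: list[SnpRecord] = []
    seen: set[str] = set()
    # header occupies line 1; data row i (0-based) is file line i + 2
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row = dict(zip(df.columns, row))
        snp_id = row[id_col]
        if snp_id is None or pd.isna(snp_id) or not str(snp_id).strip():
            raise FormatError(f"{path}: line {line}: empty SNP id")
        snp_id = str(snp_id).strip()
        if snp_id.upper().startswith("CN_"):
            continue  # Affymetrix copy-number probe
        if type_col is not None:
            t = row[type_col]
            if t is not None and not pd.isna(t) and \
                    str(t).strip().lower() in _CNV_TOKENS:
                continue
        try:
            chrom = normalize_chrom(row[chrom_col])
        except FormatError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
        if chrom not in AUTOSOMES:
            continue  # chrX (and anything non-autosomal) is excluded
        try:
            pos = int(str(row[pos_col]).strip())
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {line}: position "
                              f"{row[pos_col]!r} is not an integer") from None
        if pos < 1:
            raise FormatError(f"{path}: line {line}: position {pos} violates "
                              "the 1-based coordinate convention")
        if snp_id in seen:
            raise FormatError(f"{path}: line {line}: duplicate SNP id "
                              f"{snp_id!r}")
        seen.add(snp_id)
        category = _normalize_category(row[cat_col]) if cat_col else "other"
        records.append(SnpRecord(snp_id, chrom, pos, category))
    return records


def write_snp_manifest(records: Iterable[SnpRecord], path) -> None:
    """Write records in the tab-text manifest dialect read by this module."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tcategory\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.category}\n")


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

_FORMATS = ("gtf", "gff", "bed", "circbase_tab")


def _read_bed_frame(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            rows.append(line.split("\t"))
    return pd.DataFrame(rows)


def _gffutils_elements(path, featuretypes, id_attrs, element_class, source,
                       is_gtf):
    import gffutils

    kwargs = dict(dbfn=":memory:", force=True, keep_order=True,
                  merge_strategy="create_unique")
    if is_gtf:
        kwargs.update(disable_infer_genes=True, disable_infer_transcripts=True)
    db = gffutils.create_db(str(path), **kwargs)
    out = []
    for ftype in featuretypes:
        feats = list(db.features_of_type(ftype))
        if not feats:
            continue
        for f in feats:
            eid = None
            for attr in id_attrs:
                if attr in f.attributes and f.attributes[attr]:
                    eid = f.attributes[attr][0]
                    break
            if eid is None:
                eid = f.id
            # GTF/GFF are 1-based inclusive
            out.append(AnnotationElement(element_class, eid, f.seqid,
                                         f.start - 1, f.end, source))
        break
    if not out:
        raise FormatError(f"{path}: no features of type "
                          f"{'/'.join(featuretypes)} found")
    return out


def read_annotation_track(path, format: str, element_class: str,
                          source: str = "") -> list[AnnotationElement]:
    """Read an annotation track into internal 0-based half-open elements.

    ``format`` is one of ``gtf`` (gene-level records), ``gff`` (miRBase
    dialect; precursor ``miRNA_primary_transcript`` features), ``bed``
    (BED3/BED4) or ``circbase_tab`` (dialect defined in the module
    docstring).
    """
    if format not in _FORMATS:
        raise FormatError(f"unknown annotation format {format!r} "
                          f"(expected one of {', '.join(_FORMATS)})")
    path = str(path)
    if format == "gtf":
        return _gffutils_elements(path, ("gene",), ("gene_id", "gene_name"),
                                  element_class, source, is_gtf=True)
    if format == "gff":
        return _gffutils_elements(
            path, ("miRNA_primary_transcript", "gene"), ("Name", "ID"),
            element_class, source, is_gtf=False)

    df = _read_bed_frame(path)
    out: list[AnnotationElement] = []
    if format == "bed":
        for i, row in df.iterrows():
            if row.count() < 3:
                raise FormatError(f"{path}: BED row {i + 1} has fewer than "
                                  "3 columns")
            name = row[3] if row.count() > 3 and row[3] else f"bed_{i + 1}"
            try:
                start, end = int(row[1]), int(row[2])
            except ValueError:
                raise FormatError(f"{path}: BED row {i + 1}: non-integer "
                                  "coordinates") from None
            try:
                out.append(AnnotationElement(element_class, str(name),
                                             row[0], start, end, source))
            except FormatError as exc:
                raise FormatError(f"{path}: BED row {i + 1}: {exc}") from exc
        return out

    # circbase_tab; tolerate an optional header line
    start_row = 0
    if len(df) and not str(df.iloc[0, 1]).strip().lstrip("-").isdigit():
        start_row = 1
    for i in range(start_row, len(df)):
        row = df.iloc[i]
        if row.count() < 4:
            raise FormatError(f"{path}: circbase row {i + 1} has fewer than "
                              "4 columns")
        try:
            start, end = int(row[1]), int(row[2])
        except ValueError:
            raise FormatError(f"{path}: circbase row {i + 1}: non-integer "
                              "coordinates") from None
        src = source
        if not src and row.count() >= 6 and row[5]:
            src = str(row[5])
        elif not src and row.count() >= 5 and row[4]:
            src = str(row[4])  # gene symbol as provenance tag
        try:
            out.append(AnnotationElement(element_class, str(row[3]), row[0],
                                         start, end, src))
        except FormatError as exc:
            raise FormatError(f"{path}: circbase row {i + 1}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# BED / blocks output
# ---------------------------------------------------------------------------

def _as_bed_row(item, i):
    chrom = getattr(item, "chrom")
    start = getattr(item, "start")
    end = getattr(item, "end")
    name = getattr(item, "element_id", None)
    if name is None:
        snp_ids = getattr(item, "snp_ids", None)
        if snp_ids:
            name = f"{snp_ids[0]}|{snp_ids[-1]}"
        else:
            name = f"region_{i + 1}"
    return (chrom, int(start), int(end), str(name))


def write_bed(items: Sequence, path) -> None:
    """Write intervals/blocks/elements as BED4 (sorted by chrom, start).

    Chromosomes are emitted with a ``chr`` prefix; reading the file back
    with :func:`read_annotation_track` returns identical internal
    intervals.
    """
    rows = sorted((_as_bed_row(x, i) for i, x in enumerate(items)),
                  key=lambda r: (chrom_sort_key(r[0]), r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"chr{chrom}\t{start}\t{end}\t{name}\n")


def read_blocks_bed(path) -> list:
    """Read a BED file of LD-block intervals (membership unknown)."""
    from .ld_blocks import LdBlock

    elements = read_annotation_track(path, "bed", "SE")  # class is a dummy
    return [LdBlock(chrom=e.chrom, snp_ids=(), start=e.start, end=e.end)
            for e in elements]


def write_blocks_details(blocks, path) -> None:
    """Sidecar text listing member SNP ids per block (Plink ``.blocks``-like)."""
    with open(path, "w") as fh:
        for b in blocks:
            ids = " ".join(b.snp_ids) if b.snp_ids else "."
            fh.write(f"chr{b.chrom}\t{b.start}\t{b.end}\t{ids}\n")


def write_gtf(elements: Iterable[AnnotationElement], path,
              source_field: str = "synthetic") -> None:
    """Write gene-level GTF (1-based inclusive) for lncRNA-style tracks."""
    with open(path, "w") as fh:
        for e in elements:
            attrs = (f'gene_id "{e.element_id}"; gene_name "{e.element_id}"; '
                     f'gene_type "lncRNA";')
            fh.write(f"chr{e.chrom}\t{source_field}\tgene\t{e.start + 1}\t"
                     f"{e.end}\t.\t+\t.\t{attrs}\n")


def write_gff3(elements: Iterable[AnnotationElement], path) -> None:
    """Write miRBase-dialect GFF3 (precursor features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(elements, 1):
            attrs = f"ID=MI{i:07d};Name={e.element_id}"
            fh.write(f"chr{e.chrom}\t.\tmiRNA_primary_transcript\t"
                     f"{e.start + 1}\t{e.end}\t.\t+\t.\t{attrs}\n")


def write_circbase_tab(elements: Iterable[AnnotationElement], path) -> None:
    """Write the fixed circbase_tab dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcircRNA_id\tgene_symbol\tsource\n")
        for e in elements:
            fh.write(f"chr{e.chrom}\t{e.start}\t{e.end}\t{e.element_id}\t"
                     f".\t{e.source}\n")
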