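"""Orchestration: blocks -> mapping -> overlap -> enrichment, with reporting.

A single YAML config captures every input path and parameter, the seed is
recorded in every output, and the same machinery serves any disease SNP
list — the replication on a second disease is just a second config sharing
the manifest and blocks.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_overlap, block_mapping, io_formats, ld_blocks
from .enrichment import EnrichmentModel, NullConstraints
from .io_formats import FormatError, GenomicInterval

__all__ = ["RunConfig", "ConfigError", "PipelineError", "run_full",
           "compare_diseases"]

logger = logging.getLogger("ldblock_enrich")


class ConfigError(ValueError):
    """The run configuration is invalid (missing file, bad field...)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _parse_region(spec: str) -> GenomicInterval:
    try:
        chrom, rest = spec.split(":")
        start, end = rest.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start), int(end))
    except Exception as exc:
        raise ConfigError(f"cannot parse region {spec!r} "
                          "(expected chrom:start-end)") from exc


@dataclass
class RunConfig:
    """Everything one enrichment run needs; see ``from_yaml`` for the schema."""

    manifest: str
    disease_snps: str
    tracks: dict[str, dict]          # class -> {path, format}
    blocks_bed: str | None = None
    vcf: str | None = None
    dosage_table: str | None = None
    block_params: ld_blocks.BlockCallingParams = field(
        default_factory=ld_blocks.BlockCallingParams)
    null: dict = field(default_factory=dict)
    iterations: int = 1000
    seed: int = 0
    outdir: str = "results"
    min_overlap_bp: int = 1

    @classmethod
    def from_dict(cls, d: dict, base_dir: str | Path = ".") -> "RunConfig":
        base = Path(base_dir)

        def resolve(p):
            return None if p is None else str((base / p).resolve()
                                              if not Path(p).is_absolute()
                                              else Path(p))

        try:
            cfg = cls(
                manifest=resolve(d["manifest"]),
                disease_snps=resolve(d["disease_snps"]),
                tracks={c: {"path": resolve(t["path"]),
                            "format": t["format"]}
                        for c, t in d["tracks"].items()},
                blocks_bed=resolve(d.get("blocks_bed")),
                vcf=resolve(d.get("vcf")),
                dosage_table=resolve(d.get("dosage_table")),
                block_params=ld_blocks.BlockCallingParams(
                    **d.get("block_params", {})),
                null=d.get("null", {}),
                iterations=int(d.get("iterations", 1000)),
                seed=int(d.get("seed", 0)),
                outdir=resolve(d.get("outdir", "results")),
                min_overlap_bp=int(d.get("min_overlap_bp", 1)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config field {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(d, base_dir=Path(path).parent)

    def validate(self) -> None:
        for label, p in [("manifest", self.manifest),
                         ("disease_snps", self.disease_snps),
                         ("blocks_bed", self.blocks_bed),
                         ("vcf", self.vcf),
                         ("dosage_table", self.dosage_table)] + [
                             (f"tracks.{c}", t["path"])
                             for c, t in self.tracks.items()]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label}: file not found: {p}")
        if not (self.blocks_bed or self.vcf or self.dosage_table):
            raise ConfigError("one of blocks_bed, vcf or dosage_table "
                              "is required")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")

    def null_constraints(self, disease_snps) -> NullConstraints:
        n = dict(self.null)
        mode = n.get("mode", "match_snp_count")
        frac = n.get("intronic_fraction")
        if frac is None:
            from .enrichment import _intronic_fraction
            frac = _intronic_fraction(disease_snps)
        regions = n.get("excluded_regions")
        if regions is None:
            from .enrichment import DEFAULT_HLA_REGION
            excluded = (DEFAULT_HLA_REGION,)
        else:
            excluded = tuple(_parse_region(r) for r in regions)
        try:
            return NullConstraints(
                mode=mode,
                n_snps=n.get("n_snps") if mode == "match_snp_count" else None,
                target_length_bp=(n.get("target_length_bp")
                                  if mode == "match_total_length" else None),
                intronic_fraction=float(frac),
                excluded_regions=excluded,
                excluded_chroms=frozenset(n.get("excluded_chroms", ("X",))),
                length_tolerance_bp=n.get("length_tolerance_bp"),
            )
        except ValueError as exc:
            raise ConfigError(f"null constraints: {exc}") from exc


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except (ConfigError, PipelineError):
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    logger.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
    return out


def run_full(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``.

    Returns a dict with the in-memory results (``blocks``, ``assignments``,
    ``observed``, ``enrichment``) and the paths written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    try:
        manifest = _stage("manifest", io_formats.read_snp_manifest,
                          config.manifest)
        disease = _stage("disease_snps", io_formats.read_snp_manifest,
                         config.disease_snps)

        def load_blocks():
            if config.blocks_bed:
                return io_formats.read_blocks_bed(config.blocks_bed)
            if config.vcf:
                matrix = ld_blocks.GenotypeMatrix.from_vcf(config.vcf)
            else:
                matrix = ld_blocks.GenotypeMatrix.from_dosage_table(
                    config.dosage_table)
            return ld_blocks.call_blocks(matrix, config.block_params)

        blocks = _stage("blocks", load_blocks)

        def load_tracks():
            return {c: io_formats.read_annotation_track(
                        t["path"], t["format"], c)
                    for c, t in config.tracks.items()}

        tracks = _stage("tracks", load_tracks)
        constraints = config.null_constraints(disease)

        def build_model():
            return EnrichmentModel(disease, manifest=manifest, blocks=blocks,
                                   tracks=tracks, constraints=constraints,
                                   min_overlap_bp=config.min_overlap_bp)

        model = _stage("mapping+overlap", build_model)

        def do_fit():
            return model.fit(
                n_iterations=config.iterations, seed=config.seed,
                progress=lambda i, n: logger.info(
                    "enrichment iteration %d/%d", i, n))

        results = _stage("enrichment", do_fit)

        paths = {
            "blocks_bed": outdir / "blocks.bed",
            "assignments": outdir / "assignments.tsv",
            "counts": outdir / "counts.tsv",
            "enrichment_json": outdir / "enrichment.json",
            "summary": outdir / "summary.txt",
        }
        io_formats.write_bed(blocks, paths["blocks_bed"])
        if not config.blocks_bed:
            io_formats.write_blocks_details(blocks,
                                            outdir / "blocks.details.txt")
        with open(paths["assignments"], "w") as fh:
            fh.write("snp_id\tstatus\tchrom\tblock_start\tblock_end\n")
            for a in model.assignments:
                if a.block is None:
                    fh.write(f"{a.snp_id}\tunassigned\t.\t.\t.\n")
                else:
                    fh.write(f"{a.snp_id}\tassigned\t{a.block.chrom}\t"
                             f"{a.block.start}\t{a.block.end}\n")
        row = annotation_overlap.count_table(model.observed_result)
        row.to_frame().T.to_csv(paths["counts"], sep="\t", index=False)
        results.save(paths["enrichment_json"])
        with open(paths["summary"], "w") as fh:
            fh.write(f"# seed={config.seed} iterations={config.iterations}\n")
            fh.write(results.summary() + "\n")
        logger.info("run complete; outputs in %s", outdir)
        return {"blocks": blocks, "assignments": model.assignments,
                "observed": model.observed_result, "enrichment": results,
                "model": model, "paths": {k: str(v) for k, v in paths.items()}}
    finally:
        logger.removeHandler(handler)
        handler.close()


def compare_diseases(configs: list[RunConfig]) -> pd.DataFrame:
    """Run several disease lists through the shared null machinery.

    All configs must reference the same manifest (and blocks source); the
    result is one report row per disease list.
    """
    if not configs:
        raise ConfigError("at least one config is required")
    first = configs[0]
    for c in configs[1:]:
        if c.manifest != first.manifest:
            raise ConfigError(
                "compare_diseases requires a shared manifest; got "
                f"{first.manifest} vs {c.manifest}")
    rows = []
    for c in configs:
        out = run_full(c)
        res = out["enrichment"]
        row = {"disease": Path(c.disease_snps).stem,
               "n_blocks": res.observed_n_blocks,
               "total_mb": res.observed_total_bp / 1e6}
        for cls in res.classes:
            row[f"n_{cls}"] = res.observed[cls]
            row[f"p_{cls}"] = res.p_value[cls]
        rows.append(row)
    return pd.DataFrame(rows)
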