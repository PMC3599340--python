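"""End-to-end orchestration: filter -> spectrum -> consequence -> enrichment.

Produces one TSV per stage plus a JSON run manifest. Stage counts in the
consolidated outputs come straight from the cascade's FilterReport.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .consequence import classify_callset, index_gene_models, recurrent_gene_table
from .filter_cascade import FilterConfig, run_cascade
from .go_enrichment import (enrich_terms, enrichment_tsv, propagate_annotations,
                            read_annotations, read_obo)
from .spectrum_stats import (ContingencyTable2x2, build_spectrum, count_ratio,
                             fisher_exact_two_sided, titv_ratio)
from .variant_io import (SamplePair, read_coverage, read_known_db, read_vcf,
                         write_vcf)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "bundled_go_files"]


def bundled_go_files() -> tuple[Path, Path]:
    """Paths of the small packaged ontology + annotation fixtures."""
    data = resources.files("somavar") / "data"
    return Path(str(data / "mini_go.obo")), Path(str(data / "mini_annotations.tsv"))


@dataclass
class PipelineConfig:
    out_dir: str
    tumor_vcf: str
    normal_vcf: str
    tumor_cov: str
    normal_cov: str
    known_db: str
    gtf: str | None = None
    fasta: str | None = None
    obo: str | None = None
    annotations: str | None = None
    pair_id: str = "pair1"
    correction: str = "bh"
    namespaces: tuple[str, ...] = ("biological_process", "molecular_function")
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = FilterConfig(**raw.pop("filters", {}))
        if "namespaces" in raw:
            raw["namespaces"] = tuple(raw["namespaces"])
        return cls(filters=filt, **raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageFailure(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage, writing report files into ``cfg.out_dir``.

    Returns the mapping of report name -> path. Raises StageFailure naming
    the failing stage; outputs of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage %s starting", name)
        return name

    # --- load inputs -------------------------------------------------------
    name = stage("load_inputs")
    try:
        for label, p in (("tumor VCF", cfg.tumor_vcf), ("normal VCF", cfg.normal_vcf),
                         ("tumor coverage", cfg.tumor_cov),
                         ("normal coverage", cfg.normal_cov)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")
        if not Path(cfg.known_db).exists():
            raise FileNotFoundError(
                f"known-variant database (needed for database subtraction) "
                f"not found: {cfg.known_db}")
        tumor = read_vcf(cfg.tumor_vcf)
        normal = read_vcf(cfg.normal_vcf)
        if tumor.sample_id == normal.sample_id:
            tumor = read_vcf(cfg.tumor_vcf, sample_id=tumor.sample_id + "_tumor")
        pair = SamplePair(cfg.pair_id, normal, tumor,
                          read_coverage(cfg.normal_cov), read_coverage(cfg.tumor_cov))
        db = read_known_db(cfg.known_db, positional=cfg.filters.db_positional)
    except Exception as exc:
        raise StageFailure(f"stage {name}: {exc}") from exc

    # --- filter cascade ----------------------------------------------------
    name = stage("filter")
    try:
        tumor_specific, normal_specific, report = run_cascade(pair, db, cfg.filters)
        path = out / "filter_report.tsv"
        path.write_text(report.to_tsv())
        written["filter_report"] = path
        for cs, fname in ((tumor_specific, "tumor_specific.vcf"),
                          (normal_specific, "normal_specific.vcf")):
            write_vcf(cs, out / fname)
            written[fname.removesuffix(".vcf")] = out / fname
        for sc in report.stages:
            log.info("filter %-16s %-14s %6d -> %6d",
                     sc.stage, sc.sample_id, sc.n_in, sc.n_out)
    except Exception as exc:
        raise StageFailure(f"stage {name}: {exc}") from exc

    # --- spectrum + comparison statistics ----------------------------------
    name = stage("spectrum")
    try:
        spec_t = build_spectrum(tumor_specific)
        spec_n = build_spectrum(normal_specific)
        lines = ["sample\tclass\tcount"]
        for spec in (spec_t, spec_n):
            for klass, count in spec.counts.items():
                lines.append(f"{spec.sample_id}\t{klass}\t{count}")
        path = out / "spectrum.tsv"
        path.write_text("\n".join(lines) + "\n")
        written["spectrum"] = path

        stats_lines = ["comparison\ta\tb\tc\td\tvalue"]
        if min(spec_t.n_transversions, spec_n.n_transversions) > 0:
            table = ContingencyTable2x2(spec_t.n_transitions, spec_t.n_transversions,
                                        spec_n.n_transitions, spec_n.n_transversions)
            p = fisher_exact_two_sided(table)
            stats_lines.append(
                f"titv_fisher\t{table.a}\t{table.b}\t{table.c}\t{table.d}\t{p:.6g}")
            stats_lines.append(
                f"titv_tumor\t\t\t\t\t{titv_ratio(tumor_specific):.4g}")
            stats_lines.append(
                f"titv_normal\t\t\t\t\t{titv_ratio(normal_specific):.4g}")
        if len(normal_specific) > 0:
            stats_lines.append(
                "count_ratio\t\t\t\t\t"
                f"{count_ratio(len(tumor_specific), len(normal_specific)):.2f}")
        path = out / "spectrum_stats.tsv"
        path.write_text("\n".join(stats_lines) + "\n")
        written["spectrum_stats"] = path
    except Exception as exc:
        raise StageFailure(f"stage {name}: {exc}") from exc

    # --- consequences + recurrence ----------------------------------------
    study_genes: set[str] = set()
    universe_genes: set[str] = set()
    if cfg.gtf and cfg.fasta:
        name = stage("consequence")
        try:
            index = index_gene_models(cfg.gtf, cfg.fasta)
            universe_genes = {m.gene_id for m in index.models}
            per_sample = []
            lines = ["sample\tchrom\tpos\tref\talt\tgene\ttranscript\tcategory\tdisruptive"]
            for cs in (tumor_specific, normal_specific):
                calls = classify_callset(cs, index)
                per_sample.append((cs.sample_id, calls))
                for cc in calls:
                    v = cc.variant
                    lines.append(
                        f"{cs.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                        f"{cc.gene_id}\t{cc.transcript_id}\t{cc.category}\t"
                        f"{int(cc.disruptive)}")
            path = out / "consequence.tsv"
            path.write_text("\n".join(lines) + "\n")
            written["consequence"] = path

            tumor_only = [ps for ps in per_sample if ps[0] == tumor_specific.sample_id]
            summaries = recurrent_gene_table(tumor_only)
            study_genes = {s.gene_id for s in summaries}
            lines = ["gene\ttotal_disruptive\tsamples_hit\tin_all_samples"]
            for s in summaries:
                lines.append(f"{s.gene_id}\t{s.total}\t{s.samples_hit}\t"
                             f"{int(s.samples_hit == len(tumor_only))}")
            path = out / "recurrence.tsv"
            path.write_text("\n".join(lines) + "\n")
            written["recurrence"] = path
        except Exception as exc:
            raise StageFailure(f"stage {name}: {exc}") from exc

    # --- GO enrichment -----------------------------------------------------
    obo_path, ann_path = cfg.obo, cfg.annotations
    if obo_path is None and ann_path is None:
        obo_path, ann_path = bundled_go_files()
    if obo_path and ann_path and universe_genes:
        name = stage("enrichment")
        try:
            dag = read_obo(obo_path)
            direct = read_annotations(ann_path)
            propagated = propagate_annotations(direct, dag)
            universe = {g for g in universe_genes if propagated.get(g)}
            study = study_genes & universe
            rows = []
            for ns in cfg.namespaces:
                rows.extend(enrich_terms(study, universe, propagated, dag,
                                         namespace=ns, correction=cfg.correction))
            path = out / "enrichment.tsv"
            path.write_text(enrichment_tsv(rows))
            written["enrichment"] = path
        except Exception as exc:
            raise StageFailure(f"stage {name}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "outputs": {k: str(v) for k, v in written.items()},
        "cutoffs": report.cutoffs,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = path
    return written
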