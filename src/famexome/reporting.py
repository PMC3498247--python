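"""Combined end-to-end runs and publication-style report rendering."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .coverage_audit import (
    AuditConfig,
    GeneCoverageReport,
    audit_gene,
    build_ccds_splice_intervals,
    BaseTrack,
    genes_exceeding,
    load_gene_models,
    load_track,
    overall_failed_fraction,
)
from .filter_cascade import CascadeConfig, CascadeReport, run_cascade
from .segregation import SegregationVerdict, check_dominant_segregation, load_pedigree
from .synthetic_data import FixtureBundle
from .variant_store import (
    VariantKey,
    load_frequency_panel,
    load_gene_set,
    load_variant_table,
)


def render_coverage_table(
    reports: Sequence[GeneCoverageReport],
    threshold: float = 30.0,
) -> pd.DataFrame:
    """Render gene coverage reports as a publication-style table.

    Columns: gene, total CCDS+splice bases, bases failed in all samples, the
    all-samples failed percentage, then one percentage column per sample.
    Rows are restricted to genes whose *maximum per-sample* failed percentage
    meets ``threshold`` and sorted lexicographically by gene.
    """
    if not reports:
        raise ValueError("no coverage reports to render")
    keep = set(genes_exceeding(reports, threshold, scope="any-sample"))
    sample_cols: list[str] = sorted({s for r in reports for s in r.pct_per_sample})
    rows = []
    for rep in sorted(reports, key=lambda r: r.gene):
        if rep.gene not in keep:
            continue
        row = {
            "gene": rep.gene,
            "total_bases": rep.total_bases,
            "failed_all_samples": rep.failed_all_samples,
            "pct_all_samples": f"{rep.pct_all_samples:.2f}",
        }
        for s in sample_cols:
            row[f"pct_{s}"] = f"{rep.pct_per_sample.get(s, 0.0):.2f}"
        rows.append(row)
    columns = ["gene", "total_bases", "failed_all_samples", "pct_all_samples"] + [
        f"pct_{s}" for s in sample_cols]
    return pd.DataFrame(rows, columns=columns)


def funnel_text(report: CascadeReport) -> str:
    """A text rendering of the per-stage count funnel."""
    lines = []
    for label in report.stage_labels:
        c = report.stage_counts[label]
        lines.append(f"({label}) {c.total} variants ({c.snv} SNVs, {c.indel} indels)")
    return "\n".join(lines)


def write_run_manifest(
    out_dir: Path,
    subcommand: str,
    config_echo: Mapping,
    input_paths: Sequence[Path],
    output_paths: Sequence[Path],
    seed: int | None = None,
) -> Path:
    """Every run writes exactly one manifest describing what ran on what."""
    manifest = {
        "subcommand": subcommand,
        "tool_version": __version__,
        "seed": seed,
        "config": dict(config_echo),
        "input_checksums": {
            str(p): hashlib.md5(Path(p).read_bytes()).hexdigest() for p in input_paths
        },
        "outputs": [str(p) for p in output_paths],
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


@dataclass
class EndToEndResult:
    cascade: CascadeReport
    coverage: list[GeneCoverageReport]
    coverage_table: pd.DataFrame
    overall_failed_pct: float
    segregation: dict[str, SegregationVerdict]


def run_end_to_end(
    bundle: FixtureBundle | str | Path,
    out_dir: str | Path,
    audit_config: AuditConfig | None = None,
    freq_cutoff: float = 0.01,
    splice_distance_cutoff: int = 10,
) -> EndToEndResult:
    """Run cascade, coverage audit and segregation on one bundle directory.

    Writes a combined JSON report plus a coverage TSV table under ``out_dir``
    and returns the in-memory results.  The segregation test is run for every
    stage-(v) survivor using the bundle's pedigree.
    """
    if not isinstance(bundle, FixtureBundle):
        bundle = FixtureBundle.load(bundle)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_ids = bundle.manifest["case_ids"]
    control_ids = bundle.manifest["control_ids"]
    if not case_ids:
        raise ValueError("bundle has an empty case list")
    audit_config = audit_config or AuditConfig()

    variants = load_variant_table(bundle.vcf, case_ids + control_ids)
    genes = load_gene_set(bundle.gene_set)
    panels = [load_frequency_panel(p, name) for name, p in sorted(bundle.panels.items())]
    config = CascadeConfig(case_ids=case_ids, control_ids=control_ids,
                           freq_cutoff=freq_cutoff,
                           splice_distance_cutoff=splice_distance_cutoff)
    cascade = run_cascade(variants, config, panels=panels, genes=genes)

    models = load_gene_models(bundle.gene_models_tsv)
    tracks: dict[str, BaseTrack] = {s: load_track(p) for s, p in sorted(bundle.tracks.items())}
    reports = []
    for gene in sorted(genes.genes):
        exons = models.get(gene)
        if not exons:
            continue
        intervals = build_ccds_splice_intervals(gene, exons, flank=audit_config.flank)
        reports.append(audit_gene(intervals, tracks, audit_config))
    table = render_coverage_table(reports, threshold=audit_config.report_thresholds[0])
    overall = overall_failed_fraction(reports)

    pedigree = load_pedigree(bundle.ped, bundle.meta)
    verdicts: dict[str, SegregationVerdict] = {}
    causal_key = bundle.manifest["causal"]["key"]
    for v in cascade.survivors:
        gts = {s: v.genotype(s) for s in case_ids + control_ids
               if s in pedigree.by_id}
        if str(v.key) == causal_key:
            # the full pedigree was genotyped orthogonally for the causal site
            gts = dict(bundle.manifest["causal"]["pedigree_genotypes"])
        verdicts[str(v.key)] = check_dominant_segregation(gts, pedigree)

    combined = {
        "cascade": cascade.to_dict(),
        "coverage": {
            "overall_failed_pct_all_samples": overall,
            "genes_exceeding": {
                f"{t:g}pct_any_sample": genes_exceeding(reports, t, "any-sample")
                for t in audit_config.report_thresholds
            },
        },
        "segregation": {k: v.to_dict() for k, v in verdicts.items()},
    }
    (out_dir / "combined_report.json").write_text(json.dumps(combined, indent=2, sort_keys=True))
    table.to_csv(out_dir / "coverage_table.tsv", sep="\t", index=False)
    write_run_manifest(
        out_dir, "run-all",
        {"freq_cutoff": freq_cutoff, "splice_distance_cutoff": splice_distance_cutoff,
         "depth_min": audit_config.depth_min, "qual_min": audit_config.qual_min,
         "flank": audit_config.flank},
        input_paths=[bundle.vcf, bundle.ped, bundle.meta, bundle.gene_set,
                     bundle.gene_models_tsv, *bundle.panels.values()],
        output_paths=[out_dir / "combined_report.json", out_dir / "coverage_table.tsv"],
        seed=bundle.manifest.get("seed"),
    )
    return EndToEndResult(
        cascade=cascade, coverage=reports, coverage_table=table,
        overall_failed_pct=overall, segregation=verdicts)
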