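"""End-to-end orchestration: aggregate -> reference comparison ->
distribution -> gene content -> ORA, with a run manifest and a
consolidated report.

The run configuration is a flat key=value mapping (parsed from a simple
``key = value`` text file or passed as a dict).  All thresholds default
to the pipeline's canonical values: 3 Mb inclusion cap, 0.75 reciprocal
overlap, 5 Mb windows / 0.5 Mb steps / 9 Mb flanks, alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .aggregate import (
    deduplicate,
    filter_inclusion,
    summarize_counts,
    write_regions_bed,
    write_summary,
)
from .distribution import (
    densities_frame,
    genome_track,
    make_windows,
    per_chromosome_counts,
    plot_density_profile,
    plot_genome_track,
    profile_by_offset,
    window_cnv_fraction,
)
from .enrichment import run_ora, write_enrichment
from .genes import (
    annotate_catalogs,
    intersect_genes,
    recurrent_bands,
    tally_biotypes,
    write_gene_hits,
    write_recurrent_bands,
)
from .io import (
    CnvType,
    read_catalog,
    read_cnv_table,
    read_gene_models,
    read_genome_layout,
    read_gmt,
    read_reference_variants,
    write_rejects,
)
from .reference import classify_reported, tally_statuses, write_overlap_calls

log = logging.getLogger("cnvmap")

DEFAULTS = {
    "max_size_bp": 3_000_000,
    "min_size_bp": 0,
    "ro_threshold": 0.75,
    "window_bp": 5_000_000,
    "step_bp": 500_000,
    "flank_bp": 9_000_000,
    "alpha": 0.05,
    "adjust": "none",
    "cnv_dialect": "tsv_1based",
    "reference_dialect": "bed_typed",
    "plots": True,
}

REQUIRED_INPUTS = {
    "aggregate": ("cnv",),
    "dgv-compare": ("reference",),
    "distribution": ("sizes", "gap", "centromere", "cytoband"),
    "genes": ("gtf", "phenotype_catalog", "expression_catalog"),
    "ora": ("gmt",),
}


class ConfigError(ValueError):
    """Raised when the run configuration is incomplete or inconsistent."""


def read_config(path: str | Path) -> dict:
    """Parse a ``key = value`` run-configuration file."""
    config: dict = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{line_no}: expected 'key = value'")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


def _coerce(config: dict) -> dict:
    cfg = dict(DEFAULTS)
    cfg.update(config)
    for key in ("max_size_bp", "min_size_bp", "window_bp", "step_bp", "flank_bp"):
        cfg[key] = int(cfg[key])
    cfg["ro_threshold"] = float(cfg["ro_threshold"])
    cfg["alpha"] = float(cfg["alpha"])
    if isinstance(cfg["plots"], str):
        cfg["plots"] = cfg["plots"].lower() in ("1", "true", "yes")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Stage order: aggregate -> dgv-compare -> distribution -> genes -> ora.
    Any missing input aborts with a :class:`ConfigError` naming the stage.
    """
    cfg = _coerce(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()

    for stage, keys in REQUIRED_INPUTS.items():
        for key in keys:
            if key not in cfg:
                raise ConfigError(f"stage {stage}: missing input '{key}'")
            if not Path(cfg[key]).exists():
                raise ConfigError(f"stage {stage}: input '{key}' not found: {cfg[key]}")

    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "parameters": {
            k: cfg[k]
            for k in (
                "max_size_bp", "min_size_bp", "ro_threshold",
                "window_bp", "step_bp", "flank_bp", "alpha", "adjust",
            )
        },
        "inputs": {},
        "outputs": {},
        "counts": {},
    }
    for stage, keys in REQUIRED_INPUTS.items():
        for key in keys:
            manifest["inputs"][key] = _digest(Path(cfg[key]))
    config_text = json.dumps(
        {k: str(v) for k, v in sorted(cfg.items())}, sort_keys=True
    )
    manifest["config_hash"] = hashlib.sha256(config_text.encode()).hexdigest()

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}

    # --- aggregate -----------------------------------------------------
    log.info("stage aggregate")
    records, rejects = read_cnv_table(cfg["cnv"], dialect=cfg["cnv_dialect"])
    kept, excluded = filter_inclusion(records, cfg["max_size_bp"], cfg["min_size_bp"])
    regions = deduplicate(kept)
    summary = summarize_counts(kept, regions)
    write_rejects(rejects, out_dir / "rejects.tsv")
    emit("rejects", out_dir / "rejects.tsv")
    write_regions_bed(regions, out_dir / "regions.bed")
    emit("regions", out_dir / "regions.bed")
    write_summary(summary, out_dir / "summary.tsv")
    emit("summary", out_dir / "summary.tsv")
    manifest["counts"]["aggregate"] = {
        "n_rows": len(records) + len(rejects),
        "n_records": len(records),
        "n_rejects": len(rejects),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "n_cnvr": len(regions),
    }
    if not kept:
        log.warning("empty cohort after filtering; downstream tables will be empty")

    # --- dgv-compare ---------------------------------------------------
    log.info("stage dgv-compare")
    reference, n_skipped = read_reference_variants(
        cfg["reference"], dialect=cfg["reference_dialect"]
    )
    calls = classify_reported(regions, reference, threshold=cfg["ro_threshold"])
    write_overlap_calls(calls, out_dir / "overlap_calls.tsv")
    emit("overlap_calls", out_dir / "overlap_calls.tsv")
    status_tally = tally_statuses(calls)
    manifest["counts"]["dgv-compare"] = {
        "n_reference": len(reference),
        "n_reference_skipped": n_skipped,
        **status_tally,
    }

    # --- distribution --------------------------------------------------
    log.info("stage distribution")
    layout = read_genome_layout(
        cfg["sizes"], cfg["gap"], cfg["centromere"], cfg["cytoband"]
    )
    counts = per_chromosome_counts(kept)
    counts.to_csv(out_dir / "chrom_counts.tsv", sep="\t")
    emit("chrom_counts", out_dir / "chrom_counts.tsv")
    windows = make_windows(layout, cfg["window_bp"], cfg["step_bp"], cfg["flank_bp"])
    for label, cnv_type in (("all", None), ("gain", CnvType.GAIN), ("loss", CnvType.LOSS)):
        dens = window_cnv_fraction(windows, kept, layout, cnv_type=cnv_type)
        df = densities_frame(dens)
        df.to_csv(out_dir / f"window_density_{label}.tsv", sep="\t", index=False)
        emit(f"window_density_{label}", out_dir / f"window_density_{label}.tsv")
        profile = profile_by_offset(df)
        profile.to_csv(out_dir / f"density_profile_{label}.tsv", sep="\t", index=False)
        emit(f"density_profile_{label}", out_dir / f"density_profile_{label}.tsv")
        if cfg["plots"] and len(profile):
            plot_density_profile(profile, out_dir / f"density_profile_{label}.png")
    track = genome_track(kept, layout)
    track.to_csv(out_dir / "genome_track.tsv", sep="\t", index=False)
    emit("genome_track", out_dir / "genome_track.tsv")
    if cfg["plots"]:
        plot_genome_track(track, layout, out_dir / "genome_track.png")
    manifest["counts"]["distribution"] = {"n_windows": len(windows)}

    # --- genes ---------------------------------------------------------
    log.info("stage genes")
    gene_models = read_gene_models(cfg["gtf"])
    hits, distinct = intersect_genes(regions, gene_models)
    write_gene_hits(hits, out_dir / "gene_hits.tsv")
    emit("gene_hits", out_dir / "gene_hits.tsv")
    biotypes = tally_biotypes(hits)
    biotypes.to_csv(out_dir / "biotypes.tsv", sep="\t", index=False)
    emit("biotypes", out_dir / "biotypes.tsv")
    phenotype = read_catalog(cfg["phenotype_catalog"])
    expression = read_catalog(cfg["expression_catalog"])
    catalog_table, funnel = annotate_catalogs(distinct, phenotype, expression)
    catalog_table.to_csv(out_dir / "gene_catalog.tsv", sep="\t", index=False)
    emit("gene_catalog", out_dir / "gene_catalog.tsv")
    bands = recurrent_bands(kept, layout)
    write_recurrent_bands(bands, out_dir / "recurrent_bands.tsv")
    emit("recurrent_bands", out_dir / "recurrent_bands.tsv")
    manifest["counts"]["genes"] = {
        "n_hits": len(hits),
        "n_distinct_genes": len(distinct),
        **funnel,
    }

    # --- ora -----------------------------------------------------------
    log.info("stage ora")
    gene_sets = read_gmt(cfg["gmt"])
    universe = sorted(
        {g.gene_name for g in gene_models if g.biotype == "protein_coding"}
    )
    coding_hits = {h.gene_name for h in hits if h.biotype == "protein_coding"}
    gain_regions = {r.region_id for r in regions if r.cnv_type is CnvType.GAIN}
    loss_regions = {r.region_id for r in regions if r.cnv_type is CnvType.LOSS}
    queries = {
        "combined": coding_hits,
        "gain": {
            h.gene_name for h in hits
            if h.biotype == "protein_coding" and h.region_id in gain_regions
        },
        "loss": {
            h.gene_name for h in hits
            if h.biotype == "protein_coding" and h.region_id in loss_regions
        },
    }
    ora_counts = {}
    for label, query in queries.items():
        rows, n_dropped = run_ora(
            query, gene_sets, universe, alpha=cfg["alpha"], adjust=cfg["adjust"]
        )
        write_enrichment(rows, out_dir / f"ora_{label}.tsv")
        emit(f"ora_{label}", out_dir / f"ora_{label}.tsv")
        ora_counts[label] = {
            "n_query": len(query),
            "n_dropped": n_dropped,
            "n_terms": len(rows),
            "n_significant": sum(r.significant for r in rows),
        }
    manifest["counts"]["ora"] = ora_counts

    manifest["runtime_s"] = round(time.time() - started, 3)
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    summarize_run(manifest, out_dir)
    return manifest


def summarize_run(manifest: dict, out_dir: str | Path) -> Path:
    """Write the consolidated report (markdown) from stage outputs."""
    out_dir = Path(out_dir)
    lines = ["# CNV landscape run report", ""]
    counts = manifest["counts"]

    lines += ["## Parameters", ""]
    for key, value in manifest["parameters"].items():
        lines.append(f"- {key}: {value}")
    lines += ["", "## Cohort accounting", ""]
    summary_path = out_dir / "summary.tsv"
    if summary_path.exists():
        lines += ["```", summary_path.read_text().rstrip(), "```", ""]
    agg = counts.get("aggregate", {})
    lines.append(
        f"- {agg.get('n_records', 0)} parsed calls, {agg.get('n_rejects', 0)} rejects, "
        f"{agg.get('n_kept', 0)} within the inclusion window, "
        f"{agg.get('n_cnvr', 0)} CNVRs after deduplication"
    )
    dgv = counts.get("dgv-compare", {})
    lines += [
        "",
        "## Reference comparison",
        "",
        f"- reported: {dgv.get('reported', 0)}, unreported: {dgv.get('unreported', 0)}, "
        f"not evaluable: {dgv.get('not_evaluable', 0)}",
    ]
    bands_path = out_dir / "recurrent_bands.tsv"
    if bands_path.exists():
        lines += ["", "## Top recurrent bands", "", "```"]
        lines += bands_path.read_text().rstrip().splitlines()[:11]
        lines += ["```"]
    bio_path = out_dir / "biotypes.tsv"
    if bio_path.exists():
        lines += ["", "## Gene biotypes", "", "```", bio_path.read_text().rstrip(), "```"]
    genes = counts.get("genes", {})
    lines += [
        "",
        "## Catalog funnel",
        "",
        f"- distinct genes: {genes.get('n_distinct_genes', 0)}",
        f"- with any catalogued phenotype: {genes.get('n_any_phenotype', 0)}",
        "- embryonic lethal / abnormal embryo: "
        f"{genes.get('n_embryonic_lethal_or_abnormal_embryo', 0)}",
        f"- abnormal placenta: {genes.get('n_abnormal_placenta', 0)}",
        f"- placenta expressed: {genes.get('n_placenta_expressed', 0)}",
    ]
    ora_path = out_dir / "ora_combined.tsv"
    if ora_path.exists():
        lines += ["", "## Top enrichment rows (combined)", "", "```"]
        lines += ora_path.read_text().rstrip().splitlines()[:21]
        lines += ["```"]
    report = out_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
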