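"""CNVR gene content: interval intersection with gene models, biotype
tallies, phenotype/expression catalog cross-referencing and recurrent
cytoband ranking.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import CatalogEntry, CnvType, GeneModel, GenomeLayout


@dataclass(frozen=True)
class GeneHit:
    region_id: str
    gene_id: str
    gene_name: str
    biotype: str
    overlap_bp: int


def intersect_genes(
    regions: Sequence,
    gene_models: Sequence[GeneModel],
    min_overlap_bp: int = 1,
) -> tuple[list[GeneHit], list[GeneModel]]:
    """All (region, gene) pairs overlapping by at least ``min_overlap_bp``.

    Any overlap (>= 1 bp) counts by default, the intersect-style
    convention; half-open adjacency ([100,200) vs [200,300)) is not an
    overlap.  A gene overlapped by k regions yields k hits; the distinct
    genes are returned alongside.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in gene_models:
        trees[g.chrom].addi(g.start, g.end, g)

    hits: list[GeneHit] = []
    seen: dict[str, GeneModel] = {}
    for region in regions:
        for iv in sorted(trees[region.chrom].overlap(region.start, region.end)):
            g: GeneModel = iv.data
            overlap = min(region.end, g.end) - max(region.start, g.start)
            if overlap >= min_overlap_bp:
                hits.append(
                    GeneHit(region.region_id, g.gene_id, g.gene_name, g.biotype, overlap)
                )
                seen.setdefault(g.gene_id, g)
    distinct = sorted(seen.values(), key=lambda g: g.gene_id)
    return hits, distinct


#: Biotype classes grouped as "noncoding" in the two-way summary; every
#: biotype not listed here or as protein_coding falls into "other"
#: (pseudogene classes land there under the default grouping).
NONCODING_BIOTYPES = {
    "lincRNA",
    "lncRNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "misc_RNA",
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncrna",
}


def tally_biotypes(
    hits: Sequence[GeneHit],
    noncoding_biotypes: set[str] | None = None,
) -> pd.DataFrame:
    """Distinct-gene counts per biotype, with a protein_coding /
    noncoding / other grouping column.

    Each distinct gene counts once under its biotype regardless of how
    many regions hit it.
    """
    grouping = NONCODING_BIOTYPES if noncoding_biotypes is None else noncoding_biotypes
    by_gene: dict[str, str] = {}
    for h in hits:
        by_gene[h.gene_id] = h.biotype
    counts: dict[str, int] = defaultdict(int)
    for biotype in by_gene.values():
        counts[biotype] += 1
    rows = []
    for biotype in sorted(counts):
        if biotype == "protein_coding":
            group = "protein_coding"
        elif biotype in grouping:
            group = "noncoding"
        else:
            group = "other"
        rows.append({"biotype": biotype, "n_genes": counts[biotype], "group": group})
    return pd.DataFrame(rows, columns=["biotype", "n_genes", "group"])


# catalog category vocabulary
PHENOTYPE_ANY = "any_phenotype"
EMBRYONIC = ("embryonic_lethal", "abnormal_embryo")
PLACENTA_PHENO = "abnormal_placenta"
PLACENTA_EXPR = ("placenta_expressed", "placenta_specific")


def annotate_catalogs(
    genes: Sequence[GeneModel],
    phenotype_catalog: Sequence[CatalogEntry],
    expression_catalog: Sequence[CatalogEntry],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene category flags plus funnel counts.

    Matching is case-sensitive on the gene symbol.  Genes absent from a
    catalog are flagged ``uncataloged`` for it — absence of evidence,
    never treated as a negative phenotype.  The funnel counts, in order:
    genes with any catalogued phenotype, the embryonic-lethal/abnormal-
    embryo subset, the abnormal-placenta subset, and placenta-expressed
    genes.
    """
    pheno: Mapping[str, frozenset[str]] = {e.gene_name: e.categories for e in phenotype_catalog}
    expr: Mapping[str, frozenset[str]] = {e.gene_name: e.categories for e in expression_catalog}

    rows = []
    for g in sorted({g.gene_name: g for g in genes}.values(), key=lambda g: g.gene_name):
        p = pheno.get(g.gene_name)
        x = expr.get(g.gene_name)
        rows.append(
            {
                "gene_name": g.gene_name,
                "biotype": g.biotype,
                "in_phenotype_catalog": p is not None,
                "embryonic_lethal_or_abnormal_embryo": bool(p) and any(c in p for c in EMBRYONIC),
                "abnormal_placenta": bool(p) and PLACENTA_PHENO in p,
                "in_expression_catalog": x is not None,
                "placenta_expressed": bool(x) and any(c in x for c in PLACENTA_EXPR),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_name",
            "biotype",
            "in_phenotype_catalog",
            "embryonic_lethal_or_abnormal_embryo",
            "abnormal_placenta",
            "in_expression_catalog",
            "placenta_expressed",
        ],
    )
    if len(table):
        funnel = {
            "n_genes": int(len(table)),
            "n_any_phenotype": int(table["in_phenotype_catalog"].sum()),
            "n_embryonic_lethal_or_abnormal_embryo": int(
                table["embryonic_lethal_or_abnormal_embryo"].sum()
            ),
            "n_abnormal_placenta": int(table["abnormal_placenta"].sum()),
            "n_placenta_expressed": int(table["placenta_expressed"].sum()),
        }
    else:
        funnel = {
            "n_genes": 0,
            "n_any_phenotype": 0,
            "n_embryonic_lethal_or_abnormal_embryo": 0,
            "n_abnormal_placenta": 0,
            "n_placenta_expressed": 0,
        }
    return table, funnel


@dataclass(frozen=True)
class RecurrentBand:
    band: str  # e.g. 19p13.3
    n_cases: int
    n_gain: int
    n_loss: int
    min_size: int
    max_size: int


def band_full_name(chrom: str, band_name: str) -> str:
    """Cytogenetic band id: chromosome number + band, e.g. chr19 + p13.3."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"{body}{band_name}"


def recurrent_bands(
    records: Sequence, layout: GenomeLayout
) -> list[RecurrentBand]:
    """Rank cytobands by the number of distinct cases carrying an
    overlapping CNV.

    A CNV contributes to every band it overlaps by >= 1 bp.  Recurrence
    counts distinct sample ids; records without a sample id each count as
    their own case (with a warning).  Ties rank by band name.
    """
    samples: dict[str, set[str]] = defaultdict(set)
    gains: dict[str, int] = defaultdict(int)
    losses: dict[str, int] = defaultdict(int)
    sizes: dict[str, list[int]] = defaultdict(list)
    warned = False
    for i, rec in enumerate(records):
        sid = rec.sample_id
        if not sid:
            if not warned:
                warnings.warn(
                    "records without sample_id each count as their own case",
                    stacklevel=2,
                )
                warned = True
            sid = f"__record{i}"
        for s, e, name in layout.cytobands.get(rec.chrom, []):
            if min(rec.end, e) - max(rec.start, s) >= 1:
                band = band_full_name(rec.chrom, name)
                samples[band].add(sid)
                if rec.cnv_type is CnvType.GAIN:
                    gains[band] += 1
                elif rec.cnv_type is CnvType.LOSS:
                    losses[band] += 1
                sizes[band].append(rec.size)
    bands = [
        RecurrentBand(
            band,
            n_cases=len(samples[band]),
            n_gain=gains[band],
            n_loss=losses[band],
            min_size=min(sizes[band]),
            max_size=max(sizes[band]),
        )
        for band in samples
    ]
    bands.sort(key=lambda b: (-b.n_cases, b.band))
    return bands


def write_gene_hits(hits: Sequence[GeneHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("region_id\tgene_id\tgene_name\tbiotype\toverlap_bp\n")
        for h in hits:
            fh.write(
                f"{h.region_id}\t{h.gene_id}\t{h.gene_name}\t{h.biotype}\t{h.overlap_bp}\n"
            )


def write_recurrent_bands(bands: Sequence[RecurrentBand], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("band\tn_cases\tn_gain\tn_loss\tmin_size\tmax_size\n")
        for b in bands:
            fh.write(
                f"{b.band}\t{b.n_cases}\t{b.n_gain}\t{b.n_loss}\t{b.min_size}\t{b.max_size}\n"
            )
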