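"""Synthetic genomes, CNV cohorts, reference catalogs, annotations and
gene sets with known ground truth.

The generator emulates the pooled study conditions: roughly 564 CNV calls
from 442 cases, sizes drawn from a truncated log-normal with mean about
690 kb on 6 kb–3 Mb support, gains outnumbering losses about 2:1, a small
unknown-direction fraction, positional bias toward pericentromeric and
sub-telomeric flanks, a planted recurrent sub-telomeric band, planted
exact duplicates to exercise deduplication, a reference catalog with a
controlled reported fraction, and a planted over-represented gene-set
term.  Every stage writes the exact file dialects the readers in
:mod:`cnvmap.io` parse, plus a truth JSON that fully determines the
expected output of each downstream pipeline stage.

One root seed derives independent per-stage streams (genome, cohort,
reference, annotation), so identical configurations reproduce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregate import deduplicate
from .io import (
    CnvRecord,
    CnvType,
    GeneModel,
    GenomeLayout,
    GeneSet,
    CatalogEntry,
    RefType,
    ReferenceVariant,
    write_catalog,
    write_cnv_table,
    write_gene_models,
    write_gmt,
    write_reference_variants,
)

# truncated log-normal parameters solved so the mean CNV size on
# [6 kb, 3 Mb) support is ~690 kb (median ~515 kb, ~5% of mass re-drawn
# above the 3 Mb cap)
SIZE_LOG_MU = 13.1513
SIZE_LOG_SIGMA = 1.1


@dataclass
class SimConfig:
    """All knobs of the synthetic bundle; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chromosomes: int = 8
    chrom_length: int = 80_000_000
    centromere_halfwidth: int = 400_000
    n_random_gaps: int = 2  # per chromosome, besides centromere/telomere gaps
    random_gap_size: tuple[int, int] = (50_000, 200_000)
    telomere_gap: int = 10_000
    bands_per_arm: int = 8
    # cohort
    n_samples: int = 442
    n_cnvs: int = 564
    size_min: int = 6_000
    size_max: int = 3_000_000
    size_log_mu: float = SIZE_LOG_MU
    size_log_sigma: float = SIZE_LOG_SIGMA
    gain_fraction: float = 349 / 564
    unknown_fraction: float = 30 / 564
    pericentromeric_bias: float = 3.0
    bias_flank_bp: int = 9_000_000
    planted_band: str = "1p8"  # sub-telomeric band on the first chromosome
    planted_n_samples: int = 12
    planted_gain_fraction: float = 0.75
    planted_size_range: tuple[int, int] = (523_900, 1_500_000)
    n_duplicates: int = 85
    # reference
    reported_fraction: float = 0.52
    decoy_fraction: float = 0.5  # of intended-unreported regions, emit a decoy
    jitter_shrink: float = 0.10  # per-flank shrink of matching reference variants
    # annotation / gene sets / catalogs
    n_genes: int = 600
    gene_size_range: tuple[int, int] = (5_000, 50_000)
    biotype_mix: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.45,
            "lincRNA": 0.20,
            "miRNA": 0.10,
            "processed_pseudogene": 0.15,
            "antisense": 0.10,
        }
    )
    n_terms: int = 20
    term_size_range: tuple[int, int] = (20, 60)
    planted_term_size: int = 40
    planted_term_query_overlap: int = 30
    catalog_lethal_fraction: float = 0.25
    catalog_placenta_fraction: float = 0.05
    catalog_expressed_fraction: float = 0.10

    @classmethod
    def hg19_scale(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Load-testing preset with chromosome sizes near the real genome
        (23 x 130 Mb); analyses stay identical, only slower."""
        defaults = dict(seed=seed, n_chromosomes=23, chrom_length=130_000_000,
                        n_genes=3_000)
        defaults.update(overrides)
        return cls(**defaults)

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genome", "cohort", "reference", "annotation")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# genome


def make_genome(config: SimConfig, out_dir: str | Path) -> tuple[GenomeLayout, dict]:
    """Emit chrom.sizes, gap, centromere and cytoband files plus the layout.

    Chromosomes are metacentric with the centromere at the midpoint (also
    recorded as a gap, as in hg19), short telomeric gaps at both ends,
    and ``n_random_gaps`` additional assembly gaps; cytobands tile each
    arm into ``bands_per_arm`` equal bands named distally-to-proximally
    on the p arm (pK..p1, then q1..qK), so band "1p8" under the defaults
    abuts the first chromosome's p telomere, like the 19p13.3 hotspot.
    """
    rng = config.streams()["genome"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length
    chrom_lengths = {c: L for c in chroms}
    mid = L // 2
    centromeres = {c: (mid - config.centromere_halfwidth, mid + config.centromere_halfwidth) for c in chroms}

    gaps: dict[str, list[tuple[int, int]]] = {}
    for c in chroms:
        g = [
            (0, config.telomere_gap),
            (L - config.telomere_gap, L),
            centromeres[c],
        ]
        for _ in range(config.n_random_gaps):
            size = int(rng.integers(*config.random_gap_size))
            start = int(rng.integers(config.telomere_gap, L - config.telomere_gap - size))
            g.append((start, start + size))
        gaps[c] = sorted(g)

    cytobands: dict[str, list[tuple[int, int, str]]] = {}
    for c in chroms:
        cen_start, cen_end = centromeres[c]
        bands = []
        k = config.bands_per_arm
        p_edges = np.linspace(0, cen_start, k + 1).astype(int)
        for i in range(k):
            bands.append((int(p_edges[i]), int(p_edges[i + 1]), f"p{k - i}"))
        bands.append((cen_start, cen_end, "cen"))
        q_edges = np.linspace(cen_end, L, k + 1).astype(int)
        for i in range(k):
            bands.append((int(q_edges[i]), int(q_edges[i + 1]), f"q{i + 1}"))
        cytobands[c] = bands

    layout = GenomeLayout(chrom_lengths, gaps, centromeres, cytobands)

    paths = {
        "sizes": out_dir / "chrom.sizes",
        "gap": out_dir / "gap.txt",
        "centromere": out_dir / "centromere.txt",
        "cytoband": out_dir / "cytoBand.txt",
    }
    with paths["sizes"].open("w") as fh:
        for c in chroms:
            fh.write(f"{c}\t{chrom_lengths[c]}\n")
    with paths["gap"].open("w") as fh:
        for c in chroms:
            for s, e in gaps[c]:
                fh.write(f"{c}\t{s}\t{e}\tgap\n")
    with paths["centromere"].open("w") as fh:
        for c in chroms:
            s, e = centromeres[c]
            fh.write(f"{c}\t{s}\t{e}\tacen\n")
    with paths["cytoband"].open("w") as fh:
        for c in chroms:
            for s, e, name in cytobands[c]:
                stain = "acen" if name == "cen" else "gneg"
                fh.write(f"{c}\t{s}\t{e}\t{name}\t{stain}\n")
    return layout, {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# cohort


def _band_interval(layout: GenomeLayout, band: str) -> tuple[str, int, int]:
    for chrom, bands in layout.cytobands.items():
        body = chrom[3:] if chrom.startswith("chr") else chrom
        for s, e, name in bands:
            if f"{body}{name}" == band:
                return chrom, s, e
    raise ValueError(f"planted band {band!r} absent from layout")


def _draw_size(rng: np.random.Generator, config: SimConfig) -> int:
    while True:
        size = float(rng.lognormal(config.size_log_mu, config.size_log_sigma))
        if config.size_min <= size < config.size_max:
            return int(size)


def _biased_point(rng: np.random.Generator, layout: GenomeLayout, chrom: str,
                  config: SimConfig) -> int:
    """Draw a target point with extra weight in pericentromeric and
    sub-telomeric flanks."""
    L = layout.chrom_lengths[chrom]
    w = config.pericentromeric_bias
    if w == 1.0 or chrom not in layout.centromeres:
        return int(rng.integers(0, L))
    f = config.bias_flank_bp
    cen_s, cen_e = layout.centromeres[chrom]
    zones = [
        (0, min(f, L)),
        (max(0, cen_s - f), cen_s),
        (cen_e, min(L, cen_e + f)),
        (max(0, L - f), L),
    ]
    zones = [(s, e) for s, e in zones if e > s]
    # merge flank zones, then weight them w vs 1 for the remainder
    from .distribution import merge_intervals, subtract_intervals

    flanks = merge_intervals(zones)
    rest = subtract_intervals((0, L), flanks)
    weights = [w * (e - s) for s, e in flanks] + [float(e - s) for s, e in rest]
    pieces = flanks + rest
    total = sum(weights)
    idx = rng.choice(len(pieces), p=[x / total for x in weights])
    s, e = pieces[idx]
    return int(rng.integers(s, e))


def _draw_type(rng: np.random.Generator, gain_fraction: float,
               unknown_fraction: float) -> CnvType:
    u = rng.random()
    if u < unknown_fraction:
        return CnvType.UNKNOWN
    # gain_fraction is the *overall* target fraction, unknowns included
    if rng.random() < gain_fraction / (1 - unknown_fraction):
        return CnvType.GAIN
    return CnvType.LOSS


def simulate_cohort(
    layout: GenomeLayout, config: SimConfig
) -> tuple[list[CnvRecord], dict]:
    """Generate the CNV call table plus its ground truth.

    The table contains, in order: background calls, the planted recurrent
    calls (one per planted sample, inside the planted band), and exact
    duplicates of randomly chosen earlier calls assigned to different
    samples.  Because background breakpoints are drawn from a continuous
    range, the CNVR count after exact deduplication equals
    ``n_cnvs − n_duplicates``.
    """
    rng = config.streams()["cohort"]
    n_background = config.n_cnvs - config.planted_n_samples - config.n_duplicates
    if n_background < 0:
        raise ValueError("planted + duplicate counts exceed n_cnvs")

    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    chroms = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    records: list[CnvRecord] = []
    provenance: list[dict] = []

    for _ in range(n_background):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        L = layout.chrom_lengths[chrom]
        size = _draw_size(rng, config)
        point = _biased_point(rng, layout, chrom, config)
        start = int(np.clip(point - size // 2, 0, L - size))
        sample = samples[int(rng.integers(len(samples)))]
        records.append(
            CnvRecord(
                sample, "synthetic", chrom, start, start + size,
                _draw_type(rng, config.gain_fraction, config.unknown_fraction),
            )
        )
        provenance.append({"origin": "background"})

    band_chrom, band_s, band_e = _band_interval(layout, config.planted_band)
    planted_samples = [
        samples[i]
        for i in rng.choice(len(samples), config.planted_n_samples, replace=False)
    ]
    n_gain = int(round(config.planted_gain_fraction * config.planted_n_samples))
    for j, sample in enumerate(planted_samples):
        lo, hi = config.planted_size_range
        size = int(rng.integers(lo, min(hi, band_e - band_s)))
        start = int(rng.integers(band_s, band_e - size))
        cnv_type = CnvType.GAIN if j < n_gain else CnvType.LOSS
        records.append(
            CnvRecord(sample, "synthetic", band_chrom, start, start + size, cnv_type)
        )
        provenance.append({"origin": "planted_recurrent", "band": config.planted_band})

    dup_pairs = []
    for _ in range(config.n_duplicates):
        src_idx = int(rng.integers(len(records)))
        src = records[src_idx]
        others = [s for s in samples if s != src.sample_id]
        sample = others[int(rng.integers(len(others)))]
        records.append(
            CnvRecord(sample, "synthetic", src.chrom, src.start, src.end, src.cnv_type)
        )
        provenance.append({"origin": "duplicate", "duplicate_of": src_idx})
        dup_pairs.append((src_idx, len(records) - 1))

    truth = {
        "n_records": len(records),
        "n_background": n_background,
        "planted_band": config.planted_band,
        "planted_samples": sorted(planted_samples),
        "n_planted": config.planted_n_samples,
        "n_duplicates": config.n_duplicates,
        "duplicate_pairs": dup_pairs,
        "provenance": provenance,
        "expected_n_cnvr": config.n_cnvs - config.n_duplicates,
    }
    return records, truth


# ---------------------------------------------------------------------------
# reference set


def _brute_force_status(region, reference: list[ReferenceVariant],
                        threshold: float = 0.75) -> str:
    """All-pairs reported/unreported call, independent of the pipeline's
    indexed classifier (used only for generator bookkeeping)."""
    if region.cnv_type is CnvType.UNKNOWN:
        return "not_evaluable"
    a_len = region.end - region.start
    for ref in reference:
        if ref.chrom != region.chrom:
            continue
        if ref.ref_type is not RefType.BOTH and ref.ref_type.value != region.cnv_type.value:
            continue
        inter = min(region.end, ref.end) - max(region.start, ref.start)
        if inter <= 0:
            continue
        ro = min(inter / a_len, inter / (ref.end - ref.start))
        if ro > threshold:
            return "reported"
    return "unreported"


def make_reference_set(
    records: list[CnvRecord], config: SimConfig
) -> tuple[list[ReferenceVariant], dict]:
    """Build a reference catalog with a controlled reported fraction.

    The cohort is deduplicated into CNVRs; an exact ``reported_fraction``
    share of the direction-evaluable CNVRs is sampled as *intended
    reported* and receives a matching-direction reference variant shrunk
    by ``jitter_shrink`` per flank (reciprocal overlap 1 − 2·shrink,
    comfortably above 0.75).  Of the remaining evaluable CNVRs, a
    ``decoy_fraction`` share receives a decoy that fails the rule —
    opposite direction at the same coordinates, or same direction shifted
    by 60% of the length (reciprocal overlap 0.4).

    Because CNVRs can overlap each other, a variant planted for one CNVR
    may incidentally satisfy the rule for a neighbour; the recorded truth
    status is therefore recomputed per CNVR against the finished catalog
    with an all-pairs sweep, so truth and emitted files are always
    mutually consistent.  Intended assignments are kept alongside.
    """
    rng = config.streams()["reference"]
    regions = deduplicate(records)
    evaluable = [r for r in regions if r.cnv_type is not CnvType.UNKNOWN]
    n_reported = int(round(config.reported_fraction * len(evaluable)))
    reported_idx = set(
        rng.choice(len(evaluable), n_reported, replace=False).tolist()
    )

    reference: list[ReferenceVariant] = []
    intended: dict[str, str] = {}
    ref_no = 0
    for i, region in enumerate(evaluable):
        if i in reported_idx:
            shrink = int(region.size * config.jitter_shrink)
            start, end = region.start + shrink, region.end - shrink
            if end <= start:  # degenerate tiny region: copy exactly
                start, end = region.start, region.end
            ref_no += 1
            reference.append(
                ReferenceVariant(
                    f"ref{ref_no:05d}", region.chrom, start, end,
                    RefType(region.cnv_type.value),
                )
            )
            intended[region.region_id] = "reported"
        else:
            intended[region.region_id] = "unreported"
            if rng.random() < config.decoy_fraction:
                ref_no += 1
                if rng.random() < 0.5:  # wrong direction, same coordinates
                    flipped = RefType.LOSS if region.cnv_type is CnvType.GAIN else RefType.GAIN
                    reference.append(
                        ReferenceVariant(
                            f"ref{ref_no:05d}", region.chrom,
                            region.start, region.end, flipped,
                        )
                    )
                else:  # same direction, shifted to reciprocal overlap 0.4
                    shift = int(region.size * 0.6) or 1
                    reference.append(
                        ReferenceVariant(
                            f"ref{ref_no:05d}", region.chrom,
                            region.start + shift, region.end + shift,
                            RefType(region.cnv_type.value),
                        )
                    )

    status = {r.region_id: _brute_force_status(r, reference) for r in regions}
    truth = {
        "n_cnvr": len(regions),
        "n_evaluable": len(evaluable),
        "n_intended_reported": n_reported,
        "intended": intended,
        "status": status,
    }
    return reference, truth


# ---------------------------------------------------------------------------
# annotation, gene sets, catalogs


def make_gene_annotation_and_sets(
    layout: GenomeLayout,
    config: SimConfig,
    records: list[CnvRecord] | None = None,
) -> tuple[list[GeneModel], list[GeneSet], list[CatalogEntry], list[CatalogEntry], dict]:
    """Generate gene models, GMT terms, and phenotype/expression catalogs.

    Genes are placed uniformly with the configured biotype mix.  When the
    cohort is supplied, the planted GMT term draws
    ``planted_term_query_overlap`` of its members from protein-coding
    genes overlapped by a CNVR (the eventual ORA query) and the rest from
    unhit genes, so the term is genuinely over-represented; decoy terms
    are uniform draws from the protein-coding universe.
    """
    rng = config.streams()["annotation"]
    chroms = list(layout.chrom_lengths)
    biotypes = list(config.biotype_mix)
    probs = np.array([config.biotype_mix[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = layout.chrom_lengths[chrom]
        size = int(rng.integers(*config.gene_size_range))
        start = int(rng.integers(0, L - size))
        biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
        genes.append(
            GeneModel(
                gene_id=f"SYNG{i + 1:05d}",
                gene_name=f"GENE{i + 1:04d}",
                biotype=biotype,
                chrom=chrom,
                start=start,
                end=start + size,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )

    coding = [g for g in genes if g.biotype == "protein_coding"]
    coding_symbols = [g.gene_name for g in coding]

    hit_symbols: set[str] = set()
    if records is not None:
        cnv_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in records:
            cnv_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for g in coding:
            for s, e in cnv_by_chrom.get(g.chrom, []):
                if min(e, g.end) - max(s, g.start) >= 1:
                    hit_symbols.add(g.gene_name)
                    break

    gene_sets: list[GeneSet] = []
    planted_term_id = "TERM_PLANTED"
    hit_list = sorted(hit_symbols)
    unhit_list = sorted(set(coding_symbols) - hit_symbols)
    n_from_query = min(config.planted_term_query_overlap, len(hit_list))
    n_filler = min(config.planted_term_size - n_from_query, len(unhit_list))
    members = [
        hit_list[i] for i in rng.choice(len(hit_list), n_from_query, replace=False)
    ] + [
        unhit_list[i] for i in rng.choice(len(unhit_list), n_filler, replace=False)
    ]
    if members:
        gene_sets.append(
            GeneSet(planted_term_id, "planted over-represented term", frozenset(members))
        )
    for t in range(config.n_terms):
        size = int(rng.integers(*config.term_size_range))
        size = min(size, len(coding_symbols))
        members = [
            coding_symbols[i]
            for i in rng.choice(len(coding_symbols), size, replace=False)
        ]
        gene_sets.append(
            GeneSet(f"TERM{t + 1:03d}", f"random term {t + 1}", frozenset(members))
        )

    # phenotype catalog: flag random coding genes as lethal and/or placental
    n_lethal = int(round(config.catalog_lethal_fraction * len(coding_symbols)))
    n_plac = int(round(config.catalog_placenta_fraction * len(coding_symbols)))
    lethal = {
        coding_symbols[i]
        for i in rng.choice(len(coding_symbols), n_lethal, replace=False)
    }
    placental = {
        coding_symbols[i]
        for i in rng.choice(len(coding_symbols), n_plac, replace=False)
    }
    phenotype = []
    for sym in sorted(lethal | placental):
        cats = set()
        if sym in lethal:
            cats.add("embryonic_lethal" if rng.random() < 0.6 else "abnormal_embryo")
        if sym in placental:
            cats.add("abnormal_placenta")
        phenotype.append(CatalogEntry(sym, frozenset(cats)))

    n_expr = int(round(config.catalog_expressed_fraction * len(coding_symbols)))
    expressed = {
        coding_symbols[i]
        for i in rng.choice(len(coding_symbols), n_expr, replace=False)
    }
    expression = [
        CatalogEntry(
            sym,
            frozenset(
                ["placenta_specific" if rng.random() < 0.3 else "placenta_expressed"]
            ),
        )
        for sym in sorted(expressed)
    ]

    biotype_truth: dict[str, int] = {}
    for g in genes:
        biotype_truth[g.biotype] = biotype_truth.get(g.biotype, 0) + 1
    truth = {
        "n_genes": len(genes),
        "biotype_counts": biotype_truth,
        "planted_term": planted_term_id,
        "planted_term_members_in_query": n_from_query,
        "n_hit_coding_genes": len(hit_symbols),
        "lethal_genes": sorted(lethal),
        "placental_phenotype_genes": sorted(placental),
        "expressed_genes": sorted(expressed),
    }
    return genes, gene_sets, phenotype, expression, truth


# ---------------------------------------------------------------------------
# full bundle


def make_bundle(config: SimConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic input bundle plus truth.json.

    Returns a manifest of file paths; every file is in a dialect
    :mod:`cnvmap.io` reads back, so the bundle can drive the whole
    pipeline end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout, genome_paths = make_genome(config, out_dir)
    records, cohort_truth = simulate_cohort(layout, config)
    reference, ref_truth = make_reference_set(records, config)
    genes, gene_sets, phenotype, expression, anno_truth = (
        make_gene_annotation_and_sets(layout, config, records)
    )

    paths = dict(genome_paths)
    paths["cnv"] = str(out_dir / "cnv_calls.tsv")
    write_cnv_table(records, paths["cnv"])
    paths["reference"] = str(out_dir / "reference_variants.tsv")
    write_reference_variants(reference, paths["reference"])
    paths["gtf"] = str(out_dir / "genes.gtf")
    write_gene_models(genes, paths["gtf"])
    paths["gmt"] = str(out_dir / "gene_sets.gmt")
    write_gmt(gene_sets, paths["gmt"])
    paths["phenotype_catalog"] = str(out_dir / "phenotype_catalog.tsv")
    write_catalog(phenotype, paths["phenotype_catalog"])
    paths["expression_catalog"] = str(out_dir / "expression_catalog.tsv")
    write_catalog(expression, paths["expression_catalog"])

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "cohort": cohort_truth,
        "reference": ref_truth,
        "annotation": anno_truth,
    }
    paths["truth"] = str(out_dir / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
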