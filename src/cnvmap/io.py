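"""Readers and writers for every external file format the pipeline touches.

All coordinates are normalised at this boundary to 0-based half-open
intervals and chromosome names to the UCSC ``chr``-prefixed convention;
nothing downstream ever converts coordinates again.  Readers never drop
rows silently: anything unparseable is returned in a rejects list with a
reason, so ``len(rows) == len(records) + len(rejects)`` always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class CnvType(str, Enum):
    """Direction of a copy-number change."""

    GAIN = "gain"
    LOSS = "loss"
    UNKNOWN = "unknown"


class RefType(str, Enum):
    """Direction recorded for a reference (population) variant."""

    GAIN = "gain"
    LOSS = "loss"
    BOTH = "both"


#: Default mapping from the heterogeneous labels used by source studies to
#: the internal trichotomy.  Callers may pass an extended copy.
TYPE_SYNONYMS: dict[str, CnvType] = {
    "gain": CnvType.GAIN,
    "dup": CnvType.GAIN,
    "duplication": CnvType.GAIN,
    "microduplication": CnvType.GAIN,
    "loss": CnvType.LOSS,
    "del": CnvType.LOSS,
    "deletion": CnvType.LOSS,
    "microdeletion": CnvType.LOSS,
    "unknown": CnvType.UNKNOWN,
    "na": CnvType.UNKNOWN,
    "n/a": CnvType.UNKNOWN,
    "": CnvType.UNKNOWN,
}

REF_TYPE_SYNONYMS: dict[str, RefType] = {
    "gain": RefType.GAIN,
    "duplication": RefType.GAIN,
    "loss": RefType.LOSS,
    "deletion": RefType.LOSS,
    "gain+loss": RefType.BOTH,
    "both": RefType.BOTH,
}


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


def normalize_chrom(name: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name.

    Accepts both UCSC (``chr1``) and Ensembl (``1``) styles; ``MT`` is
    mapped to ``chrM``.
    """
    name = name.strip()
    if name.upper() == "MT":
        return "chrM"
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class CnvRecord:
    """One CNV call from one sample: a half-open genomic interval plus type."""

    sample_id: str
    source: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    cnv_type: CnvType
    platform: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene locus from the annotation, with its biotype."""

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval [{self.start},{self.end})")
        if not self.biotype:
            raise ValueError(f"gene {self.gene_id} has empty biotype")


@dataclass(frozen=True)
class ReferenceVariant:
    """A structural variant from a reference catalog of healthy individuals."""

    ref_id: str
    chrom: str
    start: int
    end: int
    ref_type: RefType

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")


@dataclass(frozen=True)
class GeneSet:
    """One functional term (GO/KEGG-style) and its member gene symbols."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


@dataclass(frozen=True)
class CatalogEntry:
    """Phenotype/expression annotations for one gene symbol."""

    gene_name: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"catalog entry {self.gene_name} has no categories")


@dataclass
class GenomeLayout:
    """Chromosome lengths plus gap, centromere and cytoband interval tracks.

    Telomere anchor positions are implicit: position 0 and the chromosome
    length.  All intervals are validated to lie within their chromosome.
    """

    chrom_lengths: dict[str, int]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    cytobands: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise FormatError(f"{chrom}: non-positive length {length}")
        for track_name, track in (("gap", self.gaps), ("cytoband", self.cytobands)):
            for chrom, ivals in track.items():
                length = self._require_length(chrom, track_name)
                for iv in ivals:
                    s, e = iv[0], iv[1]
                    if not (0 <= s < e <= length):
                        raise FormatError(
                            f"{track_name} interval [{s},{e}) exceeds "
                            f"chromosome {chrom} (length {length})"
                        )
        for chrom, (s, e) in self.centromeres.items():
            length = self._require_length(chrom, "centromere")
            if not (0 <= s < e <= length):
                raise FormatError(
                    f"centromere [{s},{e}) exceeds chromosome {chrom}"
                )
        for chrom, bands in self.cytobands.items():
            ordered = sorted(bands)
            for (s1, e1, _), (s2, _e2, _) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise FormatError(f"overlapping cytobands on {chrom}")
            self.cytobands[chrom] = ordered

    def _require_length(self, chrom: str, what: str) -> int:
        if chrom not in self.chrom_lengths:
            raise FormatError(
                f"{what} refers to {chrom}, absent from the sizes file"
            )
        return self.chrom_lengths[chrom]

    def length(self, chrom: str) -> int:
        """Length lookup accepting both bare and chr-prefixed names."""
        return self.chrom_lengths[normalize_chrom(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.chrom_lengths


@dataclass(frozen=True)
class RejectedRow:
    line_no: int
    content: str
    reason: str


# ---------------------------------------------------------------------------
# CNV call tables


def read_cnv_table(
    path: str | Path,
    dialect: str = "tsv_1based",
    source_label: str | None = None,
    type_synonyms: dict[str, CnvType] | None = None,
) -> tuple[list[CnvRecord], list[RejectedRow]]:
    """Read a CNV call table into records plus a rejects report.

    Parameters
    ----------
    dialect
        ``tsv_1based``: headered TSV with columns ``sample``, ``chrom``,
        ``start``, ``end``, ``type`` (and optional ``source``,
        ``platform``), coordinates 1-based inclusive.
        ``bed_0based``: headerless BED3+ (chrom, start, end, type
        [, sample]), coordinates already 0-based half-open.
    source_label
        Label recorded on every record; for the TSV dialect a ``source``
        column, when present, takes precedence.

    Returns
    -------
    (records, rejects) with ``len(rows) == len(records) + len(rejects)``.
    """
    if dialect not in ("tsv_1based", "bed_0based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    synonyms = dict(TYPE_SYNONYMS)
    if type_synonyms:
        synonyms.update(type_synonyms)

    path = Path(path)
    records: list[CnvRecord] = []
    rejects: list[RejectedRow] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv_1based":
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = [h.strip().lower() for h in lines[0].split("\t")]
        required = ("sample", "chrom", "start", "end", "type")
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column '{col}'")
        idx = {name: header.index(name) for name in header}
        body = lines[1:]
        offset = 2
    else:
        idx = {}
        body = lines
        offset = 1

    for line_no, line in enumerate(body, start=offset):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if dialect == "tsv_1based":
                sample = fields[idx["sample"]].strip()
                chrom = normalize_chrom(fields[idx["chrom"]])
                start = int(fields[idx["start"]]) - 1  # 1-based -> 0-based
                end = int(fields[idx["end"]])
                raw_type = fields[idx["type"]].strip().lower()
                source = (
                    fields[idx["source"]].strip()
                    if "source" in idx and idx["source"] < len(fields)
                    else (source_label or "unspecified")
                )
                platform = (
                    fields[idx["platform"]].strip()
                    if "platform" in idx and idx["platform"] < len(fields)
                    else None
                )
            else:
                chrom = normalize_chrom(fields[0])
                start = int(fields[1])
                end = int(fields[2])
                raw_type = fields[3].strip().lower() if len(fields) > 3 else ""
                sample = fields[4].strip() if len(fields) > 4 else f"row{line_no}"
                source = source_label or "unspecified"
                platform = None
        except (IndexError, ValueError) as exc:
            rejects.append(RejectedRow(line_no, line, f"unparseable row: {exc}"))
            continue
        if raw_type not in synonyms:
            rejects.append(
                RejectedRow(line_no, line, f"unrecognised type '{raw_type}'")
            )
            continue
        if end <= start:
            rejects.append(RejectedRow(line_no, line, "inverted interval"))
            continue
        if start < 0:
            rejects.append(RejectedRow(line_no, line, "negative coordinate"))
            continue
        records.append(
            CnvRecord(sample, source, chrom, start, end, synonyms[raw_type], platform)
        )
    return records, rejects


def write_cnv_table(records: Sequence[CnvRecord], path: str | Path) -> None:
    """Write records in the headered 1-based TSV dialect (round-trips)."""
    with Path(path).open("w") as fh:
        fh.write("sample\tchrom\tstart\tend\ttype\tsource\tplatform\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start + 1}\t{r.end}\t"
                f"{r.cnv_type.value}\t{r.source}\t{r.platform or ''}\n"
            )


def write_rejects(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("line_no\treason\tcontent\n")
        for r in rejects:
            fh.write(f"{r.line_no}\t{r.reason}\t{r.content}\n")


# ---------------------------------------------------------------------------
# Genome layout (UCSC-style files)


def _read_ucsc_intervals(path: str | Path) -> list[tuple[str, int, int, list[str]]]:
    """Parse a UCSC tab file as (chrom, start, end, extra columns).

    Tolerates the database-dump variant with a leading integer ``bin``
    column, as in ``gap.txt`` / ``cytoBand.txt`` downloads.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        shift = 0
        try:
            int(fields[0])
            shift = 1  # leading bin column
        except ValueError:
            pass
        chrom = normalize_chrom(fields[shift])
        start, end = int(fields[shift + 1]), int(fields[shift + 2])
        out.append((chrom, start, end, fields[shift + 3:]))
    return out


def read_genome_layout(
    sizes_path: str | Path,
    gap_path: str | Path | None = None,
    centromere_path: str | Path | None = None,
    cytoband_path: str | Path | None = None,
) -> GenomeLayout:
    """Assemble a validated :class:`GenomeLayout` from UCSC-style files."""
    chrom_lengths: dict[str, int] = {}
    for line in Path(sizes_path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, length = line.split("\t")[:2]
        chrom_lengths[normalize_chrom(chrom)] = int(length)

    gaps: dict[str, list[tuple[int, int]]] = {}
    if gap_path is not None:
        for chrom, start, end, _extra in _read_ucsc_intervals(gap_path):
            gaps.setdefault(chrom, []).append((start, end))
        for ivals in gaps.values():
            ivals.sort()

    centromeres: dict[str, tuple[int, int]] = {}
    if centromere_path is not None:
        for chrom, start, end, _extra in _read_ucsc_intervals(centromere_path):
            if chrom in centromeres:
                prev = centromeres[chrom]
                centromeres[chrom] = (min(prev[0], start), max(prev[1], end))
            else:
                centromeres[chrom] = (start, end)

    cytobands: dict[str, list[tuple[int, int, str]]] = {}
    if cytoband_path is not None:
        for chrom, start, end, extra in _read_ucsc_intervals(cytoband_path):
            name = extra[0] if extra else f"{start}-{end}"
            cytobands.setdefault(chrom, []).append((start, end, name))

    return GenomeLayout(chrom_lengths, gaps, centromeres, cytobands)


# ---------------------------------------------------------------------------
# Gene models (GTF, GENCODE dialect)


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Read gene-level rows from a GENCODE-style GTF.

    Only ``feature == "gene"`` rows contribute; coordinates convert from
    GTF's 1-based inclusive to 0-based half-open.  Duplicate gene_ids and
    missing biotype attributes are format errors.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_rows = 0
    for line_no, line in enumerate(Path(gtf_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"{gtf_path}:{line_no}: fewer than 9 GTF columns")
        n_rows += 1
        if fields[2] != "gene":
            continue
        attrs = _parse_gtf_attributes(fields[8])
        biotype = attrs.get("gene_type") or attrs.get("gene_biotype")
        if not biotype:
            raise FormatError(
                f"{gtf_path}:{line_no}: gene row missing "
                "gene_type/gene_biotype attribute"
            )
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise FormatError(f"{gtf_path}:{line_no}: gene row missing gene_id")
        if gene_id in seen:
            raise FormatError(f"{gtf_path}:{line_no}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=attrs.get("gene_name", gene_id),
                biotype=biotype,
                chrom=normalize_chrom(fields[0]),
                start=int(fields[3]) - 1,
                end=int(fields[4]),
                strand=fields[6],
            )
        )
    if n_rows and not genes:
        warnings.warn(f"{gtf_path}: no gene-level rows found", stacklevel=2)
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene-level GTF rows (round-trips through read_gene_models)."""
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_type "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Reference variants


def read_reference_variants(
    path: str | Path, dialect: str = "dgv_flat"
) -> tuple[list[ReferenceVariant], int]:
    """Read a reference variant catalog.

    ``dgv_flat``: headered TSV with at least ``variantaccession``/``chr``/
    ``start``/``end``/``variantsubtype`` columns, 1-based inclusive
    coordinates (the DGV flat-file layout).  ``bed_typed``: headerless
    chrom/start/end/id/type with 0-based half-open coordinates.

    Returns the variants plus the count of records skipped for having a
    subtype outside the gain/loss/both vocabulary (e.g. inversions).
    """
    if dialect not in ("dgv_flat", "bed_typed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    variants: list[ReferenceVariant] = []
    n_skipped = 0
    if dialect == "dgv_flat":
        header = [h.strip().lower() for h in lines[0].split("\t")]
        for col in ("chr", "start", "end", "variantsubtype"):
            if col not in header:
                raise FormatError(f"{path}: missing required column '{col}'")
        idx = {name: header.index(name) for name in header}
        id_col = idx.get("variantaccession")
        for i, line in enumerate(lines[1:], 2):
            fields = line.split("\t")
            subtype = fields[idx["variantsubtype"]].strip().lower()
            if subtype not in REF_TYPE_SYNONYMS:
                n_skipped += 1
                continue
            variants.append(
                ReferenceVariant(
                    ref_id=fields[id_col] if id_col is not None else f"ref{i}",
                    chrom=normalize_chrom(fields[idx["chr"]]),
                    start=int(fields[idx["start"]]) - 1,
                    end=int(fields[idx["end"]]),
                    ref_type=REF_TYPE_SYNONYMS[subtype],
                )
            )
    else:
        for i, line in enumerate(lines, 1):
            fields = line.split("\t")
            subtype = fields[4].strip().lower()
            if subtype not in REF_TYPE_SYNONYMS:
                n_skipped += 1
                continue
            variants.append(
                ReferenceVariant(
                    ref_id=fields[3],
                    chrom=normalize_chrom(fields[0]),
                    start=int(fields[1]),
                    end=int(fields[2]),
                    ref_type=REF_TYPE_SYNONYMS[subtype],
                )
            )
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} records with unmapped subtype",
            stacklevel=2,
        )
    return variants, n_skipped


def write_reference_variants(
    variants: Sequence[ReferenceVariant], path: str | Path
) -> None:
    """Write the bed_typed dialect (round-trips)."""
    with Path(path).open("w") as fh:
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.start}\t{v.end}\t{v.ref_id}\t{v.ref_type.value}\n"
            )


# ---------------------------------------------------------------------------
# Gene sets and catalogs


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{line_no}: GMT line with <3 fields")
        members = [m for m in fields[2:] if m]
        if len(set(members)) != len(members):
            warnings.warn(
                f"{path}:{line_no}: duplicate members in {fields[0]}",
                stacklevel=2,
            )
        sets.append(GeneSet(fields[0], fields[1], frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write(f"{s.term_id}\t{s.term_name}\t" + "\t".join(sorted(s.members)) + "\n")


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read a per-gene catalog: ``gene<TAB>cat1;cat2;...`` lines."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, _, cats = line.partition("\t")
        categories = frozenset(c.strip() for c in cats.split(";") if c.strip())
        entries.append(CatalogEntry(gene.strip(), categories))
    return entries


def write_catalog(entries: Sequence[CatalogEntry], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in entries:
            fh.write(f"{e.gene_name}\t" + ";".join(sorted(e.categories)) + "\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write BED4 rows (chrom, start, end, name)."""
    with Path(path).open("w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append(
            (
                normalize_chrom(fields[0]),
                int(fields[1]),
                int(fields[2]),
                fields[3] if len(fields) > 3 else "",
            )
        )
    return out
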