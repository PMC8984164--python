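"""Inclusion filtering, CNVR deduplication and source-level accounting.

A CNVR (copy number variant region) is the deduplicated representative of
CNV calls that are exactly identical — same chromosome, breakpoints and
direction — across cases.  Exact equality is the most conservative reading
of cross-case deduplication; an optional reciprocal-overlap relaxation
exists for cross-platform inputs but is off by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import CnvRecord, CnvType
from .reference import reciprocal_overlap


@dataclass
class CnvRegion:
    """A deduplicated CNV shared by one or more cases."""

    region_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    support: int
    sources: Counter = field(default_factory=Counter)
    samples: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExcludedRecord:
    record: CnvRecord
    reason: str


def filter_inclusion(
    records: Sequence[CnvRecord],
    max_size_bp: int = 3_000_000,
    min_size_bp: int = 0,
    per_source_min_bp: dict[str, int] | None = None,
) -> tuple[list[CnvRecord], list[ExcludedRecord]]:
    """Keep records with ``min_size_bp <= size < max_size_bp``.

    The upper bound is strict (a 3 Mb call is excluded under the default);
    the default floor is 0 because pooled published calls go well below
    any single cohort's reporting threshold.  ``per_source_min_bp`` lets
    individual sources carry a stricter floor (e.g. a 100 kb institutional
    reporting threshold) without imposing it on the pool.  Input order is
    preserved in both outputs.
    """
    if max_size_bp <= min_size_bp:
        raise ValueError(
            f"max_size_bp ({max_size_bp}) must exceed min_size_bp ({min_size_bp})"
        )
    floors = per_source_min_bp or {}
    kept: list[CnvRecord] = []
    excluded: list[ExcludedRecord] = []
    for rec in records:
        floor = max(min_size_bp, floors.get(rec.source, 0))
        if rec.size >= max_size_bp:
            excluded.append(ExcludedRecord(rec, "size >= max"))
        elif rec.size < floor:
            excluded.append(ExcludedRecord(rec, "size < min"))
        else:
            kept.append(rec)
    return kept, excluded


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (int(body), "")
    order = {"X": 23, "Y": 24, "M": 25}
    return (order.get(body.upper(), 26), body)


def deduplicate(
    records: Sequence[CnvRecord],
    match_mode: str = "exact",
    ro_threshold: float = 0.99,
) -> list[CnvRegion]:
    """Collapse identical CNVs observed in different cases into CNVRs.

    ``match_mode="exact"`` (default) groups on (chrom, start, end, type).
    ``match_mode="reciprocal"`` additionally merges groups of the same
    chromosome and type whose reciprocal overlap is >= ``ro_threshold``
    (single-linkage over exact groups), for cross-platform inputs.

    Output is sorted by (chrom, start, end, type) with deterministic
    region ids ``chrom:start-end:type``.
    """
    groups: dict[tuple, list[CnvRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.chrom, rec.start, rec.end, rec.cnv_type)].append(rec)

    merged: list[list[CnvRecord]] = [list(v) for v in groups.values()]
    if match_mode == "reciprocal":
        merged = _merge_reciprocal(merged, ro_threshold)
    elif match_mode != "exact":
        raise ValueError(f"unknown match_mode {match_mode!r}")

    regions = []
    for members in merged:
        chrom = members[0].chrom
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        cnv_type = members[0].cnv_type
        regions.append(
            CnvRegion(
                region_id=f"{chrom}:{start}-{end}:{cnv_type.value}",
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=cnv_type,
                support=len(members),
                sources=Counter(m.source for m in members),
                samples=frozenset(m.sample_id for m in members),
            )
        )
    regions.sort(
        key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.end, r.cnv_type.value)
    )
    return regions


def _merge_reciprocal(
    groups: list[list[CnvRecord]], threshold: float
) -> list[list[CnvRecord]]:
    # single-linkage union-find over exact-match groups
    n = len(groups)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        gi = groups[i][0]
        for j in range(i + 1, n):
            gj = groups[j][0]
            if gi.chrom != gj.chrom or gi.cnv_type != gj.cnv_type:
                continue
            ro = reciprocal_overlap((gi.start, gi.end), (gj.start, gj.end))
            if ro >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[CnvRecord]] = defaultdict(list)
    for i, g in enumerate(groups):
        clusters[find(i)].extend(g)
    return list(clusters.values())


@dataclass
class SourceSummary:
    """Table-style accounting of calls and CNVRs, per source and overall."""

    per_source: dict[str, dict[str, int]]
    overall: dict[str, int]

    def check_identities(self) -> None:
        """Raise if gains + losses + unknown != total anywhere."""
        rows = dict(self.per_source)
        rows["Total"] = self.overall
        for label, row in rows.items():
            if row["n_total"] != row["n_gain"] + row["n_loss"] + row["n_unknown"]:
                raise AssertionError(f"accounting identity violated for {label}")
        if "n_cnvr" in self.overall:
            o = self.overall
            if o["n_cnvr"] != o["n_cnvr_gain"] + o["n_cnvr_loss"] + o["n_cnvr_unknown"]:
                raise AssertionError("CNVR accounting identity violated")


def _count_types(types: Sequence[CnvType]) -> dict[str, int]:
    c = Counter(types)
    return {
        "n_total": len(types),
        "n_gain": c[CnvType.GAIN],
        "n_loss": c[CnvType.LOSS],
        "n_unknown": c[CnvType.UNKNOWN],
    }


def summarize_counts(
    records: Sequence[CnvRecord], regions: Sequence[CnvRegion] | None = None
) -> SourceSummary:
    """Per-source and overall gain/loss/unknown counts, pre- and post-dedup."""
    by_source: dict[str, list[CnvType]] = defaultdict(list)
    for rec in records:
        by_source[rec.source].append(rec.cnv_type)
    per_source = {src: _count_types(ts) for src, ts in sorted(by_source.items())}
    overall = _count_types([r.cnv_type for r in records])
    if regions is not None:
        cnvr = _count_types([r.cnv_type for r in regions])
        overall.update(
            {
                "n_cnvr": cnvr["n_total"],
                "n_cnvr_gain": cnvr["n_gain"],
                "n_cnvr_loss": cnvr["n_loss"],
                "n_cnvr_unknown": cnvr["n_unknown"],
            }
        )
    summary = SourceSummary(per_source, overall)
    summary.check_identities()
    return summary


def write_summary(summary: SourceSummary, path: str | Path) -> None:
    cols = ["n_total", "n_gain", "n_loss", "n_unknown"]
    extra = [c for c in ("n_cnvr", "n_cnvr_gain", "n_cnvr_loss", "n_cnvr_unknown")
             if c in summary.overall]
    with Path(path).open("w") as fh:
        fh.write("source\t" + "\t".join(cols + extra) + "\n")
        for src, row in summary.per_source.items():
            fh.write(src + "\t" + "\t".join(str(row[c]) for c in cols)
                     + ("\t" * len(extra)) + "\n")
        fh.write(
            "Total\t"
            + "\t".join(str(summary.overall[c]) for c in cols + extra)
            + "\n"
        )


def write_regions_bed(regions: Sequence[CnvRegion], path: str | Path) -> None:
    """BED4+type+support output for CNVRs."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.cnv_type.value}\t{r.support}\t"
                + ",".join(sorted(r.samples))
                + "\n"
            )
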