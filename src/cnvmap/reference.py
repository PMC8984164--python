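"""Reported/unreported classification against a reference variant catalog.

A CNVR counts as *reported* when some reference variant on the same
chromosome has reciprocal overlap strictly greater than the threshold
(default 75%) and a compatible direction: a gain matches a gain, a loss a
loss, and catalog records typed ``both`` (gain+loss) match either.
Regions of unknown direction cannot satisfy the direction rule and are
flagged ``not_evaluable`` rather than counted as unreported.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .io import CnvType, RefType, ReferenceVariant


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for two half-open intervals.

    Both intervals must cover at least this fraction of each other; 0.0
    when disjoint.  Symmetric by construction.  Callers comparing across
    chromosomes must handle the chromosome check themselves (intervals on
    different chromosomes overlap by 0 by contract).
    """
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass(frozen=True)
class OverlapCall:
    region_id: str
    status: str  # reported | unreported | not_evaluable
    best_ref_id: str | None
    reciprocal_fraction: float


def _type_compatible(region_type: CnvType, ref_type: RefType) -> bool:
    if ref_type is RefType.BOTH:
        return True
    return region_type.value == ref_type.value


def classify_reported(
    regions: Sequence,
    reference: Sequence[ReferenceVariant],
    threshold: float = 0.75,
    require_type_match: bool = True,
    strict: bool = True,
) -> list[OverlapCall]:
    """Classify each CNVR against the reference catalog.

    Parameters
    ----------
    threshold
        Reciprocal-overlap cutoff in (0, 1]; the comparison is strict
        (``> threshold``) by default, matching the "more than 75%" rule;
        ``strict=False`` switches to ``>=`` for sensitivity analyses.
    require_type_match
        When on (default), only direction-compatible reference variants
        can report a region, and unknown-direction regions come back
        ``not_evaluable``.

    The best match is the type-compatible reference variant with maximal
    reciprocal fraction; ties break by smallest reference start, then
    lexicographic ref_id.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ref in reference:
        by_chrom[ref.chrom].addi(ref.start, ref.end, ref)

    calls: list[OverlapCall] = []
    for region in regions:
        if require_type_match and region.cnv_type is CnvType.UNKNOWN:
            calls.append(OverlapCall(region.region_id, "not_evaluable", None, 0.0))
            continue
        best: tuple[float, int, str] | None = None  # (-ro, start, ref_id)
        best_ref = None
        for hit in by_chrom[region.chrom].overlap(region.start, region.end):
            ref: ReferenceVariant = hit.data
            if require_type_match and not _type_compatible(region.cnv_type, ref.ref_type):
                continue
            ro = reciprocal_overlap((region.start, region.end), (ref.start, ref.end))
            key = (-ro, ref.start, ref.ref_id)
            if best is None or key < best:
                best, best_ref = key, ref
        frac = -best[0] if best else 0.0
        passed = frac > threshold if strict else frac >= threshold
        calls.append(
            OverlapCall(
                region.region_id,
                "reported" if passed else "unreported",
                best_ref.ref_id if best_ref is not None else None,
                frac,
            )
        )
    return calls


def write_overlap_calls(calls: Sequence[OverlapCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("region_id\tstatus\tbest_ref_id\treciprocal_fraction\n")
        for c in calls:
            fh.write(
                f"{c.region_id}\t{c.status}\t{c.best_ref_id or ''}\t"
                f"{c.reciprocal_fraction:.6f}\n"
            )


def tally_statuses(calls: Sequence[OverlapCall]) -> dict[str, int]:
    out = {"reported": 0, "unreported": 0, "not_evaluable": 0}
    for c in calls:
        out[c.status] += 1
    return out
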