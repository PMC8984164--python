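"""Chromosomal CNV counts, pericentromeric/sub-telomeric window densities
and a plot-ready genome track.

The density statistic is the fraction of *un-gapped* nucleotides in a
sliding window covered by at least one CNV in the pooled set (union
coverage — overlapping calls never double-count a base).  Windows are
anchored at the centromere edges and at the two chromosome ends, stepping
away from the anchor through a fixed flank: with the defaults (5 Mb
windows, 0.5 Mb steps, 9 Mb flanks) each anchor carries
``floor((9 − 5)/0.5) + 1 = 9`` windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import CnvType, GenomeLayout

ANCHORS = ("telomere_p", "telomere_q", "centromere_left", "centromere_right")


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    anchor: str
    offset_index: int
    clipped: bool = False


@dataclass(frozen=True)
class WindowDensity:
    window: GenomicWindow
    ungapped_bp: int
    covered_ungapped_bp: int

    @property
    def fraction(self) -> float | None:
        """Covered fraction of un-gapped bases; None when fully gapped."""
        if self.ungapped_bp == 0:
            return None
        return self.covered_ungapped_bp / self.ungapped_bp


# ---------------------------------------------------------------------------
# interval arithmetic helpers (half-open, per chromosome)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    ivals = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_total(
    merged: Sequence[tuple[int, int]], start: int, end: int
) -> int:
    """Total bases of a merged (disjoint, sorted) set within [start, end)."""
    total = 0
    for s, e in merged:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


def subtract_intervals(
    base: tuple[int, int], cuts: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """``base`` minus a merged cut set, as disjoint half-open pieces."""
    pieces = []
    cursor = base[0]
    for s, e in cuts:
        if e <= base[0] or s >= base[1]:
            continue
        if s > cursor:
            pieces.append((cursor, min(s, base[1])))
        cursor = max(cursor, e)
    if cursor < base[1]:
        pieces.append((cursor, base[1]))
    return pieces


# ---------------------------------------------------------------------------


CHROM_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def per_chromosome_counts(records: Sequence, by_type: bool = True) -> pd.DataFrame:
    """Count CNVs per chromosome, split by gain/loss/unknown.

    Rows are ordered chr1..chr22, chrX, chrY, then any other chromosome
    names sorted; the grand total always equals the input size.
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        row = rows.setdefault(
            rec.chrom, {"gain": 0, "loss": 0, "unknown": 0, "total": 0}
        )
        row[rec.cnv_type.value] += 1
        row["total"] += 1
    known = [c for c in CHROM_ORDER if c in rows]
    extra = sorted(c for c in rows if c not in CHROM_ORDER)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(known + extra)
    df.index.name = "chrom"
    if not by_type and not df.empty:
        df = df[["total"]]
    return df.fillna(0).astype(int)


def make_windows(
    layout: GenomeLayout,
    window_bp: int = 5_000_000,
    step_bp: int = 500_000,
    flank_bp: int = 9_000_000,
) -> list[GenomicWindow]:
    """Tile sliding windows through each anchor's flank.

    Anchors are the two telomeres (positions 0 and chromosome length) and
    the two centromere edges.  Telomere-p windows step rightward from 0,
    telomere-q leftward from the chromosome end, centromere_left leftward
    from the centromere start, centromere_right rightward from the
    centromere end.  Windows that would cross a chromosome boundary are
    clipped and flagged; chromosomes shorter than one window are skipped
    with a warning.
    """
    if window_bp > flank_bp:
        raise ValueError("window_bp must not exceed flank_bp")
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    n_per_flank = (flank_bp - window_bp) // step_bp + 1

    windows: list[GenomicWindow] = []
    for chrom in sorted(layout.chrom_lengths, key=_order_key):
        length = layout.chrom_lengths[chrom]
        if length < window_bp:
            warnings.warn(
                f"{chrom} (length {length}) shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        if chrom not in layout.centromeres:
            raise ValueError(f"no centromere recorded for {chrom}")
        cen_start, cen_end = layout.centromeres[chrom]
        for i in range(n_per_flank):
            off = i * step_bp
            for anchor, raw_start in (
                ("telomere_p", off),
                ("telomere_q", length - off - window_bp),
                ("centromere_left", cen_start - off - window_bp),
                ("centromere_right", cen_end + off),
            ):
                raw_end = raw_start + window_bp
                start, end = max(0, raw_start), min(length, raw_end)
                if end <= start:
                    continue
                windows.append(
                    GenomicWindow(
                        chrom,
                        start,
                        end,
                        anchor,
                        i,
                        clipped=(start != raw_start or end != raw_end),
                    )
                )
    return windows


def _order_key(chrom: str):
    try:
        return (CHROM_ORDER.index(chrom), chrom)
    except ValueError:
        return (len(CHROM_ORDER), chrom)


def window_cnv_fraction(
    windows: Sequence[GenomicWindow],
    records: Sequence,
    layout: GenomeLayout,
    cnv_type: CnvType | None = None,
) -> list[WindowDensity]:
    """Gap-corrected union-coverage fraction for each window.

    ``cnv_type`` restricts the pooled set to gains or losses (None = all
    calls), mirroring the gain/loss/combined density panels.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if cnv_type is not None and rec.cnv_type is not cnv_type:
            continue
        by_chrom.setdefault(rec.chrom, []).append((rec.start, rec.end))
    merged_cnv = {c: merge_intervals(v) for c, v in by_chrom.items()}
    merged_gap = {c: merge_intervals(v) for c, v in layout.gaps.items()}

    densities = []
    for w in windows:
        gaps = merged_gap.get(w.chrom, [])
        gap_bp = overlap_total(gaps, w.start, w.end)
        ungapped = (w.end - w.start) - gap_bp
        covered = 0
        for s, e in subtract_intervals((w.start, w.end), gaps):
            covered += overlap_total(merged_cnv.get(w.chrom, []), s, e)
        densities.append(WindowDensity(w, ungapped, covered))
    return densities


def densities_frame(densities: Sequence[WindowDensity]) -> pd.DataFrame:
    """Tabular form of window densities, one row per window."""
    return pd.DataFrame(
        {
            "chrom": [d.window.chrom for d in densities],
            "start": [d.window.start for d in densities],
            "end": [d.window.end for d in densities],
            "anchor": [d.window.anchor for d in densities],
            "offset_index": [d.window.offset_index for d in densities],
            "clipped": [d.window.clipped for d in densities],
            "ungapped_bp": [d.ungapped_bp for d in densities],
            "covered_ungapped_bp": [d.covered_ungapped_bp for d in densities],
            "fraction": [d.fraction for d in densities],
        }
    )


def profile_by_offset(df: pd.DataFrame) -> pd.DataFrame:
    """Cross-chromosome profile per (anchor, offset_index).

    Two aggregations are emitted side by side: the mean of per-window
    fractions and the pooled base-count ratio; fully gapped (undefined)
    windows are excluded from both.
    """
    ok = df[df["fraction"].notna()]
    grouped = ok.groupby(["anchor", "offset_index"])
    out = grouped.agg(
        mean_fraction=("fraction", "mean"),
        n_windows=("fraction", "size"),
        covered=("covered_ungapped_bp", "sum"),
        ungapped=("ungapped_bp", "sum"),
    ).reset_index()
    out["pooled_fraction"] = out["covered"] / out["ungapped"]
    return out.drop(columns=["covered", "ungapped"])


# ---------------------------------------------------------------------------
# genome track


def assign_lanes(records: Sequence) -> list[int]:
    """First-fit lane assignment so overlapping CNVs get distinct lanes.

    Returns one lane index per input record (per chromosome, greedy over
    start-sorted records), suitable as a y-offset in a rectangle track.
    """
    lanes = [0] * len(records)
    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_chrom.setdefault(rec.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (records[i].start, records[i].end))
        lane_ends: list[int] = []  # end coordinate of last record per lane
        for i in idxs:
            rec = records[i]
            for lane, lane_end in enumerate(lane_ends):
                if rec.start >= lane_end:
                    lane_ends[lane] = rec.end
                    lanes[i] = lane
                    break
            else:
                lane_ends.append(rec.end)
                lanes[i] = len(lane_ends) - 1
    return lanes


def genome_track(records: Sequence, layout: GenomeLayout) -> pd.DataFrame:
    """Plot-ready per-CNV table with lane (y-offset) assignment."""
    lanes = assign_lanes(records)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "type": [r.cnv_type.value for r in records],
            "sample": [r.sample_id for r in records],
            "lane": lanes,
        }
    )


def plot_genome_track(
    track: pd.DataFrame, layout: GenomeLayout, path: str | Path
) -> None:
    """Render a basic per-chromosome rectangle plot of the CNV map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in sorted(layout.chrom_lengths, key=_order_key)]
    fig, ax = plt.subplots(figsize=(10, 0.6 * max(len(chroms), 4) + 1))
    colors = {"gain": "#c0392b", "loss": "#2471a3", "unknown": "#7f8c8d"}
    base_y = {c: i * 1.0 for i, c in enumerate(chroms)}
    max_lane = int(track["lane"].max()) + 1 if len(track) else 1
    lane_h = 0.8 / max_lane
    for c in chroms:
        ax.hlines(base_y[c], 0, layout.chrom_lengths[c], color="0.8", lw=3)
    for _, row in track.iterrows():
        if row["chrom"] not in base_y:
            continue
        y = base_y[row["chrom"]] + 0.1 + row["lane"] * lane_h
        ax.add_patch(
            plt.Rectangle(
                (row["start"], y),
                row["end"] - row["start"],
                lane_h * 0.9,
                color=colors.get(row["type"], "k"),
                lw=0,
            )
        )
    ax.set_yticks([base_y[c] for c in chroms], chroms)
    ax.set_xlabel("position (bp)")
    ax.set_xlim(0, max(layout.chrom_lengths.values()))
    ax.set_ylim(-0.5, len(chroms))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of the mean window fraction per anchor/offset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    anchors = [a for a in ANCHORS if a in set(profile["anchor"])]
    fig, axes = plt.subplots(
        1, max(len(anchors), 1), figsize=(3.2 * max(len(anchors), 1), 3), sharey=True
    )
    if len(anchors) <= 1:
        axes = [axes]
    for ax, anchor in zip(axes, anchors):
        sub = profile[profile["anchor"] == anchor]
        ax.bar(sub["offset_index"], 100 * sub["mean_fraction"], color="#5d6d7e")
        ax.set_title(anchor)
        ax.set_xlabel("window offset")
    axes[0].set_ylabel("% un-gapped bases in CNVs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
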