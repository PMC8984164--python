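"""Chromosome counts, sliding-window construction, gap-masked density
(against a per-base boolean-mask oracle) and track lane assignment."""

import itertools

import numpy as np
import pytest

from cnvmap.distribution import (
    GenomicWindow,
    assign_lanes,
    make_windows,
    merge_intervals,
    per_chromosome_counts,
    window_cnv_fraction,
)
from cnvmap.genes import recurrent_bands  # noqa: F401  (shared fixtures)
from cnvmap.io import CnvRecord, CnvType, GenomeLayout


def rec(chrom, start, end, cnv_type=CnvType.GAIN, sample="S1"):
    return CnvRecord(sample, "src", chrom, start, end, cnv_type)


class TestPerChromosomeCounts:
    def test_conservation_and_order(self):
        records = [
            rec("chr2", 0, 10),
            rec("chr1", 0, 10),
            rec("chr2", 20, 30, CnvType.LOSS),
            rec("chrX", 5, 6, CnvType.UNKNOWN),
        ]
        df = per_chromosome_counts(records)
        assert list(df.index) == ["chr1", "chr2", "chrX"]
        assert df["total"].sum() == len(records)
        assert df.loc["chr2", "gain"] == 1 and df.loc["chr2", "loss"] == 1

    def test_empty_input(self):
        df = per_chromosome_counts([])
        assert len(df) == 0


def simple_layout(length=40_000_000, cen=(19_500_000, 20_500_000)):
    return GenomeLayout(
        {"chr1": length}, gaps={"chr1": [cen]}, centromeres={"chr1": cen}
    )


class TestMakeWindows:
    def test_default_window_count_per_flank(self):
        layout = simple_layout()
        windows = make_windows(layout)
        per_anchor = {a: 0 for a in ("telomere_p", "telomere_q",
                                     "centromere_left", "centromere_right")}
        for w in windows:
            per_anchor[w.anchor] += 1
        # floor((9 Mb - 5 Mb) / 0.5 Mb) + 1 = 9 windows per anchor
        assert all(n == 9 for n in per_anchor.values())
        assert not any(w.clipped for w in windows)

    @pytest.mark.parametrize(
        "window,step,flank",
        [(10, 1, 10), (10, 3, 25), (5, 5, 30), (7, 2, 7), (1, 1, 12)],
    )
    def test_count_formula_over_parameter_grid(self, window, step, flank):
        layout = GenomeLayout(
            {"chr1": 1000}, centromeres={"chr1": (480, 520)}
        )
        windows = make_windows(layout, window, step, flank)
        expected = (flank - window) // step + 1
        for anchor in ("telomere_p", "telomere_q",
                       "centromere_left", "centromere_right"):
            assert sum(w.anchor == anchor for w in windows) == expected

    def test_window_equal_to_flank_is_single_window(self):
        layout = simple_layout()
        windows = make_windows(layout, 9_000_000, 500_000, 9_000_000)
        assert sum(w.anchor == "telomere_p" for w in windows) == 1

    def test_short_chromosome_clips_but_stays_in_range(self):
        layout = GenomeLayout(
            {"chr1": 8_000_000}, centromeres={"chr1": (3_900_000, 4_100_000)}
        )
        windows = make_windows(layout)
        assert windows  # some clipped windows survive
        for w in windows:
            assert 0 <= w.start < w.end <= 8_000_000
        assert any(w.clipped for w in windows)

    def test_sub_window_chromosome_skipped_with_warning(self):
        layout = GenomeLayout(
            {"chr1": 1_000_000}, centromeres={"chr1": (400_000, 600_000)}
        )
        with pytest.warns(UserWarning, match="skipped"):
            assert make_windows(layout) == []

    def test_window_larger_than_flank_is_error(self):
        with pytest.raises(ValueError):
            make_windows(simple_layout(), 10_000_000, 500_000, 9_000_000)


class TestWindowFraction:
    def test_fully_covered_gap_free_window(self):
        layout = GenomeLayout({"chr1": 1000}, centromeres={"chr1": (400, 600)})
        w = GenomicWindow("chr1", 100, 200, "telomere_p", 0)
        (d,) = window_cnv_fraction([w], [rec("chr1", 0, 1000)], layout)
        assert d.fraction == 1.0

    def test_toy_window_with_gap(self):
        # 10 bp window, gap [0,5), CNV [0,8): ungapped 5, covered 3
        layout = GenomeLayout(
            {"chr1": 10}, gaps={"chr1": [(0, 5)]}, centromeres={"chr1": (4, 5)}
        )
        w = GenomicWindow("chr1", 0, 10, "telomere_p", 0)
        (d,) = window_cnv_fraction([w], [rec("chr1", 0, 8)], layout)
        assert (d.ungapped_bp, d.covered_ungapped_bp) == (5, 3)
        assert d.fraction == pytest.approx(0.6)

    def test_union_semantics_never_double_count(self):
        layout = GenomeLayout({"chr1": 10}, centromeres={"chr1": (4, 5)})
        w = GenomicWindow("chr1", 0, 10, "telomere_p", 0)
        (d,) = window_cnv_fraction(
            [w], [rec("chr1", 0, 6), rec("chr1", 4, 10, sample="S2")], layout
        )
        assert d.fraction == 1.0

    def test_fully_gapped_window_is_undefined(self):
        layout = GenomeLayout(
            {"chr1": 100}, gaps={"chr1": [(0, 100)]}, centromeres={"chr1": (40, 60)}
        )
        w = GenomicWindow("chr1", 10, 50, "telomere_p", 0)
        (d,) = window_cnv_fraction([w], [rec("chr1", 0, 100)], layout)
        assert d.ungapped_bp == 0 and d.fraction is None

    @pytest.mark.parametrize("seed", range(5))
    def test_per_base_mask_oracle(self, seed):
        """Interval arithmetic equals an explicit per-base boolean mask on
        synthetic chromosomes <= 100 kb, for every window."""
        rng = np.random.default_rng(seed)
        L = 100_000
        gaps = []
        for _ in range(4):
            s = int(rng.integers(0, L - 5000))
            gaps.append((s, s + int(rng.integers(100, 5000))))
        layout = GenomeLayout(
            {"chr1": L},
            gaps={"chr1": merge_intervals(gaps)},
            centromeres={"chr1": (48_000, 52_000)},
        )
        records = []
        for i in range(30):
            s = int(rng.integers(0, L - 10_000))
            records.append(
                rec("chr1", s, s + int(rng.integers(50, 10_000)), sample=f"S{i}")
            )
        windows = make_windows(layout, window_bp=10_000, step_bp=2_000,
                               flank_bp=30_000)
        densities = window_cnv_fraction(windows, records, layout)

        gap_mask = np.zeros(L, dtype=bool)
        for s, e in layout.gaps["chr1"]:
            gap_mask[s:e] = True
        cnv_mask = np.zeros(L, dtype=bool)
        for r in records:
            cnv_mask[r.start:r.end] = True
        for d in densities:
            sl = slice(d.window.start, d.window.end)
            ungapped = int((~gap_mask[sl]).sum())
            covered = int((cnv_mask[sl] & ~gap_mask[sl]).sum())
            assert (d.ungapped_bp, d.covered_ungapped_bp) == (ungapped, covered)


class TestLaneAssignment:
    def test_disjoint_records_share_lane_zero(self):
        lanes = assign_lanes([rec("chr1", 0, 10), rec("chr1", 20, 30)])
        assert lanes == [0, 0]

    def test_overlapping_records_split_lanes(self):
        lanes = assign_lanes([rec("chr1", 0, 10), rec("chr1", 5, 15)])
        assert sorted(lanes) == [0, 1]

    @pytest.mark.parametrize("seed", range(4))
    def test_no_same_lane_overlap_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(5):
            s = int(rng.integers(0, 100))
            records.append(rec("chr1", s, s + int(rng.integers(1, 60)),
                               sample=f"S{i}"))
        lanes = assign_lanes(records)
        for i, j in itertools.combinations(range(len(records)), 2):
            if lanes[i] == lanes[j]:
                a, b = records[i], records[j]
                assert min(a.end, b.end) <= max(a.start, b.start)


def test_planted_pericentromeric_bias_raises_window_density(tmp_path):
    """Cohorts simulated with 3x start density near centromeres/telomeres
    show higher mean window fractions there than in mid-arm control
    windows, across >= 20 replicate seeds."""
    from cnvmap.simulate import SimConfig, make_genome, simulate_cohort

    peri_means, mid_means = [], []
    for seed in range(20):
        config = SimConfig(
            seed=seed, n_chromosomes=2, n_cnvs=150, n_samples=120,
            n_duplicates=0, planted_n_samples=0, pericentromeric_bias=3.0,
        )
        layout, _ = make_genome(config, tmp_path / f"bias_{seed}")
        records, _ = simulate_cohort(layout, config)
        flank, window, step = 9_000_000, 5_000_000, 500_000
        peri = [
            w for w in make_windows(layout, window, step, flank)
            if w.anchor.startswith("centromere")
        ]
        # equal number of mid-arm control windows, centred between the
        # telomeric and pericentromeric flanks
        controls = []
        for chrom, length in layout.chrom_lengths.items():
            cen_s, cen_e = layout.centromeres[chrom]
            for arm_lo, arm_hi in ((flank, cen_s - flank), (cen_e + flank, length - flank)):
                mid = (arm_lo + arm_hi) // 2
                n = len(peri) // (2 * len(layout.chrom_lengths) * 2)
                for i in range(n):
                    start = mid - (n // 2) * step + i * step
                    controls.append(
                        GenomicWindow(chrom, start, start + window, "control", i)
                    )
        peri_d = [d.fraction for d in window_cnv_fraction(peri, records, layout)
                  if d.fraction is not None]
        mid_d = [d.fraction for d in window_cnv_fraction(controls, records, layout)
                 if d.fraction is not None]
        peri_means.append(np.mean(peri_d))
        mid_means.append(np.mean(mid_d))
    assert np.mean(peri_means) > np.mean(mid_means)
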