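"""Synthetic-bundle generator: determinism, truth bookkeeping, size and
positional distributions, and reference-set construction."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from cnvmap.io import CnvType, read_cnv_table, read_genome_layout
from cnvmap.reference import reciprocal_overlap
from cnvmap.simulate import (
    SimConfig,
    make_bundle,
    make_genome,
    make_reference_set,
    simulate_cohort,
)


def small_config(seed=0, **overrides):
    defaults = dict(
        seed=seed, n_chromosomes=2, n_cnvs=120, n_samples=100,
        n_duplicates=8, planted_n_samples=6,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        paths_a = make_bundle(small_config(seed=9), tmp_path / "a")
        paths_b = make_bundle(small_config(seed=9), tmp_path / "b")
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        paths_a = make_bundle(small_config(seed=1), tmp_path / "a")
        paths_b = make_bundle(small_config(seed=2), tmp_path / "b")
        assert not filecmp.cmp(paths_a["cnv"], paths_b["cnv"], shallow=False)


class TestGenome:
    def test_layout_round_trips_through_readers(self, tmp_path):
        config = small_config()
        layout, paths = make_genome(config, tmp_path)
        back = read_genome_layout(
            paths["sizes"], paths["gap"], paths["centromere"], paths["cytoband"]
        )
        assert back.chrom_lengths == layout.chrom_lengths
        assert back.centromeres == layout.centromeres
        assert back.cytobands == layout.cytobands

    def test_cytobands_tile_each_chromosome(self, tmp_path):
        config = small_config()
        layout, _ = make_genome(config, tmp_path)
        for chrom, bands in layout.cytobands.items():
            assert bands[0][0] == 0
            assert bands[-1][1] == layout.chrom_lengths[chrom]
            for (s1, e1, _), (s2, _e2, _) in zip(bands, bands[1:]):
                assert s2 == e1  # contiguous

    def test_zero_random_gaps(self, tmp_path):
        config = small_config(n_random_gaps=0)
        layout, _ = make_genome(config, tmp_path)
        # only the two telomeric gaps and the centromere remain
        for chrom, gaps in layout.gaps.items():
            assert len(gaps) == 3


class TestCohort:
    def test_truth_bookkeeping(self, tmp_path):
        config = small_config()
        layout, _ = make_genome(config, tmp_path)
        records, truth = simulate_cohort(layout, config)
        assert len(records) == config.n_cnvs
        assert truth["n_duplicates"] == config.n_duplicates
        planted = [p for p in truth["provenance"] if p["origin"] == "planted_recurrent"]
        assert len(planted) == config.planted_n_samples
        for src, dup in truth["duplicate_pairs"]:
            a, b = records[src], records[dup]
            assert (a.chrom, a.start, a.end, a.cnv_type) == (
                b.chrom, b.start, b.end, b.cnv_type,
            )
            assert a.sample_id != b.sample_id

    def test_unknown_fraction_zero(self, tmp_path):
        config = small_config(unknown_fraction=0.0)
        layout, _ = make_genome(config, tmp_path)
        records, _ = simulate_cohort(layout, config)
        assert all(r.cnv_type is not CnvType.UNKNOWN for r in records)

    def test_sizes_respect_truncation(self, tmp_path):
        config = small_config()
        layout, _ = make_genome(config, tmp_path)
        records, _ = simulate_cohort(layout, config)
        backgrounds = records[: truth_background_count(config)]
        for r in backgrounds:
            assert config.size_min <= r.size < config.size_max

    def test_summary_statistics_emulate_study_conditions(self, tmp_path):
        """Across 20 seeds, the mean CNV size is within 15% of 690.2 kb
        and the mean gain fraction within 0.05 of 349/564."""
        means, gains = [], []
        for seed in range(20):
            config = SimConfig(seed=seed)
            layout, _ = make_genome(config, tmp_path / str(seed))
            records, _ = simulate_cohort(layout, config)
            sizes = np.array([r.size for r in records])
            means.append(sizes.mean())
            gains.append(np.mean([r.cnv_type is CnvType.GAIN for r in records]))
        assert abs(np.mean(means) - 690_200) / 690_200 < 0.15
        assert abs(np.mean(gains) - 349 / 564) < 0.05

    def test_unbiased_positions_are_uniform(self, tmp_path):
        """With bias multiplier 1.0, CNV midpoints on a chromosome pass a
        KS test against uniform for almost all of 20 seeds (alpha 0.01)."""
        n_significant = 0
        for seed in range(20):
            config = small_config(seed=seed, pericentromeric_bias=1.0,
                                  planted_n_samples=0, n_duplicates=0)
            layout, _ = make_genome(config, tmp_path / str(seed))
            records, _ = simulate_cohort(layout, config)
            L = config.chrom_length
            mids = [ (r.start + r.end) / 2 / L for r in records if r.chrom == "chr1"]
            if stats.kstest(mids, "uniform").pvalue < 0.01:
                n_significant += 1
        assert n_significant <= 2

    def test_planted_band_missing_is_error(self, tmp_path):
        config = small_config(planted_band="9q99")
        layout, _ = make_genome(config, tmp_path)
        with pytest.raises(ValueError, match="absent"):
            simulate_cohort(layout, config)


def truth_background_count(config):
    return config.n_cnvs - config.planted_n_samples - config.n_duplicates


class TestReferenceSet:
    def test_jitter_keeps_reciprocal_overlap_above_threshold(self, tmp_path):
        config = small_config(reported_fraction=1.0)
        layout, _ = make_genome(config, tmp_path)
        records, _ = simulate_cohort(layout, config)
        reference, truth = make_reference_set(records, config)
        # shrinking both flanks by 10% leaves reciprocal overlap 0.8
        from cnvmap.aggregate import deduplicate

        regions = {r.region_id: r for r in deduplicate(records)}
        evaluable = [r for r in regions.values() if r.cnv_type is not CnvType.UNKNOWN]
        assert len(reference) == len(evaluable)
        for ref, region in zip(reference, evaluable):
            ro = reciprocal_overlap(
                (region.start, region.end), (ref.start, ref.end)
            )
            assert ro > 0.75

    def test_reported_fraction_bookkeeping(self, tmp_path):
        config = small_config(reported_fraction=0.52)
        layout, _ = make_genome(config, tmp_path)
        records, _ = simulate_cohort(layout, config)
        _, truth = make_reference_set(records, config)
        assert truth["n_intended_reported"] == round(0.52 * truth["n_evaluable"])
        n_intended = sum(1 for v in truth["intended"].values() if v == "reported")
        assert n_intended == truth["n_intended_reported"]

    def test_truth_status_consistent_with_emitted_catalog(self, tmp_path):
        """Every intended-reported region is reported in the recorded
        truth (incidental extra matches may add, never remove)."""
        config = small_config()
        layout, _ = make_genome(config, tmp_path)
        records, _ = simulate_cohort(layout, config)
        _, truth = make_reference_set(records, config)
        for region_id, intent in truth["intended"].items():
            if intent == "reported":
                assert truth["status"][region_id] == "reported"


def test_bundle_files_parse_with_package_readers(tmp_path):
    paths = make_bundle(small_config(), tmp_path)
    records, rejects = read_cnv_table(paths["cnv"])
    assert not rejects and len(records) == 120
    truth = json.loads(Path(paths["truth"]).read_text())
    assert truth["cohort"]["n_records"] == 120
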