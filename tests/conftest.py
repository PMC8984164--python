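import pytest

from cnvmap.io import GenomeLayout
from cnvmap.pipeline import run_all
from cnvmap.simulate import SimConfig, make_bundle

PIPELINE_INPUT_KEYS = (
    "cnv", "reference", "sizes", "gap", "centromere", "cytoband",
    "gtf", "phenotype_catalog", "expression_catalog", "gmt",
)


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    """Two ~100 kb chromosomes with gaps, centromeres and cytobands,
    small enough for per-base oracles."""
    return GenomeLayout(
        chrom_lengths={"chr1": 100_000, "chr2": 80_000},
        gaps={
            "chr1": [(0, 1_000), (48_000, 52_000), (99_000, 100_000)],
            "chr2": [(38_000, 42_000)],
        },
        centromeres={"chr1": (48_000, 52_000), "chr2": (38_000, 42_000)},
        cytobands={
            "chr1": [
                (0, 24_000, "p2"),
                (24_000, 48_000, "p1"),
                (48_000, 52_000, "cen"),
                (52_000, 76_000, "q1"),
                (76_000, 100_000, "q2"),
            ],
            "chr2": [
                (0, 38_000, "p1"),
                (38_000, 42_000, "cen"),
                (42_000, 80_000, "q1"),
            ],
        },
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic bundle (seed 1) plus a completed pipeline run."""
    root = tmp_path_factory.mktemp("bundle")
    paths = make_bundle(SimConfig(seed=1), root / "inputs")
    config = {k: paths[k] for k in PIPELINE_INPUT_KEYS}
    config["plots"] = False
    manifest = run_all(config, root / "run")
    return {"paths": paths, "config": config, "manifest": manifest,
            "out_dir": root / "run"}
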