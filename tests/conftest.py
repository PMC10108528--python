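import logging

import numpy as np
import pytest

from isletkit.simulate import SyntheticConfig, generate_world

logging.disable(logging.INFO)

WORLD_SEED = 11


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """One default synthetic world shared by manifest-oracle tests."""
    outdir = tmp_path_factory.mktemp("world")
    return generate_world(SyntheticConfig(seed=WORLD_SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    """One full pipeline run on the default synthetic world."""
    from pathlib import Path

    from isletkit.pipeline import PipelineConfig, run_all

    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=Path(outdir), synthetic=SyntheticConfig(seed=WORLD_SEED), seed=WORLD_SEED)
    return run_all(cfg)


def random_region_set(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    """Random canonical RegionSet for oracle-equivalence tests."""
    from isletkit.intervals import GenomicInterval, RegionSet

    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return RegionSet(out)
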