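import numpy as np
import pytest

from teaccess.intervals import GenomicInterval
from teaccess.pipeline import config_for_bundle_dir, run_pipeline
from teaccess.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (seed 1), shared across tests."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_bundle):
    """Full pipeline run over the default study, from persisted files."""
    outdir = tmp_path_factory.mktemp("bundle")
    from teaccess.synthetic import write_bundle

    write_bundle(default_bundle, outdir)
    config = config_for_bundle_dir(outdir)
    result = run_pipeline(config)
    return default_bundle, result


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced study for fast structural tests."""
    cfg = SimConfig(seed=7, n_tes=400, n_genes=60, n_planted=15,
                    samples_per_group=4, n_cohort=80, n_background_motifs=50)
    return simulate_study(cfg)


def random_intervals(rng, n, chrom="chr1", max_pos=20_000, max_len=400,
                     prefix="iv"):
    """Random interval list for oracle comparisons."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length,
                                   name=f"{prefix}{i}"))
    return out


def coverage_mask(intervals, length, chrom="chr1"):
    """Per-base boolean occupancy of one chromosome (oracle primitive)."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start: iv.end] = True
    return mask
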