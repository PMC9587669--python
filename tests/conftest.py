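import numpy as np
import pandas as pd
import pytest

from secircuit.core import GenomicInterval, Peak
from secircuit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """The default synthetic study, shared across the whole session."""
    return simulate_study(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_peak(chrom, start, end, density=1.0, input_density=0.0, sample_id=""):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        sample_density=density,
        input_density=input_density,
        sample_id=sample_id,
    )


def random_peaks(rng, n, genome=1_000_000, chroms=("chr1", "chr2"), max_width=3_000):
    """Random non-overlapping peaks per chromosome, shuffled across chroms."""
    peaks = []
    for chrom in chroms:
        starts = np.sort(rng.choice(genome, size=n, replace=False))
        widths = rng.integers(100, max_width, size=n)
        prev_end = -1
        for s, w in zip(starts, widths):
            if s <= prev_end:
                continue
            e = int(min(s + w, genome))
            if e <= s:
                continue
            peaks.append(make_peak(chrom, int(s), e, density=float(rng.exponential(1.0))))
            prev_end = e
    return peaks
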