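import pandas as pd
import pytest

from tumorpool.core import FilterConfig, SampleMeta


@pytest.fixture
def default_cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def three_region_meta() -> list[SampleMeta]:
    return [
        SampleMeta("N", "normal", 1.0),
        SampleMeta("R1", "region", 0.7),
        SampleMeta("R2", "region", 0.7),
        SampleMeta("R3", "region", 0.7),
    ]


def make_counts_frame(rows):
    """rows: (chrom, pos, ref, alt, sample, depth, alt_count) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample", "depth", "alt_count"],
    )
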