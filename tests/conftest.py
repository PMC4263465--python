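import numpy as np
import pandas as pd
import pytest

from mslchip import GenomeAssembly, GenomeTrack, IntervalSet


@pytest.fixture
def assembly():
    return GenomeAssembly({"chr2L": 1_000, "chrX": 2_000}, step=10)


@pytest.fixture
def make_track():
    """Build a GenomeTrack from {chrom: list-of-values} on a matching assembly."""

    def _make(values_by_chrom, step=10, semantics="log2 ChIP/input"):
        lengths = {c: len(v) * step for c, v in values_by_chrom.items()}
        asm = GenomeAssembly(lengths, step=step)
        return GenomeTrack(
            asm,
            {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()},
            semantics=semantics,
        )

    return _make


@pytest.fixture
def make_intervals():
    def _make(rows, assembly=None):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return IntervalSet(df, assembly=assembly)

    return _make


def random_track_values(rng, n, missing_frac=0.1, scale=1.0):
    """Random values with NaN holes, shared by several test modules."""
    v = rng.normal(0, scale, n)
    holes = rng.random(n) < missing_frac
    v[holes] = np.nan
    return v
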