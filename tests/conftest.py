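import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pooldiv.model import SampleCounts, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_variant(chrom="Chr1", pos=1, ref="A", samples=None, **bases):
    """One-sample variant from keyword base tallies."""
    if samples is None:
        samples = [SampleCounts.from_bases(**bases)]
    return Variant(chromosome=chrom, position=pos, ref_base=ref, samples=samples)


@pytest.fixture
def small_sync_text():
    """Ten sites, one sample: two clear SNPs (pos 3 and 7), rest invariant."""
    lines = []
    for pos in range(1, 11):
        if pos == 3:
            counts = "6:0:4:0:0:0"   # A=6, C=4
        elif pos == 7:
            counts = "0:5:0:5:0:0"   # T=5, G=5
        else:
            counts = "10:0:0:0:0:0"  # invariant A
        lines.append(f"Chr1\t{pos}\tA\t{counts}")
    return "\n".join(lines) + "\n"
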