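import numpy as np
import pytest

from tiervar.simulate import SimConfig, simulate_dataset
from tiervar.variant_model import CallerCall, Callset, VariantKey


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic sample shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_genes=80, n_somatic=150))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_key(pos, sample="S1", chrom="chr1", ref="A", alt="G"):
    return VariantKey(sample, chrom, pos, ref, alt)


def make_callset(caller_id, positions, sample="S1", vaf=0.3):
    """Callset with A>G SNVs at the given positions."""
    cs = Callset(caller_id, sample)
    for pos in positions:
        cs.add(CallerCall(make_key(pos, sample), caller_id, vaf, 30))
    return cs
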