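import numpy as np
import pytest

from indelmark.fixtures import SimulationConfig, mutate, simulate_reference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated cultivar pair with planted truth, shared across
    tests that only read it: 6 x 8 kb contigs, 0.3 % SNPs, sparse indels."""
    cfg = SimulationConfig(
        n_contigs=6,
        contig_len=8000,
        snp_rate=0.003,
        indel_rate=3e-4,
        min_planted_spacing=1200,
        chromosomes=("1H",),
        cm_per_contig=2.0,
        seed=11,
    )
    ref, anchors = simulate_reference(cfg)
    qry, truth = mutate(ref, cfg)
    return cfg, ref, anchors, qry, truth
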