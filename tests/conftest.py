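import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from stygdiv import SimConfig, generate_references
from stygdiv.seqio import AlignedSeq

BASES = "ACGT"


def seq_with_mismatches(base: str, positions, rng=None) -> str:
    """Copy ``base`` with a substitution at each 0-based position."""
    s = list(base)
    for p in positions:
        s[p] = BASES[(BASES.index(s[p]) + 1) % 4]
    return "".join(s)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def community():
    """One planted reference community under the default envelope."""
    config = SimConfig(seed=1)
    return config, generate_references(config)


def make_rows(residues_by_id, species=None, source=None, count=None):
    species = species or {}
    source = source or {}
    count = count or {}
    return [
        AlignedSeq(
            i,
            r,
            species=species.get(i),
            source=source.get(i, "clone"),
            count=count.get(i, 1),
        )
        for i, r in residues_by_id.items()
    ]
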