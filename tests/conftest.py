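import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from mitescope import GenomeSequence, PipelineConfig  # noqa: E402

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int, at: float = 0.65) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150421)


@pytest.fixture(scope="session")
def small_planted_genome():
    """200 kb genome with the five default families at 10 copies each."""
    from mitescope.synthetic import default_family_specs, generate_genome
    contigs, truth = generate_genome(
        200_000, 0.65, default_family_specs(copy_number=10), seed=42)
    return contigs, truth


def make_contig(seq: str, name: str = "c1") -> GenomeSequence:
    return GenomeSequence(id=name, residues=seq)
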