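from __future__ import annotations

import numpy as np
import pytest

from flanklift.model import GenomeAssembly, Marker

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng) -> GenomeAssembly:
    """A 5 kb single-chromosome genome, deterministic under the fixture rng."""
    return GenomeAssembly("tiny", {"chr1": random_seq(rng, 5000)})


def marker_at(genome: GenomeAssembly, chrom: str, pos0: int, mid: str = "m1") -> Marker:
    ref = genome.base(chrom, pos0)
    alt = next(b for b in "ACGT" if b != ref)
    return Marker(id=mid, chrom=chrom, pos0=pos0, ref_allele=ref, alt_allele=alt)
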