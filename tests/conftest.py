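"""Shared fixtures: small synthetic bundles and sequence helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gonadmir._seq import revcomp
from gonadmir.config import SimulationConfig

DNA = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), n))


def make_hairpin(rng: np.random.Generator, arm: int = 25, loop: int = 8,
                 mismatches: int = 2, flank: int = 0) -> str:
    """arm + loop + (reverse complement of arm with substitutions), with
    optional random flanks — the shape of a planted precursor."""
    a = random_seq(rng, arm)
    loop_seq = random_seq(rng, loop)
    a2 = list(revcomp(a))
    for pos in rng.choice(arm, size=mismatches, replace=False):
        a2[pos] = rng.choice([b for b in DNA if b != a2[pos]])
    return (random_seq(rng, flank) + a + loop_seq + "".join(a2)
            + random_seq(rng, flank))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully-featured simulation: 8 hairpins on 4 chromosomes."""
    return SimulationConfig(
        seed=11, chrom_lengths=[15_000] * 4, premirna_per_chrom=[0, 3, 3, 2],
        n_premirna=8, n_de=4, library_size_a=8_000, library_size_b=8_000,
        n_genes=24)


@pytest.fixture(scope="session")
def small_truth(small_config):
    from gonadmir.simulate import make_genome, simulate_mrna

    genome, truth = make_genome(small_config)
    simulate_mrna(truth, small_config)  # fills gene/target truth in place
    return genome, truth
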