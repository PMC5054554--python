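"""Shared fixtures: small deterministic haplotype sets and simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan.genotype_io import HaplotypeSet


def make_snp_map(positions, chrom="1"):
    positions = list(positions)
    return pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "allele0": "A",
            "allele1": "G",
        }
    )


def make_hapset(haps, positions=None, chrom="1", pop_label="test"):
    haps = np.asarray(haps, dtype=np.int8)
    if positions is None:
        positions = [1000 * (j + 1) for j in range(haps.shape[1])]
    n = haps.shape[0] // 2
    return HaplotypeSet(
        haps=haps,
        snp_map=make_snp_map(positions, chrom),
        sample_ids=[f"s{i}" for i in range(n)],
        pop_label=pop_label,
    )


@pytest.fixture
def random_hapset():
    rng = np.random.default_rng(7)
    haps = (rng.random((20, 30)) < rng.uniform(0.2, 0.8, 30)).astype(np.int8)
    return make_hapset(haps)


@pytest.fixture(scope="session")
def neutral_pair():
    """Two neutrally diverged populations at the generator defaults."""
    from sweepscan.simdata import SimConfig, simulate_two_pop

    a, b, truth = simulate_two_pop(SimConfig(seed=11))
    return a, b, truth
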