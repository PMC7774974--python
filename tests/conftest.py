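import numpy as np
import pytest

from perupop.io import (
    GenotypeTable,
    PopulationMap,
    SequenceAlignment,
    StrHaplotypeTable,
)


@pytest.fixture
def toy_alignment():
    return SequenceAlignment(
        ("s1", "s2", "s3", "s4"),
        ("ACGTACGTAC", "ACGTACGTAC", "ACGAACGTTC", "TCGAACGTTC"),
    )


@pytest.fixture
def two_pop_map():
    return PopulationMap(
        {
            "s1": ("P1", "R1", "M1"),
            "s2": ("P1", "R1", "M1"),
            "s3": ("P2", "R2", "M1"),
            "s4": ("P2", "R2", "M1"),
        }
    )


@pytest.fixture
def toy_str_table():
    return StrHaplotypeTable(
        ("y1", "y2", "y3"),
        ("DYS19", "DYS390"),
        np.array([[12, 24], [13, 24], [12, -1]]),
    )


def make_genotypes(rows, loci=None):
    """rows: {sample: [(a, b) | None per locus]}."""
    samples = tuple(rows)
    n_loci = len(next(iter(rows.values())))
    loci = tuple(loci or (f"L{j + 1}" for j in range(n_loci)))
    alleles = np.full((len(samples), n_loci, 2), None, dtype=object)
    for i, s in enumerate(samples):
        for j, g in enumerate(rows[s]):
            if g is not None:
                alleles[i, j] = g
    return GenotypeTable(samples, loci, alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
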