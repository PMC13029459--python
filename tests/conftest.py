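"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest
from Bio import Align

from genotax.genome import Genome
from genotax.simulate import generate_ancestor, mutate


def nw_edit_distance(a: str, b: str) -> int:
    """Exhaustive global-alignment edit distance via Biopython's exact DP
    aligner (match 0, mismatch/gap -1 => score = -edit distance).
    Independent oracle for the seeded/banded edlib path."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return -int(aligner.score(a, b))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def ancestor_50k():
    return generate_ancestor(50_000, 0.63, seed=1, replicon_id="chr")


@pytest.fixture(scope="session")
def ancestor_20k():
    return generate_ancestor(20_000, 0.63, seed=2, replicon_id="chr")


def as_genome(replicon, strain="S"):
    return Genome(strain_id=strain, replicons=[replicon])


@pytest.fixture(scope="session")
def mutated_pair_50k(ancestor_50k):
    """(genomeA, genomeB, truth substitution positions) at 2% divergence."""
    derived = mutate(ancestor_50k, 0.02, seed=3)
    truth = {i for i, (x, y) in enumerate(zip(ancestor_50k.seq, derived.seq))
             if x != y}
    return as_genome(ancestor_50k, "A"), as_genome(derived, "B"), truth
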