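"""Shared fixtures: small deterministic amplicons, pairs and simulations."""

import numpy as np
import pytest

from mtcbe.genome_model import EditorPair, SequenceRecord, TaleSite
from mtcbe.quantifier import _count_matrix, NucleotideCountTable
from mtcbe.simulator import random_amplicon


@pytest.fixture(scope="session")
def amplicon():
    """A 220-nt synthetic amplicon at mtDNA-like GC content."""
    return random_amplicon(220, seed=11)


@pytest.fixture(scope="session")
def pair(amplicon):
    """A geometrically valid unconstrained pair with a 14-bp spacer."""
    return EditorPair(
        TaleSite(60, 76, "top", "alpha"),
        TaleSite(90, 106, "bottom", "alpha"),
    )


def make_table(ref: SequenceRecord, calls: list[str]) -> NucleotideCountTable:
    """Hand-build a nucleotide count table from explicit per-read calls."""
    return NucleotideCountTable(ref, _count_matrix(calls, len(ref)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
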