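"""Shared fixtures: planted mini-genomes and injectable CFD tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csc.genome_index import build_target_index, reverse_complement
from csc.specificity import CFDPenaltyTable


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def make_genome_with(rng: np.random.Generator, length: int,
                     inserts: list[tuple[int, str]]) -> str:
    """Random background with planted sequences at given positions."""
    seq = list(random_dna(rng, length))
    for pos, ins in inserts:
        seq[pos : pos + len(ins)] = list(ins)
    return "".join(seq)


@pytest.fixture(scope="session")
def uniform_cfd_table() -> CFDPenaltyTable:
    """All mismatch penalties 1: every enumerated site counts with CFD 1,
    so s = 1 / (total site count) exactly."""
    mm = {(p, g, s): 1.0 for p in range(1, 21)
          for g in "ACGT" for s in "ACGT" if g != s}
    pam = {p: 1.0 for p in ("AGG", "CGG", "GGG", "TGG")}
    return CFDPenaltyTable(mm, pam)


@pytest.fixture(scope="session")
def simple_cfd_table() -> CFDPenaltyTable:
    """Known constants for hand-computable CFD products: penalty 0.6 at
    position 1, 0.5 at position 2, 0.4 at position 3, 0.3 elsewhere."""
    by_pos = {1: 0.6, 2: 0.5, 3: 0.4}
    mm = {(p, g, s): by_pos.get(p, 0.3) for p in range(1, 21)
          for g in "ACGT" for s in "ACGT" if g != s}
    pam = {p: 1.0 for p in ("AGG", "CGG", "GGG", "TGG")}
    pam["TAG"] = 0.2
    return CFDPenaltyTable(mm, pam)


@pytest.fixture(scope="session")
def planted_genome():
    """100 kb genome with a unique guide, an exact duplicate pair, and a
    2-mismatch relative pair; all planted protospacers end in AGG."""
    rng = np.random.default_rng(7)
    unique_guide = "ATGCCTAGCTTGACCATTGA"  # non-palindromic
    dup_guide = "TTGCAGGCTAGCTTAAGCCA"
    twomm_guide = "GGATCCATGCAAGTTCGACA"
    twomm_site = "GGATCCATGCAAGTTCGTCC"  # differs at positions 18, 19
    inserts = [
        (10_000, unique_guide + "AGG"),
        (30_000, dup_guide + "AGG"),
        (50_000, dup_guide + "AGG"),
        (70_000, twomm_site + "AGG"),
    ]
    genome = {"chr1": make_genome_with(rng, 100_000, inserts)}
    return {
        "genome": genome,
        "unique": unique_guide,
        "dup": dup_guide,
        "twomm": twomm_guide,
        "absent": "CCCCGGGGAAAATTTTCCCC",
    }


@pytest.fixture(scope="session")
def planted_index(planted_genome):
    return build_target_index(planted_genome["genome"], k=20)
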