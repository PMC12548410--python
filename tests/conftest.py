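"""Shared fixtures: tiny programmatically generated inputs."""

from __future__ import annotations

import numpy as np
import pytest

from ervfootprint.types import Motif, NucleotideSequence


def make_seq(residues: str, id: str = "s1", **kw) -> NucleotideSequence:
    return NucleotideSequence(id=id, residues=residues, **kw)


def random_seq(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = list("ACGTN") if with_n else list("ACGT")
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(alphabet, length, p=p))


def consensus_motif(consensus: str, weight: float = 0.97, name: str = "m1",
                    mark: str | None = None) -> Motif:
    """PWM that strongly prefers one consensus string."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(consensus)
    mat = np.full((w, 4), (1 - weight) / 3)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = weight
    return Motif(name=name, probability_matrix=mat, source_mark=mark)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
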