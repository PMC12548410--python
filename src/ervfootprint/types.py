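"""Shared domain types.

Coordinates are 0-based half-open internally; the Bismark cytosine-report
dialect (1-based) is converted only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

ALPHABET = "ACGT"
ALLOWED = set("ACGTN")


class VariantClass(str, Enum):
    """Whether a provirus is a germline integrant or an infectious virus."""

    ENDOGENOUS = "endogenous"
    EXOGENOUS = "exogenous"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class NucleotideSequence:
    """One proviral or genomic sequence with group labels.

    ``residues`` is uppercase over {A,C,G,T,N}; anything else is rejected.
    """

    id: str
    residues: str
    virus: str = "unknown"
    variant_class: VariantClass = VariantClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains disallowed symbols: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite evidence (Bismark cytosine-report row).

    ``position`` is 1-based as in the report; ``trinucleotide`` is read on
    the cytosine's own strand starting at the cytosine.
    """

    seq_id: str
    position: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context_class: str  # CpG | CHG | CHH
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("read counts must be non-negative")
        if self.context_class not in ("CpG", "CHG", "CHH"):
            raise ValueError(f"unknown context class {self.context_class!r}")
        if len(self.trinucleotide) != 3 or self.trinucleotide[0] != "C":
            raise ValueError(
                f"trinucleotide must be a 3-mer starting with C, got "
                f"{self.trinucleotide!r}"
            )
        if self.context_class == "CpG" and self.trinucleotide[1] != "G":
            raise ValueError(
                f"CpG context requires trinucleotide[1]=='G', got "
                f"{self.trinucleotide!r}"
            )

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated


@dataclass(frozen=True)
class Motif:
    """A position probability matrix in MEME minimal-format terms."""

    name: str
    probability_matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    source_mark: Optional[str] = None  # e.g. H3K27ac

    def __post_init__(self) -> None:
        mat = np.asarray(self.probability_matrix, dtype=float)
        object.__setattr__(self, "probability_matrix", mat)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 2:
            raise ValueError(f"motif {self.name!r}: matrix must be width>=2 x 4")
        if np.any(mat < 0):
            raise ValueError(f"motif {self.name!r}: negative probabilities")
        rowsums = mat.sum(axis=1)
        bad = np.where(np.abs(rowsums - 1.0) > 1e-3)[0]
        if bad.size:
            raise ValueError(
                f"motif {self.name!r}: row {int(bad[0])} sums to "
                f"{rowsums[bad[0]]:.4f}, not 1"
            )
        if abs(float(bg.sum()) - 1.0) > 1e-3:
            raise ValueError(f"motif {self.name!r}: background does not sum to 1")

    @property
    def width(self) -> int:
        return int(self.probability_matrix.shape[0])

    @property
    def consensus(self) -> str:
        # ties resolved toward the alphabetically first base
        return "".join(ALPHABET[int(i)] for i in self.probability_matrix.argmax(axis=1))


@dataclass(frozen=True)
class CpGIslandRecord:
    """A genomic interval passing GC% and CpG O/E thresholds (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    mean_gc: float
    mean_oe: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start
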