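"""Observed/expected k-mer statistics (D-ratios).

The D-ratio of a motif is its observed frequency divided by the frequency
expected under a background model.  For trinucleotides XYZ the background is
a first-order Markov model,

    P_exp(XYZ) = P_obs(XY) * P_obs(YZ) / P_obs(Y),

so a trinucleotide is judged against the dinucleotides it is built from.
For dinucleotides XY the classical zeroth-order product P_obs(X)*P_obs(Y)
is used (under a first-order background every dinucleotide O/E would be
identically 1).  Frequencies use per-k valid-window denominators: windows
containing N are skipped and do not enter the denominator.

CpG D-ratio << 1 is the signature of methylation-driven CpG decay; TpG and
CpA D-ratios > 1 are the complementary gain from deamination of methylated
cytosines.  No reverse-complement folding is performed anywhere: TpG and
CpA are deliberately distinct observations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import isnan
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ervfootprint.types import NucleotideSequence

DEFAULT_MOTIFS = (
    "CG", "TG", "CA",
    "CGA", "CGC", "CGG", "CGT",
    "TGC", "CAC", "CCG", "CTG", "CCA",
)


@dataclass
class KmerSpectrum:
    """Counts of 1/2/3-mers over N-free windows of one sequence."""

    counts: dict[int, Counter] = field(default_factory=dict)
    valid_windows: dict[int, int] = field(default_factory=dict)

    def frequency(self, kmer: str) -> float:
        """count(kmer) / valid_windows(len(kmer)); NaN when no valid window."""
        k = len(kmer)
        denom = self.valid_windows.get(k, 0)
        if denom == 0:
            return float("nan")
        return self.counts[k][kmer] / denom


@dataclass(frozen=True)
class DRatioResult:
    motif: str
    p_obs: float
    p_exp: float
    d_ratio: float  # NaN when undefined
    undefined: bool

    def __post_init__(self) -> None:
        if not self.undefined and self.p_exp > 0:
            assert abs(self.d_ratio - self.p_obs / self.p_exp) < 1e-12


def count_kmers(seq: NucleotideSequence | str, k: int) -> KmerSpectrum:
    """Count all length-k windows (linear, one strand); N-containing windows skipped."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1,2,3}}, got {k}")
    if k > len(residues):
        raise ValueError(f"k={k} exceeds sequence length {len(residues)}")
    counts: Counter = Counter()
    for i in range(len(residues) - k + 1):
        window = residues[i : i + k]
        if "N" not in window:
            counts[window] += 1
    spec = KmerSpectrum()
    spec.counts[k] = counts
    spec.valid_windows[k] = sum(counts.values())
    return spec


def full_spectrum(seq: NucleotideSequence | str) -> KmerSpectrum:
    """1-, 2- and 3-mer counts in one spectrum."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    spec = KmerSpectrum()
    for k in (1, 2, 3):
        if k <= len(residues):
            part = count_kmers(residues, k)
            spec.counts[k] = part.counts[k]
            spec.valid_windows[k] = part.valid_windows[k]
        else:
            spec.counts[k] = Counter()
            spec.valid_windows[k] = 0
    return spec


def expected_frequency(spectrum: KmerSpectrum, motif: str) -> float:
    """Background-model expected frequency of a 2- or 3-mer.

    Returns NaN when the conditioning frequency is zero (flagged upstream,
    never silently zero).
    """
    motif = motif.upper()
    if len(motif) == 2:
        px = spectrum.frequency(motif[0])
        py = spectrum.frequency(motif[1])
        if isnan(px) or isnan(py):
            return float("nan")
        return px * py
    if len(motif) == 3:
        pxy = spectrum.frequency(motif[:2])
        pyz = spectrum.frequency(motif[1:])
        py = spectrum.frequency(motif[1])
        if isnan(pxy) or isnan(pyz) or isnan(py) or py == 0:
            return float("nan")
        return pxy * pyz / py
    raise ValueError(f"motif must be a 2- or 3-mer, got {motif!r}")


def d_ratio(
    seq: NucleotideSequence | str,
    motif: str,
    spectrum: KmerSpectrum | None = None,
) -> DRatioResult:
    """Observed/expected ratio of one motif on the given strand."""
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if spectrum is None:
        spectrum = full_spectrum(seq)
    p_obs = spectrum.frequency(motif)
    p_exp = expected_frequency(spectrum, motif)
    undefined = isnan(p_obs) or isnan(p_exp) or p_exp == 0
    value = float("nan") if undefined else p_obs / p_exp
    return DRatioResult(
        motif=motif,
        p_obs=p_obs,
        p_exp=p_exp,
        d_ratio=value,
        undefined=undefined,
    )


def d_ratio_table(
    seqs: Iterable[NucleotideSequence],
    motifs: Sequence[str] = DEFAULT_MOTIFS,
) -> pd.DataFrame:
    """One row per sequence x motif; undefined entries carried with a flag.

    Columns: seq_id, virus, variant_class, motif, p_obs, p_exp, d_ratio,
    undefined.
    """
    seqs = list(seqs)
    if not seqs or not motifs:
        raise ValueError("d_ratio_table requires non-empty sequences and motifs")
    rows = []
    for s in seqs:
        spec = full_spectrum(s)
        for m in motifs:
            res = d_ratio(s, m, spectrum=spec)
            rows.append(
                {
                    "seq_id": s.id,
                    "virus": s.virus,
                    "variant_class": s.variant_class.value,
                    "motif": res.motif,
                    "p_obs": res.p_obs,
                    "p_exp": res.p_exp,
                    "d_ratio": res.d_ratio,
                    "undefined": res.undefined,
                }
            )
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, by: Sequence[str] = ("virus", "variant_class", "motif")) -> pd.DataFrame:
    """Median (the headline statistic) and mean D-ratio per group."""
    defined = table[~table["undefined"]]
    out = (
        defined.groupby(list(by))["d_ratio"]
        .agg(median="median", mean="mean", n="count")
        .reset_index()
    )
    return out
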