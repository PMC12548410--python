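"""Summaries of per-cytosine bisulfite evidence.

Per-site percent methylation is 100 * methylated / (methylated +
unmethylated) reads.  CpG sites are stratified by the trinucleotide context
on the cytosine's strand (CGA, CGC, CGG, CGT) — DNA methyltransferases show
context preferences, and a higher CGC median is the footprint this package
looks for.  Plus- and minus-strand calls stay separate sites by default
(the cytosine report is strand-resolved); ``collapse_dyads=True`` sums
counts across each CpG dyad instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ervfootprint.comparative_stats import GroupTestResult, group_compare
from ervfootprint.types import CytosineRecord

CPG_CONTEXTS = ("CGA", "CGC", "CGG", "CGT")


@dataclass(frozen=True)
class MethylationSummary:
    context: str
    site_values: tuple[float, ...]  # per-site percent methylation
    median: float
    n_sites: int


@dataclass
class MethylationTrack:
    seq_id: str
    bin_size: int
    bin_percent: np.ndarray   # NaN where a bin has no covered site
    bin_coverage: np.ndarray  # summed reads per bin
    overall_median: float     # median over qualifying sites


def _records_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": r.seq_id,
            "position": r.position,
            "strand": r.strand,
            "meth": r.count_methylated,
            "unmeth": r.count_unmethylated,
            "context_class": r.context_class,
            "trinucleotide": r.trinucleotide,
        }
        for r in records
    )


def site_methylation(
    records: Sequence[CytosineRecord],
    min_coverage: int = 1,
    collapse_dyads: bool = False,
) -> pd.DataFrame:
    """Per-site percent methylation table.

    Columns: position (1-based), strand, percent, coverage, trinucleotide,
    context_class.  Sites below *min_coverage* are excluded.  When
    *collapse_dyads* is set, a minus-strand CpG call at position p+1 is
    summed into the plus-strand call at p (the CpG dyad) and reported on
    the plus strand.
    """
    if not records:
        return pd.DataFrame(
            columns=["seq_id", "position", "strand", "percent", "coverage",
                     "trinucleotide", "context_class"]
        )
    ids = {r.seq_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple seq_ids: {sorted(ids)}")
    df = _records_frame(records)

    if collapse_dyads:
        cpg = df[df["context_class"] == "CpG"].copy()
        other = df[df["context_class"] != "CpG"]
        # map minus-strand member of a dyad onto its plus-strand position
        cpg["dyad_pos"] = np.where(cpg["strand"] == "-", cpg["position"] - 1,
                                   cpg["position"])
        agg = cpg.groupby("dyad_pos").agg(
            seq_id=("seq_id", "first"),
            meth=("meth", "sum"),
            unmeth=("unmeth", "sum"),
            trinucleotide=("trinucleotide", "first"),
            context_class=("context_class", "first"),
        ).reset_index(names="position")
        agg["strand"] = "+"
        df = pd.concat([agg, other], ignore_index=True)

    df["coverage"] = df["meth"] + df["unmeth"]
    df = df[df["coverage"] >= max(min_coverage, 1)].copy()
    df["percent"] = 100.0 * df["meth"] / df["coverage"]
    cols = ["seq_id", "position", "strand", "percent", "coverage",
            "trinucleotide", "context_class"]
    return df[cols].sort_values(["position", "strand"]).reset_index(drop=True)


def context_methylation(
    records: Sequence[CytosineRecord],
    contexts: Sequence[str] = CPG_CONTEXTS,
    min_coverage: int = 1,
    collapse_dyads: bool = False,
) -> tuple[list[MethylationSummary], Optional[GroupTestResult]]:
    """Per-trinucleotide-context methylation distributions and a cross-context test.

    Only CpG-context records are used.  Contexts with zero qualifying sites
    get an empty summary and are excluded from the Kruskal-Wallis/Dunn (or
    Mann-Whitney, at two contexts) comparison; with fewer than two testable
    contexts no test is run.
    """
    contexts = tuple(c.upper() for c in contexts)
    sites = site_methylation(
        [r for r in records if r.context_class == "CpG"],
        min_coverage=min_coverage,
        collapse_dyads=collapse_dyads,
    ) if records else site_methylation([], min_coverage=min_coverage)

    summaries = []
    for ctx in contexts:
        vals = tuple(sites.loc[sites["trinucleotide"] == ctx, "percent"])
        summaries.append(
            MethylationSummary(
                context=ctx,
                site_values=vals,
                median=float(np.median(vals)) if vals else float("nan"),
                n_sites=len(vals),
            )
        )

    testable = sites[sites["trinucleotide"].isin(contexts)]
    counts = testable["trinucleotide"].value_counts()
    usable = [c for c in contexts if counts.get(c, 0) >= 2]
    test = None
    if len(usable) >= 2:
        test = group_compare(
            testable[testable["trinucleotide"].isin(usable)],
            group_col="trinucleotide",
            value_col="percent",
        )
    return summaries, test


def provirus_track(
    records: Sequence[CytosineRecord],
    seq_length: int,
    bin_size: int = 100,
    min_coverage: int = 1,
    context_class: str = "CpG",
) -> MethylationTrack:
    """Coverage-weighted per-bin mean percent methylation across a provirus.

    Bins tile [0, seq_length); a bin with no qualifying site is NaN.  The
    overall median is over qualifying sites (the per-virus summary point of
    the methylation-vs-O/E panel).
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    sites = site_methylation(
        [r for r in records if r.context_class == context_class],
        min_coverage=min_coverage,
    )
    n_bins = int(np.ceil(seq_length / bin_size))
    pct = np.full(n_bins, np.nan)
    cov = np.zeros(n_bins)
    seq_id = records[0].seq_id if records else "seq"
    if len(sites):
        seq_id = sites["seq_id"].iloc[0]
        bins = ((sites["position"] - 1) // bin_size).to_numpy()
        if bins.max() >= n_bins:
            raise ValueError("cytosine positions exceed the stated sequence length")
        meth_reads = sites["percent"].to_numpy() / 100.0 * sites["coverage"].to_numpy()
        cov = np.bincount(bins, weights=sites["coverage"], minlength=n_bins)
        meth = np.bincount(bins, weights=meth_reads, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1e-300), np.nan)
    overall = float(np.median(sites["percent"])) if len(sites) else float("nan")
    return MethylationTrack(
        seq_id=seq_id, bin_size=bin_size, bin_percent=pct,
        bin_coverage=cov, overall_median=overall,
    )


def write_track_bedgraph(track: MethylationTrack, path) -> None:
    """bedGraph-style per-bin percent methylation (no-data bins omitted)."""
    with open(path, "w") as fh:
        for i, v in enumerate(track.bin_percent):
            if not np.isnan(v):
                fh.write(
                    f"{track.seq_id}\t{i * track.bin_size}\t"
                    f"{(i + 1) * track.bin_size}\t{v:.3f}\n"
                )
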