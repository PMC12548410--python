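"""PWM scanning and set-based motif enrichment.

Scanning scores every position on both strands with the log-odds (bits) of
the motif's probability matrix against its background; the calling
threshold is the score whose exceedance probability under the background
model is at most ``threshold_quantile``, computed exactly by dynamic
programming over the (discretized) column score distributions.

Enrichment between a primary and a control sequence set is a one-sided
Fisher's exact test on presence/absence of at least one hit, with a
Bonferroni E-value (p times the number of motifs tested).  On top of the
E-value cutoff sits a strict all-or-almost-all presence rule: a motif
counts as enriched only when it hits every primary sequence with at most
one control sequence, or all but one primary sequence with no control
sequence at all.  Hits for promoter-associated histone marks (H3K4me3,
H3K27ac, H3K27me3) can additionally be restricted to CpG islands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from ervfootprint.types import ALPHABET, CpGIslandRecord, Motif, NucleotideSequence

log = logging.getLogger(__name__)

DEFAULT_QUANTILE = 1e-4
DEFAULT_EVALUE = 0.05
CGI_RESTRICTED_MARKS = frozenset({"H3K4me3", "H3K27ac", "H3K27me3"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SCALE = 1000  # log-odds discretization: 0.001-bit granularity


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif_name: str
    start: int  # 0-based, plus-strand coordinates
    strand: str
    score: float  # log-odds bits


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    n_primary_with_hit: int
    n_primary: int
    n_control_with_hit: int
    n_control: int
    p_value: float
    e_value: float
    passes_bespoke_filter: bool
    cgi_restricted: bool = False


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _log_odds_matrix(motif: Motif, pseudo: float = 1e-4) -> np.ndarray:
    """width x 4 integer matrix of discretized log2-odds scores."""
    p = motif.probability_matrix + pseudo
    p = p / p.sum(axis=1, keepdims=True)
    bg = motif.background + pseudo
    bg = bg / bg.sum()
    lo = np.log2(p / bg)
    return np.rint(lo * _SCALE).astype(np.int64)


def score_threshold(motif: Motif, threshold_quantile: float = DEFAULT_QUANTILE) -> float:
    """Smallest score t with P_background(score >= t) <= threshold_quantile.

    The null distribution of the total score for a background-drawn window
    is built exactly by convolving the per-column score distributions
    (dynamic programming over discretized scores).
    """
    lo = _log_odds_matrix(motif)
    bg = motif.background / motif.background.sum()
    dist: dict[int, float] = {0: 1.0}
    for row in lo:
        nxt: dict[int, float] = {}
        for acc, prob in dist.items():
            for b in range(4):
                key = acc + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + prob * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    tail = np.cumsum([dist[int(s)] for s in scores[::-1]])[::-1]
    ok = np.flatnonzero(tail <= threshold_quantile)
    if ok.size == 0:
        # nothing exceeds: threshold just above the maximum attainable score
        return float(scores[-1] + 1) / _SCALE
    return float(scores[ok[0]]) / _SCALE


def _scan_strand(residues: str, lo: np.ndarray, thr_int: int) -> list[tuple[int, float]]:
    w = lo.shape[0]
    idx = np.full(len(residues), -1, dtype=np.int64)
    for b, base in enumerate(ALPHABET):
        idx[np.frombuffer(residues.encode(), dtype=np.uint8) == ord(base)] = b
    hits = []
    n = len(residues) - w + 1
    if n <= 0:
        return hits
    # windows containing N (idx -1) are skipped
    valid = np.ones(n, dtype=bool)
    bad = np.flatnonzero(idx < 0)
    for p in bad:
        lo_s = max(0, p - w + 1)
        valid[lo_s : min(n, p + 1)] = False
    starts = np.flatnonzero(valid)
    if starts.size == 0:
        return hits
    windows = idx[starts[:, None] + np.arange(w)[None, :]]
    scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
    for s, sc in zip(starts[scores >= thr_int], scores[scores >= thr_int]):
        hits.append((int(s), float(sc) / _SCALE))
    return hits


def scan_motif(
    seq: NucleotideSequence,
    motif: Motif,
    threshold_quantile: float = DEFAULT_QUANTILE,
) -> list[MotifHit]:
    """All positions on both strands scoring above the background threshold.

    Minus-strand hits are reported in plus-strand coordinates of the
    window they occupy.  Overlapping hits are allowed.  A motif wider than
    the sequence yields an empty list with a warning.
    """
    if motif.width > seq.length:
        log.warning(
            "motif %s (width %d) wider than sequence %s (length %d)",
            motif.name, motif.width, seq.id, seq.length,
        )
        return []
    lo = _log_odds_matrix(motif)
    thr = score_threshold(motif, threshold_quantile)
    thr_int = int(np.rint(thr * _SCALE))
    hits = [
        MotifHit(seq.id, motif.name, start, "+", score)
        for start, score in _scan_strand(seq.residues, lo, thr_int)
    ]
    rc = reverse_complement(seq.residues)
    w = motif.width
    for start_rc, score in _scan_strand(rc, lo, thr_int):
        hits.append(
            MotifHit(seq.id, motif.name, seq.length - start_rc - w, "-", score)
        )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def sea_enrich(
    primary: Sequence[NucleotideSequence],
    control: Sequence[NucleotideSequence],
    motifs: Sequence[Motif],
    n_motifs_tested: Optional[int] = None,
    threshold_quantile: float = DEFAULT_QUANTILE,
    evalue_cutoff: float = DEFAULT_EVALUE,
    islands: Optional[Sequence[CpGIslandRecord]] = None,
    restricted_marks: Iterable[str] = CGI_RESTRICTED_MARKS,
) -> list[EnrichmentResult]:
    """Per-motif presence/absence enrichment of primary vs control sets.

    Presence means >= 1 hit after the optional CpG-island restriction for
    *restricted_marks*.  E-value is p times *n_motifs_tested* (default: the
    number of motifs supplied).
    """
    if not primary or not control:
        raise ValueError("primary and control sets must both be non-empty")
    if n_motifs_tested is None:
        n_motifs_tested = len(motifs)
    results = []
    for motif in motifs:
        def present(seqs: Sequence[NucleotideSequence]) -> int:
            count = 0
            for s in seqs:
                hits = scan_motif(s, motif, threshold_quantile)
                if islands is not None:
                    hits = cgi_overlap_filter(hits, islands, restricted_marks,
                                              motif_widths={motif.name: motif.width},
                                              motif_marks={motif.name: motif.source_mark})
                count += bool(hits)
            return count

        k1, k0 = present(primary), present(control)
        n1, n0 = len(primary), len(control)
        _, p = stats.fisher_exact(
            [[k1, n1 - k1], [k0, n0 - k0]], alternative="greater"
        )
        res = EnrichmentResult(
            motif_name=motif.name,
            n_primary_with_hit=k1, n_primary=n1,
            n_control_with_hit=k0, n_control=n0,
            p_value=float(p), e_value=float(p) * n_motifs_tested,
            passes_bespoke_filter=False,
            cgi_restricted=islands is not None,
        )
        object.__setattr__(res, "passes_bespoke_filter", bespoke_filter(res, evalue_cutoff))
        results.append(res)
    return results


def bespoke_filter(result: EnrichmentResult, evalue_cutoff: float = DEFAULT_EVALUE) -> bool:
    """Strict presence rule layered on the E-value cutoff.

    True iff E <= cutoff and either every primary sequence has the motif
    with at most one control sequence also having it, or all but one
    primary sequence has it with zero control sequences having it.
    """
    if result.e_value > evalue_cutoff:
        return False
    all_primary = result.n_primary_with_hit == result.n_primary
    almost_all = result.n_primary_with_hit == result.n_primary - 1
    return (all_primary and result.n_control_with_hit <= 1) or (
        almost_all and result.n_control_with_hit == 0
    )


def cgi_overlap_filter(
    hits: Sequence[MotifHit],
    islands: Sequence[CpGIslandRecord],
    marks: Iterable[str],
    motif_widths: Optional[dict[str, int]] = None,
    motif_marks: Optional[dict[str, Optional[str]]] = None,
) -> list[MotifHit]:
    """Keep restricted-mark hits only when they intersect a CpG island.

    Hits whose motif's histone mark is not in *marks* pass through
    untouched.  *motif_widths* / *motif_marks* map motif names to widths
    and source marks (needed because hits carry only names).
    """
    marks = {m for m in marks}
    motif_widths = motif_widths or {}
    motif_marks = motif_marks or {}
    kept = []
    for h in hits:
        mark = motif_marks.get(h.motif_name)
        if mark is None or mark not in marks:
            kept.append(h)
            continue
        w = motif_widths.get(h.motif_name, 1)
        lo_, hi_ = h.start, h.start + w
        if any(
            isl.seq_id == h.seq_id and lo_ < isl.end and isl.start < hi_
            for isl in islands
        ):
            kept.append(h)
    return kept
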