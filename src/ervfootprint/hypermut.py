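"""APOBEC3G hypermutation detection on query-vs-reference alignments.

APOBEC3G deaminates cytosines on the minus strand of reverse-transcribing
retroviruses, which reads out as G->A changes on the plus strand in a
characteristic downstream context.  Following the published Hypermut
convention, each reference G is stratified by its two downstream reference
bases: the primary (APOBEC-preferred) stratum is G·R·D with R in {A,G} and
D in {A,G,T}; every other resolvable context is the control stratum.  A
one-sided Fisher's exact test asks whether G->A changes are enriched in the
primary stratum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from ervfootprint.types import NucleotideSequence

ALPHA = 0.05
PRIMARY_R = frozenset("AG")
PRIMARY_D = frozenset("AGT")


@dataclass(frozen=True)
class HypermutCounts:
    primary_mutated: int
    primary_total: int
    control_mutated: int
    control_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.primary_mutated <= self.primary_total):
            raise ValueError("primary mutated count exceeds total")
        if not (0 <= self.control_mutated <= self.control_total):
            raise ValueError("control mutated count exceeds total")


@dataclass(frozen=True)
class HypermutResult:
    seq_id: str
    counts: HypermutCounts
    p_value: float
    rate_ratio: float  # inf when control rate is 0 and primary rate > 0
    significant: bool


def _context_is_primary(b1: str, b2: str, r=PRIMARY_R, d=PRIMARY_D) -> bool:
    return b1 in r and b2 in d


def classify_contexts(
    reference: NucleotideSequence | str,
    query: NucleotideSequence | str,
    primary_r: frozenset = PRIMARY_R,
    primary_d: frozenset = PRIMARY_D,
) -> HypermutCounts:
    """Stratify reference G positions by downstream context; count G->A in query.

    Sequences must be equal length (pre-aligned; gaps as '-').  A position
    is skipped when reference or query carries a gap or N there; the two
    downstream context bases are the next two ungapped reference bases, and
    positions without two such bases are skipped.
    """
    ref = (reference.residues if isinstance(reference, NucleotideSequence)
           else str(reference).upper())
    qry = (query.residues if isinstance(query, NucleotideSequence)
           else str(query).upper())
    if len(ref) != len(qry):
        raise ValueError(f"length mismatch: reference {len(ref)} vs query {len(qry)}")

    # positions of ungapped reference bases, for downstream-context lookup
    ref_pos = [i for i, b in enumerate(ref) if b != "-"]
    next_idx = {p: k for k, p in enumerate(ref_pos)}

    pm = pt = cm = ct = 0
    for i, b in enumerate(ref):
        if b != "G":
            continue
        if qry[i] in ("-", "N"):
            continue
        k = next_idx[i]
        if k + 2 >= len(ref_pos):
            continue
        b1, b2 = ref[ref_pos[k + 1]], ref[ref_pos[k + 2]]
        if b1 == "N" or b2 == "N":
            continue
        mutated = qry[i] == "A"
        if _context_is_primary(b1, b2, primary_r, primary_d):
            pt += 1
            pm += mutated
        else:
            ct += 1
            cm += mutated
    return HypermutCounts(pm, pt, cm, ct)


def hypermut_test(counts: HypermutCounts, seq_id: str = "query") -> HypermutResult:
    """One-sided Fisher's exact test for primary-stratum mutation enrichment."""
    if counts.primary_total == 0 or counts.control_total == 0:
        raise ValueError(
            "a context stratum has zero G positions; a longer alignment is needed"
        )
    table = [
        [counts.primary_mutated, counts.primary_total - counts.primary_mutated],
        [counts.control_mutated, counts.control_total - counts.control_mutated],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    primary_rate = counts.primary_mutated / counts.primary_total
    control_rate = counts.control_mutated / counts.control_total
    if control_rate == 0:
        ratio = float("inf") if primary_rate > 0 else float("nan")
    else:
        ratio = primary_rate / control_rate
    return HypermutResult(
        seq_id=seq_id,
        counts=counts,
        p_value=float(p),
        rate_ratio=ratio,
        significant=bool(p < ALPHA),
    )


def majority_consensus(seqs: Sequence[NucleotideSequence | str]) -> str:
    """Column-wise majority consensus of equal-length aligned sequences.

    Ties break deterministically in the order A < C < G < T < '-'; N is
    ignored unless a column is all-N.
    """
    rows = [
        s.residues if isinstance(s, NucleotideSequence) else str(s).upper()
        for s in seqs
    ]
    if not rows:
        raise ValueError("no sequences")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("aligned sequences must share one length")
    order = {b: i for i, b in enumerate("ACGT-")}
    out = []
    for col in zip(*rows):
        counts = Counter(b for b in col if b != "N")
        if not counts:
            out.append("N")
            continue
        best = min(counts, key=lambda b: (-counts[b], order.get(b, 9)))
        out.append(best)
    return "".join(out)


def screen_sequences(
    seqs: Sequence[NucleotideSequence],
    reference: Optional[NucleotideSequence | str] = None,
) -> list[HypermutResult]:
    """Hypermutation test for every query against a reference.

    When *reference* is None the majority consensus of the set is used
    (the standard choice when no named exogenous reference exists).
    """
    ref = reference if reference is not None else majority_consensus(seqs)
    results = []
    for s in seqs:
        counts = classify_contexts(ref, s)
        results.append(hypermut_test(counts, seq_id=s.id))
    return results
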