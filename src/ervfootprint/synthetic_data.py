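"""Simulation of methylation-driven CpG decay in proviral sequences.

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes:

1. an ancestral provirus drawn from a first-order Markov chain whose C->G
   transition is calibrated so the expected CpG O/E equals a target;
2. context-dependent CpG methylation (elevated at CGC/CGG by default,
   dyad-symmetric);
3. per-generation deamination of methylated CpGs — each event converts the
   plus-strand C->T (CG->TG) or, with equal probability, the minus-strand
   C->T, i.e. plus-strand G->A (CG->CA); a deaminated site is no longer a
   CpG and cannot fire again;
4. binomially sampled per-cytosine bisulfite evidence at Poisson coverage;
5. motif implantation for enrichment testing.

All randomness flows from a single seed through spawned sub-streams, so
each stage is independently reproducible.  No back-mutation, selection or
indels: the minimal mechanism sufficient to exercise every estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ervfootprint.types import ALPHABET, CytosineRecord, Motif, NucleotideSequence
from ervfootprint import cgi_detect

DEFAULT_CONTEXT_METH_PROB = {"CGC": 0.9, "CGG": 0.8, "CGA": 0.5, "CGT": 0.5}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated lineage panel.

    Defaults model a provirus-sized sequence (8 kb) at neutral CpG content
    (O/E 1.0 before decay), methyltransferase context preference for
    CGC/CGG, a 5% per-generation deamination hazard per methylated CpG,
    and 30x mean bisulfite coverage.
    """

    length: int = 8_000
    target_cpg_oe: float = 1.0
    context_meth_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_METH_PROB)
    )
    default_meth_prob: float = 0.5
    deamination_rate: float = 0.05
    generations: int = 10
    n_lineages: int = 20
    coverage: float = 30.0
    minus_strand_bias: float = 0.5  # probability a deamination hits the minus strand
    seed: int = 0

    def __post_init__(self) -> None:
        for ctx, p in self.context_meth_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"context probability {ctx}={p} outside [0,1]")
        if not 0 <= self.deamination_rate <= 1:
            raise ValueError("deamination_rate outside [0,1]")
        if not 0 <= self.minus_strand_bias <= 1:
            raise ValueError("minus_strand_bias outside [0,1]")
        if self.length < 1:
            raise ValueError("length must be positive")


@dataclass
class LineageRecord:
    """Ground truth for one simulated lineage."""

    ancestor: NucleotideSequence
    descendant: NucleotideSequence
    cpg_positions: np.ndarray       # plus-strand C index of each ancestral CpG
    methylated: np.ndarray          # bool per ancestral CpG
    surviving_methylated: np.ndarray  # bool: methylated and still CpG at the end
    n_cg_to_tg: int
    n_cg_to_ca: int


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# 1. Markov background


def _calibrate_cg_transition(target: float) -> float:
    """C->G transition probability whose stationary CpG O/E equals target.

    With uniform rows for A/G/T and the C row giving s to G and (1-s)/3 to
    each of A/C/T, the stationary solution gives
    pi_C = 0.25 / (1.25 - (1-s)/3) and pi_G = 0.25 (1 - pi_C) + s pi_C,
    and the product-form O/E is s / pi_G.  Solve s = target * pi_G(s) by
    fixed-point iteration.
    """
    s = 0.25 * target
    for _ in range(100):
        pi_c = 0.25 / (1.25 - (1.0 - s) / 3.0)
        pi_g = 0.25 * (1.0 - pi_c) + s * pi_c
        s_new = target * pi_g
        if abs(s_new - s) < 1e-14:
            s = s_new
            break
        s = s_new
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"target CpG O/E {target} is not attainable")
    return s


def gen_markov_sequence(config: SimulationConfig, lineage: int = 0) -> NucleotideSequence:
    """Sample one ancestral sequence from the calibrated first-order chain."""
    s = _calibrate_cg_transition(config.target_cpg_oe)
    trans = np.full((4, 4), 0.25)
    c = ALPHABET.index("C")
    g = ALPHABET.index("G")
    trans[c] = (1.0 - s) / 3.0
    trans[c, g] = s
    rng = _rng(config.seed, 0, lineage)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(config.length)
    seq = np.empty(config.length, dtype=np.int64)
    seq[0] = rng.integers(4)
    for i in range(1, config.length):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i])
    residues = "".join(ALPHABET[b] for b in seq)
    return NucleotideSequence(
        id=f"sim{lineage}", residues=residues, virus="simulated",
    )


# ---------------------------------------------------------------------------
# 2. Context-dependent methylation


def assign_methylation(
    seq: NucleotideSequence,
    context_meth_prob: Optional[dict] = None,
    seed: int = 0,
    default_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli methylation state per plus-strand CpG, by trinucleotide context.

    Returns (cpg_positions, methylated).  Dyad symmetry is assumed: the
    minus-strand cytosine of each CpG shares the state.  CpGs at the very
    end of the sequence (no third base) use the default probability.
    """
    probs = dict(DEFAULT_CONTEXT_METH_PROB if context_meth_prob is None
                 else context_meth_prob)
    r = seq.residues
    positions = np.array(
        [i for i in range(len(r) - 1) if r[i : i + 2] == "CG"], dtype=np.int64
    )
    if positions.size == 0:
        raise ValueError("sequence contains no CpG")
    p = np.array(
        [probs.get(r[i : i + 3], default_prob) for i in positions]
    )
    rng = _rng(seed, 1)
    methylated = rng.random(positions.size) < p
    return positions, methylated


# ---------------------------------------------------------------------------
# 3. Generational deamination


def evolve_deamination(
    seq: NucleotideSequence,
    cpg_positions: np.ndarray,
    methylated: np.ndarray,
    rate: float,
    generations: int,
    seed: int = 0,
    minus_strand_bias: float = 0.5,
) -> LineageRecord:
    """Deaminate methylated CpGs over generations.

    Each surviving methylated CpG fires with probability *rate* per
    generation; a firing converts CG->TG (plus-strand C->T) or CG->CA
    (minus-strand C->T seen as plus-strand G->A) with probabilities
    (1 - minus_strand_bias, minus_strand_bias).  Fired sites are no longer
    CpG and never fire again; non-CpG positions never change.
    """
    rng = _rng(seed, 2)
    residues = list(seq.residues)
    alive = methylated.copy()
    n_tg = n_ca = 0
    for _ in range(generations):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        fire = idx[rng.random(idx.size) < rate]
        for j in fire:
            i = int(cpg_positions[j])
            if rng.random() < minus_strand_bias:
                residues[i + 1] = "A"  # CG -> CA
                n_ca += 1
            else:
                residues[i] = "T"      # CG -> TG
                n_tg += 1
        alive[fire] = False
    descendant = replace(seq, id=f"{seq.id}_desc", residues="".join(residues))
    return LineageRecord(
        ancestor=seq,
        descendant=descendant,
        cpg_positions=cpg_positions,
        methylated=methylated,
        surviving_methylated=alive,
        n_cg_to_tg=n_tg,
        n_cg_to_ca=n_ca,
    )


# ---------------------------------------------------------------------------
# 4. Bisulfite evidence


def emit_cytosine_report(
    seq: NucleotideSequence,
    site_probs: dict[tuple[int, str], float],
    coverage: float,
    seed: int = 0,
) -> list[CytosineRecord]:
    """Sample per-cytosine read counts for the given sites.

    *site_probs* maps (0-based position, strand) to the true methylation
    probability of that cytosine.  Coverage is Poisson(*coverage*) per
    site, methylated reads Binomial(coverage, p).  The trinucleotide
    column is read from the sequence on the cytosine's own strand.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    r = seq.residues
    rng = _rng(seed, 3)
    records = []
    for (pos, strand), p in sorted(site_probs.items()):
        if strand == "+":
            if r[pos] != "C":
                raise ValueError(f"no plus-strand C at position {pos}")
            tri = r[pos : pos + 3]
        else:
            if r[pos] != "G":
                raise ValueError(f"no minus-strand C at position {pos}")
            tri = r[max(0, pos - 2) : pos + 1].translate(_COMPLEMENT)[::-1]
        if len(tri) < 3 or "N" in tri:
            continue
        context = "CpG" if tri[1] == "G" else ("CHG" if tri[2] == "G" else "CHH")
        cov = int(rng.poisson(coverage))
        meth = int(rng.binomial(cov, p)) if cov > 0 else 0
        records.append(
            CytosineRecord(
                seq_id=seq.id,
                position=pos + 1,  # report dialect is 1-based
                strand=strand,
                count_methylated=meth,
                count_unmethylated=cov - meth,
                context_class=context,
                trinucleotide=tri,
            )
        )
    return records


def cpg_report_from_lineage(
    lineage: LineageRecord,
    coverage: float,
    seed: int = 0,
    p_methylated: float = 0.95,
    p_unmethylated: float = 0.02,
) -> list[CytosineRecord]:
    """Bisulfite report for the descendant's surviving CpG dyads.

    Methylated dyads read out near-fully methylated (bisulfite non-
    conversion and errors put the true rates just off 0 and 1).
    """
    desc = lineage.descendant.residues
    probs: dict[tuple[int, str], float] = {}
    for j, i in enumerate(lineage.cpg_positions):
        i = int(i)
        if desc[i : i + 2] != "CG":
            continue
        p = p_methylated if lineage.surviving_methylated[j] else p_unmethylated
        probs[(i, "+")] = p
        probs[(i + 1, "-")] = p
    return emit_cytosine_report(lineage.descendant, probs, coverage, seed=seed)


# ---------------------------------------------------------------------------
# 5. Motif implantation


def implant_motifs(
    seqs: Sequence[NucleotideSequence],
    motif: Motif,
    where: str | tuple[int, int] = "anywhere",
    seed: int = 0,
) -> tuple[list[NucleotideSequence], list[int]]:
    """Overwrite each sequence with the motif consensus at a sampled position.

    *where* is "anywhere", an explicit (start, end) interval to sample
    within, or "in-CGI" to sample inside a called CpG island (error when a
    sequence has none).  Returns the modified sequences and the implant
    positions.
    """
    consensus = motif.consensus
    w = len(consensus)
    rng = _rng(seed, 4)
    out, positions = [], []
    for s in seqs:
        if w > s.length:
            raise ValueError(
                f"motif width {w} exceeds sequence {s.id} length {s.length}"
            )
        if where == "anywhere":
            lo, hi = 0, s.length - w
        elif where == "in-CGI":
            islands = cgi_detect.find_islands(s)
            islands = [isl for isl in islands if isl.length >= w]
            if not islands:
                raise ValueError(f"sequence {s.id} has no CpG island to implant into")
            isl = islands[int(rng.integers(len(islands)))]
            lo, hi = isl.start, isl.end - w
        else:
            lo, hi = where
            hi = min(hi, s.length) - w
            if hi < lo:
                raise ValueError("interval too small for the motif")
        pos = int(rng.integers(lo, hi + 1))
        residues = s.residues[:pos] + consensus + s.residues[pos + w:]
        out.append(replace(s, residues=residues))
        positions.append(pos)
    return out, positions


# ---------------------------------------------------------------------------
# Panel-level driver


def simulate_lineages(config: SimulationConfig) -> list[LineageRecord]:
    """One deaminated lineage per replicate, generations varying across lineages.

    Lineage k runs for ``1 + k * (config.generations * 4 - 1) //
    (n_lineages - 1)`` generations when n_lineages > 1 — i.e. generations
    spread evenly over 1..4*generations so the panel spans light to heavy
    CpG decay (the spread that makes the deamination-signature correlation
    estimable).
    """
    records = []
    max_gen = max(config.generations * 4, 1)
    for k in range(config.n_lineages):
        if config.n_lineages > 1:
            gen = 1 + round(k * (max_gen - 1) / (config.n_lineages - 1))
        else:
            gen = config.generations
        seq = gen_markov_sequence(config, lineage=k)
        positions, states = assign_methylation(
            seq, config.context_meth_prob,
            seed=config.seed * 1_000 + k,
            default_prob=config.default_meth_prob,
        )
        rec = evolve_deamination(
            seq, positions, states,
            rate=config.deamination_rate,
            generations=gen,
            seed=config.seed * 1_000 + k,
            minus_strand_bias=config.minus_strand_bias,
        )
        records.append(rec)
    return records
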