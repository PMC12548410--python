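"""Readers and writers for every external format the pipeline touches.

No science here: FASTA sequences (group labels as ``key=value`` header
tokens or a TSV manifest), Bismark genome-wide cytosine reports (7-column
TSV, 1-based), MEME minimal motif files, and BED6 output.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from ervfootprint.types import ALPHABET, CytosineRecord, Motif, NucleotideSequence, VariantClass

log = logging.getLogger(__name__)

_NON_ACGT = re.compile(r"[^ACGT]")


def _clean_residues(raw: str) -> str:
    """Uppercase, U->T, anything outside {A,C,G,T} -> N."""
    s = str(raw).upper().replace("U", "T")
    return _NON_ACGT.sub("N", s)


def _parse_header_labels(description: str) -> dict:
    labels = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, val = token.partition("=")
            labels[key.lower()] = val
    return labels


def read_fasta(
    path: str | Path,
    manifest: Optional[str | Path] = None,
) -> list[NucleotideSequence]:
    """Read a FASTA file into :class:`NucleotideSequence` records.

    Group labels come from ``virus=`` / ``class=`` header tokens, or from an
    optional TSV *manifest* (``id<TAB>virus<TAB>class``) which overrides them.

    Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    side: dict[str, tuple[str, str]] = {}
    if manifest is not None:
        for ln, line in enumerate(Path(manifest).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{manifest}:{ln}: expected 3 tab-separated columns")
            side[parts[0]] = (parts[1], parts[2])

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        labels = _parse_header_labels(rec.description)
        virus = labels.get("virus", "unknown")
        klass = labels.get("class", "unknown")
        if rec.id in side:
            virus, klass = side[rec.id]
        try:
            variant = VariantClass(klass.lower())
        except ValueError:
            variant = VariantClass.UNKNOWN
        records.append(
            NucleotideSequence(
                id=rec.id,
                residues=_clean_residues(str(rec.seq)),
                virus=virus,
                variant_class=variant,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an alignment FASTA as (id, residues) pairs, preserving '-' gaps.

    All sequences must share one length; symbols outside {A,C,G,T,-} map to N.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        s = str(rec.seq).upper().replace("U", "T")
        s = re.sub(r"[^ACGT\-]", "N", s)
        pairs.append((rec.id, s))
    if not pairs:
        raise ValueError(f"no FASTA records found in {path}")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    return pairs


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id} virus={s.virus} class={s.variant_class.value}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Bismark genome-wide cytosine report


def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    """Parse a Bismark genome-wide cytosine report.

    Columns: seq_id, position (1-based), strand, count_methylated,
    count_unmethylated, context class (CpG/CHG/CHH), trinucleotide.
    Malformed rows raise with their line number; an empty file yields an
    empty list with a logged warning.
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{ln}: expected 7 tab-separated fields, got {len(parts)}"
                )
            seq_id, pos, strand, meth, unmeth, ctx, trinuc = parts
            try:
                rec = CytosineRecord(
                    seq_id=seq_id,
                    position=int(pos),
                    strand=strand,
                    count_methylated=int(meth),
                    count_unmethylated=int(unmeth),
                    context_class=ctx,
                    trinucleotide=trinuc.upper(),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            records.append(rec)
    if not records:
        log.warning("cytosine report %s is empty", path)
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.position}\t{r.strand}\t{r.count_methylated}\t"
                f"{r.count_unmethylated}\t{r.context_class}\t{r.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path: str | Path) -> list[Motif]:
    """Parse MEME minimal motif format.

    The file-level background line is attached to every motif; uniform 0.25
    when absent. A histone-mark label is recognised in the motif name or its
    alternate name (e.g. ``MOTIF m1 H3K27ac``).
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[Motif] = []
    i = 0
    mark_re = re.compile(r"(H[1-4]K\d+(?:me\d|ac|ub)?)", re.IGNORECASE)
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            vals: list[float] = []
            while i < len(lines) and len(vals) < 8:
                toks = lines[i].split()
                if not toks or toks[0].upper() == "MOTIF":
                    break
                for a, b in zip(toks[::2], toks[1::2]):
                    if a.upper() in "ACGT":
                        vals.append(float(b))
                i += 1
            if len(vals) >= 4:
                background = np.array(vals[:4])
            continue
        if line.upper().startswith("MOTIF"):
            toks = line.split()
            name = toks[1] if len(toks) > 1 else f"motif_{len(motifs) + 1}"
            mark = None
            for tok in toks[1:]:
                m = mark_re.fullmatch(tok)
                if m:
                    mark = m.group(1)
            i += 1
            # seek the letter-probability header
            while i < len(lines) and not lines[i].strip().lower().startswith(
                "letter-probability"
            ):
                if lines[i].strip().upper().startswith("MOTIF"):
                    raise ValueError(
                        f"{path}: motif {name!r} has no letter-probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise ValueError(
                    f"{path}: motif {name!r} has no letter-probability matrix"
                )
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                toks = lines[i].split()
                if not toks or not _is_float(toks[0]):
                    break
                rows.append([float(t) for t in toks[:4]])
                i += 1
            mat = np.array(rows)
            for ri, rowsum in enumerate(mat.sum(axis=1)):
                if abs(rowsum - 1.0) > 1e-3:
                    raise ValueError(
                        f"{path}: motif {name!r} row {ri} sums to {rowsum:.4f}, not 1"
                    )
            motifs.append(
                Motif(
                    name=name,
                    probability_matrix=mat,
                    background=background.copy(),
                    source_mark=mark,
                )
            )
            continue
        i += 1
    return motifs


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_meme_motifs(motifs: Sequence[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {p:.5f}" for b, p in zip(ALPHABET, bg)) + "\n\n"
            )
        for m in motifs:
            alt = f" {m.source_mark}" if m.source_mark else ""
            fh.write(f"MOTIF {m.name}{alt}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width}\n"
            )
            for row in m.probability_matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED6


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float]],
    path: str | Path,
) -> None:
    """Write (seq_id, start, end, name, score) tuples as BED6 (strand '.')."""
    with open(path, "w") as fh:
        for seq_id, start, end, name, score in intervals:
            if start >= end:
                raise ValueError(f"interval start {start} >= end {end} for {name!r}")
            fh.write(f"{seq_id}\t{start}\t{end}\t{name}\t{score}\t.\n")
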