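"""Sliding-window CpG-island calling.

A fixed-width window (default 100 bp) slides one base at a time; each
window's GC percentage and Gardiner-Garden/Frommer CpG observed/expected
ratio,

    O/E = #CG * window / (#C * #G),

are profiled.  A window passes when O/E >= 0.6 and GC >= 50%; islands are
maximal unions of passing windows, kept when at least ``min_length`` long
(200 bp for conventional islands, 100 bp to pick up the shorter CpG-rich
regions of compact proviruses).  Windows containing N never pass.

The window-level O/E here is the product-form island definition, distinct
from the Markov-model D-ratio of :mod:`ervfootprint.kmer_stats`; both are
exposed and never conflated.  Island means are computed over the passing
windows that form the island, so every reported island re-satisfies its
thresholds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ervfootprint.types import CpGIslandRecord, NucleotideSequence

DEFAULT_WINDOW = 100
DEFAULT_MIN_LENGTH = 200
DEFAULT_OE_MIN = 0.6
DEFAULT_GC_MIN = 50.0


@dataclass
class WindowProfile:
    seq_id: str
    window_size: int
    gc_percent: np.ndarray  # per-start; NaN where the window contains N
    cpg_oe: np.ndarray      # per-start; NaN where the window contains N

    @property
    def n_windows(self) -> int:
        return len(self.gc_percent)


def window_profile(
    seq: NucleotideSequence | str,
    window: int = DEFAULT_WINDOW,
) -> WindowProfile:
    """Per-start GC% and product-form CpG O/E over sliding windows."""
    seq_id = seq.id if isinstance(seq, NucleotideSequence) else "seq"
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    L = len(residues)
    if L < window:
        raise ValueError(f"sequence length {L} < window {window}")

    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_n = (arr == ord("N")).astype(np.int32)
    is_cg = np.zeros(L, dtype=np.int32)
    is_cg[:-1] = is_c[:-1] & is_g[1:]

    def windowed(x: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(x)))
        return cs[w:] - cs[:-w]

    n_c = windowed(is_c, window)
    n_g = windowed(is_g, window)
    n_n = windowed(is_n, window)
    # CG dinucleotides fully inside the window: starts s..s+w-2
    n_cg = windowed(is_cg, window)[: L - window + 1] - is_cg[window - 1 : L]

    gc = 100.0 * (n_c + n_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cg * window / (n_c * n_g), 0.0)
    gc = gc.astype(float)
    oe = oe.astype(float)
    has_n = n_n > 0
    gc[has_n] = np.nan
    oe[has_n] = np.nan
    return WindowProfile(seq_id=seq_id, window_size=window, gc_percent=gc, cpg_oe=oe)


def call_islands(
    profile: WindowProfile,
    min_length: int = DEFAULT_MIN_LENGTH,
    oe_min: float = DEFAULT_OE_MIN,
    gc_min: float = DEFAULT_GC_MIN,
) -> list[CpGIslandRecord]:
    """Maximal unions of passing windows, length-filtered post hoc.

    Windows with NaN profile values (N content) never pass.  Overlapping or
    adjacent passing windows merge; interval means are the means of the
    passing windows inside each merged run.
    """
    w = profile.window_size
    with np.errstate(invalid="ignore"):
        passes = (profile.cpg_oe >= oe_min) & (profile.gc_percent >= gc_min)
    passes &= ~np.isnan(profile.cpg_oe)

    islands: list[CpGIslandRecord] = []
    starts = np.flatnonzero(passes)
    if starts.size == 0:
        return islands

    # group passing starts into runs whose windows overlap or touch
    run_start = starts[0]
    prev = starts[0]
    members = [starts[0]]

    def emit(run_first: int, run_last: int, member_idx: list[int]) -> None:
        start, end = int(run_first), int(run_last) + w
        if end - start >= min_length:
            idx = np.array(member_idx)
            islands.append(
                CpGIslandRecord(
                    seq_id=profile.seq_id,
                    start=start,
                    end=end,
                    mean_gc=float(profile.gc_percent[idx].mean()),
                    mean_oe=float(profile.cpg_oe[idx].mean()),
                )
            )

    for s in starts[1:]:
        if s <= prev + w:  # windows [prev, prev+w) and [s, s+w) overlap or touch
            members.append(s)
            prev = s
        else:
            emit(run_start, prev, members)
            run_start = prev = s
            members = [s]
    emit(run_start, prev, members)
    return islands


def find_islands(
    seq: NucleotideSequence,
    window: int = DEFAULT_WINDOW,
    min_length: int = DEFAULT_MIN_LENGTH,
    oe_min: float = DEFAULT_OE_MIN,
    gc_min: float = DEFAULT_GC_MIN,
) -> list[CpGIslandRecord]:
    """Convenience: profile then call in one step."""
    return call_islands(
        window_profile(seq, window),
        min_length=min_length, oe_min=oe_min, gc_min=gc_min,
    )
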