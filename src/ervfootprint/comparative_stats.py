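"""Group comparisons and correlations on per-sequence D-ratio tables.

Two groups are compared with a two-sided Mann-Whitney U test (exact when the
combined n is at most 20, normal approximation with tie correction above
that); three or more groups with Kruskal-Wallis followed by Dunn's pairwise
z-tests, Bonferroni-adjusted by default (Holm available).  Correlations are
Spearman rank correlations except the methylation-vs-O/E panel, which uses
Pearson after a Shapiro-Wilk normality gate.  Significance is defined as
p < 0.05 throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_MW_MAX_N = 20  # combined-n switch between exact and asymptotic MW


@dataclass(frozen=True)
class GroupTestResult:
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    statistic: float
    p_value: float
    test: str  # "mann-whitney" | "kruskal-wallis"
    effect_direction: int  # sign of median(group1) - median(group2); 0 for >2 groups
    posthoc: Optional[list[tuple[tuple[str, str], float]]] = None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    r: float
    p_value: float
    n: int
    undefined: bool = False
    excluded: tuple[str, ...] = field(default_factory=tuple)

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p_value < ALPHA


# ---------------------------------------------------------------------------
# Rank tests


def _dunn_posthoc(
    samples: dict[str, np.ndarray],
    adjust: str = "bonferroni",
) -> list[tuple[tuple[str, str], float]]:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )
    with T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    offsets = np.cumsum([0] + [len(samples[g]) for g in labels])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    raw = []
    for a, b in combinations(labels, 2):
        denom = np.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        if denom == 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
            p = 2.0 * stats.norm.sf(abs(z))
        raw.append(((a, b), p))

    m = len(raw)
    if adjust == "bonferroni":
        return [(pair, min(1.0, p * m)) for pair, p in raw]
    if adjust == "holm":
        order = np.argsort([p for _, p in raw])
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx][1]))
            adj[idx] = running
        return [(raw[i][0], adj[i]) for i in range(m)]
    raise ValueError(f"unknown adjustment {adjust!r}")


def group_compare(
    values: pd.DataFrame,
    motif: Optional[str] = None,
    group_col: str = "variant_class",
    value_col: str = "d_ratio",
    adjust: str = "bonferroni",
) -> GroupTestResult:
    """Compare a D-ratio (or any value column) across labelled groups.

    *values* is a long table with at least *group_col* and *value_col*;
    rows are filtered to *motif* when given (requires a ``motif`` column).
    Undefined entries (``undefined`` column true or NaN value) are dropped.
    """
    df = values
    if motif is not None:
        df = df[df["motif"] == motif.upper()]
    if "undefined" in df.columns:
        df = df[~df["undefined"]]
    df = df.dropna(subset=[value_col])

    samples = {
        str(g): np.asarray(sub[value_col], dtype=float)
        for g, sub in df.groupby(group_col, sort=True)
    }
    if len(samples) < 2:
        raise ValueError(f"need >=2 groups, got {len(samples)}")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n={len(v)} < 2")

    labels = tuple(samples)
    ns = tuple(len(samples[g]) for g in labels)
    pooled = np.concatenate(list(samples.values()))

    if np.ptp(pooled) == 0:
        log.warning("all values identical across groups; p set to 1")
        return GroupTestResult(
            groups=labels, n_per_group=ns, statistic=float("nan"), p_value=1.0,
            test="mann-whitney" if len(labels) == 2 else "kruskal-wallis",
            effect_direction=0,
            posthoc=(None if len(labels) == 2
                     else [((a, b), 1.0) for a, b in combinations(labels, 2)]),
        )

    if len(labels) == 2:
        x, y = samples[labels[0]], samples[labels[1]]
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
        # no continuity correction: makes the asymptotic two-group test agree
        # exactly with Kruskal-Wallis (z^2 == H, tie corrections included)
        stat, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        direction = int(np.sign(np.median(x) - np.median(y)))
        if p >= 1.0:
            p = 1.0
        return GroupTestResult(
            groups=labels, n_per_group=ns, statistic=float(stat),
            p_value=float(p), test="mann-whitney",
            effect_direction=direction, posthoc=None,
        )

    stat, p = stats.kruskal(*[samples[g] for g in labels])
    posthoc = _dunn_posthoc(samples, adjust=adjust)
    return GroupTestResult(
        groups=labels, n_per_group=ns, statistic=float(stat), p_value=float(p),
        test="kruskal-wallis", effect_direction=0, posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# Correlations


def _spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            method="spearman", r=float("nan"), p_value=float("nan"),
            n=len(x), undefined=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return CorrelationResult(method="spearman", r=float(rho), p_value=float(p), n=len(x))


def deamination_correlation(
    table: pd.DataFrame,
    x_motif: str = "CG",
    y_motifs: tuple[str, str] = ("TG", "CA"),
    combine: str = "mean",
) -> CorrelationResult | dict[str, CorrelationResult]:
    """Correlation between a CpG-type motif and its deamination products.

    Each sequence contributes one point: x is its *x_motif* D-ratio, y the
    arithmetic mean of the two *y_motifs* D-ratios (``combine='separate'``
    returns one Spearman result per y motif instead).  A negative rho is the
    deamination signature: CpG loss mirrored by TpG/CpA gain.
    """
    x_motif = x_motif.upper()
    y_motifs = tuple(m.upper() for m in y_motifs)
    df = table[~table["undefined"]] if "undefined" in table.columns else table
    wide = df.pivot_table(index="seq_id", columns="motif", values="d_ratio")
    needed = [x_motif, *y_motifs]
    missing = [m for m in needed if m not in wide.columns]
    if missing:
        raise ValueError(f"motifs missing from table: {missing}")
    wide = wide.dropna(subset=needed)
    if len(wide) < 4:
        raise ValueError(f"need >=4 sequences with defined D-ratios, got {len(wide)}")

    x = wide[x_motif].to_numpy()
    if combine == "separate":
        return {m: _spearman(x, wide[m].to_numpy()) for m in y_motifs}
    if combine != "mean":
        raise ValueError(f"combine must be 'mean' or 'separate', got {combine!r}")
    y = wide[list(y_motifs)].mean(axis=1).to_numpy()
    return _spearman(x, y)


def meth_vs_oe_correlation(
    points: pd.DataFrame,
    exclude: Optional[str] = None,
    label_col: str = "virus",
    x_col: str = "median_meth_percent",
    y_col: str = "median_cpg_dratio",
) -> CorrelationResult:
    """Pearson correlation of per-virus median %CpG methylation vs median CpG O/E.

    An optional outlier label is excluded and reported; a Shapiro-Wilk
    normality check on both margins gates the Pearson test (a warning is
    logged when either margin rejects normality at 0.05 — the correlation is
    still reported, flagged via the log, matching permissive practice).
    """
    df = points.copy()
    excluded: tuple[str, ...] = ()
    if exclude is not None:
        mask = df[label_col] == exclude
        excluded = tuple(df.loc[mask, label_col])
        df = df[~mask]
    df = df.dropna(subset=[x_col, y_col])
    if len(df) < 3:
        raise ValueError(f"need >=3 points after exclusion, got {len(df)}")
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            method="pearson", r=float("nan"), p_value=float("nan"),
            n=len(x), undefined=True, excluded=excluded,
        )
    for name, v in (("x", x), ("y", y)):
        if len(v) >= 3:
            w, p_norm = stats.shapiro(v)
            if p_norm < ALPHA:
                log.warning(
                    "Shapiro-Wilk rejects normality of %s margin (p=%.3g); "
                    "Pearson r may be unreliable", name, p_norm,
                )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        method="pearson", r=float(r), p_value=float(p), n=len(x), excluded=excluded,
    )
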