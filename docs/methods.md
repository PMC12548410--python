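# Methods

## The model

A provirus integrated in the germline is subject to host CpG methylation.
Methylated cytosine spontaneously deaminates to thymine; because methylation
is dyad-symmetric, an unrepaired deamination converts the dinucleotide CG
either to TG (plus-strand C→T) or to CA (minus-strand C→T, read as G→A on
the plus strand). Over generations this depletes CpG below its
composition-based expectation and enriches TpG/CpA above theirs, and does so
preferentially in the trinucleotide contexts the host methyltransferases
favour. The package's estimators read this history out of sequence and
bisulfite data; its simulator generates data with exactly this mechanism so
every estimator can be validated end to end.

## Observed/expected statistics

For trinucleotides the background is a first-order Markov model:
`P_exp(XYZ) = P_obs(XY)·P_obs(YZ)/P_obs(Y)`. For dinucleotides the
first-order background is degenerate (it would make every dinucleotide O/E
identically 1), so the classical zeroth-order product `P_obs(X)·P_obs(Y)` is
used — the standard CpG O/E definition. All frequencies use per-k
valid-window denominators: windows containing N are excluded from both
numerator and denominator, which keeps the formulas exact on short
sequences rather than approximating with sequence length. Counting is
linear (proviruses are linear integrants) and single-stranded: no
reverse-complement symmetrisation anywhere, because distinguishing TpG from
CpA is the point of the deamination analysis. When a conditioning frequency
is zero the result carries an explicit undefined flag (NaN value) rather
than a silent zero, and tables propagate the flag. Group-level summaries
report the median (the headline statistic; distributions over integrants
are skewed) with the mean alongside.

## Statistical comparisons

Two groups: two-sided Mann-Whitney U, exact when the combined n is ≤ 20
and there are no ties, otherwise the normal approximation with tie
correction and **no continuity correction** — dropping the correction makes
the two-group test coincide exactly with Kruskal-Wallis (z² = H, tie terms
included), so two- and multi-group analyses can never disagree on the same
data. Three or more groups: Kruskal-Wallis followed by Dunn's pairwise
z-tests on pooled ranks with tie correction, Bonferroni-adjusted by default
(Holm available). Dunn's test is implemented here directly (the standard
rank-mean z statistic) and verified against brute-force rank computation.
Correlations are Spearman with average ranks, except the per-virus
methylation-vs-O/E panel, which follows field convention in using Pearson;
a Shapiro-Wilk check on both margins logs a warning when normality is
doubtful. Significance is fixed at p < 0.05. Degenerate inputs (all values
identical, constant margins) return p = 1 or an undefined flag with a
warning, never an exception, so batch runs survive pathological groups.

When CpG is correlated against its two deamination products, the y value
per sequence is the arithmetic mean of the TpG and CpA D-ratios; a
`separate` mode reports the two correlations individually. The mean is a
choice, not a necessity — the two products are symmetric under the model,
and the separate mode exists precisely so the symmetry can be inspected.

## CpG islands

A 100-bp window slides one base at a time; a window passes when GC ≥ 50 %
and the Gardiner-Garden product-form O/E `#CG·w/(#C·#G)` is ≥ 0.6. Islands
are maximal unions of passing windows, reported when at least `min_length`
(200 bp default; 100 bp for the short CpG-rich regions of compact
proviruses). This union definition is deliberately simpler than the
averaging/shrinking loop inside EMBOSS cpgplot: it is deterministic, easy
to reason about, and testable (monotonicity in each threshold, shift
equivariance, disjointness). Edge behaviour differs from EMBOSS accordingly
— e.g. a window half-covered by a CG block sits at exactly 50 % GC and
passes, extending islands roughly half a window beyond a sharp block
boundary. Island means (GC, O/E) are computed over the passing windows that
form the island, so every reported island re-satisfies its thresholds by
construction; windows containing N never pass. The window-level product
O/E and the Markov D-ratio are distinct statistics and are never conflated.

## Bisulfite summaries

Per-site percent methylation is `100·m/(m+u)`. Plus- and minus-strand CpG
calls are separate sites by default — the Bismark report is
strand-resolved, and collapsing is an analysis decision, available as
`collapse_dyads` (counts summed across the dyad, reported on the plus
strand). Trinucleotide context is taken from the report's own column, so
the module needs no reference genome. Default `min_coverage` is 1
(permissive bulk summaries); validation properties use ≥ 20. Binned tracks
are coverage-weighted means; bins without qualifying sites are NaN, not
zero. Overall medians are over sites, not integrant copies.

## Hypermutation test

Each reference G with two downstream ungapped reference bases is assigned
to the APOBEC3G-preferred stratum when the context matches G·R·D (R∈{A,G},
D∈{A,G,T}), otherwise to the control stratum; a G→A change in the query
marks the position mutated. The published convention is pinned as the
default and the context sets are overridable parameters. Enrichment is a
one-sided Fisher's exact test. The reference defaults to the column-wise
majority consensus of the input set (ties broken deterministically in the
order A, C, G, T, gap), surfaced in the output metadata, since screens of
endogenous integrants rarely have a canonical exogenous reference. The test
is conservative: under equal stratum rates its empirical type-I error sits
below the nominal 0.05 (validated to lie in [0.02, 0.08] over 2,000
simulations), with power > 0.95 against a 15 % vs 1 % rate contrast on an
8-kb reference.

## Motif scanning and enrichment

PWM scores are log₂-odds against the motif's background, discretized at
0.001 bit; the calling threshold is the smallest score whose exceedance
probability under the background is ≤ `threshold_quantile` (default 10⁻⁴),
computed exactly by convolving per-column score distributions. A pseudocount
of 10⁻⁴ regularises zero matrix entries. Both strands are scanned; hits are
reported in plus-strand coordinates.

Set enrichment is deliberately simpler than SEA's internal machinery
(optimal score thresholds, shuffled backgrounds): presence means ≥ 1 hit at
the fixed threshold, the test is a one-sided Fisher on the presence 2×2,
and the E-value is Bonferroni (p × motifs tested). What is preserved
exactly is the decision rule the conclusions rest on: a motif is accepted
only when E ≤ 0.05 **and** it is present in all primary sequences with at
most one control, or in all but one primary with zero controls. Hits for
H3K4me3, H3K27ac and H3K27me3 — marks that live at promoters and CpG
islands — can be restricted to called islands; other marks pass through.

## The simulator

`SimulationConfig` defaults define the study conditions: 8,000-bp
proviruses, ancestral CpG O/E 1.0, context methylation probabilities
CGC 0.9 / CGG 0.8 / CGA 0.5 / CGT 0.5 (unlisted contexts 0.5), deamination
hazard 0.05 per methylated CpG per generation, 20 lineages whose
generation counts spread evenly over 1–40 so the panel spans light to heavy
decay, and mean bisulfite coverage 30×.

The ancestral chain is uniform except the C row, whose C→G probability *s*
is calibrated by fixed-point iteration so the *stationary* product-form CpG
O/E equals the target: naively setting `s = 0.25·target` biases the
realised O/E upward for targets below 1, because depressing C→G also
depresses the stationary G frequency in the denominator. The calibrated
generator lands within ±0.05 of targets 1.0 and 0.5 at 10 kb.

Methylation is dyad-symmetric; deamination picks the plus or minus strand
with probability ½ each (a `minus_strand_bias` knob emulates
APOBEC-like asymmetry); a fired site is no longer CpG and cannot fire
again; nothing else ever changes — no back-mutation, selection or indels.
This is the minimal mechanism sufficient to exercise every estimator, and
its conservation law (ancestor and descendant differ exactly at fired
sites; TG events + CA events = CpGs lost) is asserted in tests. All
randomness flows from one seed through spawned, purpose-keyed substreams,
so each stage is independently reproducible.

What the simulator does *not* emulate — selection on coding sequence,
recombination between lineages, multiple integration waves, bisulfite
conversion failure gradients, mapping bias — bounds what green tests mean:
they demonstrate the estimators recover the modelled mechanism from data
shaped like real inputs, not that real proviruses contain no confounders.

## Problem sizes and numerical choices

Validation runs use 8–30 kb sequences, 6–20 lineages, 200-replicate
oracle-equivalence sweeps, and 500–2,000 simulation replicates for test
operating characteristics — sizes at which every stochastic acceptance
band (±0.05 on calibration and survival, rho < −0.5, type-I in
[0.02, 0.08], power > 0.95) holds with wide margin across seeds.
Undefined D-ratios and degenerate statistics always carry explicit flags;
exact tests switch to asymptotics at combined n > 20 (Mann-Whitney) purely
on feasibility grounds; PWM score discretization at 0.001 bit is far below
any meaningful score difference.

## Known limitations

Island calling diverges from EMBOSS cpgplot at block edges (documented
above). The zeroth-order dinucleotide expectation makes dinucleotide and
trinucleotide D-ratios answer subtly different questions (composition vs
dinucleotide-structure surprise); both are exposed, never mixed. The
enrichment module's fixed-threshold presence test is not SEA and will
differ from it on marginal motifs. The hypermutation consensus reference
can be dragged toward hypermutants when most inputs are heavily mutated —
supplying an explicit reference is better when one exists. Alignment,
trimming, bisulfite read mapping and motif learning are all upstream of
this package and out of scope.
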