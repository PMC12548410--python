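# ervfootprint

Epigenetic sequence footprints of retroviral endogenization.

When a retrovirus endogenizes — integrates into the germline and becomes a
heritable part of its host's genome — the host silences it, chiefly through
CpG methylation. Methylated cytosines deaminate to thymine over evolutionary
time, so long-silenced proviruses accumulate a characteristic scar: CpG
dinucleotides decay into TpG on the plus strand and CpA on the minus strand's
complement, with methyltransferase context preferences (e.g. for CGC)
visible as trinucleotide-specific depletion. `ervfootprint` computes the
statistics that expose these footprints and distinguishes endogenous from
exogenous proviral sequences by them. It is aimed at retrovirologists and
comparative epigenomicists working with proviral FASTA sets, Bismark
bisulfite cytosine reports, and MEME-format histone-mark motifs.

## What it computes

**k-mer D-ratios.** The core statistic is the observed/expected (O/E) ratio
of a motif. For a trinucleotide *XYZ* the expectation comes from a
first-order Markov model over the sequence's own dinucleotides,

```
P_exp(XYZ) = P_obs(XY) · P_obs(YZ) / P_obs(Y),      D = P_obs(XYZ) / P_exp(XYZ)
```

and for a dinucleotide *XY* from the classical base-composition product
`P_obs(X) · P_obs(Y)` (the Gardiner-Garden form of CpG O/E). CpG D ≪ 1
signals methylation-driven decay; TpG and CpA D > 1 are the complementary
gain. TpG and CpA are never folded together by reverse complementation —
their separate behaviour carries the strand information the deamination
analysis needs.

**Comparative statistics.** Mann-Whitney U (exact for small samples) for
two groups, Kruskal-Wallis plus Dunn's Bonferroni-adjusted post-hoc tests
for more, Spearman correlations between CpG-type and deamination-product
D-ratios, and a Shapiro-Wilk-gated Pearson correlation of per-virus median
%CpG methylation against median CpG O/E.

**CpG islands.** Sliding 100-bp windows, GC ≥ 50 % and window O/E ≥ 0.6,
islands as maximal unions of passing windows of at least 200 bp (100 bp to
capture the shorter CpG-rich regions of compact proviruses).

**Bisulfite summaries.** Per-site percent methylation from Bismark
genome-wide cytosine reports, stratified by CpG trinucleotide context
(CGA/CGC/CGG/CGT), binned per-provirus tracks, and per-virus medians.

**APOBEC3G hypermutation.** Reference G positions stratified by the G·R·D
downstream context (R∈{A,G}, D∈{A,G,T}); a one-sided Fisher's exact test
for G→A enrichment in the preferred context against a majority consensus
or supplied reference.

**Motif enrichment.** Exact-threshold PWM scanning (dynamic programming
over the log-odds score distribution) and presence/absence Fisher
enrichment between sequence sets, with a Bonferroni E-value and a strict
presence rule: a motif counts only if it hits *every* primary sequence with
at most one control, or all but one primary with no control at all.
Promoter-associated marks (H3K4me3, H3K27ac, H3K27me3) can be restricted to
CpG islands.

**Simulator.** A generator that produces all of the above's inputs with the
assumed mechanism built in: Markov-background proviruses calibrated to a
target CpG O/E, context-preferential dyad-symmetric methylation,
per-generation deamination (CG→TG / CG→CA at 50/50), Poisson-coverage
binomial bisulfite sampling, and motif implantation.

## Worked example

Simulate a 20-lineage panel of 8-kb proviruses decaying under methylation
and deamination, then measure the deamination signature:

```bash
$ ervfootprint simulate --seed 7 --out-dir sim
20 lineages -> sim

$ ervfootprint dratio --fasta sim/descendants.fa --motifs CG,TG,CA --out dr.tsv
$ head -3 dr.tsv
seq_id	virus	variant_class	motif	p_obs	p_exp	d_ratio	undefined
sim0_desc	simulated	unknown	CG	0.06388298537317165	0.062047781249999996	1.0295772723246515	False
sim0_desc	simulated	unknown	TG	0.06700837604700588	0.06623625	1.0116571521939404	False

$ ervfootprint deamination-corr --table dr.tsv
CG vs mean(TG,CA)	rho=-0.9654	p=5.932e-12	n=20
```

Each row is one provirus × motif: `p_obs` the motif's frequency, `p_exp`
its background expectation, `d_ratio` their quotient. Lineage `sim0` has
barely decayed (CpG D ≈ 1.03); lineages evolved for more generations have
lost CpG and gained TpG/CpA, and the Spearman rho of −0.97 (p ≈ 6 × 10⁻¹²
over 20 lineages) is the recovered deamination signature — CpG loss
mirrored, nearly one-for-one, by TpG/CpA gain.

The same subcommands run on real data: `dratio` on a proviral FASTA with
`virus=`/`class=` header labels, `meth-summary` on a Bismark cytosine
report, `hypermut` on an aligned FASTA, `enrich` on two FASTA sets plus a
MEME motif file, or `ervfootprint run config.yaml` for the whole pipeline
into one results directory with a reproducibility manifest.

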