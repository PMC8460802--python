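# cyclemark

Joint RNA-seq + ChIP-seq analysis of cell-cycle synchronized time
courses. The package detects genes with cell-cycle-dependent expression,
assigns them to cycle phases, quantifies RNA polymerase II and histone
mark (H3K4me3, H3K27me3) occupancy in promoter windows, and classifies
genes by how well their transcription machinery tracks their RNA — the
analysis used to nominate lncRNAs with likely proliferation roles. It
ships with a synchronized-population simulator that generates every
pipeline input with known ground truth.

## The problem and who this is for

Chemically synchronized cells (double thymidine block) released at the
G1/S boundary traverse roughly two cell cycles over 24 h while gradually
losing synchrony. Sampling RNA-seq, ChIP-seq (Pol II, H3K4me3,
H3K27me3), and FACS phase fractions every 3 h in two replicates gives a
multi-omics time course in which cell-cycle-regulated genes trace damped
periodic profiles. This package is for computational biologists who want
to run — or stress-test against simulated truth — the downstream
analysis of such an experiment, starting from a count matrix, aligned
read positions (BED), a FACS fraction table, and a GTF annotation.

## The method

**Cyclic gene detection.** Counts are filtered (genes with a zero in any
profile are dropped), transformed to log2 counts-per-million and given
voom-style precision weights `w = s(λ)^-4` from a lowess fit of
`sqrt(sd)` against mean log count. A PLS2 regression of the gene matrix
X on the FACS fraction matrix Y (columns G1/S/G2M, used directly as the
multivariate response) summarizes each gene's importance as a VIP score.
Significance comes from a permutation test: each gene's
precision-weighted R² onto the rank-truncated column span of centered Y
is compared with its null under random re-ordering of time points within
each replicate; Benjamini–Hochberg control at q ≤ 0.05 defines the
cyclic set. Non-cyclic genes above the cyclic set's minimum mean
expression are split into high/low reference sets (`!CC_high`,
`!CC_low`) by a two-component Gaussian mixture on their bimodal mean
expression.

**Phase assignment.** Each cyclic gene's z-scored per-time-point mean
profile is Pearson-correlated with marker-gene templates for G1/S, S,
G2, G2/M, and M/G1; the argmax wins.

**ChIP quantification.** Reads are extended from their 5′ end to the
150 bp fragment size, the 10,000 bp window around each gene's
representative TSS (the longest transcript variant's 5′ end) is split
into 200 bins of 50 bp, each read is assigned to the single bin holding
its fragment count point (5′ + 75), bins are RPKM-scaled and divided by
the mean input coverage (log2 ratio with pseudo-count 0.5), and the
scalar per-gene signal is the oriented bin containing TSS + 75.

**Integration.** Per gene and antibody, Spearman's ρ between the RNA
and ChIP sample profiles classifies genes as high (ρ > 0.2), low
(ρ < −0.2), or middle; the joint Pol II/H3K4me3 classes yield five
groups; Welch t, one-way ANOVA, Fisher exact enrichment by TSS
arrangement, and a ranked table of cyclic lncRNAs with highly
correlated promoter signals complete the analysis.

## Worked example

`examples/02_detect_cyclic_genes.py` simulates the default study
conditions (1000 genes, 100 cyclic with amplitude ≥ 1 log2 unit, 9 time
points × 2 replicates, negative-binomial dispersion 0.05) and runs the
detection and phase assignment:

```
genes analyzed: 997 (of 1000; zero-count profiles removed)
cyclic genes called at q <= 0.05: 104
sensitivity vs truth: 0.98   observed FDR: 0.058

assigned phases:
phase
G1/S    25
G2/M    22
G2      21
S       19
M/G1    17

agreement with truth phase: 0.90
```

98% of the truly cyclic genes are recovered with about 6% false
discoveries, and 90% of the recovered genes land in the phase containing
their true expression peak. The other examples cover simulation output
(`01`), TSS-window ChIP quantification and promoter-mark calling (`03`),
and the full RNA–ChIP integration with lncRNA candidate ranking (`04`);
each prints the numbers it computes and a line on what they mean.

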