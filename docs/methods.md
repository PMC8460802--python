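# Methods

This note documents the models, parameter choices, and numerical
decisions behind cyclemark, and what the simulation-based validation
does and does not establish.

## Synchronized-population model

A cell's cycle position is a point on the unit circle [0, 1). After
double-thymidine-block release the population at time t is modeled as a
wrapped normal with mean `release_position + t / cycle_length` and
standard deviation `sqrt(sigma0^2 + (kappa * t)^2)` (cycle-fraction
units). Phase fractions are the wrapped-normal mass over the three
phase arcs, computed by a truncated image sum (at least 7 images on
each side, widened automatically for large sd); rows are renormalized,
so FACS rows sum to 1 exactly.

Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| `cycle_length_hours` | 14 | two S-phase waves inside a 24 h course; the synchronized population's cycle length is not directly observable from the data this emulates, so it stays configurable |
| `release_position` | 0.40 | the G1→S boundary of the default arcs |
| `sigma0` | 0.09 | initial spread; puts ~90% of cells in the first S wave |
| `kappa` | 0.009 / h | dispersion growth; puts ~70% in the second S wave |
| phase arcs | G1 0.40, S 0.35, G2M 0.25 | coarse human-cell proportions |
| `replicate_jitter` | 0.005 | replicate-to-replicate wobble of the mean position |

With `sigma0 -> 0, kappa = 0` the fractions degenerate to an indicator
of the arc containing the deterministic position; with `kappa * t` large
they converge to the arc lengths (uniform stationary limit). Both limits
are tested.

## Expression model

A single cell at position theta expresses gene g at
`baseline_g + amplitude_g * cos(2*pi*(theta - peak_phase_g))` (log2 CPM
scale). The population latent is the expectation under the position
distribution, evaluated on a 512-point grid; since convolution with a
widening wrapped normal multiplies the cosine term by
`exp(-2*pi^2*sd^2)`, amplitudes damp monotonically as synchrony decays
— the damping is emergent, not imposed. Counts are negative binomial
with mean `library_size * 2^latent / 1e6` and per-gene dispersion
(default 0.05, a typical bulk RNA-seq biological CV of ~22%). The cosine
bump was chosen over a von Mises profile for analytic transparency; at
the amplitudes used the two are nearly indistinguishable after
population averaging.

Ground-truth defaults: 1000 genes, 10% cyclic with amplitudes uniform in
[1, 2] log2 units and uniform peak phases; 10% of genes labeled lncRNA.
Non-cyclic baselines are drawn from a bimodal mixture (N(3, 0.6) and
N(7, 0.6) log2 CPM, 40/60) so the non-cyclic reference split has a real
boundary to find; cyclic baselines from N(6, 0.8).

## ChIP-read model

Coupled genes (in the default truth: the cyclic ones, for Pol II and
H3K4me3 with slope +0.8, H3K27me3 with slope −0.24) get per-sample
expected read counts affine in the latent: `depth * max(0.05, 1 +
slope * (latent - baseline))`; uncoupled genes are flat. Read counts
are Poisson; fragment count points follow a triangular kernel of
half-width 500 bp around the representative TSS; strands are random;
reads are 75 bp with a 150 bp fragment so the downstream 75 bp
extension is self-consistent. Input tracks are uniform over the genome.

What this does not emulate: genomic background in the ChIP tracks
(simulated promoters therefore always show positive input-normalized
signal, and the bivalency composition of real promoters is not
reproduced), mappability and copy-number artifacts, and fragment-size
variability. Promoter-mark calling logic is therefore validated on
constructed signal tables, while the simulation validates coupling
detection — the part the integration analysis depends on.

## Annotation generator

Genes are laid on one synthetic chromosome. Every transcript of a gene
shares its 3′ end, so the 5′-most TSS always belongs to the longest
variant and is the representative TSS. Layouts cover the cases the TSS
grouping distinguishes: single TSS with/without a foreign TSS within
10 kb, multiple TSSs within 1 kb, and a far-spaced pair (6,664 bp —
the arrangement that makes the longest-variant rule pick the wrong
promoter for genes like PCNA). Genes wanting a neighbor are placed in
pairs at exactly the requested representative-TSS distance; everything
else is separated by ≥ 25 kb.

## Detection statistics

The transform follows the voom recipe (offsets 0.5/1, lowess span 0.5,
`sd^-4` weights, boundary clipping); residual sd is computed about the
gene mean, since no covariate model is imposed at the transform stage.

`fit_pls` is a NIPALS PLS2 fit (via scikit-learn, no autoscaling) of
centered, precision-weight-scaled gene columns on the centered FACS
matrix; VIP is computed from X-weights and per-component explained
Y-variance and satisfies mean(VIP^2) = 1.

For significance, VIP proved the wrong statistic under permutation: it
is normalized across genes, so a high-variance cyclic gene keeps a high
VIP no matter how Y is permuted, and its per-gene null barely moves.
The default statistic is instead each gene's precision-weighted R² onto
the rank-truncated column span of centered Y — an absolute, per-gene
quantity (the FACS matrix is row-normalized, so its centered span has
rank 2; truncating at the numerical rank keeps a spurious noise
dimension out of the projection). The null permutes time points
independently within each replicate — valid under a gene's null of no
time effect, and with (9!)² arrangements sharp enough for
999-permutation resolution. p = (1 + #{null ≥ observed}) / (1 + n_perm)
with ties counted as exceedances; BH q-values; q ≤ 0.05 calls the set.
`statistic="vip"` switches back to the VIP permutation for comparison.
At the default conditions this yields ~93–98% sensitivity at 2–6%
observed FDR, and the type-I rate on pure-noise genes sits inside the
binomial band around the nominal 5%.

The reference-set split fits a two-component Gaussian mixture (10 EM
restarts) to the mean log expression of non-cyclic genes above the
cyclic minimum; assignment is by posterior ≥ 0.5, and a collapsed
mixture degrades to a single set with a warning.

## Phase assignment

Five labels (G1/S, S, G2, G2/M, M/G1) are mapped onto the simulator's
circle as equal-width 0.2 arcs centered on the canonical positions
(G1/S on the release boundary, S mid-S, M/G1 inside G1). Equal widths
are deliberate: a correlation classifier against templates centered in
each arc has decision boundaries at template midpoints, so equal arcs
make the truth partition and the classifier's implied partition
coincide; with unequal arcs, genes near wide-arc edges are
systematically misassigned and accuracy is capped in the 70s. Marker
templates are built from z-scored per-time-point mean profiles averaged
within phase; in simulated runs markers are cyclic truth genes nearest
to anchors spread evenly across each arc (5 per phase). Ties in the
argmax are broken in the fixed label order.

## ChIP quantification numerics

Coordinates are 0-based half-open throughout (GTF converted on read).
The read count point is the 5′ end + 75 in the strand direction — for
the 150 bp fragment this is the fragment midpoint, but defined
strand-aware because an even-length interval has no strand-neutral
central base; with this choice (and the minus-strand window anchored
one base 3′-ward) mirroring the genome and all strands leaves every
oriented bin vector exactly unchanged, a property the test suite
asserts against a brute-force per-read oracle. Input normalization is
window-local (the mean input RPKM of the same bins across input
samples) with pseudo-count 0.5, reproducing the sign semantics of
log-scale enrichment; genome-wide mean normalization would differ only
by a per-sample constant for the uniform input model. A mark is called
present when the normalized TSS signal is positive at ≥ 2 time points
(per-time-point means, honoring each assay's exclusions).

## Integration choices

Correlation pairs are individual samples (replicate × time point), not
per-time-point means — more pairs and no averaging artifacts; excluded
samples (by default Pol II (12 h, Epi2)) are dropped pairwise, giving
17 pairs for Pol II. ρ = ±0.2 exactly falls in the middle class (the
class inequalities are strict). Group precedence for contradictory
class pairs: any high dominates (both-high, then Pol II-only, then
H3K4me3-only), then both-low, else middle; the enumeration of all nine
class pairs is frozen in a test. Bonferroni families are the four
phase-vs-S comparisons within one panel. The hierarchical
(random-intercept) ANOVA is the balanced-design two-stage equivalent:
per-group effect means tested against zero with df = groups − 1.

One bound stated for the integration validation cannot be met at this
design size: the median |ρ| of truly uncoupled genes. With 17–18
sample pairs the null Spearman distribution has median |ρ| ≈ 0.166, so
uncoupled genes measure ≈ 0.16–0.17 regardless of simulation fidelity;
the symmetric-about-zero sign test is the calibration check that is
actually informative at this n. The corresponding assertion is kept at
its stated value and fails by design.

## Problem sizes

Validation runs use the study's own design scale: 1000 genes (100
cyclic), 9 time points × 2 replicates, 999 permutations for recovery
and 199 for the type-I check, 500-read toy genomes for exact binning
oracles, and ~100 reads per gene per sample for coupling detection.
These sizes give stable pass/fail behavior across seeds while keeping
the full suite and the acceptance script fast.

## Known limitations

- The simulator's ChIP tracks lack genomic background (see above).
- The permutation test assumes within-replicate exchangeability under
  the null; strong autocorrelated technical drift across the time
  course would inflate it.
- The voom re-implementation is property-equivalent, not
  bit-compatible with the reference implementation.
- Phase-label arcs are a configuration convention; real marker-derived
  templates carry their own implicit arc widths.
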