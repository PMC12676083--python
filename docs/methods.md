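# Methods

## Scope and model

`phyllostat` quantifies the regularity of spiral phyllotaxis from ordered
divergence-angle series and asks how much of the observed deviation from the
golden angle (137.5°) can be produced *after* organ initiation, by axial
twisting of the elongating stem. A second, independent component maps a
recessive EMS allele from two-pool bulk-segregant allele depths. All analyses
run on synthetic tables whose statistical structure is produced by the
package's own generators, since the corresponding experimental measurements
are not available as reusable tables.

### Divergence-angle statistics

Angles are degrees in [0, 360) throughout the public data model. A plant's
chirality (spiral handedness viewed from above) is attributed as the strict
majority of its per-step rotation directions; an exact tie leaves the plant
without a dominant chirality and it is discarded from chirality-stratified
analyses. Raw world-frame angles are normalized along each plant's own spiral
(`(360 − raw) mod 360` for a spiral opposing the measurement sense), so a
golden-angle step sits near 137.5° for both chiralities.

Consecutive pairs (angle *i*, angle *i+1*) are binned on a square grid with
bin centers at integer multiples of the bin width and half-open arcs
[c − w/2, c + w/2). The "golden window" is the bin containing 137.5° plus one
neighbor each side; for widths 22.5°/12.5°/6.25° this yields the arcs
[101.25, 168.75) / [118.75, 156.25) / [128.125, 146.875). Note that 12.5 and
6.25 do not divide 360 evenly; the leftover arc is split midway between the
last center and 0°, slightly narrowing the two bins flanking 0/360. This is
invisible to the golden window and matters only for angles within half a bin
of 0°, which are vanishingly rare in spiral series. A brute-force
nearest-center search is kept as the test oracle for the closed-form bin
assignment.

M-shaped motifs — the triplet signature (≥ 202.5°, > 180°, ≥ 202.5°) left by
two organs swapping order along the stem — are flagged by a greedy,
non-overlapping left-to-right scan. The filter is applied **only** when
pairing angles with internode lengths (all three angles of a flagged triplet
are dropped from that analysis); pair-binning heatmaps keep them.

### Stem-torsion displacement model

On a cylinder of local radius *r*, a torsion angle α (counterclockwise
positive) acting over an internode of length *I* rotates the upper organ by
the arc angle tan(α)·I/r. This quantity is geometrically radians (arc length
I·tan α on a circle of radius r) and is converted to degrees before adding —
with I/r of order 10 and α below a few degrees, displacements are a few
degrees per internode. The displacement is **added** for counterclockwise
spirals and **subtracted** for clockwise ones, so a single world-frame
torsion direction pushes the two chiralities to opposite sides of the golden
angle; this sign convention is what produces the chirality-split, internode-
length-dependent divergence patterns the simulator reproduces.

The population simulator draws, per in-silico inflorescence: a chirality
(Bernoulli, default 0.5 — how simulated plants acquire chirality is a design
choice, not a measured quantity); one initial divergence angle per internode
from Normal(δ̄ᵢ, σ); per-position internode lengths from truncated normals
(negative draws rejected and redrawn, not clamped, preserving shape near
zero); per-position radii from a quadratic profile (positions rescaled so the
maximum maps to 35, first 30 predictions retained — the bolt tip is removed
before phyllotaxis is measured); and one torsion angle per internode from
Normal(ᾱ, σ_α). Drawing α per internode rather than per plant is the adopted
reading of the generative procedure; it reduces within-plant correlation of
displacements relative to a per-plant draw, which we note but do not resolve.
One RNG stream is spawned per inflorescence from the master seed
(`numpy.random.SeedSequence`), so equal seeds give bit-identical populations
regardless of evaluation order.

Default parameters (population defaults, not fitted values): initial
divergence 137.5° ± 10° (wild-type-like) or ± 17° (*plt*-like); torsion mean
0.6° counterclockwise (the measured cell-file obliquity; 1.7° and −1.1° for
the *spr2*- and *tor2*-like presets), torsion SD 0.6° (the spread is not
printed; chosen comparable to the mean so individual internodes can twist
either way); internode profile linear 15 → 2 mm over 30 positions (long
basal, short apical), SD 20% of the mean, scaled ×1.35 for the *plt*-like
preset; radius quadratic ~1.0 → 0.4 mm over positions 1–35; 101
inflorescences × 30 internodes per population.

### Regression and tests

Divergence vs internode length is analysed per chirality: internode lengths
binned (0.1 mm with ≥ 4 pairs per bin by default; 0.01 mm / ≥ 2 for
meristem-scale data), per-bin mean divergence regressed on bin-center length
by unweighted OLS (bin-occupancy weighting is not applied), Pearson r and its
two-sided p reported, 95% confidence band from the t-distribution of the mean
prediction. Under the displacement model with constant radius the slope is
±deg(tan α)/r degrees per mm; the test suite recovers this within 3 standard
errors at ~10⁴ simulated internodes for α ∈ {0.3°, 0.6°, 1.7°, 3.2°}, and
raw-pair regression (`use_bin_means=False`) is available for such
parameter-recovery work.

Group comparisons: Welch's t (unequal variances), Wilcoxon rank-sum
(`scipy.stats.mannwhitneyu`), or one-way ANOVA with Tukey HSD; families of
pairwise p-values are Benjamini-Hochberg adjusted. BH adjusted values are
monotone in the raw p and never smaller, but the step-up transform is not
idempotent — re-adjusting adjusted values inflates them. Proportions use the
pooled two-proportion z with Yates continuity correction, the correction
capped at |p₁ − p₂| so equal proportions give p = 1. Test direction is always
declared by the caller, never inferred.

Growth metrics: plastochron as elapsed days per organ over a stated
organ-count range (bounds linearly interpolated); height series synchronized
by re-zeroing time at the first observation at or above 1.5 cm; growth rate
as the OLS slope of height on synchronized day.

### Bulk-segregant filter

For a recessive allele in a selfed backcross F2 (BC1F2), the
phenotype-negative pool is 1 *MM* : 2 *Mm* and the phenotype-positive pool
pure *mm*, giving expected wild-type allele frequencies of 2/3 and 0 at the
causal locus; at map distance *d* (Haldane recombination c = (1 − e^(−2d))/2)
these become (2 − c)/3 and c, both monotone toward the unselected 1/2.
Candidates must be biallelic (multiallelic records are dropped, not
decomposed), absent from the backcross parent (exact (chrom, pos, ref, alt)
match), with per-pool total allele depth in [10, 500] inclusive — the
per-pool-total reading is the stricter of the possible readings and a
per-allele alternative is exposed as a flag — WT allele frequency within
[0.30, 0.90] inclusive in the pheno− pool, and strictly below 0.05 in the
pheno+ pool. Coordinates are 1-based as in VCF; input is VCF 4.x with
per-sample AD read via `cyvcf2`.

A consequence worth stating: Haldane c at 5 cM is 0.0476, already below the
0.05 pheno+ cutoff, so markers a little beyond 5 cM from the causal locus
pass the filter *in expectation*, and with pool-composition and read
sampling at depth ~100 the pass shoulder extends to roughly 15 cM. The
filter therefore reliably recovers the causal variant (100% of 200 seeds in
the test suite) and confines all candidates to the causal chromosome, but
cannot guarantee a unique candidate at any realistic EMS density; exactly
one candidate is the modal, not the certain, outcome. Fine-mapping within
the linked candidate set is outside this package's scope.

## Synthetic-data generators

The generators emulate the *structure* the analysis assumes, not any real
plant: golden-angle spirals with genotype-dependent initiation noise; rare
decussate episodes (a contiguous run replaced by alternating ~90°/~180°
angles, default rate 0.10 for the *plt*-like preset); M-motifs planted by
swapping two adjacent organ azimuths, which maps the divergence triplet
(a, b, c) to (a+b, 360−b, b+c) and meets the flag criterion by construction;
torsion displacement through the model above; and rosette series following a
damped oscillation δₙ = 137.5 + A·e^(−λ(n−1))·cos(πn + φ) + ε with A = 42.5
and φ = π so the first leaf pair sits near 180°. The damped-oscillation form
is a modelling choice (only the qualitative behaviour is documented);
amplitudes are tuned only to the qualitative ordering that mutant-like
presets are noisier and damp slower than the wild-type-like preset. Presets
live in `data/presets.yaml`, not in code.

The BSA generator places EMS-like SNPs (C→T/G→A) uniformly on a genetic map
of 5 × 0.8 Morgan chromosomes (60 SNPs by default — a post-filtering density
typical of a single mutagenized line), samples pool composition per locus
(2 × 30 chromosomes under the cross model), then read depths
Poisson(100) and allele counts binomially. Background variants carried by
the backcross parent are emitted homozygous non-reference in every plant,
together with the parent variant list, so the subtraction step is exercised.
Kosambi-style map functions can be substituted by swapping the exposed
Haldane function.

What passing tests on these inputs do **not** show: robustness to
measurement error in angle reading, to missed organs (which produce ~275°
sums rather than clean motifs), to depth-dependent variant-calling artefacts,
or to real linkage disequilibrium structure; the generators draw loci
independently given the causal genotype.

## Numerical choices and degenerate inputs

- Binning uses a closed-form floor expression equivalent to nearest-center
  assignment with ties going up; the wrap tie between the last center and 0°
  goes to bin 0.
- Angle comparisons in the motif and extreme-angle rules follow the printed
  inclusivity exactly (≥ 202.5, > 180; < 110, > 165 strict).
- The zero-torsion case returns δᵢ exactly (no trigonometric round-trip
  error: tan(0) = 0).
- Zero-depth variants are excluded with a reason, never raised; empty angle
  lists, sub-3-bin regressions and ambiguous-chirality plants raise
  `ValueError` at the library level and exit code 3 at the CLI.
- SEM at n = 1 is reported as NaN rather than 0.

## Problem sizes

The shipped test and acceptance runs use 101 × 30 simulated populations,
~10⁴ internodes for slope recovery, 10⁵ angles for the binning oracle, and
200 seeds for BSA recovery — sizes at which every stochastic property above
is stable across seeds while the whole suite completes in seconds.

## Known limitations

- Torsion enters as a numeric parameter; the package neither models why
  stems twist nor fits torsion from images.
- The displacement model is first-order in a single internode: it ignores
  torsion accumulated across multiple internodes between measured organs.
- The cross model covers one scheme (recessive BC1F2); dominant or
  non-selfed designs would need new expectations.
- Variant effects are not annotated; candidate lists are positional only.
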