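# Methods

## Model and scope

The package treats chromosome-arm proximity bias as the observable
consequence of a truncation mixture: when Cas9 cuts a locus, a fraction
of cells fail to repair the break and lose the acentric fragment from
the cut to the telomere. A perturbed population is then a mixture of
clean knockouts and knockouts that additionally carry loss-of-function
of every gene telomeric of the cut. Three observable signatures follow,
and each has a dedicated estimator:

1. **Map-level bias.** Aggregated gene vectors of same-arm targets share
   contamination, so same-arm cosine similarities are stochastically
   larger than cross-arm ones. Quantified by the Brunner–Munzel
   probability `P(intra > inter) + ½P(intra = inter)` from joint average
   ranks; 0.5 is the no-bias baseline. Genome, arm and gene level use
   the exact estimator over the full pair universes (unordered pairs,
   no self-pairs); the Monte-Carlo variant samples N pairs per side with
   replacement for T trials and averages, for bootstrap pipelines where
   the exact pair universe changes per draw.
2. **Telomere-ward fading.** A target's contamination is the sum of key
   (phenotypically active) genes telomeric of it, so gene-level bias
   declines with relative arm position; measured by Spearman rank
   correlation of gene-level probabilities against the 0→1
   centromere→telomere position, per arm, Bonferroni across arms.
3. **Proximal loss in expression.** In cells carrying the truncation,
   genes between the cut and the telomere drop to the residual dosage.
   The caller scores each cell/well with a windowed relative-expression
   statistic and flags cells whose flank near the target is coherently
   depressed.

## Statistical details

**Brunner–Munzel p-values.** The studentized statistic with
Welch–Satterthwaite degrees of freedom gives one-sided p-values (the
alternative: intra similarities dominate). Zero-variance rank
configurations fall back to p ∈ {0, 1} by the sign of the effect, and
all-tied inputs give probability 0.5, p = 1. The implementation is
cross-checked in the tests against an independent rank-sum oracle
(enumeration of `P(X>Y) + ½P(X=Y)`) and, for the p-value, against
`scipy.stats.brunnermunzel`. Note that similarity pairs within one map
share gene vectors; deep-tail p-values at the arm level are therefore
mildly optimistic on small maps. The effect-size scale (0.5 baseline)
is unaffected, which is why conclusions are drawn from probabilities,
with p-values as a ranking aid — the same practice the arm-level scans
follow.

**Pair universes.** Acrocentric p arms (chr13/14/15/21/22 in the
bundled human table) and sex chromosomes are excluded from arm-level
statistics by default (configurable), leaving 39 autosomal arms and 741
unordered arm pairs. Arms need ≥ 20 within-arm pairs to be tested.

**Recall benchmarking.** Predicted relationships are the top 5% plus
bottom 5% of off-diagonal similarities, selected by rank with stable
tie-breaking and capped at ⌈2·tail_frac·n_pairs⌉. Recall is computed
over annotation pairs whose genes are both present in the map
(annotation pairs involving unscreened genes are uninformative about
the map and are dropped from the denominator). Random annotations give
2·tail_frac = 0.1.

**zFPKM.** Positive FPKM values are log2-transformed; the mode of the
density (Gaussian KDE, Silverman bandwidth, 2048-point grid) gives μ and
the standard deviation of values ≥ μ, mirrored about μ, gives σ;
zFPKM = (log2 FPKM − μ)/σ, with a −∞ sentinel at FPKM = 0. Genes with
zFPKM < −3 are unexpressed. Arms need ≥ 5 unexpressed genes to be
corrected (a smaller set estimates the arm mean too noisily); arms
below that are passed through and reported, never silently skipped.

**Arm correction.** Operates on gene vectors before cosine (subtracting
from the similarity matrix would not be a geometric correction of the
representation). Per correctable arm the feature-wise mean over the
arm's unexpressed genes is subtracted from every gene on the arm;
idempotent by construction. A small-sample caveat discovered during
design and verified in simulation: the *estimation noise* of the arm
mean is shared by all genes on the arm and itself induces intra-arm
correlation of order 1/n_unexpressed among noise-dominated genes, so
the correction needs tens of unexpressed genes per arm to leave a null
map at 0.5. With a realistic unexpressed fraction (~40% of genes,
roughly what a single cell type does not transcribe) the positive
(expressed–expressed) and negative (unexpressed–unexpressed) artifact
contributions also balance in the rank statistic.

**CNV scores and the caller.** The copy-number score is a deliberately
simple windowed estimator in the inferCNV tradition and is the
package's own: counts-per-10k library normalization (a fixed target
total keeps the score exactly invariant to per-row depth), log1p,
subtraction of the per-gene reference (control) mean, clipping at ±1.5,
and a centered running mean over 101 genes in coordinate order per
chromosome (shrinking windows at chromosome ends; chromosomes shorter
than the window are smoothed as one window, with a warning). Exact
parity with external CNV tools is out of scope; because the smoother is
simplified, the −0.05 loss threshold is exposed in configuration for
recalibration on other data profiles. A cell shows proximal loss on a
side when ≥ 70% of the up-to-150 same-chromosome genes in that side's
coordinate direction score ≤ −0.05; a side with < 20 genes is
untestable. The 3′/5′ side is mapped to a telomeric/centromeric label
through strand and arm. Specificity is one-sided: the fraction of
on-target cells flagged must reach the background mean + 3 SD, where
the background is the flagged fraction of every perturbation's cells
in the *same* window (the target's own perturbation included by
default; both choices are exposed). Two degenerate regimes are guarded:
a zero-variance background with f = μ is not specific, and a call must
rest on ≥ 2 flagged cells — a single cell clears any SD-based bar when
the background is quiet, but is no evidence of a truncated
subpopulation.

**Dependency analyses.** Gene rows are mean-centered over the chosen
line subset before cosine (removing the shared essentiality offset).
CNV-clean lines for an arm have < 1% of the arm's genes outside copy
number (1.75, 2.25); arm-pair values are computed on the intersection
of the two arms' clean sets, two orientations per pair. Genotype
splits: LOF = CN ≤ 1.5; AMP = CN ≥ 2.5 without a nonsense/frameshift
mutation; WT = CN in (1.5, 2.5) without a damaging mutation — damaging
mutations are functional LOF whatever the copy number, so such lines
are kept out of the WT comparison group. The TP53 backgrounds are
WT-like and partial-LOF (CN ≤ 1.5), applied before the split. The
stratified bootstrap samples 20 lines per condition, builds a map,
computes the Monte-Carlo probability (T = 200), repeats S times
(4 for screening, 32 for confirmation), requires ≥ 25 lines per
condition, and compares conditions with a Welch t-test on the bootstrap
values — Bonferroni across genes in the mediator screen, while the
subtype-dependency screen uses Benjamini–Hochberg across genes; the two
screens deliberately use different corrections. The spurious screen
flags genes that are significantly *more* essential in the subtype
(adjusted p < 0.01), have subtype TPM < 0.3, and lie centromeric of a
supplied driver on the same arm.

## The synthetic-data generators

The generators define the package's study conditions; their defaults
were fixed once from the design analysis below and are not data-fitted.

**Toy genome** (`make_genome`): `n_chrom` chromosomes × 2 arms ×
`genes_per_arm` evenly spaced genes (50 Mb arms, 3 Mb centromere gap),
random strands, and a per-arm unexpressed subset of 40% — roughly the
fraction of protein-coding genes a single cell type does not
transcribe, and, as noted above, enough unexpressed genes per arm for
the correction's arm-mean estimate to be stable at desk scale.

**Phenomics** (`simulate_phenomics`): 20% of expressed genes are "key"
genes with a sparse Gaussian loss-of-function effect (nonzero on 25% of
128 features, per-feature scale 0.4); a configurable number of key-gene
pairs on different chromosomes share an effect vector, providing
ground-truth relationships for recall tests. Each well targeting gene g
carries g's effect plus, with probability ρ (the truncation rate), the
summed effects of key genes telomeric of g, plus N(0, 1) feature noise;
4 guides × 6 wells per gene (24 replicate wells, a desk-scale version
of a high-replicate arrayed screen) and controls carrying noise only.
An optional interstitial mode truncates to a random interior breakpoint
instead of the telomere. With these magnitudes the per-gene effect norm
roughly matches the aggregated noise norm, so related pairs sit in the
top similarity tail without saturating the map, and ρ = 0.15 produces a
genome-level probability near 0.75–0.8 — qualitatively the regime of
real Cas9 maps — while ρ = 0 calibrates to 0.500 ± 0.002 per replicate.

**Expression** (`simulate_expression`): negative-binomial
(Gamma–Poisson) counts with lognormal per-gene means (log-mean 2.5,
log-sd 0.8; median ≈ 12 counts/gene) and dispersion 0.01 — a deeply
sequenced, low-overdispersion plate-style profile. This choice is
deliberate: the windowed score's noise floor is set by per-gene
dispersion (the 101-gene mean divides the per-gene sd by ~10), and at
10x-style shallow counts the −0.05/70% rule flags a few percent of
*unperturbed* cells, which is the regime where real callers also lose
specificity; the bundled profile keeps the null flag rate near zero so
that planted-signal recovery tests measure the caller, not the
sequencing depth. Targets are drawn one-per-arm round-robin among genes
with ≥ 160 telomeric neighbors (a genome-wide screen's spread; also
guarantees the planted loss spans a full calling window). An
`affected_fraction` subset of each target's cells has the target and
all telomeric genes scaled by `dosage` (default 0.5, heterozygous
loss).

**Dependency** (`simulate_dependency`): dependency = per-gene base
essentiality + subtype driver effect (−1 in the driver's subtype) +
truncation spillover + N(0, 0.3) noise. The spillover has two planted
components mirroring the cutting artifact: a nested per-line random
walk summing key-gene losses telomeric of each gene (arm-scale
co-dependency that survives CNV-clean restriction), and a transfer of
a fraction (default 0.3) of each driver's effect to genes centromeric
of it on the same arm (the spurious-dependency signal). Copy-number
events are whole-arm gains/losses per line at rate 0.1; TPM is
lognormal for expressed genes and < 0.2 for unexpressed ones; an
optional mediator gene doubles the spillover in its planted LOF lines.

What the generators do **not** emulate: batch/plate effects beyond the
control-centering contract, guide-level off-target variation,
cell-cycle or lineage covariance in expression, interaction structure
between drivers, and realistic CNV focality. Passing the planted-signal
tests therefore demonstrates the estimators' correctness and
calibration under the truncation mechanism, not performance on any
particular real dataset; on shallow single-cell data the caller's
thresholds need recalibration, as flagged above.

## Numerical choices and degenerate inputs

* Ranks: `scipy.stats.rankdata` average ranks everywhere ties occur;
  the display quantile transform uses Φ⁻¹((rank − 0.5)/n)·σ, so tied
  inputs map to identical outputs and the transform is idempotent.
* Arm assignment uses the transcript start as the representative point
  (cut-site semantics for guides); genes in the centromere gap attach
  to the nearer boundary within 1 Mb, else are excluded and reported;
  coordinate ties rank by gene id for reproducibility.
* Zero-variance control features scale by 1 with a warning; all-zero
  gene vectors are a hard error naming the genes (cosine undefined).
* All randomness flows through `numpy.random.Generator` seeds threaded
  explicitly; every generator is byte-deterministic under its seed, and
  the pipeline writes its config hash and seed next to its outputs.
* Desk-scale problem sizes used by the test suite and the acceptance
  script: 8 arms × 50 genes × 200 replicates for null calibration;
  8 arms × 200 genes × 3 replicates for mechanism recovery; 20 arms ×
  220 genes, 20 targets × 200 cells for caller recovery (one signal
  replicate, ten null replicates). These were chosen as the smallest
  sizes at which the quantities of interest are estimated well inside
  their tolerance bands.

## Known limitations

* The CNV smoother is intentionally minimal; it shares the spirit, not
  the numerics, of inferCNV-family tools.
* Arm-level and gene-level p-values inherit the pair-dependence
  optimism discussed above; treat them as ordering devices.
* The geometric correction assumes the confound is additive in feature
  space and shared along the arm; position-dependent contamination is
  only removed in its arm-mean component (the residual is visible in
  simulation as a small, sign-balanced intra-arm structure).
* The bundled human arm table is approximate in coordinates (exact in
  topology); analyses at base-pair resolution should supply a real
  cytoBand file.
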