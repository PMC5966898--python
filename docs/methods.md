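# Methods

## The model

Both platforms are modelled with the same heteroscedastic non-negative
factorization. For a data matrix `D` (features × samples; log2 expression or
promoter methylation β),

    D_ij ~ Normal( (A P)_ij , Σ_ij ),    A ≥ 0,  P ≥ 0,

where `P` (p × samples) holds the *patterns* — trajectories across the
time-course samples, each row scaled to maximum 1 — and `A` (features × p)
holds the *amplitudes*, each column quantifying how strongly every gene
follows the corresponding pattern. The per-entry uncertainties are

* expression: `Σ_ij = max(0.1 · D_ij, 0.5)` on the log2 scale — a 10%
  multiplicative error with an additive floor for low counts;
* methylation: `Σ_ij = sqrt(β_ij (1 − β_ij) / (M_ij + U_ij + 1))`, the
  standard deviation of a beta distribution with pseudo-counts given by the
  methylated/unmethylated probe intensities. When intensities are missing a
  configurable total (default 100) preserves the variance shape.

The fit minimizes `χ² = Σ_ij ((D − AP)_ij / Σ_ij)²`, optionally plus an L1
penalty `λ Σ A` (default λ = 0, see below). Missing entries get zero weight.

## Optimization and identifiability

The solver alternates multiplicative updates (monotone for the weighted
Frobenius objective with L1 on `A`) and finishes with exact per-row
weighted NNLS passes; iteration cap 2000, relative tolerance 1e-6, both
configurable. Several restarts are run and the best (penalized) objective
is kept; a fixed seed is bit-reproducible.

The critical design point is initialization. This model is not identifiable
from the likelihood alone when all patterns share a positive baseline:
baseline mass can be shuffled between patterns with exact compensation in
`A`, so rotated bases reach equal — after noise fitting, even lower — χ²
than the planted basis, and generic (SVD or random) initializations
converge to them. The Bayesian samplers used for this model class escape
this through their sparse prior on `A`. Our deterministic analog exploits
the *marker structure* of the data directly: rows of genes dominated by a
single pattern are proportional to that pattern's trajectory, so k-means
centroids of the unit-normalized gene rows seed `P` inside the
marker-respecting basin (a separability argument). Every restart uses a
differently randomized clustering; SVD and random initializations remain
available as options. With cluster seeding the L1 penalty is not needed for
identifiability, and λ = 0 keeps the NNLS polish exact and the objective
exactly invariant under rescaling of all Σ.

## Choosing the number of patterns

For each candidate p, several restarts each fit a random half of the
features and the fitted pattern rows are matched greedily across restart
pairs by Pearson correlation. Feature subsampling is essential: restarts on
the *same* data reproduce surplus patterns, because an extra component can
absorb dataset-wide residual structure (for example the distortion induced
by the mean–variance coupling of β noise) perfectly reproducibly. Across
independent feature halves such components either vanish (pure noise) or
reveal themselves as weak shared structure.

Selection uses the *worst* matched pattern per restart pair, averaged over
pairs: a dimensionality is supported only when every pattern reproduces
(threshold 0.85, configurable). The mean matched similarity is recorded too
but is too forgiving — one junk pattern among five perfect ones still
averages 0.9. The selected p is the largest one reachable from the smallest
candidate without dipping below threshold; reproducibility can rebound
spuriously at larger p, so contiguity is required. On the default synthetic
design this selects 5 expression patterns in every seed tested and 3
methylation patterns modally; the occasional 4th methylation pattern is a
genuinely generalizing weighting-bias component, the synthetic analog of a
technical-variation pattern, and the pipeline default fixes the methylation
dimensionality at 3.

A parallel-set consensus mode (random feature partition, independent fits,
correlation-matched pattern averaging, final amplitude refit with `P`
fixed) reproduces the genome-wide consensus strategy used for large probe
sets.

## Pattern interpretation

*PatternMarkers.* Each gene's amplitude row over the non-excluded patterns
is scaled to unit maximum; the statistic for pattern k is the Euclidean
distance to the k-th unit basis vector, the gene is assigned to the argmin
(ties to the lowest pattern index) and ranked by distance. Flat
(highly-expressed) patterns are excluded from the calculation by default —
otherwise they absorb every highly expressed gene — while technical
patterns are retained so that genes tracking batch artifacts are removed
from the biological signatures.

*Separation dating.* The separation generation of a pattern is the
earliest generation g from which the treated−control difference keeps a
constant sign and exceeds both `c·s` (default c = 2; s estimated from the
pre-g differences, or from the parental replicate spread when fewer than
two earlier generations exist) and an absolute floor of 5% of the
pattern's magnitude. The floor matters for fitted patterns: imperfect
separation from co-fitted patterns leaves a small persistent cross-arm
bias that would otherwise be read as generation-1 divergence.

*Labels.* Flat: coefficient of variation < 0.1. Control drift: both arms
monotone (Spearman |ρ| > 0.8, same sign) with no appreciable arm split —
tested before the parental-contrast rule because a shared ramp necessarily
makes generation-0 samples extreme. Technical: parental-vs-rest contrast
exceeding twice the pooled within-group SD and twice the largest cross-arm
difference. Otherwise: immediate (separation at generation 1), resistance
(later separation, treated above control) or repression (treated below).
For methylation, "resistance" and "repression" correspond to
hypermethylation and demethylation switches respectively.

## Gene-set statistic

Activity of a gene set in a pattern is the mean amplitude of its members;
the null draws same-size sets without replacement from the measured
universe (conditioning on the filtered analysis set, not the genome).
One-sided p-values use the add-one rule, so p ≥ 1/(n_perm+1) and fixed
seeds reproduce exactly; default n_perm = 1000. BH-adjusted q-values are
reported per pattern as additional, clearly labelled columns. Unlike the
original Bayesian implementation the statistic is unweighted: the
deterministic solver produces no posterior uncertainty on `A`.

## Driver calling and clone validation

Candidates are the PatternMarker genes of the resistance-associated
methylation patterns. Per candidate, Pearson correlation between
expression and β is computed across all shared time-course samples (both
arms pooled — pooling maximizes dynamic range and matches how the paired
design is visualized). A gene is called when r < 0 and its BH-adjusted
one-sided anti-correlation p is below α = 0.05. The adjustment is
deliberately one-sided: many candidates are genuinely positively
correlated (e.g. demethylation paired with falling expression), and under
a two-sided adjustment their small p-values relax the BH threshold enough
to let weak chance negatives through. The two-sided p is reported
alongside.

Clone validation requires, in a stable resistant-clone panel: parental
β ≥ 0.3, some clone with β ≤ 0.1 and log2 expression more than 1 above
parental, and a negative expression–methylation correlation across the
panel.

## Projection

External samples are scored by OLS regression of their z-scored expression
profiles (per gene, across the new samples) on the shared-gene rows of the
amplitude signature. Standardization makes the weights invariant to
per-gene affine rescaling — platform and unit differences are absorbed —
at the cost that weights track the training patterns only up to a
per-pattern affine map, so downstream use relies on correlations and group
contrasts, not absolute scale. A raw-scale mode recovers the pattern
weights of noiseless data exactly and a non-negative mode is available.
Group comparisons use Welch's unequal-variance t-test. Multi-probe genes
are collapsed beforehand to the probe with the highest SD.

## The synthetic study design

The generator emulates a two-arm passaging experiment: parental replicates
(default 3) at generation 0, treated and control arms at generations 1–11,
profiled on expression and promoter methylation. Archetypes (pattern rows,
maximum 1, baseline 0.1):

* expression — *immediate* (step to 1 in the treated arm from generation
  1), *resistance* (logistic rise of width 1 generation centred on the
  onset generation, default 4, exactly zero before onset−1), *repression*
  (linear decline in the treated arm from onset), *technical* (indicator
  of parental samples), *flat* (constant 1; the highly-expressed
  signature);
* methylation — *control drift* (linear rise in both arms),
  *demethylation* and *hypermethylation* (sharp logistic switches, width
  0.5, at the methylation onset, default 5 — one generation after the
  expression onset, encoding the observed lag).

A configurable fraction of genes (default 0.7) loads on a single pattern
with exponential amplitudes (expression) or near-unit loadings
(methylation); the rest split their loading over two patterns. Expression
archetypes are drawn compatibly with each gene's methylation archetype so
that *only* the planted drivers (default 20) are anti-correlated across
platforms: drivers are hypermethylated at baseline, demethylate at the
methylation onset and follow the resistance expression archetype.

Noise: expression adds Gaussian noise with the model Σ evaluated on the
clean signal (clipped at 0, as log-scale pipelines produce exact zeros);
methylation draws a Poisson total intensity `T ≈ coverage` (default 100)
and `β ~ Beta(μT, (1−μ)T)` with `M = βT`, `U = (1−β)T`, so the β-variance
formula used in fitting is the exact noise model of the generated data.
`noise_scale` multiplies the implied SD on both platforms; 0 returns the
noiseless product exactly.

What the generator does *not* emulate: count-level sequencing noise,
probe-level cross-hybridization, copy-number or mutational confounding,
batch structure beyond the single parental contrast, and genes whose
methylation–expression coupling is partial or lagged differently than the
planted archetypes. Passing tests therefore demonstrate that the pipeline
recovers the designed signal class under its own noise assumptions, not
performance on arbitrary real data.

The clone panel generator emulates stable single-cell clones: one
designated clone carries every planted driver demethylated (β = 0.05) and
overexpressed (+2.5 log2), the others draw heterogeneous profiles
uncorrelated with the resistance signature.

## Problem sizes and numerical choices

Tests and the acceptance script run the full design at 2000 genes × 25
samples (pattern recovery, dimension selection over 20 seeds, driver
calling over 10 seeds), 1000 genes for the 50-seed timing study, and
500–600 genes for reconstruction and projection checks — sizes at which
every measured property is stable. Degenerate inputs are defined
explicitly: zero-intensity β entries are missing (zero weight), all-zero
amplitude rows are reported unassigned, constant pattern rows yield
missing correlations, and zero-variance group comparisons yield missing
p-values. Tie-breaks (marker assignment, probe selection) go to the lowest
index / lexicographically first identifier.

## Known limitations

* The factorization's restart family is deterministic given the seed; it
  explores far less of the posterior than an MCMC sampler and reports no
  uncertainty on `A` or `P`.
* Dimensionality selection measures reproducibility, not evidence; a
  systematically shared artifact (e.g. variance-weighting bias) can
  support an extra pattern, as it plausibly does in real arrays.
* Separation dating assumes a single persistent divergence; oscillating
  or transient responses return no separation by design.
* Driver calling is correlational; anti-correlation across a time course
  does not establish that methylation causes the expression change.
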