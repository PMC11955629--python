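# Methods

This note documents the models, estimators and numerical conventions
behind `mockbench`, the choices made where the design was genuinely open,
and what the synthetic generators do and do not emulate.

## Data model

A profile is a taxa × samples matrix whose rows are canonical lineage
strings (`k__...;p__...;c__...;o__...;f__...;g__...;s__...`). Taxon
identity is the *full* lineage string, so a genus-only record
(`g__Bacillus;s__`) is a different row from any species of that genus;
accuracy scoring depends on keeping the two apart. Missing ranks may be
written as empty tokens or omitted; both normalise to the empty label, and
any spelling of the same lineage canonicalises to one row identity. Three
value modes are supported: `counts` (raw or rescaled library counts),
`relative` (proportions; column sums must be 1 within 1e-9) and `percent`
(published percent columns rounded to 2 decimals; column sums are only
required to be within 0.5 of 100, since printed tables do not close
exactly). Conversion `counts → relative` is explicit and refuses
already-relative input so a table can never be silently renormalised
twice.

## Mock-control scoring

The reference is a list of species with supplier-stated theoretical
percentages (the bundled default is the 8-species ZymoBIOMICS community,
theoretical percentages summing to 100.0), plus an alias map for
classifier-era synonymy (`Lactobacillus fermentum` →
`Limosilactobacillus fermentum`, `Escherichia coli` →
`Escherichia/Shigella coli`). Scoring is strictly species-rank:

* a reference species is **detected** iff some species-rank taxon
  alias-resolves to it with relative abundance above the detection floor;
* species-rank taxa resolving to no reference species are **spurious**;
* a reference species missed at species rank whose genus appears at genus
  rank is a **genus rescue** — reported, never counted as TP.

The detection floor defaults to 0 (any nonzero abundance counts): rare
spurious taxa are deliberately kept, and the floor is exposed for users
who want to study the effect of removing them. Precision, sensitivity and
F-score follow the standard confusion formulas; when TP+FP = 0 precision
is undefined and reported as 0 with an explicit flag.

O/E ratios divide each species' observed percent by its theoretical
percent, per control. Undetected species contribute ratio 0 and zeros are
*included* in the median and range — a species missed in two of seven
controls shows a zero-inflated range such as `1.07 (0.00–1.13)`. Medians
are the standard mean-of-middle-two for even n. An algebraic identity used
as a test oracle: Σ_species ratio × theoretical % equals the percent
correctly classified for that control (exactly, on unrounded data).

Percent correctly classified sums species-rank abundances that resolve to
reference species. On published tables printed at 2 decimals this
reproduces printed values to ±0.02 (and exactly where the printed
arithmetic closes, e.g. 80.84).

All report rendering rounds half-up to 2 decimals at the output boundary
only; full precision is kept internally and in JSON.

## Contaminant filtering

Decontamination is performed separately per plate against that plate's
own negative controls; a plate without negatives is an error, never a
silent skip. Two p-like evidence channels per taxon:

* **Prevalence** — one-sided Fisher exact test on the 2×2 table
  (presence/absence × negative/real), alternative = enrichment in
  negatives. Chosen over chi-square for small-sample safety: plates carry
  only a handful of negatives. Presence means count > 0 by default
  (configurable floor).
* **Frequency** — when ≥3 real samples carry DNA concentrations, a
  one-sided Spearman test of the taxon's relative frequency against
  inverse concentration. Reagent contaminants enter at a roughly fixed
  absolute level, so their share rises as input DNA falls. Taxa with
  fewer than 3 nonzero observations get a non-informative score of 1.

When both channels exist they are combined with Fisher's method (−2 Σ ln p
against χ²₄); a taxon is flagged iff the combined score falls below the
threshold (default 0.1, separately settable for the combined mode).
Filtering is row deletion only: surviving counts are untouched, and
conversion to relative abundance is a separate step. The pipeline order is
fixed and documented: decontaminate → median-library normalize →
to_relative. The frequency channel with ~tens of null taxa and ~12 samples
produces chance flags at the percent level; validation of exact planted
recovery therefore runs prevalence-only (`use_frequency=False`), and the
combined channel is exercised separately. No batch-effect correction step
is included by design: plate-wise decontamination already operates per
batch, and stacking a second correction on top proved counterproductive in
the setting this package targets.

Median library-size normalization rescales each sample's counts so every
library totals the median of the original totals. It preserves
within-sample proportions exactly and leaves values fractional ("rescaled
counts").

## Diversity

Alpha: observed richness counts taxa with abundance > 0 at the analysis
rank; Shannon is −Σ p ln p in **natural log** (a config switch changes the
base); Simpson is reported as the Gini–Simpson index 1 − Σ p², bounded in
[0,1]. Taxa unresolved at the analysis rank are pooled into an unassigned
bin that is excluded from all three measures.

Beta: Bray–Curtis Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) (abundance-weighted; equal on counts
and proportions when library totals are equal) and Jaccard on
presence/absence, 1 − |A∩B|/|A∪B| — the unweighted variant, chosen
because the presence/absence reading is what makes it complementary to
Bray–Curtis. Distances are computed with scipy's `pdist` and returned as
scikit-bio `DistanceMatrix` objects.

## Paired statistics

**Wilcoxon.** Two-sided paired signed-rank test on the pair differences.
Zero differences are dropped (Wilcoxon's original treatment); the exact
null distribution is used for n ≤ 25 without ties, otherwise the normal
approximation with continuity correction (delegated to
`scipy.stats.wilcoxon`; an independent brute-force enumeration over all
2ⁿ sign assignments serves as the test oracle for n ≤ 8). The 95%
confidence interval is Hodges–Lehmann: order statistics of the n(n+1)/2
Walsh averages (dᵢ+dⱼ)/2 at depths from the signed-rank null distribution,
computed exactly by subset-sum dynamic programming for n ≤ 60 and by
normal approximation beyond; the point estimate is the median Walsh
average (pseudo-median). Degenerate input (all differences zero) yields
p = 1 with a collapsed interval at 0, flagged explicitly.

**dICC.** The distance-based intraclass correlation is estimated by
method of moments on squared distances:

    MS_within = mean over pairs of d(a,b)²
    MS_total  = mean of d(i,j)² over all cross-pair sample pairs
    dICC      = 1 − MS_within / MS_total

Rationale: under Euclidean distance on univariate data with subject
variance σ_b² and replicate noise σ_w², E[d(a,b)²] = 2σ_w² within pairs
and 2(σ_b²+σ_w²) across subjects, so the estimator targets
σ_b²/(σ_b²+σ_w²) — the classical one-way ICC — and the same argument
extends coordinate-wise to multivariate profiles. It is exactly 1 when
every pair is duplicated and centres on 0 under random relabelling.
Estimates may go slightly negative by sampling noise, as classical ICC
can; values are reported unclipped and the qualitative bands
(poor < 0.5 ≤ moderate < 0.75 ≤ good) are applied to the raw value. No
permutation p-value is attached: the dICC is reported as a point estimate
with its interpretation band. Within-pair distances are excluded from
MS_total so the two moments are independent summaries of the same matrix.

## Synthetic generators

The generators emulate the study design the statistics are built for:
seven-plate runs carrying one whole-cell and one pre-extracted-DNA mock
control each, four negative controls per plate, and replicate pairs.

* **Mock controls.** Species proportions are the theoretical composition
  jittered by log-normal factors with sd 1/√(noise_concentration)
  (concentration → ∞ gives the exact composition); log-normal + closure
  was chosen over Dirichlet resampling so the noise scale maps
  monotonically to Bray–Curtis spread. Each species drops out at species
  rank with a per-species probability; a dropped species is rescued to
  genus rank with probability `genus_rescue_prob` (its mass moves to the
  genus row, so percent-correct falls), otherwise its mass is
  redistributed proportionally. Spurious taxa arrive Poisson (default
  mean 4/control) with percent abundances uniform in [0.01, 0.5], drawn
  from a fixed 50-name decoy catalogue of skin/oral/environmental species
  shipped as a fixture so outputs stay human-readable. Defaults (noise
  concentration 400, dropout 0.15, rescue 0.5) loosely reproduce the
  spread seen in real extraction controls — two-ish dropouts across seven
  controls, O/E scatter of a few percent — and are illustrative, not
  fitted.
* **Pairs.** Subject latent log-abundance profiles μ ~ N(0, σ_b²·I) over
  60 taxa, replicate members μ + N(0, σ_w²·I), softmax-closed, then
  truncated at a 0.005 proportion detection limit and re-closed (without
  a detection limit every taxon is present everywhere and Jaccard
  degenerates). The implied ICC σ_b²/(σ_b²+σ_w²) is recorded as truth;
  defaults (σ_b = 1, σ_w = 1/3, 17 pairs) mimic tight within-run
  technical replicates, ICC 0.9. The latent Gaussian matrix is also
  returned so Euclidean-distance checks can target the closed form
  exactly.
* **Plates.** Community taxa (17 by default) get Poisson counts
  proportional to a sample-specific library size (uniform in
  [50 000, 200 000]) scaled by input-DNA concentration; planted
  contaminants (3 by default) are Poisson around a fixed absolute level,
  enriched 10× in all negatives but only sporadically (15%) carried into
  real libraries — the signature both decontamination channels detect. A
  planted contaminant is guaranteed detectable *by design*: the truth
  record is only meaningful if the planted presence pattern separates in
  a 4-negative 2×2 table at the 0.1 threshold. Negatives also receive 5%
  trace cross-talk from community taxa, which must not be flagged.

All randomness flows through numpy Generators seeded from the spec's
master seed (per-stream children derived with a stable CRC of the stream
name), so identical spec + seed reproduces identical TSV bytes.

What the generators do **not** emulate: read-level errors (chimeras, PCR
substitutions), taxonomic misclassification between related species,
overdispersion beyond Poisson, depth-dependent detection curves, or real
gut community structure (taxa are exchangeable). Passing tests therefore
demonstrate that the estimators recover planted truth under their own
model assumptions — dropout, spurious taxa, variance components,
contaminant enrichment — not that any particular wet-lab protocol is
accurate.

## Problem sizes and numerical conventions

Validation workloads are sized for interactive runs: the dICC recovery
check uses a 3×3 grid of (σ_b², σ_w²) with 20 seeds × 50 pairs per cell,
type-I-error calibration uses 1000 null simulations at 17 pairs, and
contaminant-recovery checks use 10 seeded plates; each completes in
seconds. Other conventions: ties in rounding go half-up (away from zero)
at 2 decimals, only at the report boundary; relative-mode closure is
enforced at 1e-9; distance-matrix symmetry at 1e-12; percent-mode column
sums at 0.5. The Fisher-method combination clamps p-values at 1e-300
before logging. Degenerate inputs are errors, not silent passes:
zero-total samples, plates without negatives, designs with fewer than two
pairs, empty samples at a rank.
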