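# Methods

## The problem and the approach

Guilt-by-association infers shared function from covariation: across a
large panel of cell lines or patient samples, proteins operating in one
pathway tend to have correlated abundances even when they never physically
interact. `gbacorr` implements this as a rank-correlation pipeline over a
wide proteins × samples intensity matrix, with set-level statistics to
validate that a given dataset carries the signal, and a replicate-based
differential layer for two-condition depletion experiments.

## Missing values and imputation

Mass-spectrometry proteomes are sparse, and absence is informative: a
protein below the detection limit in a sample is usually a genuinely
low-abundance protein there. The pipeline therefore imputes **zeros** for
all missing cells before correlating, rather than pairwise-deleting
samples. Consequences the rest of the pipeline is built around:

* Zero imputation creates massive ties at zero. Ranks are therefore
  average (mid-)ranks; Spearman is computed as the Pearson correlation of
  those ranks, which equals the classical 1 − 6Σd²/(n(n²−1)) only in the
  tie-free case.
* A protein missing in *every* sample becomes a constant zero vector with
  no defined rank correlation. Such entries are stored as 0 — consistent
  with treating undetected as absent — but additionally tracked: the
  `CorrelationMatrix` records the set of constant proteins, and the dense
  symmetric undefined mask can be materialised on demand or written next
  to the matrix. Internally only the constant-row id set is stored because
  the dense mask is fully determined by it and costs O(p²) memory at the
  15,000-protein scale.
* Two proteins detected in the same few samples can show ρ exactly 1
  (duplicate rank profiles). The term-median statistic excludes pairs with
  ρ = 1 for exactly this reason (see below).

## The correlation engine

All-vs-all Spearman is computed by ranking each protein's row once,
centring and normalising the rank rows, and taking one matrix product —
mathematically identical to per-pair computation but O(p²n) through BLAS.
Numerical conventions:

* float64 throughout; the product is clamped to [−1, 1]; exact symmetry is
  enforced by mirroring the upper triangle; the diagonal is set to exactly
  1 regardless of constancy, so a query always heads its own ranked list.
* Entries within 1e-13 of ±1 are snapped to exactly ±1. Identical rank
  profiles should give exactly 1 (as reference correlation routines return)
  but a floating-point dot product can land a few ulp short; since the
  closest attainable non-unit Spearman value is 1 − 12/(n³−n) — orders of
  magnitude further from 1 than the guard band for any realistic sample
  count — only true duplicates are affected. This keeps the literal
  "exclude ρ = 1" rule effective.
* No per-correlation p-values are computed: the ranking use case
  deliberately applies no significance cutoff.

## Ranked association lists

The full correlation row of a query is sorted descending; ties break
lexicographically on partner id so output is deterministic. The query is
included at rank 1 by default, so a reported position "k of N" counts the
query itself; `include_query=False` yields partner-only ranks, which differ
by exactly one. Top-k prefixes preserve ranks, and cross-dataset top-k
overlap excludes the queries.

## Set statistics

**Term medians.** For each annotation term, the correlations of all
unordered pairs of members present in the matrix are collected (diagonal
never included, each pair once) and pairs with ρ exactly 1 are dropped;
the median of the remainder is the term's statistic. An option widens the
exclusion to |ρ| ≥ 1 − tol for users worried about near-duplicate profiles
that escape the exact rule. Terms with fewer than two present members, or
with every pair excluded, report an ABSENT median rather than an error. No
term-size filtering beyond the structural ≥ 2 present members is applied.

**Background.** The comparison distribution is all off-diagonal
correlations (upper triangle, each pair once — p(p−1)/2 values).
Undefined-set-to-zero entries are included by default, matching a
"all correlations in the dataset" reading; a flag excludes them. The
diagonal is excluded: including p self-correlations of 1 would inflate the
background toward 1 for no informational gain.

**Pair sets.** For a curated pair list (e.g. high-confidence
synthetic-lethal pairs filtered by evidence label at read time), the
correlations of pairs with both members present form the set distribution;
the shift is set median − background median, and absent pairs are counted.
A random-set empirical null (`random_set_null`) draws member sets of
matched size to calibrate shifts beyond the visual comparison.

## Panel profiles

A panel (defaults to the bundled centromere-protein list, excluding
CENP-F and CENP-J, plus the NDC80/NUF2/SPC24/SPC25 complex; fully
user-overridable) is profiled three ways: the sub-matrix restricted to the
panel in panel order; each protein's correlation quartiles against all
proteins; and each protein's abundance quartiles across samples computed
**after** NA→0 imputation, with a separate count of zero-or-missing
samples. A protein undetected in most samples therefore shows quartiles
pinned at 0 — the display that distinguishes "uncorrelated because absent"
from "uncorrelated because independent". Quartiles use the inclusive
linear-interpolation convention (numpy's `linear` method); conventions
differ between tools, so this is stated rather than assumed.

## Differential analysis

Per protein with ≥ 2 finite replicates per condition (configurable; others
carry ABSENT statistics rather than being dropped): log2fc = mean(log2 B) −
mean(log2 A); p from a two-sided Welch unequal-variance comparison of the
replicate log2 values; q by Benjamini–Hochberg over all tested proteins
(step-up, never below raw p). Raw intensities must be strictly positive
and are log2-transformed; already-log2 tables pass `log_input=True`.
Degenerate rows with zero variance in both conditions report p = 1 with a
warning when means agree. Welch on log2 intensities is the robust default
for small-n proteomics; note that at 4 + 4 replicates the
Welch–Satterthwaite approximation runs slightly conservative (true type I
≈ 0.041 at nominal 0.05 under normality), which is visible in null
simulations. No between-replicate normalisation and no moderated-variance
shrinkage are applied — inputs are assumed pre-normalised.

**Group fold change.** A named group (e.g. the subunits of one complex) is
summarised as 2^(arithmetic mean of member log2fc) — the geometric mean of
member fold changes, which weights subunits equally on the multiplicative
scale. Untested members are listed as skipped.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with known ground truth and no external data:

* **Modules.** Each planted module shares one latent factor per sample:
  z = b + λf + √(1−λ²)ε on the log2 scale, so every member pair has
  Pearson correlation λ². The loading is calibrated to a *Spearman* target
  through the Gaussian relation ρ_S = (6/π)·arcsin(ρ_P/2), i.e.
  λ = √(2·sin(πρ_S/6)). A single factor per module is deliberate: it
  controls pairwise ρ exactly, is cheap, and keeps the truth interpretable.
* **Scales.** Baselines are N(20, 1.5²) on the log2 scale with unit
  within-protein sample variation — intensities around 10⁶ in linear
  units, a typical published order of magnitude; Spearman is invariant to
  any monotone rescaling, so these choices affect realism, not results.
* **Missingness.** Cells are censored with probability
  sigmoid(c − slope·z_std) of their standardised latent log-abundance, the
  intercept solved so the realised expected rate matches the requested
  global rate. With a positive slope, low-baseline proteins lose most of
  their cells — reproducing the >90%-missing rows seen for sparsely
  detected proteins in real atlases, which is what exercises the
  undefined-correlation policy. Slope 0 gives uniform missingness.
* **Companions.** Annotation maps contain one coherent term per module
  plus uniformly random terms; pair sets sample within-module ("planted")
  and between-independent ("null") pairs with recorded classes; depletion
  tables shift condition B by log2(fold) for planted proteins around
  N(0, σ²) replicate noise.

What the generator does **not** emulate: real intensity distributions,
batch or tissue structure, correlated missingness between related
proteins, shared-peptide quantification artifacts, or inter-module
correlation. Passing tests on these cohorts show the pipeline recovers the
structure it models — module recovery under detection-limit censoring,
calibrated nulls — not that any particular biological dataset carries such
structure.

## Problem sizes and test design

The validation suite runs at sizes chosen to make the statistical checks
sharp but cheap: oracle equivalence on 30 × 20 matrices against an
independent per-pair implementation (1e-10) and the tie-free closed form
(1e-12); module recovery on a 1000-protein × 500-sample cohort with one
8-protein module at target ρ_S = 0.7 and 20% abundance-dependent
missingness; set-statistic shifts on the same cohort with 50 random terms
and 20/50 planted/null pairs; differential calibration on a 2000-protein
null and a 500-protein table with 50 planted two-fold effects (σ = 0.2,
4 + 4 replicates); and one full-scale 15,000 × 1,200 all-vs-all run with
spot checks, exercising the rank-once matrix-product path at the largest
published-atlas shape. Seeds are fixed in tests; the acceptance script
derives all randomness from its `--seed` argument. Note that BH sensitivity
depends on the surrounding table: the same two-fold effect recovered at
~95% among 500 proteins drops to ~50% among 2000, because the step-up
threshold tightens with the number of tests.

## Known limitations

* Zero imputation is aggressive: for proteins quantified in only part of
  the panel it deflates correlations toward co-detection patterns, which
  is informative for presence/absence biology but can mask regulation
  visible only within detected samples.
* Undefined correlations are reported as 0, so heavily-missing proteins
  cluster spuriously at the background centre; consult the undefined mask
  and the panel missingness counts before interpreting flat profiles.
* The ranking provides no significance or FDR; it is a hypothesis
  generator, and downstream validation is the user's responsibility.
* Only Spearman is offered; only flat annotation maps are read (no
  ontology propagation or semantic similarity); no sparse or approximate
  correlation path beyond the dense BLAS product.
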