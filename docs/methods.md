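# Methods

## Problem and scope

`traitcomm` analyses how plant functional traits structure a grassland
community in which a few species are highly abundant (dominants) and many
are not (subordinates). Given a relevé table (plots × species cover on the
Braun-Blanquet scale or in percent) and a typed species × trait table, it:

1. converts cover codes to percent and classifies species by dominance;
2. computes community-weighted mean traits (CWM) and Rao quadratic
   functional diversity (FD) per relevé, separately for each group;
3. tests whether the groups differ in trait composition (PERMANOVA),
   spread (beta-dispersion) and individual traits (t-tests, PCA);
4. scans each quantitative trait for convergence or divergence via Mantel
   tests between species co-occurrence and trait dissimilarity.

Because real relevé datasets of this kind are rarely deposited, the package
ships a synthetic-community generator with known ground truth, so every
stage's behaviour can be verified by parameter recovery.

## Cover scale and classification

Braun-Blanquet codes are converted with the van der Maarel midpoints
(r → 0, + → 0.1, 1 → 5.0, 2 → 17.5, 3 → 37.5, 4 → 62.5, 5 → 87.5 %). A code
`r` is a presence at 0 % cover and is distinct from absence: presence/absence
analyses (co-occurrence) count it, abundance weights give it zero mass.

Classification thresholds: a species is **dominant** if its cover is
*strictly above* 25 % in at least one relevé and **retained** if it reaches
*at least* 1 % in at least one relevé; retained non-dominants are
**subordinate**, the rest **excluded** and dropped before any downstream
computation. With Braun-Blanquet input the strict/inclusive choice can
never be ambiguous (17.5 < 25 < 37.5), so codes 3–5 are exactly the
dominant-qualifying values. Both thresholds are configurable.

## Traits and dissimilarity

The default schema has 14 traits: five categorical (life form ×4 classes,
growth form ×4, clonal-growth-organ type ×8, CGO role ×4, bud bank ×4),
seven continuous (plant height cm, SLA mm²/mg, LDMC mg/g, flowering length
months, CGO persistence yr, clonal offspring shoots, lateral spread m), one
circular (flowering start in degrees around the year), and the Grime CSR
strategy carried as three continuous scores. Binary expansion of the
categorical traits gives 24 + 7 + 1 + 3 = 35 numeric columns. Multi-state
categorical values (`"CGO9|CGO10"`) set several indicators — clonal-trait
databases routinely record more than one organ per species.

Per trait group, species dissimilarities are Gower-style in [0, 1]:

- continuous: |xᵢ − xⱼ| / range. The normalisation range defaults to the
  *pooled* retained species (passed as `range_basis`), so dominant-only and
  subordinate-only matrices share a scale and their FD values are
  comparable; a zero range yields an all-zero matrix with a warning.
- circular: shortest angular distance / 180°.
- categorical: mean absolute difference of the group's indicator vectors.

Missing values use pairwise deletion: a pair with no shared non-missing
information gets a missing dᵢⱼ, excluded from FD with renormalisation of
the remaining pair weights.

Flowering start is treated as circular because the flowering calendar
wraps; when source data give months, 360·(month − 1)/12 maps them to
degrees reversibly.

## CWM and FD

CWM_jk = Σᵢ p_ik·x_ij with p the within-group, within-plot renormalised
cover proportions. Missing trait values are dropped with weight
renormalisation. The flowering-start column is aggregated as the direction
of the weighted mean resultant vector; when the resultant length falls
below 1e-9 (e.g. equal weight on antipodal dates) the mean is undefined and
flagged NaN rather than fabricated. Plots where a group has no member (or
no member with positive cover) produce missing rows, which downstream
tests drop pairwise.

FD is Rao's quadratic entropy Q = Σᵢ Σⱼ dᵢⱼ·pᵢ·pⱼ over **all ordered
pairs** with dᵢᵢ = 0 — the expected dissimilarity of two individuals drawn
with replacement. The ordered-pair convention is stated explicitly because
an i<j convention differs by a factor of two; with d ∈ [0, 1] the ordered
form is bounded by 0.5. One FD index is computed per trait group; the
default grouping is the 16 natural source-trait groups (13 basic traits
plus C, S, R), and the grouping is a parameter (`fd_groups`) because other
partitions of the 35 columns are defensible.

## Group comparison

The two CWM matrices are stacked into one observation table (each relevé
contributes its dominant-group profile and its subordinate-group profile;
rows with missing entries dropped with a log note) and analysed with:

- **PERMANOVA** on Euclidean distances, 999 permutations by default.
  Pseudo-F comes from the distance-only decomposition
  SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ/n_g; for
  Euclidean distances this equals the explicit centroid geometry, which the
  tests assert to 1e-9.
- **beta-dispersion**: principal-coordinate embedding of the distance
  matrix, distance of each observation to its own group centroid with the
  standard negative-eigenvalue correction (squared contributions along
  "imaginary" axes are subtracted, then clipped at zero), followed by a
  one-way F with classical and permutation p-values. Cross-checked against
  `vegan::betadisper(type = "centroid")`.
- **Student's t-tests** per trait column across plots. Welch's correction
  is available but off by default, and no multiple-testing correction is
  applied by default (per-trait α = 0.05); both choices favour fidelity to
  common practice in this literature over robustness and are flagged here
  as known limitations. Columns constant in both groups are flagged
  `undefined` instead of propagating NaN.
- **PCA** by SVD of the standardised (correlation-matrix) data — the
  expanded columns mix scales, so covariance PCA would be dominated by the
  large-valued traits. Component signs are fixed deterministically.

The stacked construction treats the 70 group-plot observations as
independent, although dominant and subordinate profiles of the same plot
share an environment; the permutation test does not account for that
pairing. This caveat applies equally to any analysis of this design.

All permutation p-values use (1 + exceedances)/(1 + n_perm), which cannot
return 0 and is exact under exchangeability.

## Assembly scan

Species co-occurrence within a group is Jaccard association on
presence/absence by default (phi, the 2×2 correlation, as the alternative;
abundance-weighted association is deliberately not the default because the
ecological reading of the scan is about co-occurrence). The sign logic of
the scan is invariant to any monotone association choice.

For each continuous/circular trait, the Mantel statistic is the Pearson
correlation of the upper triangles; the null permutes rows and columns of
one matrix simultaneously, which preserves each matrix's value multiset.
The test is two-sided with post-hoc sign classification at α = 0.05:
negative r → convergence, positive r → divergence. Each trait in a scan
gets its own derived permutation stream so removing one trait does not
shift the others' p-values.

## Synthetic community generator

Defaults emulate a ~35-relevé dry-grassland survey: 8 dominants and a pool
of 93 subordinates, target mean richness 38 species/plot (SD 4). Dominants
are present in each plot with probability 0.85 and draw covers from codes
{2, 3, 4}; each is guaranteed one code ≥ 3 somewhere. Subordinates draw
from {+, 1, 2} with a guaranteed code ≥ 1 somewhere, so their cover can
never cross 25 % and the classifier must recover the planted labels
exactly — classification recovery is an exact, not statistical, check.

Trait distributions are group-specific: dominants are narrow, tall,
high-LDMC/low-SLA stress-tolerators, long-flowering, clonal with rhizomes
and a deep bud bank; subordinates are wide on every continuous trait, more
ruderal, and uniform on flowering start. This builds in the
narrow-dominant/wide-subordinate variance contrast that makes subordinate
FD exceed dominant FD.

Two mechanisms shape subordinate occupancy:

- **Environmental filtering** (convergence), default on flowering start:
  each plot draws a uniform latent optimum; candidates are visited in a
  weighted random order with weights exp(−strength·d), d the [0, 1]
  normalised (circular) trait distance to the optimum — equivalent to
  weighted sampling without replacement, so strength 0 is exactly a
  uniform permutation and plots still fill to their richness target.
  Default strength 3.0.
- **Limiting similarity** (divergence), default on clonal offspring
  number: walking down that order, a candidate within `min_separation` of
  any already-admitted resident on the trait is rejected. Default 0.15 on
  a trait spanning roughly [1, 10].

The defaults were fixed once by calibrating three conditions jointly —
realised mean richness within ±20 % of the target, both mechanisms
recoverable by the Mantel scan in ≥ 90 % of seeds, and a ≈ 5 % false-call
rate with both mechanisms off — and are not tuned per analysis. An earlier
sequential accept/reject admission rule was replaced by the weighted-order
rule because discarding rejected candidates under-filled plots (mean
richness ≈ 22).

What the generator does **not** emulate: spatial autocorrelation between
relevés, species' abundance–occupancy relationships beyond the two-group
split, phylogenetic trait correlation, missing trait values, multi-state
categorical records, and observer error in cover estimation. Passing
recovery tests therefore show the pipeline detects the planted mechanisms
under clean conditions, not that it would under field noise.

## Numerical choices and degenerate inputs

- Permutation seeds: every stochastic routine takes an explicit seed;
  derived seeds are small integer offsets. Two runs of the full pipeline
  with the same config are byte-identical (no timestamps in outputs).
- Groups with < 2 members are rejected by the comparison tests; groups
  with < 3 species by the assembly scan ("insufficient replication"
  errors, never silent NaN).
- A plot with a single group member has FD = 0 (no pairs), not missing.
- Mantel r is refused (flagged) when either triangle has zero variance or
  fewer than 3 complete pairs.
- PCA requires complete rows; constant columns are dropped under
  standardisation, all-constant input is an error.

## Problem sizes

Tests and the acceptance script run the generator at its default size
(35 plots, 101-species pool): classification recovery over 50 seeds,
Mantel recovery over 20 seeds at 999 permutations, oracle equivalences
over 500–1000 random small instances, and permutation type-I calibration
over 200 replicates at 199 permutations — sizes chosen so the whole suite
completes in a few minutes while keeping the binomial envelopes tight
enough to detect miscalibration.
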