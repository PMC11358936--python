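# traitcomm

Trait-based community-assembly analysis for vegetation relevé data — for
community ecologists asking why some grassland species are abundant and
others are not.

Given a plots × species cover table (Braun-Blanquet codes `r, +, 1…5` or
percent cover) and a species × trait table (categorical, continuous and
circular plant functional traits), `traitcomm`:

- converts cover codes to percent (van der Maarel midpoints) and splits the
  flora into **dominants** (cover > 25 % in ≥ 1 relevé), **subordinates**
  (≥ 1 % somewhere, never > 25 %) and excluded species;
- expands categorical traits to binary indicators and computes, per relevé
  and per group, the **community-weighted mean** CWM_j = Σᵢ pᵢ·x_ij and the
  per-trait **functional diversity** as Rao's quadratic entropy
  Q = Σᵢⱼ dᵢⱼ·pᵢ·pⱼ (ordered pairs, dᵢⱼ ∈ [0, 1] Gower-style);
- compares the groups with **PERMANOVA** (Euclidean, 999 permutations),
  a **beta-dispersion** test, per-trait **Student's t-tests** and **PCA**;
- detects **trait convergence/divergence** per quantitative trait with
  **Mantel tests** between species co-occurrence (Jaccard or phi) and trait
  dissimilarity: significant negative r → co-occurring species are more
  similar than expected (environmental filtering), significant positive
  r → more dissimilar (limiting similarity).

Because relevé surveys of this kind are rarely deposited, the package
includes a synthetic-community generator with planted ground truth
(known dominants, one filtered trait, one divergent trait), used by the
test suite for exact and statistical parameter recovery. See
`docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
survey (seed 42) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_classify.py
python analysis/03_functional_indices.py
python analysis/04_group_comparison.py
python analysis/05_assembly_tests.py
```

Output printed by these scripts (tables land in `results/`):

```
simulated 35 releves over 101 retained species (mean richness 36.1/plot)
classified 8 dominants, 93 subordinates, 0 excluded
agreement with planted labels: 101/101
CWM matrices: 35 plots x 35 trait columns
FD matrices:  35 plots x 16 trait groups
subordinates have higher mean FD for 16/16 trait groups
PERMANOVA: pseudo-F = 49.06, p = 0.001 (999 permutations)
beta-dispersion: F = 91.44, permutation p = 0.001
t-tests: 33/35 traits differ at alpha = 0.05
PCA on significant traits: PC1/PC2 explain 70.3% / 4.4%
subordinate: 2/11 traits significant at alpha = 0.05
  F_start: r = -0.190, p = 0.001 -> convergence
  NoCloSh: r = +0.181, p = 0.001 -> divergence
dominant: 0/11 traits significant at alpha = 0.05
```

Reading: the classifier recovers every planted label; dominant and
subordinate communities differ strongly in trait composition (PERMANOVA)
and spread (beta-dispersion); subordinates carry more functional diversity
for every trait group; and the Mantel scan flags exactly the two planted
mechanisms — convergence on flowering start, divergence on clonal
offspring number — in the subordinate group only.

The same stages are available as a CLI
(`traitcomm simulate|classify|cwm|fd|compare|assembly|all`) and as library
functions (`traitcomm.classify_species`, `build_group_matrices`,
`permanova`, `mantel_test`, ...).

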