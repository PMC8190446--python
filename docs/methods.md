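# Methods

## The scientific problem

Mitochondria are maternally inherited, so selection on mitochondrial DNA
acts only through females. Mutations that harm males while being neutral or
beneficial in females can therefore accumulate — the *mother's curse*
hypothesis. Its testable signature in a mitonuclear panel (every
mitochondrial haplotype crossed into every isogenic nuclear background) is
**greater mitochondrial genetic variance in males than in females**: each
haplotype carries its own load of male-biased mutations, so swapping
haplotypes perturbs male phenotypes more than female ones.

`mitocurse` implements the complete inference sequence for such panels on a
continuous, sexually dimorphic trait (the motivating application is wing
centroid size in a 9 nuclear x 9 mitochondrial *Drosophila melanogaster*
panel with one inviable combination, leaving 80 of 81 genotypes):

1. **Factorial ANOVA.** A fixed-effects linear model
   `trait ~ sex * mito * nuc` with sequential (type-I) sums of squares in
   the fixed order sex, mito, nuc, sex:mito, sex:nuc, mito:nuc,
   sex:mito:nuc, plus per-sex models `trait ~ mito * nuc`. The proportion of
   variance attributed to a term is its SS divided by the total corrected SS.
2. **Mitochondrial coefficients of variation.** Within each
   (nucleus, sex) group, the line means (per-genotype trait means) of all
   haplotypes form a vector; CV = sample SD (n−1) / mean, computed on
   untransformed data. A bootstrap resamples the *vector of line means*
   with replacement (B = 1000 by default) for percentile intervals.
3. **The curse sign test.** Per nucleus, the male−female CV point
   difference; zero differences dropped; the remaining signs go into an
   exact two-sided binomial sign test at p = ½,
   `p = min(1, 2·min(P(X≤k), P(X≥k)))`. A percentile CI of the
   across-nuclei mean difference is taken from paired bootstrap replicates.
4. **Male-variability control.** CVs across nuclei computed from coevolved
   lines only, per sex. If males were intrinsically more variable (e.g. X
   hemizygosity), this nuclear CV would already be male-biased. The sex
   contrast is a one-way F test between the bootstrap CV distributions and
   is always emitted with a caveat flag: bootstrap replicates are not
   independent observations, so the nominal p overstates certainty and the
   comparison is descriptive.
5. **Intersex genetic correlation.** Pearson r between male and female
   line means over genotypes (overall, and within each nucleus), two-sided
   p from the t distribution on n−2 df. Raw (unstandardized) means are used.
6. **Mantel tests.** Genetic distance = pairwise SNP counts between
   haplotype mtDNA sequences, excluding masked intervals (the AT-rich
   hypervariable control region maps poorly, so calls there are excluded;
   the mask is always supplied as coordinates, never hard-coded).
   Phenotypic distance = pairwise |Δ line mean| within a (nucleus, sex)
   group. The Mantel statistic is the Pearson correlation of lower-triangle
   entries; the null jointly permutes rows and columns of one matrix
   (10,000 permutations by default) and the p-value uses the add-one
   estimator `(1 + #extreme)/(1 + n_perm)`, one-sided "greater" by default
   with a two-sided option.

Standardization (dividing each value by its nucleus x sex mean) is provided
for visual comparison across backgrounds; CVs are scale-free within group,
so it does not affect the inference and the CV pipeline uses raw data.

## Numerical and design choices

- **Sequential SS by projection.** Term blocks of full indicator columns
  are appended to the design matrix in the documented order; each term's SS
  is the drop in residual SS, its df the rank increase (SVD-based
  least squares). Missing (inviable) cells therefore reduce interaction df
  to the estimable contrasts automatically (63 instead of 64 for the
  80-genotype panel), and results are invariant to factor level order
  because each block spans the full indicator space of its term. On
  balanced complete designs this equals the closed-form orthogonal
  decomposition to better than 1e-6 relative error (tested against both a
  cell-mean oracle and statsmodels' type-I ANOVA).
- **Sequential order sensitivity.** Type-I SS depends on term order on
  unbalanced data; the near-balanced panels this package targets make the
  effect negligible, and the order is fixed and documented rather than
  configurable.
- **CV denominator.** Sample SD with n−1; the bootstrap target is the same
  statistic, so point estimate and bootstrap distribution are consistent.
- **Tie handling.** Zero CV differences are dropped before the sign test
  (classical convention; exact ties are essentially impossible on
  continuous data). Mantel permutation ties count as extreme (conservative),
  with a 1e-12 guard against float jitter.
- **Determinism.** Every stochastic routine takes an explicit seed and uses
  its own `numpy` Generator; no global RNG state. The pipeline derives one
  independent substream per stage from the root seed, so stages can be
  rerun in isolation and full runs are byte-identical.
- **Degenerate inputs** (single-level factors, zero residual df, constant
  traits, constant distance matrices, groups with fewer than two
  haplotypes, non-positive mean line means) raise typed errors naming the
  offending group rather than returning NaN.

## The synthetic panel generator

`simulate_panel` draws

    y = mu + s*delta + alpha_nuc + beta_(mito,sex) + gamma_(nuc,mito,sex) + eps

with `s` a female indicator. Effects are drawn **once per label** and
reused across replicates (genotypes are clonal lines, so line means are
meaningful); `beta` and `gamma` are drawn per sex from a bivariate normal
with cross-sex correlation `cross_sex_corr` (default 0.8, matching the
strongly concordant intersex line means real panels show). Incompatible
design cells emit no rows. Replicate labels group individuals into vials of
five but carry no vial effect: within-vial variance structure is not part
of the model (a deliberate omission — no empirical basis for choosing one).

Default parameters emulate a wing-size-like trait in mm: grand mean 2.50
(male baseline), dimorphism +0.25 (females larger), sigma_nuc 0.055,
sigma_mito 0.0075 (f) / 0.012 (m), sigma_epi 0.026 (f) / 0.031 (m),
sigma_resid 0.045. These give expected per-sex variance shares of roughly
nuclear 50%, interaction 11–16%, mitochondrial 1–2.5% (male > female),
residual ~35%, and an expected overall intersex correlation near 0.9 —
the variance hierarchy such panels report. With only 9 labels per factor
the *realized* shares of any one panel scatter widely around these
expectations (the sample variance of 9 effect draws has ~50% relative SD);
that scatter is real sampling behaviour, not a generator defect.

What the simulator does **not** emulate: sequence evolution (effects are
drawn, not evolved), vial/block effects, non-normal residuals, and
measurement artefacts. Passing tests therefore validate the inference
machinery, not the biology of any particular dataset.

### Benchmark scenarios

Two frozen conditions (`curse_scenario`, `curse_free_scenario`) back the
power and calibration guarantees:

- **Curse condition**: sigma_mito_m = 2 x sigma_mito_f = 0.05 with small
  epistasis (0.005) and residual 0.025 at 15 per cell. The per-nucleus
  male/female variance ratio of line means is then ~3.7; since the sample
  variance ratio is F(8,8)-distributed around it, each nucleus is positive
  with probability ~0.96 and >= 8 of 9 nuclei are positive in the large
  majority of panels.
- **Curse-free condition**: fully sex-symmetric — equal mito SDs *and*
  `sex_effect = 0`, with epistasis dominating mito (0.03 vs 0.01). Both
  choices are structural requirements for an honest null: CV divides by
  the group mean, so equal absolute spreads across unequal sex means would
  mechanically inflate the smaller sex's CV; and mitochondrial effects are
  shared across nuclei, so a mito-dominated spread would correlate the nine
  per-nucleus signs and the sign test (which assumes independent pairs)
  would over-reject. Under this condition the empirical rejection rate
  sits at the exact test's true level (20/512 ≈ 3.9%).

The second point is worth noting as a genuine methodological caveat of the
CV-difference sign test itself: in real panels where mitochondrial main
effects dominate mitonuclear epistasis, the nine nuclei do not provide nine
independent confirmations.

## Problem sizes used in validation

Monte-Carlo suites use 200 replicate panels for sign-test power/type-I
rates, 500 replicates for Mantel and correlation p-value uniformity
(999 permutations each), 200 replicates for per-sex ANOVA null calibration,
and exhaustive enumeration oracles for the sign test (all 2^n patterns,
n <= 12) and the Mantel test (all n! relabelings, n <= 6). Variance-
component recovery averages method-of-moments estimates over 30 independent
15 x 15 x 2 x 100 panels: with L labels the sample variance of the drawn
effects has relative SD sqrt(2/(L-1)), so a single 9 x 9 panel cannot pin a
component to better than ~50% and the averaged design brings the
Monte-Carlo SE of each component to ~7%, comfortably inside the 15%
acceptance band.

## Known limitations

- Fixed-effects OLS only; no mixed/random-effects estimation, REML, or
  type-II/III SS.
- The nuclear-CV sex contrast's F test on bootstrap distributions is
  descriptive (caveat flag always set).
- No partial Mantel, phylogenetic correction, or indel-aware distances;
  SNP distances ignore gap/ambiguity positions per pair.
- No alternative dispersion tests (Levene/Brown–Forsythe); the CV-based
  procedure is the method under study.
- The bracketed interval reported next to the sign-test p is implemented
  as the percentile CI of the across-nuclei mean CV difference over paired
  bootstrap replicates; this is one reasonable reading of an
  underspecified convention and is labelled as such in the results object.
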