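# Methods

This note documents the statistical machinery implemented in `resorb`, the
design of the synthetic-data generator, the numerical choices, and what the
test suite does and does not establish.

## Resorption metrics

For a nutrient with green- and senesced-leaf concentrations `g` and `s`
(mg g⁻¹) and a mass loss correction factor `m` (senesced/green leaf dry
mass, per species):

- `RE = (1 − s/g × m) × 100 %`.  The correction accounts for carbon lost
  during senescence: without it (`m = 1`) RE is systematically
  underestimated because the remaining mass concentrates the nutrient.
  RE is deliberately not capped below: values < −100 % are meaningful
  accumulation.  An "uncorrected" RE is available as the `m = 1` special
  case; no other uncorrected variant is implemented.
- `RP = s`, with the convention that lower RP = higher proficiency.
- MLCF is computed per species as the ratio of species-mean senesced to
  species-mean green dry mass.  Whether the original field protocol pooled
  at species or group level is not documented anywhere we could find;
  per-species is the finer-grained choice and reduces to the group value
  when species are homogeneous.
- LDMC is dry/saturated mass (the universal 0–1 definition; some sources
  print the reciprocal), SLA is area/dry mass (cm² g⁻¹), and succulence is
  leaf water mass per leaf area expressed in g m⁻² so the conventional
  "succulent above 500 g m⁻²" threshold applies directly.
- RE can be aggregated at species level (from species-mean concentrations;
  the default, matching how group tables are usually printed) or per
  individual green/senesced pair.  For secretohalophytes the Na value
  carries a caveat flag: salt secretion removes Na by a pathway the RE
  arithmetic cannot distinguish from resorption, so the number is
  reported but should not be read as resorption.

## Phylogenetic signal

Blomberg's K is computed from the matrix formulas: with `C` the tip
variance–covariance matrix (shared root-to-tip path lengths),
`â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`,

```
K = [ MSE0 / MSE ] / [ (tr C − n/(1ᵀC⁻¹1)) / (n − 1) ],
MSE0 = Σ(xᵢ−â)²/(n−1),   MSE = (x−â)ᵀC⁻¹(x−â)/(n−1).
```

K = 1 is the Brownian-motion expectation on the given tree; star trees
give K = 1 identically for any non-constant trait (both ratios reduce to
the common branch length), which the tests exploit as an exact identity.

Significance uses the conventional randomisation test: the observed
statistic is the variance (mean square) of the standardised independent
contrasts, the null distribution shuffles trait values across tips, and
`p = (1 + #{null ≤ observed}) / (n_perm + 1)` — one-tailed, because only
*lower* contrast variance than random indicates signal.  The permutation
count defaults to 999 and every test is seeded; p can never fall below
`1/(n_perm + 1)`.  Contrasts for all permutations are evaluated in one
vectorised pruning pass, so 999 permutations on 36 tips cost milliseconds.

Independent contrasts follow Felsenstein's pruning algorithm; polytomies
are resolved in input child order with zero-length branches (this leaves
`C` unchanged), and a zero-length pair of sibling branches raises rather
than dividing by zero.  PIC correlations are computed through the origin,
`r = Σcₓc_y/√(Σcₓ²Σc_y²)`, with p from `t = r√((n−2)/(1−r²))` on n − 2
degrees of freedom.

The categorical plant group enters signal tests as an integer coding
(Eu=1, Se=2, Ps=3, Gl=4) by default — this yields a single K for the
group trait; an indicator mode (four 0/1 traits) is provided because no
canonical coding exists for categorical K.

## Classical statistics

- One-way ANOVA from the explicit SS decomposition; compact letter
  displays come from pairwise Tukey HSD: letters are the maximal cliques
  of the "not significantly different at α" graph, lettered a, b, c … in
  descending order of the largest group mean in each clique.
- One-sample t-tests compare RE against 0 % (no resorption); comparisons
  against published global reference means accept either a reference
  vector (Welch's t) or a single printed mean (one-sample t) or a
  (mean, sd, n) summary triple (Welch from summary statistics).
- PCA operates on the correlation matrix (elements span two orders of
  magnitude, so covariance PCA would be a Na/K analysis); loadings are
  orthonormal with the sign convention that each component's
  largest-magnitude loading is positive.
- SMA: `slope = sign(r)·sd(y)/sd(x)`, intercept through the means,
  significance from the Pearson correlation test.  The fit is reciprocal
  (`slope_xy·slope_yx = 1`) and equals the OLS slope divided by |r|.
- Variance partitioning uses sequential (Type I) sums of squares computed
  by nested least-squares fits, with site entered before the taxonomic
  factor (group or family).  Nested RSS reductions rather than a packaged
  ANOVA table because the survey design is structurally aliased —
  glycophytes occur only on gravel-desert sites — which sequential SS
  tolerates (the later factor is credited only with what it adds) but
  textbook ANOVA implementations reject.  A factor adding no design rank
  at all still raises an error naming it.

## The synthetic world

The generator emulates a 36-species, 15-family desert survey with four
Na-regulation groups (10 Eu, 5 Se, 11 Ps, 10 Gl species) and 5–8 tagged
individuals per species, each sampled once green and once senesced:

- **Tree**: seeded pure-birth (Yule) tree, depth rescaled to 1.  The
  simulator is written in-package so that terminal branches include the
  final holding time; a simulator that stops at the n-th birth leaves
  zero-length tip branches and a singular `C`.
- **Groups**: contiguous blocks of the tip order (unions of clades), so
  group labels carry phylogenetic signal; a `clustered=False` mode
  assigns labels uniformly at random for null calibration.
- **Green concentrations**: species-level log-normal variation around
  published group-mean anchors for all six elements (N, P, K, Na, Ca,
  Mg).  The log-sd per element × group is derived from the anchor table's
  standard errors (`CV = SE·√n/mean`); a weight parameter splits the
  species-level variation between a Brownian component on the tree and an
  i.i.d. component (default 0.5).  Deviations are demeaned within group
  and shifted by −sd²/2, so each group's arithmetic mean sits on its
  anchor rather than drifting with the clade-correlated BM draw.
- **True RE**: group-level values derived from the green and senesced
  anchor means at the reference MLCF 0.8 (the midpoint of the per-species
  MLCF ~ Uniform(0.6, 1.0) default), jittered per species (sd 0.05).
  This builds in the published directions of effect, e.g. net Na
  accumulation in euhalophytes.
- **Leaves**: individual green concentration = species mean × lognormal
  (0, `noise_sd` = 0.2); senesced concentration = species mean ×
  (1 − RE)/MLCF × an independent lognormal — the exact algebraic
  inversion of the corrected-RE formula.  At `noise_sd = 0` the estimated
  RE therefore equals the true RE to machine precision, the key oracle
  for the whole metric layer.  Senesced dry mass is green dry mass ×
  MLCF exactly, so mass-based MLCF estimates also recover the truth.
- **Sites**: halophytes on saline sites, glycophytes on gravel sites, at
  the survey's density of roughly two species per site.  Site carries no
  generative effect of its own; it exists so the variance-partition
  design has the real survey's structure, including the group/site
  aliasing.
- **Leaf morphology**: euhalophytes draw low SLA (40–100 cm² g⁻¹) and low
  LDMC (0.15–0.30), others 80–250 and 0.25–0.50, which places succulence
  (water/area) above the 500 g m⁻² flag mostly in euhalophytes.

What the generator does **not** emulate: within-site spatial structure,
soil chemistry as a driver (site is a label, not a covariate), secretion
physiology (Se leaves simply follow the same inversion with a caveat
flag), measurement error distinct from biological variation, green/
senesced sampling at different dates, and any covariance between elements
beyond what the shared tree induces.  A green test therefore establishes
that the estimators recover a *known, well-behaved* world — not that the
field protocol was unbiased.

## Numerical choices and edge cases

- `C⁻¹`-products use `numpy.linalg.solve`, never explicit inverses (the
  explicit-inverse evaluation survives in the tests as the independent
  brute-force oracle).  A singular `C` (duplicate tips, zero depths)
  raises with a tree diagnostic.
- Constant traits make K undefined (MSE0 = 0) and raise.
- Contrast weights use the `b₂/(b₁+b₂)` form, stable when polytomy
  resolution introduces one zero-length sibling branch.
- Degenerate t-tests: zero variance with mean equal to the null value
  returns p = 1 with a warning; zero variance away from the null raises.
- Trait CSVs are comma-separated UTF-8 with "." decimals; floats are
  written at full precision (`repr`), so accepted rows round-trip
  bit-exactly and fixed-seed runs are byte-identical.
- Newick trees without branch lengths default to unit lengths (logged);
  Grafen-style depth scaling is available (`Phylogeny.grafen_lengths`)
  for callers who prefer it.  How the original survey's tree service
  assigned branch lengths is undocumented, so both options are explicit
  rather than silently chosen.
- The ambiguity of "n leaf samples" (pairs vs. total leaves) is exposed as
  the generator's `layout` parameter (`paired` default, `total`
  alternative).

## Known limitations

- The permutation test calibrates exactly only under exchangeable tips;
  traits generated with strong BM violate the null by construction (that
  is the point of the test, but it means the p-value is one-tailed
  evidence of signal, not a goodness-of-fit test for BM).
- K's small-sample distribution is skewed; the BM calibration tests check
  the mean over 200 replicates, not per-replicate closeness to 1.
- Integer group coding imposes an ordering (Eu < Se < Ps < Gl) that is a
  convention, not biology; the indicator mode exists for sensitivity
  analysis.
- Variance-partition shares depend on factor entry order (sequential SS);
  the order is part of the configuration and echoed in the output.
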