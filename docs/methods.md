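# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `inbreedage`. Notation: F is Wright's inbreeding
coefficient (probability the two alleles at a locus are identical by descent,
IBD); "age" of autozygosity is the number of generations g to the common
ancestor of the two allele copies.

## Pedigree inbreeding and its age partition

F of an animal equals the kinship of its parents. Full-pedigree coefficients
are computed with a Meuwissen–Luo-style recursion over genetic-contribution
(L) vectors, using the decomposition A = L D L′ of the numerator relationship
matrix: kinship(s, d) = ½ Σⱼ L_sj L_dj D_j, with D_j the Mendelian-sampling
variance of ancestor j (½ − ¼(F_sire + F_dam), adjusted for unknown parents).
Cost is O(N · ancestors) and the dense tabular A-matrix construction is kept
in the package as an independent cross-check (`relationship_matrix`); the two
agree to 1e-10 in the test suite. Kinship through an unknown parent
contributes zero; an animal with an unknown parent has F fixed at 0 and is
flagged `incomplete`, so depression analyses can exclude such records.

**Changing base generation.** F_new(t) is F recomputed on a per-focal
truncated pedigree: ancestors reachable within at most t parent steps, with
the parents of ancestors at minimum depth exactly t set unknown. Truncation
removes ancestral paths only, so F_new(t) is non-decreasing in t and
F_old(t) = F_ped − F_new(t) ≥ 0; the pair sums to F_ped to 1e-12 by
construction. Two implementations share this definition:

- *generational pedigrees* (every non-founder has both parents in the
  immediately preceding cohort, as in the simulator): truncation at t for a
  focal in generation G is a global cut at generation G − t, so one
  vectorized cohort-by-cohort kinship recursion per cut serves all animals —
  this is what makes 14-threshold grids over thousands of animals cheap;
- *general pedigrees*: per-focal truncated sub-pedigree plus the recursive
  kinship above. The tests assert exact agreement of the two paths.

Whether a tool counting "t generations" should cut at minimum or maximum
ancestor depth is genuinely ambiguous for non-generational pedigrees; minimum
depth is used because it corresponds to the pedigree-subset (renumbering)
semantics of standard pedigree software. For generational pedigrees the two
coincide.

Pedigree-quality metrics: MaxGen is the longest ancestor chain; ECG
(equivalent complete generations) uses the recursion
ecg(i) = ½(1 + ecg(sire)) + ½(1 + ecg(dam)) with missing-parent terms
dropped, equal to Σ(½)ⁿ over all ancestor paths (verified against exhaustive
path enumeration).

## ROH detection and the length partition

Detection is a deterministic maximal-run scan per animal × chromosome: a run
is a maximal marker window with at most `max_het_per_segment` heterozygous
(default 2) and `max_missing_per_segment` missing calls (default 5), and no
adjacent-marker gap above `max_gap_bp` (default 500 kb). Runs then pass the
minimum-SNP (15), minimum-length (1 Mb) and density (≤ 500 kb/SNP) filters;
bounds are the first/last marker positions and length = end − start.
Feasibility is hereditary, so a two-pointer scan enumerates exactly the
maximal windows; the tests compare it against a definitional
feasibility-matrix oracle on a thousand random vectors. Because the het and
missing budgets make maximal windows overlap occasionally, surviving runs are
accepted greedily from the left so reported segments never overlap — one
deterministic dialect of the windowed scans used by standard tooling, not a
byte-identical reimplementation of any of them (window size and hit-rate
heuristics of those scans are deliberately not modelled). A maximal window
may begin or end on a heterozygous call if the budget allows; the filters and
the reported `n_het`/`n_missing` make this auditable.

F_ROH = Σ L_ROH / L_AUTO with L_AUTO the SNP-covered span (sum over
chromosomes of last − first marker position). The length partition at m Mb
assigns segments with length ≥ m to the recent class (a tie is recent —
longer segments indicate younger ancestors). Expected segment length for
age-g autozygosity is 1/(2g) Morgan; with the uniform 1 cM/Mb map this gives
the conversions g = 100/(2·l_mb) and l = 100/(2g), so the default m grid
3–17 Mb spans roughly 17 down to 3 generations.

**Mixture classification.** The two-component Gaussian mixture is fitted on
log10 segment lengths (raw lengths are strongly right-skewed; the scale is a
package choice and is documented because reasonable alternatives exist). The
EM is seeded: quantile-based means plus seeded jitter across `n_init`
restarts, best log-likelihood kept, making the fit reproducible; the
log-likelihood path is exposed and tested for monotonicity, and the means are
cross-checked against scikit-learn's GaussianMixture. The short/long boundary
solves w₁N(x; m₁, v₁) = w₂N(x; m₂, v₂) — a quadratic on the log scale — and
keeps the root between the means; if the components are too entangled to
cross there, the midpoint is used. Variance collapse raises an error
suggesting more segments.

## Gene dropping (new vs ancestral inbreeding)

Single-locus gene dropping assigns every founder two unique allele labels and
transmits one uniformly random allele per parent per replicate, in
topological order. An individual is autozygous when its labels match.
Exposure bookkeeping follows the "already IBD in the past" idea: the two
allele copies of an autozygous individual acquire a sticky exposed flag that
travels with transmission; autozygosity involving a previously exposed copy
counts as ancestral (F_anc), otherwise as new (F_new), so F_new + F_anc = F
holds replicate by replicate. A Ballou-style column (probability either
parental copy was ever exposed, regardless of current autozygosity) is
emitted as well. Estimates carry binomial standard errors √(p(1−p)/n); the
default 100,000 replicates put the SE near 0.0015 at p = 0.25 and are
configurable upward. For pedigrees with at most 22 transmission events an
exact enumerator (`exact_drop_small`) computes the same quantities over all
equally likely transmission patterns and anchors the Monte-Carlo tests. The
formalization of exposure cannot be cross-validated against published numbers
for the motivating herd (its inputs are not public); it is validated
internally against hand path-counting and the exact enumerator.

## Depression models

Covariates are z-scored ((x − mean)/sd, n−1 denominator) within the analysed
records, separately per analysis, so coefficients are trait units per
covariate SD and comparable across thresholds; a constant covariate is an
error (the grid search records such thresholds as skipped). New and old are
always fitted jointly.

The mixed model y = Xb + Zu + Wm + Sp + e is solved by Henderson's MME with
A⁻¹ assembled by Henderson's rules including inbreeding (Mendelian-sampling
variances from the computed F). When both direct and maternal genetic effects
are present the penalty block is G⁻¹ ⊗ A⁻¹ with
G = [[σ²ᵤ, σᵤₘ], [σᵤₘ, σ²ₘ]] (σᵤₘ defaults to 0); the maternal
permanent-environment block is identity-penalized over dams with records.
Fixed-effect SEs come from the fixed block of C⁻¹ × σ²ₑ. The solver is exact
sparse LU; tests verify equality (1e-6) with dense GLS using
V = ZAZ′σ²ᵤ + WAW′σ²ₘ + SS′σ²ₚ + Iσ²ₑ, and that it degenerates to OLS as
σ²ᵤ → 0. Variance components are configuration inputs, not estimated
(no REML/Gibbs); simulator defaults are h² = 0.35 direct, 0.10 maternal,
0.05 maternal permanent environment when maternal terms are enabled.

Model-comparison criteria are computed only for fixed-effects-only fits:
Adj.R² = 1 − (1 − R²)(n − 1)/(n − k), RMSE = √(RSS/n), and Gaussian
log-likelihood AIC/BIC with p = k + 1 parameters (residual variance counted,
the R `stats` convention — so AIC and BIC differ by exactly p(ln n − 2)).
Significance uses |β̂/SE| > 2, strict inequality, no multiple-testing
adjustment. Birth year is an unordered factor; age enters linearly where the
trait warrants it.

## Grid search

Thresholds are scanned most-recent-first: t ascending for pedigree grids
(default 3–16), m descending for ROH grids (default 17, 15, …, 3 Mb). At each
threshold the model above is fitted (mixed model by default for threshold
search; fixed-only fits drive the method-comparison criteria). For
higher-is-better traits the rule fires when β_new ≤ β_old, ties included
(exact ties are compared with a 1e-9 relative tolerance so that analytically
tied fits are not broken by rounding); the first firing threshold is
selected, all firings are reported (`crossings_`) because the curves can
cross more than once, and a never-firing grid returns no threshold with a
logged diagnostic. Thresholds with a constant covariate are skipped but
recorded; thresholds where at least half the animals have f_new = 0 are
fitted but flagged information-poor. The stored trace (β_new, SE, β_old, SE,
rule outcome per threshold) deterministically reconstructs the selection.

## The synthetic herd

The generator stands in for a non-public line-bred cattle herd and is
first-class, tested code.

*Pedigree*: discrete generations from `n_founders` founders; each of
`n_matings` matings draws a dam and either (with probability
`consanguinity_rate`) a sire whose closest shared ancestor with the dam sits
at a target depth drawn from `consang_weights` (depth j creates inbreeding
loops of age j + 1 in the offspring; depth 1 = half/full sibs, 2 = first
cousins), or the most distantly related sire available, avoiding shared
ancestors within `avoidance_depth` generations — the avoidance mimics managed
herds that minimize close inbreeding and is what places the youngest
inbreeding at a known age. Defaults (80 founders, 12 generations, 200
matings × 2 offspring, 40-sire pool, 35% deliberate matings at depths 4–5,
avoidance depth 4) produce ~2,000 phenotyped animals in the last five
generations whose inbreeding is a mixture of age-5/6 deliberate loops and
deeper drift — a herd whose true age boundary is 6 generations.

*Genomes*: linked gene dropping. Founder chromosomes carry unique haplotype
labels; each meiosis draws Poisson crossovers at 1 cM/Mb (Haldane, no
interference). Every transmitted chunk is a node in a copy tree pointing at
the chunk it was copied from, so for any autozygous interval the most recent
common copy gives the coalescence age g = (k₁ + k₂)/2 from the meiosis counts
of the two paths (always an integer in generational pedigrees; fractional
ages are possible in principle for unequal path lengths, which is why the
track column is a float). Contiguous intervals of equal age are one tract: an
ancestor's own mosaic boundaries do not interrupt IBD descent through that
ancestor. Getting this merge right matters — splitting at inherited
breakpoints biased mean tract lengths far below 1/(2g) in early versions; the
exponential-law test (mean length of age-2/5/10 tracts vs 25/10/5 Mb within
3 Monte-Carlo SE, on one long chromosome so edge truncation is negligible)
guards it. Chromosomes are homogeneous 100 Mb units by default (29 of them)
for analytic tractability; lengths, counts and the cM/Mb scale are
configurable.

*Markers*: evenly spaced (default 80 kb) with founder-allele frequencies from
Beta(2, 2) clipped to [0.05, 0.95]. Chance (non-IBD) homozygosity therefore
exists — detected F_ROH runs ~0.16 against ~0.07 true autozygosity in the
default consanguineous test herd while correlating ~0.99 with it — so
short-segment false positives are exercised without drowning the signal (a
U-shaped MAF distribution was tried and rejected: near-fixed alleles made
chance ROH cover ~45% of the genome).

*Phenotypes*: y = μ + sex + birth-year + age + β_new·z(f_new) +
β_old·z(f_old) + u (+ maternal terms) + e, with u built by
Mendelian-sampling recursion (so u ∼ N(0, A σ²ᵤ) exactly), year effects
random draws fitted as fixed factors, and the depression betas applied to
z-scored components so that configured values (−0.8/−0.2 trait SD by
default) are on the same scale as fitted coefficients. The truth partition is
caller-supplied: pedigree-based truth makes the depression model exactly
correctly specified (used for coefficient-recovery studies); IBD-track truth
(realized autozygosity) adds errors-in-variables attenuation, closer to
reality and used for the detection/partition sanity checks.

## What the simulations do and do not show

Passing recovery tests show the machinery is consistent: when depression
really acts through an age-partitioned inbreeding covariate, the grid search
finds the boundary (within ±1 generation in ≥ 70% of replicates at n = 2,000)
and the mixed model recovers the coefficients. They do not show that real
herds have a sharp age boundary (purging is gradual), nor do they reproduce
any particular herd's thresholds; with real data the selected threshold
inherits all the uncertainty visible in the trace SEs, and the old-inbreeding
coefficient is poorly identified wherever deep inbreeding varies little
between herdmates. The ROH side additionally depends on panel density: at
80 kb spacing segments below ~1 Mb are undetectable, which is why the m grid
stops at 3 Mb.

## Numerical and degenerate-input conventions

- Floating identities are asserted at 1e-12 (partition sums), 1e-10
  (inbreeding oracle agreement), 1e-6 (MME vs GLS).
- Segment length is end − start (not +1); a segment exactly m Mb long is
  recent.
- Unknown parents: kinship contribution 0; Henderson D = 1 (no parents) or
  ¾ − ¼F (one parent).
- EM variance floor 1e-6 on the log10 scale; collapse raises rather than
  silently regularizing.
- Empty ROH sets, animals without segments, and never-firing grids are valid
  results (zeroes / None), not errors; constant covariates and rank-deficient
  designs are errors naming the offending columns.
- All randomness flows through numpy Generators seeded from explicit seeds;
  per-component streams are derived with SeedSequence so pedigree, genome and
  phenotype draws are independently reproducible.

## Problem sizes used in the shipped studies

The packaged experiments run on one CPU in a few minutes total: oracle
comparisons on 200-animal pedigrees, 1,000 random marker vectors, 200,000
gene-dropping replicates, ≤ 50-record mixed models; the exponential-length
study on one 2,500 Mb chromosome (so that 25 Mb tracts are far from the
ends); and 20 recovery herds of ~4,900 animals with 2,000 phenotyped. These
sizes are the package's own choices for routine verification; all scale up
via configuration.
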