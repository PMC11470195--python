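# Methods

This note records the models, estimators, numerical choices and known
limitations behind `riverpopgen`, in the order data flows through the
pipeline.

## Data model

Genotypes are biallelic dosages (0/1/2, sentinel −1 for missing) in a dense
individuals × loci matrix with per-locus metadata (tag, placement, mean
depth, reproducibility) and per-sample metadata (site, river distance in km,
capture date, total length, ancestry, cohort). Dosages are re-oriented to
count the minor allele at load time (computed over the whole file); every
downstream statistic used here (Ho, He, FIS, r², FST, relatedness) is
invariant to that orientation, and the flip is recorded per locus for audit.
Positions are 1-based as in VCF; unplaced loci are excluded only by
operations that need coordinates (LD decay, distance thinning).

## QC chain

Filters run in a fixed order: depth window [6, 50] → reproducibility ≥ 0.95
→ locus missingness ≤ 10% → individual missingness ≤ 20% → excess
heterozygosity → one SNP per tag → optional minor-allele-count floor
(MAC ≥ 2 is intended for kinship subsets, where singletons are noise). The
excess-heterozygosity screen flags likely collapsed paralogs: an exact
one-sided binomial test of the per-locus heterozygote count against rate
0.5, Bonferroni-corrected across tested loci by default (FDR available).
Thresholds are strict inequalities on the "bad" side (e.g. reproducibility
< 0.95 is removed). The chain is idempotent; the only randomness is the
choice of SNP within a tag, driven by the user's seed.

Distance thinning keeps one random locus per non-overlapping window
(default 50 kb) anchored at position 0 per chromosome — the simplest
reproducible rule; it guarantees at most one retained locus per window but
not a minimum gap across window boundaries. LD decay bins composite r²
against physical distance and reports the mean r² of random
cross-chromosome pairs as the background level.

## Diversity and inbreeding

PHt is the fraction of an individual's called loci that are heterozygous.
Group summaries average per-locus observed heterozygosity Ho and expected
heterozygosity He = 2p(1−p) over an explicit, caller-supplied locus panel so
that groups are comparable; He carries no 2n/(2n−1) small-sample correction
— the uncorrected form is what makes the effective-inbreeding arithmetic
(below) reproduce its reference values from tabulated He. FIS is summarised
as the mean of per-locus 1 − ho/he over loci with he > 0 (not the ratio of
the mean Ho and He, which differs slightly in unbalanced panels).

Effective inbreeding of a focal group relative to an outbred reference is
Fe = 1 − He_focal/He_reference. It can be negative for groups more diverse
than the reference (returned with a warning, not clipped). The diversity
regressions (PHt on river km) and group comparisons (ANOVA with Tukey HSD,
nested-model F tests) go through statsmodels OLS.

## LD-based effective size

The estimator treats linkage disequilibrium among physically unlinked,
selectively neutral loci as a drift signal. For each locus pair, over the S
individuals called at both loci, the Burrows composite disequilibrium is

    Δ̂ = [ (1/S) Σᵢ xᵢyᵢ / 2 − 2 p̂ q̂ ] · S/(S−1)

with p̂, q̂ the allele frequencies among those S individuals, and the
squared correlation is

    r̂² = Δ̂² / [ (p̂(1−p̂) + D̂_A)(q̂(1−q̂) + D̂_B) ],

where D̂ is the within-locus departure of homozygote frequency from p̂²
(Weir's genotypic correction). The S/(S−1) factor and the D̂ terms matter:
the downstream calibration constants presume them, and without them the
estimator runs ~15% hot on Ne in simulation. The plain textbook composite
(no corrections) is available via `pair_r2(..., corrected=False)` and is
what the LD-decay scan uses, where only relative levels matter.

Loci with minor-allele frequency below Pcrit (default 0.01) **within the
analysis group** are excluded first — rare alleles inflate r̂². Pairs are
weighted by S (pairs with more joint calls count more); the harmonic mean of
S across retained pairs sets the sampling expectation

    E[r̂²] = 1/S + 3.19/S²                      (S ≥ 30)
    E[r̂²] = 0.0018 + 0.907/S + 4.44/S²         (S < 30)

and the residual r²′ = mean r̂² − E[r̂²] is inverted through the
random-mating drift relation

    N̂ₑ = (1/3 + √(1/9 − 2.76 r²′)) / (2 r²′)     (S ≥ 30; analogous
                                                   constants 0.308/2.08 for
                                                   S < 30).

Boundary behaviour: r²′ ≤ 0 (no drift signal beyond sampling noise) gives
N̂ₑ = ∞ — the estimator refuses to hallucinate a finite size for a large
panmictic population. A drift component so large that the discriminant goes
negative (which happens under extreme mixture LD, e.g. pooling many strongly
diverged demes) is clamped to the discriminant-zero limit, so the inversion
stays finite, continuous and monotone decreasing: an enormous LD signal
means a very small estimate, never an infinite one.

Confidence intervals are a delete-one-individual jackknife on r²′: the pair
sufficient statistics are rank-1 downdated per individual (O(L²) per
replicate), the jackknife variance gives a normal-theory 95% interval on
r²′ (preferred over percentile intervals for stability in small groups),
and the endpoints map through the same inversion; an interval reaching
r²′ ≤ 0 has an infinite upper bound. The leave-one-out replicates reuse the
full-sample Pcrit locus panel — re-screening per replicate would make the
delete-one statistic discontinuous. LD-based CIs of this family are known
to be anticonservative; the validation suite asserts ≥60% empirical
coverage, not 95%.

Scope: single-sample, random-mating model only; no temporal or sibship
estimators; no claim of numerical identity with any particular existing
implementation — the contract is parameter recovery under simulation
(median N̂ₑ within [70, 140] for true Nₑ = 100 at S = 60, 2,000 SNPs).

## Life-history adjustment and rescue calculators

A raw single-cohort LD estimate mixes the per-cycle number of breeders Nb
and the per-generation Nₑ. With adult lifespan AL and age at maturity α
(defaults 23 y and 3 y — the Macquarie perch values), the two-trait
regression Nb/Nₑ = 0.485 + 0.758·log₁₀(AL/α) (= 1.156; the logarithm is
base-10, which is what reproduces that value) gives the correction
N̂b,adj = N̂b/(1.26 − 0.323·Nb/Nₑ) = N̂b/0.887 and
N̂ₑ,adj = N̂b,adj/(Nb/Nₑ). The divisor must be positive (Nb/Nₑ ≲ 3.9);
outside that range the adjustment is refused. Reported integers are rounded
at the presentation layer only.

The rescue calculators convert an inbreeding target (default Fₑ < 0.1, half
the level at which severe inbreeding depression is typically observed) into
the migrant fraction f = max(0, 1 − √(Fₑ,target/Fₑ,site)) and head-count
Nm = f·Nb/(1−f). These are planning formulas operating on whatever Fe and
Nb the caller supplies; the pipeline feeds them per-site Fe (local ancestry
only) and adjusted per-site Nb.

## Structure and kinship

PCA runs on mean-imputed, column-centred dosages via SVD with component
signs fixed (largest-magnitude loading positive), so results are
deterministic; this is the standard genotype-PCA shortcut, and acceptance is
cluster separation, not score equality with any other implementation.
Ancestry classification uses one PC axis anchored by reference individuals
of both parental populations, oriented so the source mean lies below the
local mean; the default admixed band is the central 50% of the gap between
reference means (dataset-specific cutoffs can be supplied instead).
Classification is F1-oriented; later-generation backcrosses are not reliably
separable on one axis and are out of scope.

Pairwise FST is the Weir–Cockerham (1984) two-level estimator,
ratio-of-sums across loci, negatives floored at zero in the reported matrix
(raw values returned alongside). The Mantel test correlates off-diagonal
upper triangles and permutes rows/columns of the second matrix jointly
(seeded; p = (#{|r*| ≥ |r|} + 1)/(n_perm + 1), default 999 permutations).

Kinship is a deliberately simple surrogate for full-likelihood sibship
reconstruction: the symmetrised Queller–Goodnight moment estimator with
allele frequencies from the full dataset (relatives included — a small
downward bias, acceptable at the validation tolerances and flagged when a
dataset is dominated by one family), genotype mismatch rate for recapture
detection (components of pairs with mismatch ≤ 0.02), and single-linkage
clustering of pairs with r̂ ≥ 0.35 into full-sib-like families. Families
spanning multiple sites are emitted as connectivity evidence. No parentage
assignment, no half-sib resolution, no error-model likelihoods.

## Growth

Age classes come from total length with sampling-year-specific bins (YOY
< 90 mm; 1–2YO up to 210 mm in 2020 and 180 mm in later years; 2–3YO to
270 mm; adults above 271 mm). Lengths in the unassigned gaps (90–100 mm and
the 270–271 mm boundary) resolve to the nearer bin edge — a choice the
source rules leave open. Cohorts subtract the class age from the capture
year, minus one more if capture precedes the spawning month (default
November). Adults are pooled, not assigned a birth year.

The Gompertz curve L(t) = b1·exp(−b2·exp(−b3·t)) is fitted by
Levenberg–Marquardt from starting values (200, 0.5, 0.3); ages enter as
class midpoints (0.5/1.5/2.5 y) since exact ages are unknown. This
parameterisation and the midpoint convention are configuration, as the
alternatives (other Gompertz forms, integer ages) are equally defensible.
Degenerate fits (no convergence, non-positive asymptote or rate, constant
lengths) are flagged rather than silently returned. The
inbreeding-depression screen fits the nested ladder site → cohort →
site+cohort → site×cohort (interaction skipped when cells are empty), picks
the best main-effects model by nested F tests, adds PHt, and reports whether
PHt significantly improves fit at α = 0.05.

## Simulator

The generator is a discrete-generation Wright–Fisher metapopulation:
unlinked biallelic loci with shared ancestral frequencies drawn from a
Beta(0.5, 0.5) truncated to [0.05, 0.95]; each offspring in deme d draws two
parents whose demes come from row d of a backward, row-stochastic migration
matrix (supporting asymmetric up/downstream rates and hard barriers) and
receives one allele per parent per locus. A source population evolves in
isolation at larger size, so the focal demes diverge from it and lose
diversity by drift; translocation events inject source adults into a
recipient deme, whose matings with locals produce F1s (ancestry is tracked
as a fraction, so F1s and later backcrosses are distinguishable in truth).
Sampling draws individuals without replacement from the last generations
(cohorts) and an older "adult" snapshot, attaches site/river-km/capture
metadata, and generates lengths from the growth module's Gompertz curve
plus Gaussian noise — closing the loop so the growth machinery runs on
simulated data.

Closed-form oracles validate the engine: per-generation heterozygosity
decay (1 − 1/(2Nₑ)), FST accumulation 1 − (1 − 1/(2Nₑ))ᵗ between isolated
demes, and the martingale property of allele frequencies. A separate
haplotype-based helper simulates one recombining chromosome
(adjacent-locus recombination 0.5·(1 − e^(−d/25 kb))) for LD-decay tests
only.

The study-like preset (`make_study_like`) encodes the monitored-river
regime: nine linearly ordered demes with true sizes 8–130 (small upstream,
large downstream), downstream-biased stepping-stone migration with barriers,
a 400-strong divergent source, translocations into the two downstream demes
in the last generations, and ~330 sampled individuals across recent cohorts
plus adults at ~3,000 loci. Forty generations of drift at these sizes
produce the intended signatures: an upstream-to-downstream diversity
gradient, a source/local He ratio around 1.4, per-site N̂b spanning an
order of magnitude, and a pooled estimate far below every per-site one.

What the simulator deliberately omits: overlapping generations (the Nb/Nₑ
distinction is handled analytically in the demography module, not
simulated), mutation and selection (negligible on monitoring timescales),
linked loci outside the LD-decay helper, and genotyping error (tests inject
it explicitly where relevant). Passing tests therefore demonstrate
estimator correctness under the model's assumptions, not robustness to
every artefact of real reduced-representation data.

## Problem sizes used in validation

The test suite scales simulations to what each property needs: estimator
recovery uses 20 replicates of an isolated deme (Nₑ = 100, S = 60, 2,000
loci, 40 generations); the structure- and admixture-bias checks use 20
replicates each at 1,000 loci; drift oracles use 400–500 loci with 200
small replicates for the martingale test; kinship validation uses 1,000
loci with frequencies from the truncated Beta; pipeline end-to-end tests
run the study preset at 500 loci. The full suite finishes in a few minutes
on one CPU with no network access.

## Known limitations

- The Ne estimator assumes random mating and a closed, unstructured group;
  the package's own bias demonstrations show what happens otherwise — that
  is the point — but no correction for admixture or overlap is attempted
  beyond the life-history adjustment.
- Jackknife CIs are anticonservative at small group sizes.
- The kinship surrogate cannot reach the accuracy of full-likelihood
  sibship reconstruction; family splits/merges near the r̂ threshold are
  expected, and replicate-consensus (meaningful only for stochastic
  reconstruction) has no analogue here.
- Two-row vendor genotype reports are not parsed; the single-row dosage
  dialect is the supported interchange format, with the two-row parser a
  documented extension point.
- Group He/Ho summaries assume a shared locus panel; comparing summaries
  computed on different panels is unsupported and will mislead.
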