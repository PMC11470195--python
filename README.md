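# riverpopgen

Genetic monitoring of small, fragmented riverine fish populations from SNP
genotypes. The package was built around the monitoring problem posed by the
endangered Macquarie perch (*Macquaria australasica*) in a barrier-fragmented
river: a handful of breeding sites, per-site effective sizes spanning from a
few fish to low hundreds, ongoing genetic-rescue translocations from a
divergent, more diverse reservoir population, and the question of which
genetic indicators can be trusted to track all of that.

It provides, as one tested toolchain:

- **SNP QC** — the reduced-representation filtering chain (read-depth window,
  reproducibility, locus/individual missingness, exact-binomial
  excess-heterozygosity screen, one SNP per tag, MAC floor) plus LD-decay
  estimation and physical-distance thinning.
- **Diversity & inbreeding** — individual heterozygosity (PHt), per-group
  Ho/He/FIS on a fixed locus panel, and the effective inbreeding coefficient
  *F*ₑ = 1 − *H*ₑ,inbred/*H*ₑ,outbred of a focal group against an outbred
  reference, with the regression/ANOVA machinery for testing diversity
  gradients.
- **LD-based effective size** (the core) — a from-scratch single-sample
  estimator: Burrows composite disequilibrium r² over all locus pairs,
  allele-frequency screening (*P*crit), subtraction of the finite-sample
  expectation E[r²] = 1/S + 3.19/S², and inversion of the drift relation
  N̂ₑ = (⅓ + √(1⁄9 − 2.76·r²′)) / (2 r²′) with delete-one-individual
  jackknife confidence intervals.
- **Life-history adjustment & rescue calculators** — Nb/Ne = 0.485 +
  0.758·log₁₀(AL/α); N̂b,adj = N̂b/(1.26 − 0.323·Nb/Ne); migrant fraction
  f = 1 − √(Fₑ,target/Fₑ,site) and head-count Nm = f·Nb/(1 − f).
- **Structure & kinship** — PCA with reference-anchored ancestry calls
  (local / source / F1-admixed), Weir–Cockerham pairwise FST, seeded Mantel
  isolation-by-distance, Queller–Goodnight relatedness with recapture
  detection and full-sib family clustering as connectivity evidence.
- **Growth** — length-based age/cohort assignment, Gompertz size-at-age
  residuals, and the site/cohort/PHt model ladder used to screen for
  inbreeding depression.
- **A Wright–Fisher metapopulation simulator** — linear stepping-stone demes
  with asymmetric migration and barriers, a divergent source population,
  translocation events producing F1 admixed offspring, multi-cohort sampling
  and a Gompertz length model. Every estimator above is validated against
  this simulator's known truth.

The package's simulations reproduce the central methodological finding of
this kind of monitoring data: **population structure and admixed individuals
bias LD-based N̂ₑ sharply downward** (pooling diverged demes, or including a
few F1s, collapses the estimate), while **heterozygosity rises with
admixture** — so He/PHt, not N̂ₑ, is the robust indicator for tracking
genetic augmentation.

## Worked example

Estimate the effective number of breeders for a single cohort of 60 fish
genotyped at ~2,000 SNPs (here simulated from a deme of true Nₑ = 100), then
apply the species' life-history adjustment and the rescue calculator:

```python
from riverpopgen.simulate import single_deme_dataset
from riverpopgen.ldne import LDNe
from riverpopgen.demography import nb_ne_ratio, adjust_nb, rescue_plan

ds, truth = single_deme_dataset(ne=100, sample_size=60, n_loci=2000,
                                n_generations=40, seed=1)
res = LDNe(ds, label="site8.cohort2020-like").fit()
print(res.summary())
```

```
LD-based effective size estimate
================================
group:              site8.cohort2020-like
individuals:        60
loci (post-Pcrit):  1612
locus pairs:        1298466
harmonic mean S:    60.00
mean r2:            0.020390
E[r2] (sampling):   0.017553
r2 drift component: 0.002837
Ne_hat:             115.4
95% CI (jackknife): [89.8, 160.8]
```

The mean pairwise r² (0.0204) exceeds what finite sampling alone would
produce (0.0176); the excess is the drift signal, and inverting it recovers
the true size within the jackknife interval. Continuing:

```python
ratio = nb_ne_ratio(23, 3)                      # adult lifespan 23 y, maturity 3 y
adj = adjust_nb(res.ne_hat, ratio)
plan = rescue_plan("site-2-like", fe_site=0.431, nb_site=adj.nb_adj,
                   fe_target=0.1)
```

```
Nb/Ne ratio  : 1.156
divisor      : 0.887
Nb_adj       : 130.1
Ne_adj       : 112.6
f_migrant    : 0.518
Nm           : 140.0
```

For an iteroparous fish, the raw single-cohort estimate mixes per-cycle and
per-generation quantities; dividing by 0.887 gives the per-cycle number of
breeders. A site at effective inbreeding Fₑ = 0.431 needs just over half its
breeders to be outbred migrants to reach Fₑ < 0.1.

There is also a CLI:

```bash
riverpopgen simulate --seed 4 --out sim/          # synthetic study-like data
riverpopgen qc --genotypes sim/genotypes.csv --metadata sim/samples.csv --out qc/
riverpopgen rescue --fe-site 0.431 --nb 9         # calculators only
riverpopgen all --config pipeline.yaml            # full pipeline
```

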