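# Methods

## Model and procedure

A scat's diet profile is its vector of per-taxon read proportions
p_i (reads of taxon j / total reads). Scats with a successful molecular
sex call are binned into Location × Sex × Year × Month groups; within a
group the population diet q is the unweighted mean of member profiles and
each member's specialization is the proportional similarity index

    PSi = 1 − 0.5 Σ_j |p_ij − q_j|  =  Σ_j min(p_ij, q_j).

PSi ∈ [1/N, 1] for a group of N members: 1 when the individual mirrors the
group diet, 1/N when it monopolizes a resource nobody else uses (the
*theoretical minimum*). Because small groups mechanically inflate PSi,
groups with N < 5 are flagged and excluded from inference, and a Spearman
correlation of group mean PSi against N is reported as a bias diagnostic.

Downstream, group mean PSi values are summarized with a percentile
bootstrap of the mean; per-sample PSi is logit-transformed and modeled
with REML linear mixed models whose fixed effects come from
{Sex, Month, Sex × Month} and whose random intercepts are SampleSize,
Location and Year (crossed). Candidates are ranked by AIC and
Burnham–Anderson Akaike weights w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC_k/2);
variance explained is reported as Nakagawa-style marginal
(fixed effects only) and conditional (fixed + random) r². Prey–PSi
relationships use Spearman rank correlations of each taxonomic order's
dietary proportion (and the per-scat benthic fraction) against PSi, with a
Bonferroni-corrected alpha over the base orders.

## Key conventions and parameters

- **Population diet weighting.** q is the *unweighted* mean of member
  proportion vectors (each scat weighs equally, regardless of read depth).
  This is the only convention under which the theoretical minimum is
  exactly 1/N, which the group tables rely on.
- **Resource axis.** PSi is computed on species-level proportions over the
  union of taxa observed within the group; order-level vectors are used
  only for the correlation analyses.
- **Singleton groups.** A group of one has PSi = 1 by the formula
  (self-comparison). Published group tables sometimes print 0 for such
  groups as a reporting convention; the loader preserves the printed value
  as data while the computation keeps the formula's value. Singletons are
  always filtered before inference, so the choice never reaches a model.
- **Logit clamp.** PSi = 1 (identical diets) is clamped to 1 − 1e−6 before
  the logit, with a warning; retained groups make PSi = 0 impossible
  because every member contributes to q.
- **Sex calling.** Male iff ≥1 ZFY and ≥1 ZFX reaction amplified; female
  iff ≥1 ZFX and no ZFY; no ZFX → excluded (ZFY-only patterns are flagged
  separately). The false-negative estimator conditions on classification
  as male: with per-reaction dropout q, the single-positive fraction among
  males is f = 2q/(1+q), inverted as q̂ = f/(2−f), FN = q̂². An
  unconditional variant (inverting 2q(1−q) = f) is available via
  `method="unconditional"`.
- **Juvenile/adult salmon split.** Applied per salmonid species:
  juvenile = p·r, adult = p·(1−r), summed into two pseudo-orders that
  conserve the Salmoniformes total exactly. The ratio r resolves
  sample → month (location+year) → season (location+year, then global)
  → 0 (all adult), and the scope used is logged. Pooled-order splitting is
  possible by supplying one ratio for all salmonid species.
- **Group-size filter** min_n = 5; **bootstrap** R = 100,000 by default
  (percentile CI, reported as half-width (upper−lower)/2 plus bounds);
  **moments** are population moments, kurtosis non-excess (normal = 3);
  **Bonferroni** alpha = 0.05/13 = 0.0038 for the order tests, inherited
  by the juvenile/adult pseudo-orders.
- **AIC convention.** AIC = −2·(REML log-likelihood) + 2k with k = number
  of fixed coefficients + number of variance components + 1 (residual).
  Absolute AICs are therefore comparable only within a run; weight
  arithmetic is convention-free.
- **"SampleSize" as a random factor.** Each distinct group size is a
  factor level shared by all samples from groups of that size; it is the
  device by which sampling-intensity bias enters the model.

## Numerical choices

- Mixed models delegate optimization to statsmodels MixedLM in the
  variance-components formulation (one all-encompassing group, one
  component per crossed factor). Gradient optimizers can stall on the
  boundary when a component's true variance is ~0, so `fit_lmm` runs BFGS
  and then Powell and keeps the fit with the higher REML log-likelihood; a
  component estimated at zero is reported as zero with a warning, not an
  error. If no grouping factor varies, the fit degenerates to OLS.
- Spearman rho is the Pearson correlation of mid-ranks; p-values use the
  exact permutation distribution for n ≤ 10 and the t approximation
  t = ρ√((n−2)/(1−ρ²)) above. Constant vectors are an error (ranks carry
  no information); the sex-ratio wrapper downgrades that to a warning with
  NaN rho because paired designs can legitimately be tiny.
- Bootstrap resampling and every simulation consume a caller-supplied
  seed; child RNGs are derived deterministically, and identical
  config + seed reproduces outputs byte-for-byte.
- Dirichlet draws with very small concentration parameters are generated
  via gamma variates with a 1e−12 floor; a (vanishingly rare) all-zero row
  falls back to uniform.

## The synthetic-data generator

`simulate_study` emulates the structure of the real data: the default
group layout *is* the printed 111-group table (5 haul-outs, 4
non-sequential years, months April–November, 1,099 sexed scats), read
depths are lognormal (median ≈ 1,800, floor 100), qPCR dropout is 0.10 per
reaction (implying the ~1% male→female false-negative rate such assays
report) and 25% of scats fail sexing outright, matching a 75% field
success rate. Diets are Dirichlet-multinomial: group base diet
q0 ~ Dirichlet(0.6) over 29 realistic Salish Sea prey taxa, individual
diets p_i ~ Dirichlet(c·q0). The concentration c is the specialization
knob (E[PSi] is monotone in c); defaults c_female = 4 < c_male = 8 with a
×2 male multiplier in summer/fall plant the female-more-specialist
contrast and the male late-season generalist shift that the analysis stack
is designed to detect. Hard-part juvenile fractions are Beta(2,2) at month
scope (70% availability) with season-scope fallbacks.

What the generator does *not* emulate: amplification bias among taxa,
chimeras, spatial movement between haul-outs, within-individual diet
autocorrelation, and any relation between read depth and diet. Passing
recovery tests therefore demonstrate that the estimators invert their own
generative assumptions at realistic sizes — not that metabarcoding
proportions are unbiased measures of a wild diet.

## Problem sizes used in the test suite

Property checks run at: bootstrap coverage over 500 datasets of n = 100
(R = 2,000); false-negative recovery at 100,000 simulated males per
dropout level {0.02, 0.05, 0.1}; PSi-vs-concentration monotonicity at
2,000 Monte Carlo replicates per c ∈ {1, 5, 25, 125} (K = 10, N = 20);
mixed-model interaction recovery over 100 replicates of n = 2,000 with a
planted 0.8 logit-scale Sex × late-month shift; variance-component
recovery at n = 4,000. These sizes are the package's chosen study
conditions and are fixed by seeds.

## Known limitations

- The shipped habitat annotation (benthic/demersal/pelagic per taxon) is
  an illustrative starter table, not an authoritative classification.
- The printed source tables the fixtures reproduce are internally
  inconsistent (their group sizes total 46 scats fewer than the sexed-scat
  table; see `reconciled_group_sizes`), so a handful of published summary
  statistics cannot be recovered exactly from print.
- Read proportions measure "biomass specialization": similar proportions
  can arise from few large or many small prey, so PSi here does not count
  independent capture decisions.
- Exact permutation p-values enumerate all n! rank orders and are only
  used for n ≤ 10.
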