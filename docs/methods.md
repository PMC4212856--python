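# Methods

This note records the models, estimators, numerical choices and known
limitations behind `aflpop`. Notation: a biallelic dominant locus has
null-allele frequency `q`; the band-absence phenotype frequency is
`x = q² + F q(1−q)` for an individual with inbreeding coefficient `F`
(`x = q²` under Hardy–Weinberg); `p = 1 − x` is the band-presence frequency.

## Data model and filtering

Input is a binary individuals × loci matrix (1 band present, 0 absent,
`?` missing) plus a sample table assigning each individual to a patch with
WGS84 coordinates; a patch is a single sampled point, so all its members
share coordinates and within-patch pair distances are exactly 0. All
frequency computations use non-missing entries only.

The locus filter retains loci whose band-presence frequency f satisfies
`lower < f < upper` (defaults 0.03/0.97, strict inequalities). Loci near
fixation carry almost no information for any downstream estimator and are
the typical product of scoring artefacts in fingerprint data.

Geographic distances are great-circle (haversine) with the IUGG mean Earth
radius 6371.0088 km, no projection: over a ~300 km extent the spherical
error is far below the patch-position uncertainty.

## Bayesian allele frequencies

With a Beta(a, b) prior on the band-absence frequency x and `n₀` absences
among `n` individuals, the posterior is Beta(a+n₀, b+n−n₀) and the
null-allele frequency is reported as the posterior mean of √x,

    q̂ = B(a+n₀+½, b+n−n₀) / B(a+n₀, b+n−n₀),

computed via log beta functions. The non-uniform prior is moment-matched to
the across-locus spread of observed absence proportions (a = m(m(1−m)/v−1),
b = (1−m)(m(1−m)/v−1)), falling back to the uniform prior when the variance
is degenerate or over-dispersed; it is fitted per population, since the
frequency spectrum is what the prior is meant to encode.

Diversity per population: PLP is the fraction of loci with minor *allele*
frequency ≥ 0.05 (allele, not phenotype, following the convention of
dominant-marker diversity software); Nei's gene diversity per locus is
`2q̂(1−q̂)·2n/(2n−1)` and H_j is its across-locus mean with the across-locus
standard error.

F_ST is the Weir–Cockerham ANOVA moment estimator applied to the estimated
per-population allele frequencies, treated as if observed from 2n alleles
(the extra sampling noise of dominant-data estimation is *not* propagated —
a deliberate simplification, see Limitations). Loci combine as a ratio of
sums; negative estimates truncate to 0; the linearised form F_ST/(1−F_ST)
feeds the Mantel regression on ln(km).

## Kinship from dominant phenotypes

To first order in the kinship θ of a non-inbred pair,
cov(Y_i, Y_j) = 4θqp(1−p)/(1+q), so the multilocus estimator is

    θ̂_ij = Σ_l (Y_il − p_l)(Y_jl − p_l) / Σ_l 4 q_l p_l (1−p_l)/(1+q_l)

with reference frequencies estimated on the pooled sample and loci fixed in
the reference, or missing in either member, excluded pairwise. Exactness and
bias are established by enumeration over Jacquard identity modes: the
estimator is exactly unbiased for classes without a double-IBD mode
(unrelated, parent–offspring), while full sibs have per-locus expectation
(1+3q)/(16q) — a documented positive bias that is asserted, not corrected.
An optional inbreeding-adjusted mode replaces p by 1 − q² − Fq(1−q) and the
weight by the matching first-order covariance 4(q(F+(1−F)q)² − x²); the
default is F = 0.

Per-pair, per-locus numerators are stored so that any derived statistic
(class means, regression slopes, Sp) can be jackknifed over loci by exact
leave-one-out recomputation: SE = √((L−1)/L · Σ_l (s₍₋l₎ − s̄)²).

## Spatial autocorrelation, Sp, Mantel

Distance classes are {0} (within patch), (0, w], then doubling intervals
with an open last class; defaults w = 10 km, six positive classes
({0, 10, 20, 40, 80, 160, >160} km). The null envelope permutes individual
locations (joint row/column permutation of the distance matrix against the
fixed kinship matrix; default 9,999 permutations, envelope at the
2.5th/97.5th percentiles per class).

The regression of θ̂ on ln(distance) uses all pairs at positive distance
(zero-distance pairs define f(1) but cannot enter a log regression);
Sp = −b₁/(1 − f(1)), with slope and Sp standard errors jackknifed over
loci. The Mantel statistic is the Pearson correlation of upper-triangle
entries, with a one-sided permutation p-value for positive association
(two-sided available); p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm).

## F_ST-outlier scan

The neutral null is the Balding–Nichols island draw: ancestral absence
frequency from the fitted prior mapped to the allele scale (q = √x), deme
frequencies Beta(q(1−F)/F, (1−q)(1−F)/F) — the infinite-island limit, which
is the natural biallelic analogue of the classical infinite-alleles null for
data that are intrinsically biallelic. Phenotypes are sampled binomially at
the observed per-deme sample sizes and re-estimated through the same
Bayesian machinery as the data, so estimator distortions cancel between
observed and simulated loci. Default cloud size 50,000 iterations.

Calibration: the trimmed mean (central 70%) of per-locus F_ST estimates is
strongly attenuated at small deme samples (Bayesian shrinkage plus the skew
of per-locus ratios) — at 15 demes of n = 9 a true F = 0.05 yields a
trimmed mean near 0.01 — but identically so for data and cloud. The scan
therefore solves by bisection for the simulation F_ST whose cloud trimmed
mean matches the observed trimmed mean; in simulations this recovers the
generating island-model F_ST. Each observed locus is then placed at its
empirical quantile among the k = 2,000 simulated points nearest in H_e
(k-nearest-neighbour conditioning; smooth and well-defined at the H_e
extremes, unlike fixed bins), with ties counted half. Quantile > 0.99 flags
directional selection, < 0.01 stabilizing; flagged loci are removed before
the spatial and inbreeding stages.

## Inbreeding MCMC

Model: Fᵢ ~ Beta(a, b) per individual, uniform priors on each q_l,
phenotypes Bernoulli with P(absence) = q_l² + Fᵢ q_l(1−q_l), missing cells
skipped. The sampler is Metropolis-within-Gibbs: per sweep, random-walk
logit-scale updates of all q_l (conditionally independent columns) and all
Fᵢ (rows), with proposal SDs adapted toward 20–45% acceptance during
burn-in only; defaults 100,000 sweeps after 10,000 burn-in, thinning 10.
Three further move types address the geometry of this posterior:

* **Reflection move** — proposes logit(Fᵢ) → −logit(Fᵢ) for a random half of
  the individuals each sweep. Low-concentration Beta priors (a = b = 0.1)
  are bimodal at 0 and 1 and a random walk rarely crosses the central
  valley; the reflection restores mixing across modes. (A deterministic
  always-accepted flip would alias with the thinning interval; hence the
  random half.)
* **Ridge move** — the likelihood depends on (q, F) only through the
  absence probabilities, which are invariant along q² + Fq(1−q) = const;
  per-locus frequencies can absorb any common shift of the Fᵢ. The ridge
  move proposes a common logit shift of all Fᵢ and deterministically
  re-solves each q_l to preserve the absence probabilities at the *mean* F,
  with the exact Jacobian of the induced map; this lets the chain traverse
  the nearly flat direction that single-site updates cannot.
* **Shape updates** — a and b are updated by log-scale random walks under
  uniform (0, 100] priors, so the supplied (a, b) are initial guesses and
  F = a/(a+b) is estimated rather than assumed. `update_shapes=False`
  freezes them, which is the correct mode for prior-recovery checks (a
  constant-likelihood run then reproduces Beta(a, b) exactly; verified by a
  Kolmogorov–Smirnov test, and the full sampler matches brute-force grid
  integration of a tiny posterior to three decimals).

Reported: F as the posterior mean of the sweep-wise mean of the Fᵢ, with
central 95% credible interval; per-individual summaries; mean and SD of the
data log-likelihood; acceptance rates. `prior_sensitivity` reruns the chain
from a = b ∈ {0.1, 1, 5} and flags disjoint credible intervals.

**Identifiability.** Because of the likelihood ridge above, the *location*
of mean F is informed only by across-individual heterogeneity of the Fᵢ
(the intercept q² and slope q(1−q) of each locus's dependence on Fᵢ are
tied through q). At realistic scales (≈150 individuals × 80 loci,
SD(Fᵢ) ≈ 0.1) the log-likelihood varies by only a few nats across
F ∈ [0.05, 0.5]: the honest posterior for mean F is very wide, and
prior-volume effects tilt it toward mid-range values. Point estimates of
mean inbreeding from dominant phenotypes alone should therefore be read
with caution; the prior-sensitivity harness and the reported credible
interval are the meaningful outputs. With shapes held fixed the posterior
of mean(Fᵢ) collapses onto the prior of the mean of n i.i.d. Beta(a, b)
draws regardless of the data — the strongest argument for estimating the
shapes.

## Synthetic data

Generators emulate sporocarp-style sampling: few individuals per patch,
~15 patches over a 300 × 300 km square mapped to WGS84 around 50°N.

* `gen_unstructured` — one Hardy–Weinberg pool, Beta-distributed q (default
  Beta(1.5, 1.5): most loci informative, some near fixation), random patch
  placement. The null for all permutation and type-I-error checks.
* `gen_island` — Balding–Nichols deme frequencies around U(0.1, 0.9)
  ancestral values at a target F_ST; calibration oracle for the F_ST
  estimator and the outlier scan.
* `gen_related_pairs` — founders from population frequencies, relatives by
  gamete transmission; pedigree kinship 0 / 0.25 / 0.25 / 0.5 for
  unrelated / parent–offspring / full-sib / self recorded as truth.
* `gen_inbred` — Fᵢ ~ Beta with mean `f_mean` and concentration `f_shape`
  (defaults 0.15 and 10, i.e. Beta(1.5, 8.5): a unimodal distribution with
  most individuals mildly inbred, SD ≈ 0.11); absence probability
  q² + Fᵢq(1−q).
* `gen_ibd_landscape` — forward-time frequency simulation on a torus
  lattice of demes: binomial drift over 2N alleles, then a fraction m of
  each deme's pool replaced by the mean of its four neighbours (discrete
  stepping-stone; tractable truth with the kinship-vs-ln(distance) decay
  the Sp analysis assumes). `m = 1` is interpreted as unrestricted
  dispersal — the migrant pool is the lattice-wide mean — giving a true
  panmictic control; migration follows drift, so at m = 1 sampled
  individuals draw from the fully mixed pool. Truth records the sampled
  demes' final frequencies (full lattice histories are large and
  recomputable from the seed).

What the generators do *not* emulate: genotyping error and band homoplasy,
linkage, selection, continuous-space dispersal, and temporal sampling.
Passing tests demonstrate estimator correctness under the stated models,
not robustness to these real-data complications.

## Problem sizes and numerical choices

Statistical checks run at the following sizes (chosen to keep Monte-Carlo
error comfortably below the tolerances they assert): kinship calibration
10,000 pairs × 100 loci; F_ST recovery 10 demes × 30 × 200 loci; Mantel
size 1,000 null replicates at 199 permutations (the p < 0.05 threshold is
exact at 199); envelope coverage 200 replicates of 100 × 100 at 999
permutations; outlier false-positive rate three 200-locus datasets with
5,000-iteration clouds; inbreeding recovery 20 chains of 20,000 sweeps on
150 × 80 datasets; landscape detection 20 positive and 20 panmictic
replicates. Chains are deterministic given (dataset, spec): identical seeds
give bit-identical records. Log-likelihoods floor probabilities at 1e-300;
logistic values are clipped to [1e-15, 1−1e-15]; fixed loci (q ∈ {0, 1})
are excluded from kinship sums; pairs with fewer than 10 usable loci are
flagged.

## Known limitations

* Dominant-data uncertainty in q̂ is not propagated into F_ST or kinship
  weights (moment-style treatment); F_ST recovery is accurate at the tested
  designs but the estimator inherits a small upward pull from estimation
  noise partially offset by prior shrinkage.
* Mean inbreeding is weakly identified from dominant phenotypes (see
  above); credible intervals are honest but wide, and mid-range tilt is
  expected at low Fᵢ heterogeneity.
* The full-sib kinship bias is documented, not corrected.
* The outlier scan's null is biallelic Balding–Nichols, a simplification of
  classical infinite-alleles nulls; its calibration is validated by
  false-positive rate, not by matching any particular legacy software.
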