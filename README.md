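# aflpop

Population-genetic analysis of **dominant presence/absence markers** (AFLPs
and similar fingerprints), built for studies of fine-scale spatial genetic
structure in patchily distributed organisms — the motivating case being
fungivorous beetles sampled from individual fungus sporocarps scattered over
a few hundred kilometres.

A dominant biallelic locus is observed only as band presence (1) or absence
(0): band absence is the homozygous null genotype, so with null-allele
frequency *q* the absence phenotype has frequency *q²* under Hardy–Weinberg
and allele frequencies must be *inferred*, not counted. Everything in this
package flows from that constraint.

## What it computes

| Stage | Statistic | Module |
|---|---|---|
| Allele frequencies | posterior mean of √x under Beta prior on the absence frequency x: q̂ = B(a+n₀+½, b+n−n₀)/B(a+n₀, b+n−n₀) | `allele_freq` |
| Diversity | PLP (proportion of loci with minor allele frequency ≥ 5%), Nei's gene diversity H_j = 2q(1−q)·2n/(2n−1) | `allele_freq` |
| Differentiation | Weir–Cockerham moment F_ST (ratio of sums over loci), linearised F_ST/(1−F_ST) | `allele_freq` |
| Isolation by distance | Mantel permutation test of linearised F_ST vs ln(km) | `sgs` |
| Kinship | pairwise multilocus coefficient θ̂ᵢⱼ = Σ(Yᵢ−p)(Yⱼ−p) / Σ 4qp(1−p)/(1+q) | `kinship` |
| Spatial autocorrelation | distance-class correlogram ({0}, (0,10], …, doubling, >160 km), permutation envelope, jackknife-over-loci SE | `sgs` |
| Structure intensity | **Sp = −b₁/(1 − f(1))**, b₁ the slope of kinship on ln(distance), f(1) the within-patch mean kinship | `sgs` |
| Neutrality scan | FDist-style F_ST-outlier test against a Balding–Nichols island-model null conditional on H_e (0.99/0.01 quantile cutoffs) | `outliers` |
| Inbreeding | Metropolis-within-Gibbs MCMC for individual Fᵢ ~ Beta(a,b) with P(absence) = q² + Fᵢq(1−q) | `inbreeding` |
| Synthetic data | seeded generators with known truth: panmixia, Balding–Nichols islands, pedigree pairs, beta-inbred samples, forward-time stepping-stone landscapes | `simulate` |

The `aflpop` CLI exposes each stage (`simulate`, `diversity`, `fst`,
`mantel`, `sgs`, `outliers`, `inbreeding`) and a full pipeline (`all`) that
runs them in the standard order, removing outlier-flagged loci before the
spatial and inbreeding stages.

## Worked example

Simulate an isolation-by-distance landscape (stepping-stone lattice,
migration rate 0.01, 200 generations) and run the spatial analysis:

```bash
aflpop simulate --generator ibd_landscape --seed 1 \
    -p grid=20 -p N_deme=50 -p m=0.01 -p generations=200 -p L=100 --out sim1
aflpop sgs sim1/genotypes.tsv sim1/samples.tsv --out sgs1 --n-perm 999 --seed 1
```

which prints

```
wrote 120 individuals x 100 loci to sim1
b1 = -0.00173 (SE 0.00492); f1 = 0.2841; Sp = 0.00242
```

Read: within-patch pairs share kinship f(1) ≈ 0.284 — very strong local
structure, as expected when lattice demes drift at Nm = 1 — while kinship
between patches declines only gently with ln(distance) (b₁ ≈ −0.0017, within
its jackknife SE here: at this migration rate differentiation is mostly
local, and the between-patch decay is shallow relative to across-locus
noise). The first-class excess, not the slope, carries the detection — the
`correlogram.tsv` written alongside holds the per-class means, pair counts,
jackknife SEs and the 95% permutation envelope, and the first class sits far
above it. Under panmixia (`-p m=1`) the same pipeline yields a flat profile
inside the envelope.

For comparison with published beetle data: a slope of −0.0015 with
within-sporocarp kinship 0.0386 gives Sp = 0.0015/(1 − 0.0386) = 0.0016 —
an order of magnitude weaker structure than the strong-drift simulation
above.

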