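# Methods

## The quantitative-genetic model

Log-transformed flight initiation distance (FID, meters; natural log) is
treated as a Gaussian trait

y_i = μ + β_hab·1[urban_i] + β_sex·1[female_i] + a_i + e_i,

where a is an additive genetic value with Cov(a) = **A** σ²_A (**A** the
numerator relationship matrix of the pedigree) and e ~ N(0, σ²_R) is a
residual. Heritability is h² = σ²_A / (σ²_A + σ²_R); total phenotypic
variance is V_P = σ²_A + σ²_R because year and permanent-environment terms
are deliberately absent (FID is highly repeatable across a bird's life, so
one value — or the mean of repeated measures, averaged on the meter scale
before the log — represents an individual).

Two estimators are implemented.

**Parent–offspring regression.** Offspring are grouped into full-sib broods
keyed by the (sire, dam) couple; the brood value is the mean log-FID of the
measured sibs (pseudo-replication immunity: duplicating sibs changes
nothing). h² is the OLS slope on the midparent value, or 2b/(1 + r) on a
single parent, where r is the phenotypic correlation between mates:
assortative mating inflates a single parent's predictive value by (1 + r)
but cancels out of the midparent regression, whose predictor variance grows
by the same factor. The SE of the corrected estimate is scaled by the same
2/(1 + r) factor, since the estimator is linear in the slope. Broods enter
unweighted regardless of size. Estimates are compared with
z = (x_i − x_j)/√(SE_i² + SE_j²) and two-sided normal p-values; a second
"reported" pair (z rounded to 2 decimals, p computed from the rounded z and
rounded to 4) mirrors the convention used in published tables of this
analysis, which is why both are exposed.

**Animal model.** A Gibbs sampler over (β, a, σ²_A, σ²_R) with a flat prior
on β and independent scaled inverse-chi-square priors on both variances
(scale V = 1, degrees of belief ν = 0.02 — the univariate inverse-Wishart
convention of the mixed-model MCMC packages; effectively flat). Full
conditionals: β Gaussian; the breeding-value block jointly Gaussian from the
mixed-model equations; σ²_A ~ scaled-inv-χ²(ν + q, (a'A⁻¹a + νV)/(ν + q))
with q the pedigree size; σ²_R analogously from the residual sum of squares.

*Numerics.* The joint breeding-value draw is performed in a whitened
eigenbasis: with **A** = **LL**' (Cholesky) and **W** the phenotyped rows of
**L**, write a = **LQ**u where **Q** diagonalises **W**'**W**. The full
conditional of u is then diagonal and a'A⁻¹a = u'u, so one sweep costs O(q)
after a single O(q³) setup — an exact reparameterisation with the same
stationary distribution as the usual sparse-solve update, chosen because the
recovery experiments need a million total iterations in minutes. The
trade-off is the dense O(q²) setup memory, fine up to a few thousand
individuals (the intended scale); very large pedigrees would want the sparse
route. The residual sum of squares is accumulated from precomputed inner
products; the float64 cancellation error is ~1e-13 relative at this scale.

The default chain matches the published analysis (1,000,000 iterations,
10,000 burn-in, thin 200); `AnimalModelSpec.desk()` scales it to
50,000/5,000/50 for the simulation experiments, which the diagnostics justify:
effective sample sizes of the ~900 stored draws are typically >750, and the
prior-sensitivity test (V ∈ {0.5, 1, 2}) moves the posterior mean h² by
less than 0.05. Posterior summaries: mean and Gaussian-KDE mode of the h²
draws (the source analysis does not say which it reports, so both are
given), shortest-interval (HPD) 95% credible intervals (equal-tailed
available via flag), a fixed effect is "significant" when its HPD excludes
zero, and effective sample size uses Geyer's initial-positive-sequence
estimator (a constant chain reports ESS 0 with a warning).

## Pedigree machinery

Pedigrees are validated (unique ids, no self-parentage or cycles, referenced
parents present, an id never used as both sire and dam, declared sexes
consistent with parental roles) and topologically sorted with input order
preserved among ties. Founders — both parents unknown — are assumed
unrelated and non-inbred; individuals with exactly one known parent are
allowed (unringed mates identified through their offspring). Inbreeding
coefficients come from a memoised kinship recursion; **A** from the tabular
method (dense, intended for ≤ ~5,000 individuals); **A**⁻¹ directly from
Henderson's rules with inbreeding, d_i = 0.5 − 0.25(F_sire + F_dam), the
unknown-parent terms dropped (founder d = 1, one known parent
0.75 − 0.25F). The three routes are mutually checking: diag(**A**) − 1 must
equal the recursion's F exactly, and **A**⁻¹**A** = **I**; the test suite
additionally rebuilds **A** by brute-force path counting.

## The synthetic population

The generator emulates the study design that motivated the package: two
habitats, three non-overlapping generations, FID measured once per bird.
Because mating depends on the phenotype, pedigree, breeding values and
phenotypes are generated together, generation by generation; a growing
relationship matrix supplies parental inbreeding for the Mendelian sampling
variance 0.5·V_A·(1 − 0.5(F_s + F_d)). Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| founders per habitat | 140 | with mean brood 2.8 yields ~1,200 individuals over 3 generations, the published pedigree scale |
| h²_true | 0.43 | the published animal-model estimate |
| V_P of log-FID | 1.0 | not published; free knob, order-of-magnitude of log-scale spreads |
| μ (rural male) | 3.4 | exp(3.4) ≈ 30 m, the rural median FID |
| β_habitat (urban) | −0.42 | published fixed effect |
| β_sex (female) | +0.06 | published fixed effect |
| mate_r | urban 0.61, rural 0.72 | the *within-habitat* mate correlations; the pooled 0.78 mixes the two habitat clouds and would overstate within-habitat assortment, and the generator only pairs within habitat |
| philopatry | 1.0 | owls breed in their natal habitat |
| brood size | Poisson(2.8) capped at 8 | unspecified in the source; Poisson is the neutral choice |

Mates are matched by ranking females on phenotype against a male latent
score ρz + √(1−ρ²)ε with ρ set to the target correlation; rank matching of
Gaussian samples is nearly comonotone, so the realised Pearson r of pairs
approaches the target (verified to ±0.05 over 50 replicates of 500 pairs).
Assortative mating acts on the phenotype, not the breeding value, matching
how mate correlations are measured in the field.

What the generator does **not** emulate: overlapping generations and
survival, dispersal distance, extra-pair paternity (social = genetic
parents), founder relatedness, selection on FID, non-additive variance, and
measurement error beyond the optional repeated-measures mode (within-bird
noise at repeatability 0.9). Passing recovery tests therefore demonstrate
estimator correctness under the stated generative model, not robustness to
those field realities. One deliberate consequence of phenotypic assortative
mating: gametic-phase disequilibrium inflates realised V_A slightly in
generations 1–2, so whole-population regression estimates run a few
hundredths above h²_true = 0.43 while the animal model, which pools
information across generations through the pedigree, centres on it (mean
posterior-mean h² 0.4315 over the 20-replicate recovery experiment).

## Experiment sizes

Simulation experiments are sized to be decisive yet desk-scale: the
relationship-matrix oracle sweep uses 100 random pedigrees of ≤ 30
individuals (path enumeration is exponential in depth); the exact-likelihood
cross-check uses a ~45-individual pedigree, where the dense grid over
h² ∈ {0.01, …, 0.99} is exact and the 200,000-iteration chain makes the KDE
mode stable; parameter recovery runs 20 replicates of the full ~1,200-bird
design with the desk chain; estimator calibration averages 100 seeds of
~400-brood two-generation designs at h² ∈ {0, 0.6, 1} (two generations so
the midparent slope estimates the founder h² without the assortative-mating
drift described above).

## External data

Raw parent–offspring FID values from the field study are distributed as the
article's supplementary material and are not bundled here. The reader
(`read_parent_offspring`) accepts a long-format CSV — columns `brood`,
`habitat`, `father_fid`, `mother_fid`, `offspring_fid`, one row per measured
offspring, parent cells empty when unmeasured — and the corresponding
acceptance test documents the expected estimates (midparent h² ≈ 0.64 for
all birds; mother–offspring h² ≈ 0.63 with r = 0.78); it fails until that
file is supplied at `data/supplementary_s1.csv`.

## Known limitations

- Dense **A** (and the O(q³) sampler setup) caps practical pedigree size at
  a few thousand; the published study scale (1,265) is comfortably inside.
- The KDE posterior mode is boundary-biased when h² piles near 0 or 1; at
  very small n the marginal posterior mode can legitimately sit ~0.1 from
  the profile MLE even with a correct sampler.
- Single chains only; ESS and the prior-sensitivity check stand in for
  multi-chain convergence diagnostics.
- The z comparison treats estimates as independent Gaussians, which is the
  published convention; rural/urban vs "all" comparisons share data and are
  therefore conservative only in that convention's sense.
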