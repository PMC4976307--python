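# owlfid — heritability of the fear of humans from pedigree data

`owlfid` estimates the heritability of flight initiation distance (FID) — the
distance at which a bird flees an approaching human, a standard measure of
fear of humans — in a two-habitat (urban/rural) population such as the
burrowing owl (*Athene cunicularia*). It implements the two classical routes
to h² and everything needed to exercise them without field data:

- **Parent–offspring regression** on log-FID: h² is the slope of the
  midoffspring-on-midparent regression, or twice the single-parent slope.
  Full sibs are averaged per brood to avoid pseudo-replication, and because
  mates pair assortatively on FID, single-parent estimates are corrected by
  the factor (1 + *r*), with *r* the phenotypic correlation between mates:
  h² = 2*b*/(1 + *r*).
- **Pairwise comparison** of estimates via z = (x_i − x_j)/√(SE_i² + SE_j²)
  with two-sided normal p-values (both raw and reported-rounding conventions).
- **A Bayesian animal model**: y = **Xβ** + **Za** + e with
  **a** ~ N(0, **A**σ²_A) over the full pedigree (**A** the numerator
  relationship matrix), e ~ N(0, **I**σ²_R), habitat and sex as fixed
  effects, and h² = σ²_A/(σ²_A + σ²_R). A Gibbs sampler with scaled
  inverse-chi-square priors (V = 1, ν = 0.02) yields the posterior of h²,
  summarised as mean, kernel-density mode and 95% HPD interval.
- **Pedigree machinery**: validation and topological sorting, inbreeding
  coefficients, the tabular-method **A**, and its sparse inverse by
  Henderson's rules.
- **A synthetic-population generator** reproducing the study design: a
  ~1,200-individual, 3-generation pedigree split across urban and rural
  habitats, log-FID phenotypes with h² = 0.43, an urban effect of −0.42 and a
  female effect of +0.06 on the log scale, within-habitat phenotypic
  assortative mating (urban r = 0.61, rural r = 0.72) and natal-habitat
  philopatry.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a simulated
population and write their tables under `results/`:

```sh
python analysis/01_simulate_population.py
python analysis/02_parent_offspring_heritability.py
python analysis/03_compare_heritabilities.py
python analysis/04_animal_model.py
```

`01` prints the population structure — here 1,126 owls over three
generations, realised mate correlations of 0.71 (rural) and 0.58 (urban),
median FIDs of 20 m (urban) vs 30 m (rural) and a habitat contrast of
F = 63.61 (p = 3.7e-15) on log-FID: urban birds let humans approach closer.
`02` reports the regression heritabilities per habitat, e.g. a midparent h²
of 0.49 ± 0.04 from 290 broods, with the (1 + r) correction bringing the
father/mother estimates into agreement (0.40–0.50). `03` shows that none of
the 12 pairwise z comparisons is significant — as expected when every
stratum shares one true h². `04` fits the animal model and prints

```
h2 = 0.43 (mode 0.43; 95% HPD 0.35-0.52) [simulated truth 0.43]
  intercept       +3.431  95% HPD (+3.272, +3.581) (excludes 0)
  habitat_urban   -0.476  95% HPD (-0.670, -0.281) (excludes 0)
  sex_female      -0.027  95% HPD (-0.143, +0.075)
```

i.e. the model separates the habitat fixed effect from the additive genetic
variance and recovers the simulated heritability of 0.43.

The same steps are available as a CLI (`owlfid simulate | amatrix |
po-regress | compare | animal-model | report`); every command writes a JSON
run log with its seed, configuration and package versions.

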