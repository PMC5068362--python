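# commdecomp

Disentangling environmental and spatial drivers of community structure —
taxonomic, functional and phylogenetic — with variation partitioning.

Community ecologists working across environmental gradients (here, the
motivating system is a Neotropical leaf-nosed bat metacommunity sampled at
~15 sites along a forest loss and fragmentation gradient) routinely need to
ask: is community structure shaped by the measured environment (landscape
composition and configuration), by spatial processes such as dispersal
limitation, or by spatially structured environment that confounds the two?
`commdecomp` implements the full inference chain for that question:

1. **Species distances** — weighted Gower dissimilarities on mixed
   binary/mensural trait tables (each niche axis receives equal total
   weight regardless of its attribute count), and cophenetic (patristic)
   distances from a Newick phylogeny, with least-squares-on-mass imputation
   of missing mensural traits within subfamilies and congener substitution
   for missing categorical traits and absent tree tips.
2. **Responses** — the Hellinger-transformed site-by-species matrix X̄_T
   (taxonomic structure), and the decomposition of functional/phylogenetic
   structure into a **composition** component (X̄_F, X̄_P: the per-site
   occurrence-weighted mean position on the leading principal-coordinate
   axis u of the species distance matrix) and a **dispersion** component
   (s_F, s_P: the per-site weighted spread around that mean), obtained by
   redistributing the sum of squares of the abundance-by-scores
   total-variation matrix into means and variances among sites.
3. **Spatial predictors** — Moran's eigenvector maps (MEM): minimum
   spanning tree + longest-edge-threshold connectivity, eigenvectors of the
   doubly centred connectivity matrix, with the large-positive-eigenvalue
   eigenvector as the default spatial predictor; Moran's I permutation
   tests for spatial autocorrelation.
4. **Variation partitioning** — full and partial redundancy analysis with
   Ezekiel-adjusted R², splitting each response's variation into

   ```
   [a] = adjR²(E+S) − adjR²(S)      unique environment
   [b] = adjR²(E) + adjR²(S) − adjR²(E+S)   spatially structured environment
   [c] = adjR²(E+S) − adjR²(E)      unique space
   [d] = 1 − adjR²(E+S)             residual
   ```

   with permutation tests for the unique fractions: response-row
   permutation for the taxonomic (matrix) response, and a double
   permutation for trait responses (site rows of the tested predictor
   block, and species entries of the score vector u with the decomposition
   recomputed each draw), combined conservatively as the maximum of the two
   p-values. Significance codes: `**` P ≤ 0.01, `*` 0.05 ≥ P > 0.01,
   `@` 0.10 ≥ P > 0.05. Negative adjusted fractions are reported raw and
   clamped to zero for display.

A synthetic metacommunity generator with four known assembly mechanisms
(environmental filtering, a niche-availability dispersion gradient, purely
spatial structure, and an exchangeable null) emulates the study design
(15 sites, 34 species, 27 trait attributes in 7 niche axes, 9 spatially
autocorrelated environmental columns) so every stage has parameter-recovery
and calibration tests without any external data.

## Worked example

Simulate a metacommunity whose trait dispersion tracks an environmentally
driven niche-availability score, then partition three responses:

```sh
commdecomp simulate -m dispersion_gradient --seed 42 --out demo
# (write a config.yaml pointing at the bundle's files, then)
commdecomp run -c demo/config.yaml --out demo/out
```

`demo/out/results.csv` from this run:

```
             response   provenance      a      b      c     d  adj_abc   p_a  sig_a
           dispersion   functional  0.647  0.099 -0.047 0.300    0.700 0.238
           dispersion phylogenetic -0.252  0.237 -0.228 1.242   -0.242 0.829
taxonomic_composition               0.396 -0.029  0.031 0.602    0.398 0.026  *
```

Reading the functional-dispersion row: environment and space together
explain 70% of the variation in the per-site spread of trait values
(`adj_abc`), almost all of it borne by the environment fractions
([a]+[b] = 0.75) rather than unique space ([c] ≤ 0) — the generating
mechanism recovered. The negative [c] and the phylogenetic fractions
illustrate that adjusted fractions can go below zero (interpreted as
zeros).  `demo/out/decomposition_summary.csv` shows where the trait
variation lives:

```
season   provenance  composition_share  dispersion_share
   dry   functional           0.032224          0.967776
   dry phylogenetic           0.031764          0.968236
```

97% of the total trait variation is within-site spread (dispersion), not
between-site mean shifts (composition) — communities everywhere share the
same weighted mean trait position and differ in how widely their members
spread around it, exactly what the dispersion-gradient mechanism encodes.

The same `commdecomp run` drives real data: abundance CSVs per season,
a 3-header-row trait CSV, a Newick tree (with an optional species→tip
substitution map), site coordinates, and one environmental predictor CSV
per focal scale; `commdecomp validate -c config.yaml` checks the bundle's
species/site consistency first.

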