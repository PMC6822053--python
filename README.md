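# responseguilds

Response-guild analysis of ecosystem-function resilience from long-term
species abundance time series.

## The problem

Predicting how ecosystem functions (food provision to higher trophic
levels, wildflower pollination, cultural value of wildlife) respond to
environmental change is hard when trait-by-trait approaches demand data
that rarely exist. An alternative is to let decades of population
monitoring speak for themselves: species whose year-to-year population
changes are synchronous have evidently responded to past environmental
drivers in the same way and can be grouped into **response guilds**. If
the species that dominate an ecosystem function are concentrated in one
guild, a single adverse driver can depress the whole function; if they
are spread across guilds, asynchrony buffers the aggregate (the
portfolio effect) and the function is resilient.

This package implements that analysis for anyone with (a) a species ×
year table of log abundance indices, (b) optionally a set of candidate
phylogenies, and (c) a species trait table. It was built around UK
butterfly monitoring data (54 species, 1976–2014) but is agnostic to
taxon.

## The method

1. **Dynamics distance.** Per species, standardize the log abundance
   index and difference it: Δ_t = x_t − x_{t−1}. For each species pair
   compute Pearson's r over complete pairs of observations and transform
   to d = 1 − r, so d = 0 is perfect synchrony, 1 independence, 2
   opposition.
2. **Response guilds.** Hierarchically cluster d (complete linkage by
   default) and cut the dendrogram at one or more resolutions (by height
   or by guild count k).
3. **Phylogenetic signal.** Average patristic distances over a set of
   candidate trees, trim both matrices to shared species, and run a
   permutation Mantel test against d — a positive correlation means
   responses to environmental change are heritable.
4. **Production functions.** Per-species function scores, each
   normalized to [0, 1] by the community maximum:
   relative density D = O·A / max(O·A); larval biomass B = D·L /
   max(D·L); wildflower pollination P = D·M / max(D·M); per-family
   pollination P_x = D·M·X / max(D·M·X) with X ∈ {0,1} flower
   visitation; cultural function C = Y / max(Y) over the public-survey
   top-18.
5. **Function–dynamics association.** Turn each score vector into a
   |z_i − z_j| distance matrix and Mantel-test it against d. One-tailed
   p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) with 9,999 permutations by
   default, plus species-bootstrap 95% confidence limits.

A synthetic-community module generates all three inputs with known
ground truth (guild structure, Brownian-heritable driver loadings,
clustered or dispersed function scores), so every stage is testable
without access to the original monitoring data.

## Worked example

`examples/03_phylogenetic_signal.py` simulates a community whose driver
loadings evolved by Brownian motion along a tree, then asks whether
population dynamics carry phylogenetic signal:

```
Mantel r = 0.738, one-tailed p = 0.0001 (9999 permutations)
bootstrap 95% limits: [0.652, 0.809]
```

r > 0 with p < 0.05: distantly related species have more dissimilar
dynamics, i.e. responses to environmental change are heritable — exactly
the structure the generator planted.

`examples/05_full_analysis.py` runs the whole pipeline on a neutral
("dispersed") synthetic community and prints the six-comparison
association table:

```
                    matrix2  mantel_r  p_value  ci_lower  ci_upper
                  phylogeny -0.014271   0.6755 -0.084738  0.091799
             larval_biomass -0.005605   0.5636 -0.085773  0.078694
          cultural_function -0.014946   0.6881 -0.090416  0.068181
        general_pollination  0.038164   0.1251 -0.051025  0.133379
   pollination_Brassicaceae  0.013214   0.4532 -0.037378  0.074971
pollination_Caryophyllaceae  0.026688   0.2407 -0.038680  0.120942
```

Large p-values throughout: functionally important species are not
clustered into any response guild, so all three functions look resilient
in this community — as they should, since the generator dispersed them.

The other examples cover simulation (`01`), guild recovery (`02`) and
production-function scoring against the published UK butterfly score
table that ships with the package (`04`). A thin CLI mirrors the
stages: `responseguilds simulate | dynamics | guilds | phylo |
functions | mantel | run`.

## Layout

- `src/responseguilds/` — `data_io`, `synthetic`, `dynamics`, `guilds`,
  `phylo`, `production`, `mantel`, `pipeline`, `cli`
- `docs/methods.md` — models, assumptions, parameter choices, numerics
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end acceptance suites
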