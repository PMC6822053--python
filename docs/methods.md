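# Methods

## Dynamics distance

Abundance inputs are national-scale collated indices on a log scale,
one row per species, one column per calendar year, with missing cells
allowed. Each series is z-scored over its observed years before
differencing. The z-score is a convention, not a substantive choice:
Pearson correlation is invariant to any per-species affine rescaling,
so only the published-data reproduction (not the statistics) would
depend on the exact standardization used upstream; this invariance is
asserted by a property test. Species with zero variance cannot be
standardized and are excluded with a warning.

Interannual changes Δ_t = x_t − x_{t−1} are labelled by the later year
(a 1976–2014 input yields changes 1977–2014). A change is missing iff
either source year is missing, so one missing year blanks two changes.

Pairwise Pearson correlations use complete pairs only. Pairs with fewer
than `min_pairs` overlapping changes (default 10; below that the
correlation is noise-dominated) are left undefined rather than
fabricated, and an undefined pair is a hard error at the clustering
stage — the user must either raise coverage or lower `min_pairs`
deliberately. The distance is d = 1 − r ∈ [0, 2] (0 synchony, 1
independence, 2 opposition), with the diagonal forced to 0.

## Response guilds

Agglomerative clustering on d, complete linkage by default (the default
of the standard hierarchical-clustering tool in R, which this pipeline
mirrors); single, average and Ward variants are accepted and recorded
in outputs. Species are sorted canonically before clustering so
equal-height merges resolve identically regardless of input order.
Dendrogram cuts are specified by height threshold or by guild count k;
k is the reproducible interface since published height thresholds for
multi-resolution guild tables are typically not reported. Guild labels
are renumbered 1..G in dendrogram leaf order, which makes nested cuts
visibly consistent across resolutions. The dendrogram is exported both
as a JSON linkage matrix and as Newick with branch lengths equal to
merge-height gaps.

Recovery of a known partition is scored by the adjusted Rand index
(1 = identical up to relabeling, ≈0 for random labels).

## Phylogenetic distances

Per tree, the patristic distance between two species is the sum of
branch lengths on the unique connecting path; the across-tree matrix is
the plain elementwise arithmetic mean (no tree weighting). The averaged
matrix need not be additive on any tree — it is treated purely as a
distance table. Zero-length branches are accepted; ultrametricity is
neither required nor checked, since tree sets are typically posterior
samples. Before comparison, both matrices are trimmed to the sorted
intersection of their species (at least 3 required).

## Production functions

All scores are ratios to the community maximum, hence unit-free, in
[0, 1], attaining 1 at the dominant species, and invariant to common
rescaling of any input:

- D = O·A / max(O·A): O = mean occupied 10-km squares, A = mean
  standardized survey count. Both mandatory.
- B = D·L / max(D·L): L = larval length in mm, a proxy for larval
  biomass up to a constant factor.
- P = D·M / max(D·M): M = mobility index; mobile, abundant species move
  more pollen between patches.
- P_x = D·M·X / max(D·M·X): X ∈ {0,1} records whether the species
  visits plant family x; the maximum is family-specific.
- C = Y / max(Y): Y = mean count in a mass-participation public survey,
  defined for the published top-N species (N defaults to 18, the length
  of the published list, and is configurable); all others score exactly
  0.

Missing required inputs (L for B, M for P and P_x) make a score
missing, never zero — zero is reserved for true zeros (non-visitors,
species outside the survey top-N). Normalization denominators are taken
over species with complete inputs.

For association testing a score vector is z-scored (sample sd, ddof=1)
over species with defined values and expanded to the pairwise matrix
f[i,j] = |z_i − z_j| (the one-dimensional Euclidean distance). Species
with missing scores are dropped listwise and reported.

The package ships a plain-text copy of the published standardized UK
butterfly score table (54 species; 8 without biomass scores). Cells
printed as "<0.001"/">0.001" are stored as the placeholder 0.0005 with
a qualifier flag; only their sign is meaningful and only counts/signs
are used in tests.

## Mantel test

Statistic: Pearson correlation of the strictly-lower triangles. The
classical cross-product form is a strictly increasing function of this
under joint row/column permutation of one matrix (permutation leaves
both triangles' means and variances unchanged), so the two forms give
identical permutation rankings and p-values; a test asserts the
identical ordering. One-tailed p (positive association, the default) is
(#{r_perm ≥ r_obs} + 1)/(n_perm + 1) — the +1 is the standard sampled-
permutation continuity correction. When n! ≤ n_perm the test switches
to exact enumeration of all n! relabelings (p = hits/n!). Ties at the
observed statistic count as hits, with a 1e-12 tolerance.

Confidence limits are 2.5/97.5 percentiles of the statistic over
species-level bootstrap resamples (default 500). Pairs formed by two
copies of the same resampled species are excluded from the resampled
triangle: such pairs are zero in both matrices by construction and
would otherwise bias the bootstrap correlation upward. The bootstrap
method is a package choice; published tables in this literature report
2.5%/97.5% limits without describing their construction.

Note that Mantel tests are anticonservative when both matrices carry
strong internal block structure; the type-I error test uses
unstructured matrices, and the no-heritability null simulation uses
rho = 0 dynamics for the same reason.

## Synthetic communities

The generator's defaults mirror the motivating study's scale: 54
species × 39 years (so 38 changes), 4 guilds, within-guild change
correlation rho = 0.5 (between the exemplar synchronous pair r ≈ 0.8
and unrelated pairs r ≈ 0), AR(1) density-dependence strength
phi = 0.3, 5% missing cells, 100 candidate trees around one generating
tree. Where the study conditions do not pin a value these were chosen
once as field-realistic and are not tuned.

- `guild_blocks`: Δ_i,t = √rho·e_g(t) + √(1−rho)·ε_i,t with iid
  standard-normal drivers e_g and noise ε. Expected change correlation
  is exactly rho within guilds and 0 between.
- `brownian_loadings`: a unit-rate pure-birth tree is simulated,
  rescaled to height 1 (scale-free comparisons), and a K = n_guilds
  loading vector evolves from 0 by Brownian motion along it; tip
  vectors are unit-normalized so the change correlation of two species
  equals the cosine similarity of their loadings — an analytic target.
  Close relatives therefore have higher expected synchrony: heritable
  responses. Species names are shuffled onto tree leaves so externally
  imposed structure (contiguous guild blocks) is independent of
  topology; the pure-birth process is also run one extra exponential
  waiting time past the last speciation so no two tips coincide.
- Abundance: x_t = (1−phi)·x_{t−1} + Δ_t, x_0 = 0. phi = 0 is a pure
  random walk; larger phi mean-reverts faster. Differencing inverts
  integration exactly at phi = 0.
- Missingness is completely at random, but each species' first two
  observations are protected so every series stays analyzable.
- Tree sets: each copy multiplies every branch by an independent
  lognormal factor with mean 1 (σ = tree_noise), so the expected
  patristic matrix equals the generating tree's and the average
  converges to it; noise 0 reproduces the tree exactly.
- Traits emulate published ranges (O up to thousands of squares, L ≈
  12–45 mm, lognormal mobility, survey counts for exactly top-N
  species; ~10% missing L and M). The "clustered" scenario concentrates
  the high-function species (large O·A, the survey counts, the
  visitation flags) in guild 1, planting a positive
  function–dynamics association; "dispersed" spreads them at random —
  the null.

What the generator does *not* emulate: temporal autocorrelation of the
environmental drivers, observation error in the indices, trends,
species interactions, or non-MCAR missingness. Passing tests show the
pipeline's statistics behave correctly under the stated model, not that
real monitoring data satisfy that model.

## Numerical and design choices

- Species keys are canonical binomials ("Genus epithet", single spaces,
  genus capitalized); matching across inputs is by canonical name, and
  unmatched species are dropped with a warning — mirroring the trimming
  of matrices to shared species.
- All randomness flows through explicit seeds; multi-test reports and
  the pipeline derive per-stage substreams from one root seed via seed
  sequences, so outputs are byte-identical across reruns (fixed float
  formatting, no timestamps in outputs).
- Test problem sizes (e.g. 199-permutation Mantel tests in simulation
  studies, 40-species communities, 10–50 trees) were chosen to keep the
  default suite fast while leaving each check statistically
  informative; the study-scale end-to-end test runs the full 9,999 ×
  6-comparison configuration.

## Known limitations

- The Mantel test inherits the field-standard caveats: low power
  against non-linear association and inflated type-I error under strong
  autocorrelation in both matrices.
- Listwise deletion of species with missing function scores (the
  published treatment is not stated); pairwise alternatives are not
  offered.
- Exact reproduction of the motivating study's tables requires its
  undeposited source data; this package reproduces the procedures and
  their structural properties.
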