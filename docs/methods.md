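# Methods

This note documents the models and procedures implemented in `mitogeodiv`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Sequence data model

An alignment is an ordered set of equal-length sequences over
`{A, C, G, T, -, N}`. `-` is an alignment gap, `N` is missing data (a locus
not sequenced for a specimen). Column coordinates are 0-based half-open
throughout. Input order is never re-sorted, so outputs diff cleanly across
runs. Ambiguous IUPAC codes other than `N` are rejected on input rather than
silently recoded; datasets containing them must be cleaned upstream.

**Gap elimination** removes every column in which at least one row carries a
gap. This is the "common core" reduction used for control-region fragments
whose flanks align poorly; no conservation- or flank-based column filtering
is attempted, because for this use case the gapped flanks are the only
columns that need removing and a literal rule is exactly reproducible.

**Concatenation** pads specimens absent from a partition with `N` across
that partition's columns, so a two-locus matrix can carry specimens with
only the first locus sequenced. Partition intervals are returned alongside
the merged alignment and slicing by them round-trips the inputs.

## Deduplication of repeat noninvasive samples

Without genotypes, two droppings from the same individual cannot be told
apart except by haplotype and location. The rule implemented: within each
class of bitwise-identical rows (`N` positions compare literally — no
mismatch tolerance is defensible without an error model), a greedy pass in
input order drops any sample lying strictly closer than `min_km` (default
1.0 km, beyond a water shrew's home range) to an already-kept sample of the
same haplotype. Ties at exactly `min_km` are kept. Distances are haversine
on a sphere of radius 6,371.0088 km; the sub-0.5% ellipsoidal error is
irrelevant at a 1-km threshold. Greedy first-kept-wins makes the result
deterministic; samples with distinct haplotypes are never dropped.

## Diversity estimators

* **p-distance**: differing sites / comparable sites, a site being
  comparable iff both characters are in `{A,C,G,T}` (pairwise deletion).
  A pair with zero comparable sites is an error, not a zero.
* **π**: mean pairwise p-distance over all n(n−1)/2 pairs. Pairwise deletion
  maximizes data use for the headline statistic.
* **θ_W** = S/(a_n·L) with complete deletion of any column containing a
  non-ACGT character, so S and L are counted on the same site set. π and
  θ_W therefore use different deletion rules by design.
* **Haplotype diversity**: n/(n−1)·(1 − Σ f_k²) over bitwise-identical
  classes.
* **Model distances**: JC69 = −(3/4)·ln(1 − 4p/3); K80 from the
  transition/transversion proportions P and Q via
  −½ln(1−2P−Q) − ¼ln(1−2Q). Saturated pairs (log argument ≤ 0) raise an
  error rather than returning infinity. Both are cross-checked against
  `ape::dist.dna` in the test suite.

Downstream analyses default to the uncorrected p-distance; JC69/K80 are
selectable by flag. At the divergences involved here (≈1%) the choice is
numerically immaterial, so the ambiguity is exposed as configuration rather
than decided silently.

## Moving-window diversity surface

For each sampling point, π of all samples of the **same phylogroup** within
`radius_km` (default 75 km; closed ball — a neighbor at exactly the radius
is included, and the center is always a member). Windows supported by fewer
than `min_samples` (default 5) are omitted, not zero-filled. Windows are
centered on sampling points, not on a raster grid; no interpolation is done.
The per-window π is computed by averaging a precomputed pairwise-distance
submatrix, which is numerically identical to running the π estimator per
window (asserted in tests). π is written to 4 decimals.

The phylogroup restriction is the load-bearing choice: in contact zones,
windows mixing clades ≈1% divergent would otherwise report inflated
diversity that reflects lineage mixing, not local polymorphism. The test
suite verifies both directions — restricted window π in simulated overlap
zones is statistically indistinguishable from the same group outside them,
while an unrestricted surface is significantly inflated there.

## One-way AMOVA

Excoffier–Smouse–Quattro method-of-moments on squared distances:

    SS_total  = (1/n) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    SS_among  = SS_total − SS_within
    σ²_within = MS_within
    σ²_among  = (MS_among − MS_within)/n̄,  n̄ = (n − Σ n_g²/n)/(k−1)
    Φ_ST      = σ²_among/(σ²_among + σ²_within)

Negative σ²_among is reported as computed (standard for method-of-moments
estimators); only the display helper clamps the percent to [0, 100].
Significance comes from `n_perm` label permutations with group sizes fixed,
using the unbiased estimator p = (1 + #{Φ* ≥ Φ})/(1 + n_perm); the default
is 999 permutations and a required seed, so p-values reproduce bit-exactly.
The decomposition is validated against `vegan::adonis2` (whose one-factor
SS partition is identical) to better than 6 significant digits, and the
permutation null's rejection rate at α = 0.05 is checked to sit in
[0.03, 0.07] over 500 simulated null datasets. The null is slightly
conservative when many haplotypes are identical (ties in Φ*), which is why
the calibration check simulates a diverse locus.

## SDM post-processing

Model fitting is out of scope; the package consumes continuous suitability
rasters. Rasters are single-band ESRI ASCII grids (a plain-text format that
round-trips the simple equal-angle grids used here); values in [0, 1] with
NaN as no-data in memory.

* **Predictor pruning**: greedy scan in input order (BIO variable
  numbering); a variable is dropped iff |Pearson r| ≥ threshold (default
  0.8) against any already-kept variable. Order-dependence is inherent to
  any greedy rule; fixing input order makes it deterministic and
  documented.
* **Percentile threshold**: the cutoff is the pct-th percentile (linear
  interpolation) of suitability values at occurrence localities — the
  "percentile training presence" convention; a flag switches to percentiles
  over all raster cells. Cells with suitability ≥ cutoff become 1. Raising
  pct never enlarges the predicted area.
* **Consensus**: cellwise sum of binary layers; a cell's value is the
  number of models predicting presence. No-data propagates.

## Synthetic data generator

The generator emulates the target study design: ~132 sequences of 752 bp
from two phylogroups on an Iberia-sized box (36–44° N, 9° W–3° E), group
ranges as longitude slices overlapping in contact bands (default 60 km
wide), ten river basins as longitude bands, and per-group within-basin
diversity defaulting to (0.004, 0.0015) — one more-diverse and one
less-diverse clade, inside the 0.0003–0.005 span the window map should
reproduce. The default among-basin variance fraction is 0.19 and the
default between-group sample divergence 0.0116.

Sites evolve independently under a uniform substitution scheme (a layer of
rate x substitutes a site with probability x, uniformly over the other
three bases). Layers compose multiplicatively in e = 1 − 4x/3, and two
lineages carrying independent layers xa, xb differ at a site with
probability P(xa,xb) = 1 − [(1−xa)(1−xb) + xa·xb/3]. Each sample is
root → group ancestor (rate g) → group×basin ancestor (rate q) → private
mutations (rate r). The three rates are solved numerically so that:

* the expected within-basin pairwise p-distance equals `within_theta`;
* the among-basin variance fraction of a one-way AMOVA equals
  `basin_effect`, using the exact identity f = (E[d²_b] − E[d²_w])/E[d²_b]
  with E[d²] = p² + p(1−p)/L (the differing-site count is Binomial(L, p),
  so the sampling variance of the p-distance is part of E[d²]);
* the expected p-distance between samples of different groups equals
  `between_group_div` — calibrated at the sample level, not the ancestor
  level, so the observable statistic is on target.

An optional hotspot bounding box multiplies the private rate (default ×2)
inside a region, creating a known high-diversity area for recovery tests.
Coordinates are uniform within each group's range; a single RNG stream per
dataset makes output bitwise reproducible from the seed.

**What this emulates and what it does not.** The star-shaped within-basin
genealogy makes every calibration exact and the AMOVA expectations
analytic, but it is not a coalescent: haplotype frequency spectra, linkage
of mutations along genealogies, and the n-dependence of θ_W under drift
are not reproduced. For that reason the π–θ_W consistency check in the
test suite uses msprime's neutral coalescent as the independent source of
equilibrium data rather than this generator. Passing tests demonstrate
correct arithmetic and faithful recovery of planted spatial/hierarchical
structure; they do not validate demographic realism, rate heterogeneity,
or selection — none of which the downstream statistics assume.

Suitability rasters are generated as a shared Gaussian optimum plus
smoothed model-specific noise, clipped to [0, 1], with a one-cell no-data
border; presence points are drawn proportionally to the true field.

## Problem sizes used in validation

Estimator oracles run on 120 random alignments (n ≤ 10, L ≤ 50) against
exhaustive enumeration at 1e−12. AMOVA agreement uses 20 random Euclidean
instances; the null calibration uses 500 datasets of 30 × 752 bp with 199
permutations. Hotspot recovery uses 100 landscapes of 400 samples
(within-basin diversity 0.004, doubled inside the hotspot); the among-basin
recovery uses 100 datasets of 100 samples; contact-zone non-inflation pools
10 datasets of 300 samples. These sizes give each check stable statistical
power while keeping the default suite fast on a laptop.

## Known limitations

* Distances assume a spherical Earth; no projected CRS support.
* AMOVA is single-level only (no hierarchical designs, no pairwise Φ_ST
  matrices between basins).
* The window surface is point-supported; no kriging or gridded
  interpolation is provided.
* The "θ estimator" diversity-map variant is implemented (`watterson_theta`)
  but the mapped statistic defaults to π.
* Raster I/O is limited to single-band ESRI ASCII grids.
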