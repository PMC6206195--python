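# mitogeodiv

Spatial mitochondrial phylogeography for desk-scale datasets: a few hundred
georeferenced mitochondrial sequences (e.g. cytochrome *b* and a control-region
fragment from noninvasive riverine sampling of a semi-aquatic mammal), a sample
table with coordinates, river basins and phylogroup assignments, and a handful
of habitat-suitability rasters from species distribution models.

The package is aimed at phylogeographers who have already inferred phylogroup
membership (from ML/Bayesian trees) and want the downstream spatial analyses to
be scripted, tested and reproducible:

- **Alignment handling** — FASTA I/O over `{A,C,G,T,-,N}`, elimination of every
  column containing a gap (the common-core reduction used for poorly aligning
  control-region flanks), and concatenation of loci with `N` padding for
  specimens sequenced at only one locus.
- **Repeat-sample deduplication** — noninvasive samples with an identical
  haplotype are collapsed unless collected at least 1 km apart (farther than a
  water shrew's home range), using haversine great-circle distances.
- **Diversity estimators** — nucleotide diversity
  π = (2 / n(n−1)) Σ_{i<j} d_ij with d_ij the pairwise p-distance under
  pairwise deletion; Watterson's θ_W = S / (a_n L) under complete deletion;
  haplotype diversity H = n/(n−1)·(1 − Σ f_k²); and p / JC69 / K80 distance
  matrices.
- **Moving-window diversity mapping** — for each sampling point, π of the
  same-phylogroup samples within a 75-km radius, reported only when supported
  by ≥ 5 samples. The phylogroup restriction keeps window π from being
  inflated in contact zones where divergent clades co-occur.
- **One-way AMOVA** — Excoffier–Smouse–Quattro decomposition of squared
  pairwise distances with river basin as the single factor: variance
  components σ²_among and σ²_within, Φ_ST = σ²_among/(σ²_among+σ²_within),
  percent variation among basins, and a label-permutation p-value.
- **SDM post-processing** — greedy pruning of predictors correlated above a
  Pearson |r| cutoff, percentile thresholds over training-presence
  suitabilities, and cellwise multi-model consensus rasters (ESRI ASCII grids).
- **Synthetic data** — a calibrated generator that reproduces this study
  design (two divergent phylogroups with narrow contact bands on an
  Iberia-sized landscape, longitude-band basins, a tunable among-basin
  variance fraction) with exact closed-form expectations, so every stage is
  testable end to end without any downloads.

## Worked example

```python
from mitogeodiv import (
    SimConfig, simulate_dataset, dedup_by_haplotype,
    diversity_surface, amova_oneway, between_group_p_distance,
)
from mitogeodiv.diversity_stats import p_distance_matrix

cfg = SimConfig(seed=1)                      # 132 samples, phylogroups A and B
aln, samples = simulate_dataset(cfg)
kept, dropped = dedup_by_haplotype(samples, aln, min_km=1.0)

rows = {g: [aln.row(s.seq_name) for s in kept if s.phylogroup == g] for g in "AB"}
print(f"between-lineage p-distance: {100 * between_group_p_distance(rows['A'], rows['B']):.2f}%")

points = diversity_surface(kept, aln, radius_km=75.0, min_samples=5)
pis = [p.pi for p in points]
print(f"window pi range: {min(pis):.4f} - {max(pis):.4f} over {len(points)} windows")

group_a = [s for s in kept if s.phylogroup == "A"]
d = p_distance_matrix([aln.row(s.seq_name) for s in group_a])
res = amova_oneway(d, [s.basin for s in group_a], n_perm=999, seed=2)
print(f"AMOVA: {res.pct_among:.1f}% of variation among basins (p = {res.p_value:.3f})")
```

prints

```
between-lineage p-distance: 1.06%
window pi range: 0.0011 - 0.0064 over 24 windows
AMOVA: 17.7% of variation among basins (p = 0.001)
```

The between-lineage divergence fluctuates around its configured expectation
(1.16%) from seed to seed; the window-π range spans the low diversity of the
B phylogroup and the higher diversity of A; and the within-phylogroup AMOVA
recovers the generator's among-basin variance fraction (19%).

The same stages are available from the shell:

```bash
mitogeodiv simulate --seed 1 --out-dir data/
mitogeodiv pipeline --config config.yaml --out-dir results/
```

`pipeline` runs dedup → gap-strip/concatenate → distances → diversity map →
AMOVA → SDM consensus and writes a `manifest.json` listing every output with
the parameters and seed used; reruns are bitwise identical.

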