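# florahom

Quantifying the floristic homogenization of regional floras caused by
naturalized alien plants.

When an alien plant species establishes self-sustaining wild populations
(naturalizes) in a region, it changes how similar that region's flora is to
every other region's flora. `florahom` measures that change — taxonomically
and phylogenetically — for every pair of regions in a checklist compilation,
and relates it to geographic distance, climatic distance and administrative
ties (same country, colonial or dependency links). It is aimed at
macroecologists and biogeographers working with species-by-region checklist
data (native + naturalized status), a region registry with centroids, a
dated phylogeny in Newick, and per-region bioclimatic summaries.

## The indices

For two regions with `a` shared species and `b`, `c` species unique to each,
taxonomic similarity uses the richness-insensitive Simpson index

```
SimTax = 1 − min(b, c) / (a + min(b, c))
```

(the Sørensen index `2a / (2a + b + c)`, which is additionally sensitive to
nestedness, is available throughout as an alternative). The phylogenetic
analogue replaces species counts with summed branch lengths `A`, `B`, `C` of
the rooted subtrees spanned by each regional flora:

```
SimPhyl = 1 − min(B, C) / (A + min(B, C))
```

The homogenization index for a pair is the log-response ratio of the
similarity of the combined (native + naturalized) floras to the similarity
of the native floras alone,

```
H = ln((Sim_combined + 0.001) / (Sim_native + 0.001))
```

with a small offset guarding against division by zero. `H > 0` means the
naturalizations made the two floras more alike (homogenization), `H < 0`
less alike (differentiation).

Around these kernels the package provides:

- checklist reading and cleaning (infraspecific collapse, hybrid removal,
  native/naturalized status-conflict resolution) — `florahom.checklists`
- Newick I/O, grafting of missing species into their genus or family, and a
  fast branch-incidence index — `florahom.phylo`
- pairwise similarity tables with naturalization-scenario filters
  ("native to one", "non-native to both") — `florahom.similarity`
- great-circle and PCA-based climatic distance matrices — `florahom.geoclim`
- log-link binomial distance-decay fits and halving distances —
  `florahom.decay`
- multiple regression on distance matrices (MRM) with a simultaneous
  row/column permutation null, and decay-slope contrasts across
  administrative categories — `florahom.mrm`
- per-region summaries (mean H, donor score, endemism, Faith PD) and the
  region-level regression with a spatial autocovariate — `florahom.regions`
- a fully seeded synthetic world generator with known ground truth —
  `florahom.synth`
- an end-to-end pipeline and CLI — `florahom.pipeline`, `florahom` command

## Worked example

The similarity kernels on a four-tip toy tree:

```python
import florahom as fh

tree = fh.parse_newick("((s1:1,s2:1):1,(s3:1,s4:1):1);")
a, b = {"s1", "s3"}, {"s1", "s4"}

fh.simpson_tax(a, b)            # 0.5     (a=1 shared, b=c=1 unique)
fh.branch_overlap(tree, a, b)   # BranchOverlap(A=3.0, B=1.0, C=1.0)
fh.simpson_phylo(tree, a, b)    # 0.75    = 1 - 1/(3+1)
fh.homogenization_index(0.75, 0.5)  # 0.40479955067927  (homogenization)
```

A full run on a simulated 200-region world:

```bash
florahom all --seed 4 --outdir out --n-perm 19
```

prints (abridged):

```
regions: 200; species: 3000
region pairs: 19900 (0 flagged)
taxonomic: homogenized pairs 10680/19900 (53.7%), differentiated 6854 (34.4%), median change in similarity +9.6%
phylogenetic: homogenized pairs 15705/19900 (78.9%), differentiated 4195 (21.1%), median change in similarity +7.3%
halving distance (taxonomic, native): 1745 km
halving distance (taxonomic, combined): 1926 km
halving distance (phylogenetic, native): 6536 km
halving distance (phylogenetic, combined): 7035 km
```

Reading the output: a majority of region pairs became more similar once
naturalized species were added to the native floras; the "halving distance"
is the distance at which the fitted exponential decay predicts similarity to
have dropped by half, and it grows when naturalized species are included —
the naturalizations flatten the natural distance decay of similarity. The
generating world used a native halving scale of 1800 km, which the fit
recovers (1745 km). The `out/` directory holds the pair table, distance
matrices, decay fits, MRM coefficient tables, region summaries and a JSON
manifest with the configuration hash and row counts; rerunning with the same
seed reproduces them bit for bit.

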