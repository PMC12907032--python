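# halo

Null-model analysis of sediment microbial communities along salinity
gradients.

Coastal lagoons and other salinising systems impose steep environmental
filters on their sediment microbiota. Understanding how a community is
assembled along such a gradient — which taxa are salinity *specialists*
versus *generalists*, whether composition is governed by deterministic
selection or stochastic dispersal and drift, and how co-occurrence
structure reorganises under osmotic stress — requires a chain of
null-model statistics rather than any single index. `halo` implements
that chain as a tested, reusable Python library and command-line tool
for microbial ecologists working with amplicon-derived count tables.

## What it computes

Given a taxa × samples count table, a rooted phylogeny (Newick), and
sample metadata (site, coordinates, season, salinity and companion
physico-chemistry), `halo` provides:

* **Niche-breadth classification** — Levins' niche width
  `B_n = 1/(R·Σpᵢ²)`, occurrence and habitat Shannon entropy per taxon,
  compared against a permutation null (1000 redistributions of each
  taxon's reads, proportional to sample totals). Taxa below the null 95%
  interval are specialists, above it generalists, else non-significant;
  the default "triple" rule requires all three indices to agree.
* **Community assembly processes** — abundance-weighted βMNTD, its null
  z-score βNTI (999 tip-shuffling randomisations), and Raup–Crick
  Bray–Curtis (RC_bray) under a richness- and abundance-constrained
  null; each sample pair is classified as heterogeneous selection
  (βNTI > 2), homogeneous selection (βNTI < −2), dispersal limitation
  (RC_bray > 0.95), homogenising dispersal (RC_bray < −0.95) or
  undominated, with per-gradient-category summaries.
* **Diversity statistics** — Bray–Curtis matrices; multi-term
  sequential-SS PERMANOVA (continuous covariates, factors and
  interactions, permutation p values, verified against
  `vegan::adonis2`); richness / Shannon / Faith PD; Wilcoxon rank-sum
  tests; distance–decay regressions of community similarity on haversine
  geographic distance and scaled-salinity distance, by season and
  pooled.
* **Signed co-occurrence networks** — CLR transform, neighbourhood
  selection (per-taxon lasso) with StARS stability selection of the
  sparsity penalty, per-salinity-category subnetworks, and Table-style
  topology summaries including positive/negative edge partitions by the
  niche label of the endpoints.
* **A synthetic community generator** — Yule tree, Brownian niche
  optima with deep-branch conservation, planted generalist/specialist
  breadths, a clustered site × season salinity design, and
  niche/neutral-mixture multinomial counts — used throughout the test
  suite for calibration and parameter-recovery checks, and available to
  users as `halo.simulate_dataset`.

## Worked example

```python
import halo

table, tree, meta, niches, truth = halo.simulate_dataset(
    n_taxa=150, n_sites=9, n_seasons=2, library_size=5000, w=0.2, seed=42)
rare = halo.rarefy(table, 5000, seed=0)

env = {s: s for s in rare.sample_ids}
obs = halo.niche_indices(rare, env)
null = halo.permutation_null(rare, env, n_perm=1000, seed=1)
prof = halo.classify_taxa(obs, null)
print(prof["label"].value_counts().to_string())

pairs = halo.pairwise_assembly(rare, tree, n_null=999, seed=2)
print(halo.summarize_processes(pairs)[["process", "fraction"]].to_string(index=False))

bc = halo.bray_curtis(rare)
print(halo.permanova(bc, meta, ["salinity", "temperature", "ph"],
                     n_perm=999, seed=3).round(4).to_string())
```

prints

```
label
non_significant    88
specialist         62

                process  fraction
heterogeneous_selection  0.019608
  homogeneous_selection  0.000000
   dispersal_limitation  0.810458
 homogenizing_dispersal  0.013072
            undominated  0.156863

             Df      SS      R2       F      p
term
salinity      1  0.6206  0.3722  9.8018  0.001
temperature   1  0.1038  0.0622  1.6389  0.155
ph            1  0.0565  0.0339  0.8928  0.467
Residual     14  0.8864  0.5316     NaN    NaN
Total        17  1.6672  1.0000     NaN    NaN
```

Reading the output: 62 of 150 simulated genera are confidently narrow
(specialists) while none rise above the null's evenness — the expected
asymmetry of this null family (see `docs/methods.md`). At this modest
pool size with a 20% neutral component, most sample pairs fall to the
taxonomic null (dispersal limitation / undominated) rather than to
|βNTI| > 2 selection; the deterministic-assembly signal strengthens with
pool size and filter strength, which the acceptance script demonstrates.
Salinity alone explains 37% of community variance (PERMANOVA R² 0.37,
p = 0.001); temperature and pH add nothing significant once salinity is
in the model.

The same stages are exposed as a CLI:

```bash
halo simulate --n-taxa 300 --n-sites 9 --seasons 4 --w 0.2 --seed 7 --out-dir sim/
halo rarefy --table sim/table.tsv --depth 11400 --seed 1 --out sim/rarefied.tsv
halo classify --table sim/rarefied.tsv --n-perm 1000 --mode triple --seed 2 --out profiles.tsv
halo assembly --table sim/rarefied.tsv --tree sim/tree.nwk --n-null 999 \
     --metadata sim/metadata.tsv --group-by salinity_category --seed 3 \
     --out-pairs pairs.tsv --out-summary summary.tsv
halo run --out-dir run1 --seed 11   # full pipeline with manifest + checksums
```

## Layout

```
src/halo/core_io.py     tables, taxonomy, metadata, trees; rarefaction,
                        agglomeration, filtering, salinity categories
src/halo/synthetic.py   gradient-community generator with ground truth
src/halo/niche.py       niche indices, permutation nulls, classification
src/halo/assembly.py    βMNTD / βNTI / RC_bray, process classification
src/halo/diversity.py   Bray-Curtis, PERMANOVA, alpha diversity, DDR
src/halo/network.py     CLR, neighbourhood selection + StARS, topology
src/halo/pipeline.py    end-to-end runs with manifests and seeds
src/halo/cli.py         `halo` command-line interface
docs/methods.md         models, nulls, parameters, limitations
```
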