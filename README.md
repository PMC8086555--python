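# endonet

Diversity, community-composition and co-occurrence **network analysis for
plant-endophyte OTU tables** — the downstream statistics used to ask whether
a host plant's organs (e.g. buds vs twigs) filter their fungal mycobiome,
and whether the fungi inside an organ facilitate or exclude one another.

`endonet` takes a taxa × samples read-count matrix with per-sample metadata
(organ, site, tree) and provides, as a library, a CLI and a reproducible
pipeline:

- **Curation** — removal of rare (< 10 reads) and single-sample taxa,
  binarization, seeded rarefaction (multivariate hypergeometric subsampling),
  and Venn-style shared-taxon counts across site–organ groups.
- **Diversity** — richness, Shannon *H* (nats), Fisher's α (the root of
  S = α ln(1 + N/α)), Hill numbers N1 ≥ N2 = e^H ≥ N3 = 1/Σp², sample-based
  accumulation curves, and permutation tests for group differences.
- **Community composition** — Bray–Curtis on √(relative abundance), Jaccard
  on occurrences, NMDS (Kruskal stress-1, multi-start), ANOSIM and PERMANOVA
  with seeded permutations.
- **Networks** — per organ: a bipartite plant–fungus occurrence network
  (connectance, nestedness temperature *T* on a 0–100 scale), its fungi–fungi
  projection, and **Raup–Crick co-occurrence partitioning**: every taxon pair
  is scored by

  rc(A, B) = [#(s_null < s_obs) + ½·#(s_null = s_obs)] / 999,

  where s_obs is the observed number of shared samples and each null
  replicate redraws both taxa's sample sets (occupancy fixed, samples picked
  without replacement with probability ∝ sample richness). Pairs with
  rc > 0.5 form the *positive* network, rc < 0.49 the *negative* network.
  Each network is summarized by small-world σ = (C/C_rand)/(L/L_rand),
  a rewiring-normalized rich-club coefficient, and degree assortativity.
  Organ differences in any index are tested by shuffling organ labels over
  samples and rebuilding both networks per replicate (one-tailed, tail
  chosen by the sign of the observed difference).
- **Guilds** — trophic-guild assignment from a local lookup TSV
  (P/PSa/PSSy/Sa/SSy/U) and per-group relative abundances.
- **Synthetic data** — a seeded community generator (organ preferences,
  occupancy gradient, log-normal abundances and depths, declared pairwise
  exclusion/facilitation) with ground truth, plus a recovery/power suite.

## Worked example

```python
import endonet as en

params = en.CommunityParams(seed=7, exclusion_pairs=[("otu010", "otu012", 1.0)])
table, truth = en.generate_community(params)
table = en.filter_otus(table)                      # drop rare / single-sample taxa
presence = en.to_presence(table)

div = en.diversity_table(table)
jac = en.jaccard_distance(presence)
r, p = en.anosim(jac, table.metadata["organ"], n_perm=999, seed=1)

rc = en.raup_crick_matrix(presence, n_null=999, seed=2)
pos, neg = en.partition_cooccurrence(rc)
res = en.permutation_compare(presence, "nestedness_T", n_perm=999, seed=3)
```

printing (via the calls shown in `scripts/acceptance.py`-style reporting):

```text
79 taxa x 16 samples, depths 12349-121885
mean richness: bud 27.6, twig 34.6
ANOSIM (organ, Jaccard): R = 0.341, p = 0.001
positive edges: 1526, negative edges: 1448
rc(otu010, otu012) = 0.004  (declared exclusion pair; in negative network: True)
nestedness T: twig - bud = -2.17, one-tailed p = 0.314 (left tail)
```

Reading the output: the simulated twigs host richer communities than buds
and the two organs differ compositionally (ANOSIM R = 0.34 at p = 0.001).
The planted strength-1 competitive exclusion between `otu010` and `otu012`
is recovered — the pair never co-occurs, its Raup–Crick score (0.004) is far
below the 0.49 cutoff, so the pair lands in the negative network. The organ
difference in nestedness temperature is small and non-significant here.

The same stages run from the shell:

```bash
endonet simulate --seed 7 --out-dir demo/
endonet run --config config.yaml        # every stage, seeded, to an output dir
endonet compare --counts demo/counts.tsv --metadata demo/metadata.tsv \
    --index nestedness_T --network bipartite --seed 3
```

A pipeline config is a YAML file with the fields of
`endonet.PipelineConfig` (input paths or synthetic parameters, filter
settings, permutation counts, thresholds, one mandatory seed). Identical
config + seed reproduces every report byte for byte; `manifest.json`
records the per-stage seeds and a parameter hash.

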