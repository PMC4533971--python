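# rsnet — co-occurrence networks of ecological regime shifts and their drivers

Ecosystems can undergo regime shifts: large, persistent, often abrupt
reorganizations of their structure and function (lake eutrophication, coral
reef transitions, collapse of polar ice sheets).  Each shift is pushed by a
set of drivers — variables outside the system's feedback loops, from nutrient
inputs and fishing to greenhouse gases — and the same driver often appears
behind many different shifts.  `rsnet` is a toolkit for the comparative,
network-based analysis of such data: given a bipartite table linking generic
regime shift types to their documented drivers, it quantifies how strongly
drivers co-occur, whether that co-occurrence exceeds what the drivers'
ubiquity alone would produce, and how the pattern relates to driver
attributes such as the scale at which each driver can be managed.

It is written for ecologists and global-change researchers working with
curated shift–driver tables (e.g. exports of the Regime Shifts Database),
but every statistic applies to any binary bipartite incidence data.

## The statistics

Let `A` be the `m × n` incidence matrix (rows: regime shifts, columns:
drivers, `A_ij = 1` when the literature links driver *j* to shift *i*).

- **One-mode projections.** Drivers weighted by shared shifts
  (`W = AᵀA`, zero diagonal) and shifts weighted by shared drivers
  (`A Aᵀ`); the mean binary degree of a projection counts co-occurrence
  partners per node.
- **Co-occurrence (open triangles).** Two same-side nodes attached to a
  common node of the other side; the total is `Σ C(k, 2)` over opposite-side
  degrees `k`, reported per node pair and per *co-occurring* pair.  The
  per-pair index is fixed by the degree sequences, so only the
  per-connected-pair version can differ from a degree-preserving null —
  and it is mechanically tied to the projection mean degree: fewer
  co-occurring pairs sharing a conserved total means more co-occurrence per
  pair.
- **Bipartite clustering.** `C = 4·squares / three-paths`, the fraction of
  open three-link paths closed into four-cycles (1 on complete bipartite
  graphs).
- **NODF nestedness** (0–100), from paired overlap with decreasing fill:
  pairs of rows (and columns) with strictly different degrees score the
  percentage of the smaller set contained in the larger; equal-degree pairs
  score zero.  Per-node contributions provide the display ordering.
- **Fixed-margin null models.** Binary matrices with both degree sequences
  held at the observed values, sampled by curveball trades (uniform;
  default) or sequential importance sampling.  Observed statistics are
  summarized as standardized effect sizes `(obs − mean)/sd`, add-one
  empirical p-values, and one-sample t-tests.
- **Attributes.** Driver categories (15 detailed in 5 broad global-change
  classes) aggregate by matrix multiplication to drivers-per-shift-per-
  category; management scales (local / regional-national / international)
  yield per-shift proportions and global shares; homophily — do drivers
  sharing an attribute co-occur preferentially? — is tested by permuting
  labels on the weighted projection.
- **Clustering & ordination.** Sørensen–Dice and Jaccard distances on
  neighbour sets, UPGMA dendrograms (deterministic lexical tie-breaking,
  newick export), classical multidimensional scaling, and vector fitting of
  explanatory variables onto the ordination with permutation p-values.

A synthetic-data module generates database-scale networks (25 shifts × 57
drivers, mean 11.2 drivers per shift, 14 idiosyncratic drivers) with
planted nestedness, guild structure and scale homophily, so the whole
pipeline is testable without any download.

## Worked example

The package ships a transcription of the 25 generic regime shift types with
their three "selected drivers" each (75 links), plus a curated synonym map.

```
$ python analysis/01_build_networks.py --seed 1
worked example: 25 shifts, 44 raw drivers -> 32 canonical, 75 links (11 merges) -> results/fixture
synthetic dataset: 25 shifts x 57 drivers, 280 links (mean 11.2 drivers/shift) -> results/synthetic

$ python analysis/02_network_stats.py --seed 1
[fixture] 25 shifts x 32 drivers, 75 links; idiosyncratic 9 (28%), half-coverage 9 (28%)
          clustering 0.128, NODF 4.3, driver projection mean degree 4.0
          10 driver pairs co-occur in >= 2 shifts
[synthetic] 25 shifts x 57 drivers, 280 links; idiosyncratic 14 (24%), half-coverage 14 (24%)
          clustering 0.491, NODF 27.5, driver projection mean degree 21.8
          9 driver pairs co-occur in >= 10 shifts
```

After canonicalization the 44 raw driver labels merge to 32 (e.g. the
"NSO"/"ENSO" and greenhouse-gas spelling variants), and *climate change*
emerges as the most generalist driver, linked to 9 of the 25 shifts.  On
the synthetic network, 14 of 57 drivers (24%, truncated) are idiosyncratic —
tied to a single shift — matching the planted condition.

```
$ python analysis/03_null_comparison.py --seed 1
[synthetic] observed vs 1000 fixed-margin nulls:
  clustering_coefficient             obs    0.491  null    0.273 +-  0.007  greater p_emp 0.000999
  nodf_total                         obs   27.521  null   26.988 +-  0.452  greater p_emp 0.1189
  mean_degree_drivers                obs   21.754  null   28.386 +-  0.411  less    p_emp 0.000999
  co_occurrence_connected_drivers    obs    2.463  null    1.888 +-  0.027  greater p_emp 0.000999
```

The planted structure reproduces the empirical signature: more four-cycle
clustering and more co-occurrence per co-occurring pair than randomized
networks with the same margins, while each driver co-occurs with *fewer*
distinct partners (segregated guilds), and nestedness sits above the null
mean.  `analysis/04_attributes.py` adds the management-scale shares and the
homophily test (within-scale share 0.421 vs 0.322 expected, p = 0.003),
and `analysis/05_ordination.py` writes dendrograms, MDS coordinates and
fitted variable vectors.

The same pipeline runs from the shell: `rsnet all --seed 1 --out results/run`
(subcommands `stats`, `null`, `attributes`, `ordination`, `synth`; defaults:
10 000 null networks, 999 permutations).

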