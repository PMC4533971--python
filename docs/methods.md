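# Methods

This note documents the models, conventions and design choices behind
`rsnet`: what each statistic measures, how the null models and permutation
tests are constructed, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Data model

The central object is a binary bipartite incidence matrix `A` (rows: regime
shift types, columns: drivers; `A_ij = 1` when the literature documents a
causal influence).  Duplicate edge records collapse to one link; node order
is the order of first appearance in the input, and all reported tables are
sorted by name so identical runs produce byte-identical outputs.  All-zero
rows or columns are reported rather than silently accepted.

Driver labels in curated tables carry case and spelling variants
("cropping" vs "agriculture"-style synonymy).  Canonicalization merges
columns that share a canonical name by logical OR and returns a merge log;
chained or cyclic synonym maps are rejected.  A canonical name that
coincides with an existing driver merges with it — that is the intended
semantics of a synonym map, and merging can only reduce the number of
drivers and never the set of links.  The packaged worked example (25 shift
types × 3 selected drivers; 75 links) keeps the raw transcription and its
curated synonym map separate so the merge step stays auditable.

## Network statistics

**Projections and co-occurrence.**  Projection weights are shared-neighbour
counts; projection mean degree is computed on the *binarized* projection
(the number of distinct co-occurrence partners, not their intensity).  The
open-triangle count equals `Σ C(k,2)` over opposite-side degrees and is
reported both per node pair (`count / C(n,2)`) and per *connected* pair.
The distinction matters for inference: the total — and hence the per-pair
index — is a function of the degree sequences alone, so it cannot differ
from a fixed-margin null; only its concentration on fewer or more pairs
can.  Because the total is conserved, "more co-occurrence per co-occurring
pair" and "lower projection mean degree" are two sides of the same
observation; the package reports both, and the degenerate per-pair
comparison is flagged (SES undefined, p = 1) rather than dropped.

**Clustering.**  `C = 4·squares / three-paths`, counting unlabeled
subgraphs: squares are distinct four-cycles (`Σ C(s_ij, 2)` over row pairs,
`s_ij` shared neighbours) and three-paths are counted per central edge as
`(deg(u)−1)(deg(v)−1)`.  Each square contains four of the counted
three-paths, so complete bipartite graphs score 1.  With no three-path the
coefficient is undefined and returned as NaN.

**NODF.**  Paired overlap with decreasing fill: for two rows (or columns)
with strictly different degrees, the score is the percentage of the
smaller neighbour set contained in the larger; equal degrees score 0.
Row, column and total scores average over the respective pairs; the
per-node contribution (mean score of pairs involving the node) supplies a
node ordering for display.  The implementation is cross-checked against an
independent double-loop oracle and against `vegan::nestednodf` in R.

**Summaries.**  Idiosyncratic drivers are those of degree 1; the
half-coverage set is the smallest prefix of drivers, sorted by descending
degree with alphabetical tie-breaking, whose links strictly exceed half of
all links.  Printed percentages use integer truncation (14/57 → 24), the
convention behind "approximately %" figures in curated summaries.

## Fixed-margin null models

The null hypothesis is that a driver's apparent importance reflects only
how often it is reported, i.e. links are random given both degree
sequences.  The default sampler is **curveball**: a trade picks two rows
and re-deals the columns held by exactly one of them uniformly; the chain's
stationary distribution is uniform over the margin class.  Each ensemble
sample restarts from the observed matrix and applies `5·min(m, n)` trades
(configurable; a single-chain mode with burn-in and thinning is also
provided).  On enumerable margin classes (all 2×2 and 3×3 classes and the
4×4 permutation class were measured) the total-variation distance to the
uniform distribution is below 0.05 at 30 000 samples, and margins are
conserved exactly on every draw.

A **sequential importance sampler** (column-by-column construction with
Gale–Ryser feasibility checks) is provided for parity with constructive
samplers used in the field.  Its importance weights are approximate
(sequential-selection probabilities with dead-end restarts) and unweighted
summaries are used by default; nothing downstream depends on SIS weights.

Comparisons report the standardized effect size `(obs − μ)/σ`, an add-one
empirical p-value `(1 + #extreme)/(n + 1)` in the observed direction
(never exactly zero; Monte-Carlo-valid), and a two-sided one-sample t-test
of the null draws against the observed value with the direction annotated.
When the null is degenerate (σ = 0, as for margin-determined statistics)
the SES is flagged undefined and the empirical p is still returned.
Calibration was verified by drawing the "observed" matrix itself from the
null: the fixed-direction empirical p is uniform (Kolmogorov–Smirnov over
200 replicates, 99-sample ensembles, 8×10 matrices at fill 0.35).

## Attributes and homophily

Category counts are the matrix product of the incidence matrix with the
(mutually exclusive) driver-category membership matrix, so row sums equal
shift degrees by construction; broad categories aggregate detailed ones.
Management-scale proportions are per-shift compositions over the three
levels (local, regional/national, international — the three-level naming is
used throughout, matching the level set used for reporting rather than the
two-word shorthand that sometimes appears in narrative text).

Whether drivers sharing an attribute co-occur preferentially is tested by
**label permutation** on the weighted projection: the statistic is the
share of total projection weight on same-label pairs, the null permutes
labels over nodes, p is one-sided (greater) with the add-one rule.  This
replaces model-based (exponential random graph) homophily terms: fitting
curved ERGMs is a package-scale effort orthogonal to the question, whereas
the permutation test answers it with verifiable type-I error control
(calibration confirmed by simulation; single-label inputs are rejected
since their within-share is trivially 1).

## Synthetic data

The generator's defaults are the study conditions: 25 shifts × 57 drivers,
mean 11.2 drivers per shift (280 links exactly), 14 idiosyncratic drivers,
nestedness strength 5, homophily strength 0.8.  Its purpose is to produce
networks whose observed-vs-null signature matches the empirical one —
nestedness, clustering and connected-pair co-occurrence above the null,
driver-projection mean degree below it — so that the whole pipeline can be
exercised and power-checked offline.

**Mechanism.**  A deterministic template splits both sides into two latent
guilds (52%/48%, echoing an aquatic/terrestrial divide) and fills each
guild with a nested staircase: driver degrees decay geometrically from the
guild's shift count down to 1, each column covering the top-ranked shifts
of its guild.  Columns of equal degree tile successive disjoint segments
instead of stacking; identical tied columns would pour the (margin-
conserved) overlap mass into pairs that a paired-overlap nestedness score
ignores, weakening the planted signal.  `nestedness_strength` `s` maps to
the fraction `1 − exp(−s/2)` of links that keep their template position;
the rest relocate uniformly.  Strength 0 is therefore a margin-matched
random network ("no planted order") and large strength approaches the pure
template.  After noise, repairs enforce the exact invariants: no empty
nodes, exactly `n_idiosyncratic` degree-1 columns (lowest-degree columns
pruned to one link, kept at their best-connected shift; stray degree-1
columns lifted), and the exact link total (weighted additions/removals
that never create or destroy idiosyncratic columns).

A global rank-product link-probability surface — the more obvious
mechanism — was implemented first and rejected on evidence: probabilistic
containment makes every driver pair co-occur, so the projection is
*denser* than the null (the opposite of the empirical signature), and
adding block assortativity to thin the projection destroys
nestedness-above-null because fixed margins conserve total pairwise
overlap.  Within-guild containment plus between-guild separation is the
minimal structure that delivers both at once.

**Planted homophily.**  Scale labels anchor to structure: the generalist
tier (top third by degree) to `international`, and the two specialist
co-occurrence communities — the sign split of the second eigenvector of
the degree-normalized driver projection — to `local` and
`regional_national`.  Each driver keeps its anchor with probability
`homophily_strength`, else draws uniformly.  At strength 0 labels are
independent of the network; at strength 1 they are a deterministic
function of it.  Label *copying* along the projection was rejected: at
database fill (~0.2) the projection is nearly complete, so copying
converges to consensus, and a consensus labeling is indistinguishable from
its own permutations — no permutation test can detect it at any strength.

**Recovery at the defaults** (100 seeds, 40-sample null ensembles,
199 permutations): nestedness above the null mean in 99%, clustering and
connected-pair co-occurrence in 100%, driver-projection mean degree below
in 100%, homophily rejected at α = 0.05 in 93% of seeds.  The
shift-side projection is uninformative at this scale — 25 nodes at fill
0.45 make it nearly complete both observed and randomized — so the
recovery criterion uses the driver projection, where the
generalist/idiosyncratic structure lives.

**What the generator does not emulate:** citation provenance, the actual
heavy-tail shape of the empirical degree distributions (the geometric
staircase is an assumption), correlations between ecosystem type and the
guild structure, and any temporal ordering or intensity of drivers.
Passing tests on synthetic data therefore validate the machinery and the
direction of the planted effects, not the empirical values of the real
database, whose full 57-driver classification is not packaged.

## Ordination and clustering

Shift distances use Sørensen–Dice on shared-driver sets (favouring shared
presences over shared absences, appropriate for co-occurrence data);
driver distances use Jaccard.  Nodes with empty neighbour sets make these
undefined and are reported by name.

UPGMA is implemented in-package so that exact distance ties break
deterministically (the pair whose sorted representative leaf names are
lexically smallest merges first); it agrees with an independent
average-linkage implementation on tie-free random instances, and heights
are non-decreasing on proper dissimilarities.  Dendrograms export as
newick with ultrametric branch lengths (half-height differences).

Multidimensional scaling is **classical (metric)** scaling: double-center
the squared distances, eigendecompose, keep the top-k positive-eigenvalue
axes (k = 2 by default).  Negative eigenvalues — expected since the
distances are non-Euclidean — are reported but never used; requesting more
axes than positive eigenvalues warns and truncates.  Proportions explained
are over the positive spectrum.  Non-metric MDS was deliberately not used:
the distance-based pipeline stays deterministic and testable, and the
ordination feeds a regression-based fit rather than a stress criterion.

Vector fitting regresses each (centered, scaled) variable on the
ordination coordinates: r² from the fit, direction as the normalized
coefficient vector, p by permuting the variable's values (add-one rule),
with a p < 0.05 filtered view.  Binary variables are treated as numeric
0/1; centroid fitting for multi-level factors is not implemented (one-hot
indicators serve that purpose).  Constant variables are flagged and
skipped.  Per-block distances over the binary shift-variable blocks
(ecosystem processes 5, provisioning services 8, regulating services 8,
cultural services 4, drivers 10, land use 11, scales 8, reversibility 3)
drop all-zero variables first and reject shifts whose block profile is
empty after cleaning.

## Pipeline

`run_full_analysis` executes load/canonicalize → statistics → null
comparison → attributes → ordination, writing a results bundle (TSV
tables, newick trees, JSON manifest with seed, configuration and package
version; no timestamps, so identical configurations give byte-identical
numeric outputs).  Each stochastic stage derives its generator from the
master seed and a CRC of the stage name, so toggling one stage never
shifts another's randomness.  Reference defaults: 10 000 null samples, 999
permutations, significance filter 0.05, shared-pair threshold 10 — all
overridable; the test suite and validation scripts use 40–1000 null
samples and 99–199 permutations, sizes chosen to keep the procedures
quick at desk scale while leaving the Monte-Carlo bands (TV < 0.05,
KS α = 0.01, recovery thresholds) unchanged.

## Known limitations

- The per-pair co-occurrence index is margin-determined; it is reported
  for completeness but carries no information beyond the degree sequences.
- SIS importance weights are approximate; use curveball (default) for
  uniform sampling.
- The homophily test conditions on the projection weights; it tests label
  assortment, not the joint formation of links and labels.
- NODF's equal-degree convention makes it insensitive to structure among
  tied-degree nodes; this also shapes the generator design (tiled ties).
- Binary links ignore driver intensity and temporal ordering; nothing here
  addresses how interactions strengthen or weaken over time.
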