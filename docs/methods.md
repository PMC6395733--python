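# Methods

## Problem and model

Biosynthetic gene clusters (BGCs) are genomic regions whose genes jointly
encode the production of a specialised metabolite. Across a large collection
of BGCs, small groups of genes — *subclusters* or *modules* — recur together
far more often than chance would allow, because they implement a coherent
chemical step (e.g. the biosynthesis of one sugar or one extender unit) and
travel through evolution as a unit. `bgcmodules` detects such modules purely
from gene-order statistics, with no sequence-level computation.

Genes are abstracted to orthogroup labels (smCOGs). Two kinds of pairwise
interaction are counted inside clusters:

* **adjacency** — the two orthogroups occupy immediately neighbouring
  positions (linear order, no wraparound);
* **colocalization** — they occur anywhere within the same cluster.

Genes without an orthogroup still occupy their positions; they contribute no
interactions but are counted as available slots.

### Null model and exact p-values

For a pair (A, B), fix every A gene where it is and ask how surprising the
observed interaction count would be if the B_tot B genes were scattered
uniformly over the N_tot positions not occupied by A. Positions partition
into classes: for adjacency, by the number of A neighbours (capacities
N_a, N_b, N_c for 0/1/2 neighbours), the observed count being
i = B_b + 2·B_c; for colocalization, by whether the host cluster contains A
(i = B_b, the number of co-resident B genes). The class occupancies follow a
(multivariate) hypergeometric law,

    P(B_a, B_b, B_c) = C(N_a,B_a) C(N_b,B_b) C(N_c,B_c) / C(N_tot,B_tot),

and the p-value is the exact upper tail P(i ≥ i_orig), summed over all
feasible occupancy vectors. Because either member of the pair can play the
fixed role, each pair gets two directional p-values; the **larger** is kept
(the conservative choice). All conservative p-values, adjacency and
colocalization pooled into one family, are adjusted with Benjamini–Yekutieli,
which controls the false-discovery rate under arbitrary dependence — the
tests share clusters and are thoroughly dependent.

### Duplicate collapse for colocalization

The colocalization null would otherwise need one class per possible
within-cluster copy number of A. Before colocalization counting (only), any
orthogroup occurring k ≥ 2 times in a cluster has all k occurrences replaced
in place by empty positions and the k genes re-appended at the cluster end
behind one empty separator. The empty positions stay available to the null,
which inflates the co-resident class and therefore biases p-values upward in
the case the transform exists for (duplicated *fixed* genes). The transform
is heuristically, not uniformly, conservative: when orthogroups other than
the fixed one are duplicated, the inflation also affects the non-co-resident
class and the bound can fail slightly; the property test constrains
duplication to the fixed orthogroup, where the bound holds. Adjacency is
always counted on the original, uncollapsed clusters.

As printed definitions of this family of tails are easy to get wrong with
floating factorials, all tails are evaluated in exact integer rational
arithmetic (`math.comb` on big ints); profiles with more than 20,000 draws
switch to a log-gamma/log-sum-exp path, and a test pins both paths to
agree to 1e-10 relative on overlapping sizes. An observed count of zero
returns p = 1 exactly.

### Module detection

At a threshold t, orthogroups form a graph with an edge wherever a pair's
best (min over the two kinds) adjusted p ≤ t. Every maximal clique with ≥ 3
nodes is a putative module; requiring a full clique means every internal
pair is individually significant. Every distinct adjusted p ≤ 0.1 in the
data is used as a threshold in turn; a clique emitted at several thresholds
is a single module identified by its orthogroup set, carrying the smallest
(strictest) emitting threshold. Nested modules at different thresholds are
deliberately kept as distinct records. Modules whose members do not all
co-occur in at least two clusters are discarded as artefacts of pairwise
testing. Clique enumeration uses `networkx.find_cliques`
(Bron–Kerbosch); a brute-force subset-enumeration oracle checks it on small
random graphs. The full ladder is the default; `ladder_steps` subsamples it
(always keeping the extremes) purely as a performance knob.

### Data conditioning

Before testing: (1) clusters are trimmed end-inward, dropping extreme genes
whose probability of carrying a biosynthesis-relevant domain is < 0.1
(interior low-probability genes survive; clusters lacking probabilities are
left alone); (2) orthogroups with fewer than 3 member genes are dissolved,
their genes kept in place as unassigned placeholders; clusters left with no
assigned gene are dropped; (3) clusters with identical orthogroup
composition (as a *multiset* — copy numbers matter, order does not) are
reduced to the shortest representative, ties broken by smallest cluster id;
(4) each orthogroup receives a functional category from its member genes'
categories: top share > 60% wins, unless the top is "other" and the
runner-up exceeds 40%; a top share < 60% with top+second > 75% yields a
double category "top/second"; anything else is "mixed". All inequalities
are strict; exact frequency ties are broken by the fixed priority
core > tailoring > transport > regulator > other, chosen once for
determinism.

### Prioritisation (MIB score)

Per module: size; number of supporting clusters (clusters containing every
member); number of those carrying a curated-database flag; strictest
threshold; number of distinct compound classes among supporting clusters and
their Shannon entropy SE = −Σ f_i ln f_i (natural log; SE is 0 for one class
and ln k for k uniform classes — high entropy means the module serves many
chemistries and is likely a genuine functional unit rather than a lineage
artefact); and the percentage of member orthogroups per functional category,
double categories contributing 0.5 to each named part. The MIB score ranks
modules per metric (better = higher rank; larger is better everywhere except
the threshold, where smaller is better; ties get average ranks, making the
score invariant under monotone transforms of any metric), sums the ranks
with weights — defaults: size 2, entropy 15, supporting clusters 10,
threshold 5, tailoring percentage 10, everything else 0 — and rescales
linearly to [1, 100]. When all modules tie, the degenerate rescale maps
everything to 100. A one-sided Fisher exact test
(`quartile_enrichment`) is provided to ask whether a chosen module subset is
over-represented in the top quantile of scores.

## Synthetic collections

The generator emulates the corpus structure at desk scale. Defaults: 100
clusters of 5–15 genes; 30 background orthogroups filling 70% of positions
by uniform sampling *with replacement* (so within-cluster duplicates occur
and exercise the collapse transform); five compound classes assigned at
random per cluster; 10% of clusters flagged as curated; gene categories
drawn from a fixed profile (core .25, regulator .10, tailoring .30,
transport .15, other .20). These sizes keep every background orthogroup
above the 3-member cutoff (~23 members each) while leaving pairwise
co-occurrence counts in the unremarkable range, and a full pipeline run
under a second. Planted modules are fixed sets of 3–6 orthogroups inserted
together into a chosen fraction of clusters, contiguously (producing
adjacency and colocalization signal) or scattered (colocalization only).
Compound classes can optionally be correlated with planting to mimic the
lineage-driven co-occurrence that entropy is meant to down-rank.

What the generator does *not* model: phylogenetic structure (related genomes
contributing correlated clusters), realistic orthogroup abundance skew,
gene-order conservation beyond the planted block, or any sequence feature.
Passing recovery tests therefore demonstrates the statistical machinery on
exchangeable backgrounds, not robustness to phylogenetic confounding.

## Numerical and degenerate-input choices

* Exact integer rationals by default; log-space only for very large
  profiles; the exact path makes tail-direction cancellation a non-issue.
* p-values are validated to (0, 1]; a zero p is treated as an error.
* The collapse transform is made idempotent by recognising already-collapsed
  terminal blocks (a duplicated orthogroup whose occurrences form a
  contiguous terminal run preceded by an empty position is left alone).
* Self-pairs are never tested; pairs are only tested when at least one
  interaction of the kind is observed.
* Empty threshold ladder (nothing at p ≤ 0.1) yields an empty module list.
* Module ids are the sorted member lists joined with "+", so output tables
  are byte-stable across reruns.

## Problem sizes

The bundled tests and the acceptance script run entirely on generated data:
profiles with C(N_tot, B_tot) ≤ 1e5 for brute-force comparisons, 5–15-gene
clusters in collections of 5–100, 20,000-draw permutation references, and
10–20 replicate seeds per recovery experiment — sizes chosen so the whole
suite completes in a few minutes on one CPU while leaving every code path
exercised.

## Known limitations

* Directional colocalization counts are asymmetric when duplicates exist
  (fixing A against two co-resident B genes observes i = 2; the reverse
  observes 1); the conservative max-p rule absorbs the asymmetry.
* The BY family pools both interaction kinds; per-kind families would be
  slightly more powerful but are not what the method describes.
* The trimming stage requires per-gene domain probabilities from an external
  cluster-boundary predictor; without them clusters pass through untrimmed.
* No phylogenetic correction: recurrent co-occurrence caused by shared
  ancestry rather than function will be detected as modules; the entropy
  metric only mitigates this at the ranking stage.
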