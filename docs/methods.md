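# Methods

## The model

The unit of analysis is a conserved operon cluster: an ordered list of
operons, each an ordered list of gene labels (the reference model ships
the E. coli-style `tufB`-`secE`-`rpoBC`-`str`-`S10`-`spc`-`alpha`
arrangement, 45 genes).  The four tRNAs of the `tufB` operon are
excluded from event calling by default because their presence/absence is
hyper-variable across genomes and would swamp the event counts; the
exclusion set is part of the model YAML and fully configurable.

### Adjacency characters

Each adjacent gene pair of the model is scored per genome as one of
three states: CONNECTED (both genes on one replicon with an intergenic
gap below `distance_threshold`, default 10,000 bp), DISCONNECTED
(different replicons, or gap at/above the threshold — the boundary is
inclusive: a 10,000 bp gap is disconnected) or DELETED (either gene
absent from the genome).  No distance is recorded for disconnected
pairs.  Two deliberate choices:

* *Connectivity ignores intervening genes.*  A small insertion that
  breaks operon concatenation but keeps the pair within the threshold
  leaves the pair CONNECTED; the insertion is captured separately
  through `intervening_count` and classified as an event downstream.
  This keeps the character model three-valued while preserving the
  insertion signal.
* *Multi-copy genes resolve to the in-cluster copy.*  Cluster membership
  is defined by grouping model-gene occurrences into blocks (consecutive
  occurrences < threshold apart); the block with the most distinct model
  genes is the cluster region.  This mirrors the type-1/type-2 typing of
  duplicate ribosomal genes (an in-operon copy vs. a distal homolog).

Strand is ignored by the characters; inversions are detected from strand
flips during event classification.  Replicons are linear unless a table
declares otherwise; no circular adjacency is assumed.

### Ancestral reconstruction

For each pair, the minimum number of state changes on the ingroup tree
is computed twice with the root state fixed: to CONNECTED (N_connected)
and to DISCONNECTED (N_disconnected).  The computation is a
Sankoff-style dynamic program with unit transition costs (no cost matrix
is implied by the three-state model; unit cost is the minimal
assumption, and the cost function is a parameter).  Polytomies — which
arise from support-collapsing — are handled natively: each child
contributes independently at a node.  A pair is ancestrally connected
iff N_connected &le; N_disconnected (ties go to connected) **and** the
outgroup agrees; outgroup agreement defaults to CONNECTED in at least
half of the informative outgroup genomes (those with both genes
present), with an "any" rule available.  No informative outgroup genome
means the rule fails, with a warning — absence of evidence is not
treated as agreement.

N_disconnected fixes the root to DISCONNECTED only (not the minimum over
disconnected/deleted): the alternative hypothesis is "both genes present
ancestrally but not connected".  An exhaustive-enumeration oracle
(`brute_force_min_changes`, feasible to 12 internal nodes) validates the
DP in the test suite.

Gene content of the ancestor: a gene is dropped from the ancestral model
only when both its flanking pairs are judged not connected *and* the
gene is deleted in a majority of ingroup genomes.  This is a stated
design choice — adjacency characters only imply gene content.

### Event inference and placement

Each ingroup genome is diffed against the reconstructed ancestor.
Alterations follow a two-class taxonomy: **deletions** remove genes but
leave concatenation intact (`gene_loss` when no copy remains,
`gene_translocation` when a homologous copy exists elsewhere), and
**rearrangements** change operon structure or concatenation
(`insertion`, `transposon_integration`, `full_disconnection`,
`inversion`).  Classification precedence at a junction is
full_disconnection > insertion > inversion, since a &ge; 10 kb
separation makes intervening-gene identity moot.  Consecutive absent
genes merge into one deletion event (a two-gene `rplJL` translocation is
a single event).

Distal blocks of model genes are classified by a concatenation test: if
the main cluster bridges directly over the block's gene run (the run's
ancestral flanks are adjacent and connected in the main block), the
block is an excised, translocated copy and its genes count as deleted
from the cluster; otherwise it is a disconnection fragment and its genes
still count as in-cluster.  Excluded labels are skipped when finding the
flanks.

Transposable-element payloads are recognized by a configurable keyword
rule on labels and products (`transposase`, `insertion sequence`, `tnp`
prefix, `IS` followed by a digit).

Identical alterations across genomes (same subtype, junction, payload
and novel context, compared orientation-insensitively) merge into one
*novel-neighborhood character* with a presence map.  Characters are
placed under a single-origin (Dollo/dominant) assumption: one gain on
the branch subtending the MRCA of the carriers; carrier-clade members
lacking the character are explained by secondary losses, one per maximal
absent subtree.  Secondary losses are recorded but excluded from
headline totals (primary events only); a `count_losses` flag includes
them.  With dominance off, non-monophyletic carriers produce a conflict
record instead of a placement.  When several candidate species trees are
available, trees are ranked by total alterations (gains + implied
losses) ascending, then mean internal support descending.

### HGT test

A gene tree is compared against the species tree after contracting every
internal edge whose child node has bootstrap support below the threshold
(default 80; exactly 80 is retained — the boundary is strict).  Both
trees are collapsed by default (a flag restricts collapsing to one
side).  The Robinson–Foulds distance is the symmetric difference of the
non-trivial bipartition sets of the unrooted topologies; RF = 0 is
"consistent with vertical descent", anything larger is a conflict with
the discordant bipartitions listed.  A star-vs-star comparison returns
RF = 0 — consistent but uninformative, and logged as such.

### Rates

A branch's substitution count is branch length (amino-acid
substitutions/site) times the concatenated-alignment length in columns
(defaults 9,429 and 10,199 for the two data-set tags); the rate is
1000 × events / substitutions.  Group summaries average only branches
carrying at least one alteration (the convention behind "mean ± sd over
altered branches"); zero-length branches with events have undefined
rates and are excluded with a warning.  Order-wide rates sum events and
substitutions over all branches whose descendant leaves lie wholly
inside the order, including zero-event branches; non-monophyletic orders
use their maximal wholly-contained subtrees.  Group comparison uses
Welch's two-sided t-test by default (a pooled-variance flag exists).
Printed integers (percentages, folds) round half away from zero.

## The simulator

`simulate_tree` draws a Yule (pure-birth) topology, rescales branch
lengths to a mean of `branch_scale` (default 0.05 substitutions/site, a
typical interior-branch scale for a class-level protein phylogeny) and
sets all supports to 100.  `evolve_cluster` walks the tree root-to-tip
carrying an arrangement (an ordered list of loci, each an ordered gene
list) and draws per-branch Poisson event counts per type, rates in
events per unit branch length:

| parameter | default | meaning |
|---|---|---|
| `r_insertion` | 1.0 | novel genes at an inter-operon junction, k ~ Geometric(0.5) |
| `r_deletion` | 1.0 | one model gene removed; homolog copy left with `p_homolog_copy` = 0.5 |
| `r_disconnection` | 0.5 | split at an inter-operon junction; far locus 50 kb away |
| `r_inversion` | 0.25 | 1–3 model genes reversed and strand-flipped |
| `r_transposon` | 0.25 | single keyword-labelled gene inserted |
| `invasion_bias` | 5.0 | weight multiplier for disconnection at already-invaded junctions |

Defaults give roughly 3 events per unit branch length at the cluster
level; the low-rate conditions used for recovery checks (0.7 / 0.7 /
0.3 / 0.15 / 0.15) correspond to about 0.05 events per adjacent pair
per unit branch length over the model's ~40 pairs.  The invasion bias
encodes the two-step invasion–separation pattern: junctions already
carrying an insertion are preferentially chosen for full disconnection.

Randomness is keyed per branch (seed + CRC of the branch's clade id), so
adding taxa does not reshuffle events on unchanged branches; novel-gene
labels embed the same stable tag.  Leaf tables get realistic coordinates
(gene length ~ N(900, 200) bp clipped at 150, intergenic gaps ~
Exp(100) bp, loci separated by 50 kb) from dedicated per-leaf streams,
which lets `replay_log` reproduce the emitted tables byte-identically
from the truth log alone.

What the simulator does *not* emulate: multi-replicon genomes, circular
chromosomes, sequence evolution (branch lengths are taken as given),
HGT between lineages, annotation error, and gene-boundary drift.
Passing recovery tests therefore show the inference machinery is
self-consistent under the stated event model — not that it is robust to
annotation noise or to processes outside that model.

## Numerical and degenerate-input choices

* Ties in the decision rule go to "connected" (N_connected &le;
  N_disconnected), matching the rule's direction.
* The cluster-region tie-break (equal distinct-gene counts) prefers the
  larger, earlier block, making region choice deterministic.
* Overlapping genes get gap 0; the gap is `start(next) − end(prev) − 1`
  on 1-based inclusive coordinates.
* An empty outgroup is a validation error before any computation; a
  genome with zero cluster genes scores all-DELETED with a warning.
* Event tables are ordered by branch preorder then event id; all
  pipeline outputs are byte-stable across reruns.

## Known limitations

* Insertions later overwritten by disconnection at the same junction are
  attributed to the surviving carriers only (the dominance placement
  then dates the gain too shallowly); histories that restore the
  ancestral adjacency are invisible to gene-order comparison.
* Nested insertions can push a junction past the 10 kb threshold, in
  which case the method reads a full disconnection — faithful to the
  rules, but a different event count than the generating history.
* Recurrent identical deletions in distant lineages merge into one
  character and place at the joint MRCA (homoplasy is folded into the
  single-origin assumption, as dominance dictates).
* The t-test operates on per-branch rates as independent observations;
  phylogenetic non-independence of branches is not modelled.
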