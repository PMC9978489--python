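# Methods

## Scope and model

`cernax` treats ceRNA-axis discovery as a sequence of set-valued
filters over curated catalogs, not as statistical inference from
expression matrices. The inputs are direction calls (up/down per
molecule per study) and interaction catalogs; the outputs are the
subsets that survive explicit, individually testable predicates. This
mirrors how multi-study curation actually works in cancers where no
single matched lncRNA/miRNA/mRNA/protein dataset exists: directions
are the only statistic that survives aggregation across heterogeneous
platforms, so the pipeline deliberately consumes nothing else. The
corollary is that `cernax` quantifies no sponge effect sizes — a triad
is a direction-consistent, evidence-tiered candidate, not a measured
interaction (see Limitations).

## Identifier canonicalisation

All joins are string joins, so identifiers are normalised at the I/O
boundary: gene/protein/lncRNA symbols are trimmed and upper-cased;
miRNA ids get a lower-case `hsa-` prefix, `miR` casing, and keep their
`-3p`/`-5p` arm suffix if — and only if — the source supplied one. An
arm is never guessed at load time; arm expansion is an explicit step of
triad assembly (below). A two-column alias table hook runs before
normalisation for synonym harmonisation across source studies; the
package ships no synonym dictionary of its own, because any fixed
choice would silently change joins. Normalisation is idempotent
(property-tested over random-case corpora).

Direction tokens accept `up`/`down` in any casing plus signed numerics
mapped by sign. PPI combined scores in [0, 1] are rescaled to the
0–1000 STRING integer convention; values in (1, 1000] are taken as
already scaled.

## Consensus rule

A molecule is `up` iff n_up > n/2 over its voting units, `down`
symmetrically, else `ambiguous`; ambiguous molecules stay in the table
(for reporting) but are excluded from every downstream stage. With
transcript-resolved evidence the rule applies twice: one vote per
transcript by strict majority of that transcript's studies, then
strict majority over transcript votes. Two conventions had to be fixed
where practice varies:

* ambiguous transcripts **abstain** at the gene level rather than
  entering the denominator — this keeps the ">50 % of transcripts"
  rule well-defined for any mix of tied and untied transcripts;
* each evidence row is one vote, so a study reporting a molecule in
  both directions through different probes contributes one vote per
  row (and, absent transcript ids, such a study is internally tied and
  pushes the molecule toward ambiguity — which is the conservative
  reading).

Molecules measured in several classes (a gene as mRNA and as protein)
are called independently per class; cross-class concordance is a
pairing-stage annotation, not a consensus-stage merge.

## Pairing and integration

Three pure filters, in any order (they commute; property-tested):
usable calls at both endpoints, opposite directions, and confidence
(observed, or predicted with CWCS ≤ −0.4, boundary inclusive — "−0.4
or lower"). The transcript layer pairs targets against mRNA-class
calls, the protein layer against protein-class calls; integration is a
union keyed by (miRNA, target) with evidence-method/layer union and
"observed" dominating "predicted". `dual_level` is a property of the
target (usable calls in both classes), `dual_concordant` additionally
requires sign agreement; an edge whose two layers disagree on the
target direction is kept but flagged discordant and never concordant.

## Centralities

All four are implemented in-package so that their exact definitions
are part of the contract (rankings, not absolute values, drive hub
calls, and different tools' variants rank differently):

* **degree** — neighbour count on the thresholded, unweighted graph.
* **closeness** — harmonic form C(v) = Σ_{w reachable} 1/d(v,w).
  Chosen over the classic (n−1)/Σd because score-thresholded PPI
  graphs are routinely disconnected and the harmonic form needs no
  per-component convention; the classic variant (restricted to the
  node's component) is available via `variant="classic"` because the
  two can rank differently on disconnected graphs.
* **betweenness** — Brandes accumulation, unnormalised, unordered
  pairs, endpoints excluded. Correctness is defined against (and
  tested against) explicit all-pairs shortest-path enumeration;
  normalisation is omitted because it is a monotone per-graph constant
  and cannot change a top-k list.
* **bottleneck** — for each root, a BFS shortest-path tree over the
  root's reachable component; a non-root node scores 1 when its
  subtree holds strictly more than a quarter of the tree's nodes. The
  tree is not unique, so determinism is imposed: nodes are visited in
  sorted label order and each node's parent is the lexicographically
  smallest equal-distance predecessor. Both the strict ">" and the
  1/4 fraction are exposed as parameters since published descriptions
  of the metric are informal.

Hubs are the intersection of the four top-k lists (k = 10 default).
`top_k` expands ties at the k-th boundary — with integer-valued
metrics like degree and bottleneck, truncating inside a tie class
would make hub membership depend on label order, which is worse than
an occasional longer list. Secondary sort is by node label for
determinism.

## Over-representation

Upper-tail hypergeometric p-values come from `scipy.stats.hypergeom`
(exact and stable well past N = 10⁵) and BH FDR from
`statsmodels`; both raw-p and FDR significance flags are reported
because curated-analysis conventions threshold on either. The universe
defaults to the union of the collection's members and is overridable —
the choice moves every p-value and must never be implicit. Sets are
scored after intersection with the universe; query genes outside the
universe are dropped with a warning.

## Triad assembly

For each anchor gene with a usable call, retained miRNA partners
(inverse-paired, confidence-filtered) are joined to the lncRNA–miRNA
catalog. A miRNA id without an arm is expanded to both `-3p` and `-5p`
for the sponge join only; the original id is kept on the miRNA–target
edge and the triad records the arm-resolved id plus an `arm_expanded`
provenance flag. Direction lookup for an arm-resolved id falls back to
the arm-less base id, since expression studies index mature arms
inconsistently. The consistency predicate —
lnc_direction = target_direction ≠ mir_direction — is sign-symmetric
(flipping every call preserves the consistent set; property-tested).
Evidence tiers are carried on both legs: a miRNA–target edge is
*strong* iff any of {reporter assay, western blot, qPCR} backs it; the
lncRNA–miRNA tier comes from the input catalog rather than being
recomputed, because sponge databases publish their own tiering.
Anchors that yield no triad are reported explicitly rather than
silently dropped.

## Packaged fixtures

`src/cernax/data/` ships two literature-curated gallbladder-cancer
catalogs: the hub-gene axes (TP53/CCND1/CTNNB1, including the three
functionally validated TP53 regulators miR-125b-5p, miR-34a-5p,
miR-30a-5p, and an arm-less miR-200a→CTNNB1 edge that exercises arm
expansion) and the dual-level axes (EZH2/PTMA, six sponge-consistent
triads). The interaction partners and tiers are curated; the direction
calls in these files are synthetic sponge-consistent assignments
(tumour genes up, their miRNAs down, sponges up), as the fixtures
exist to exercise assembly, not to re-measure expression.

## Synthetic data

The generator emulates exactly the structure the pipeline consumes:

* **studies** — each of `n_studies` reports each molecule's true
  direction, flipped independently with probability `flip_noise`
  (must be < 0.5; at 0.5 the majority rule carries no signal). With
  5 studies at flip 0.2 the per-molecule correct-call probability is
  Σ_{i≤2} C(5,i)0.2ⁱ0.8⁵⁻ⁱ = 0.94208, the closed form the recovery
  test checks against.
* **interaction catalogs** — planted axes appear as observed,
  strong-evidence, inverse-direction edges with a sponge partner;
  decoys are adversarial by category, each violating exactly one
  retention predicate (same-sign directions, predicted CWCS above
  −0.4, or no lncRNA partner) and labelled with it in the manifest, so
  each filter has dedicated violators and recovery is exact *under the
  true directions*. Axis recovery and direction-call error are thereby
  deliberately separated: the binomial bound quantifies the latter,
  precision/recall = 1 certifies the former.
* **PPI** — an Erdős–Rényi background (scores ≥ 900) with hubs wired
  to `hub_degree` random background nodes, plus sub-threshold decoy
  edges (< 900) so thresholding is exercised; the generator enforces
  hub_degree ≥ 4 × expected background degree so hubs stand clear of
  the degree distribution. Defaults (60 background nodes, edge
  probability 0.05, 3 hubs of degree 30) give essentially certain
  hub recovery at k = 10.
* **gene sets** — one planted set sharing a fixed overlap with the
  generated query (defaults: overlap 25, set size 40, universe =
  the mRNA pool), putting its hypergeometric p far below 10⁻⁴; the
  rest are uniform draws.

One integer seed drives everything through numpy's splittable
`SeedSequence`. What the generator does **not** emulate: expression
magnitudes, count-level noise, correlated studies, annotation errors
in the catalogs, or scale (presets top out at thousands of molecules).
Passing recovery tests therefore demonstrate the *logic* — every
filter removes exactly its violators and the assembly is exhaustive —
not robustness to real-data pathologies such as systematic direction
biases shared across studies.

## Pipeline conventions

`run_all` executes consensus → pairing → hubs (on the subgraph induced
by observed targets, switchable off for inputs whose PPI table is
already the network of interest) → ORA (query = observed targets) →
triads. The default anchor set is hub genes ∪ dual-concordant targets,
filtered to anchors with usable calls; explicit lists and single-group
modes are available. All thresholds default to the values quoted above
and live in one serialisable config; artifacts are plain TSV/GraphML
plus a machine-readable `summary.json`. Problem sizes in the test and
acceptance runs (200 oracle graphs of ≤ 25 nodes, 100 PPI seeds,
2,000 molecules for the consensus bound, default bundle of ~500
molecules) were chosen as the smallest sizes at which the statistical
checks have their stated power.

## Known limitations

* No sponge-effect quantification: no expression-correlation or
  conditional-mutual-information test ever runs; triads are catalog
  joins. Candidates need experimental follow-up by construction.
* The strict-majority rule weights all studies equally, ignoring study
  size and quality.
* Top-k tie expansion means hub lists can exceed k; on small or highly
  symmetric graphs the four-way intersection can be large (an
  edgeless graph ties everyone at zero).
* Normalisation assumes human (`hsa-`) miRNA nomenclature; other
  species go through the alias table.
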