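# Methods

This note documents the models, algorithmic choices and limitations behind
`cladetrace`, in the spirit of a methods appendix: what is simulated, how
each estimate is computed, which knobs exist and why their defaults are what
they are, and what passing the test suite does and does not demonstrate.

## Scenario generator

A scenario is a dated, rooted, binary species tree (node ages in years
before present, tips extant), a list of introgression events, and the
clock/substitution parameters.  The bundled `fig1_fig3` preset encodes a
hominin history:

| node | age (YBP) | status |
| --- | --- | --- |
| Pan / Homo (calibration) | 8,000,000 | fixed by construction |
| Hss / Hsn (modern vs Neanderthal+Denisovan stems) | 800,000 | scenario-defining |
| Hsnd / Hsnn (Denisovan vs Neanderthal) | 700,000 | free choice |
| SH_Hsnn / Hsnn* (Sima de los Huesos vs classic Neanderthal) | 600,000 | free choice |
| mtDNA capture, Hss stem → Hsnn* | 500,000 | scenario-defining |
| modern-human crown (Mbuti/San vs rest) | 250,000 | scenario-defining |
| first and second Yoruba divergences | 225,000 / 180,000 | scenario-defining |
| Mbuti / San | 150,000 | free choice |
| non-African crown (Lund / French) | 125,000 | scenario-defining |

The three "free choice" ages are unconstrained by the scenario; they only
need to bracket the capture age (600,000 > 500,000) and the crown ages, and
were fixed once at round values in those intervals.  The taxon set is the
minimum that realises every scenario-defining node: one outgroup, three
archaic lineages, four Africans (two of them Yoruba lineages so that both
Yoruba divergences exist) and two non-Africans.  All tips are placed at the
present — a deliberate idealisation: the real archaic specimens are ancient,
but modelling tip dates would break the strict ultrametricity the dating
procedure assumes and adds nothing to what the pipeline is meant to test.

**Introgression events** name donor and recipient *lineages* by leaf-label
sets; the lineage is the branch ancestral to the MRCA of those leaves at the
event age.  Only whole-locus capture is modelled: deriving a locus tree
detaches the recipient lineage at the event age and re-attaches it to the
donor lineage at the same age, so the locus tree stays ultrametric in time.
Events must be strictly younger than the donor/recipient divergence and are
applied youngest first.  The species tree and the mtDNA tree of the preset
then differ by exactly one leaf placement (`Hsnn_star`), which is the
discordance signal the downstream modules detect.

**Sequence evolution** is strict-clock and site-independent under K2P
(JC69 = K2P with κ=1).  Branch lengths in expected substitutions are
`(parent age − child age) × r`.  Defaults: `r = 1.5e-8`
substitutions/site/year and 16,500 sites, chosen so that (i) the locus is
mtDNA-sized and (ii) the deepest distance in the scenario (Pan–human,
2 × 8 MY × r = 0.24 substitutions/site) is strong signal but comfortably
below the saturation bounds of the corrections (observed p ≈ 0.2 < 0.75);
κ = 4 is a typical mammalian-mtDNA transition/transversion rate ratio.
Transition probabilities use the closed-form K80 expressions with the rate
matrix normalised so branch length equals expected substitutions
(transversion rate β = 1/(κ+2), transition rate α = κβ, α + 2β = 1).
There is no rate heterogeneity across sites, no indel process, and no
within-population sampling (one exemplar per lineage, matching the
single-representative sampling design the pipeline analyses); simulated
sequences contain only A/C/G/T, though N and `-` are accepted on input
everywhere downstream.  The random stream is a single seeded numpy
generator consumed in a fixed branch order (preorder, children sorted by
their smallest descendant leaf label), so a seed determines the alignment
byte-for-byte across platforms.

What passing on these simulations does **not** show: robustness to rate
variation among sites or lineages, to alignment error, to recombination or
incomplete lineage sorting, or to within-population polymorphism.  The
simulations validate the *logic* of the pipeline under its own assumptions,
not the historical claims themselves.

## Distances

Observed proportions use pairwise deletion (a site counts for a pair only
if both sequences have an unambiguous base), which preserves taxa with
patchy missing data at the cost of slightly different effective lengths per
pair.  Corrections are JC69 and K2P; K2P is the default because mtDNA is
transition-rich.  Proportions outside a correction's domain raise a
saturation error rather than being truncated — on simulated data saturation
always indicates a mis-specified scenario, and silently capped distances
would poison the additivity the tree builders rely on.

## Tree building

Neighbor joining follows the standard Q-criterion agglomeration and is
exact on additive matrices.  Two determinism/robustness choices:

* **Tie-breaking.**  Whenever two candidate joins tie numerically (within
  1e-10 relative), the pair whose sorted cluster keys (smallest member leaf
  label) are lexicographically smallest is joined — results are identical
  across platforms and library versions.
* **Negative branch estimates** are clamped to zero with the deficit moved
  to the sibling branch of the same join, preserving path lengths through
  the joined node (the usual practical fix on noisy matrices).

UPGMA (average linkage, heights = half the merged mean distance) is
provided as the ultrametric cross-check backend.  Outgroup rooting places
the root at the midpoint of the outgroup's pendant edge; no information in
the data locates the root more precisely along that edge, and the dating
step is only mildly sensitive to the choice (see below).

Fitch small parsimony treats N and gaps as missing (full state set at the
leaf) and compresses columns to site patterns before scoring.  Exhaustive
topology enumeration is by stepwise leaf insertion and is capped at 9
leaves ((2n−5)!! growth); the exhaustive search reports the best score, the
number of topologies strictly better than a reference, and the histogram of
their margins — the statistic needed to quantify "how many trees beat this
published tree, and by how much".

## Progressive phylogenetic analysis

Each PPA step re-infers the tree from scratch on the enlarged sampling
(full rebuild, not grafting a leaf onto a fixed core): the per-step trees
are then exactly what a one-shot analysis of that sampling would give, and
the final tree provably equals the full-sampling inference.  The newcomer's
attachment edge is computed afterwards by removing its pendant edge and
locating the merged edge in the previous tree; if the rebuild also
rearranged the previous taxa, the record carries a `topology shifted` flag
and the nearest previous edge by bipartition overlap.

Group classification on the outgroup-rooted tree (outgroup excluded):
monophyletic iff the group equals the leaf set of its MRCA; **paraphyletic
iff the remainder of that MRCA clade is itself a single clade** (group =
clade minus one nested clade, the textbook reptiles-without-birds pattern);
polyphyletic otherwise.  A group whose MRCA-clade remainder consists of two
or more separate clades is thus reported polyphyletic; this conservative
reading keeps "paraphyletic" a sharp, checkable claim, and it is the
definition stated in every report header.

## Chronology

Node ages come from one calibration and linear scaling — deliberately the
simplest defensible procedure, with no rate smoothing:

1. depth(v) = mean over descendant leaves of the path length v → leaf
   (substitutions/site), repaired in postorder so a parent is never
   shallower than a child;
2. age(v) = cal_age × depth(v) / depth(calibration node).

Mean-path depths (rather than UPGMA heights) let the dating run on the same
NJ topology the rest of the report describes; UPGMA is available as a
cross-check.  Ages are exact floats; the 25,000-year rounding seen in
report text is cosmetic only.

Two knowable biases of this procedure, both visible in the validation runs
and both well inside the 10% recovery band:

* the calibration (root) depth averages the outgroup's pendant path, and
  midpoint rooting places the root slightly too close to the outgroup when
  the ingroup is much shallower — together worth about −4% on all ages of
  the preset scenario;
* monotonicity repair can only raise, never lower, noisy internal depths.

Parameter recovery under default settings: median estimated ages over 20
seeded replicates fall within 10% of every generating node age
(`tests/test_chronology.py`, `tests/test_acceptance.py`), with the
scenario-defining chain 800k / 500k / 250k / 225k / 125k YBP recovered at
roughly −3% to −7%.

## Discordance and direction

Topology comparison is unrooted and bipartition-based (the symmetric
difference is the Robinson–Foulds distance).  The displaced-taxon search is
exact over leaf subsets of size ≤ k (default and cap 3), smallest subsets
first, lexicographic tie-breaking; every reported prune set is re-verified
to reconcile the restricted topologies before it is returned, and an
unreconcilable pair yields an explicit result object, not an exception.
Note the minimal reconciling set after a single leaf SPR is not always
unique — a local move can be healed by removing either endpoint's
neighbour — so ties are resolved deterministically rather than
"biologically".

Direction inference is the sister-group argument made operational: for a
displaced taxon x, the donor is the smallest reference-tree clade that
contains x's sister group in the test tree; the recipient is x.  The rule
trace records x's sister group in both trees so a reader can check which of
the two competing configurations (transfer into x vs transfer out of x) the
test tree matches.  This is a purely topological argument: it cannot by
itself exclude lineage sorting or other discordance processes, and report
output says so explicitly.

## Problem sizes and validation design

The validation suite uses the preset's own conditions: 16,500-site
replicates, 20 of them for the date chain and 50 for the stochastic
verdict/direction rates (thresholds at 95%), plus exact oracles — NJ
against matrices built from random trees, Fitch against brute-force
enumeration of internal assignments, topology counts against (2n−5)!!,
self-calibration identity, and displaced-taxon pruning on random single-SPR
pairs.  At these sizes the whole suite runs in well under a minute; the
replicate counts match the validation protocol the scenario was designed
around, and the Monte-Carlo tolerances (3 standard errors at 10⁵ sites for
the simulator-calibration checks) are derived from binomial sampling noise,
not tuned.

## Limitations

* Strict clock and a single calibration: rate variation among lineages
  translates directly into dating error, with no smoothing to absorb it.
* The direction rule assumes exactly the whole-locus-capture discordance
  pattern it models; multiple overlapping captures, or discordance from
  lineage sorting, are outside its vocabulary (the search then reports
  irreconcilability or a larger prune set).
* Parsimony inference is exhaustive and thus capped at 9 taxa; beyond that
  the package deliberately refuses rather than silently switching to a
  heuristic search.
* No real mtDNA data ships with the package; all quantitative validation is
  parameter recovery on simulations from the documented generator.
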