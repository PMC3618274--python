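# Methods

`motudelim` bundles the species-delimitation analyses commonly applied to
single-locus DNA barcodes (COI and similar markers) into one tested
pipeline: distance-based barcode-gap methods, tree-topology statistics,
the general mixed Yule-coalescent model, and a consensus layer that turns
per-method decisions into min–max species counts. A multispecies-coalescent
simulator generates fully specified datasets so every stage can be
verified without external data.

## Distances

Pairwise distances are uncorrected p-distances or Kimura two-parameter
(K2P) distances. K2P separates transitions (proportion `P`) from
transversions (proportion `Q`) over the comparable sites of a pair:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Comparable sites are columns where both sequences carry an unambiguous
base; gaps, `?` and IUPAC ambiguity codes never enter `P` or `Q`. Two
deletion policies are offered: *complete* (one global site set — any
column with a non-base character in any sequence is dropped for every
pair) and *pairwise* (per-pair site sets; the default for gap analyses, so
that indel-rich loci do not erase signal elsewhere). When a log argument
is non-positive the pair is *saturated*: the distance is flagged
inapplicable (NaN) rather than clamped, and group summaries exclude such
pairs with a warning.

Group summary tables report mean within-group distance on the diagonal
("n/c" for singleton groups) and mean between-group distance off it.
Standard errors come from a bootstrap over alignment columns (default 500
replicates, seeded): the distance computation is repeated on column-
resampled alignments and the SE is the standard deviation of the group
mean across replicates — the convention of the standard distance
software. The alignment is therefore carried along with the distance
matrix; a matrix loaded without its alignment cannot produce SEs.

## Barcode-gap analysis

For a focal group, *overall* gap analysis (OGA) pools all other ids as the
comparison set; *pairwise* gap analysis (PGA) compares one partner group
at a time, and an aggregator records any partner with which no gap exists
(the "blocking" group). A gap is present when the minimum inter-group
distance exceeds the maximum intra-group distance; the gap range is that
difference when positive. Four decision rules are layered on top:

| rule | supported when | notes |
|------|----------------|-------|
| fixed 3% | mean intra < 0.03 and min inter ≥ 0.03 | classic barcode boundary |
| fixed 4% | mean intra < 0.04 and min inter ≥ 0.04 | land-snail calibration |
| 10× | mean inter ≥ 10 × mean intra | fold rule |
| 3.2–4.1× | mean inter ≥ 3.2 × mean intra | `strong` flag at ≥ 4.1× |

The fixed rules deliberately compare the *mean* (not the maximum) intra
distance against the threshold: a deeply subdivided group can exceed the
threshold with a few extreme pairs yet still be scored as supported when
its typical variation is below it and a clean gap exists. Singleton focal
groups have no intra distances; every rule returns `na`.

## ABGD-style partitioning

For one prior `P` (an upper bound on intraspecific divergence) the sorted
pairwise distances are scanned for the first gap `w_i = d[i+1] - d[i]`
exceeding `X · theta_i`, where `theta_i = max(P, mean(d[1..i]))` is the
running intraspecific scale floored at the prior, with the additional
requirement `d[i+1] > P`. The partition is single linkage below the gap
midpoint; detection is re-applied inside each component until no gap
remains (the recursive partition). The whole procedure runs over a
log-spaced prior series (default 0.001–0.1 in 10 steps). The relative gap
width defaults to `X = 1.5`, the customary value for this family of
methods; much larger values (e.g. 15) demand gaps wider than the entire
divergence range of realistic data and detect nothing, and are exercised
in the tests for exactly that contrast.

## Tree-based statistics

**GSI.** The genealogical sorting index of a labeled group on a rooted
tree uses the minimal spanning set `U` of internal nodes connecting the
group's tips to their MRCA (inclusive): `GS = n / Σ_{u∈U} (c_u − 1)` with
`c_u` the child count (the weight handles polytomies), normalized to
`gsi = (GS − GS_min)/(GS_max − GS_min)` where `GS_max = n/(n−1)` is the
monophyly value and `GS_min` takes `U` to be every internal node of the
actual tree — making the index tree-shape aware. `gsi = 1` iff the group
is monophyletic. Significance comes from permuting tip labels (default
10,000 permutations) with the add-one estimator
`p = (1 + #{gsi* ≥ gsi}) / (1 + B)`, which can never return zero but is
slightly conservative, especially on small trees where the index is
coarsely discrete. Holm's step-down (sequential Bonferroni) correction is
provided for multi-group testing.

**Rosenberg's P_AB.** The probability that two labeled groups of sizes
`a` and `b` are reciprocally monophyletic when every sequence of
coalescent joins is equally likely. Reciprocal monophyly requires each
group to resolve internally before the final root join, giving

    P_AB = 2 · C(a+b−2, a−1) · a!(a−1)! b!(b−1)! / [(a+b)! (a+b−1)!]

The closed form is verified in the tests against exhaustive enumeration of
join sequences for all `a + b ≤ 8` (e.g. `P_AB(2,2) = 1/9`).

**Rodrigo's P(RD).** A clade's distinctiveness ratio is its mean crown
depth over its stem branch length; small ratios mean distinct clades. The
null distribution is built from size-matched clades on simulated neutral
single-population coalescent trees with the input tree's tip count
(default 1,000 simulations, seeded), and `p` is the lower-tail proportion.
The choice of a coalescent (rather than Yule) null and the size-matching
are declared defaults; other nulls would shift p-values somewhat.

**SDP summary.** Per group: mean intra patristic distance ("n/c" for
singletons), the closest group (minimum mean between-group patristic
distance), their ratio, and *P ID(Strict)* implemented as a leave-one-out
nearest-neighbor criterion — the proportion of members whose nearest tip
is a group-mate — with a Wilson 95% CI. This is an operational
approximation to tree-walking identification probabilities: it agrees
with them when groups are exclusive clusters and is cheaper and easier to
audit.

## GMYC

The model assumes an ultrametric binary gene tree on which branching
switches from a diversification process to within-species coalescent
processes. For inter-node interval `i` (duration `x_i`) the total rate is

    b_i = λ_div · k_i^{p_div} + λ_coal · Σ_j (n_ij (n_ij − 1))^{p_coal}

with `k_i` species-level lineages and `n_ij` lineages inside species `j`;
the log-likelihood is `Σ_i [ln b_i − b_i x_i]` over the n−2 waiting
intervals that end in a branching event. The null model is the
single-species special case `b_i = λ (n_i(n_i−1))^p`; its `λ` has a
closed-form profile and `p` is optimized on [0, 2].

The single-threshold fit profiles the transition age over inter-node
intervals. Any age inside an interval yields the same classification, so
candidates are interval midpoints plus two boundary configurations:
"above the root" (identical to the null, which guarantees the nested-
likelihood ordering) and "below every node" (every tip its own species).
The four rate parameters are re-optimized per candidate (L-BFGS-B on log
rates, warm-started from the previous candidate; a fixed pair of default
starts guards against local optima). The likelihood-ratio test against
the null uses df = 3 (five parameters — two rate blocks and the threshold
— versus two). The multiple-threshold fit refines the single-threshold
solution greedily: the crown node of one species subtree at a time is
promoted to a diversification event, keeping the move with the largest
likelihood gain, until AIC (one parameter per added transition age) stops
improving; the LR test then uses df = 2 + #thresholds by default
(configurable), i.e. one degree per transition age plus the two extra
rate parameters.

Preparation resolves polytomies into zero-length bifurcations (children in
sorted leaf-label order, so deterministic), verifies ultrametricity within
a relative tolerance, and breaks tied node ages with a seeded jitter of
1e-8 × tree height so every waiting interval is positive. Rate smoothing
of non-ultrametric trees is out of scope — GMYC requires ultrametric
input.

Entities are the maximal subtrees whose root age falls below the
threshold: clusters (≥ 2 tips) plus singletons.

**Known limitation — oversplitting.** Single-threshold GMYC has a
documented tendency to promote deep within-species coalescent nodes to
species boundaries, particularly in large samples where the basal
two-lineage waiting time is an appreciable fraction of the species depth.
On the default synthetic datasets this costs the method a minority of
exact-recovery cases (it overestimates the species count by one or two)
while the distance-based routes are unaffected; the effect is
scale-invariant in the coalescent, so it cannot be removed by rescaling
and mirrors the method's behavior on real barcode data, where it
routinely proposes the largest species counts.

## Consensus counting

Per-method decisions over a set of candidate hypotheses — groups, their
nested sub-groups, and composite alternatives (a group plus a named part
of another) — form a support matrix with cells `+`, `-`, `na` (untestable,
e.g. singletons under intra-based rules) or empty. The species count a
method implies over a scope is computed by exact tiling: enumerating all
sets of supported, pairwise-disjoint hypotheses whose union covers the
scope's ids. Nesting automatically makes a parent and its children
mutually exclusive alternatives, and a composite hypothesis excludes its
parts, because overlap is checked on id sets. Ids covered only by
untestable hypotheses are dropped from the scope with a warning (an
untestable singleton should not veto every tiling). The search is
exhaustive and anchored on the smallest uncovered id, so each tiling is
produced exactly once; it is intended for hypothesis counts up to a few
dozen.

## Synthetic data

The generator emulates a deeply structured barcode study. A Yule topology
over `K` species receives split ages mapped into [0.55, 1] × the species
depth — even the shallowest between-species divergence stays above half
the deepest, the situation typical of long-isolated barcode clusters —
with the root split exactly at the configured depth (default 0.09
substitutions/site, i.e. pairwise between-species divergences around
15–21% after ancestral coalescence is added). Each species' samples
coalesce in an independent neutral Kingman coalescent of scale
`pop_scale` grafted at the species tip, and each species-tree join adds
one ancestral coalescent waiting time. The default `pop_scale = 0.002`
puts pairwise within-species divergence near 0.4%, the scale of
well-sorted barcode clusters (the units delimitation methods actually
recover); the deliberately composite, deeply subdivided groups of real
studies sit far above this and are what the methods are supposed to
split. Default sample sizes (26, 1, 12, 6, 12, 6, 19) include a singleton
species so the `na` pathways are exercised.

Sequences evolve site-independently under a two-parameter
transition/transversion process (default rate ratio κ = 4) whose branch
lengths are expected substitutions per site, so pairwise K2P estimates
recover path lengths; the exact K2P transition probabilities are used per
branch, not a discretized approximation. Group-diagnostic indels are
injected post hoc as disjoint species-specific deletion blocks with the
truth columns reported, which round-trips through the diagnostic-column
finder by construction. Indel *evolution* is not modeled; neither are
recombination, migration or selection. The gene trees come from grafted
per-species coalescents rather than a full multispecies-coalescent
sampler: there is no incomplete lineage sorting across species, so tests
passing on these data say nothing about robustness to ILS, introgression
or sampling artifacts in real data.

Everything is seeded: a dataset is byte-identical under the same
configuration, and derived seeds for sequence evolution and indel
placement are decoupled from the tree seed.

## Numerical choices and degenerate inputs

* Distance matrices must have a zero diagonal and exact symmetry; NaN
  marks inapplicable entries and is excluded (with a warning) from every
  summary.
* ABGD refuses matrices with inapplicable entries — a saturated pair
  cannot anchor a deterministic linkage graph.
* GMYC requires ≥ 3 tips, binary topology after preparation, and strictly
  positive waiting intervals (hence the jitter).
* Optimization failures after all restarts raise with diagnostics rather
  than returning a partial fit.
* All permutation/simulation p-values use add-one estimators or explicit
  proportions; none can silently be 0.

## Problem sizes used in the test suite

The suite runs the full pipeline at the scale of a single barcode study:
82-tip default datasets, 50 seeded replicates for recovery rates, 200
50-tip coalescent trees for the type-I calibration of the GMYC LR test,
and exhaustive enumerations up to 8 tips for the reciprocal-monophyly
oracle. These sizes keep each statistical check to a few minutes while
leaving the Monte-Carlo error well below the decision margins being
tested.
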