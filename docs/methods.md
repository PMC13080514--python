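# Methods

## Model and statistics

seedprox treats the interactome as an undirected simple graph over protein
identifiers; edge confidence scores are used only for optional load-time
filtering, never as weights. For a seed protein *s* and a gene set *G*
mapped onto the node set (seed removed), three statistics are computed:

- level-1 count `|N(s) ∩ G|`;
- level-2 count `|{v ∈ G : d(s, v) = 2}|`, with distance the unweighted
  shortest path, so level-1 and level-2 partition *G* and a member adjacent
  to the seed is never double-counted at distance two;
- bridging count `|{u ∈ N(s) : u adjacent to some level-2 member}|`.

Bridging is defined purely topologically rather than restricted to
non-gene-set nodes: an intermediary that happens to be in the gene set is
reported both as level-1 and as bridging. Forcing the classes disjoint
would silently drop exactly the biologically interesting case of a direct
interactor that also relays a second gene-set protein.

The production path is a breadth-first expansion truncated at depth 2,
precomputed once per (network, seed) (`SeedNeighborhoodIndex`) so that
resampling thousands of null sets costs a few set operations each. An
independent oracle (`neighborhood_oracle`) recomputes the same contract
from a full all-pairs shortest-path table and shares no traversal code; the
test suite requires exact agreement of all three member sets on hundreds of
random graphs.

Degenerate inputs are defined, not errors: an isolated seed or an empty
gene set yields all-zero counts; a gene set that maps to zero network nodes
produces a flagged all-zero report row with p = 1.

## Null model

Observed counts are compared with `n_samples` random gene sets of the same
size, degree-matched to the observed set: for each member, one node is
drawn uniformly without replacement from that member's degree stratum.
Matching is exact-degree by default; `log2` strata (floor of log2 degree,
degree-0 nodes apart) are available for sparse degree spectra. A stratum
with too few candidates falls back to the nearest non-empty stratum (this
cannot occur for valid templates under exact matching, but guards external
bin assignments); the seed is never a candidate.

The empirical p-value uses the add-one estimator `(1 + k)/(1 + n)` with
`k` the number of null samples at or above the observed value. It is never
zero, and ties count toward the tail, which makes the test conservative on
discrete counts: when the achievable tail probabilities of a small count
statistic straddle α, the realized type-I error falls below α (measured
~0.01–0.05 at α = 0.05 for size-30 sets on ~500-node networks, depending
on the network instance and statistic granularity). This conservatism is a
property of any tie-respecting permutation p on integer counts and is
accepted rather than patched with mid-p or randomized rejection.

Fold change is `observed / mean(null)`. When the null mean is zero the
value would be an artefact, so it degenerates to 1.0 if the observed count
is also zero and to an undefined sentinel (NaN, `NA` in reports, `null` in
JSON) otherwise.

Defaults: `n_samples = 1000`, `alpha = 0.05`, exact matching. All
randomness descends from a single root seed through named
`numpy.random.SeedSequence` sub-streams: one child per null sample, and in
the multi-study workflow one stream per study keyed by a hash of the study
name, so adding or removing a study leaves every other row's p-values
bit-identical. Identical inputs and seed give byte-identical reports.

## Multi-study workflow

Each study is mapped, counted and tested independently; a study is
significant when any of its three p-values is below α. No cross-study
multiplicity correction is applied by default — per-study flags feed the
union step, where pooling already dilutes isolated false positives — but a
Benjamini–Hochberg option (`bh_correct`, applied per statistic across
studies) is available. The union of the significant studies' raw gene sets
is then re-analyzed exactly like a single study, with fresh null draws from
its own sub-stream, and every level-1 interactor of the union is attributed
to the significant studies containing it.

## Synthetic data

The generator emulates what the analysis assumes about real inputs:

- **Networks.** Barabási–Albert preferential attachment (`m` edges per
  arriving node, default 3) or a power-law configuration model (exponent
  default 2.5, minimum degree 2, degrees capped at n/4, self-loops and
  multi-edges discarded, largest component kept). The minimum degree of 2
  keeps the stand-in near the dense core of curated PPI networks — whose
  mean degree is far above 2 — and prevents largest-component selection
  from shedding a quarter of the nodes. Node labels are synthetic
  (`P0000`…).
- **Seed choice.** By default the highest-degree node whose closed
  2-neighborhood covers at most 30% of the network
  (`seed_ball_coverage = 0.30`). At genome scale a hub seed's 2-ball is a
  small minority of the interactome; on a 500-node surrogate the top hub's
  2-ball can cover ~80% of the graph, in which case a "proximal" gene set
  is barely distinguishable from a uniform one and the planted alternative
  collapses into the null. The cap restores the minority-coverage geometry;
  `None` disables it (plain top hub), and an explicit `seed_node` overrides.
- **Gene sets.** Each member is drawn with probability π uniformly from
  the seed's distance-≤2 nodes and otherwise uniformly from all remaining
  non-seed nodes, without replacement: π = 0 is exactly uniform (the null),
  π = 1 draws only from the 2-neighborhood (error if it is smaller than the
  set size). Planted sets are deliberately *not* degree-matched to
  anything: they emulate GWAS hit lists, whose degree bias is precisely
  what the degree-matched null corrects; removing that bias from the
  generator would assume away the problem.

What the generator does **not** emulate: literal interactome size (~17k
proteins; defaults use hundreds of nodes), edge-confidence structure,
study-to-study gene overlap, and identifier noise. Passing tests therefore
demonstrate correctness and calibration of the machinery at surrogate
scale, not numeric agreement with any database snapshot — counts against a
specific interactome version must be reproduced with that version as
input.

## Calibration and power experiments

`calibration_experiment` draws, per replicate, a uniform template and
replaces it by one draw of the matched sampler itself, so observed and
null sets are exchangeable and the nominal rejection rate is the target.
It runs at the network's top hub regardless of the coverage cap:
calibration holds for any seed by exchangeability, and the hub is where
all three counts have non-degenerate null distributions, making the rate
estimate informative rather than trivially conservative.

`benchmark` sweeps a π grid on one scenario network (rejection = any
statistic below α, matching the workflow's flag), reporting per-statistic
and any-statistic rates with Clopper–Pearson 95% intervals. Default
experiment sizes (400 calibration replicates, 100 power replicates, 500
null samples) estimate a 5% rate to ±2 percentage points and keep a full
run within about a minute on one CPU.

A structural note on planted-study recovery: with three studies of which
one is planted and flagging at α = 0.05 per study without correction, the
expected rate of runs in which the planted study is the *only* flag is
`power × (1 − t)²` where `t ≈ α` is each uniform study's false-flag rate —
about 0.90 even at power 1. The planted study itself is recovered in
essentially every run; occasional extra flags are the calibrated test
doing what a 5% level permits.

## Identifier handling

All identifiers are whitespace-trimmed and upper-cased on load, giving one
case-insensitive namespace shared by network and gene sets. When the two
use genuinely different vocabularies (UniProt entry names vs gene
symbols), a two-column TSV map translates gene symbols to network
identifiers; no online mapping service is consulted. The seed is removed
from any gene set containing it (logged), since a protein cannot be its
own interactor.

## Known limitations

- Empirical p-values are bounded below by `1/(n_samples + 1)`; ranking
  studies far beyond that floor requires more null samples.
- Exact-degree matching on very sparse degree spectra can make null sets
  nearly deterministic within rare strata; use `log2` matching there.
- The workflow's union step inherits per-study false flags at rate ≈ α
  per study when run uncorrected (by design, mirroring per-study
  reporting); enable `bh_correct` when many studies are screened.
- No statistics beyond distance 2 are defined, and confidence scores are
  not propagated into the statistics.
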