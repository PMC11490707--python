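# Methods

## The model

`traitnets` treats the functional structure of a community as a graph.
The observation unit is a community sample (a site or transect in modern
surveys, a whole assemblage in fossil time bins); the variables are
*trait values* — the individual levels of categorical traits, e.g.
"corallivore" within trophic level. Two trait values are connected when
their prevalences co-vary across observations. The resulting undirected
graph summarizes which parts of trait space are occupied together, and
its structure is read as a proxy for community resilience: high
modularity, edge density and degree centralization indicate redundancy
and buffering, while the loss of nodes or edges after a disturbance
indicates loss of functional breadth.

The pipeline is:

1. **One-hot expansion.** Each categorical trait with L levels becomes L
   binary columns; a species with data for a trait has exactly one 1
   among that trait's columns. A species missing a trait gets all-zero
   columns for it and is flagged.
2. **Observation matrix.** With abundance/biomass data, the
   community-weighted mean `CWM(s, t) = Σ_i w_si x_it / Σ_i w_si` gives
   the weighted share of community `s` carrying trait value `t` (in
   presence/absence mode, the share of present species). Species missing
   a trait are excluded from that trait's denominator only, so other
   traits' CWMs are unbiased. Without site structure (fossil mode) the
   one-hot species × trait-value matrix is used directly, species as
   rows.
3. **Correlation.** Pearson product-moment r per trait-value pair across
   observations, two-sided p from the exact t transform with n−2 df. On
   binary columns this r *is* the phi coefficient, so fossil-mode
   networks need no special casing. Zero-variance columns (trait values
   absent or universal) are dropped from the node set with a warning —
   a trait value wiped out by an extinction simply vanishes from the
   post-event network.
4. **Thresholding.** The default inclusion rule requires both p < α
   (default 0.05) and |r| ≥ r\* (default 0.2). Both pieces, the
   p-only / r-only variants, a positive-only mode, optional
   Benjamini–Hochberg correction, and a switch excluding within-trait
   pairs are configurable and recorded in the network's provenance.
5. **Metrics.** Edge density m/C(n,2); modularity Q of a detected
   partition (Newman–Girvan form); Freeman degree centralization
   Σ(d_max − d_i)/((n−1)(n−2)); per-node degree, standardized degree
   d/(n−1), and the keystone ranking (degree descending, lexicographic
   ties). All metrics ignore edge weights: the network under study is
   the thresholded binary graph.

## Choices that were genuinely open

**Signs.** One-hot levels of the same trait are structurally negatively
correlated. By default negative correlations do form edges (sign kept as
an edge attribute), and within-trait pairs are included; both are
switches. For *module interpretation* the positive-only network is the
meaningful object: modules are sets of trait values that co-occur, and
an unsigned modularity cannot use the information that two blocks
anti-correlate — it will happily merge blocks connected by negative
edges. The planted-block recovery analyses therefore use
`signed="positive_only"`.

**Module detection.** Default is deterministic greedy agglomerative
(Clauset–Newman–Moore) modularity maximization over a canonically
node-ordered copy of the graph, so repeated runs agree without seeds —
run-to-run stability matters when thousands of bootstrap networks are
compared. `fastgreedy` is the same algorithm in igraph's C
implementation (also deterministic), used where many replicate networks
must be scored; `louvain` is available with a mandatory seed. Greedy
CNM can stop short of the global optimum: on all fixture graphs with
n ≤ 8 it matches exhaustive search except the 6-path (Q 0.26 vs 0.30),
which the tests pin explicitly. Edgeless graphs get singleton modules
and Q = 0 by convention.

**Degree centrality as one number.** The network-level "degree
centrality" is implemented as Freeman centralization, which is 1 for a
star and 0 for any regular graph. Note that at fixed (n, m) it is a
function of the maximum degree alone, so its null distribution under
G(n, m) is strongly atomic — relevant for test calibration (below).

**Bootstrap unit.** The resampling unit is the observation row: sites in
CWM mode, species in direct mode. Row resampling preserves the
trait-column structure and is the standard bootstrap for "how variable
is this network under re-sampling of the communities we measured". It
does *not* capture variability in the species pool itself when rows are
sites; a comparison between groups that differ in species composition
beyond site sampling will be anti-conservative to a degree that grows
with the unmodelled variance.

**Comparison decision rule.** `compare_groups` reports group medians and
IQRs, percentile 95% CIs and their overlap, Welch's t and Mann–Whitney
U (two-sided) — the statistics conventionally quoted — plus the
percentile 95% CI of the replicate-wise metric difference, to which the
`significant` flag is keyed. The U and t tests treat two ensembles of B
bootstrap replicates as 2B independent observations, which they are not:
each ensemble clusters tightly around its own dataset's statistic, so
those p-values overstate evidence and should be read as descriptive.
The difference CI is a proper percentile bootstrap test and is the
calibrated decision under the bootstrap's own assumptions.

**Permutation p-values.** p = (k+1)/(B+1) with ties counting as extreme;
p is never 0. Two-sided doubles the smaller tail, capped at 1. With a
continuous metric (modularity Q) the type-I error sits at the nominal
level; with an atomic metric (centralization at fixed (n, m)) ties make
the test conservative — a safe direction, but worth knowing when a
"non-significant" centralization is reported against nulls.

**Seeding.** Every stochastic operation takes a master seed which spawns
one child stream per replicate (`numpy` SeedSequence). Enlarging B
extends an ensemble without reshuffling early replicates, and identical
seed + config gives bit-identical ensembles and comparison results.

## The synthetic generator

The generator plants trait structure through latent *strategy blocks*
(the r- vs K-strategist picture): each species belongs to a block, each
block has one signature level per trait, and a species draws its own
block's signature with probability ρ_in, a specific other block's with
ρ_out, otherwise uniformly. With ρ_in = ρ_out, block membership is
uninformative and between-trait edges appear at the nominal α rate.
Site biomass is log-normal scaled by a Gaussian affinity between the
site's gradient position and the block's optimum, plus an occupancy
draw, so opposite ends of the gradient are dominated by different
strategies and signature trait values co-vary across sites.

Default shapes mirror the two data settings the method targets: a
modern survey (183 species, 40 sites, five traits with 4/4/6/8/5 levels
→ 27 trait values, ρ_in = 0.85, log-normal σ = 0.8, gradient width 0.4)
and a fossil assemblage (115 taxa, four traits with 4/5/5/4 levels → 18
trait values, no site structure). The extinction filter multiplies a
base survival probability by per-trait-value factors; survival 0 for a
trait value removes every carrier and hence the node.

What the generator does *not* emulate: spatial autocorrelation between
sites, intraspecific trait variation, preservation bias beyond
trait-targeted downsampling, and real abundance distributions' zero
inflation beyond a simple occupancy draw. Tests passing on these data
show the machinery is correct and the effects detectable under planted
structure; they do not show that real communities carry such structure.

## Validation experiments and the sizes used

* **Closed forms / oracles.** Metrics checked to 1e-12 against direct
  formula evaluations on ~30 fixture graphs; detected partitions against
  exhaustive maximum-Q search for n ≤ 8; correlation r/p against an
  independent two-pass textbook implementation on 100 random matrices,
  including the phi identity on binary data.
* **Null-model calibration.** 500 observed networks drawn from
  G(18, 31); each tested two-sided on modularity Q against B = 999
  nulls (fastgreedy backend for both sides of the comparison).
  Rejection at α = 0.05 lands within 0.05 ± 0.02. Q is used because it
  is continuous; centralization's atomic null makes the tie-conservative
  p systematically under-reject, which is reported, not hidden.
* **Bootstrap null coverage.** 200 repeats; each draws two independent
  surveys from one scenario with exchangeable sites (no gradient
  structure, 60 species × 60 sites, 10 trait values), bootstraps each
  B = 200, and compares edge density. The difference-CI decision is
  non-significant in ≈95% of repeats. Exchangeable rows are the
  bootstrap's validity premise; with a strong site gradient or with
  group sizes far from this regime the test drifts conservative or
  anti-conservative respectively, which is inherent to bootstrapping
  thresholded network statistics, not fixable by a switch.
* **Planted-structure recovery.** 20 seeds of the default two-block
  survey scenario; detected modules of the positive-correlation network
  match the planted blocks with median adjusted Rand index 1.0
  (required ≥ 0.8).
* **Extinction direction.** 20 seeds of the fossil scenario with
  survival 0.15 on one block's signature values (0.9 elsewhere): median
  post-extinction edge density falls below the pre-extinction median,
  with node loss when a trait value loses all carriers.

These sizes are the package's chosen simulation conditions and are the
same ones `scripts/acceptance.py` re-runs.

## Reproducing published-style analyses with real data

The two workflows the package automates end-to-end — a two-region
bootstrap comparison of survey data and a pre/post extinction contrast
of fossil occurrence data — expect a site × species CSV and a species ×
trait CSV (`traitnet build|compare|nulltest`), or occurrence lists per
time bin in direct mode. With the corresponding published datasets in
hand, the same configuration reproduces those analyses; no such data
ship with the package, so its tests rely on the synthetic scenarios
above.

## Known limitations

* Pearson r on CWM compositions ignores the compositional constraint
  (within a trait, level CWMs sum to 1); within-trait negative edges are
  partly structural. The within-trait switch exists for this reason.
* Bootstrap ensembles underestimate between-dataset variance whenever
  the groups differ by more than row sampling (see above).
* Greedy modularity is a heuristic; exact maximization is exponential
  and only used as a test oracle at n ≤ 8.
* Metrics are computed on the binary thresholded graph; weighted
  analyses are out of scope.
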