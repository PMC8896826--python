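# Methods

## Trees and the patristic metric

All computation happens on a rooted (or basally multifurcating) Newick
tree with non-negative branch lengths in expected substitutions per site.
Leaf labels are kept byte-exact — no quoting/underscore translation — so
they can serve as join keys against screen tables. Missing branch lengths
default to 0 with a warning; negative lengths are a hard error, since the
patristic metric is undefined for them. Internal-node labels (bootstrap
supports) are carried through I/O but never used.

The patristic distance d(i,j) is the sum of branch lengths on the unique
path between leaves i and j. It is computed in one postorder sweep (each
node carries distances to its descendant leaves; cross-child pairs are
completed by an outer sum), O(n²) time, exact to floating-point addition.
Distances are rooting-invariant; the clade-restricted clustering below is
not, and uses the tree as written.

The "distances from the focal leaf" vector excludes the focal's own zero
entry, so a tree of n leaves yields n−1 distances — matching the
convention of reporting 191/195 distances for 192/196 orthologs.

## Representative selection

**Stage 1 — threshold clustering.** Two diameter-constrained variants:

* `max_clade` (default): a clade is kept whole iff its leaf-pair diameter
  ≤ threshold; otherwise recurse into its children. Per-clade heights and
  diameters come from one bottom-up pass.
* `max`: clusters need not be clades. A bottom-up greedy sweep merges
  child lineages at each node and, whenever the two deepest incoming
  lineages would join two leaves at distance > threshold, cuts the deeper
  lineage off as a finished cluster (ties cut the lineage with the lower
  post-order index). On a tree metric this greedy attains the minimum
  possible number of clusters; the test suite verifies that against an
  exhaustive bitmask-DP partition oracle on small trees.

The default threshold 1.75 is the study-scale value for ML protein trees
of this kind. Cluster ids are assigned in leaf post-order of each
cluster's first member, making output deterministic.

**Stage 2 — subclustering.** Each cluster of size n_c is split into
k_c = min(n_c, max(1, ⌈f·n_c⌉)) subclusters, f = 0.2 by default: the
ceiling-with-floor-one rule guarantees every cluster contributes at least
one representative, which is why ~24% of leaves end up selected at
f = 0.2 when many clusters are small. Agglomerative clustering runs
directly on the patristic submatrix with average (default), complete, or
single linkage; `average` here is the unweighted mean of all original
cross-group distances. Merge ties are broken toward the pair with the
lexicographically smallest (min-label, min-label) signature. The
implementation is in-package so this tie-break is explicit; on tie-free
data it coincides with `scipy.cluster.hierarchy.linkage` + `cut_tree`,
which the tests use as an independent cross-check.

**Stage 3 — one representative per subcluster.** Highest user-supplied
priority rank wins (convention: reference strain = 2, previously tested
= 1, everything else 0); ties fall back to the subcluster medoid (minimum
summed patristic distance to the other members, tolerance 1e-12 on sum
ties); remaining ties take the lexicographically smallest label. The
selection reason (`priority` / `medoid` / `lexicographic`) is recorded per
representative.

## Rank statistics

**Wilcoxon rank-sum / Mann-Whitney.** Mid-ranks handle ties. For pooled
sizes ≤ 25 the exact two-sided p is the doubled smaller tail of the
permutation distribution of the rank-sum over the observed pooled
multiset, computed by integer dynamic programming over doubled mid-ranks
(with ties that distribution is asymmetric, which is why the doubled-tail
convention — the one exact implementations use — is fixed here). Above
that, a normal approximation with tie-corrected variance

σ² = (n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))]

and a 0.5 continuity correction (toggleable) gives p = 2·Φ(−|z|), capped
at 1.

**Kruskal-Wallis.** H = 12/(N(N+1)) Σ R_c²/n_c − 3(N+1), divided by the
tie correction 1 − Σ(t³−t)/(N³−N); p from χ² with C−1 degrees of freedom.
All-identical data short-circuits to H = 0, p = 1.

**Representativeness.** The selected subset's distances-from-focal are
compared against the *full* set's (the subset is part of the reference
sample, deliberately reproducing how subset representativeness is
conventionally assessed). Because the samples overlap, the test is
conservative: under random 25% subsampling the p-values are uniform for
the disjoint subset-vs-complement comparison but skew high (median ≈ 0.6)
for the overlapping one. Diversity-stratified selection skews them higher
still — by design it is *more* representative than a random draw. The
calibration tests assert exactly this: uniformity for the disjoint
comparison, never-anti-conservative behaviour and median p > 0.3 for the
pipeline's own selections, and p < 0.05 in ≥ 95% of replicates when the
selection is deliberately biased to the most distant leaves.

## Correlation ratio

η² = SS_between/SS_total of the distances across outcome categories;
η = +√η². Errors are raised when only one category or zero total variance
remains — an association is undefined there, not zero. η is invariant
under affine rescaling of the distances and, for binary outcomes, equals
the R² of the dummy-coded least-squares fit (both property-tested).
Screen outcomes are binarized with `partial` (+/−) counting positive by
default (the published counts include the partial complementer among the
8 positives); not-tested and unknown entries are dropped. The focal
host's row (distance 0, positive) is included by default, as it is a row
of the reference screens; a flag excludes it.

## Screen tables

The two bundled TSVs transcribe the published NadA and IspG screens (48
rows each) with controlled vocabularies enforced at load time; violations
are reported with row numbers. The `complemented_or_recovered` column is
validated against — never trusted over — the disjunction of the
per-condition columns. "Additional" recovery counts exclude the anchor
ortholog already active in the reference condition (the SUF-donor row for
*B. subtilis* SUF counts). For the proteomics counts, an ortholog is
*unrecovered* when neither growth condition (aerobic, anaerobic) supported
complementation: the detection cultures were grown without helper-protein
coexpression, so recovery by coexpressed SUF or electron carriers does not
enter that denominator — this is the reading under which the detection
counts (7/7 and 5/5 for NadA; 16 analyzed / 10 detected / 8 of 13
unrecovered for IspG) are internally consistent.

## Synthetic data

**Trees.** Yule (pure-birth) process: at k extant lineages the waiting
time to the next split is Exp(k·λ), the splitting lineage uniform; a final
Exp(n·λ) stretch follows the last split. Expected root-to-tip depth is
Σ_{k=2..n} 1/(kλ) (≈ 4.88 at n = 200, λ = 1), which the tests check to
15% over 200 replicates. Pure birth was chosen over birth–death precisely
for this analytic checkability. λ = 1 puts depths on the same scale as the
reference ML trees.

**Traits.** `clade_gain` picks the internal (non-root) clade containing
the focal leaf whose size is closest to `clade_fraction·n` and draws
positives with p_in inside, p_out outside — coupling clade membership and
distance-from-focal the way an oxygen-tolerance clade couples them around
an aerotolerant host. `distance_decay` uses a logistic
P(+) = 1/(1+exp((d−d0)/s)). `random` is iid Bernoulli. Defaults
(p_in = 0.95, p_out = 0.05, clade_fraction = 0.5; unstructured base rate
8/47) are the observed outcome rates of the reference screens: 22 of 23
in-clade and 1 of 24 out-of-clade aerobic-including-SUF complementers for
the structured enzyme, 8 of 47 for the unstructured one. The helper
`default_focal` returns a leaf inside the best-matching clade, mirroring a
host ortholog that sits inside its family's dominant clade.

What the simulation does **not** emulate: real ML branch-length error,
non-ultrametric rate variation, correlated traits beyond a single clade
or monotone distance effect, and the particular topology of any real
enzyme family. Passing calibration tests therefore shows the statistics
and pipeline behave correctly under controlled signal/no-signal regimes,
not that any specific biological screen will reach a particular η.

**Permutation null.** `eta_null_distribution` shuffles outcome labels
over leaves with distances fixed and reports the observed η's percentile.
Under random labels that percentile is uniform (KS-checked over 200
seeds); under injected clade signal the observed η exceeds the 99th null
percentile.

## Problem sizes and determinism

Calibration and acceptance computations use 100–200 replicates of
100–192-leaf trees — large enough for stable means and KS tests, small
enough that the entire test suite runs in well under a minute. Every
random draw descends from an explicit integer seed; simulation outputs
embed their parameters and seed, and reruns are byte-identical.

## Known limitations

* The `max` clustering oracle guarantee is verified exhaustively only up
  to 10 leaves; beyond that the greedy's optimality rests on the known
  result for tree metrics.
* The exact rank-sum DP is O(n₁·N²·maxrank) and is capped at pooled size
  25; larger samples use the tie-corrected normal approximation.
* Subclustering is O(n_c³) per cluster in the worst case — fine for the
  tens-of-leaves clusters this pipeline produces, not meant for thousands.
* The overlapping representativeness test is conservative (see above);
  its p-values are not uniform under the null and should be read as
  "large means no evidence of bias", not as calibrated error rates.
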