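# Methods

This note documents the models, estimators and design choices behind
`engramnet`, in the spirit of the methods appendices of statsmodels or
msprime: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not establish.

## Network construction

Per animal and time bin, the Spearman rank correlation rho and its
two-sided p-value are computed for every unordered region pair
(scipy's t-approximation by default; an exact permutation option exists
for bins of fewer than ~8 samples, where the approximation is poor).
Midranks handle ties.  The multiple-comparison family is the set of
m = C(n_regions, 2) pairs — with the full 21-region panel, m = 210 —
and the Bonferroni-adjusted p is min(1, m * p_raw).  An edge enters the
functional network iff p_adj < alpha (default 0.001) **and** rho > 0;
the retained rho is the edge weight.  Negative correlations are never
edges, and the node set is always the full region panel, so nodal
tables keep 21 rows even when regions are isolated.

Group consensus networks retain an edge iff it is significant in at
least `min_fraction` (default 0.75) of the group's individual networks;
its weight is the mean rho over the networks in which it was
significant.  An option averages over all animals instead, as a
sensitivity variant; the per-edge retention fraction is always
recorded.  The family covers pairs only, not bins: each bin's network
is a separate analysis.

## Graph measures

Edge weights are correlations, so strong coupling means functional
proximity; all path-based measures use edge length 1/w.  Global
efficiency is the mean of 1/d(i,j) over unordered pairs, with
disconnected pairs contributing 0.  Clustering is the global
transitivity (3 x triangles / connected triples) of the binarized edge
set — the triangle/triple definition is inherently unweighted.  Edge
density is |E| / C(n, 2).

Hub scores are eigenvector centralities: the leading eigenvector of the
weighted adjacency (dense symmetric eigendecomposition), sign-fixed,
clipped at 0 and scaled to max = 1.  On a disconnected graph the
component with the largest eigenvalue carries the scale and other
components score ~0, matching common graph-library behavior.  Scores
are invariant to uniform weight rescaling.  Betweenness uses Brandes'
algorithm with fractional credit for tied shortest paths; closeness is
(n_reachable − 1) / sum of distances within a node's component.
Per-animal measures are compared across groups after normalization to
percent of the group's baseline-bin (T1) mean, so the group baseline
mean is exactly 100%.

## Communities, diversity, roles

Louvain maximization of weighted modularity (resolution 1) with a
seeded shuffle makes partitions reproducible; the reported Q is
re-evaluated from the returned partition, and a test asserts agreement
with a from-definition modularity sum to 1e-12.  Diversity is the
Shannon entropy, in bits, of the distribution of a node's neighbors
over communities; isolated nodes score 0.  The entropy base only
rescales ranks, which is all the role rule consumes.  Roles cross two
flags computed from empirical upper quantiles (default top 20%, i.e.
the ceil(0.2 n)-th largest value, ties included so exact-equality
boundaries never drop a node arbitrarily): hub x connector =
ConnectorHub, hub only = ProvincialHub, connector only =
NonHubConnector, neither = Peripheral.

## Resampling inference

**BCa bootstrap.**  Group contrasts of per-animal (baseline-normalized)
measures resample each group with replacement (default 1000 draws) and
report bias-corrected-and-accelerated intervals at 95/99/99.9%.  The
bias correction z0 comes from the proportion of bootstrap draws below
the observed difference, with a midpoint rule for draws exactly equal
to it (so a symmetric discrete bootstrap distribution yields z0 = 0);
the acceleration comes from the jackknife skewness of the pooled
leave-one-out replicates.  Significance at a level means that interval
excludes zero.  A test cross-checks the endpoints against scipy's
independent BCa implementation.

**Rewiring permutation test.**  The observed statistic is the per-node
hub-score difference between two consensus networks.  Each null draw
rewires both networks by degree-preserving double-edge swaps — a swap
relocates two edges, each keeping its weight, and is rejected if it
would create a self-loop or duplicate — targeting 10 x |E| accepted
swaps per draw with a cap of 100 tries per requested swap (consensus
networks are dense, so acceptance rates of a few percent are normal and
the cap binds; the resulting ~1.5 x |E| accepted swaps still fully
randomize the 21-node graphs).  The two-sided p-value is
(#{|null| >= |obs|} + 1)/(n_perm + 1), never exactly 0.  The swap loop
is numba-compiled; the null loop runs on flat edge arrays.

This null answers a specific question: *is the observed hub-score
difference larger than the degree sequences alone would produce?*  It
is **not** calibrated against cohort resampling variation — under a
no-effect cohort null the observed differences (sampling noise, ~0.01-
0.05) are an order of magnitude smaller than rewired-null draws
(~0.1-0.5), so the test is strongly conservative there (empirically a
0% rejection rate at alpha = 0.05 over 200 null cohorts).  Consequently
a planted effect is detectable only when it changes *weight
organization at fixed degrees*; see the generator design below.  The
permutation count is a parameter (default 1000) since both 1,000 and
10,000 are defensible conventions.

**Behavior correlation.**  Per-animal hub scores from each animal's own
final-bin thresholded network (individual networks are the only route
to per-animal values) are correlated with late extinction-learning
percent-correct, pooled across both groups, with per-region Pearson r
and two-sided p.

## Disruption propagation (in-silico lesions)

All nodes start with activity 1.  Deleting the target sets it to 0;
every surviving node's activity becomes 1 − (incident weight lost to
deleted nodes)/(original total incident weight); nodes below the
activity threshold theta join the deleted set; iterate to fixed point
(capped at n iterations).  Surviving edge weights scale by the product
of endpoint activities, and DeltaGE = GE(original) − GE(surviving
subgraph).  The cited propagation idea is reconstructed here as an
explicit, parameterized rule — theta (default 0.5) and the iteration
cap are echoed into every output so sensitivity to the reconstruction
is measurable.  GE(after) is computed over surviving nodes only, so
deleting an isolated node can *raise* efficiency through the pair-count
change; monotonicity is guaranteed only for weight shrinkage on a fixed
node set, and the tests assert exactly that.

## Synthetic cohort generator

Each animal's signal is a latent-factor model: one white-noise factor
per community plus a global factor; region r in community c emits
`L_c f_c + g f_glob + sum cross-loadings + noise` per sample.  Defaults
emulate the study design: 21 named regions in four latent communities
(dorsal-hippocampal, ventral-hippocampal, prefrontal, midline relay),
2 groups x 8 animals, 4 bins x 900 samples (15 min at TR = 1 s; the
per-bin count is a parameter since the acquisition arithmetic admits
readings between 900 and 1200), within-community rho ~0.5-0.6 and
significant cross-community rho ~0.2 — a regime typical of band-passed
anesthetized-rodent BOLD.  An optional AR(1) coefficient (default 0)
injects autocorrelation for sensitivity checks; there is no hemodynamic
convolution, since rank correlations are the only consumer.

The planted reactivation effect is deliberately a *weight* effect at
fixed topology: the hub regions (dDG, dCA3, dCA1) hold supra-threshold
baseline loadings onto the relay community in both groups, and the
reactivation boost multiplies those loadings (per-animal gain
multiplier ~ N(1, 0.25), clipped at 0) in post-injection bins.  Both
group networks then share edge sets and degree sequences, and the
boosted mutual (hub-hub) and hub-relay coupling concentrates the
leading eigenvector on the hub triad — which is precisely the kind of
difference the degree-preserving rewiring null can detect.  Two
connector regions (PPC and RE) with fixed cross-loadings keep the
networks integrated; the ventral module's stronger within-loading (1.3)
anchors the control groups' dominant eigenvector away from the hubs, so
hub scores have room to rise under reactivation despite max-
normalization.  Earlier designs in which the boost *added* edges were
rejected: a degree-preserving null reproduces degree-driven
eigencentrality changes, making such effects undetectable by
construction.

Behavior: controls start above chance (65%) and extinguish to 50%
across three blocks; reactivation animals persist near 70%, with the
final ("late") block equal to chance + 2 + 12 x (planted hub strength)
plus N(0, 5) noise, clipped to [0, 100].  Because the group gap in
behavior co-occurs with a broad group shift in eigenvector anchoring,
the pooled behavior-hub correlation flags more regions than the three
planted hubs; the planted hubs are always among them, which is what the
end-to-end tests assert.

What passing tests on this generator do **not** show: robustness to
hemodynamic autocorrelation, motion or physiological artifacts,
between-animal ROI misregistration, or non-Gaussian noise; and the
single-anchor eigenvector structure is cleaner than real data.  The
generator validates the *pipeline logic*, not the acquisition chain.

## Validation design and known limitations

Every graph measure is checked against independent brute-force oracles
(Floyd-Warshall, exhaustive triangle/triple and path enumeration,
shifted power iteration) on hundreds of random weighted graphs with
n <= 8, plus closed-form cases.  Monte-Carlo studies run at the full
design scale with reduced permutation counts (99-199 draws, p-value
resolution 0.005-0.01) chosen so the whole suite completes in about a
minute while leaving the measured rates unchanged.

Two of the suite's target properties are knowingly not met, and the
corresponding tests assert them anyway rather than loosening the bar:
(i) the rewiring permutation test cannot reject at an
exact 5% rate under a cohort-resampling null (see above — it is
conservative by construction); (ii) the Pearson correlation between
DeltaGE and hub score on the synthetic reactivation consensus is ~0.65,
not >0.9: the three planted hubs are mutually redundant, so single-hub
deletions are cheap relative to the sole inter-module bridges (PPC,
RE), making the hub->DeltaGE relation monotone (rank correlation ~0.95)
but convex, which Pearson penalizes.  Adding redundant connector routes
raises the correlation to ~0.78 at the cost of the planted hubs' top-5
eigencentrality margin, and was rejected.
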