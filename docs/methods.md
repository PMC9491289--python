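# Methods

`richclubkit` analyses weighted structural connectomes — symmetric matrices
of streamline counts (NOS) between brain regions — for *rich-club
organization*: the tendency of high-degree hub regions to be more densely
and more strongly interconnected than their degrees alone require. This
note records the models, the parameter choices, and the numerical decisions
behind the implementation, and states what the synthetic validation does
and does not establish.

## Network construction

Raw directed seed-to-target streamline counts are symmetrized by the
arithmetic mean of the (i, j) and (j, i) entries. Two thresholding steps
follow, in this order:

1. **Proportional threshold** — exactly `floor(p * M)` of the `M` nonzero
   edges are retained, keeping the largest weights (default `p = 0.23`;
   stability sweeps use 0.30 and 0.55). Ties at the cut are broken by
   (weight descending, then smaller row, then smaller column index) so that
   reruns are byte-identical; the retained weights are never modified.
2. **Group prevalence mask** — an edge survives only if present in at least
   a fraction `tau` (default 0.60, boundary inclusive) of the subject's
   *own* group. Masks are computed per group, so group supports can differ;
   this mirrors the common practice for removing idiosyncratic
   (likely spurious) tractography edges.

Binary networks set every surviving weight to 1. Basic checks on the
constructed networks: density (present / possible edges), total
connectivity (sum of undirected edge weights), and connectedness (fraction
of non-isolated nodes, flagged when ≤ 80%).

## Graph measures

- **Clustering** — binary: triangles over possible triangles; weighted:
  Onnela geometric-mean of max-normalized triangle weights (delegated to
  networkx, which implements exactly this form). The global coefficient
  averages over all nodes, with degree < 2 nodes contributing 0.
- **Efficiency** — global efficiency is the mean over ordered pairs of
  1/d(i, j), with disconnected pairs contributing 0; local efficiency of a
  node is the global efficiency of its neighbor-induced subgraph (0 for
  degree < 2). Weighted path lengths use `l = max(W) / w`, the conventional
  inverse-weight map after max-normalization; the choice matters only up to
  a global scale, which cancels in 1/d ratios within a network but makes
  efficiencies comparable across subjects with different weight scales.
- **Small-world index** — `sigma = (C / C_rand) / (L / L_rand)` on the
  binary network's largest connected component, with the reference values
  averaged over degree-preserving rewirings (default 100, configurable;
  deliberately fewer than the rich-club ensemble since sigma is a coarse
  screen, not an inferential target).

## Null networks

Topology is randomized by Maslov–Sneppen double-edge swaps (10 attempts per
edge by default); every accepted swap preserves the degree sequence
exactly, and unswappable graphs (e.g. complete) are returned unchanged.

For weighted networks the original weight multiset is placed onto the
rewired edge set. Two placements are provided:

- **`rank_match`** (default): edges are scored by the sum of their
  endpoints' original strengths and sorted weights are assigned in rank
  order; a few dampened iterations rescale the working targets by the
  realized-to-target strength ratio and the assignment with the best
  strength rank-correlation is kept. This preserves the degree sequence and
  weight multiset exactly and the strength sequence to rank correlation
  ≈ 0.99 on log-normal-weight test graphs.
- **`carry`**: each weight rides along with its edge through the swaps,
  preserving the multiset exactly and the strength *distribution* only
  loosely.

The choice is consequential. A strength-sequence-preserving null
concentrates the largest weights on hub–hub edges at least as effectively
as any empirical network whose weights align with its strengths; under
`rank_match` the weighted normalized coefficient of such networks is
bounded near 1. Under `carry` the reference is weaker and planted weighted
organization stands out clearly. `rank_match` is the default because the
strength sequence is the quantity the weighted normalization claims to
control for; users comparing with literature that used weight-carrying
rewiring should select `carry`. Ensembles (default 1000 members for
rich-club normalization) draw per-member seeds from a spawned
`SeedSequence`, making every member independently reproducible.

## Rich-club analysis

With `S(k)` the set of nodes of (binary) degree strictly greater than `k`:

- topological: `phi(k) = 2 E(S) / (|S| (|S|-1))`, undefined for `|S| < 2`;
- weighted: `phi_w(k) = W_in(S) / (sum of the E(S) largest weights
  network-wide)`, undefined when the club spans no edge.

Curves are computed for all k in one pass by sorting nodes by descending
degree (every club is then a prefix) and accumulating prefix edge and
weight sums — O(N²+ E log E) per network, verified against brute-force
subgraph enumeration. Normalization divides by the null-ensemble mean at
each k, excluding members whose coefficient is undefined there (treating
them as 0 would bias high-k levels downward); the one-sided empirical
p-value uses the add-one estimator `(1 + #{phi_rand >= phi}) / (n_nulls
+ 1)`, which cannot return 0. The tested degree range is the longest
contiguous run of k where at least 97% of subjects (configurable) have a
normalized coefficient above 1; undefined levels count against a subject.

Hubs are the `ceil(f * N)` highest-degree nodes per subject (default
f = 0.16, sweeps 0.05–0.25), ties broken by strength then node index; the
group-level rich club is the intersection across subjects. Edges are
classed rich-club / feeder / local by endpoint membership, and per class we
report connectivity strength (weight sum) and weighted connectivity density
(class share of whole-network strength, computed so the three shares sum to
1 exactly). Per-k measures are summarized by trapezoidal AUC over the
tested range.

## Statistics

Group differences use two-sided permutation tests on the difference of
group means: exact enumeration whenever the number of distinct label
assignments fits in the permutation budget, otherwise sampled permutations
with add-one smoothing. Ordered three-group alternatives use the
Jonckheere–Terpstra statistic with a three-tier p-value: exact enumeration
(≤ 1e5 arrangements), seeded Monte Carlo permutation for small totals
(n ≤ 36, 9999 draws — the normal tail is anticonservative there), and the
tie-corrected normal approximation otherwise; all-tied data return p = 0.5
by symmetry. Per-k families are Benjamini–Hochberg corrected within one
measure and one comparison (q = 0.05 by default), matching the analysis
they accompany. Effect sizes are Hedges' g (pooled SD,
small-sample correction `J = 1 - 3/(4n - 9)`). Brain–behavior
correlations use Spearman partial correlation via rank residualization,
with a t-approximation on `n - 2 - #covariates` degrees of freedom; when
residual rank variance falls below the numerical floor the correlation is
reported as 0 rather than correlating round-off noise. Demographic tables
are compared with one-way ANOVA; a summary-statistics mode reconstructs the
sums of squares exactly from per-group (n, mean, SD), which is also how the
bundled worked example recomputes published F values from printed
summaries (inputs rounded to one decimal bound the attainable agreement).

## Synthetic cohorts

The generator emulates probabilistic-tractography NOS matrices well enough
to exercise every stage: a near-dense raw matrix whose strong edges follow
a planted core–periphery block structure and whose weak edges are noise.

A cohort-shared *template* (seeded independently of subjects) assigns
structural edges with probabilities `p_hh = .85 > p_hf = .20 > p_pp = .15`
and log-normal weights with log-means 7 / 6 / 5 (sigma 0.6); remaining
pairs receive background edges (presence 0.75, log-mean 3). Subjects
perturb the template: structural edges flip out with probability 0.02,
weights get independent log-normal jitter (sigma 0.2), background presence
is resampled, and weights are rounded to integers. Proportional
thresholding strips the background, and because subjects share the
template, the prevalence mask retains the planted structure — the two
properties real cohorts have that make the construction pipeline
meaningful. The block probabilities were sized so that the planted
hub–hub density (.85) clearly exceeds the configuration-model expectation
given the resulting degree sequence (≈ 0.5): only that surplus *is*
rich-club organization, and parameterizations whose hub degrees are too
high relative to periphery degrees (e.g. a hub–periphery probability of
.35 at a 16% hub fraction) force hub–hub contact in every degree-matched
null and therefore cannot show `phi_norm > 1` at any significance.

Group effects are planted on hub–hub edges: a deleted fraction `gamma_t`
(topological deficit) and a weight multiplier `gamma_w` (< 1 deficit, > 1
boost). Defaults: controls (0, 1.0), patients (0.10, 0.80), siblings
(0.15, 1.20) — a patient weight-and-edge deficit with a sibling
compensation pattern. Clinical covariates are group-shifted normals with
no built-in coupling to network structure.

What the generator does **not** emulate: spatial embedding and
distance-dependent wiring, hemispheric symmetry, the empirical NOS
magnitude (~1e9 at high-resolution parcellations; scale cancels in every
density-type measure), scanner/site effects, and any genuine
brain–behavior coupling. Passing tests therefore demonstrate correctness
of the measures and calibration of the inference on networks with the
targeted topological features — not sensitivity under realistic anatomical
confounds.

## Validation sizes and determinism

The test suite and the acceptance script run the full pipeline at 60–90
nodes with 28-subject groups (some checks 4–12 subjects), 200-member null
ensembles and 5000 permutations — sizes chosen so the planted effects are
comfortably detectable while the whole suite stays fast; the analysis
defaults (250 nodes, 1000 nulls, 50 000 permutations) remain the
recommended settings for real data. Every stochastic stage draws named
sub-seeds from the master seed (`SeedSequence`), and rerunning a pipeline
with the same configuration reproduces byte-identical output tables, which
the run manifest records as SHA-256 hashes.

## Known limitations

- The weighted rich-club verdict depends on the weighted-null flavor (see
  above); both flavors are exposed, and the run manifest records which was
  used.
- The prevalence mask is applied per group as described for the original
  analysis; group supports therefore differ, and between-group differences
  partly reflect support differences when prevalence differs strongly.
- Exact Jonckheere–Terpstra enumeration is limited to ~1e5 arrangements;
  beyond that small-sample accuracy rests on the Monte Carlo tier.
- `small_world_index` requires a connected dominant component and a
  rewireable graph; it raises on degenerate inputs rather than guessing.
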