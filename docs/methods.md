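# Methods

This note documents the models, numerical choices, and design decisions
behind `semfluent`, and what the synthetic cohorts used in the test suite
do and do not establish about real fluency data.

## Censored-random-walk likelihood

A fluency list x₁…x_L over a candidate network G is scored as

```
log P(list | G) = log( deg(x₁) / Σᵥ deg(v) )
               + Σ_{k≥2} log P(first-hit at x_k | visited x₁…x_{k−1}, at x_{k−1})
```

Each first-hit factor treats the visited items as transient states of an
absorbing Markov chain (the walk passes through them silently) and all
unvisited items as absorbing. The factor is obtained by solving
(I − T_VV) x = T_VU e_{x_k} restricted to the connected component of the
current node inside the visited-induced subgraph; restricting to that
component removes the exactly-singular block that closed visited subsets
would otherwise contribute, and the remaining system is strictly
substochastic with an escape row, hence nonsingular. A factorization-based
solve (LAPACK via `numpy.linalg.solve`) is used; the explicit fundamental
matrix is never formed. All accumulation is in log space; any zero factor
(isolated start, unreachable continuation, trapped visited component)
yields −∞ for the whole list.

Lists are treated as time-limited prefixes: truncation carries no stopping
penalty. Lists from the same participant are independent restarts and
their log-likelihoods add.

The per-prefix solves sit inside the estimator's innermost loop, so they
are compiled with numba (`semfluent._walk`). A pure-numpy mirror of the
same computation (`uinvite.first_hit_distribution`) exists for inspection
and is held equal to the kernel — and to an explicit truncated
walk-enumeration sum with a geometric tail bound — by the test suite.

## Edge prior and MAP search

The prior over networks is independent Bernoulli per unordered node pair:
p = 2/3 for pairs joined in the reference association network, p = 2/5 for
pairs whose nodes are both in the reference but not joined, p = 1/2 when
either node is missing from it. These three probabilities are configurable;
the defaults are the standard values for this estimator family. The
packaged reference network is a deterministic G(60, 240) graph over the
bundled 70-item toy animal lexicon — a stand-in object, generated by
`synthetic.make_reference_network`, not an empirical association network;
users substitute their own reference via `reference_path`.

The search is a pure hill-climb: starting from the consecutive-adjacency
graph (an edge wherever two items are adjacent in some list, which
guarantees a finite likelihood), all vocabulary pairs are swept in
seeded-random order, toggling one edge at a time; a toggle is kept iff it
improves the log posterior by more than `tolerance` (default 1e-12 — i.e.
strict improvement; ties reject). The search stops after one
acceptance-free sweep or `max_sweeps` (default 100; in practice 2–4 sweeps
suffice at the sizes we use). Single-edge toggles are the minimal complete
move set; the schedule is deterministic given the seed. This is a local
optimizer: it guarantees a posterior at least as high as the
initialization, not a global MAP.

The vocabulary of each participant's network is the union of that
participant's cleaned items. Group-level vocabularies are not used.

## Cleaning conventions

Normalization is lower-casing, trimming, and whitespace collapsing only —
no spell correction or plural folding, so behavior is fully determined by
the lexicon. An intrusion is any normalized item absent from the lexicon;
a perseveration is a within-list repeat. Both are removed before
estimation, and the cleaning report preserves exact counts (cleaned length
+ intrusions + perseverations = raw length, per list). How spelling
variants of the same animal should be reconciled is left to the lexicon
author; the cleaner does not guess.

## Graph statistics

- **ASPL** and **small-world σ** are computed on the largest connected
  component (ties broken toward the component containing the
  lexicographically smallest label). **Clustering** (average local,
  Watts–Strogatz; a transitivity variant is switchable) and **modularity**
  are computed on the full graph — the largest-component convention is
  documented for path-based measures only, and degree-local quantities are
  well defined on disconnected graphs.
- **Modularity** is the best Newman–Girvan Q over seeded Louvain restarts
  (default 10), with the single-community partition (Q = 0) always a
  candidate; exact maximization is infeasible in general, so "optimal
  modularity" means best-found, deterministic given (seed, restarts).
- **σ** uses G(n, m) Erdős–Rényi null graphs with matched node and edge
  counts (default 100 replicates); a replicate degenerating to zero
  clustering is redrawn, with a retry cap (200) that turns pathological
  sizes into an explicit error rather than a division by zero.

## Default Bayes factors

The JZS t-test Bayes factor integrates the noncentral-t likelihood of the
observed t over a Cauchy(0, √2/2) prior on the standardized effect δ, via
adaptive quadrature split at the likelihood peak (relative tolerance
1e-10), divided by the central-t density under the null. The correlation
Bayes factor integrates the exact sampling density of the sample
correlation (Hotelling's Gaussian-hypergeometric form, with ρ-free
constants cancelled in the likelihood ratio) over a stretched-beta prior
of width κ (κ = 1, the default, is uniform on (−1, 1)). Directional tests
truncate the symmetric prior to a half-line and renormalize, so the mean
of the two one-sided BF10s equals the two-sided BF10 — an identity the
tests enforce. Marginal likelihood ratios are formed in log space and stay
accurate for |t| up to ~50. The pooled-variance (Student) t is used
throughout, matching the degrees of freedom convention of the analysis
battery this package reproduces.

Both tests are cross-checked against pingouin's closed-form
implementations and against brute-force oracles (fine-grid trapezoid
quadrature over δ; Monte-Carlo prior-draw averaging over ρ), which bound
the quadrature error independently of the implementation under test.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: three groups
(monolingual n = 25, English-Spanish n = 13, Spanish-English n = 28),
three lists per participant, per-group list-length means 42.1 / 42.1 /
33.3 (SD 6.5, clipped at a 5-item floor and the component size) — the
lower mean for the SE group reflecting second-language testing. Each
participant's ground-truth network is a perturbation of the shared
reference (each edge dropped with p = 0.2; non-edges added at the
density-preserving rate), and their lists are censored walks on that
truth. Intrusions (rate 0.005, echoing the sub-0.6% rate such studies
report) come from a disjoint out-of-category token pool; perseverations
(rate 0.015, a typical fluency figure) re-emit an earlier item.

Values the design does not pin down were chosen once as field-plausible
and are not tuned: monolingual creativity mean 15.6 (between the two
bilingual group means of 16.7 and 14.5); creativity SD 6.5 (back-derived:
a t of 1.0 at df 39 with those means and sizes implies a pooled SD ≈ 6.5);
intelligence scored on a 12-item matrix-reasoning scale, mean 8, SD 2.

Creativity and intelligence are drawn through a Gaussian copula on the
*realized* per-participant statistics (ASPL, clustering, modularity, σ,
mean items): the realized values are rank-normalized, a weight vector
w = S⁻¹ρ (S their empirical correlation matrix) makes the creativity
latent achieve the target correlations ρ exactly in population, and an
infeasible target (explained variance ≥ 1) errors before generation. The
default preset is the null world — all metric-creativity correlations 0,
intelligence-creativity 0.185. List lengths are Gaussian draws rather than
time-budget simulations, because the censored-walk likelihood treats lists
as prefixes, making length ancillary to the network inference.

What passing tests show: the estimator, metrics and tests behave correctly
*under the generating model* — censored walks on sparse graphs with the
stated noise. What they do not show: robustness to real-data features the
generator omits — word-frequency effects, semantic subcategory clustering,
retrieval strategies beyond a memoryless walk, cross-language intrusions,
or spelling variation.

## Problem sizes in the shipped suites

The test and acceptance suites run at desk scale, chosen so the full run
completes in a few minutes: likelihood-oracle checks on all ≤5-node
graphs; 10⁵-walk simulator calibration; recovery over 50 seeds with a
10-node truth and up to 50 lists; and a 20-seed null-world sweep of
92-participant cohorts using a reduced-scale configuration (25-node
reference, list-length means 12 / 12 / 9, two hill-climb sweeps) — the
null-correlation property under test does not depend on list length. The
92-participant correlation sample is obtained by scaling the three group
sizes to 35 / 18 / 39, standing in for the full sample whose extra
participants fall outside the two language-classification cutoffs.

## Known limitations

- The hill-climb is a faithful but not bit-identical stand-in for the
  stochastic search of the original estimator's reference implementation,
  whose schedule is not published; posteriors agree in kind, not edge for
  edge.
- The bundled reference network and lexicon are toys; scientific use
  requires a real association network and category lexicon.
- Edge-list files cannot express isolated nodes; node sets are preserved
  separately in the estimation summary JSON.
- The copula targets population correlations; realized sample correlations
  scatter around them (and rounding/clipping of scores attenuates them
  slightly).
- Bayes factors recomputed from rounded summary inputs inherit the
  rounding: ~10% relative error is the meaningful reproduction tolerance
  against published values.
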