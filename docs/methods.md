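# Methods

## Data model and preprocessing

The pipeline consumes post-summarization array data: a strictly
positive intensity matrix (probe sets × arrays) on a MAS5-like scale
with a target intensity of 100, an aligned Present/Marginal/Absent
detection-call matrix, and per-array metadata (group ∈ {sham,
immobilized}, week ∈ {1, 2, 4, 8, 16}, replicate). Computation of
intensities and calls from raw probe-level data is upstream and out of
scope.

Two filters run per series, each series independently:

- **Absent filter.** A probe set is removed iff its call is "A" in
  every array of the series. A single Present or Marginal call anywhere
  retains it; only "A" is special, "M" is treated as informative.
- **Low-expression filter.** A probe set is removed iff its per-week
  replicate median is below the floor (default 100) at *every* week;
  retention requires at least one week at or above the floor. The rule
  is deliberately per-probe/all-weeks: removing whole probes (not
  individual values) is the only reading under which the filter
  arithmetic of a probe-count bookkeeping stays consistent
  (initial = all-absent + below-floor + retained), and the package
  asserts that identity in its run manifest.

Replicate aggregation is the standard sample median; with an even
replicate count (the design supplies 4 arrays per cell) the midpoint of
the two central order statistics is used. Medians are order-invariant
in the sample columns and scale-equivariant; log2 ratios
y_t = log2(m_t / m_1) are scale-*invariant*, so global intensity
rescaling cannot change any downstream result. Week 1 is the baseline
and is excluded from ratio profiles (its value is identically 0); a
helper can re-append the zero for plotting.

## Fold-change binning

Ratios r_t are re-expressed as signed fold changes, sFC = r if r ≥ 1
else −1/r, so |sFC| ≥ 1 and magnitude thresholds act symmetrically.
Bins are half-open on |sFC|: [1.5, 2.0) and [2.0, ∞); the boundary
value 2.0 belongs to the upper bin so that "2-fold or more" is
non-empty at the boundary, applied identically in both directions.
Direction totals count distinct probes (a probe crossing at several
weeks counts once per direction); probes crossing in both directions
across weeks are counted in both totals and flagged. Attribution
percentages — the share of a direction's probes whose event occurs at a
named week subset — are computed on distinct probes and rounded to one
decimal; they need not sum to 100 over a partition of weeks.

## Trajectory clustering

Each profile y ∈ R^4 (weeks 2, 4, 8, 16) is modelled as
y = Xβ + ε, ε ~ N(0, σ²I), where X is the Vandermonde design
(1, x, x², x³) on centered, unit-variance week values — standardizing
the covariate keeps the design conditioned out to week 16. The prior is
conjugate normal–inverse-gamma:

    β | σ² ~ N(m0, τ² σ² I),    σ² ~ Inv-Gamma(a0, b0)

with defaults m0 = 0, τ = 1, a0 = 1, b0 = 0.1. Under this prior the
marginal likelihood of any profile set sharing one trajectory — all
members' points stacked into one regression — is available in closed
form via the standard normal–inverse-gamma update; it equals a
multivariate Student-t density evaluation and involves no sampling.
The defaults encode weak information on a log2-ratio scale: prior noise
sd around 0.3 with a heavy tail, coefficients of order 1.

Agglomeration is greedy: start from singletons; merge the pair with the
largest log Bayes factor log BF = logML(A∪B) − logML(A) − logML(B)
while the largest is strictly positive; stop otherwise. All O(n²)
candidate pairs are maintained (scores for pairs involving a new
cluster are recomputed after each merge from cached sufficient
statistics, vectorized over candidates), which is exact and fast at the
filtered-set scale of a few hundred to a few thousand profiles. Exact
ties on log BF are broken toward the pair whose smallest member probe
id is lexicographically least, making the partition invariant to input
row order up to relabeling. Cluster ids are assigned by size (largest
first), then least member id.

With 4 time points and an order-3 polynomial the per-series design is
saturated: a singleton is fitted perfectly under any trajectory. The
proper prior keeps every evidence term finite, and merges are decided
by cross-series agreement — two series can share one trajectory only if
their profiles agree to within the noise scale the prior admits. This
is the intended regime: the model order matches the analysis it
re-implements, and the test suite verifies the greedy optimum against
exhaustive partition enumeration on small instances and against planted
structure at scale.

Profiles enter clustering only if max_t |y_t| strictly exceeds 1.0
(a 2-fold change at some week); clusters are *selected* iff their
center (member-mean trajectory) strictly exceeds the same threshold.
Trend classification of a center is a declared convention:
"increased" if the center never dips below −0.25 and exceeds +1
somewhere; "decreased" mirrored; otherwise "variable". The 0.25 log2
tolerance permits small early dips in otherwise monotone trajectories.
Clustering operates on log2 *ratios* to baseline (the trajectory space
in which selection thresholds are defined); the mathematics is
indifferent to ratios vs absolute log2 values, and callers can pass
absolute profiles if desired.

## Group comparison and gene collapse

Selected probe sets of the two series are compared by exact set
operations. Gene-level immobilization-only membership is the set
difference of the *collapsed* gene sets, not the collapse of the probe
difference: a gene with one shared and one immobilized-only probe
responds in both series and is excluded. In the strict map dialect a
probe maps to exactly one gene; a permissive flag keeps the first
listed gene for multi-annotated probes. Unmapped probes are excluded
from collapse with a warning.

## Over-representation

For query size n from background N, a term with K background members
and overlap k gets p = P(X ≥ k), X ~ Hypergeometric(N, K, n), computed
by scipy's survival function; term sets are intersected with the
background first, and query genes outside the background are dropped
with a warning. The EASE variant replaces k by max(k − 1, 0) before the
tail sum, so single-gene overlaps can never appear enriched; EASE p ≥ p
always. Benjamini–Hochberg q-values are provided across each
collection, but the raw p remains the primary column because the
analysis this mirrors reported raw p-values. The default background is
the set of genes surviving preprocessing on the array. Cross-tabulation
attributes each overlapping gene to every cluster containing ≥ 1 of its
probes; the modal cluster's share of the overlap is rounded to a whole
percent. Term databases themselves are supplied as GMT files; no GO
graph propagation or live service query is performed.

## IHC scoring

Each rat contributes 4 microscope fields scored by 2 independent
examiners as percent DAB-positive cells. Per field the examiner mean
and the inter-rater absolute difference are computed; per rat the field
with the largest difference is removed (ties remove the lowest field
index), leaving 3 fields under the reference design. The retained field
means are pooled within group at each week — the unit of analysis is
the field, which pseudo-replicates rats; this matches the plotted
per-field design being mirrored, and is flagged here as a caveat rather
than resolved. Groups are compared per week with the Kruskal–Wallis
test (tie-corrected H, chi-square approximation with 1 df for two
groups); an exact permutation option enumerates all C(N, n1) group
assignments, which is feasible at these sample sizes. When every
observation ties, the tie-correction denominator vanishes and H is
defined as 0 (p = 1), the conventional limit. Kruskal–Wallis is kept
for the two-group case (rather than an equivalent rank-sum form) to
mirror the analysis re-implemented.

## Synthetic data

The generator emulates the study design end to end: 31,099 probe sets
by default, two groups × 5 weeks × 4 arrays, log-normal intensities
around a per-probe baseline (log2 mean 8, sd 1) modulated by planted
cluster trajectories in log2-ratio space, i.i.d. log2 replicate noise
(sd 0.1), global scaling to a trimmed-mean target of 100, and
Present/Marginal/Absent calls (2% Marginal among expressed probes, 1%
sporadic Absent). Cluster specs are polynomial coefficients over
standardized time; `coeffs_from_trajectory` converts intended center
values into coefficients exactly (the order-3 design on 4 weeks is
square). Default absent and below-floor fractions are 5616/31099 and
8771/25483, the reference design's proportions.

Absent probes are all-"A" but keep positive intensities: absence is a
call, not a zero. Below-floor probes get uniform intensities in
[0.2, 0.95] × floor after scaling, so their weekly medians sit strictly
below the floor; expressed probes are nudged above the floor at their
best week if scaling happened to leave them under it, and are
guaranteed one Present call. Planted counts are therefore *exact* by
construction. Absent and below-floor probes are drawn from the flattest
planted trajectories first: unexpressed probes are by nature not the
dynamically responding ones, and this keeps planted dynamic clusters
intact for recovery tests (a flag restores uniform selection).

What the generator does not emulate: probe-level effects and spatial
artifacts, intensity-dependent (heteroscedastic) noise, correlated
replicates, batch effects, or realistic detection-call/intensity
coupling. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and the clustering engine's behaviour under its
own model class — not robustness to real-array noise structure.

## Problem sizes and verification

The test suite verifies: filter bookkeeping at full scale (31,099
probes); the marginal likelihood against dense-grid double integration
(order-0 model, ≤ 1e-3 in log space) and against scipy's multivariate
Student-t (orders 0–3, ≤ 1e-9); greedy agglomeration against the
exhaustive maximum over all 4,140 partitions of 8 profiles; planted
two-to-four-cluster recovery with ARI ≥ 0.9 on 200-probe instances over
10 seeds; the hypergeometric tail against brute-force enumeration of
all C(20, 5) draws plus a 1000-replicate null-uniformity check; and
Kruskal–Wallis H and exact permutation p against from-scratch
enumeration plus a 500-replicate type-I-error calibration. The
end-to-end script regenerates a full-scale study (two groups, 718
planted dynamic probes among 31,099) and recomputes every stage from
scratch in well under a minute.

## Known limitations

- Greedy agglomeration is a local search; optimality is verified only
  on well-separated fixtures, and overlapping clusters can be merged or
  split relative to the evidence optimum.
- The conjugate prior's hyperparameters are conventions, not estimates;
  cluster granularity responds to b0 and τ.
- Field-level pooling in the IHC test treats fields as independent;
  rat-level random effects are not modelled.
- The strict (>, not ≥) inclusion and selection thresholds and the
  2.0-in-upper-bin fold-change boundary are declared conventions at
  measure-zero boundaries.
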