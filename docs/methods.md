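# Methods

`thermoclade` implements two analyses that together link molecular species
delimitation in marine macroalgae to the thermal structure of their
geographic ranges: (1) generalized mixed Yule-coalescent (GMYC) species
delimitation on an ultrametric gene tree, and (2) per-species sea-surface
temperature (SST) summaries from occurrence records, culminating in a
regression of log range size on the maximum thermal tolerance range.  A
synthetic-data module generates every input with the statistical structure
the analyses assume, so the whole pipeline is testable offline.

## Trees and branching schedules

The delimitation substrate is a rooted, ultrametric gene tree with branch
lengths in substitutions/site.  Depths are measured back from the tips
(tips at depth 0), matching the convention in which the delimitation
threshold is a genetic distance from the branch tips.  Parsing validates
that all root-to-tip path lengths agree within a relative tolerance
`ultra_tol` (default 1e-6 of tree depth; real relaxed-clock trees carry
rounding noise, and a `force_ultrametric` flag pins tips to depth 0 when
needed).  Polytomies are resolved deterministically into binary nodes
joined by zero-length branches, children in input order; the resulting
simultaneous events are merged (depth tolerance 1e-10) into multi-lineage
increments and zero-length intervals are skipped, so logarithms of
zero-length waiting times never arise.

The branching schedule lists the distinct event depths, root first, with
the lineage count and duration of each inter-event interval.  The root
event opens the process and carries no likelihood term; the shallowest
interval ends at the present without an event.

## The mixed Yule-coalescent likelihood

Under the null (single-process) model every interval with `n` lineages
and duration `x` contributes `log b - b*x` if terminated by a branching
event and `-b*x` otherwise, with `b = lam * n^p`.  With `p` fixed at 1
the ML rate has the closed form `lam = E / sum(n_i x_i)` (`E` = number of
event-terminated intervals), which the tests use as an oracle; the
free-`p` fit profiles that closed form over a bounded scalar search.

The mixed model classifies each branch segment relative to a threshold
depth `T`: segments deeper than their governing threshold belong to the
diversification (generalized Yule) process with rate `lam1 * n_div^p1`;
below the threshold, each cluster contributes a generalized coalescent
term.  The package's interval convention — fixed by hand-worked
three-tip examples and verified by parameter-recovery simulations — is:

* sweeping from the root, intervals are cut at every event and at every
  threshold (no event at a cut);
* a cluster that has entered its coalescent phase but not yet produced
  all of its tips contributes `lam2 * (v*(v-1))^p2`, where `v` is the
  lineage count the cluster holds after its next event (so a cluster
  stem awaiting its first coalescence contributes `lam2 * 2^p2`, and a
  completed cluster contributes nothing);
* singletons contribute nothing below the threshold;
* each event-terminated sub-interval adds `log b - b*x` with `b` the sum
  of all active components; event-free sub-intervals add `-b*x`.

With `p2 = 1` the within-cluster rates run `2*1, 3*2, ..., m*(m-1)` — the
neutral-coalescent pair rates read forward from the threshold.  With the
threshold at depth 0 every tip is a singleton and the model reduces
exactly to the null, which guarantees a non-negative likelihood-ratio
statistic on every input.

### Threshold candidates and within-cell profiling

A threshold is interpreted through the partition it induces, which is
constant on each open interval ("cell") between consecutive distinct
event depths.  The scan enumerates every cell, plus the all-singleton
threshold at depth 0 and one all-coalescent candidate beyond the root.
At fixed rates the log-likelihood is linear in `T` within a cell (only
the exposure split at the cut moves), so the within-cell profile is a
maximum of linear functions — convex — and its supremum sits at a cell
edge.  Each partition is therefore evaluated at both near-edge points
(0.1% inside the cell) and the better value taken; the *reported*
threshold is the cell midpoint, the conventional summary of where the
transition occurred.  Evaluating at midpoints instead biases the scan
toward oversplitting (the stem exposure of every cluster is maximal in
mid-gap), which the recovery simulations below make visible.

### Optimization

Rates and exponents are fit by bounded quasi-Newton search (L-BFGS-B) on
`(log10 lam1, p1, log10 lam2, p2)` with analytic gradients, bounds
`lam in [1e-8, 1e6]`, `p in [-3, 5]`, from a deterministic ladder of up
to five start points (moment-matched rate scales at several exponents,
plus warm starts from the neighbouring candidate).  Restarts stop early
once they stop improving the incumbent by more than 1e-8 log units.
Estimates within 1e-3 (in optimization coordinates) of a bound set a
`boundary` flag; everything is deterministic, so identical inputs give
identical fits.

### Significance, confidence sets, multiple thresholds

The LR statistic `2*(L_GMYC - L_0)` is referred to chi-square with 3
degrees of freedom (the threshold counted as one parameter).  The
confidence set for the entity count collects all scanned solutions
within 2 log-likelihood units of the maximum.

The multiple-threshold model assigns each entity its own local
threshold.  The search is greedy and deterministic, seeded at the
single-threshold optimum (so its likelihood can never fall below the
single-threshold fit): every entity proposes moving its local threshold
one event deeper (absorbing its parent's subtree into one cluster) or
one event shallower (re-clustering its own subtree), each proposal is
evaluated at both near-edge points of the new local cell and refit, and
the best strictly improving move is accepted until a fixed point or
`max_iter` iterations.  Ties prefer the deepest proposal.

### Known limitation: the chi-square reference is strongly anticonservative

The LR test compares a null with two parameters against a fit that also
maximizes over ~n candidate partitions and the within-cell threshold
placement.  On simulated structureless pure-birth trees (n = 50) the
resulting LR concentrates far above the chi-square(3) critical value and
the nominal 5% test rejects essentially always; the acceptance suite
computes and reports this rejection rate rather than hiding it.
Anticonservative behaviour of threshold-based delimitation tests on
shallow or structureless trees is well documented in the delimitation
literature; users who need calibrated error rates should calibrate the
LR by simulation (the `synthetic` module makes this a few lines) instead
of relying on the chi-square approximation.  The delimitation itself —
the entity count and membership — is validated independently by the
recovery simulations.

## Sequence distances

Uncorrected p-distances use pairwise deletion: only sites where both
sequences carry an unambiguous A/C/G/T are compared (gaps, N and IUPAC
ambiguity codes excluded), mirroring the behaviour of standard
distance software.  Pairs with no comparable site are reported missing
with a warning.  Haplotype collapsing keeps the first occurrence of each
exact (normalized) sequence string; the pipeline order is collapse →
tree, and collapsing never changes distances among representatives.
The pooled intraspecific 95th percentile uses linear interpolation
between order statistics, one of several conventions behind a statement
like "95% of values at or below x"; the choice is exposed here rather
than hidden.

## Thermal summaries

SST layers (minimum / mean / maximum climatology, deg C) arrive as three
ESRI ASCII grids sharing one header, cell-center registered, row 1
northernmost.  Extraction takes the containing cell's values; coastal
records routinely fall on land (nodata) cells of marine rasters, so a
nodata hit falls back to the nearest valid cell center within a search
radius (default 2 cells, ties broken row-major), and records beyond the
radius are dropped with a warning.

Per species the summary reports: record count; latitudinal range
(max - min latitude); longitudinal range (raw max - min span on
[-180, 180] by default — a `circular_lon` option computes the minimal
covering arc instead, but published spans for near-cosmopolitan species
are raw spans); the means over records of per-record max/mean/min SST;
and the **maximum thermal tolerance range**, defined as the largest
per-record maximum SST minus the smallest per-record minimum SST.  Being
extreme-based, it always satisfies `max_range_c >= max_c - min_c`, and
adding a record can never shrink it.  Duplicate coordinates are kept.

## Association

Ordinary least squares of `log(range)` on `max_range_c`, per axis.
Log base defaults to 10 (R² and the p-value are invariant to the base);
species with non-positive range are excluded with a warning rather than
floored; significance uses the t distribution with n-2 degrees of
freedom, two-sided.  Phylogenetic non-independence is deliberately not
corrected — the statistic mirrors the plain correlations reported in
this literature — so R² here describes association, not an evolutionary
rate relationship.

The packaged ten-species table of published range/SST summaries
reproduces R² = 0.827 for the longitudinal axis (published: 0.828).  The
latitudinal recomputation from the rounded table gives ~0.77 against a
published 0.751 — the original was evidently computed from unrounded
per-record data — so the latitudinal value is treated as approximate.

## Synthetic data

* **Trees**: a Yule species tree conditioned on `k` tips (rate
  `lam_yule = 1.0` per lineage; an extra exponential stem keeps the
  shallowest divergence above the present), with a Kingman coalescent of
  `m` tips per species (scale `theta = 0.05`; waiting time with `j`
  lineages ~ Exp(j(j-1)/(2 theta))).  Within-species subtrees are rescaled
  so that (min species divergence)/(max coalescent depth) equals the
  separation factor `s` (default 10; near 1 for hard cases) — this
  guarantees an identifiable threshold for power tests, at the cost of
  making the within/between depth ratio exact rather than noisy.
* **Sequences**: JC69 only; per site and branch the substitution
  probability is `3/4 (1 - exp(-4 d / 3))`.  Richer substitution models
  would not change anything the tests assert.
* **Rasters**: mean SST `t_eq - delta_t (|lat|/90)^2` (28 °C equator,
  30 °C pole-ward drop), seasonal amplitude `a0 |lat|/90` (10 °C at the
  pole) giving min/max = mean ∓ amplitude, cell-wise Gaussian noise
  (sd 0.3 °C) added to the mean surface before the layers are formed so
  min <= mean <= max holds by construction; rectangular land masks set
  nodata.  Default grid: 60 x 120 cells of 3 degrees.
* **Occurrences**: uniform draws over raster cells whose min/max SST lie
  inside a species' niche interval, placed at cell centers so
  suitability holds exactly.  The graded-niche world used by the
  end-to-end checks gives 8 species niche widths from 4 to 30 °C, which
  re-creates the positive tolerance-vs-range relationship.

What the generators deliberately do **not** emulate: rate variation and
non-clock noise in real gene trees, uneven and biased geographic
sampling, spatially autocorrelated SST anomalies, coastline geometry
(occurrences sample open-ocean cells), and identification error in
occurrence records.  Green tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to these
real-data pathologies.

## Problem sizes in the shipped checks

The test and acceptance runs use: 50 recovery trees of 10 species x 5
samples (separation 10); 200 structureless 50-tip trees for the
calibration report; 6 trees of <= 8 tips against the brute-force grid
(two-stage 200 x 200 rate grid per threshold evaluation point); and 20
graded-niche worlds of 8 species x 20 records.  These sizes give stable
percentages while keeping a full run in a few minutes on one core.
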