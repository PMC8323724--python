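# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the choices that were genuinely open, and what its tests
do and do not demonstrate.

## Data model

A dataset is an N×M real matrix with unique row and column labels; NaN is
the missing marker and infinities are rejected at the boundary. CSV is the
only file format (comma-separated, optional header); on input the tokens
`""`, `NaN`, `nan`, `NA` mark missing cells (configurable,
case-insensitive), on output numeric cells are written in shortest
round-trippable form so write→read is value-exact. Row and column order is
preserved by every operation, and imputed outputs always have the shape and
ordering of their inputs.

## Missingness generators

All three mechanisms target a missing-data ratio MDR in percent of the
V = N·M cells and stop at the first state whose achieved ratio reaches MDR.

* **MCAR** masks `ceil(MDR·V/100)` distinct uniformly random cells — the
  closed form of masking one random unmasked cell at a time until the ratio
  is reached, with the same distribution but guaranteed termination.
  Overshoot < 100/V.
* **MAR** draws one causative attribute and `na` distinct dependent
  attributes uniformly at random; the records that lose their values are
  the holders of the smallest causative values, added in ascending order
  (ties resolve to the lowest row index) until the ratio is reached; the
  mask is exactly records × dependent attributes. Overshoot < 100·na/V.
  The causative attribute may itself be drawn as a dependent, in which case
  it loses its own values and the mechanism shades into MNAR;
  `exclude_causative=True` redraws dependents to prevent that.
* **MNAR** is the same construction with the record set drawn uniformly at
  random: what drives the loss is not observable in the data.

MDR must lie strictly in (0, 100); a target above `100·na/M` is rejected as
unreachable for MAR/MNAR (masking every record cannot get there). One
seeded generator drives all draws of a call and is recorded in the mask's
provenance, so masks replay bit-identically.

## Partial distance and the kNN layer

Distances between incomplete records use the partial-distance convention:
`d(a,b) = sqrt((M/m_obs) · Σ_{j co-observed} (a_j − b_j)²)`, +∞ when no
attribute is co-observed. This keeps donors with different observed
supports comparable and reduces to the classical Euclidean distance on
complete records. Neighbour ranking breaks distance ties by the lower row
position and places infinite rows last; a query that is infinitely far from
every candidate raises rather than returning arbitrary donors.

## Automatic k selection

For a recipient R_i inside its pool P (N_p rows including R_i), one probe
attribute z is drawn uniformly from R_i's observed attributes and its value
AV withheld. Candidate k ∈ [2, N_p − 1] are scored by |AV − r̂_iz(k)| where
r̂_iz(k) is the mean of z over the k nearest donors that observe it (the
donors' overall observed mean of z stands in if none of the first k observe
it); the smallest k attaining the minimum wins. One distance sort serves
the whole sweep; the per-k estimates roll forward incrementally.

Two points were genuinely open and are resolved as follows:

* The probe value is withheld from the similarity as well as from the
  estimate. Keeping it in the query makes the score circular — donors get
  selected partly because their probe values match AV, flattening the error
  curve. One degenerate exception: if withholding the probe would leave the
  recipient with no observed attribute at all (e.g. a two-column dataset
  with one missing cell), the probe stays in the query, since otherwise
  every distance is undefined. The final donor search, after selection,
  always uses the full record.
* R_i is a member of its own pool, per the pool construction, but is
  excluded from its own neighbour list: a zero-distance self-match would
  answer the probe with the withheld value itself.

The selection is a single-draw estimate and is noisy by construction: the
running-mean error curve can cross AV at essentially any k, so very small
and very large k are both selected with appreciable frequency. This is the
method's principal instability; see "Known limitations".

## Round-robin regression over the donor subset

`RoundRobinImputer` fills the subset S = d_k ∪ {R_i}: missing cells start
at their column's observed mean; each incomplete column in turn (fewest
missing first, ties by index) is regressed on all other columns using the
rows where it is observed, and its missing cells are predicted; sweeps
repeat until the largest imputed-cell change relative to the column's
observed range falls below `tol` (default 1e-3) or `max_rounds` (default
10) is hit. Observed cells are never modified and the procedure has no
internal randomness.

The per-column regressor defaults to an evidence-maximising Bayesian ridge.
The donor subsets this imputer exists for are small — k+1 rows against M−1
predictors — so the design is routinely square or under-determined, where
any fixed near-zero penalty interpolates exactly and extrapolates without
bound at the query row; the adaptive penalty shrinks towards the column
mean precisely when the evidence is weak, while still reproducing exact
linear structure (a withheld value of an exactly collinear column is
recovered to machine precision). Passing a number as `ridge_lambda`
switches to a fixed-penalty ridge. Predictions are not clipped to the
observed range by default (`clip_to_observed_range` enables it). Only the
recipient's cells are accepted by the caller; donor-row imputations are
discarded.

## KI

Incomplete records are processed in ascending row order. Per record: build
A_mis and the pool P (all other rows observed on every column of A_mis —
donors may be missing elsewhere, so KI runs on datasets without a single
complete record), select k, take the k nearest donors, regress over S, and
write the record back before the next record starts, so later records may
draw on earlier imputations. When the pool has fewer than 3 rows, when no
donor shares an observed attribute with the recipient (including a record
missing all M values), or when nobody observes the probe, the record falls
back to observed column means; every fallback is logged. The per-record log
(chosen k, pool size, cluster, fallback) and the full parameter echo are
returned with the imputed dataset.

## Fuzzy c-means and FCKI

FCM minimises `J = Σ_i Σ_k δ_ik^{m′} d²(R_i, c_k)` by alternating the
closed-form updates. Missing cells enter through the partial distance, and
the centroid update weights each record by `δ^{m′}·M/m_obs` — the same
rescaling its distances carry — so both updates minimise one objective and
the trace is provably non-increasing. A record coinciding with a centroid
takes membership 1 there; a fully missing record has no defined distance
and keeps uniform membership. Membership rows are initialised from a flat
Dirichlet draw under the seed (reproducible, and two centroids can never
start coincident). Defaults: fuzzifier m′ = 2.0 (the conventional choice in
(1, ∞); larger values blur clusters together, values near 1 approach hard
k-means), tol 1e-4 on the largest membership change, 100 iterations cap.

The cluster count is chosen at the elbow of the converged objective curve:
FCM is fitted for every c in [c_min, c_max] (default [2, min(10,
floor(sqrt(N/2)))]) and the interior c maximising the discrete second
difference J(c−1) − 2J(c) + J(c+1) is returned, degenerating to c_min when
the curve bends nowhere. Note the boundary value c_min itself can only be
returned through the degenerate branch — a genuinely 2-cluster dataset
tends to come out as 3 — and equicorrelated clusters are elongated, which
this criterion tends to subdivide. `FCKIImputer(n_clusters=...)` overrides
the sweep.

FCKI hard-assigns every record to its highest-membership cluster (ties to
the lowest cluster index) and runs the KI procedure within each cluster,
sharing one record-level RNG across clusters in cluster order. A record
whose within-cluster pool is too small is retried against the whole
dataset before the column-mean fallback. With `n_clusters=1`, or a dataset
too small for the elbow sweep, clustering is bypassed entirely and the
output is bit-identical to `KIImputer` under the same seed.

## Baselines

Column-mean imputation replaces each missing cell with its column's
observed mean (every hole in a column gets the same value — the baseline
that ignores all correlation). Global kNNI fills each incomplete record
from its k nearest records over the whole dataset under the partial
distance, each missing cell taking the observed mean of that attribute over
the neighbours (overall column mean if none observes it), always from the
original values — no sequential update.

## Metrics and benchmark harness

RMSE, NRMSE and MAE are computed over the artificially masked cells only:
the (predicted, true) pairs at the masked positions, with N the number of
such pairs and O_max/O_min the extremes of the masked cells' true values.
This is the only reading under which imputation error is defined — the
observed cells are unchanged by construction. NRMSE is NaN when the masked
true values span zero range.

The harness runs, per dataset, the full grid of 3 mechanisms × 4 ratios
(1, 5, 10, 20 % — twelve conditions), generating one mask per condition
and replicate from a seed derived deterministically from the master seed
and the grid coordinates, imputing with every requested method and scoring
on the masked cells. Columns are min-max scaled to [0, 1] before masking by
default (`scale_01`), so errors are comparable across features and
datasets; MAR/MNAR use `na=1` dependent attribute by default, the choice
with the smallest overshoot of the target ratio. Aggregation views average
a method over the other axes per dataset, per mechanism or per ratio, with
the across-dataset standard deviation appended to the per-dataset view.

## Synthetic data

The generator draws one or more multivariate-Gaussian clusters with unit
marginal variances and constant within-cluster pairwise correlation,
centroids `separation` within-cluster standard deviations apart along the
all-ones direction, plus iid jitter of scale `noise_sigma` (default 0.1);
rows are shuffled and the generating labels returned. By default each
cluster beyond the first carries its own ±1 orientation of the dependence
structure, drawn under the seed: the magnitude of every within-cluster
correlation is the target, but which pairs co-vary positively differs from
cluster to cluster. That is the regime cluster-routed imputation exists
for — a donor from the wrong cluster is actively misleading, not merely
distant; with a single shared structure, restricting donors to a cluster
can only discard information. `vary_orientation=False` restores one shared
structure.

What the generator emulates: local record similarity (clusters), global
feature correlation (the regression signal), cluster-specific dependence,
and measurement noise. What it does not: heterogeneous feature scales and
types, outliers, nonlinear dependence, and missingness entangled with the
data-generating process. Results on it bound what the methods can do under
clean Gaussian assumptions; they do not certify behaviour on messy real
tables.

## Desk-scale comparison and known limitations

The shipped comparison (see `scripts/acceptance.py`) runs column-mean,
global kNNI (k = 5), KI and FCKI on 300×8 three-cluster data with
within-cluster correlation 0.9, cluster-specific orientation and 10 % MCAR,
over ten seeds. Mean imputation is far worst (its error is an order of
magnitude above the rest) and FCKI improves on KI; global kNNI with a
well-chosen fixed k is a very strong baseline under these Gaussian
conditions and KI does not reliably undercut it at this scale.

Known limitations, in the package's own assessment:

* The automatic k is selected from a single withheld value, and its
  arg-min is noisy; a non-trivial fraction of records receives a very
  small or very large k, which respectively inflates regression variance
  and dilutes locality. Averaging several probes would stabilise it at
  proportional cost.
* The elbow criterion cannot return its lower boundary except
  degenerately, and subdivides elongated (strongly correlated) clusters.
* KI is O(N) distance sorts of O(N) donors per incomplete record; it is a
  desk-scale method, and FCKI's clustering is the intended mitigation for
  larger N.
* Categorical attributes, weighted distances and multiple-imputation
  variance estimates are out of scope.
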