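# Methods

## Curve model

Amplification curves are modelled by the asymmetric five-parameter
sigmoid

F(t) = Fm · (1 + e^(−Sc(t−Cs)))^(−As) + Fb,

a Richards-type generalized logistic. `Fm` (a.u.) is the fluorescence
rise above baseline, `Fb` (a.u.) the baseline, `Sc` (per cycle) sets the
maximum reaction speed, `Cs` (cycles) is the curve centre linked to the
cycle threshold, and `As` (dimensionless) skews the curve between its
exponential and plateau phases (`As = 1` is the symmetric logistic). The
first two derivatives are closed-form:

F′(t) = Fm·Sc·As·u / (1+u)^(As+1),  F″(t) = Fm·Sc²·As·u·(As·u − 1) / (1+u)^(As+2),

with u = e^(−Sc(t−Cs)). All three are evaluated through
log-sum-exp-stable forms so that deep tails return the exact asymptote
(0 or Fm+Fb) rather than overflowing; this matters because filtering and
fitting routinely evaluate far outside the transition region.

Useful identities used throughout (and verified by the test suite
against finite differences and bracketed numerical optimization):

- the maximum slope sits at x_ms = Cs + ln(As)/Sc, where As·u = 1;
- for As = 1 the maximum slope is exactly Fm·Sc/4;
- the extrema of F″ are the roots of As²u² − (3As+1)u + 1 = 0 in u.

## Fitting

Plain (unweighted) nonlinear least squares via `scipy.optimize.least_squares`
(trust-region reflective) with the analytic Jacobian. Initialization is
data-driven: Fb ← min(F), Fm ← range(F), Cs ← the half-maximum crossing,
Sc ← 4·(max finite-difference slope)/range, As ← 1. Bounds keep the
optimizer out of degenerate regimes while admitting strong asymmetry:
Fm ∈ (0, 10·range], Fb ∈ [min−range, max], Sc ∈ (0, 10], Cs ∈ [t₀−10,
t_end+10], As ∈ (0.01, 20]. Cost tolerance 1e−10, at most 5000 model
evaluations. A failed or flat fit returns `converged=False` rather than
raising; only malformed input (length mismatch, non-increasing cycle
axis, fewer than 20 points) is an error. The fit is scale-equivariant:
rescaling fluorescence by k rescales Fm and Fb by k and leaves Sc, Cs,
As untouched.

A known degeneracy: for very shallow curves (Sc well below ~0.1 per
cycle) only part of the transition is visible in a 45-cycle window and
Sc trades off against As, so the fitted Sc of a shallow curve can exceed
its generative value by a factor of ~2. The quality filter's
low-efficiency gate therefore operates with a comfortable margin between
real assays (Sc ≳ 0.4) and the gate (0.1).

## Quality filtering

Three deterministic gates replace the unsupervised adaptive-mapping
filter used on digital-PCR panels, reproducing its stated purpose in an
auditable form: (1) relative gain (max−min)/min ≥ 0.10, with gain below
0.02 labelled `flat` (NTC-like) and below 0.10 `low_gain`; (2) converged
fit with R² ≥ 0.99 (`poor_fit` otherwise); (3) fitted Sc ≥ 0.1 per cycle
(`low_efficiency`). Filtering is idempotent and monotone in each
threshold. The exact criteria of the original unsupervised procedure are
not public; these defaults were chosen once for the synthetic study
conditions and are fully configurable.

## Kinetic features

Thirteen features per curve: the five fitted parameters plus eight
derived from the fiducial points. x_ms is closed-form; x_s and x_e are
the two solutions of F′(t) = TH·F′(x_ms) bracketing x_ms, found by
Brent root-finding after outward bracket expansion; x_p1/x_p2 are
located by bounded scalar minimization of ∓F″ on either side of x_ms
(the closed-form quadratic above serves as an independent oracle in the
tests, keeping implementation and check on separate routes). TH is
*relative* (default 5% of the maximum slope): an absolute threshold
would break the scale invariance the features rely on. The phase
areas use the fundamental-theorem identity A1 = F(x_ms)−F(x_s),
A2 = F(x_e)−F(x_ms) — no quadrature.

Derived features: span_exp = x_e−x_s, span_p = x_p2−x_p1, slope_ms =
F′(x_ms), curv_p1 = F″(x_p1), neg_curv_p2 = −F″(x_p2), asym_span =
(x_e−x_ms)/(x_ms−x_s), asym_area = A2/A1, asym_curv = −F″(x_p1)/F″(x_p2).
All spans and ratios are invariant to fluorescence rescaling and to Cs
shifts; slope and curvature magnitudes scale linearly with fluorescence.
Cs-shift invariance is the mechanism behind concentration robustness:
template dilution moves Cs but not the shape.

Standardization uses the population (ddof = 0) convention; a
zero-variance column is an error naming the column.

## Feature selection

Per candidate feature: (1) mean silhouette score across target labels
(Euclidean, a_i excluding the point itself, b_i the minimum over other
labels of the mean distance to that label); the gate keeps features with
MSS ≥ 2× the median MSS of all candidates — a ratio-to-median
operationalization of "well above the field"; (2) Kruskal–Wallis across
concentration groups in every efficiency group, robust iff p > 0.01.
This is deliberately "fail to reject": non-significance is not
equivalence, and the gate is a screen, not a proof. Dunn's post-hoc
(pairwise rank z-tests with tie correction, Holm-adjusted by default)
localizes offending concentration pairs; (3) Pearson r ≥ 0.85 between
singleplex and multiplex features computed on per-primer-set median
curves (per-cycle median fluorescence, then fit and extract). A
per-target consistency floor (minimum per-target mean silhouette ≥ 0,
configurable) excludes features that separate most targets but fail one
— the scenario in which a span feature can look good on average while
being useless for a specific target.

The default selected set for multi-feature strategies is
(slope_ms, curv_p1, neg_curv_p2, sc).

## Distances, strategies, ranking

A candidate assay assigns one primer set per target; its simulated
multiplex dataset pools each assigned set's singleplex feature vectors
as that target's cluster (no resampling, no trace mixing — the working
assumption is that a well-chosen set's kinetics transfer to multiplex up
to a linear attenuation). Distances between two target clusters:

- **median**: Euclidean distance between coordinate-wise medians
  (translation-, axis-permutation- and sign-flip-invariant; not
  rotation-invariant, since coordinate-wise medians do not commute with
  rotations);
- **clustering**: the mean silhouette of the two clusters, in [−1, 1],
  invariant to rigid transforms and uniform scaling, and monotonically
  decreasing in within-cluster spread at fixed medians.

ADS is the mean and MDS the minimum over all C(n,2) target pairs.
Strategies: S1 = median distances on `sc` only (the predecessor
approach); S2 = median distances on the selected feature set; S3 =
clustering distances on the selected feature set.

**Standardization scope.** Features are standardized once over the
pooled singleplex feature table, and every candidate is scored on those
globally standardized values. A per-candidate scope was considered and
rejected: standardizing within each candidate makes median distances
scale-free per candidate, which silently couples S1 scores to
within-cluster spread and breaks the exact identity between S1 and S2
restricted to `sc`. A global affine map keeps scores comparable across
candidates and leaves single-feature rankings identical to rankings on
the raw parameter.

Ranking: candidates are ordered by the sum of their descending-ADS rank
and descending-MDS rank ("min" tie convention at both levels), so two
candidates can legitimately share a place; listing order breaks ties by
mix id for determinism.

## ACA classification

Default model: k-nearest-neighbours (k = 5) on standardized selected
features behind a pluggable interface — deterministic, assumption-light,
and sufficient when separability in feature space is the quantity being
evaluated. Schemes: stratified 30-fold cross-validation (out-of-fold
predictions pooled into one confusion matrix; accuracy = trace/total by
construction), leave-one-concentration-out (one fold per concentration;
a class absent from a fold's training data is flagged in the report, not
silently ignored), and panel-ensemble majority voting with a
deterministic lowest-label tie-break. The silhouette of the standardized
feature embedding is reported through the same `mean_silhouette`
implementation used in selection (single source of truth).

## Synthetic data generator

The generator emulates the structure the framework assumes, not PCR
chemistry: per-(target, primer set) mean parameter vectors with
unit-mean lognormal jitter (positivity-preserving) at small coefficients
of variation (defaults: Fm 5%, Fb 2%, Sc 3%, Cs 1%, As 5%); Cs shifted
by 3.32 cycles per 10-fold dilution (the perfect-efficiency value) with
shape parameters drawn independently of concentration; additive Gaussian
fluorescence noise with σ = 0.5% of Fm; a 45-cycle unit grid. Multiplex
curves attenuate Fm and Sc by configurable factors (default 0.8) with 2%
multiplicative jitter per primer set, producing the near-linear
singleplex→multiplex feature relationship the selection criteria test.
Contaminants (flat baseline traces, low-gain sigmoids at a few percent
of baseline, shallow Sc = 0.03 curves) carry ground-truth type labels.

Bundled scenarios: `preset_7plex` (7 respiratory-panel-like targets × 2
primer sets × 4 concentrations spanning three decades),
`attenuation_10set_scenario` (10 primer sets at one fixed concentration,
20 curves each — a single concentration because the per-cycle median
curve of a set is only well defined when its curves are not Ct-shifted
against each other), and `overlap_3plex_features` (a feature-level 3-plex
in which the all-"B" candidate has the farthest-apart cluster medians
but within-cluster spread of the same order as the gaps, so median-based
scoring promotes it while silhouette-based scoring demotes it).

What the generator does *not* emulate — and hence what passing tests do
not establish about instrument data: per-cycle efficiency chemistry,
primer–primer interactions beyond a linear attenuation, inhibitor
kinetics, baseline drift, well-to-well optical artifacts, and the heavy
non-Gaussian tails of real qdPCR panels. Results on synthetic data
validate the algorithmic machinery, not assay performance.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use deliberately small
study conditions chosen once for the synthetic scenarios: 4–18 curves
per (target, primer set, concentration) depending on the check, 200
seeded replicates for the robustness simulation, 100 replicates for
noisy fit recovery, 1000 random parameter draws for derivative
verification. Root-finding tolerances are 1e−12 (absolute) for
threshold crossings, 1e−10 for curvature-peak location, and the fit
stops at cost tolerance 1e−10. Ties in ranking and in panel voting are
broken deterministically (mix id, lowest class label). Degenerate
inputs — flat curves, singleton clusters, zero-variance features, a
single concentration group — raise explicit errors or return
non-converged results as documented per function.

## Known limitations

- The three-gate filter is a stated simplification of unsupervised
  adaptive-mapping filtering; its thresholds are not calibrated to any
  instrument.
- The Sc–As degeneracy of partial sigmoids (above) limits how sharply
  "low efficiency" can be defined from the fitted Sc alone.
- Median-curve features assume curves within a primer set share a
  concentration; pooling Ct-shifted curves makes the per-cycle median
  bimodal and the fitted parameters unstable.
- Four additional derived features of the extended feature family are
  not implemented; the selection machinery treats the feature list as an
  open extension point.
- The k-NN default is a stand-in for whatever classifier a deployment
  would use; the evaluation schemes, not the model, are the contract.
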