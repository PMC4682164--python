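# Methods

This note documents the statistical models behind `phenodyn`, the design
choices that were genuinely open, what the synthetic-data generator does
and does not emulate, and the numerical conventions that affect results.

## Synthetic data: the factor model

Parcel time series are generated from a one-factor-per-network model.
Parcel *i* in network *m* at session *s*:

    x_i(t) = sqrt(b) g(t) + sqrt(w_ms − b) f_m(t) + sqrt(1 − w_ms) e_i(t)

with independent unit-variance global factor *g*, network factors *f_m*
and noise *e_i*. The implied parcel–parcel correlation is exactly `w_ms`
within network *m* and `b` between networks, so empirical correlations
converge to the configured values as the session length grows (verified
at T = 5000 to within 0.02). Feasibility requires
`0 ≤ b ≤ w_ms < 1`; configurations that violate this — including via
session modulation — raise a parameterization error rather than
silently clipping.

All longitudinal structure enters through `w_ms`: a fed/fasted shift
(fasted sessions get `+state_effect_size`; the schedule alternates
deterministically, emulating a Tuesday/Thursday design), per-network
linear and quadratic session trends on a centred session index, and an
AR(1) session-noise term (coefficient `ar1_coef`, default 0.5; marginal
SD `session_noise_sd`, default 0.02) that gives session summaries the
autocorrelation the ARMA-error tests assume. Censoring masks are built
from geometric runs (mean bad-run length 3 frames, overall rate
`censor_rate`, default 3%, matching the ~97% frame-retention regime of
motion censoring), so short usable segments occur and the
minimum-contiguous-frames rule (`censor_short_runs`, 5 frames) is
exercised.

Gene counts are gamma–Poisson (negative binomial, var = μ + αμ²) around
module-specific latent factors; per-gene log-loadings are uniform on
[0.35, 0.6] with 25% negative-sign members, library sizes are log-normal
(SD 0.25), and α defaults to 0.2. A configurable fraction of genes is
flagged small-RNA and another is given extreme (very low / very high)
base means so the expression filters have planted removal counts; the
bookkeeping uses the same size-factor normalization the filter uses, so
the counts match exactly. Metabolites are log-normal around cluster
exemplar profiles; behaviour series are AR(1) with missing-completely-
at-random gaps at `missing_rate` (default 15%, the order of missingness
in session-level self-report tables). Cross-domain effects are planted
by construction: a module factor named in `planted_associations` is
built as r·z(anchor) + sqrt(1−r²)·noise against the standardized
within-network connectivity target series, so the population correlation
is exactly the configured r.

Defaults (630 parcels, 12 networks, 84 sessions, 48 omics sessions)
mirror the data inventory of a dense single-subject study. The gene
panel (2000 genes, 10 modules) and session length (500 frames) are
deliberately desk-scale; the generator is O(parcels × frames) so larger
settings work but are unnecessary for validating operating
characteristics. What the generator does **not** emulate: hemodynamics,
scanner noise spectra and motion artefact structure, spatially smooth
parcel geometry (centroids are scattered around network centres, with
hemispheres assigned by mirroring), non-MCAR missingness, and
count-depth-dependent dispersion trends beyond the α(μ) = a₁/μ + a₀
family. Passing tests therefore demonstrate correctness of the
statistics under the stated model, not robustness to acquisition
artefacts.

## Connectome estimators

Covariances use 1/(n−1) over usable frames only; a trace-scaled ridge
(10⁻⁸·tr(S)/p) is added before any inversion. Constant parcels are
zeroed with a warning record, never raised mid-pipeline. The
density-targeted graphical lasso brackets the penalty in [10⁻⁴, 1] with
geometric expansion (factor 4, up to 20 expansions each way) and then
bisects geometrically, exploiting that achieved density is non-increasing
in the penalty; convergence is |density − target| ≤ tol (default 0.001,
or one edge in the pair count if that is coarser), with the bracketing
interval reported on failure. The ridge partial correlation inverts
S + λI directly. Binarization ranks pairs by *signed* weight (the
functional graphs here keep the strongest positive edges; the field's
convention when the source is silent), breaks ties toward the smaller
(i, j) index pair for determinism, and removes pairs closer than the
exclusion radius (30 mm default) *before* ranking. Centroid distances are
Euclidean in mm — a documented approximation to geodesic distance, since
surface geometry is out of scope.

## Graph cartography

The base community detector is pluggable (Infomap default, modularity
maximization fallback), seeded, and isolated behind one interface; the
consensus layer is what is specified exactly. Consensus: per threshold,
modules below 9 parcels dissolve to unassigned; module identity is
tracked across thresholds by greedy maximal-Jaccard matching (ties to
lower module id); each node takes its label at the sparsest threshold
where assigned; with multiple thresholds, labels present at only one
threshold are removed. A node in a dissolved small module counts as
unassigned at that threshold. Consensus is idempotent.

Signed modularity combines Newman modularities of the positive and
negative parts with the asymmetric weighting Q⁺ − (s⁻/(s⁺+s⁻))Q⁻ —
the standard choice for signed correlation matrices. Unassigned nodes
are treated as singleton modules. Efficiency maps weight → length as
1/w on positive weights; negative weights carry no edge; disconnected
pairs contribute zero. Participation sums over every category a
neighbour can occupy (including "unassigned") so Σₘ kᵢₘ = kᵢ holds
exactly; isolated nodes get P = 0 with a flag. Hub thresholds (z > 1.0,
P split 0.3) follow standard network-cartography practice.

## Regression with ARMA errors

The association test is a feasible GLS: candidate ARMA(p, q) parameters
on the [0..3]² grid come from Levinson–Durbin (pure AR) and
Hannan–Rissanen regression (q > 0), each scored with the *exact*
Gaussian likelihood from the innovations algorithm and AICc
(k = p + q + 1); non-stationary or non-invertible candidates are
dropped, ties resolve to the lexically smallest order. Differencing
d ∈ {0, 1} comes from a KPSS level-stationarity pretest at α = 0.05.
The slope is tested on the innovations-whitened regression against a t
distribution with n − k − (p + q) degrees of freedom.

Three design points matter for calibration and were validated by
simulation (n = 48, AR(1) φ = 0.7 and white-noise nulls, 1000+
replicates each):

- **What the order is selected on.** Selecting on OLS residuals
  under-whitens — a spurious OLS slope absorbs part of the response
  autocorrelation — and inflates the null rejection rate to ~0.084.
  Selection on the centred response calibrates (~0.04–0.06) and is the
  default for stochastic regressors. Deterministic regressors are the
  exception in both directions: a *trend* soaks up low-frequency AR
  noise, so trend tests select on the response with no refinement; the
  *alternating* fed/fasted contrast would alias into a period-2 error
  term under response selection (halving power), so the state test
  selects on residuals.
- **Test versus estimate.** The selection-consistent fit gives null t
  statistics that are t-distributed out to the far tail (empirical
  P(p ≤ 5·10⁻⁴) ≈ 3.5–5·10⁻⁴ across null regimes), which
  Benjamini–Hochberg at scan scale depends on. But its whitening
  parameters, fitted to the raw response, absorb part of a true slope
  and attenuate the coefficient by a few percent. The reported p-value
  therefore comes from the unrefined fit, while the reported
  coefficient comes from iterating a parameter refresh (order fixed) on
  the residuals around the current fit until the slope stabilizes —
  unbiased to Monte-Carlo precision in recovery simulations.
- **Missingness.** Pairwise-complete sessions are compacted into a
  contiguous series before fitting (the bivariate-analysis rationale
  for uneven missingness across variables); gaps are not modelled.

Scans apply BH-FDR per scan across the tested pairs, flag significance
only when |Pearson r| > 0.2 as well, and report Bonferroni-corrected
p-values for headline use. The exhaustive grid (not stepwise search)
was chosen for reproducibility; max order 3 matches typical automated
selection defaults below a hundred observations.

The replication power solver uses the bias-corrected Fisher-z
approximation — effect atanh(r) + r/(2(n−1)), null critical correlation
from the t quantile at n − 2 df, variance 1/(n−3) — because the plain
Fisher-z approximation does not reproduce the printed 24/51 session
requirements; the continuous solution is found by bracketing + Brent
and rounded to the nearest integer.

## Omics

Size factors are DESeq-style median-of-ratios over genes with nonzero
counts in every session (a pseudocount option covers degenerate
matrices); note these factors are invariant to a *global* rescaling of
all sessions — only relative factors are identified. The expression
filter uses normalized means and inclusive [4, 10000] boundaries, with
small-RNA removal first and removal counts reported by category. The
variance-stabilizing transform fits α(μ) = a₁/μ + a₀ to per-gene moment
dispersions (one 3-SD trimming pass), then applies the closed-form
antiderivative of 1/√(μ + αμ²), anchored to log₂ at high counts; a
non-positive a₀ falls back to shifted log₂ with a warning. Nuisance
regression residualizes each feature on supplied covariates plus the
top session-level principal components of the full matrix; a
rank-deficient design is an error naming the collinear columns.

Coexpression modules: biweight midcorrelation (median/MAD centring,
Tukey biweight with the conventional 9-MAD width; Pearson fallback on
zero MAD, flagged), adjacency |bicor|^β with β chosen as the smallest
power whose log-log degree-frequency fit reaches signed R² ≥ 0.8
(argmax fallback; diagnostics table returned), topological overlap
TOM = (Σ a·a + a)/(min(k) + 1 − a), average-linkage clustering of
1 − TOM, and a *static* cut. The cut is taken at 0.99 of the relative
merge-height range (h_min + 0.99(h_max − h_min)): absolute heights
concentrate near 1 once weak adjacencies are raised to a soft power, so
a quantile on absolute heights is uninformative. Static cutting
replaces dynamic tree cut deliberately — it is simpler, deterministic,
and module recovery is the validation surface. Minimum module size 30;
smaller clusters go to the unassigned (grey, 0) module. Eigengenes are
first principal components of standardized module profiles,
sign-aligned to positive mean loading, unit variance. Projection onto
an external cohort applies the stored memberships after that cohort's
own nuisance regression and skips modules with < 50% gene overlap.

At desk scale a caveat applies that the full-size analysis does not
share: with only a handful of planted modules, the top expression
principal components *are* the module factors, so the recovery
validation uses covariate-only nuisance regression (PC removal is
exercised by its own orthogonality and signal-survival tests).

Metabolite peak heights are divided by the per-session mean across
metabolites. Affinity propagation runs on negative squared Euclidean
distance between standardized profiles with damping 0.9 and median
preference (standard defaults; the source states neither), and raises
with advice to increase damping if messages oscillate. On n ≤ 8 inputs
its exemplar set matches exhaustive search within 1% of net similarity.

## Integration

The task connectome correlates parcel activation profiles across
contrasts on raw statistics (no per-contrast normalization). The
structure–function chance line relocates the structural edge set
uniformly at random, preserving edge count only — the literal reading
of "randomization of the connections" — with a degree-preserving
variant available. Structural generation plants a configurable
agreement with the model's functional edge set; that agreement is
identifiable from the overlap precisely at the density equal to the
planted within-network pair fraction (below it, the tied within-network
edges make the reference set arbitrary — the validation uses the
matched density). Interhemispheric proportions and edge-length
statistics are straight ratios/Euclidean lengths over surviving edges.
The phenome network keeps edges with BH-adjusted p < 0.05, excludes
graph-theoretic derivative measures as nodes and within-class pairs for
gene modules and metabolites, records the edge sign as an attribute
(not separate layers), and reports the community partition and
modularity of the resulting graph.

## Pipeline

The orchestrator is strict about configuration (unknown keys are
errors), seeds every stochastic step from the single run seed, writes
every output into a JSON manifest, and is bit-identical across reruns
with the same config and seed (manifest timestamp aside). Analysis
defaults are the printed conventions (densities 1–6%, 7.5% partial
density, 30 mm exclusion, q = 0.1 / 0.05, |r| > 0.2, filter bounds
4/10000, soft power 8); the default *simulation* block is desk-scale
(120 parcels, 30 sessions) so a full run completes in seconds. Problem
sizes in the validation suites (e.g. 630-parcel recovery at 5 seeds,
1000-replicate calibration, 200×200 FDR scans) are the package's chosen
validation scale.

## Known limitations

- The ARMA-error test's coefficient and p-value come from two fits (see
  above); the reported t is not coef/se of the reported coefficient.
- Session index, not calendar date, is the trend regressor; missing
  sessions leave gaps in the index but the fitted error process treats
  the compacted series as contiguous.
- Geodesic parcel distances are approximated by Euclidean distances.
- The static tree cut can split one planted module across two labels
  near the cut height; the recovery criterion (Jaccard ≥ 0.7 on ≥ 4 of
  5 modules) tolerates this.
- Exact reproduction of the source study's printed association tables
  is out of reach by construction: those numbers derive from one
  subject's real data, and the automated order-selection settings used
  there (stepwise vs exhaustive, maximum orders, seasonal terms) are
  not fully specified.
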