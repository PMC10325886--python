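# Methods

## The question the package answers

Biodiversity is multidimensional: species richness, total abundance,
diversity, evenness, taxonomic breadth and biogeographic composition each
summarize a community differently, and monitoring programs must decide which
of them to track. Correlation between indicator *values* is a poor guide,
because responses to environmental change are condition dependent. This
package instead compares indicators by the *dynamics* of their time series:
if an environmental change alters the rules governing some dimension of
biodiversity, every indicator reflecting that dimension should show a change
in its dynamical rule at the same time. Indicators whose dynamics break in
the same way under the same forcing are treated as interchangeable probes of
one biodiversity dimension.

## Indicators

Ten indicators are computed per survey from the abundance vector n_i (see
`divdyn.indicators` for the exact formulas): richness S, total abundance N,
Berger–Parker dominance p_max, Simpson diversity D, Shannon diversity H
(natural logs), Simpson evenness E_D = D·S/(S−1), Shannon evenness
E_H = H/ln S, Smith–Wilson evenness E_var (arctan of the 1/S-normalized
variance of ln n_i), Warwick–Clarke taxonomic diversity δ (pair weights 1, 2,
3, 4 for the finest shared rank genus/family/order/none), and the
community-weighted mean cCOD of species' standardized latitudinal centers of
distribution. Conventions worth stating:

* sums run over species present (n_i > 0) in the survey;
* evenness ratios are undefined at S = 1 and δ is undefined for a single
  individual; undefined values propagate as missing, never as zeros, and the
  pipeline refuses to window series containing them;
* COD z-scores use the mean and *population* variance of the full set of
  species ever observed in the dataset, computed once, so cCOD is comparable
  across surveys. Population rather than sample variance is a documented
  choice (the source convention is unstated); with ~40–95 species the
  difference is far below the variability of the series;
* the taxonomy reader validates that genus ⊂ family ⊂ order is properly
  nested, and complete labels are required rather than guessing weights for
  partially known taxonomy.

## Sliding-window mutual prediction

Each indicator series (n = 88 surveys in the reference conditions) is cut
into all n − w + 1 stride-1 windows of length w = 48 (41 windows). For each
training window a simplex-projection forecaster is built: the window is
delay-embedded with lag τ = 1 at dimension E chosen by minimizing its own
leave-one-out one-step (Tp = 1) forecast error over E = 1..10 (capped so the
library keeps at least E + 2 points, ties toward smaller E); forecasts are
the exp(−d/d_min)-weighted average of the E + 1 nearest neighbors' futures.
Entry (i, j) of the mutual-prediction matrix is the error of window i's
forecaster on window j's points, standardized by the population sd of window
j's observed targets:

    sRMSE_ij = RMSE_ij / sd_j.

sd_j is the RMSE of the untrained model that always predicts the test mean,
so sRMSE = 1 exactly at that baseline and sRMSE ≥ 1 (strict < 1 is
"success") marks deterministic prediction failure. Design details:

* the sd is taken over the *prediction targets* of window j, not the whole
  window, keeping the untrained-model interpretation exact (targets depend
  on the row's E; the convention is applied per entry);
* when library and test windows overlap (stride-1 windows do), a library
  point sharing a time index with the target is excluded — the same rule as
  leave-one-out on the diagonal. The Theiler exclusion is 0 extra points
  beyond that and is configurable;
* zero-distance neighbor ties give those neighbors weight 1 and all others
  weight 0; remaining ties break toward earlier library times, making every
  entry deterministic;
* determinism of an indicator = fraction of the 41 diagonal (self-prediction)
  entries strictly below 1.

A regime shift planted at index c shows up as a block pattern: entries whose
train and test windows lie on opposite sides of c exceed the within-side
entries. `block_contrast` quantifies this as mean(cross) − mean(within),
assigning windows to sides by containment (windows straddling the boundary
dropped) or, when w is too large for containment, by window center — the
latter is what `window_size_scan` tabulates, together with mean
self-prediction sRMSE, as the skill-versus-sensitivity report for candidate
window lengths. The scan reports; it never selects.

## Nonlinearity (regularized S-map)

Per window, a locally weighted linear one-step forecaster is fit at each
locality value θ in {0, 0.1, 0.3, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8}:
for each target point the other embedded points are weighted by
exp(−θ·d/d̄) (d̄ = mean distance to the target) and an elastic-net
(mixing 0.5) linear map is fit, with the penalty chosen from
{1e−4, …, 1} by the same leave-one-out criterion; the window is z-scored
first so the penalty grid has a fixed scale. θ = 0 is a single global linear
model; error that keeps dropping as θ grows means the local Jacobian varies
across state space — nonlinear, state-dependent dynamics.

θ* selection uses the one-standard-error rule by default: the smallest θ
whose mean leave-one-out loss is within one SE of the minimum. For linear
stochastic windows the error curve in θ is nearly flat and a strict argmin
is decided by selection noise, inflating θ* under the null; the 1-SE rule
resolves near-ties toward the linear hypothesis while leaving chaotic
windows (whose error falls by half or more) untouched. Strict argmin is
available via `selection="min"`.

Significance of "θ = 0 in all windows" is tested per indicator with a
one-sided one-sample t statistic on the per-window θ*, adjusted across the
ten indicators by the Šidák step — a many-to-one (Dunnett-style) comparison
against the fixed reference 0 that is exact under independence of the
indicator-level statistics. Because the dependence between overlapping
windows is unknown, a sign-flip permutation version of the per-indicator
test is provided as a cross-check. Zero-variance θ vectors are decided
exactly (all 0 → p = 1; all equal > 0 → p = 0).

## Classification (Ward + SIMPROF)

The distance between two indicators is the Euclidean norm of the entrywise
difference of their mutual-prediction matrices (entries undefined in any
matrix are dropped from all of them; sRMSE is dimensionless so no
standardization is applied). Ward's method (the Ward.D2 convention, via
scipy) builds the dendrogram; indicator names are sorted before clustering
so results do not depend on input order.

SIMPROF gates the tree top-down. At each node with ≥ 3 objects the observed
ordered profile of pairwise distances is compared with the mean ordered
profile of tables in which every variable is permuted independently across
the node's objects; the statistic π is the summed absolute deviation, its
null distribution comes from a second independent permutation batch, and
p = (1 + #{π_perm ≥ π_obs}) / (1 + n_perm) (add-one, so p > 0 and α = 0 can
never split). Defaults: α = 0.01, n_perm = 999 per batch, mandatory seed.
Descent stops at non-significant (or < 3-object) nodes; the stopped leaves
partition the indicators into the significant clusters.

## Synthetic study conditions

The generator emulates the structure of ~7 years of monthly coastal
visual-census data: 88 surveys, 40 species, strong seasonality with period
12, and a +2 °C shift of the forcing mean at survey 44 (the scale of the
warm-water discharge the reference monitoring program experienced). Half of
the species form a low-latitude pool (COD ≈ 22° N vs ≈ 34° N for
residents): their growth tracks the seasonal temperature anomaly and their
immigration arrives only in the warm season, so they vanish in winter —
producing the observed-style turnover (≥ 10 % of species with at least one
absence is asserted) and a lag-12 peak in richness autocorrelation. Latent
dynamics are Ricker with weak random interspecific competition; observed
counts are Poisson around lognormally jittered latent abundances. The
generator guards its own realism: it raises if the whole community dies, if
any survey drops below two species, or if turnover is absent.

What the simulator does not emulate: true species-abundance-distribution
shapes, behavioral migration timing, observation effort drift, or any
attempt to match the real community's parameters — so green tests
demonstrate that the *method* recovers planted structure under realistic
dynamics, not that the real community behaves identically.

Scalar fixtures are logistic maps (chaotic, deterministic) and AR(1)
series (stochastic, linear), the standard positive and negative controls
for determinism and nonlinearity diagnostics.

## Problem sizes and numerical choices

The reference analysis uses all 41 windows of length 48. The S-map grid
search is the expensive stage (~1–2 s per window), so the nonlinearity
drivers and the acceptance script estimate θ on every 2nd–4th window — the
t test needs only the per-window sample, and the diagnostic's conclusions
are unchanged by the thinning (`theta_stride` is a config knob, default 1).
Simulation-based checks use 20 replicates with fixed seeds. All
floating-point "success" comparisons against the sRMSE = 1 baseline are
strict. Degenerate cases are flagged rather than patched: constant test
windows give undefined matrix columns (logged), constant windows refuse
S-map fitting, and an all-equal COD distribution is an error.

## Known limitations

* τ, Tp, the neighbor-weighting kernel, the E range and the θ grid are
  package conventions (standard empirical-dynamic-modeling practice), not
  uniquely determined by the problem; all are configurable.
* The t-based θ test treats windows as exchangeable replicates although
  stride-1 windows overlap heavily; the sign-flip variant is offered for
  sensitivity analysis, and both are conservative only as far as the 1-SE
  selection keeps null θ* at zero.
* SIMPROF permutes variables independently across objects; with 10 objects
  and ~1700 highly correlated matrix entries the test is approximate — its
  empirical size is property-tested (≤ 5 % multi-cluster rate at α = 0.01
  on exchangeable nulls).
* With 48-point windows on an 88-point series, no window lies wholly inside
  either half, so regime contrasts at that window length rely on the
  center-based assignment.
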