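# Methods

This note documents the models implemented in `kcdyn`, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
data do and do not emulate.

## The biological system

After an excitotoxic striatal lesion, scattered parenchymal astrocytes
activate a latent neurogenic program. Each activation seeds a transient
proliferative focus — a Ki67 cluster (KC), operationally a group of at least
4 Ki67⁺ cells in direct contact — that expands through transit-amplifying
progenitors (TAPs, Ki67⁺DCX⁻) and proliferating neuroblasts (prNBs,
Ki67⁺DCX⁺), sheds postmitotic neuroblasts (Ki67⁻DCX⁺), and exhausts. The
package quantifies three aspects: population turnover, single-clone fate
dynamics, and the spatial organization of foci.

## Steady-state renewal model (`turnover_model`)

Assumptions: the KC pool of size *N* is stationary; initiations form a
homogeneous Poisson stream at rate *rN* per day; each KC lives a fixed
duration τ (deterministic), so stationarity forces *r* = 1/τ and the
steady-state age distribution is uniform on [0, τ). An exponential-lifetime
option (memoryless, mean τ) is provided; both agree to first order for
chases ≪ τ.

The fixed lifetime is the default because labeling-index curves saturate
sharply at a well-defined breakpoint — a hallmark of near-deterministic
lifetimes — whereas an exponential lifetime would round the shoulder of the
curve substantially.

Closed forms used throughout:

- BrdU pulse-chase: unlabeled-KC fraction after chase *c* is min(*c*/τ, 1)
  (fixed) or 1 − e^(−c/τ) (exponential). The inverse estimator
  *r* ≈ f/c is a linearization, valid for c ≪ τ, and is documented as an
  approximation.
- Tamoxifen lineage tracing: LI(t) = *p*·min(t, τ)/τ with lineage-labeling
  probability *p*; initial slope *p·r*, plateau *p*.
- KC/astrocyte ratio → activation rate: a cross-sectional KC census
  integrates activations over one lifetime, so rate = ratio/τ.

`fit_li_curve` fits LI(t) = s·min(t, b) through the origin by profiling the
breakpoint over a 0.25-day grid (the slope has a closed-form solution at
each candidate b) and bootstraps standard errors nonparametrically over
observations. The plateau is flagged unidentifiable when no observation
lies past the fitted breakpoint. On the measured labeling-index sequence
(0, 4, 14, 20, 28 days → 0, 9.4, 33.5, 36.1, 36.1 %) the exact least-squares
hinge optimum sits at b = 15.0 days (plateau/early-slope = 0.361/0.024),
slightly above the 10–14-day window one reads off the curve by eye and
within two standard deviations of the independently estimated 10.6 ± 2.1-day
lifetime.

`simulate_turnover` samples the Poisson initiation stream directly (births
uniform given the Poisson count, deaths at birth + lifetime) and derives
snapshots, pulse labels (every KC alive at pulse time), and heritable
tamoxifen labels (lineages initiated after induction, with probability *p*).
A burn-in of 3τ is enforced before any stationarity claim.

Default parameters: *r* = 0.094/day, τ = 1/r = 10.64 days, *p* = 0.361,
*N* = 288 — the study conditions this package emulates.

## Clone-expansion model (`clone_model`)

State (K, D, P) = (TAPs, prNBs, pmNBs), started at (1, 0, 0) when an
astrocyte activates; the clone age clock equals the KC age. Rates (per cell
per day): TAP division λ_K (K→K+1); TAP differentiation γ_K(t)·K with
coupling mode independent (K−1, D+1), symmetric (K−1, D+2), or asymmetric
(K, D+1); prNB division λ_D (D→D+1); prNB cycle exit γ_D(t)·D (D−1, P+1),
always division-independent. Differentiation propensities are power laws of
clone age, γ(t) = γ₀·t^α with γ₀ the rate at t = 1 day; α > 1 is the
accelerated regime and the default, α = 0 the constant-propensity nested
null. Negative exponents are refused (unbounded propensity at t → 0). With
α > 0 the cumulative hazard diverges, so every clone differentiates and
exhausts almost surely.

**Simulation** is exact via thinning: on each window [t, t + 0.5 d] the total
rate is majorized by evaluating the nondecreasing γ at the window end;
proposals beyond the window advance the window, accepted proposals fire an
event chosen by the true rates at the proposal time. A vectorized endpoint
variant advances thousands of independent clones in lockstep for snapshot
sampling and fitting.

**Oracle.** `master_equation` integrates the forward Kolmogorov equations on
a truncated (K, D) lattice (P marginalized out; off-lattice transitions
suppressed so probability is conserved exactly) with DOP853. Boundary mass is
reported and the result flagged unreliable above 10⁻⁶ by default. Simulator
and oracle agree to total-variation < 0.02 at 10⁵ runs across coupling and
propensity variants; the pure-birth (Yule) and frozen-clone limits hold in
closed form.

**Snapshot sampling** mirrors the observation scheme: under steady-state
turnover a cross-section samples clone ages uniformly over one lifetime, so
ages are uniform on [0, τ] by default; snapshots with K + D < 4 fall below
the KC definition and are filtered (counts reported). Whether the real
cross-section weights ages by clone survival is unknown; uniform ages are
the declared choice.

**Fitting** minimizes the joint multinomial negative log-likelihood of the
observed TAP-per-KC and prNB-per-KC count distributions under simulated
snapshot distributions. Common random numbers (one frozen seed reused at
every proposal) make the objective deterministic; Nelder–Mead runs on
log-rates (and log-exponents for the power-law variant); a pseudocount of
0.5 per category keeps the likelihood finite. A ±50 % perturbation probe
flags weakly identified parameters. `compare_variants` ranks fits by AIC
with a ΔAIC ≤ 2 tie band — the resolution at which division-coupled and
division-independent TAP differentiation may be indistinguishable at
realistic sample sizes.

Default rates (λ_K = 0.5, λ_D = 0.25, γ_K0 = 0.01, α_K = 2.6, γ_D0 = 0.005,
α_D = 2.6) were calibrated once so that uniform-age snapshots over one
lifetime with the ≥4-cell filter reproduce the observed KC size summaries
(mean ≈ 11, upper tail ≈ 40 cells) and the maturation crescent — pure-TAP
compositions at small sizes grading into prNB-dominated ones at large sizes.
They are generator defaults, not estimates of the real rates. Known
deviation regime: with an accelerated best fit, the smallest size classes
tend to be over- and the largest under-represented relative to real data,
where dispersal of the last prNBs and rare KC fusions distort both tails;
neither process is modeled.

## Spatial statistics (`spatial_stats`)

- **G function.** Ĝ(r) = fraction of points whose nearest-neighbor distance
  is ≤ r; no edge correction. Validity is by envelope inference: data and
  null simulations are evaluated with the identical estimator in the
  identical region, so the estimator's bias cancels in the comparison.
- **CSR envelopes.** n_sim patterns with the same n are drawn uniformly in
  the same region (999 by default; fewer than 19 refused). The global p is
  the rank of an integrated-absolute-deviation statistic ∫|Ĝ − Ḡ₀|dr (max
  deviation available as an option) with each pattern's deviation measured
  against the leave-one-out mean of the others — this makes observed and
  simulated statistics exchangeable under H0 and the Monte-Carlo p exactly
  uniform on its grid, p = (k+1)/(n_sim+1) ≥ 1/(n_sim+1). Empirical type-I
  error sits on the nominal level (checked at α = 0.05 and 0.01 over 200
  replicates).
- **Moran's I.** I = (n/ΣW)·Σᵢⱼwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σᵢ(xᵢ−x̄)², with
  row-standardized weights: inverse distance with cutoff 2× the mean
  nearest-neighbor distance (default; the field rarely reports its weight
  scheme, so ours is declared, not reconstructed) or k-nearest-neighbor.
  Isolated points under a cutoff are dropped with a warning; constant marks
  are a hard error. Binary marks (pmNB association) use the same statistic —
  the join-count equivalent. p values come from random permutations of marks
  over positions; two-sided p doubles the smaller tail and caps at 1, which
  is conservative for discrete statistics.
- **Pooling.** Fisher's method (−2Σln pᵢ ~ χ²₂ₖ) via scipy. Exact zeros are
  refused: Monte-Carlo tests cannot produce p = 0, so a zero marks an
  upstream error; the floor 1/(n_sim+1) should be used instead.
- **Distance-to-nearest-KC.** One-sided Wilcoxon rank-sum comparing
  query→nearest-KC distances against KC→KC nearest-neighbor distances;
  'greater' asks whether putative new activation sites avoid existing foci.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure of reconstructed specimens;
they are the package's test bed, not an image-level simulation.

- **Regions**: box, spherical shell (lesion-border geometry), or voxel mask;
  uniform sampling is exact per region type (inverse-CDF radius for shells,
  voxel-then-offset for masks).
- **Point processes**: CSR (the null engine); Thomas clustered and hard-core
  inhibited processes as power/fixture alternatives. Infeasible hard-core
  packings fail fast rather than looping forever.
- **KC sizes**: integer-rounded truncated normal on [4, 38]. The (loc,
  scale) are calibrated so the truncated law's mean is exactly the observed
  11.8 cells; no truncated normal on this range can simultaneously reach the
  observed SD of 7.6 (the real sizes are right-skewed), and the calibration
  brings it as close as possible (≈ 7.2). The true size law lives in
  unreleased per-KC data; this is a declared stand-in.
- **Types**: (TAPs-only, mixed, prNBs-only) = (0.25, 0.50, 0.25) — half the
  KCs pure, split evenly between the pure types since the pure split is not
  separately reported. Mixed KCs draw a uniform prNB fraction with at least
  one cell of each stage.
- **pmNB association**: logistic in (prNB fraction, size) with coefficients
  (−2.2, 2.5, 0.08), rising with maturity as observed; the exact curve is
  not published.
- **Dormant astrocytes**: ≥1 with probability 0.75 (two with 0.05) — the
  clonally related Ki67⁻DCX⁻ cell seen beside most labeled KCs.
- **Labeling**: BrdU labels each cell of pre-existing KCs independently at
  0.74; tamoxifen labels founding lineages (YFP probability 0.361, or
  Confetti colors at 2.4/1.2/1.7 %) heritably. KC maturation advances with
  age: the prNB fraction tracks age/τ linearly — a deliberate simplification
  of an ordinal progression.
- **Specimens**: cell positions are the nearest-origin sites of a cubic
  lattice with spacing 0.7× the contact radius, randomly rotated and
  jittered by ≤ 10 % of the spacing — this guarantees each KC is a connected
  component under the contact radius with strictly positive cell spacings.
  Centroids are placed with a hard-core exclusion wide enough that clusters
  can never touch, making KC detection an exact round trip; with CSR
  placement instead, possible merges are surfaced as metadata warnings.

What passing tests on these data do **not** show: robustness to segmentation
error, anisotropic tissue deformation, lesion-border-driven density
gradients, KC fusion, or non-monotone maturation — none of which the
generators produce.

## KC analysis (`kc_analysis`)

Detection links Ki67⁺ cells within a contact radius (default 12 μm ≈ one
soma diameter — a Euclidean stand-in for image-morphological "direct
contact") and takes connected components; components of ≥ 4 cells are KCs,
smaller ones are returned as singles/pairs/trios. Component ids are assigned
by centroid lexicographic order, so the partition and ids are invariant to
input row order. Typing uses prNB-fraction tertiles — (0, 1/3] Low,
(1/3, 2/3] Med, (2/3, 1) High — with pure compositions as their own classes;
the boundaries used in the original figures are unpublished, and the
tertiles are exposed as the declared default. Labeling-index, clonality, and
expected-same-color summaries follow the operational definitions: a KC is
labeled if ≥ 1 cell carries the label, fully labeled KCs are counted among
labeled ones, a single-color KC has one reporter color and no non-recombined
member (non-recombined members make it mixed), and per-color expectations
are multinomial means n_kc·p_c with Monte-Carlo intervals and a two-sided
rank p for observed counts.

## Numerical choices

- Monte-Carlo p values are always (k+1)/(n_sim+1); they can never be 0.
- Ĝ grids default to ~3× the mean nearest-neighbor distance (100 points).
- The master equation uses DOP853 at rtol 10⁻⁸ on lattices sized so boundary
  mass stays below the reliability threshold; conservation is exact by
  construction (suppressed off-lattice transitions).
- The hinge-fit breakpoint grid spans the positive observation times at
  0.25-day steps; ties in RSS resolve to the smallest breakpoint.
- Clone-fit simulation sizes: 10⁴ per likelihood evaluation by default;
  analyses in the test suite and acceptance script use 1.5–3×10³ with
  matched common-random-number seeds, which recovers the generating
  parameters comfortably at n ≈ 1500 observed KCs.
- Seeds: every stochastic routine takes a seed or Generator; all generators
  are pure functions of (parameters, seed).

## Known limitations

- The renewal model has no spatial component; initiation locations are
  handled separately by the point-process fixtures.
- Clone fits constrain absolute rates only through the assumed lifetime
  horizon; from a single cross-section, time units and rates are jointly
  identified only up to that horizon (flat-profile directions are flagged,
  not hidden).
- The Moran weight scheme and the p-value pooling method used in the
  original spatial analyses are unreported; the defaults here are declared
  substitutes, and conclusions that depend on them should be checked across
  schemes (`weights="knn"`, `statistic="max-deviation"`).
- Astrocyte reactivation within a clone, pmNB dispersal, and KC fusion are
  not modeled.
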