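# kcdyn

Quantitative models and spatial statistics for **injury-induced striatal
neurogenesis**: the dynamics of the transient proliferative clusters
("Ki67 clusters", KCs) that appear when parenchymal astrocytes of the mouse
striatum activate a latent neural-stem-cell program after an excitotoxic
lesion.

The package is written for quantitative biologists analyzing 3D-reconstructed
cell maps of neurogenic tissue: it provides the generative models, estimators,
and Monte-Carlo tests needed to ask *how often astrocytes activate, how long
each neurogenic focus lives, whether foci interact in space, and how their
progenitors choose between division and differentiation* — together with a
synthetic-specimen generator so every analysis is testable end to end without
microscopy data.

## What is modeled

A KC is a group of ≥ 4 proliferating (Ki67⁺) cells in direct contact, composed
of TAPs (Ki67⁺DCX⁻ transit-amplifying progenitors) and prNBs (Ki67⁺DCX⁺
proliferating neuroblasts), optionally flanked by postmitotic neuroblasts
(Ki67⁻DCX⁺). Three quantitative layers sit on top of that definition:

**Steady-state renewal (turnover).** KCs are transient: initiations form a
Poisson stream at rate *rN* per day while each KC lives a fixed lifetime τ,
with *r* = 1/τ at steady state. Closed forms follow for the two labeling
experiments that read the model out: after a saturating BrdU pulse and a chase
of *c* days, the unlabeled-KC fraction is min(*c*/τ, 1); after tamoxifen
induction of a heritable reporter with lineage-labeling probability *p*, the
KC labeling index is LI(*t*) = *p*·min(*t*, τ)/τ — linear with slope *p·r* and
a plateau at *p*. A population simulator and a hinge (breakpoint) regression
`fit_li_curve` recover (*p·r*, *p*, τ) from data.

**Clone expansion.** Each KC is the clone of one activated astrocyte, started
as a single TAP. TAPs divide at rate λ_K and differentiate into prNBs with a
time-*accelerating* propensity γ_K(t) = γ_K0·t^α_K (α > 1); prNBs divide at
λ_D and exit the cycle with γ_D(t) = γ_D0·t^α_D. Simulation is exact
(thinning against piecewise-constant majorants); a truncated-lattice master
equation is the independent oracle; fitting is by simulated multinomial
likelihood with common random numbers, and variants (constant vs accelerated
propensity; division-coupled vs independent differentiation) are compared by
AIC.

**3D spatial statistics.** Nearest-neighbor G(r) functions with Monte-Carlo
complete-spatial-randomness envelopes (envelope-based inference, no edge
correction), Moran's I with permutation nulls for marked patterns (KC size,
prNB content, pmNB association), Fisher pooling across specimens, and a
rank-sum comparison asking whether new activation events (single/pair/trio
Ki67⁺ groups) arise farther from existing KCs than KCs are from each other.

## Worked example

```python
from kcdyn import synthetic_data as sd, spatial_stats as ss, turnover_model as tm

spec = sd.gen_specimen(sd.SpecimenConfig(n_kc=288, seed=1))
print(len(spec.cells), len(spec.kcs))          # 3714 288
print(round(spec.kcs["size"].mean(), 2))       # 11.6

env = ss.csr_envelope(spec.pattern, n_sim=999, seed=2)
print(env.p_value)                             # 0.542

res = ss.morans_i(
    ss.PointPattern3D(spec.pattern.points, spec.region,
                      marks=spec.kcs["size"].to_numpy(float)),
    weights="knn", k=6, n_perm=999, seed=3)
print(round(res.i, 4), round(res.p_value, 3))  # 0.01 0.694

p = tm.RenewalParams(rate=0.094)
print(round(p.tau, 2))                                        # 10.64
print(round(tm.expected_unlabeled_fraction(4.0, p), 3))       # 0.376
```

Reading the output: the synthetic specimen carries 288 KCs averaging ~11.6
cells; the G-function envelope test does not reject spatial randomness of the
KC centroids (p = 0.54), and KC size shows no spatial autocorrelation
(Moran's I ≈ 0.01 against a permutation-null expectation of −1/(n−1) ≈
−0.003, p = 0.69) — foci are spatially independent. A 9.4 %/day turnover rate
implies a 10.64-day KC lifetime, which predicts that 37.6 % of KCs postdate a
4-day chase and therefore carry no BrdU.

A CLI mirrors the library (`kcdyn simulate | detect | nn | gfunc | moran |
turnover | clone | run`); `kcdyn run` executes the whole chain and writes
tidy CSVs plus a provenance manifest.

## Layout

- `kcdyn.regions` — observation windows (box, spherical shell, voxel mask)
- `kcdyn.synthetic_data` — specimen / composition / labeling generators
- `kcdyn.kc_analysis` — KC detection, typing, labeling and clonality summaries
- `kcdyn.spatial_stats` — G function, CSR envelopes, Moran's I, pooling
- `kcdyn.turnover_model` — renewal model, closed forms, simulator, LI fitting
- `kcdyn.clone_model` — stochastic clone model, master equation, fitting
- `kcdyn.pipeline_io` — CSV/YAML schemas, pipeline driver, manifest

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
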