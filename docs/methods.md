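# Methods

`lesionkit` predicts compensatory brain areas for a focal lesion from two
independent routes — anatomical similarity on the healthy connectome and
homeostatic dynamics on the lesioned one — and quantifies the resulting
functional-connectivity (FC) changes. This note documents the models, the
parameters that matter, the synthetic data that stands in for empirical
connectomes, and the numerical choices behind both.

## The three-condition workflow

For a subject's structural connectome (SC) `C` and a lesion site `L`:

1. **Healthy.** The weighted Jaccard profile of `L` is computed on the
   intact `C` and the top 25% of regions become the structurally similar
   areas (SSAs). The dynamic mean-field model is tuned by feedback
   inhibition control (FIC) to the balanced excitation–inhibition state,
   yielding inhibitory weights `J` and, through the hemodynamic model, the
   healthy FC.
2. **Altered.** The lesion zeroes row and column `L` of `C`. The model is
   simulated with `J` frozen at the healthy values: excitation is lost but
   inhibition has not yet adapted — the acute, imbalanced state — giving
   the altered FC.
3. **Reorganized.** FIC runs again on the lesioned `C`, initialised at the
   healthy `J`. The final weights `J′`, the per-region re-adjustment times
   `RT`, and the weight changes `dJJ = J′ − J` quantify each region's
   homeostatic work; a further simulation gives the reorganized FC.

Dynamically similar areas (DSAs) are the intersection of the top 25% of
regions by `RT` and by `|dJJ|`. The headline statistic is the overlap
`|SSA ∩ DSA| / |DSA|`: the fraction of dynamically identified compensators
that were predictable from anatomy alone.

## Dynamic mean-field model

Each region holds an excitatory and an inhibitory population with gating
variables `S_E, S_I ∈ [0, 1]`:

    I_E_i = w_E·I0 + w₊·J_N·S_E_i + G·J_N·Σ_j C_ij·S_E_j − J_i·S_I_i
    I_I_i = w_I·I0 + J_N·S_E_i − w_II·S_I_i
    r = (aI − b) / (1 − exp(−d(aI − b)))
    dS_E/dt = −S_E/τ_E + (1 − S_E)·γ·r_E + σν(t)
    dS_I/dt = −S_I/τ_I + r_I + σν(t)

Constants are the canonical reduced two-population set: `I0 = 0.382 nA`,
`w_E = 1`, `w_I = 0.7`, `w₊ = 1.4`, `J_N = 0.15 nA`, `w_II = 1`,
`a_E = 310 nC⁻¹`, `b_E = 125 Hz`, `d_E = 0.16 s`, `a_I = 615`, `b_I = 177`,
`d_I = 0.087`, `τ_E = 100 ms`, `τ_I = 10 ms`, `γ = 0.641`, `σ = 0.01 nA`.
Integration is Euler–Maruyama at `dt = 1 ms` with clipping of the gating
variables to `[0, 1]` after every step (the stochastic scheme can leave the
physical range; clipping is the convention in published implementations).
Noise enters both population equations with the same `σ`, i.i.d. across
regions and populations.

`simulate()` runs a numba-compiled loop; `step()` is a transparent
single-step reference sharing the same formulas and operation order, and
the test suite holds the two to within accumulated rounding error
(≤1e-13 after 250 steps on shared noise; bit-exactness is precluded only by
the BLAS-vs-compiled matvec summation order). Noise-free trajectories are
validated against `scipy.solve_ivp` (Radau, rtol 1e-10) to 1e-4 at 1 s.

### Global coupling G

`G` has no universal value; in the literature it is fitted per cohort by
maximising the match between simulated and empirical FC subject to the
firing constraint. Two mechanisms are provided:

- `fit_global_coupling` — the full fitting procedure against a target FC.
- `calibrate_coupling_by_band` — a target-free surrogate: the largest grid
  `G` for which every subject's post-FIC firing stays inside the balanced
  band. Because simulated FC strength in this model family peaks just
  below the stability edge of the balanced state, this lands on the same
  operating point the FC fit would select, without needing a reference FC.

The package default `G = 1.4` was frozen by running the band criterion
across a 10-cohort × 3-subject validation sweep of default synthetic
connectomes (largest 0.05-grid value with zero band failures). The
FC-contrast analyses calibrate `G` per cohort, which matters there because
edge-level effects scale with overall FC strength.

## Feedback inhibition control

The homeostatic target is a band on each region's window-averaged
excitatory input current, `I* = b_E/a_E − 0.026 nA ± 0.005 nA`. Through
the excitatory transfer function this corresponds exactly to mean firing
between 2.63 and 3.55 Hz around the ≈3 Hz set point, which is the
operational definition of the balanced state used throughout.

The loop simulates consecutive 10 s windows without state resets. After
each window, regions above the band get `J` increased, regions below get
it decreased, by a per-region additive step (default 0.05 nA) that halves
whenever the region's deviation changes sign, with a floor of 1e-4 on the
step and 0.001 nA on `J`. Tuning stops at the first fully-in-band window
or after the window budget (default 200; 60 in the reduced profile).

`RT_i` is `window_length ×` the 1-based index of the *last* window in
which region `i` violated the band; a region never pushed out of the band
has `RT_i = 0` and `dJJ_i = 0` exactly.

Healthy runs initialise `J` from the balanced-state solution: with every
region at the set point, the required weight is affine in nodal strength,
`J_i = J* + (G·J_N·S_E*/S_I*)·strength_i`, where `(S_E*, S_I*, J*)` solve
the isolated-node fixed point (`J* ≈ 1.002 nA` at default constants). This
usually lands inside the band immediately — healthy `RT` is not an object
of study. Lesioned runs always initialise from the healthy `J_final`, so
`RT` and `dJJ` measure the work the lesion demands.

### DSA eligibility

Regions with `RT = 0` or `dJJ = 0` never responded to the lesion and are
not eligible for the DSA rank sets: including them via the deterministic
index tie-break would populate the "dynamically similar" set with regions
the dynamics never distinguished. The DSA can therefore hold fewer than
`N = round(0.25 × n_regions)` members; the overlap fraction uses `|DSA|`
as its denominator (recorded in every report).

## Hemodynamics and FC

BOLD is generated by the standard Balloon–Windkessel cascade
(`κ = 0.65 s⁻¹`, `γ_f = 0.41 s⁻¹`, `τ = 0.98 s`, `α = 0.32`, `ρ = 0.34`,
`V0 = 0.02`; `k1 = 7ρ`, `k2 = 2`, `k3 = 2ρ − 0.2`) driven by each region's
mean-centred `S_E` (centring keeps the system at its zero-drive baseline,
where the readout is exactly 0 % change), integrated by Euler at the
recorded activity resolution (10 ms by default) and sampled at `TR = 2 s`.
FC is the Pearson correlation of the per-region z-scored BOLD series; the
step response is validated against a stiff reference integrator.

Edge-wise condition contrasts are paired t-tests across subjects on
Fisher r-to-z transformed correlations (the variance-stabilising choice),
with Benjamini–Hochberg FDR at α = 0.05 (configurable) over the
upper-triangle p-values. The t statistic is oriented as second condition
minus first. FC graph metrics zero negative correlations, convert weight
to length by reciprocal, and use seeded Louvain (20 restarts, best
modularity), the weighted-triangle transitivity ratio, and Dijkstra-based
global efficiency and characteristic path length. Group summaries average
per-subject metrics rather than computing metrics of an averaged FC.

## Synthetic cohorts

No suitable empirical cohort is publicly deposited, so the generator
emulates the statistical structure the analysis relies on. Defaults: 49
subjects, 68 regions (34 per hemisphere), 4 mirrored modules per
hemisphere, intra/inter-module edge probabilities 0.7/0.15, log-normal(0, 1)
weights, multiplicative log-normal subject jitter (σ = 0.1) around a shared
group skeleton.

Three features carry the science:

- **Exponential distance rule.** Regions sit on a ring per hemisphere and
  within-hemisphere weights decay with ring distance (e-folding 6 index
  units). This couples profile similarity (shared neighbourhoods) to
  direct connection strength — in real connectomes both are consequences
  of spatial embedding, and the SSA↔DSA equivalence depends on it.
- **Mirrored callosal topography.** The edge between left-`i` and
  right-`j` is 0.4 × the mean of the two hemispheres' `i–j` weights
  (jittered, kept with probability 0.5), and the homotopic edge is
  enforced to be each region's strongest callosal link. Homotopic pairs
  thereby share third-party neighbourhoods, which is what lets a lesion's
  contralesional homologue rank highly in both SSA and DSA — the
  hemisphere-recruitment signature of the analysis.
- **Normalisation to unit maximum nodal strength.** The stability
  threshold of the coupled model scales with `G ×` the largest row sum,
  so this scaling pins the critical `G` at the same value for every
  subject and cohort. (Matrix-max scaling was rejected: it makes the
  whole coupling scale hostage to a single heavy-tailed edge.)

Optionally `planted_twin_size = k` overwrites `k` regions with near-copies
of a designated seed region's profile (strongly inter-connected, as
homotopic twins are), giving a ground truth for recovery tests.

What the generator does *not* emulate: real parcellation geometry and
distances, tractography biases (length- and curvature-dependent false
negatives), lesion-volume structure, subcortex, and the empirical FC's
global signal structure. Passing tests therefore show that the method's
mechanics behave as described on networks with the assumed statistics, not
that any specific empirical effect size would be reproduced.

## Problem sizes used by the shipped analyses

The test suite and the acceptance script run desk-scale versions of the
study protocol chosen as the package's own defaults for reproducible runs:
80 s simulations with a 20 s transient and a 60-window FIC budget for the
similarity pipeline (`ci_profile()`); 320 s simulations for FC contrasts;
3–5 subjects per cohort; 5 cohorts for the directional FC checks. The
full-protocol values (10-minute runs, 2-minute transients, 49 subjects,
200-window budget) remain the library defaults for `simulate` and
`RunConfig`.

## Known limitations

- `RT` is quantised at the window length (10 s); rank correlations with
  `RT` saturate when the FIC step dominates convergence speed (then
  `RT ∝ |dJJ|` almost exactly).
- The additive-step FIC is one member of a family; other homeostats
  (rate-PI control, excitatory scaling) are out of scope.
- Single-node lesions only; edge deletions and multi-site damage are not
  implemented.
- The acute "altered" condition freezes `J` entirely; a partial-adaptation
  continuum between conditions 2 and 3 is not modelled.
- Louvain modularity is a stochastic lower bound even with restarts; on
  dense correlation graphs small (<0.02) modularity differences between
  conditions are not meaningful at cohort sizes of 3.
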