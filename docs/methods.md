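# Methods

This note documents the model, the synthetic-experiment generator, the
numerical and statistical choices, and the limitations of `tumorcast`. It is
the design record for maintainers; every number quoted here is computed by
the test suite or by `scripts/acceptance.py`, not asserted by hand.

## Model and assumptions

The colony lives on a regular pixel grid (default 15 × 15 pixels of
430 µm ≅ a 6450 µm field of view; row-major, origin top-left, half-open
pixel cells). Counts per pixel are treated as a continuous density.

**Pre-treatment** (0 ≤ t ≤ t_dox, default 48 h): one phenotype, exponential
growth g₀ plus Fickian diffusion D₀, both spatially uniform — the
pre-treatment data show essentially no spatial structure, and the low cell
density justifies dropping the crowding term.

**Post-treatment**: the map at t_dox is split into surviving (fraction `fs`)
and irreversibly damaged (1 − `fs`) compartments. Both follow logistic
reaction-diffusion dynamics against a *shared* carrying capacity θ; the
damaged net per-capita rate `gd + kd·exp(−γd(t−t_dox)) − kd` starts at `gd`
(transient post-treatment growth) and relaxes toward `gd − kd` with delay
rate `γd` — delayed drug-induced death. The surviving reaction term is the
standard logistic form `gs·Ns·(1 − Ntot/θ)`; a density-independent variant
would not be dimensionally consistent with the exponential pre-treatment
limit. All compartments share one diffusion coefficient (`Ds = Dd = D₀`),
so diffusion is identified pre-treatment and frozen afterwards.

θ is interpreted as a **well-level** capacity: the per-pixel crowding term
uses θ / n_pixels. The alternative per-pixel reading is available through
`SolverConfig(theta_scope="pixel")`; the well-level default is consistent
with seeding counts and bulk time courses being reported per well.

### Parameters, units, admissible ranges

| parameter | meaning | unit | range | scope |
|---|---|---|---|---|
| g₀ | untreated proliferation | 1/h | [0.02, 0.035] | global, pre |
| D₀ | diffusion | mm²/h | [0, 0.005] | global, pre, then frozen |
| gs | surviving proliferation | 1/h | [0.0001, 0.035] | **local (per pixel)** |
| fs | surviving fraction at t_dox | – | [0, 1] | global |
| kd | drug-induced death rate | 1/h | [0.0001, 0.01] | global |
| gd | damaged proliferation | 1/h | [0.001, 0.05] | global |
| γd | death-delay rate | 1/h | [1/120, 1/10] | global |
| θ | carrying capacity | cells/well | [88000, 90000] | global, narrow |

The diffusion range is read as [0, 0.005] mm²/h (the admissible table prints
only the upper end). `gs` is the only locally calibrated parameter; making
more parameters local would mean fitting several hundred values per well and
invite overfitting — the sensitivity screening below is the quantitative
basis for this choice.

## Numerics

Explicit forward Euler with Δt = 1 h, 5-point central-difference Laplacian,
zero-flux boundaries via mirrored ghost nodes. The scheme is guarded by a
CFL check `D·Δt/Δx² ≤ 0.25`; at the extreme admissible diffusion
(D = 0.005 mm²/h, Δx = 0.43 mm) the CFL number is ≈ 0.027, far inside the
stable region. Properties verified by the suite: the no-flux Laplacian sums
to zero (mass conservation to ~1e−16 relative per step), zero-diffusion
trajectories match an independently coded scalar recurrence to machine
precision, and timestep halving converges with empirical order ≈ 1.

Negative densities produced by the explicit update are clipped to zero after
each step (counts are physical; clip events are logged at debug level).
Measurement times are snapped to the nearest internal step, never
interpolated. The inner Euler loops are compiled with numba when available;
a pure-numpy step implementation is kept as the reference and the two are
held equal (to 1 ulp of `exp`) by a dedicated test.

The population split at t_dox computes the larger of the two shares by
multiplication and the smaller as the complement, which makes
`Ns + Nd == Ntot` exact in floating point (Sterbenz lemma).

## Synthetic experiments

The generator emulates the study design: 9 doses
(10–300 nM) × 6 replicates plus 6 controls; 2000 cells seeded per well
(multinomially scattered, so seeding is homogeneous in expectation);
treatment at 48 h; imaging every 4 h; experiment length log-interpolated in
dose from 277 h (10 nM) to 963 h (300 nM); optional truncation at confluence
(default 0.95·θ). Centroid tables can be scattered from maps and re-binned
losslessly for I/O round trips.

Dose regimes encode the qualitative biology:

* control / low dose (< 50 nM): `fs = exp(−dose/40)` stays high, `gs`
  spatially uniform (0.025–0.0275 1/h) — near-unperturbed growth;
* medium dose (50–150 nM): 2–5 Gaussian high-`gs` foci
  (base 0.005, peak 0.015 1/h, radius 1.2–2 px) on an otherwise uniform
  field — decline for roughly two weeks, then clustered relapse;
* high dose (> 150 nM): `fs` near zero, uniform low `gs` — homogeneous decay.

The death side is dose-increasing, `kd = 0.002 + 0.008·(dose/300)^0.4`, with
`gd = 0.005` and `γd = 0.03` fixed: `kd > gd` at every treated dose, so the
damaged pool declines after the delay — the defining treatment effect.
`gd = 0.005` sits in the interior of the decay-compatible sub-range
[0.001, 0.01); placing the ground truth adjacent to a parameter bound makes
the least-squares surface collapse onto the bound and degenerates recovery
experiments. The cluster peak of 0.015 1/h reproduces the observed relapse
timescale (clusters identifiable ~2 weeks post-treatment, confluence only
near the experiment end); faster foci would erase the decline phase
entirely.

Measurement noise is additive Gaussian per pixel with
sd = max(noise_rel·count, noise_floor), clipped at zero; defaults
noise_rel = 0.05, noise_floor = 1 cell (segmentation and stage-vibration
noise has a floor independent of the signal). Recovery experiments that
state "5 % noise" use the proportional term only. Each well draws from its
own RNG stream seeded by (master_seed, dose, replicate), so datasets are
bitwise reproducible.

**What the generator does not emulate**: raw fluorescence images and
segmentation artifacts (emulated only at the centroid/count level),
pixel-correlated noise, cell-cycle structure, drug pharmacokinetics,
phenotype switching under repeat dosing. Passing recovery and forecasting
tests on these synthetics therefore demonstrates the correctness and
self-consistency of the machinery — not calibration or forecast accuracy on
real microscopy data.

## Calibration

Stage 1 fits (g₀, D₀) to all pre-treatment pixel courses jointly
(≥ 3 timepoints required); D₀ is then frozen. Stage 2 fits the 225 local
`gs` values plus the 5 globals to the post-treatment `Ntot` maps, initialized
at the measured map at t_dox split by the candidate `fs`. Residuals are the
unweighted concatenated (model − data) over every pixel and post-treatment
time; only `Ntot` enters the objective — the compartments are latent.

The optimizer is scipy's trust-region reflective `least_squares` on
variables rescaled to the unit cube (the natural scales span six orders of
magnitude), tolerances 1e−8, finite-difference step 1e−6, iteration cap 500.
Initial guesses: bound midpoints for globals, the pre-treatment g₀ for every
`gs` pixel. Pixels with an identically zero course have `gs` fixed at its
lower bound and are excluded from the optimization (and are undefined in
CCC_pixel, where the exclusion count is reported).

**Bootstrap**: the pooled residual sd defines an i.i.d. Gaussian noise model
(per-pixel noise scales are underdetermined by a single replicate); each of
the n_boot (default 100) synthetic datasets is the fitted curve plus fresh
noise, refitted *from the original initial guesses* — warm-starting at the
fitted point collapses the spread of weakly identified parameters (they
simply re-pin), understating their uncertainty. Distributions are summarized
by mean, interquartile range and NSD = sd/|mean| per parameter (`gs` via its
pixel mean). On synthetic mid-dose wells the NSDs of (kd, gd, γd) exceed
those of (gs, fs, θ) several-fold: the damaged compartment is observed only
through the total count, so the death parameters are structurally the least
precise. Note the identifiability cliff: at weak kill (shallow decline) the
(kd, γd) pair degenerates and fits pin kd at a bound — a property of the
model class, not of the optimizer.

## Sensitivity screening

Total-effect Sobol indices via Saltelli sampling (scrambled Sobol sequences,
two base matrices plus k column swaps) and the Jansen estimator; the default
base size 625 with k = 6 factors gives exactly 5000 model evaluations. The
quantity of interest is the terminal total count of a spatially uniform well
(uniform fields make diffusion inert, so the QoI reduces to the exact scalar
recurrence and the screening is cheap). The estimator is validated against
an additive model with closed-form variance shares.

θ is screened over a widened range ([9000, 90000]); over its narrow
calibration range its index collapses below 0.01 — which is precisely the
observation that makes the narrow range safe to calibrate over, while the
wide-range screening shows θ and `gs` dominating the output variance and
justifies keeping `gs` as the only local parameter. One caveat is recorded
honestly: `gd`'s admissible range ([0.001, 0.05]) is the widest of all
rates, and its true total effect sits within ~0.005 of `gs`'s; at the
5000-evaluation budget their sample ranking can swap between RNG streams
(the suite checks the ranking at the documented default stream; the
acceptance script reports the indices themselves).

## Weekly assimilation and forecasting

For the six replicates of a dose, five are fully calibrated (training set)
and averaged pixelwise into the prior grid `P_training`; the sixth is
forecast in weekly (168 h) segments:

1. Week 0→1 runs the model from the held-out replicate's measured map at
   t_dox under the prior.
2. At each weekly boundary the model is recalibrated to the held-out data
   from t_dox through the boundary (warm-started at the previous week's
   fit), giving `P_measure`.
3. Each test pixel ranks all 5·15·15 = 1125 training pixel courses by CCC of
   the raw counts over the common window; the top ⌈25 %⌉ = 282 contribute
   their calibrated parameter sets with weights CCC_k / ΣCCC (uniform
   fallback when the test course is flat or the selected CCC sum is ≤ 0;
   ties broken by pixel id, so the transfer is order-stable).
4. The refreshed prior and `P_measure` blend as
   `ω·P_training + (1−ω)·P_measure`, ω evaluated once per segment at its
   start time normalized by 963 h. All six parameters vary pixelwise in the
   blended grid — prediction needs no refitting, so locality costs nothing.
5. The next segment is initialized at the last measured map. Because `fs` is
   defined at t_dox, the measured map is split by the **propagated surviving
   share**: the blended grid is run from the measured t_dox map (split there
   by the blended `fs`) to the segment start, and its per-pixel Ns/Ntot
   ratio splits the measured map. Splitting a late-week map directly by the
   t_dox-era `fs` would misassign the survivor-dominated population and is
   demonstrably inconsistent (noiseless self-consistent forecasts collapse).
   Pixels the model empties fall back to the blended `fs`.

Forecast uncertainty: bootstrap distributions of the training and weekly
calibrations are propagated — each draw pairs one training sample
(transferred with the same similarity weights) with one weekly sample,
blends, and runs forward; segments carry the mean and 25th–75th percentile
band of these runs (defaults 100 bootstrap samples, 1000 forward draws;
reduced sizes are used in tests).

On the self-consistent design (six noiseless replicates sharing one
spatially uniform truth) every weekly forecast reproduces the held-out data
with CCC_well ≈ 1. With independent medium-dose truths the week-1 forecast
cannot contain the held-out replicate's relapse clusters (spatial CCC of the
terminal map ≈ 0.1–0.3); once the weekly updates assimilate the emerging
pattern the forecasts place elevated counts at the true cluster pixels and
the terminal-map spatial CCC rises above 0.97.

## Problem sizes

Unit and acceptance tests run the generator, calibration, bootstrap and
pipeline on a 5 × 5 grid with 400 seeded cells (the same density per pixel
as the full design) and 25 bootstrap samples; these sizes exercise every
code path while keeping the suite at a few minutes. The selection-size and
grid-geometry checks run at the full 15 × 15 geometry, and full-scale
calibrations (15 × 15, 230 fitted parameters) run in under a minute each
thanks to the compiled solver loops. `scripts/acceptance.py` uses the same
sizes and completes in about a minute.

## Known limitations

* Forward Euler is first-order; Δt = 1 h is accurate at these rates but the
  scheme is not adaptive, and stiff parameter draws rely on clipping.
* The residual bootstrap assumes i.i.d. Gaussian noise pooled across pixels
  and times; real segmentation noise is heteroscedastic and correlated.
* (kd, γd) identifiability depends on the kill regime; under weak treatment
  effect the death parameters are set-identified at best and NSDs should be
  read as spread around one basin.
* The unweighted objective lets late, high-count timepoints dominate; a
  variance-weighted objective is a natural extension but is deliberately not
  the default (the reference procedure is unweighted).
* ω's quadratic schedule and the weekly update cadence are fixed design
  choices; alternative schedules plug in via `blend_parameters`/`omega` but
  no optimality is claimed.
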