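# Methods

## Model

Two auxotrophic strains exchange essential metabolites. State variables
are live-cell densities (cells/ml) and metabolite concentrations (µM;
1 µM = 10⁶ fmol/ml, the only unit conversion used). Strain *i* releases
its product at a per-live-cell rate *r<sub>i</sub>* (fmol/cell/hr) —
release is proportional to live cells whether or not they are growing,
an assumption since starving-cell release is not separately
characterized — and consumes *c<sub>i</sub>* fmol of its required
metabolite per cell birth, so consumption flux is *c·b(L)·N*, tied to
births rather than biomass maintenance. Birth rates follow the Moser
(Hill-type) law *b(L) = b_max L^n/(K^n+L^n)*; death is an optional
first-order rate (default 0, since analytic checks assume negligible
death and no death model is empirically constrained).

Three ODE systems share these phenotypes:

* **Chemostat** (single strain, dilution *dil* = ln2/doubling time):
  live, dead, residual nutrient and released product under inflow
  *L₀*. At steady state *b(L_ss) = dil + d*, the nutrient balance
  *dil·L₀ = dil·L_ss + c·b·N_ss/10⁶* fixes the density, and the product
  balance gives *H_ss = r·N_ss/(dil·10⁶)*. These closed forms back the
  simulator tests and truth sidecars.
* **Closed community** (no flow): each strain grows on the pool its
  partner fills. When both pools stay supply-limited, the quasi-steady
  dynamics reduce to the linear system dN₁/dt = (r₂/c₁)N₂,
  dN₂/dt = (r₁/c₂)N₁ with dominant eigenvalue √(ρ₁ρ₂) (ρᵢ = rᵢ/cᵢ) and
  eigenvector ratio √((r₂/c₁)/(r₁/c₂)); `community_steady_growth` and
  `community_steady_ratio` implement these and are verified against
  brute-force eigendecomposition.
* **Competition**: two genotypes share one nutrient pool under
  dilution; no mutation process is modeled.

Integration uses LSODA with rtol 1e-8, atol 1e-10; metabolite pools can
graze zero, so states are clipped at 0 after integration (negative
excursions are bounded by the tolerances). Solver failures raise with
the offending parameter set.

## Estimators

* **Growth rate**: intensities are normalized to time zero; OLS slopes
  of the log signal over every overlapping run of 3 or 4 consecutive
  points; the maximum positive slope is the rate, with a `no_growth`
  flag (rate 0) when no window slope is positive. Window default 3;
  both sizes are supported. The max-over-windows statistic is upward
  biased by roughly the expected maximum of the window-slope noise
  (≈1.4·cv/(dt√5) for 4-point windows at spacing dt); recovery accuracy
  is therefore relative to the generating rate — fast growth near
  saturation is recovered within a few percent at 5% multiplicative
  noise, slow growth (≤0.1/hr) is systematically overestimated at the
  same noise level. This is a property of the assay definition, not of
  the implementation.
* **Growth-law fit**: `scipy.optimize.curve_fit` with initial guess
  b_max = 1.1·max(rate), K interpolated at half-max, n = 2, bounds
  b_max ∈ (0,10], K ∈ (0,10⁴] µM, n ∈ [0.5,10]; needs ≥4 distinct
  concentrations, rejects all-equal rates.
* **Steady-state detection**: trailing-window relative-range criterion
  — steady when (max−min) of the trailing 30% of points is within
  `rel_tol` (default 0.10) of the trailing mean; the onset is the
  earliest time from which the remaining series stays inside the band.
  Drifting signals whose trailing drift exceeds the band are reported
  not-reached. For data with ~10% observational noise the band must be
  widened (the noise itself fills it); pipelines pass `rel_tol≈0.5`.
* **Exchange ratio**: dil·H_ss/L₀; equals r/c at steady state up to a
  factor (1 − L_ss/L₀)·dil/(dil+d), hence the <1% residual-nutrient
  gate in the round-trip checks. A replicate variant returns a
  t-interval across runs.
* **Cytometry**: live = (fluorescent events/bead events)·(bead stock
  density·bead volume/sample volume); dead analogous. The acquisition
  fraction cancels.
* **Bioassay**: OLS standard curve (turbidity vs concentration),
  inverted; readings outside the calibrated turbidity range warn but
  still return a value, since saturation behavior is unspecified.
* **Community growth rate**: OLS log-slope over the longest trailing
  run of points whose consecutive pairwise log-slopes lie within
  `rel_tol` (default 0.15) of their mean — an operational version of
  fitting the steady regime by eye, excluding the initial lag.
* **Generations**: accumulated density at reading *k* = OD_k × product
  of fold-dilutions applied before *k*; generations = log₂ of its
  fold-change from the first reading. This accumulation convention is
  ours; the assay description leaves it implicit.
* **Flow-rate arithmetic**: flow = volume·ln2/T; dil = ln2/T.

## Inference

`predict_partner_growth_change(f) = √f − 1` follows from the geometric
mean: scaling one exchange ratio by *f* with the other fixed scales *g*
by √f. `fold_change_ci` uses point = ratio of group means and a Welch
t-interval on the difference of log-means, exponentiated — chosen for
positive, multiplicative measurement error; the interval construction
is this package's choice. Because the point is an arithmetic-mean ratio
and the interval is geometric, extremely skewed replicate sets could in
principle place the point outside the interval; in practice (replicate
CVs ≲30%) they agree closely. The predicted-change interval applies the
√ transform to the endpoints, valid by monotonicity.
`compare_groups` gates a pooled vs Welch two-tailed t-test on a
two-sided F-test of variance equality (default α = 0.05); identical
constant groups return p = 1. No multiple-testing correction is
applied.

## Synthetic data

Generators emulate the assays with lognormal multiplicative noise
(mean-1, so unbiased on the natural scale) for intensities, densities
and concentrations, and Poisson counts for cytometry events —
conventional instrument models; real data additionally have correlated
drift, plate effects and gating errors that these generators do not
emulate, so passing round-trips demonstrate estimator correctness under
idealized noise, not robustness to instrument systematics.

Default study conditions, chosen once: ancestor exchange ratio 0.10/hr
(release 0.3 fmol/cell/hr, consumption 3 fmol/cell — the consumption
matching a 21 µM feed sustaining 7×10⁶ cells/ml), mutant release
1.6-fold higher; kinetics b_max 0.44/hr, n 2, K 0.2 µM so that a
0.1/hr community-environment growth rate corresponds to ~0.1 µM
residual nutrient and chemostat residual stays below 1% of a 20 µM feed
across 4–8 hr doubling times (the regime where the exchange-ratio
identity is exact). Chemostats run 120 hr sampled every 2 hr from an
inoculum near steady state; communities 72 hr sampled every 8 hr (the
periodic-cytometry cadence — at much denser sampling with 10% noise,
adjacent log-slopes become noise-dominated and regime selection
degenerates); microscopy series image every 2 hr for 24 hr with a 2 hr
lag, defaulting to growth at the saturated rate. Every generator is
deterministic given its seed and emits a flat truth sidecar.

## Problem sizes

Simulations and recovery experiments are sized for desk-scale runs:
100 random phenotype pairs for the eigen oracle, 6-configuration
community sweep, 3 chemostat dilution rates, 20 seeds per estimator
recovery, 1000 simulated null datasets for t-test calibration and CI
coverage. The full suite completes in a few seconds.

## Limitations

Spatially structured growth is approximated as a well-mixed closed
patch; evolutionary dynamics (mutation supply, repeated sweeps) and
intracellular metabolism are out of scope. Death is a single
first-order rate with no starvation dependence. The steady-state theory
assumes both pools remain supply-limited; communities whose kinetic K
values are large relative to accumulating pools grow faster than the
geometric-mean rate until saturation, and the convergence tests
restrict to the supply-limited regime.
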