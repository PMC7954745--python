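# Methods

## Process model

`refoldctl` models dilution refolding of solubilized inclusion-body
protein as a competition between first-order folding and higher-order
off-pathway aggregation.  In a closed (batch) vessel the species
balances are

    dc_SL/dt = -(k_r c_SL + k_a c_SL^n)
    dc_NL/dt =  k_r c_SL
    dc_AL/dt =  k_a c_SL^n

with solubilized (S), native (N) and aggregated (A) protein in g/L,
folding rate constant `k_r` [1/h], aggregation coefficient `k_a`
[L^(n-1) g^(1-n)/h] and aggregation order `n` (default 2; `n = 1` is
supported for the low-concentration regime).  The three derivatives sum
to zero, so batch refolding conserves protein mass exactly.

In fed-batch operation, solubilizate is fed at rate `F_R` [L/h] from a
finite reservoir containing solubilized protein at `c_SR` [g/L] and
denaturant at `c_DR` [mol/L].  Volume and denaturant become dynamic
(`dV_L/dt = F_R`, `dc_DL/dt = (F_R/V_L)(c_DR - c_DL)`) and every species
balance gains the dilution term `(F_R/V_L)(c_in - c)`, with `c_in = 0`
for native and aggregated protein (the reservoir holds solubilizate
only).  Both denaturant concentrations are carried in mol/L; the vessel
and reservoir concentrations must share units for the dilution balance
to make sense.

Optionally the rate constants depend on the denaturant concentration
through the power law `k_i = a_i (1 + c_DL)^{b_i}` (i = r, a).  The base
`1 + c_DL` mixes a pure number with a concentration; we interpret
`c_DL` as its numeric value in mol/L (i.e. relative to a 1 mol/L
reference) and document that choice here rather than invent a fourth
parameter.  Physically sensible exponents are negative, with
aggregation suppressed more strongly than folding (`b_a < b_r < 0`).

The total protein concentration is tracked by the cumulative feed
balance `c_PL(t) = (M0 + c_SR V_fed(t)) / V_L(t)` with `M0` the protein
mass initially present.  For a constant feed, an initially empty vessel
and no depletion this reduces to the classical soft-sensor expression
`c_PL = F_R t c_SR / V_L`; the generalization handles piecewise feeds,
non-empty starts and the post-depletion phase uniformly.

## Numerical integration

`simulate` integrates the five-state system (plus cumulative fed volume)
with LSODA at rtol 1e-8 / atol 1e-10 (configurable), piecewise over the
feed-policy breakpoints.  Reservoir depletion is located as a terminal
integrator event (time accuracy well below 1e-6 h) and the run restarts
in batch mode, so phase bookkeeping is exact rather than smoothed; the
run always continues to `t_end` after depletion.  Floating-point
undershoot of concentrations is clamped to zero in reported output only,
never inside the integrator state.  The batch model with `n = 2` has the
closed-form Bernoulli solution

    c_SL(t) = k_r c0 e^{-k_r t} / (k_r + k_a c0 (1 - e^{-k_r t}))
    c_NL(t) = (k_r/k_a) ln(1 + (k_a c0/k_r)(1 - e^{-k_r t}))

which serves as the independent oracle for the integrator (agreement to
better than 1e-6, measured relative to the pointwise magnitude floored
at 0.1% of the load so roundoff on near-zero values is judged on an
absolute basis).

## Key performance indicators

Refolding yield is `c_NL / c_PL`, evaluated against the instantaneous
total protein concentration (an option allows evaluation against the
final/maximal `c_PL` instead); it is undefined (NaN) before the first
feed of an initially empty vessel.  Space-time-yield (STY) is `c_NL / t`
in g/(L h), with STY(0) = 0 — native protein grows as O(t²) from an
empty vessel, so the limit is exact.  Because the end-point STY at a
common end time is dominated by the yield effect, sweeps summarize
productivity as the **mean STY over the fed-batch phase** (trapezoidal
time-average of the instantaneous STY over [0, t_dep]); max yield is
taken over the whole trajectory, since yield keeps rising during the
batch continuation.  The feed-rate sweep (`pareto_sweep`) covers
0.015–10 mL/min (converted to L/h internally, 1 mL/min = 0.06 L/h) with
log spacing by default (linear supported) and refines the output grid
inside short fed-batch phases so the STY average stays accurate for
fast feeds.

## Synthetic measurement generation

The PAT emulator turns a ground-truth trajectory into per-channel sensor
records with a sampling period, a feedback delay (records may only be
consumed once available), additive Gaussian noise with standard
deviation `sd = sd_abs + sd_rel · truth`, and a limit of quantification:
truth below the LOQ yields a censored record carrying the LOQ itself,
and uncensored readings are floored at the LOQ.  Noise streams are keyed
per (seed, channel, sample index), so extending a trajectory does not
reshuffle earlier samples — this keeps incremental emulation inside the
closed loop self-consistent and every pipeline byte-reproducible per
seed.  The named presets (`ftir_native`, `hplc_*`, `dls_aggregate`,
`total_protein`) mimic the character of common refolding analytics —
fast inline FTIR, slow species-resolved RP-HPLC with a 0.01 g/L LOQ,
noisy light-scattering for aggregates; apart from the HPLC LOQ the
numbers are this package's own defaults, not instrument datasheet
values.  What the emulator does **not** model: spectra, drift, fouling,
outliers, correlated noise — conclusions from passing tests therefore
speak to sampling/noise/delay/censoring structure, not to instrument
physics.

## Parameter estimation and model qualification

`fit_parameters` minimizes the weighted residual sum of squares

    WRSS = Σ_q w_q Σ_i (y_obs,qi − y_model,qi)² / σ_q²

over a named subset of {k_r, k_a, a_r, a_a, b_r, b_a} with bounded
trust-region least squares (scipy `least_squares`, optional seeded
multi-start).  Weights default to inverse sensor variance (σ_q from the
generating sensor specs); censored records are excluded by default, or
treated as one-sided residuals at the LOQ on request.  Fit quality is
reported per observed quantity as R² = 1 − SS_res/SS_tot and NRMSE
(RMSE normalized by the observation range; mean/sd normalizations were
considered and rejected as less interpretable for monotone-range
refolding data).  AIC/BIC use the concentrated Gaussian forms
`n ln(WRSS/n) + 2k` and `n ln(WRSS/n) + k ln n`; a zero WRSS is a
degenerate likelihood and reports −inf with a warning.

Identifiability is checked at the optimum: the configuration is flagged
non-identifiable when the smallest singular value of the
relative-scaled Jacobian gives a Gauss–Newton curvature below 1% of the
residual level — an order-one relative parameter change would then move
the WRSS by under 1%.  Observing only total protein trips this flag, as
it must: `c_PL` follows the feed balance alone and carries no kinetic
information.

The model-quality bound (state error below 10–15%) is operationalized
as the worst per-species range-normalized RMSE of the fitted model's
state trajectories against the noise-free truth (`state_error`).  At 5%
relative measurement noise with 50 observation times and three observed
species, 20-replicate studies give a median state NRMSE near 1% and a
maximum near 3%.

## State observation

The observer ("digital twin") reconstructs (V_L, c_DL, c_SL, c_NL,
c_AL) by recursive Bayesian filtering against the fed-batch model.  The
default filter is an unscented Kalman filter (Merwe scaled sigma points,
α = 0.5, β = 2, κ = 0) — no Jacobians of the kinetics are needed and the
sigma-point transform is exact for linear systems, which is how the
implementation is validated against the closed-form scalar Kalman
recursion.  An extended Kalman filter with central finite-difference
Jacobians is provided as the alternative family; particle filtering is
out of scope.  Process noise is a per-state diagonal intensity (variance
per hour); measurement variances come from the sensor specs, floored at
(1e-6 g/L)² so a nominally noise-free channel cannot produce
near-singular innovation covariances that would amplify integrator-level
model/measurement mismatch into unmeasured states.  Covariances are
re-symmetrized after every update and jittered back to numerical
positive semidefiniteness if an eigenvalue dips below −1e-10; repeated
failure raises an observer-divergence error.  Posterior means are
clipped at zero concentration (covariance untouched).

Delayed measurements are assimilated by re-filtering: the filter stores
its estimate at every update time within the longest sensor delay; when
a delayed record becomes available it rewinds to the stored estimate at
the record's sample time, applies the update there, and replays every
later measurement and prediction up to the present.  There is no
published observer tuning for protein refolding; all defaults here are
this package's own.

## Model predictive control

The controller optimizes a piecewise-constant feed sequence over a
finite horizon (default 10 steps of 0.1 h) against the quadratic
tracking cost

    J = Σ_k [ w_Y (Y_ref − Y_k)² + w_STY (STY_ref − STY_k)² ]

with the KPIs predicted by the internal model initialized at the
observer mean (certainty equivalence), STY evaluated in global process
time, and both references treated as running targets (a terminal-only
yield option exists).  Constraints: pump bounds F_min ≤ F ≤ F_max, slew
limit |ΔF| ≤ dF_max per step, predicted volume V_L ≤ V_max (linear in
the feeds before depletion), and reservoir non-negativity (feeds are cut
at depletion inside every prediction).  The solver is SLSQP with
multi-start from the shifted previous solution and both feed bounds;
an exhaustive grid solver (`mpc_step_grid`) over discrete feed levels is
shipped as the optimization oracle.  Only the first move is applied
(receding horizon); the closed loop re-emulates newly available
measurements, updates the observer and re-solves at every step, and the
plant may run perturbed parameters for plant–model mismatch studies.
The receding-horizon consistency property (successive plans agreeing
step-for-step without disturbances) is exercised on a boundary-optimum
scenario, where it holds exactly; for interior optima a finite shifting
horizon re-weights the tail and exact agreement is not implied.

## Fixture scenarios and problem sizes

Published refolding studies fit rate constants per protein and buffer
system rather than tabulating reusable values, so the registry
scenarios use documented synthetic defaults chosen once:

- `baseline` — denaturant-dependent kinetics (a_r = 2, b_r = −1,
  a_a = 2, b_a = −2), 1 L vessel at 0.5 mol/L residual denaturant, 0.1 L
  reservoir of 40 g/L solubilizate in 6 mol/L denaturant fed at
  0.02 L/h (depletion at 5 h), 10 h horizon.
- `pareto_base` — constant rates k_r = 10/h, k_a = 10 L/(g h): folding
  on a minutes timescale, under which the 0.015–10 mL/min sweep spans
  the full yield/productivity tradeoff and the frontier is monotone.
- estimation/observer/control studies use k_r = 1/h, k_a = 1 L/(g h),
  where the dynamics are resolvable at realistic sampling periods.

Default study sizes — 20 replicates for fit/observer studies, 50
observation times, 20-rate sweeps, 10–20 control steps with horizons
3–10 — keep the full qualification suite and the acceptance script
within a couple of minutes on one CPU while leaving every statistic
well-resolved.

## Known limitations

Single well-mixed vessel; no temperature, pH or redox dependence of the
rate constants; no misfolded-state reaction with disulfide-reshuffling
reversals; no oxidizing-agent or cofactor feeds (extension hooks only);
no joint state+parameter estimation; no stochastic/robust MPC.  The
measurement model is Gaussian and memoryless.  Conclusions about real
processes require re-fitting the kinetic parameters to experimental
data for the protein and buffer system at hand.
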