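# Methods

## Model structure

Systemic disposition after a constant-rate intravenous infusion is
empirical: a two-compartment model (CL, V_C, Q, V_P; all per kg body
weight) for drugs with bi-exponential plasma decline, one compartment
(CL, V_C) otherwise. The three lung regions — trachea, bronchi, alveolar
parenchyma — are *virtual* compartments: they are driven by the plasma
concentration but return no mass to the systemic model. This is valid
because the lung tissue (0.5% of body weight) holds a negligible share of
the drug amount already represented by the systemic volumes. Each region
obeys

    dC_tis/dt = (Q·fu/V)·C_p(t) − k_a·C_tis,   k_a = Q·fu/(V·Kp),

so the tissue is a first-order filter of plasma with equilibrium ratio
Kp. The influx is written as total plasma concentration scaled by the
plasma fraction unbound, i.e. only free drug permeates; the efflux rate
constant k_a is the absorption rate constant whose half-life ln(2)/k_a
measures local retention. Region volumes are fixed anatomically
(trachea 0.0002, bronchi 0.0008, alveolar parenchyma 0.004 kg/kg; whole
lung 0.005 kg/kg) with 1 kg tissue treated as 1 L.

Assumptions worth keeping in mind: perfusion-limited uptake (no
permeability barrier or active transport — known to fail for the acidic
indomethacin in vivo), linear tissue binding, no residual blood
correction, and no between-animal variability (the two-stage analysis
pools animals).

## Closed-form backend and ODE oracle

The whole system is linear and time-invariant, so every curve is a sum of
exponentials. The step (infusion-on-forever) plasma response is computed
from the macro constants (the fast salmeterol macro constant is ~58 1/h);
tissue responses follow by analytic convolution through the first-order
filter, with the resonant case |k_a − λ| → 0 handled by the t·e^(−λt)
limit. The finite infusion is superposition: f(t) − f(t − T_inf). A Radau
integration of the full coupled ODE system is kept as an independent
oracle; tests require < 1e-6 relative agreement on all matrices (observed
~1e-11). Times are hours everywhere; seconds/minutes appear only in
formatted output. Tiny negative values (~1e-17) from floating-point
cancellation at t = 0 are clipped to zero.

## Packaged parameters and derived fraction unbound

The four drug parameter sets and the regional blood flows
(Q_T = 0.054, Q_B = 0.777, Q_A = 10.6 L/h/kg; whole-lung 11.6) are
packaged as a YAML fixture. The plasma fraction unbound is not part of
the printed parameter table, so it is *derived* at load time and the
derivation is recorded in the fixture file:

- salmeterol: from the bronchodilation EC50 anchor — a total-lung EC50 of
  36 nM corresponds to a free EC50 of 0.0271 nM via fu/Kp_B, giving
  fu = 0.0271·18.6/36 = 0.01400;
- fluticasone propionate and indomethacin: by inverting
  t½ = ln2·V·Kp/(Q·fu) against the published tracheal half-life
  (52.4 min → fu = 0.01532; 14 s → fu = 0.23501).

These single-tissue anchors reproduce the published half-lives of the
*other* regions to within ~3% (consistent with 3-significant-figure
rounding of the printed inputs), which is the package's self-consistency
test. For linezolid no fu ≤ 1 reproduces its published half-lives (the
inversion gives ≈ 7.5, physically impossible as a fraction); the fixture
defaults to fu = 1.0 with a logged warning, every linezolid operation
accepts a user-supplied fu, and linezolid is excluded from quantitative
half-life checks.

## Estimation

Two stages, as the study design dictates: plasma data identify the
systemic model; tissue data (4 time points × 3 replicates per region)
then identify Kp per drug and region plus the three blood flows. Flows
are physiological, hence shared across drugs and estimated from the
combined data of all drugs — this sharing is what makes the tracheal flow
(informed by only 12 observations per drug) identifiable.

Numerical choices:

- Residuals on log concentrations (proportional error). The original
  analysis does not state its weighting; concentrations span > 2 orders
  of magnitude and CV%-style reporting implies multiplicative error, so
  log residuals are the natural choice and make the estimator
  median-unbiased under the lognormal simulation error.
- Parameters estimated on the log scale (positivity without constraints);
  Levenberg–Marquardt on the unconstrained problem.
- CV% = 100·SE(estimate)/estimate with SE from the delta method on the
  log-scale covariance s²(JᵀJ)⁻¹, i.e. CV% = 100·SE(log θ).
- Multi-start: 5 restarts, the first from data-driven/literature starting
  values, the rest log-uniform within ±1 decade (seeded); best objective
  wins, ties to the first found. On noise-free data the literature-prior
  start and random starts reach the same optimum (a test asserts this),
  so the simulation–estimation loop uses the single prior-based start.
- Records are internally sorted (time, then value), making estimates
  bit-identical under permutation of input rows.
- Identifiability guard: with tissue observations at fewer than two
  distinct times, Kp and Q trade off exactly; the fit refuses with a
  structural non-identifiability error instead of returning an arbitrary
  point on the ridge.
- Literature starting values for the flows: cardiac output 15.1 L/h/kg
  for the alveolar region; 2.1% of cardiac output for the conducting
  airways, split between trachea and bronchi by tissue weight.

The whole-lung comparator repeats stage 2 with a single lung compartment
(one Kp per drug, one shared flow). Goodness of fit uses
R² = 1 − SSR/SST on observed vs predicted pairs — deliberately allowing
negative values when a model is worse than the mean — plus the fraction
of predictions within two-fold of the observation.

## Derived quantities and human scaling

Absorption half-lives use the fitted parameters directly. Allometric
scaling to human uses fixed exponents — 0.75 for flows, 1 for volumes,
with Kp conserved between species — so after per-kg normalisation every
regional half-life scales by exactly (BW_human/BW_rat)^0.25 ≈ 3.98 for
0.28 → 70 kg. Presentation-layer formatting picks h/min/s by magnitude;
the internal unit is always hours.

Percent-of-steady-state summaries form the replicate-level ratio
100·(C_tis/C_p)/Kp at each tissue time and report mean ± SD. Note a
subtlety the package's tests respect: after the infusion stops, plasma
falls faster than a slow tissue, so the simulated ratio *overshoots* 100%
(this is the same physics that makes the late-time plasma EC50 biased
low). The "slow regions have not yet reached steady state" pattern —
alveolar linezolid/indomethacin ≥ 95% within 15–45 min, salmeterol
trachea still below 100% at 4 h and rising — is therefore demonstrated
under a maintained infusion, where the ratio approaches Kp monotonically
from below.

## PK/PD bias experiment

Effect is linked to the unbound bronchial concentration through a
hyperbolic Emax model (Emax = 100%). The true free EC50 is the
total-tissue EC50 scaled by fu/Kp_B (0.0271 nM for salmeterol). The
dose-escalation procedure simulates unbound plasma and bronchial
concentrations over a dose grid (default 30 doses, six log-decades
centred on the dose giving 50% effect), computes the effect at the chosen
observation time, and regresses effect on unbound *plasma* concentration
with Emax fixed and EC50 free (log-scale least squares). Under linear PK
the resulting estimate equals Kp_B·C_p(t)/C_B(t) exactly, independent of
the grid and the fitting details; the package computes both routes and
tests their agreement (< 1%), as well as invariance under dose-grid
scaling. A grid that does not bracket the half-maximal effect triggers an
extrapolation warning.

## Synthetic data and SSE

The generator emulates the study conditions: 1-h infusion (arbitrary
rate — every reported quantity is dose-invariant), 0.28-kg rats, plasma
sampled every minute during the infusion plus 1.25/1.5/2/3/4 h
(65 samples, emulating the ~67 pooled samples per drug, mostly within the
first hour), and 3 tissue replicates at 0.25/0.75/2/4 h (12 per region
and drug). Residual error is multiplicative lognormal, σ² = ln(1 + CV²),
with defaults 15% (plasma) and 25% (tissue) — the original error
magnitudes are not published, so these are documented assumptions chosen
as typical bioanalytical/homogenate imprecision. No between-animal
variability is simulated; what passing tests show is therefore recovery
of pooled-design parameters under residual noise, not robustness to
inter-individual variability, nonlinear binding, or model misspecification
(e.g. the indomethacin case).

The SSE loop simulates n datasets, refits the tissue stage with systemic
parameters fixed at truth, and reports per-parameter median relative bias,
empirical CV, and the convergence rate (failures are counted, never
raised). Replicates derive their seeds from one SeedSequence, so reports
are bit-identical for a fixed seed. Design comparison ranks candidate
schedules by worst-parameter CV; at 50 replicates the packaged design
keeps median |Kp bias| around 1–3% and shows the expected degradation of
tracheal-flow precision (CV roughly doubles) when the early (< 1 h)
tissue samples are dropped. Problem sizes in the shipped tests — 50 SSE
replicates for the main property check, 12 for the replicate-scaling
check — keep the full suite under about half a minute while leaving the
Monte-Carlo conclusions stable.

## Known limitations

- Perfusion-limited, linear kinetics only: no transporters, no
  permeability barrier, no saturable (lysosomal) binding, no
  inhalation-specific processes (deposition, mucociliary clearance,
  dissolution).
- Absorption half-lives are unidirectional tissue→plasma measures, not
  effective terminal half-lives with redistribution.
- The linezolid fraction unbound is an explicit placeholder (see above).
- Fits are naive pooled least squares; no mixed-effects machinery.
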