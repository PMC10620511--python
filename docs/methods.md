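# Methods

This note records the modeling assumptions, numerical conventions and design
choices behind `combopd`, in the spirit of a model-description appendix.

## Static concentration–response

The single-agent model is the inhibitory Hill function
R(C) = R0·(1 − Imax·C^γ/(IC50^γ + C^γ)). The Hill exponent γ is carried as
a parameter but **fixed at 1 in the default pipeline** and fitted only on
request: the combination analysis uses per-drug exponents fixed from the
single-agent fits, and the published single-agent parameter tables for this
system report none, so unit exponents keep the static single-agent and
combination models mutually consistent. Concentration units are µM
throughout; the CSV reader accepts a `units="nM"` flag and converts at
ingestion.

Fitting is ordinary least squares on % viability (an optional
proportional-error weighting, residual/prediction, is available — the
residual model behind the published estimates is unreported, so this
is a package convention). Initialisation: R0 from the vehicle controls,
Imax from the observed response range, IC50 at the geometric mean of the
nonzero tested concentrations; five multi-starts perturb all free
parameters log-uniformly within a factor 3 (seeded, deterministic).
Parameters are optimised on the log scale, which enforces positivity and
makes the reported %RSE — 100·SE from the asymptotic Gauss–Newton
covariance — a relative standard error directly. A parameter fixed during
fitting is returned unchanged and has **no** RSE entry (absent, never 0).
Non-convergence is reported through the `converged` flag rather than an
exception; all-identical responses raise an estimation error ("no
concentration effect").

## Competitive interaction model and ψ

Joint static effects use the competitive interaction form given in the
README, with ψ multiplying both IC50s inside the potency ratios (a
`psi_on` switch restricts it to one drug for sensitivity analysis). Two
structural conventions matter:

* **ψ engages only where both drugs are dosed.** On the grid margins
  (one concentration zero) the model reduces exactly to the single-agent
  Hill curve for *any* ψ. This keeps single-agent information ψ-free — a
  margin row of a combination dataset refits the true single-agent
  parameters — and mirrors the dynamic model, where the single-agent
  equations are the ψ-free degenerate case. Margins are included in the ψ
  fit by default but carry no ψ information, so they cannot bias it.
* **Surface monotonicity is conditional.** The additive (ψ = 1) surface is
  non-increasing along both axes only when the two Imax are equal; with
  unequal Imax the weaker drug competitively dilutes the stronger one at
  saturating concentrations, so monotonicity is guaranteed only along the
  stronger drug's axis. The tests assert exactly this.

ψ is estimated by least squares with the single-agent parameters fixed.
Classification uses an equivalence band of ±0.05 around 1 ("additive");
the band is a package convention, the underlying point estimate is always
reported. The combination surface takes its baseline from drug A's R0 (the
two single-agent fits may estimate slightly different baselines; the
surface needs one).

## Dynamic cell-kill model

State equations, per drug x ∈ {DOX, DEX}:
K_x = Smax,x·C_x(t)/(SC50,x,eff + C_x(t)); three transit compartments
dK1/dt = (K − K1)/τ etc.; dR/dt = kg·R − (K3_DOX + K3_DEX)·R, R(0) = R0,
transit states 0. SC50,DOX,eff = SC50,DOX·ψ when both drugs are present
(ψ > 1 weakens DOX kill = antagonism), SC50,DEX is unmodified — the
asymmetric placement follows the source model; `psi_on="both"` enables the
symmetric variant for exploration. In vitro forcing is the closed form
C(t) = C0·e^(−k_deg·t) with k_deg fixed (0.022 h⁻¹ DOX, 0.054 h⁻¹ DEX —
literature estimates treated as known constants, never fitted).

Rather than integrating R directly, the solver integrates the transit
chains plus the cumulative kill integral J(t) = ∫(K3_DOX+K3_DEX)dt and
recovers R = R0·exp(kg·t − J). This is exact, keeps viability strictly
positive (down to float64 underflow at ~1e−308 for extreme kill inputs),
and removes R's scale from the error control. Integration uses LSODA with
rtol 1e−9 / atol 1e−12 for simulation (1e−8/1e−10 inside fitting loops);
golden-trajectory tests pin the solution against an independent fixed-step
RK4 oracle (dt = 0.01 h) to ≤0.1%, and a τ→0 scenario checks convergence
to the no-delay model. External concentration profiles (for translation)
are interpolated linearly, are 0 before their first time point, must cover
the simulation grid, and the solver's maximum step is capped at 1% of the
horizon so infusion kinks are not stepped over.

## Estimation of the dynamic model

The original population (SAEM) estimation is replaced by **naive-pooled
nonlinear least squares**: all arms share one parameter vector and every
record contributes one residual. Staged fitting mirrors the source
workflow: `single_agents` (control + margins; frees kg, Smax, SC50, τ per
dosed drug, ψ fixed at 1), `combination` (combination arms; everything
fixed except ψ), `all` (every arm, all of the above free). R0 is fixed at
100% by default (viability is normalised to control). kg free without a
control arm, or transit times without post-baseline observations, raise
estimation errors. Multi-start, log-scale optimisation and %RSE as above.
`profile_objective` re-optimises the remaining free parameters over a grid
of one parameter as an identifiability diagnostic.

Self-consistency — generate noise-free data from known parameters, refit,
recover them — is the package's central validation loop and is exercised
for the static ψ (recovering 1.11/0.84 on the published single-agent
estimates), the dynamic ψ (recovering 2 on the published JIMT-1 cell-kill
estimates) and the full parameter vector (≤1% from a perturbed start). The
full-vector test uses a reduced arm set (control + 3 DOX + 3 DEX + 9
combinations, five time points, one optimizer start) — a desk-scale design
chosen to keep the recovery loop fast while leaving every parameter
identifiable.

## Synthetic data

The generator reproduces the study design: DOX grid
{0.005, 0.01, 0.05, 0.1, 0.5, 1} µM and DEX grid
{6.25, 12.5, 25, 50, 100, 200} µM (the printed ranges with conventional
half-log/two-fold ladders; the exact intermediate levels are not published),
their 36 combinations, margins and a vehicle control; static endpoints at
72 h or time courses at {0, 24, 48, 72, 96} h (observation times are not
published either; this default is configurable); ≥3 replicates. Noise is
multiplicative lognormal with σ = √ln(1+CV²) so the sample CV equals the
nominal CV (viability readouts are positive and roughly
constant-CV); additive Gaussian is available by flag. Default CV 10%.

What the generator does *not* emulate: plate-layout/edge effects,
absorbance-to-viability calibration error, replicate correlation, or any
model misspecification — passing recovery tests therefore demonstrates
estimator correctness under the assumed model, not robustness on real
assay data.

## Clinical translation

PK models are linear mammillary systems (3-compartment DOX, 2-compartment
DEX) parameterised per m² BSA and solved **exactly** segment-by-segment via
the eigendecomposition of the rate matrix, so superposition and
dose-proportionality hold to machine precision. Dose events are zero-order
infusions (duration 0 = bolus). mg→µM conversion uses MW 543.5 (DOX) and
268.3 (DEX) g/mol with the central volume.

The original study's PK parameter values are not published (they derive
from earlier literature), so the shipped defaults in
`combopd.reference` are **synthetic**, constructed once for clinical
plausibility: DOX triphasic with V1 = 14 L/m², CL = 30 L/h/m², large
peripheral volume (terminal half-life ≈ 30 h); DEX biphasic with
V1 = 11 L/m², CL = 7.9 L/h/m² (half-life a few hours). Consequently all
translation-level conclusions asserted by the tests are qualitative
(orderings, equalities, convergence), never numeric AUEC values. The
regimen default is three Q3W cycles of DOX 50 mg/m² over 0.5 h, preceded
each cycle by DEX 500 mg/m² over 0.25 h finishing 0.5 h before DOX
(relative timing and durations are unreported; clinical convention gives
the cardioprotectant first — both are configurable).

Tumor scaling: Fac₁ = 57.1 for DOX (published AUC ratio), Fac₂ scenario
values {0.1, 1, 10} for DEX. Population simulation draws per-subject
lognormal multipliers (median-preserving, CV default 10% — the
distributional form is a package choice; the source states only "10% IIV")
on all PD parameters plus Fac₁ and Fac₂; PK is common across subjects.
AUEC uses the linear trapezoid on an hourly grid over the full horizon
(1512 h). AUEC is exponentially sensitive to the PD parameters (a 1%
parameter CV produces roughly 10% AUEC spread over a cycle), so the
population tests assert the convergence of the median to the deterministic
value as IIV → 0, not a fixed percentage band at finite IIV.

Under the default (synthetic-PK) conditions the scenario table reproduces
the study's qualitative picture: with antagonistic JIMT-1 parameters
(ψ = 2) every DOX+DEX arm scores a higher AUEC (less killing) than DOX
alone for all Fac₂; with additive MDA-MB-468 parameters the arms are
comparable (within 2-fold — DOX alone already drives viability to
negligible levels, so the DEX contribution barely moves the integral); and
the Fac₂ choice shifts the combination AUEC far less than the
combination-vs-DOX-alone contrast. The published absolute AUEC fold-change
(~1560-fold for JIMT-1) depends on the unpublished PK parameterisation and
is deliberately not a target.

## Known limitations

* Naive-pooled estimation understates uncertainty relative to a
  mixed-effects analysis; %RSE values are asymptotic and conditional on
  the residual model.
* The Hill exponent is not identifiable from the default 6-point designs
  with noise at realistic levels; fixing γ = 1 is a modeling commitment.
* ψ is a single global interaction descriptor; concentration-dependent
  interaction patterns visible in surface residuals are not parameterised.
* The translation layer inherits the synthetic PK defaults; absolute AUEC
  magnitudes should not be interpreted until real PK parameters are
  supplied.
* Exponential growth is unbounded (no carrying capacity), which is
  adequate for ≤96 h assays but inflates long-horizon control trajectories
  in the clinical simulations; AUEC comparisons between arms share this
  growth term and remain internally consistent.
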