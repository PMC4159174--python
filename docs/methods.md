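# Methods

## The model

`senesim` implements a mass-action reaction network for the establishment of
irradiation-induced cellular senescence in human fibroblasts. The network has
23 state variables in five modules — DNA-damage response, oxidative stress,
FoxO3a signalling, insulin/IIS–mTOR signalling, and mitochondria — linked by
41 irreversible mass-action reactions. Every reaction rate is
`k · Π(reactant amounts) · Π(modifier amounts)`; modifiers enter the rate
multiplicatively without being consumed. Two reactions are second order in a
single modifier (cooperative CDKN1A induction by DNA damage, and ROS
amplification by the old mitochondrial pool); everything else is first order
in each factor. Time is measured in days and all amounts are in arbitrary
units, consistent with western-blot-normalised readouts.

Three external inputs drive the system: insulin and amino acids (constant),
and an irradiation impulse at time zero lasting five minutes (5/1440 days)
whose amplitude encodes the 20 Gy X-ray dose. The amplitude is a model
parameter, not a physical dose conversion. The integrator is restarted at the
pulse edges so the discontinuity is not smeared.

Four activation/inactivation pairs — Akt, mTORC1, AMPK and IKK-β — have no
synthesis or degradation, so their pool totals are conserved and the system
is effectively 19-dimensional. Phosphorylated and unphosphorylated states of
the IIS–mTOR pathway start with equal amounts (cells are not starved before
irradiation); the stress-response species start at a low but non-zero basal
level; the old mitochondrial pools start empty.

The mitochondrial module splits the population into a "new" pool (created by
biogenesis, high membrane potential) and an "old" pool (created by
CDKN1A-dependent deterioration of new mitochondria, low membrane potential).
Mitophagy removes each pool with its own rate constant, constrained so that
clearance of old mitochondria is slower than clearance of new ones
(`k36 < k35`), the network's abstraction of the fission requirement for
mitophagy. Membrane potential of the new pool is generated in proportion to
new mass and lost through a basal leak plus a ROS-driven depolarisation term;
old mitochondria inherit a residual potential at the moment of conversion and
do not regenerate it.

Fourteen observables (positive scale factor times a sum of species amounts)
link the model to data: the phospho-readouts Akt-pS473, mTOR-pS2448,
AMPK-pT172, JNK-pT183 and FoxO3a-pS253; total FoxO3a (nuclear + cytoplasmic);
CDKN1A; CDKN1B; DNA damage; ROS; SA-β-gal; mitophagy; total mitochondrial
mass (new + old); and total membrane potential (new + old).

## Reconstruction and calibration

The network topology is reconstructed from its published description (module
membership, named rate constants, the assumed-a-priori IKK-β kinetics, the
conserved pools, the two-pool mitochondrial abstraction, the mitophagy
constraint). The deposited machine-readable model and the original in vitro
data tables are separate supplementary artifacts that do not ship with this
package, so the rate constants here are the package's own calibration: basal
values are fixed exactly by stationarity of the pre-irradiation state, and
the remaining gains were chosen so the irradiated trajectory reproduces the
reported qualitative course —

- DNA damage spikes within hours and relaxes to a ROS-sustained plateau;
- CDKN1A rises quickly, sags, then climbs again as oxidative stress builds;
- mTOR-pS2448 rises to a peak near day 8 and declines as AMPK activates;
- new mitochondrial mass and membrane potential fall from about day 2-5 while
  old mass accumulates, so total mass rises (~1.8x by day 21) as total
  membrane potential falls (~0.2x);
- energy falls with the new-pool potential, activating AMPK late, which
  together with stress-driven nuclear FoxO3a raises mitophagy after day 7;
- ROS, JNK and SA-β-gal rise progressively; total FoxO3a stays near-constant.

Two design choices deserve emphasis. First, the senescent transition is
driven by a positive feedback loop (old mitochondria → ROS → DNA damage →
CDKN1A → conversion of new to old mitochondria). To give this loop a large
dynamic range without destabilising the unirradiated control, the two
couplings named above are second order; the basal conversion flux is then
small enough that the control drifts by <4% over 21 days. The price of this
choice appears beyond the observation window: the loop keeps compounding
after day 21, so the reconstruction's late state is still slowly evolving
rather than sitting at an attracting fixed point (see Lyapunov stability
below). Second, FoxO3a
synthesis is constitutive in this reconstruction; its stress-responsiveness
enters through JNK-driven nuclear import. A damage-modulated synthesis term
would force the total FoxO3a pool to track the ~15-fold damage range, which
contradicts the observed stability of total FoxO3a.

## Simulation

Deterministic runs use an LSODA-class adaptive stiff/non-stiff integrator
(relative tolerance 1e-6, absolute tolerance 1e-12) reporting on a uniform
grid (21 days, interval 0.02 by default → 1051 rows). States are clipped at
zero for reporting only; solver failures are surfaced.

Stochastic runs use the exact direct-method SSA. Amounts are converted to
particle counts with a system-size parameter Ω (particles per a.u., default
1000): initial counts are `round(x·Ω)` and a propensity with `s` species
factors is rescaled by `Ω^(1-s)`, the standard density-preserving
convention (no physical volume is specified for the system). Run `r` of an ensemble uses
an independent seed derived from `(seed, r, segment)`, so ensembles are
reproducible and embarrassingly parallel. A zero total propensity ends the
run at the absorbing state without error. The inner loop is JIT-compiled
(numba) with a pure-python fallback.

## Interventions

Conserved-pool targets (mTORC1; mTORC1+Akt for a Torin-like exposure; AMPK)
are perturbed by scaling the initial amounts of both activation states by
`1-level` (inhibition) or `1+level` (over-activation); with no turnover this
fixes the pool for the whole course. Turned-over targets (ROS, FoxO3a,
Mitophagy) are perturbed throughout the time course by a dummy modulator
species entering a mass-action sink (inhibitor) or source (activator) on the
target. The modulator's rate constant is a gauge fixed at 1/day — only the
product with the amount matters — and the amount is calibrated by bisection
so that the day-1-to-21 average of the target reaches the requested fraction
of its control average (10% for full inhibition; 250% or 150% for
over-activation, both exposed as plain arguments since the published
descriptions disagree). Monotonicity of the achieved ratio in the amount is
asserted during the search. Dose–response scans rerun the simulation per
level (level 0 reproduces the control bit-for-bit); 2D scans calibrate each
axis against the unperturbed control and combine. Default test grids are
coarse (7-10 points per axis); fine steps reproduce figure-quality surfaces.

In this reconstruction, graded ROS inhibition raises total membrane potential
from day 3 on (by suppressing both the ROS depolarisation term and the
damage→CDKN1A→conversion flux), and mTOR inhibition lowers total mass at all
levels; mild AMPK over-activation lowers the old-pool burden while keeping
membrane potential near control. A known limitation: the reconstruction does
not reproduce a super-additive membrane-potential gain of combined ROS+mTOR
inhibition over the single treatments — with membrane-potential generation
strictly proportional to new mass, the biogenesis cost of mTOR inhibition
outweighs its ROS-mediated protection at high ROS inhibition. The combined
treatment does outperform mTOR inhibition alone and tracks ROS inhibition
closely.

## Sensitivity analysis

Scaled local sensitivities `s_ij(t) = (∂x_i/∂k_j)·(k_j/x_i)` are computed by
central finite differences with relative step δ = 1e-3 on each rate constant;
entries for species amounts below 1e-9 are reported as zero, and a perturbed
run that fails flags its column rather than silently zeroing it. Matrices are
normalised per matrix (not per row) by the largest absolute raw entry, sign
preserved; the per-matrix choice keeps time points comparable on a common
scale. Time-averaged matrices average the raw values over the uniform
reporting grid in the window before normalising. A forward
variational-equation integrator (exact sensitivity ODEs assembled
symbolically) serves as the oracle for the finite differences on small
models, and halving δ changes entries by <1e-3 relative.

## Lyapunov stability

The spectrum is computed for the conservation-reduced system (one species per
conserved pool eliminated algebraically). Tangent vectors are propagated with
the matrix exponential of the analytic reduced Jacobian (symbolically
derived) frozen at the midpoint of each orthonormalisation interval, then
re-orthonormalised by QR; exponents are time-averaged log stretch factors
accumulated after the transient (defaults: 19 exponents, averaging after
t = 21, overall time 50, orthonormalisation interval 1e-4). The average
divergence integrates the Jacobian trace over the same window; the sum of the
exponents must and does agree with it. Exponents are reported sorted
descending; comparisons with external tables should be by multiset since
orderings differ between tools. On the calibrated network an
orthonormalisation interval of 1e-3 already gives sum/divergence agreement to
well under 1%; analyses use 1e-3 to keep runs at desk scale, and the 1e-4
default remains available.

On this reconstruction the spectrum over the stated window (averaging from
day 21 to day 50) contains two weakly positive exponents (~+0.39 and +0.13
per day): the cooperative stress loop is still accelerating along its
old-pool-accumulation direction inside the window, so the senescent state is
not yet an attracting fixed point here. Calibration variants that force an
equilibrium inside the window were explored — a linear ROS coupling, a
flux-limited coupling through the old pool's residual membrane potential,
and a larger mitophagy rate for old mitochondria — and each either
reintroduced drift in the unirradiated control, collapsed the 21-day
senescence phenotype, or made k36 visibly influential in the rate-factor
sweeps, contradicting its observed null effect. The stability property
therefore depends on the original fitted kinetics, which this package does
not contain; what the package verifies is the machinery (exact agreement
with eigenvalues on linear systems, spectrum-sum versus divergence
consistency on every system tested).

## Calibration and identifiability

The objective is the weighted residual sum of squares between observed means
and simulated observables under a 10% relative error model (σ = 0.1·|mean|,
floored at 1e-6), plus a λ-weighted hinge penalty for the `k36 < k35`
constraint (λ = 100 by default; the constraint can also be enforced as a hard
bound). Fits run in log10 parameter space within [1e-6, 1e4] using a
trust-region reflective least-squares solver (function/step tolerances 1e-6,
at most 150 function evaluations per local fit). Multistart sequences restart
from the current best fit randomised with a log10 disturbance of 0.4
(defaults 40 sequences × 500 fits; tests and analyses run a configurable
desk-scale version of the same protocol). AIC is reported as
`χ² + 2·n_free`, with the convention recorded in output metadata.

Identifiability uses a correlation/variation proxy on the best 30% of the
ensemble: pairwise Pearson correlations of log10 parameters define tuples of
related parameters (connected components at |CC| > 0.9), and a parameter is
flagged non-identifiable when its tuple correlation exceeds 0.9 and its
coefficient of variation exceeds 0.25. This reproduces the thresholds that
drive the published decisions without the full mean-optimal-transformation
machinery, which is out of scope. The iterative fix-and-refit schedule is
expressed as a config-driven list of freeze/refit rounds rather than being
hard-coded.

## Synthetic data

The generator simulates the model at known parameters on the default sampling
grid (days 0, 1, 2, 3, 5, 7, 10, 14, 17, 21), draws five replicates per
observable and time point with multiplicative Gaussian noise of fraction 0.10
(matching the fitting error model; an additive floor is available for
near-zero signals), truncates at zero, and records mean/sd/n in the same
tab-delimited layout the calibration reader consumes. Everything is
reproducible from the seed. What passing recovery tests show is that the
estimation machinery is correct and well-conditioned for this noise model;
they do not certify the error structure of real densitometry or imaging data
(within- vs between-day variance is not modelled, noise is single-level).

## Numerical and scale choices

Problem sizes in the shipped tests and analyses are chosen for a single CPU:
scan grids of 3-10 levels, stochastic ensembles of 100-200 runs at Ω = 1e3-1e4,
multistart ensembles of tens of fits, Lyapunov orthonormalisation at 1e-3.
Each is the full algorithm at reduced scale, and every scale knob is an
explicit argument. Degenerate inputs are defined: level-0 perturbations are
exact control copies, a desired modulator ratio of 1 returns amount 0,
all-zero sensitivity matrices stay all-zero under normalisation, and SSA runs
that hit an absorbing state simply hold their final counts.

## Known limitations

- The rate constants are a reconstruction-specific calibration; quantities
  that depend on the original fitted values (the printed Lyapunov magnitudes
  and signs, the printed χ² against the in vitro data set) are not
  reproduced. The spectrum machinery's internal consistency (sum ≈
  divergence; linear-system oracles) is verified instead, and the late state
  of this calibration retains two weakly positive exponents (see Lyapunov
  stability).
- The ROS+mTOR membrane-potential synergy is not reproduced (see
  Interventions above).
- mTOR-pS2448's transient rise is shallower than the measured one; its shape
  (peak near day 8, later decline) is correct.
- No delay terms, spatial effects, inflammatory (NF-κB/TNF-α) module, or
  explicit fusion/fission mechanics; the two-pool abstraction stands in for
  mitochondrial quality control.
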