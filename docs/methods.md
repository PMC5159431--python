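# Methods

## Model structure

The disposition model is a closed circulatory loop: venous blood → lung →
arterial blood → eleven parallel tissue beds → venous blood. Gut and
spleen return through the liver (portal inflow); the liver row of the
physiological table is therefore interpreted as the *total* liver outflow,
and the hepatic-artery flow used in the liver equation is
`Q_hep = Q_liver,total − Q_gut − Q_spleen`. This is the only reading under
which the tabulated regional flows of mouse, monkey, dog and human close
the mass balance against cardiac output exactly; the rat column under-sums
cardiac output by ~1%, which we flag in `check_flow_balance` but do not
repair.

Arterial drug leaves the arterial pool at the *sum of the tissue draws*
rather than at the nominal cardiac output. For the built-in tables the two
are identical (up to the rat rounding above); the distinction matters only
when a perturbation scales individual flows without rebalancing cardiac
output — writing the equation with the nominal cardiac output would then
create or destroy drug in the arterial pool and can even invert the
direction of the clearance response to a liver blood-flow change.

All tissues are perfusion-rate limited except the brain. A
perfusion-limited brain over-predicts brain exposure for DPT (restricted
blood–brain-barrier penetration), so the brain is split into a vascular
sub-compartment in flow contact with arterial blood and an extravascular
sub-compartment behind a permeability–surface-area product `PS`. The
tables give no vascular/extravascular split; we assign 3% of the brain
volume to the vascular space (a typical cerebral vascular fraction).
Plasma pharmacokinetics are insensitive to this split; the brain
*steady-state flux* is too, and the large-`PS` limit recovers the
perfusion-limited solution up to a residual of order the vascular fraction
times `(1 − 1/K_bra:pl)` — the convergence test therefore uses a small
vascular fraction. The tissue observable for homogenate comparisons is the
volume-weighted total brain concentration.

## Units, parameters, elimination

State variables are µg/mL, volumes mL, flows mL/min. Human table entries
(printed in L, L/min) are converted on load. The blood-to-plasma ratio is
fixed at 1, so plasma ≡ venous blood. The metabolism driving concentration
`S = f_up·C_liv/K_liv:pl` is converted to µM with the DPT molar mass
398.4 g/mol (C22H22O7); the summed microsomal velocity (M2:
one Michaelis–Menten enzyme, two for monkey and dog; M7: Hill, with
Vmax in pmol/min/mg converted to nmol) is scaled to a whole-liver µg/min
rate with `PBSF` and the molar mass.

Partition coefficients for non-rat species are generated from the rat
column by the invariance of the unbound partition coefficient
`K_t:pl/f_up`; the gut value is fixed at 1.00 in rat and scaled the same
way. The rest-of-body compartment is an ordinary perfusion-limited tissue
with its own (tiny) partition coefficient. LogP (2.68) and neutrality are
stored as metadata only.

Dosing is an instantaneous intravenous bolus into the venous pool
(`C_ven(0) = D/V_ven`); no infusion duration is modelled. Integration uses
LSODA with rtol 1e-8 / atol 1e-10 µg/mL by default (configurable); these
tolerances keep all outputs non-negative and conserve mass to <0.1% over
the no-elimination horizon of the test suite.

## Non-compartmental analysis

Plain linear trapezoid (switchable in principle, log-down deliberately not
implemented), terminal slope by best adjusted-R² over trailing log-linear
windows of ≥3 positive points that start after C_max (C_max is admitted
only when fewer than three points follow it), ties resolved toward more
points. `AUC_0-∞ = AUC_0-tn + C_last/λz`; MRT uses the standard AUMC tail
corrections; `CL = D/AUC_0-∞`, `Vss = CL·MRT`, `t½ = ln2/λz`.

For a bolus profile whose first sample is after the dose, the profile is
extended back to t = 0 with a log-linearly back-extrapolated C0 (first
observed value if the profile starts rising) before areas are computed —
the standard i.v.-bolus convention of mainstream NCA software, on by
default (`bolus_c0=False` disables it). This choice is load-bearing:
without the C0 strip the sparse study schedules miss the early
distribution phase and every AUC is biased low by ~20%.

Predicted-parameter tables are evaluated on the species' published
sampling schedules; the rat and human schedules were not published and
reuse the monkey grid (2–240 min), flagged as `schedule_surrogate` in the
report.

## In vitro kinetics

Unweighted nonlinear least squares on untransformed velocities (the paper
gives no weighting scheme), parameters log-transformed for positivity,
with a deterministic log-spaced multi-start (default 10 starts) and
best-RSS selection; standard errors by the Gauss–Newton approximation and
the delta method. Replicates enter as individual points. Model choice
between Michaelis–Menten and Hill is the user's (an AICc helper is
provided); the Eadie–Hofstee transform is the diagnostic — linear with
slope −Km for hyperbolic kinetics, non-monotone ("hooked") for γ > 1. The
Hill curve is evaluated as a logistic in log-concentration, which is exact
and stays finite for the extreme exponents an optimizer may visit.

## Population simulation and VPC

Virtual subjects draw exponential random effects on the total liver inflow
(hepatic artery, gut, spleen scaled jointly — elimination depends only on
liver inflow; cardiac output is not rebalanced) and on all metabolic
maximum velocities jointly; observations add an arithmetic multiplicative
residual `(1+ε)` truncated at zero. The inter-individual variances behind
the original population analysis were never published; the defaults
ω_Q = 0.2, ω_Vmax = 0.3, σ = 0.15 are this package's choice of a realistic
pharmacokinetic spread and are *not* estimated values — VPC reproduction
is qualitative by construction. Percentile bands are the empirical
5/50/95th percentiles across all simulated observations per time point.
The variance-estimation step (FOCE-type nonlinear mixed-effects fitting)
is out of scope; variances are user inputs.

## Sensitivity analysis

One-at-a-time multiplicative perturbations of the human model (metabolic
velocity ×10/×0.1, liver blood flow ×2/×0.5, adipose volume and plasma
unbound fraction ×3/÷3), each simulated and NCA'd identically to the
control on the 0–240 min schedule. Two interpretation choices matter:

* the unbound-fraction perturbation rescales every partition coefficient
  in proportion (the unbound partition coefficient is held invariant) as
  well as the metabolism driving concentration — with partition
  coefficients fixed, Vss would barely respond, contradicting the large
  reported Vss effect;
* the adipose perturbation resizes the organ at constant perfusion (blood
  flow scales with volume). A volume-only change leaves the early uptake
  rate `Q·C_art` untouched and, because adipose turnover
  (`V·K/Q ≈ 1000 min`) far exceeds the 240 min observation window, shows
  almost no effect — and even shortens the apparent half-life. Constant-
  perfusion resizing reproduces the reported directions and approximate
  magnitudes of the AUC, Vss and t½ responses.

## Allometry and Dedrick extrapolation

Power laws are fitted by unweighted OLS on log10/log10 scale, one point
per dose group with absolute parameters (per-kg value × body weight) and
mean study weights (mouse 0.02, rat 0.25, monkey 3.51 kg); the dog is
excluded from scaling — its clearance and Vss fall far below the
allometric trend because of its very low metabolic velocity and extreme
protein binding. The Dedrick construction divides time by `W^(β1−β2)` and
concentration by `D/W^β1`; the pooled curve is fitted to a biexponential
by least squares with curve-stripping initial values and a deterministic
multi-start, phases ordered fast-before-slow, and effectively
mono-exponential input flagged degenerate rather than rejected. Closed
forms convert macro-constants to AUC, CL, MRT, Vss and terminal half-life.

## Synthetic data

The raw animal concentration records are unpublished, so fixtures are
regenerated: virtual studies from the population simulator over the
published sampling schedules and dose groups (serial design for rat,
monkey, dog; destructive design for mouse — six animals sacrificed per
time point), with default noise cv of 10% in vivo and 5% in vitro (package
choices, not reported values); microsomal rate tables over the assayed
substrate range 0.0785–3.77 µM in triplicate. Consequently the
synthetic-data tests demonstrate *self-consistency* (the estimators
recover the generator's truth; fold-errors collapse as noise vanishes) —
they cannot re-verify the original in vivo observations, whose summary
statistics are embedded as fixed constants for comparison instead. The
generator does not emulate LC–MS/MS calibration error structure or
quantification-limit censoring beyond a simple threshold.

## Problem sizes and numerical choices

The acceptance computations use the published sampling schedules (11–14
points) and run in about one second; property checks in the test suite use
dense grids of 0.5–2 min steps over 240–2000 min horizons, 40–200
replicate synthetic datasets for estimator-bias studies, and populations
of 30–120 virtual subjects for VPC convergence — sizes at which the
Monte-Carlo error is comfortably below the asserted tolerances. Scalar PS
estimation is bounded log-scale golden-section; all fits are deterministic
given a seed.

## Known limitations

Only intravenous bolus dosing; metabolite disposition, urinary/biliary
excretion of parent drug and binding kinetics are not modelled (elimination
is entirely via M2+M7 formation, as the microsomal mass balance supports).
The early (<2 min) profile depends on the venous-bolus assumption. The rat
in-silico partition coefficients are inputs, not re-derived from tissue
composition. Human predictions are unvalidated extrapolations — there are
no clinical observations to score them against.
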