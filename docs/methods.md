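# Methods

## Rate laws

The core quantity is the steady-state velocity v (uM/s) of an acyltransfer
reaction with a covalent acyl-enzyme intermediate. For donor concentration
A (acyl-CoA, uM), acceptor concentration B (holo-ACP, uM) and total enzyme
E0 (uM), the ping-pong bi-bi law is

    v = kcat E0 A B / (A Km_ACP + B Km_XCoA + A B)

and the cooperative (Hill) variant, motivated by a dimeric enzyme whose two
active sites are conformationally coupled, is

    v = kcat E0 A^hA B^hB / (A^hA K'_ACP + B^hB K'_XCoA + A^hA B^hB)

Both laws are zero when either substrate is absent, strictly increasing in
each substrate, and bounded above by kcat*E0. At the "all denominator terms
equal" point (A = Km_XCoA, B = Km_ACP; or A^h = K'_XCoA, B^h = K'_ACP) the
velocity is exactly kcat*E0/3 — a useful hand-check exercised in the tests.
Setting hA = hB = 1 recovers the ping-pong law exactly, which makes the two
models nested and allows an extra-sum-of-squares F-test.

Units are fixed package-wide: concentrations uM, time s, velocities uM/s,
kcat 1/s, specificity constants 1/(M s). The Hill constants K' carry units
of uM^h; because that unit is awkward and h-dependent, the effective
half-saturation concentration K'^(1/h) (uM) is always derived and reported
alongside, and it is the value to use in kcat/K' specificity constants.
Both the shared-exponent form (one h for both substrates, the default, as
in the printed law) and a per-substrate form (hA, hB) are supported;
neither is asserted to be the original analysis' choice.

At fixed acceptor B the Hill law factors exactly into an apparent
single-substrate Hill form with kcat_app = kcat B^h/(B^h + K'_ACP) and
K_app = K'_XCoA B^h/(B^h + K'_ACP); this identity (exact to machine
precision) backs per-series plotting and cross-checks of the global fit.

## Synthetic assay

No raw velocity dataset is publicly deposited for this system, so the
package generates its own data with the statistical structure the analysis
assumes, and the generator is first-class, tested code.

* **Designs.** The default titration grid is 12 log-spaced donor levels
  spanning 0.1-700 uM crossed with 6 (octanoyl-CoA) or 5 (myristoyl-CoA)
  log-spaced acceptor levels spanning 5-160 uM, at E0 = 0.2 uM and one
  replicate per condition — the published study design. Log spacing is our
  choice (only ranges and counts are published); it concentrates points
  where saturating curves bend. The single-substrate design emits the eight
  published multiples of a Km estimate (0.2x ... 5x).
* **Velocity noise.** v_obs = v_true (1 + eps), eps ~ N(0, cv^2),
  independent across wells, default cv = 3%. That magnitude reproduces fit
  scatter comparable to the published standard errors (about 12% on the
  donor K'). Negative observed velocities are possible and deliberately
  retained; the fitting stage must tolerate them.
* **Progress curves.** Each sample well reads background + intercept +
  slope * NADH(t) + N(0, read_sd) on a shared schedule (default 10 s
  interval, 300 s, within the instrument's 5-22 s range). NADH(t) is
  v_obs*t in linear mode; the optional depletion mode uses
  P(t) = A0 (1 - exp(-v_obs t / A0)), the closed form for a first-order
  consumed donor pool, whose initial slope is exactly v_obs. The coupling
  enzyme is treated as instantaneous (no lag): the assay is validated to
  operate in its linear regime, so depletion curvature is the only
  nonlinearity modelled. Stoichiometry is 1:1 — one NADH per transferred
  (or hydrolyzed) acyl group.
* **Plate context.** Background wells carry background + read noise only;
  standard wells hold fixed NADH concentrations (default 0-8 uM); no-ACP
  control wells progress at the acceptor-independent hydrolysis velocity
  (default 6.1e-3 1/s x E0); knockout-control wells are flat. The plate
  serializes to three CSVs (signals, layout, standards) with a lossless
  round-trip.
* **Determinism.** One root seed drives every draw; identical seeds give
  bit-identical datasets.

What the generator does *not* emulate: plate-position (edge) effects,
photobleaching or drift, coupling-enzyme lag, pipetting error correlated
across a titration series, and instrument-specific export dialects.
Passing recovery tests therefore show that the estimator chain is correct
and calibrated under the assumed noise structure — not that real plates
meet those assumptions.

## Velocity extraction

Calibration standards are background-subtracted and averaged over the
schedule, then fit by least squares (>= 3 standards spanning a nonzero
range); the standards' span is stored and genuine extrapolation (beyond 2%
of the range) warns. Background subtraction is per-timepoint against the
mean of all background wells, absorbing common drift. The initial velocity
of a well is the least-squares slope of the longest prefix window whose
linear fit keeps r^2 >= 0.98 (>= 4 points; threshold configurable), divided
by the calibration slope. If no prefix reaches the threshold the full
window is used and its sub-threshold r^2 reported. On depletion-curved
noiseless curves this policy never increases bias relative to the full
window, but r^2 is a weak curvature detector: at 50% donor consumption the
full-window r^2 is still 0.9916, so the policy only engages for stronger
curvature (at 90% consumption it picks a 14-point window and roughly halves
the slope bias). Technical replicates average to mean +/- sd/sqrt(n).
Calibration-slope uncertainty is not propagated into se_v by default (it is
small against replicate scatter). The acceptor-independent hydrolysis rate
is estimated from no-ACP wells as mean v/E0 with its se reported honestly
even when the interval spans zero; subtracting it from sample velocities is
available but off by default, since whether the original analysis did so is
unstated — both conventions can be produced.

## Global fitting

Models are fit by unweighted nonlinear least squares in log-parameter
space: positivity is structural (no active bounds), honoring "no parameter
constraints"; the Hill exponent alone is capped at 10 and the result is
flagged if it pins there. Multi-start is deterministic: eight starts for
the Hill law (h0 in {0.8, 1, 1.5, 2} crossed with two kcat scalings, K
starts from data quantiles), analogous grids for the simpler models; the
best of the converged starts wins. Optimizer tolerances are tightened to
1e-15 so noiseless identity fits recover generating parameters to ~1e-8
relative or better. Per-point 1/se^2 weighting is available by flag.

Standard errors are asymptotic and Jacobian-based, using the
heteroscedasticity-robust sandwich covariance
(J'J)^-1 J' diag(r^2) J (J'J)^-1 * n/(n-k) in log space, mapped to the
natural scale by the delta method. The robust form matters here: velocity
noise scales with the velocity itself, and the classical s^2 (J'J)^-1
estimator undercovers the saturation-determined parameters (kcat's nominal
68% interval covered truth in only ~42% of simulation seeds; the sandwich
form brings all four parameters to 62-68%). A seeded nonparametric
bootstrap (default 500 resamples, refitting from the point estimate) is
available on the results object as an alternative uncertainty convention.

Diagnostics: within each fixed-acceptor series, residuals ordered by donor
concentration get a Wald-Wolfowitz runs test on their signs (one-sided,
too-few-runs; normal approximation; series under 6 points are skipped) plus
end-bias scores (mean residual sign in the bottom and top donor quartiles).
The dataset-level flag — "systematic low/high-end deviation" — raises when
at least half the testable series have runs p < 0.05. Forcing the
ping-pong law onto cooperative (h = 1.85) data at cv 3% raises the flag in
93% of 100 simulation seeds; all-zero residuals give p = 1 by convention.

Model comparison uses AIC = n ln(rss/n) + 2(k+1) with a conventional
preference threshold of delta AIC >= 2 (ties go to the simpler model), plus
the F-test for the nested ping-pong/Hill pair. One caveat, measured and
documented rather than hidden: under multiplicative noise the *unweighted*
AIC comparison is anti-conservative on non-cooperative data (the Hill term
is spuriously preferred in ~31% of seeds at cv 3%), while variance-matched
weighting restores the nominal behavior (~6%). On genuinely cooperative
data the preference for the Hill law is unambiguous either way (100% of
seeds, delta AIC in the hundreds).

## Problem sizes

The default simulation studies use the published grids (72- and 60-point
datasets), 100 seeds for detection-rate estimates and 60 seeds for
bias/coverage tables; a single global fit takes ~40 ms, so the full test
suite and the acceptance script each complete in well under a minute of
compute.

## Known limitations

* The r^2-prefix window policy does not detect mild curvature (see above);
  a curvature-test policy would be a natural extension.
* Asymptotic intervals mildly undercover at this design size even in
  sandwich form (62-68% vs nominal 68%); the bootstrap is the conservative
  alternative.
* K' units (uM^h) follow the printed convention; comparisons across fits
  with different h should use K'^(1/h).
* Progress curves are fit at the velocity level only; direct progress-curve
  (integral) fitting is out of scope.
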