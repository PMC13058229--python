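# Methods

## Setting

Bipolar RF ablation delivers current between two catheter tips placed on
opposite faces of a myocardial wall. The bench experiment this package
emulates ablated porcine ventricular slices (nominal 10/15/20 mm) at
20/30/40/50 W for 20/60/180 s, recording the initial catheter–tissue–catheter
impedance, the impedance change over the first 5 s, whether an audible steam
pop occurred (delivery stops at a pop), and whether the lesion was
transmural. A development cohort crossed the full design grid; a later
validation cohort was run deliberately close to the steam-pop risk boundary
with duration fixed at 60 s.

Because the bench dataset is not public, the package's first-class component
is a cohort simulator with the statistical structure the analysis assumes;
every analysis stage is developed and tested against it.

## Generative model (`bipolar_rf.simulate`)

Per application, with all noise from one seeded NumPy generator:

1. **Thickness** `t = level + N(0, 1.0 mm)` — cutting tolerance around the
   nominal slice size.
2. **Initial impedance** `Z₀ = 86.213122 + 0.5057449·t + N(0, 2.5 Ω)`. The
   linear relation is the one used downstream by the depth inversion; the
   noise sd is chosen so the cohort interquartile range of `Z₀` (~6 Ω)
   matches the reported cohort spread once the thickness spread is accounted
   for.
3. **5-s impedance drop** `ΔZ₅ = −19.28 − 0.15·E + 0.20·Z₀ + N(0, 1.5 Ω)`
   (signed; negative = drop). Anchored so that the cohort-conditional
   medians land near the reported pop / no-pop medians (≈ −9.4 vs −5.8 Ω;
   ≈ −10 % vs −6 % for the percentage drop). Higher power heats faster; a
   higher baseline impedance shifts the absolute drop upward.
4. **Steam pop** `~ Bernoulli(σ(−8.60 + 0.08·E − 0.80·%ΔZ₅ − 0.35·t))`:
   pops favour high power, large early percentage drops and thin tissue.
5. **Pop truncation**: on a pop, the actual duration is drawn uniformly on
   (5 s, planned); otherwise actual = planned. The uniform pop-time model is
   a modelling convention (only the stop-at-pop rule is observed behaviour)
   and is configurable.
6. **Transmurality** `~ Bernoulli(σ(12.15 + 0.12·E + 0.02·d_actual −
   0.05·Z₀ − 0.90·t))`, on the *actual* (truncated) duration, since a pop
   cuts energy delivery short. The analysis predictor `rf_duration` is the
   planned (protocol) duration — which is why the duration-only model is
   constant in validation — while `rf_duration_actual` is carried alongside
   for mechanism-level work such as parameter recovery.

**Calibration.** The slope coefficients were fixed from the directions and
conditional medians reported for the bench cohorts; the two logistic
intercepts were then calibrated once, by large-`n` simulation over the
default grid, to the marginal outcome rates of the development experiment
(≈ 49 % transmural, ≈ 5.7 % pops). All constants live in `GeneratorConfig`,
not in code paths. At `n_per_cell = 500` the grid cohort reproduces those
rates within the tolerances asserted in the tests (±5 / ±3 percentage
points).

**Designs.** `grid` crosses all 36 design cells (round-robin for arbitrary
`n_total`). `boundary_adjacent` draws thickness uniformly on 8–13 mm, sets
power in a ±4 W band around the published `Z = 1` isopleth (clipped to the
20–50 W range) and pins duration at 60 s. With the default mechanism this
yields ~96 % transmurality and an elevated (~13 %) pop rate — thin tissue,
boundary-hugging power — which is the qualitative character of the
validation experiment; its exact rates (92 %, 23 %) were not calibration
targets.

**What the simulator does not emulate:** catheter geometry, irrigation,
contact force, intra-application impedance trajectories beyond the 5-s
summary, inter-slice correlation (applications are i.i.d. given settings),
and any bioheat physics. Passing tests therefore demonstrate correctness of
the *statistical machinery* under the assumed mechanism, not validity of the
mechanism for real tissue.

## GLM fitting (`bipolar_rf.glm`)

Maximum likelihood by IRLS; convergence when the relative change in
log-likelihood is below 1e-8 (max 100 iterations; both configurable).
Standard errors come from the observed information at the optimum.
Predictors are never standardised, so coefficients stay on the printed
watt/ohm/second/millimetre scales.

Quasi-complete separation — plausible at bench sample sizes where in-sample
AUCs approach 0.96 — is flagged when any slope magnitude exceeds 15 or any
standard error exceeds 1e3 (the intercept is exempt: on raw ohm scales it is
legitimately large). A flagged fit warns and reports `converged=False`
unless a ridge penalty is active. A rank-deficient system (e.g. duplicated
columns) automatically refits with ridge 1e-6 on the slopes, keeping
collinear problems well-posed; the fit records the penalty used. Tests
cross-check the IRLS optimum against a BFGS maximiser of the Bernoulli
likelihood and against statsmodels GLM.

## AUC and DeLong inference (`bipolar_rf.roc`)

AUC is the midrank Mann–Whitney estimator (ties count ½), identical to
exhaustive pair counting (asserted over random small fixtures). Variance
follows the DeLong structural-component decomposition in the Sun–Xu midrank
form; 95 % CIs are normal-approximation, clipped to [0, 1], so a
constant-score model reports 0.500 (0.500–0.500) rather than NaN. The paired
two-model test uses the component covariances; a zero-variance difference is
reported as an exact tie (p = 1). The paired variance is validated against a
stratified case-resampling bootstrap at small n. Operating points use
Youden's J with ties broken toward specificity (so an all-tied score vector
degenerates to the all-negative point); a fixed 0.5 probability cut is
available. p-values are two-sided and carry no multiplicity correction
across the 63 models — a deliberate mirroring of the analysis being
reproduced, and a documented caveat.

## Subset screening (`bipolar_rf.subsets`)

All 2^p − 1 non-empty subsets, enumerated by size then lexicographically,
fitted on the development cohort, scored on validation. A subset whose every
predictor is constant in validation is kept in the table at the
constant-score convention and flagged with a reason. Output sorts by
descending validation AUC with a lexicographic tie-break. Train-side CIs are
also DeLong (the method for the original train CIs is unstated; using one
method throughout is the simpler, declared choice).

## Attribution (`bipolar_rf.shapley`)

Worth of the empty coalition is 0.5 (chance AUC). Default weighting is the
Shapley kernel `|S|!(p−|S|−1)!/p!`, under which efficiency
(`Σφ = AUC(full) − 0.5`), symmetry, dummy and order independence hold and
are tested; the plain uniform average over the 2^(p−1) subsets — the literal
"average marginal gain" — is provided as an alternative, with the caveat
that it does not satisfy efficiency in general. Subset AUCs are cached by
frozenset, so symmetric predictors are treated bit-identically, and subset
sums run in a canonical order so results are invariant to predictor input
order. Both predictor universes are reported by the attribution driver: all
six candidates, and the five-predictor universe without duration (fixed in
validation) — the published account is ambiguous about which universe its
figures used, so neither is privileged.

## Risk boundary (`bipolar_rf.boundary`)

The published two-predictor model is kept as constants of record
(`−4.9498 + 1.0729·t − 0.09030·E`, scale 0.0743). The boundary statistic is
read multiplicatively, `Z = 0.0743·(1 + e^L) = 0.0743/(1 − p)`: the printed
formula is typographically garbled, and this is the unique parse for which
`Z = 1` marks the quoted 92.6 % probability (`1 − 0.0743 = 0.9257`). The
positive thickness coefficient (thicker ⇒ more pops) contradicts the
univariate bench observation; the constants are nevertheless used as
printed, with a `flip_signs` flag for exploration and no silent correction.
`boundary_power` solves `Z = z` in closed form and is affine in thickness;
round trips are tested to 1e-10.

## Depth inversion (`bipolar_rf.depth`)

"Achievable lesion depth" is operationalised as the thickness at which the
transmural probability equals a target (default 0.5; configurable, e.g.
0.9). Substituting `Z₀(t)` makes the logit affine in `t`, so the root is
unique whenever the thickness direction of the logit,
`β_t + β_{Z₀}·0.5057449`, is negative; models violating that are rejected as
having no meaningful depth. Root finding uses Brent's method on a 1–40 mm
bracket (tolerance 1e-10 mm), verified against the closed-form solution.
The dual solve for required duration is closed-form; durations outside the
tested 20–180 s protocol are flagged as extrapolation, and negative
solutions are reported as "already exceeded at 0 s". No claim is made of
reproducing the original depth figure numerically — its model coefficients
were never published; the procedure is what is reproduced.

## Reporting (`bipolar_rf.report`)

Rates are percentages rounded half-up: integer precision for transmurality,
one decimal for pop rates (the printed convention). Group comparisons use
the Wilcoxon rank-sum test — the published account reports medians/IQRs with
p-values but names no test — exact for small tie-free groups, normal
approximation with tie correction otherwise, validated against full
permutation enumeration at small n. Quartiles are linear-interpolation
quantiles.

## Problem sizes

Shared test cohorts are 420 development / 260 validation rows; the
parameter-recovery check uses 50,400 rows (36 cells × 1,400); attribution
null checks use 2,000-row cohorts; the bootstrap oracle uses 10,000
resamples at n = 12. The analysis drivers default to the bench-study sizes
(194 / 111), chosen to show realistic small-sample behaviour, including
visible sampling noise in single-draw outcome rates.

## Known limitations

- Outcomes are statistical, not physical: no bioheat modelling, and the
  impedance-drop mechanism is a linear surrogate for a nonlinear thermal
  process.
- The printed boundary model's thickness sign conflict is preserved, not
  resolved.
- DeLong CIs are asymptotic; at 11 events the development cohort sits at the
  edge of their comfort zone (the bootstrap cross-check covers the paired
  variance at small n, not the marginal CI coverage).
- Attribution can be negative for predictors that help in-sample but hurt
  validation discrimination; this is a feature of the validation-AUC game,
  not a bug.
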