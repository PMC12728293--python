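# Methods

This note documents the models, estimators, defaults and numerical choices
behind `ectophys`, and what the synthetic-data tests do and do not
demonstrate about real respirometry data.

## Oxygen solubility and the uptake conversion

DO optodes report %air-saturation. Conversions use the García–Gordon
combined fit to the Benson–Krause solubility data, evaluated in mL(STP) L⁻¹
and converted to mg L⁻¹ via the O₂ real-gas molar volume (31.9988 g mol⁻¹ /
22.3916 L mol⁻¹). The test suite re-derives solubility through the fit's
independent µmol kg⁻¹ coefficient set times EOS-80 surface density; the two
routes agree to < 0.5% across the package's validity range (−2–40 °C,
0–42 salinity). A slope *b* (%sat s⁻¹) becomes uptake
ṀO₂ = −b·3600·(C_sat/100)·V_eff with V_eff = (chamber volume − wet mass/ρ),
ρ = 1.0 g mL⁻¹ (tissue density; the standard respirometry assumption —
biases from ρ ≠ 1 are ≪ 1% at the ~40:1 water:animal volume ratios
targeted here).

## Trace processing

The chain is: centred running average (default 15 s; "auto" picks the
smallest window in {15, 30, 45, 60, 75} s whose block-median slopes reach a
median r² ≥ 0.95 — a declared heuristic, since "adjust to the noise" is not
an algorithm) → 20-s block medians laid out per phase (blocks never span a
phase boundary; each point sits at the block's time midpoint) → OLS over
the last 480 s of each sealed phase (the discarded head absorbs the
post-flush mixing transient) → r² filter at 0.90, per-animal configurable
because a rigid global cutoff on noisy animals preferentially discards low,
flat slopes and biases the SMR quantile upward → conversion to mg O₂ h⁻¹ →
background correction.

r² is computed on the block-median series (the series the slope is fitted
to), and the correction subtracts a linear blank-chamber regression fitted
to pre-introduction and post-removal sessions, floored at zero: negative
corrected uptake is physically meaningless at this scale and is clipped
rather than propagated. Consequently |corrected| ≤ |uncorrected| whenever
the background model is non-negative. SMR is estimated from
background-corrected records (correct first, then take the quantile).

Phase labels in input files always win; when absent, flush phases are
inferred from smoothed-derivative upturns above 0.01 %sat s⁻¹ (minimum
segment 40 s). The heuristic finds flush onsets reliably but assigns the
flush tail (where the relaxation rate falls below threshold) to the
following sealed phase; with the 480-s measurement window this does not
touch the fitted region, but labelled input is strongly preferred.

## SMR, MMR, aerobic scope, Q10

SMR is the empirical q = 0.2 quantile (linear interpolation) of accepted
uptakes recorded later than the acclimation window — 15 h under normoxia,
24 h under hypoxia (oxygen ≤ 50 %sat in the metadata), overridable. MMR is
the larger of (a) the steepest 3-min rolling-regression slope over the
initial post-exhaustion sealed phase, computed on the block-median series
re-interpolated to 1-s steps so windows can start every second, ties broken
by the earliest window, background-corrected at the phase midpoint; and
(b) the highest background-corrected routine-cycle record. Ties prefer the
post-exhaustion candidate. The 3-min window is exposed as a parameter
rather than claimed optimal; shorter windows raise variance (and the
max-statistic bias below), longer windows average away the decaying peak.

Animal-level QC mirrors the trial's exclusions: `no_stable_low_mo2` when
the post-window uptake coefficient of variation exceeds 25%,
`no_exercise_response` when the post-exhaustion candidate is below
1.2 × SMR, pass-through flags for moult/death, and `negative_aerobic_scope`.
Flagged animals are excluded from cohort statistics.

Q10 = (R₂/R₁)^(10/(T₂−T₁)) on treatment-mean rates. The identity
(R₃/R₁)^(10/(T₃−T₁)) = [Q₁₂^(T₂−T₁) · Q₂₃^(T₃−T₂)]^(1/(T₃−T₁)) is asserted
as a property test.

### Known estimator biases

Two max-statistics create small upward biases under noise, both inherent to
the published estimator rather than artefacts of this implementation: the
steepest-of-many rolling windows and the highest-of-many routine records.
At the default study-like configuration (SMR 0.38, MMR 1.66 mg O₂ h⁻¹,
0.3 %sat noise) the net MMR error is ~2% (median); for low-scope animals
(hypoxia: MMR ≈ 0.75, shallow EPOC decline, many near-tied windows) it
reaches +5–15%. The SMR quantile is conversely biased slightly low (~−3%)
because measurement noise widens the record distribution symmetrically but
the 0.2 quantile samples its lower flank. Treatment contrasts that compare
hypoxic with normoxic MMR on simulated cohorts therefore run a few percent
hot; contrasts computed from the reference mean table are exact arithmetic.

## The synthetic-data generator

Sealed-phase DO obeys d(DO)/dt = −100·(U_animal + U_bg)/(C_sat·V_eff·3600)
with U_animal(t) = SMR·(1 + a·e^(−t/τ_a)) + A·e^(−t/τ_EPOC) + bursts,
capped at MMR. The EPOC amplitude is A = MMR − SMR·(1 + a) so that
U_animal(0) = MMR exactly; otherwise acclimation elevation and oxygen-debt
repayment would stack above the configured maximum and "recover MMR" would
be ill-posed. Uptake is independent of DO, so integration is an exact
cumulative trapezoid at the 1-s sampling grid. Flushes relax first-order
toward the inflow DO with a 26-s time constant (≈ chamber volume over the
3.5 L min⁻¹ supply shared across 5 chambers); animal uptake during flushes
is ignored, as in the measurement model. Noise is i.i.d. Gaussian
(default 0.3 %sat) with an optional AR(1) term (default off) to exercise
the smoothing stage.

Defaults describe the study conditions: 300-mL chambers, 1-Hz sampling,
~2-h initial sealed phase then 300-s flush / 660-s sealed cycles over 50 h,
treatment-mean rates and masses from the bundled reference table with the
between-animal spread implied by its standard errors. τ_EPOC defaults to
1.5 h — a realistic crustacean oxygen-debt repayment scale consistent with
the 15–24 h acclimation windows — and the acclimation elevation (default
0.2·SMR) decays with τ_a = duration/5 so it is spent within the exclusion
window. Bursts are rectangular (30–120 s, magnitude uniform on
(0, 0.5·(MMR−SMR)), rate 0.5 h⁻¹); deterministic bursts can be injected for
tests. A mass-balance guard rejects configurations whose sealed-phase DO
would reach zero: hypoxic treatments at 10 °C physically cannot sustain a
2-h sealed phase in a 300-mL chamber, so the cohort builder shortens the
post-exhaustion phase there (3600 s at 2 °C, 2400 s at 10 °C) and the
pipeline retries with a shorter phase when an unlucky high-uptake draw
still depletes — the in-silico analogue of an experimenter flushing early.

Survival cohorts draw Weibull event times per treatment (shape 1 =
exponential; scale ∞ = no mortality), observe deaths within the 30-d
follow-up, censor exactly five randomly chosen survivors per tank at day 28
(the respirometry draw) and the rest at day 30. Day-30 survival targets for
the simulated study are 0.40 (combined drivers), 0.65 (warm + acidified)
and 0.88 (all other treatments). Enzyme panels draw a per-animal true
activity from the treatment mean/SD, then duplicate assays as
value·(1 + ε), ε ~ N(0, cv) (default cv 3%); totals are specific activity
times a per-animal protein fraction (0.18 g g⁻¹, CV 2% — small relative to
between-animal activity spread, so measured total and specific activities
correlate at r ≥ 0.8 as in real panels).

What the generator does **not** emulate: oxygen-conforming suppression of
uptake as DO falls (uptake is DO-independent until depletion), optode drift
and temperature transients, autocorrelated activity (bursts are
independent), tank effects on survival (hazards are tank-identical, so the
pooling pre-check operates at its null), and day-resolution death
recording (times are continuous). Passing recovery tests therefore show the
estimator chain is correct under the stated measurement model, not that the
model captures every pathology of real traces.

## Survival analysis

Kaplan–Meier with Greenwood variance and linear-scale confidence intervals;
the k-group log-rank uses the hypergeometric covariance and a pseudoinverse
on the first k−1 groups, with the asymptotic chi-squared reference (no
permutation option in v1, matching common practice). Tie conventions,
test-pinned: deaths at equal times aggregate into one dᵢ/nᵢ factor;
censoring tied with a death stays in that death's risk set. Pairwise
comparisons multiply raw p-values by the number of pairs (Bonferroni,
capped at 1) — deliberately not Holm, to match the workflow this package
reproduces. The replicate-tank pre-check runs a within-treatment log-rank
per treatment and approves pooling iff the minimum p exceeds α; with eight
treatments its family-wise false-alarm rate is ≈ 1−0.95⁸ ≈ 34%, which is
reported, not corrected — it is a conservatism check, not an inference.

The simulated grouping pattern (two depressed treatments separating from
all others) is assessed by majority vote over five replicate cohorts: the
closest contrast (day-30 survival 0.65 vs 0.40 at n = 140 per group) has
~0.9 single-cohort power after Bonferroni, so a single seed would flake on
a sound implementation.

## Treatment statistics

Fixed-effects models only: the tank term is omitted from the final models
(it is handled by the survival pooling pre-check and, for metabolic traits,
can be probed with a fixed tank factor), matching the workflow's final
models. Design A fits response ~ temperature × pH (+ log10 wet mass);
Design B fits response ~ treatment (+ covariate) over the four corner
treatments. F tests use Type-II sums of squares — a declared choice; on
balanced data it coincides with sequential Type-I, asserted in tests.
Metabolic rates and wet mass are log10-transformed; the transform registry
also logs ETS and CS:COX (and COX in Design A), identity otherwise.
Homogeneity of regression slopes is checked by jointly testing the
factor×covariate interactions against the base model.

Tukey HSD is computed on covariate-adjusted marginal means via model
contrasts (Tukey–Kramer under imbalance): q = |Δ|/(SE/√2) against the
studentized range with the model's residual df. With two groups this
reduces to the pooled t-test, asserted in tests. Welch's ANOVA
(Satterthwaite df) with Games–Howell per-pair Welch df handles the
heteroscedastic case (in this workflow, log10 CS:COX). Compact letter
displays use insert-and-absorb: significant pairs never share a letter,
non-significant pairs always do; letters are ordered by descending adjusted
mean.

Percent-change summaries use unweighted means of treatment means when
pooling across a factor (e.g. pH pooled over temperatures); group sizes of
8–9 make weighted and unweighted versions indistinguishable at the
reported precision.

## Degenerate inputs and numerical conventions

Constant responses flag `degenerate_zero_variance` instead of producing
0/0 F ratios; constant residuals short-circuit the assumption checks;
zero-variance groups are errors for Welch/Games–Howell; correlation of a
constant series is an error, not NaN. Quantiles use linear interpolation.
Rolling regressions evaluate every window in closed form from cumulative
sums (no per-window refits). All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical seeds give
bit-identical traces, cohorts and panels, and `run_pipeline` is
deterministic under its config seed.

## Problem sizes

The shipped defaults process 50-h, 180 000-sample traces; the full
simulated study (72 animals, survival cohort of 1120, 72 enzyme panels,
all statistics) completes in well under a minute per stage and ~40 s end
to end on one core. Monte-Carlo checks use 150–500 replicates for test
calibration and 5–20 seeds for recovery summaries; these sizes put the
simulation standard errors comfortably inside the asserted tolerances.

## Limitations

- The MMR max-statistic bias under noise (above) is inherent to
  steepest-window estimators; users comparing low-scope groups should
  prefer contrasts of the same estimator, not absolute values.
- The smoothing-window auto-selector and the phase-inference heuristic are
  declared stand-ins for judgement calls made by eye in practice.
- Survival inference is asymptotic; with very few events the chi-squared
  reference is approximate.
- Carbonate chemistry is metadata only; no mixed-effects models.
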