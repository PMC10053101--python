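# Methods

`apkin` implements the quantitative analysis pipeline used to characterize
gut alkaline-phosphatase (AP) isoform kinetics and the effect of
deglycosylation on them: assay-level activity computation, nonlinear model
fitting, thermal-inhibition estimation, isozyme partitioning, the comparison
conventions used to report the results, and sequence-level N-glycosylation
accounting.  This note records the models, their assumptions, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Units and data model

Substrate concentrations are normalized to µM at ingestion (tables may
declare mM; values are multiplied by 1000 once, and normalization is
idempotent).  Activities are specific activities in
nmol p-nitrophenol·mg protein⁻¹·min⁻¹ (1 U = 1 nmol/min); percent-of-control
series carry an explicit `is_relative` flag rather than being inferred from
magnitudes.  Every fitted stage is wrapped in an `AnalysisResult` whose
parameter map never silently omits an estimate: a parameter that could not be
estimated from a significant fit carries the explicit `"NS"` marker.

## Kinetic models

* **Michaelis–Menten** `v = Vmax·S/(Km + S)`, fitted by unweighted nonlinear
  least squares.  Initialization: `Vmax₀` = max observed velocity, `Km₀` = the
  smallest substrate level whose velocity exceeds `Vmax₀/2`.  At least four
  distinct substrate levels are required.
* **Four-parameter logistic** on a *linear* dose axis (base-10),
  `Y = Bo + (To − Bo)/(1 + 10^((ED50 − x)·h))`, for enzymatic deglycosylation
  dose-response.  `Bo`/`To` are the bottom/top plateaus, `ED50` the
  half-effective dose in U/mg protein, `h` the Hill slope.  A common reporting
  form divides the dose axis by a round constant (e.g. 500) and absorbs the
  Hill slope; `SigmoidParams.caption_rescaled` maps the canonical fit onto
  that form (`h → −1/scale`, offset `ED50/scale`).  Initialization: plateaus
  at the observed extremes, `ED50₀` at the dose nearest mid-response, and
  `|h₀| = 4/(ln10·dose span)` signed by the response direction — the magnitude
  that places the logistic transition across the observed dose window.  A
  direction-only `±1` start is unusable here: with doses up to ~1.3·10⁴ the
  exponent would overflow immediately, which is also why the model evaluation
  clips the exponent to ±300.
* **Exponential** `Y = J0·e^(b·x)` and **quadratic** `Y = c0 + c1·x + c2·x²`
  thermal responses.  The exponential initializes from OLS in log space when
  all responses are positive and falls back to direct NLS otherwise; the sign
  of `b` is unconstrained (thermotolerant bacterial AP activity *rises* with
  treatment temperature, the porcine isoform's falls).  The quadratic is plain
  OLS.

All NLS fits share one convergence policy (recorded in result provenance):
relative tolerance 1e-10, ≤ 200 iterations per attempt, ≤ 5 jittered restarts
from the data-driven start.  Standard errors come from the estimator
covariance; R² = 1 − SSres/SStot about the response mean, for nonlinear fits
too, matching the reporting convention of the source assays.  Replicates may
be fitted raw or as per-level means (`on_means=True`); the entry mode is
recorded in provenance since assay reports use both.

## Thermal-inhibition (Eadie–Hofstee) estimation

Residual activity J after a 30-min treatment at temperature I (°C) is
regressed on J/I:

    J = I_MIN + slope·(J/I),   TC50 = |slope|,   I_MAX = I_C − I_MIN

with I_C the unheated (22 °C) control-group mean.  The linearization is
algebraically exact for the saturating family `J = A·I/(TC50 + I)` (the same
identity that makes a classical Eadie–Hofstee plot linear); for any other
response shape it is a heuristic summary.  Conventions:

* The regression slope is reported as TC50 by magnitude; empirically a
  falling activity yields a *positive* fitted slope (J and J/I fall
  together), and the raw signed slope is kept in diagnostics.
* The control point enters the regression like every other point.
* **NS gating**: when the slope's OLS p-value exceeds 0.05 the series carries
  no interpretable thermal-inhibition parameters — TC50, I_MIN and I_MAX are
  all reported as `NS` and only I_C is numeric.  This is exactly the behavior
  expected for a preparation whose activity is not inhibited by heating, such
  as a thermotolerant bacterial lysate.
* An intercept not distinguishable from zero (p > 0.05) is *reported* as
  `"0"`, with the raw estimate preserved; I_MAX always uses the raw
  intercept, because `I_C − raw_intercept` reproduces the published I_MAX to
  printed rounding while `I_C − 0` does not.
* TC50 is invariant under rescaling of J (absolute vs percent-of-control),
  since J and J/I rescale identically; I_MIN, I_MAX, I_C scale by the factor.

Known limitation: the implied forward curve `J = I_MIN·I/(I − TC50)` is
singular at I = TC50, so no usable generative model corresponds to a positive
fitted slope over a grid containing TC50.  The synthetic thermal-inhibition
generator (below) therefore uses a saturating construction, and the fitted
|slope| on such data *understates* the generating TC50 by roughly a factor of
two on the 22–80 °C design; the estimator's contract is tested as (i) exact
recovery on collinear points and on the saturating family the transform is
exact for, and (ii) equivalence with the closed-form OLS oracle elsewhere.

## Partitioning and inhibitor fractionation

An isoform expressed in a host lysate is measured as *total* activity; the
vector-only lysate gives the *background*.  Two labelled partitioning routes:

* `parameter_difference`: `Vmax_specific = Vmax_total − Vmax_background`,
  SE by quadrature.  This is exact for Vmax because Michaelis–Menten curves
  add point-wise in their plateaus.
* `pointwise`: subtract the per-level mean activities on a shared substrate
  grid and fit the difference curve.  The difference of two Michaelis–Menten
  curves is *not* Michaelis–Menten, so the apparent Km of the difference is a
  fit artifact whose value is checked against an exhaustive grid-search
  oracle rather than any closed form.  Negative differences are kept (with a
  warning); clipping would bias the fit.

Inhibitor fractionation normalizes residual activities to the no-inhibitor
(0 mM) baseline (exactly 100% by construction) and classifies the dominant
isoform family from the top shared concentration: IAP-dominant when the
IAP-selective inhibitor (L-phenylalanine) removes ≥ 50% while the
TNAP-selective one (L-homoarginine) removes < 50%; the mirror case is
TNAP-dominant; anything else (both high or both low) is mixed.  The 50%
threshold is configurable.

## Comparison conventions

Fold differences use excess-over-baseline, `(max − min)/min`, the convention
that reproduces the published fold values from the printed table entries; the
plain ratio is exposed but never the default.  Percent changes are
`100·(new/ref − 1)` (increase) or `100·(ref − new)/ref` (reduction), rounded
half-away-from-zero for prose-style integers.  Parameter estimates (value ±
SE) are compared by the pooled two-tailed t statistic with the conservative
df = min of the two fits' residual df (default df = n − #parameters).
Replicate-level endpoints use one-way ANOVA with Tukey HSD (studentized-range
p-values) and a compact letter display (insert-and-absorb; shared letter =
not separated at 0.05).  Significance at p < 0.05, trend at p < 0.10.

## Sequence layer

N-glycosylation sequons are all positions `i` with `seq[i] = N`,
`seq[i+1] ≠ P`, `seq[i+2] ∈ {S, T}`, overlapping matches included, numbered
1-based on the untrimmed chain so positions remain comparable after trimming.
This is the canonical acceptor-motif rule; no neural scoring is emulated.
Chain masses use a pinned table of average residue masses
(`expasy-average-1`) plus one water, in kDa; mature-chain masses trim a
user-supplied signal peptide (1..signal_end) and optionally everything beyond
the GPI-anchor ω-site.  Signal/ω boundaries are *inputs*: this package does
not predict them, and published "C-30"-style GPI annotations are ambiguous
between an ω-residue index and a C-terminal propeptide length, so the caller
must resolve that ambiguity.  The mass difference between an observed mature
glycoform and the computed pre-mature chain is reported as the glycan mass
shift (sign preserved).

## Synthetic data

Generators are seeded (`numpy` PCG64; identical spec + seed ⇒ bit-identical
data) and additive-Gaussian on the response, reflecting the symmetric ±SE
reporting of the assays they emulate.  Default designs: 10 substrate levels
over 0–800 µM (3 replicates) and 16 levels over 0–6000 µM (4 replicates) for
kinetics; six doses {0, 1430, 4289, 7150, 8579, 12868} U/mg (4 replicates)
for dose-response; six temperatures evenly spanning 22–80 °C (4 replicates,
n = 24) for thermal series.  Presets embed the published parameter estimates
per experimental condition; preset noise levels were calibrated once so that
fitted parameter SEs on simulated data are of the same order as the published
SEs (e.g. Km SE ≈ 290–470 µM on the partitioned-lysate preset against a
printed ±450.8).

The thermal-inhibition generator uses
`J = I_C − I_MAX·I′/(TC50 + I′)` with `I′ = max(I − 22, 0)` — a saturating
inhibition curve falling from the control level toward the plateau
`I_MIN = I_C − I_MAX`.  This forward model is a package construction (no
usable generative form follows from the estimator's line, see above) and is
labelled as such.

The two-isoform mixture generator draws group activities
`total·[f_IAP·(1−φ_Phe(c)) + f_TNAP]` under the IAP-selective inhibitor (and
mirrored for the TNAP-selective one).  Four segment-like scenarios
(`SEGMENT_MIXTURES`) pin baselines to the published group means, per-replicate
noise to the published pooled SEMs (sd = SEM·√6, n = 6 animals), and
inhibition fractions to the published percent-inhibition ranges.  A caveat
the scenarios make explicit: a "mixed" pattern sitting exactly on the 50%
threshold (both inhibitors removing ~54%) cannot be recovered reliably by any
threshold classifier at this noise; the mixed scenario therefore represents
the both-below-threshold regime.

What the generators do **not** emulate: plate-level absorbance noise and
pipetting error structure, heteroscedasticity across substrate levels,
between-animal variance components, or inhibitor cross-reactivity beyond the
segment scenario constants.  Passing recovery tests therefore demonstrate
estimator correctness under idealized replicate noise, not robustness to
real-assay error structure.

## Validation approach

Because no raw assay datasets are deposited for this study design, validation
rests on three legs: (i) worked-example arithmetic over published table
values (fold/percent conventions, parameter-difference partitioning,
Eadie–Hofstee identities); (ii) noise-free closed loops — generate from a
preset, refit, recover the generating parameters to relative error < 1e-6 —
for every model family; and (iii) stochastic recovery at study-scale noise:
over 200 seeded simulations, 3·SE Wald intervals cover the generating
Michaelis–Menten parameters in ≈ 99% of runs and the logistic's reported
parameters (Bo, To, ED50) in ≈ 93%.  The Hill slope is excluded from the
coverage check: on a linear dose axis with six doses it is weakly identified,
its Wald interval undercovers (~64%), and the published fit likewise reports
no independent Hill-slope SE (the caption form absorbs it into the dose
rescaling).  Dominance-label recovery across the four segment scenarios is
197/200.  Problem sizes throughout (200 seeds, 500 random 200-mers, 10⁴
Monte-Carlo draws) were chosen as the smallest giving stable pass/fail
margins for these checks.
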