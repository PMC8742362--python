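# Methods

## Model

A fixed cohort with aligned time zero is followed over `K` half-open windows
`[t_k, t_{k+1})`, `k = 0..K-1`; `t_K` is the administrative study end.
Windows are unitless indices — no calendar durations are ever assigned, since
none of the identification statements depend on them. The structural model
is fully discrete:

1. optionally a binary unmeasured confounder `U ~ Bernoulli(p_U)`;
2. baseline covariate `L_0 ~ init_l(U)` over a finite code set;
3. while at risk at `t_k` (`Y_k = 0`):
   exposure `A_k ~ Bernoulli(exposure_law(k, U, L_0..L_k, A_0..A_{k-1}))`,
   then the event indicator
   `Y_{k+1} ~ Bernoulli(hazard_law(k, U, L_0..L_k, A_0..A_k))`,
   then (if no event and `k+1 < K`)
   `L_{k+1} ~ covariate_law(k+1, U, L_0..L_k, A_0..A_k)`.

Conventions: `Y_k = I(T < t_k)`, so "event in window k" means
`Y_k = 0, Y_{k+1} = 1`; all indices are 0-based; exposure and covariate
values are stored only for at-risk windows and are missing afterwards.
Covariates are finite discrete codes (binary in every preset) so that
saturated, nonparametric propensity estimation and exact enumeration are
both possible. `covariate_law = None` declares a time-fixed covariate.

Counterfactuals are defined for two regime families — set `A_0 := a` with
later exposures following their natural law (the ITT contrast), and
`A_k := a` for all k (the sustained "always/never exposed" PP contrast).
In simulation, all four regimes are coupled to the observed path through
shared exogenous uniforms, one per structural equation per subject-window;
this makes consistency hold row-wise by construction whenever the observed
exposure path matches a regime, and leaves every marginal interventional
distribution unchanged (the coupling is a choice; the estimands are not
sensitive to it).

## Exact computation

Because the state space is finite, the joint distribution of complete
trajectories (including `U`) is enumerated exactly; interventional
distributions are obtained by enumerating the same tree with the exposure
law replaced by the regime. Estimands (marginal risk ratio, conditional
odds ratio given `L_0`, per-window marginal or conditional hazard ratios)
are always computed from this enumeration, never by simulation —
identification is a distribution-level statement and Monte-Carlo noise
belongs only to estimator checks. An independently coded path-product
enumerator and a recursive g-formula oracle (in the test suite) cross-check
both routes.

The conditional-on-history per-protocol hazard ratio conditions on
*observed* adherence, which an intervened tree cannot represent; it is
computed from the observed law via the structural consistency of the model
(given `A_0=..=A_k=a`, `Y_{k+1}(ā)` coincides with `Y_{k+1}`). The matched
functional it is compared against is computed by an entirely separate
pair-probability integration, so the identity check is not circular.

Distribution-level identifying functionals replace sample sums with
expectations, realized control draws with exact eligible-set masses, and
selection counts with expected counts. For the risk-set schemes the
per-window sampling fraction enters only as a weight profile: the default
`sampling_model="constant"` uses the constant-fraction design the
identification results assume (the fraction then cancels in the exposure
odds ratio); `"per-case"` uses the expected fractions of the practical
fixed-m-per-case design, `m · Pr(case in window k) / Pr(eligible at k)` —
under constant hazards the two coincide, and the non-constant-hazard
violation check uses the per-case model deliberately.

## Sampling-scheme conventions

Case qualification: `Y_K = 1`, plus — for per-protocol analyses — constant
exposure over the at-risk windows before the incident event. When a
protocol deviation falls in the *same* window as the event, qualification
and censoring pull in opposite directions; the package exposes the tie-break
as `deviation_policy`. The default (`"qualify"`) does not attribute the
event to the contemporaneous deviation, which is the convention the
worked follow-up example requires; all weighted analyses use `"censor"`
internally, because the censoring step removes the entire deviation window
and the per-protocol identification algebra needs the censor-consistent
case set. The two conventions differ only for subjects who deviate in their
event window.

Control eligibility: risk-set controls must be event-free at `t_k`; in PP
mode `eligible_controls` additionally requires the subject to be uncensored
through window `k`, because censored subject-windows contribute nothing to
the weighted analysis (this adherent set is also the matched PP pool).
Selection itself, however, is drawn from the plain risk set in both modes:
the switch propensities `p_j = Pr(A_j=1 | history, Y_j=0, S_j=1)` must be
estimable from selected controls, and a selection rule that conditioned on
`A_j` would make them degenerate. Selected subject-windows past a deviation
therefore inform propensity estimation only.

The index case belongs to its own window's eligible set but is excluded
from its own draw by default (`exclude_index_case` / `exclude_self`
toggles); a matched case whose pool contains only itself is matched to
itself (degenerate pool), and a matched case with an empty pool is dropped,
logged and counted rather than erroring the run — finite-sample positivity
failures are expected and must be visible, not fatal.

Risk-set sampling offers two designs: `per-case` (m controls per case per
event window, the practical suggestion) and `bernoulli` (every risk-set
member selected with a constant per-window fraction, the literal design
assumption). The simulation-study runner uses the Bernoulli design for PP
because under time-varying confounding the per-case design's realized
fractions are not constant — which is exactly the assumption the
identification result makes — and it never samples below 30% of each risk
set there, because
saturated full-history switch propensities need dense per-stratum control
data. Weight estimation is saturated (stratum-wise frequencies) throughout;
no truncation or stabilisation is applied, since the identification results
concern the untruncated functionals. For the risk-set ITT weights the
conditioning event is selection at window 0 (the literal reading); pooling
all ever-selected controls is available as `propensity_source="pooled"` and
is a documented deviation.

## Presets

All presets use `K = 3`, binary `L` and `A`; parameters were chosen once to
give moderate confounding, event risks in the 5–25% range (so that both
cases and survivors are plentiful at n = 5,000), and effect sizes around
risk/odds/hazard ratios of 1.7–2.5.

* `null` — hazard ignores exposure; exposure switches over time. Every
  estimand and every functional equals 1.
* `confounded-binary` — frozen exposure, `Pr(A_0=1|L) = 0.25 + 0.4L`,
  hazard `b(L)·θ_L^A` with `b = (0.03, 0.10)`, `θ = (2.5, 1.4)`: baseline
  confounding with a heterogeneous effect. Satisfies the case-base and
  survivor rows; doubles as the violation preset for survivor-sourced
  case-base controls (survival depends on `A_0`) and for matched-design
  homogeneity.
* `confounded-homogeneous-rr` / `-or` — frozen exposure, cumulative risks
  chosen so the factual risk ratio (2.0) or odds ratio (2.5) given `L_0` is
  constant across strata; hazards back-solved as `1-(1-r)^{1/K}`.
* `constant-hazard` — hazards `s_k(a)·g(L)` with `s_k(a)` solved in closed
  form, window by window, so the *marginal* counterfactual hazards are
  exactly 0.05 and 0.10 despite depletion of susceptibles.
* `prop-hazard` — time-constant `b(L)·2^A`: *conditional-on-L_0*
  counterfactual hazards constant, hazard ratio homogeneous (the matched
  risk-set ITT row).
* `nonconstant-hazard` — per-window exposure effect 3.0 / 1.0 / 0.4: the
  risk-set functional then equals none of the per-window hazard ratios.
* `tv-confounding` — `L_{k+1}` responds to current exposure, `A_{k+1}` to
  current `L` and previous `A` (time-varying confounding with treatment-
  confounder feedback); hazard scales `c_k(a)` solved sequentially so the
  sustained-regime marginal hazards are exactly 0.06 and 0.12.
* `tv-confounding-prop` — same dynamics, hazard `0.05·(1+0.8L)·2^A`: the
  adherent-history hazard ratio is exactly 2 at every window and history
  (the matched PP row, which needs no exchangeability condition).
* `unmeasured-U` — binary `U` in both the exposure and hazard laws; the
  case-base functional misses the true risk ratio by 0.66.
* `rare-outcome(eps)` — unconfounded exposure (flat propensity 0.35),
  hazards scaled by `eps`; at `eps = 1e-4` the overall risk is 6.1e-4 and
  the survivor scheme's crude exposure odds ratio is within 0.05% of the
  marginal risk ratio (the rare-event approximation).

## The worked follow-up example

`figure1_fixture()` reconstructs a 9-subject, 12-window cohort from the
textual constraints of a worked follow-up illustration: four subjects
event-free throughout; events in windows 3, 4, 5, 5 and 7; two subjects
switching exposure in window 4 before their window-5 events; the window-7
case keeping its exposure until its event window. Values not pinned by the
text (covariate codes, exposure levels of the event-free rows) are fixed
arbitrary constants, and only the qualification/eligibility properties the
tests exercise are normative. One documented deviation: under our adherence
rule the two window-4 switchers are already precluded as per-protocol
controls at the second case's event window, which the narrative the fixture
reconstructs did not state; the narrative's own claims about that walk-through
are not mutually consistent, and the package resolves them as described
under "Sampling-scheme conventions" above.

## What the simulator does and does not emulate

The generator produces exactly the structures the identification theory
speaks about: discrete time, discrete covariates, binary exposure, a fixed
cohort with no entry after time zero. It does not emulate continuous time
or covariates, competing risks, loss to follow-up, outcome misclassification
or measurement error, or dynamic (calendar-time-open) cohorts. Passing
tests therefore certify the identification logic and the estimators'
behaviour under the stated assumptions — not robustness of case-control
analyses to the real-world complications listed above.

## Numerical choices

Exact checks use a tolerance of 1e-10 (pure arithmetic on float-representable
probabilities; observed errors are ~1e-15). Law outputs are validated to
[0, 1] and distributions to sum to 1 within 1e-12; enumeration is guarded by
a configurable atom cap (default 1e7). Zero cells and degenerate propensities
raise named errors (`ZeroCellError`, `PositivityViolationError`) rather than
returning infinities; an optional 0.5 continuity correction exists nowhere —
identification claims concern the uncorrected functionals, and undefined is
reported as undefined. Matched estimates with no discordant pairs return a
structured "undefined" result carrying the reason.

Monte-Carlo checks compare on the log-ratio scale. The simulation study
runs 200 replicates at n = 5,000 per scheme (mean within 3 Monte-Carlo
standard errors of the truth) plus a single n = 200,000 cohort per scheme
(estimate within 3 scaled standard errors of the exact functional); these
sizes keep each scheme's check to well under a minute while leaving the
3-SE bands a few percent wide. Replicates with infeasible sampling, empty
cells or positivity violations are flagged and counted, never silently
dropped.

## Known limitations

* Only saturated propensity models are provided; with long histories or
  many covariate levels they need large control samples (hence the 30%
  floor on the PP sampling fraction in the study runner). A parametric
  plug-in would share the output shape but is out of scope.
* 1-to-M and partial/caliper matching, conditional-logistic analysis,
  conditional risk-ratio and conditional-hazard-ratio variants of the
  unmatched results, and variance/interval estimation are out of scope.
* The per-protocol deviation-in-event-window tie-break is a genuine
  modelling choice (see above); both conventions are implemented, and they
  agree except on the tied windows.
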