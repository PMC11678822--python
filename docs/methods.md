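# Methods

This note documents the statistical models behind `bequiv`, the defaults of
the synthetic-data generator, and the numerical and design choices made
where conventions differ between implementations.

## Study design and data model

A study is a randomized two-treatment, two-sequence, two-period (2×2×2)
crossover: sequence TR receives the Test product in period 1 and the
Reference in period 2, sequence RT the reverse. Data are stored long, one
row per observed concentration (`subject, sequence, period, formulation,
time_h, conc_ng_ml, blq`), with formulation validated against (sequence,
period) on read. Concentrations below the lower limit of quantification
(LLOQ) carry an explicit boolean flag and an empty value — no `"<LLOQ"`
string dialects. *Completers* are subjects with at least one quantifiable
concentration in both periods; all comparative statistics use completers
only. A missing pre-dose sample is treated as concentration zero with a
warning (single-dose study).

## Synthetic-data generator

Profiles follow a one-compartment model with first-order absorption,

    C(t) = F·D·ka / (V·(ka − ke)) · (e^{−ke·t} − e^{−ka·t}),

which has a closed-form peak at t* = ln(ka/ke)/(ka − ke) — convenient for
testing the NCA against exact values. The two-compartment alternative would
add a distribution phase but changes none of the downstream statistics, so
the simpler model with an analytic tmax was chosen.

Parameters and defaults of the pazopanib-like presets:

| parameter | default | why |
|---|---|---|
| ka | 1.0 h⁻¹ | puts the typical peak at ~4 h, inside the observed 2–8 h window |
| t½ (→ ke = ln2/t½) | 40 h | matches the terminal half-life observed in healthy-volunteer crossover data (λz ≈ 0.017–0.018 h⁻¹, mean t½ ≈ 41–45 h); literature summaries quote "approximately 30 h", but the generator is calibrated to the measured study-scale values |
| V (apparent, V/F) | 25 L | literature value; absolute oral bioavailability (~21%) is not identifiable from oral data and is folded into the apparent volume, so F_ref = 1 |
| dose | 200 / 400 mg | the two study strengths |
| LLOQ | 50 / 100 ng/mL | lower bound of the assay calibration range per strength |
| sampling grid | 0, 0.5, 1, 1.5, 2, 2.5, 2.75, 3, 3.25, 3.5, 4, 4.5, 5, 6, 8, 10, 12, 24, 48, 72 h | the studies' 20-point schedule |
| n subjects | 24 (pilot) | pilot design; pivotal-scale runs pass `n_subjects=96+` |

Variability is lognormal throughout. Between-subject CVs default to 40% on
ka, 30% on ke and 30% on V (the literature gives no explicit values; these
produce Cmax/AUC between-subject CVs in the observed 40–60% range).
Within-subject (inter-occasion) variability is drawn fresh per period on
relative bioavailability F (default CV 50%) and on ka (default CV 20%). The
true Test/Reference exposure ratio multiplies F on Test occasions, so Cmax
and AUC scale by it exactly in the noise-free limit.

**ISCV calibration.** Because Cmax and AUC are proportional to F within a
subject, a within-subject CV of c on F contributes a ln-scale residual
variance of exactly ln(1 + c²) — the quantity the crossover ANOVA converts
back to an ISCV of c. The calibration constant is therefore 1: presets set
the F CV equal to the targeted ISCV, and the parameter-recovery test
confirms the ANOVA returns it within ±5 percentage points at 1000 subjects
(the small ka inter-occasion term adds only a second-order contribution to
Cmax and none to AUC).

The generator emulates the statistical structure the analysis assumes —
balanced sequences, lognormal multiplicative noise, an optional
multiplicative period effect, LLOQ censoring at write time. It does **not**
emulate dose-nonlinear absorption, enterohepatic recirculation, food
effects, dropout mechanisms, or assay error structure; passing tests
demonstrate the *statistics* behave correctly under the assumed model, not
that the model captures every feature of real pazopanib data.

## Non-compartmental analysis

- **Cmax/tmax**: maximum observed quantifiable concentration; ties broken
  by the earliest time (deterministic, conventional).
- **AUC0–72**: linear-up/log-down trapezoid (configurable to all-linear).
  A descending segment with two positive endpoints contributes
  (C₁ − C₂)·Δt / ln(C₁/C₂); rising, flat, or zero-touching segments use the
  linear rule (the log rule's limit). The design's truncation at 72 h is
  enforced; a profile ending early is truncated at its last quantifiable
  time and flagged non-evaluable for the BE analysis.
- **BLQ rules**: samples below the LLOQ count as 0 before the subject's
  first quantifiable concentration and as missing afterwards (excluded from
  λz; AUC intervals bridge across them). A fully unquantifiable profile has
  zero area and no Cmax (NCA failure for that subject×period).
- **λz**: ordinary least squares of ln C on t over trailing point sets of
  k ≥ 3 quantifiable points strictly after tmax; the set with the highest
  adjusted R² wins, ties toward more points. Commercial NCA tools differ in
  their exact terminal point selection; best-adjusted-R² over trailing sets
  mirrors the common "best fit" default. If fewer than three points
  follow the peak (a profile already declining at its first sample), the
  peak itself is admitted. A non-positive slope yields "λz absent".

## Average bioequivalence

The ANOVA on ln(metric) uses all-fixed effects — Sequence, Subject nested
within Sequence, Period, Formulation — exactly as in the regulatory
analysis; with subjects as fixed effects the residual mean square s² is the
within-subject variance, giving ISCV% = 100·√(e^{s²} − 1). The design
matrix uses sum-to-zero (±½) coding with subject contrasts summing to zero
within each sequence, so the formulation coefficient is ln(GMR) directly,
the intercept ± half-effect are the geometric least-square means
(equal-weight marginal means, robust to unbalanced sequences), and
df_resid = n − 2 for complete data. The 90% CI uses the t-distribution with
df_resid (two one-sided tests at α = 0.05). The ANOVA table reports
Type-III sums of squares; Sequence is tested against the
Subject(Sequence) mean square, the within-subject terms against the
residual. The fit is an explicit least-squares solve (kept lightweight so
thousands of replicate studies can be analysed in the calibration tests);
tests cross-check it against both a closed-form period-difference estimator
and `statsmodels` OLS on the same design to 1e-9.

GMR and CI bounds are reported to 2 decimals; the BE decision
(both CI bounds inside the **closed** interval [80.00, 125.00]%) is applied
to unrounded values.

## Cmax f2

Mean profiles are arithmetic means over completers at each nominal time
(leading BLQ as 0, later BLQ excluded from that time's mean). Both mean
curves are scaled by the single constant CmaxR — the maximum of the *mean
Reference* curve, earliest time on ties — and truncated at its time tmaxR.
tmaxR is deliberately the tmax of the mean profile, not the median
individual tmax: the mean curve's peak is what the normalization window is
defined on. The f2 sum runs over the n post-dose points 0 < t ≤ tmaxR; the
pre-dose point is excluded since its difference is identically zero and
would only inflate similarity. log is base 10, per the dissolution-f2
convention the statistic adapts. f2 is reported to 2 decimals; bands are
decided on the unrounded value.

Decision bands (strongest applicable wins): f2 ≥ 50 → >90% confidence
regardless of ISCV; f2 ≥ 41 and ISCV ≥ 50% → >80%; f2 ≥ 35 and ISCV > 40%
→ >60%; f2 < 35 → similarity not shown. Combinations the tabulated rules do
not cover (e.g. f2 ∈ [35, 50) at ISCV ≤ 40%) conservatively report the
weakest band, flagged "outside tabulated scenarios". Whether the Test mean
peaks before tmaxR does not change the computation: the statistic is
defined on the truncated window regardless.

## Exact TOST power

With ISCV converted to the ln-scale standard deviation s = √(ln(1 + CV²)),
the ln-ratio estimate is N(θ, s²·2/n) and the variance estimate is
s²·χ²_df/df with df = n − 2, independent. Both one-sided tests reject iff
the (1 − 2α) CI falls inside [ln 0.8, ln 1.25]; power is the probability of
that event, computed by quadrature of the conditional normal probability
over the chi distribution of ŝ/s — the Owen's-Q bivariate noncentral-t
construction. The integrand vanishes above û = (ln U − ln L)/(2·t₁₋α·s·√(2/n)),
where the CI is wider than the band: in a 24-subject ISCV-50% study this
region has ~45% probability, which is why the TOST size at the boundary
collapses to ~1.6% there while reaching the nominal ~5% at pivotal scale
(n = 96). For this reason the boundary-size simulation check runs at n = 96;
the coverage check (90% CI covering 100% under a true ratio of 1) runs at
the pilot scale n = 24. Sample sizes are the smallest *even* n (balanced
sequences) reaching the target power, with a GMR *range* resolved to its
worst-case (most extreme ln-ratio) endpoint — the endpoints of
[90.00, 111.11]% are log-symmetric, so either suffices.

Replicate sizes used by the calibration tests: 2000 studies for CI
coverage (Monte-Carlo SE ≈ 0.7%), 5000 for boundary size (SE ≈ 0.3%),
50,000 ln-scale draws for the exact-vs-simulated power comparison
(SE ≈ 0.2%), and one 1000-subject study for ISCV recovery.

## Degenerate inputs and tie-breaks

- Identical Test/Reference values: GMR = 100.00%, MSE = 0, a zero-width CI
  (allowed; downstream formatting handles it).
- ka = ke is refused (flip-flop-degenerate one-compartment curve); the
  simulator nudges extreme within-subject ka draws off ke by 0.1%.
- All ties (tmax, mean-profile maximum, λz candidate sets with equal
  adjusted R²) resolve deterministically: earliest time / more points.
- Sequence allocation is deterministic (first half TR) before a seeded
  shuffle, so designs are balanced by construction and bit-reproducible.

## Known limitations

- Only 2×2×2 designs: no replicate (3/4-period) designs, no
  reference-scaled average bioequivalence, no tmax nonparametrics, no AUC
  extrapolation to infinity or partial AUCs.
- The f2 confidence bands are applied as given decision rules; the package
  does not re-derive them, and provides no bootstrap CI for f2.
- Power/sample-size calculations cover the crossover TOST only (no
  parallel designs, no dropout inflation).
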