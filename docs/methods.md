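# Methods

## The problem

Antenatal corticosteroids (ACS, betamethasone) given before an anticipated
preterm birth reduce neonatal mortality and morbidity, but only help when the
birth actually happens soon (the benefit window is about 7 days) and may harm
when the pregnancy continues to term. Coverage alone is therefore a poor
quality indicator; the balancing metrics used here, computed per facility,
are:

* **ACS/34w rate** — among deliveries before 34+0 weeks, the percentage whose
  mothers received ACS (coverage);
* **optimal-ACS/34w rate** — same denominator, restricted to ACS given within
  7 days before delivery (timing);
* **term/ACS proportion** — among all ACS recipients, the percentage
  delivering at term, >= 37+0 weeks (overtreatment);
* **ACS rate among all deliveries** (overall use).

The package implements the full facility-level analysis over a patient-level
perinatal registry: record exclusions, facility-year metrics with outlier
filtering, standardized multivariable models of facility factors, and a
scenario engine projecting what raising coverage would do — plus a synthetic
registry generator so every stage is testable without access to real data.

## Patient-level rules

A record counts as an ACS recipient when the administration checkbox is
ticked *or* a total dose *or* an ACS-to-delivery interval is documented;
registries of this kind under-tick the checkbox, and a documented dose or
interval is unambiguous evidence of receipt. Intervals are categorical
(`<48h`, `48h-7d`, `7d-1mo`, `>1mo`); "optimal" is the union of the two
shortest categories, i.e. a 7-day window.

The exclusion cascade runs in a fixed order — exact-duplicate rows;
stillbirths or perinatal deaths with unknown timing; neonates other than
first-born in multiple pregnancies; rows missing any mandatory field
(parity, infertility treatment, number of fetuses, neonatal sex, maternal
age, gestational age, birth weight, intrapartum blood loss, maternal
survival) — and each record is counted at its first failing step, so counts
depend on the order but the retained set does not. Duplicate means all
fields identical; a key-field subset is configurable. Missing mandatory
fields are treated as entry errors and excluded, never imputed.
Stillbirths with *known* timing are retained; only unknown-timing ones are
excluded (the literal reading of the rule). Gestational age is stored in
total days; "term" is taken as >= 37+0 weeks, the standard obstetric usage,
since no other numeric definition is available.

## Facility filters

Facility-years with fewer than 10 deliveries before 34 weeks are removed
(small denominators make the rates unstable). Facility-year ACS/34w rates
farther than 2.5 median absolute deviations from the median are then removed
as reporting outliers; each facility-year is one observation, pooled across
years. The MAD here is the raw median absolute deviation — no 1.4826
Gaussian-consistency constant — because the filter is defined directly in
MAD units; the constant is exposed as a parameter for anyone who wants the
Gaussian-calibrated version, and a one-sided variant (drop only anomalously
low rates, the signature of under-reporting) is available. Filter order is
fixed: exclusions → volume floor → MAD.

Profiles average each facility's retained years without weighting ("annual
means"): every proportion-based factor is formed per facility-year and then
averaged; undefined rates (zero denominators) are skipped, never counted as
zero. Facilities contributing any number of retained years are kept, with
`n_years_retained` reported.

## Association models

One OLS model per outcome over the facility profiles. Covariates: care level
(Comprehensive Perinatal Care Center vs other — grouped because almost no
facilities are nondesignated), government-designated-city location, annual
deliveries, annual deliveries <34w, the seven complication prevalences among
<34w births (TPL, HDP, preterm PROM, previa, multiple pregnancy, FGR,
abruption), maternal-transfer and cesarean rates among <34w births; the
ACS/34w rate additionally enters the other three models. Continuous
covariates are standardized with the sample SD, so coefficients are
comparable ("pp of outcome per 1 SD"); binary covariates stay 0/1.
De-standardized (per-natural-unit) coefficients are reported alongside:
`slope_per_unit = slope_per_SD / SD`.

Confidence intervals are classical t-based with n − p degrees of freedom and
significance means the 95% CI excludes zero; no robust errors, no weighting
by facility volume or years, and no multiple-testing correction — the
analysis is descriptive, not confirmatory. These were open choices; t-based
classical intervals are the default convention and are configurable in
principle via the statsmodels results object. Variance inflation factors
(1/(1−R²) of each covariate on the rest) are reported per model; all should
stay below 3. The overall-use model unavoidably mixes mathematically
interrelated volume variables; it is fit as specified and flagged through
its VIFs rather than re-specified.

The sensitivity variant drops pregnancies with placental abruption or a
Grade-1 (most urgent) cesarean — cases where there is no opportunity to give
ACS — and rebuilds the *entire* pipeline from the subset before refitting;
metrics are recomputed, not re-filtered. A covariate that becomes
structurally constant under the subset (abruption prevalence is zero
everywhere by construction) cannot be standardized and is dropped from every
model of that run.

## Scenario engine

For a facility with `N` annual deliveries, `n34` of them before 34 weeks,
and baseline coverage `R` (pp), lifting coverage to `R*` (ΔR = R* − R):

```
Δtreated34 = n34 · ΔR / 100                  (exact, rational arithmetic)
Δoptimal34 = n34 · s_opt · ΔR / 100
ΔA         = N · s_all · ΔR / 100
T*         = (A + ΔA) · (p_term + s_term · ΔR) / 100
```

where `A` is baseline recipients overall, `p_term = 100·T/A` the baseline
term share among recipients, and the slopes are the de-standardized
regression coefficients (defaults 11.5/16.3, 1.6/16.3 and 2.0/16.3 pp per
pp — the published per-SD coefficients divided by the 16.3-pp SD of the
ACS/34w rate; fitted slopes can be substituted via
`SimulationSlopes.from_model_fits`). The term-birth delta decomposes into a
part linear in ΔR and the cross term `ΔA · s_term · ΔR / 100`, quadratic in
ΔR: more coverage adds recipients *and* raises the term share among them, so
term-exposed births accelerate as the target rises. Projections are defined
for increases only; rounding to one decimal happens only in the report
layer. The population scenario lifts every facility below the cap (default
80%) to exactly the cap, using each facility's own profile as its baseline,
and sums the deltas.

Risk–benefit translation multiplies a chosen delta by user-supplied absolute
risk differences: benefits (e.g. perinatal death, IVH, developmental delay)
per additional treated-<34w birth — or per optimally timed one, switchable —
and harms (e.g. any mental and behavioral disorder) per additional
term-exposed birth. The benefit denominator defaults to treated-<34w births.
The effect sizes are configuration, not estimates made here.

## Synthetic registry generator

The generator emulates the structure of a tertiary-center-dominated national
perinatal registry, 244 facilities over 2020–2022 by default: lognormal
facility sizes (mean 583.2, SD 335.3 annual deliveries, floored at 50, with
8% year-to-year jitter), a five-stratum gestational-age mix (1.4 / 2.2 /
2.7 / 10.6 / 83.1% for <28, 28–31, 32–33, 34–36, >=37 weeks), and a
facility-level case-mix tilt — a lognormal factor on the preterm strata,
damped against volume with exponent −0.5 so that smaller referral centers
are preterm-heavier — reproducing both the ~6.3% (±~4 pp) share of <34w
births and the published dispersion of per-facility <34w counts.

Complication prevalences among <34w births (TPL 48.8%, HDP 19.2%, preterm
PROM 29.3%, previa 4.8%, multiple 11.4%, FGR 14.3%, abruption 5.9%) vary
between facilities as Beta-distributed propensities whose SDs match the
published between-facility dispersions; per-record flags are Bernoulli given
the facility propensity. Purely record-independent draws would leave only
binomial (~5 pp) between-facility spread, an order less than observed, and
would starve the recovery tests of covariate variance. Transfer and cesarean
rates among <34w births are modeled the same way.

ACS receipt before 34 weeks is logistic: a facility random intercept
(SD 0.63 logits, tuned once so facility-year rates spread ~16 pp) around an
intercept solved so the marginal rate is 63.4%, plus planted slopes on the
facility's *realized* annual-mean factor values — computed exactly the way
the profiles stage computes its covariates. Slopes are specified in pp of
ACS/34w rate per natural unit and converted internally to the logit scale
via `b_logit = slope_pp / (100 · E[p(1−p)])` (Gauss–Hermite quadrature over
the random intercept), so `planted_truth` passes the stated slope through
exactly. Planting on realized rather than latent factors removes
errors-in-variables attenuation: recovery tests measure estimation quality,
not an arbitrary measurement-error level. Late-preterm (34–36w) deliveries
receive ACS at 20%, term deliveries at a Beta-dispersed facility propensity
around 0.93% — values backed out from the published overall-use,
term-exposure and recipient counts. Interval categories are drawn from
stratum-specific mixes (74% within 7 days for <34w recipients, 33%
otherwise, chosen to reproduce the published optimal-timing and pooled
within-7-day figures); dose categories and missingness follow the published
recipient-level distribution. Timing is otherwise independent of covariates —
no timing model is described for the source registry, so none is invented.

Artifact realism: ~0.1% exact-duplicate rows, ~0.3% of rows with one
mandatory field blanked, 0.3% unknown-timing stillbirths, 5% unfilled
checkboxes among recipients, and optional emission of later-born multiple
rows — together these exercise every step of the exclusion cascade. A
recipient whose checkbox, dose *and* interval are all blank (~1 in 10⁴) is
genuinely unobservable, emulating under-reporting.

Reproducibility: a single integer seed spawns one RNG stream per facility,
so facility k's records are invariant to `n_facilities`.

What the generator does **not** model: gestational-age dynamics, tocolysis,
transfer networks, any patient-level joint law between complications and ACS
timing, or year trends. Passing tests show the pipeline recovers structure
that is *planted at the facility level under independence assumptions*; they
cannot show robustness to the confounding patterns of real registry data.

## Recovery harness and problem sizes

The recovery study regenerates 200 independent cohorts at the study scale
(244 facilities × 3 years, ~420k records each), plants one TPL slope of the
magnitude seen in the real analysis (0.27 pp/pp ≈ 4.4 pp per SD), runs the
full pipeline, and refits the coverage model. The MAD filter is disabled in
this harness: on a clean synthetic cohort the raw-MAD 2.5 rule truncates
roughly the outer 9% of a smooth outcome distribution, which mechanically
attenuates any slope; the filter exists to remove reporting artifacts that
the clean generator does not produce. Acceptance requires the mean estimate
within 10% of the planted slope, CI coverage in [90%, 99%], and sign
recovery in >= 95% of replicates; the suite runs this once (about two
minutes) and shares the result between tests.

The deposited data behind the real analysis are facility-level aggregates;
they are not redistributable here, so a deterministic *synthetic* stand-in
table (`facility_table.synthetic_file_s1`) encodes the published cohort
aggregates as construction constraints (Beta/lognormal quantile shapes,
exact moment matching, and a pairing calibration for the 80%-cap scenario
identities). Tests against it verify the descriptive and population-scenario
arithmetic on realistic inputs; they are not a recovery of the real table.

## Numerical choices and degenerate inputs

Zero-denominator rates are NaN and excluded from means. A MAD of zero
excludes exactly the off-median values; an infinite multiplier excludes
nothing. The treated-<34w delta uses `fractions.Fraction`, so integer inputs
give drift-free deltas. Zero-variance continuous covariates raise by name in
`standardize_design`; rank-deficient designs raise listing the collinear
columns (infinite VIFs are reported as such). Scenario targets below
baseline raise rather than extrapolate downward, and targets above 90% are
untested territory — the published histogram has almost no mass there.

## Known limitations

* Facility factors are modeled independent of each other (no correlation
  between, say, TPL prevalence and transfer rate beyond the volume link).
* The ACS model is a single random intercept plus planted slopes; real
  between-facility variation is surely richer.
* Effect sizes for the risk–benefit translation must come from outside.
* The scenario engine is a linear(–quadratic) extrapolation of
  cross-sectional associations; it carries no causal claim and no
  uncertainty intervals.
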