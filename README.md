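# acsbalance

Facility-level analysis of antenatal corticosteroid (ACS) use in a perinatal
registry: coverage, timing and overtreatment metrics per facility,
standardized multivariable models of the facility factors that move them, and
scenario projections of what raising coverage would do — for perinatal
epidemiologists and quality-improvement teams working with registry data.

ACS (betamethasone) matures fetal lungs before preterm birth, but only helps
when given within about 7 days of delivery, and pregnancies that continue to
term after exposure may be harmed. Coverage alone is therefore not a quality
measure. The package computes, per facility and year, the four balancing
metrics in standard use:

* **ACS/34w rate** — recipients among deliveries before 34+0 weeks (coverage);
* **optimal-ACS/34w rate** — recipients <34w treated within 7 days before
  delivery (timing);
* **term/ACS proportion** — term deliveries among all recipients
  (overtreatment);
* **ACS rate among all deliveries** (overall use);

applies the registry exclusion cascade with a full audit log, filters
unstable facility-years (<10 births before 34 weeks) and outliers (rates
beyond 2.5 raw median absolute deviations from the median), fits one
standardized OLS model per metric (coefficients in pp per SD, t-based 95%
CIs, VIF diagnostics), and projects coverage-increase scenarios in which

```
Δtreated34 = n34·ΔR/100          Δoptimal34 = n34·s_opt·ΔR/100
ΔA         = N·s_all·ΔR/100      T*         = (A+ΔA)(p_term + s_term·ΔR)/100
```

so the term-exposed count T grows with a component quadratic in ΔR. A
synthetic registry generator with planted facility-level structure stands in
for real data and makes every stage testable end to end.

## Worked example

```python
import acsbalance as ab
from acsbalance import models
from acsbalance.scenario import ScenarioBaseline, SimulationSlopes, simulate_facility

# synthetic cohort: 244 facilities x 3 years, planted TPL association
reg = ab.generate_registry(ab.RegistryConfig(seed=20201))
profiles, log = ab.profiles_from_records(reg.records, reg.attributes)
print(log.exclusions)

fit = models.fit_outcome_model(profiles, models.ModelSpec(outcome="acs34_rate"))
print(fit.table.loc["tpl", ["coef", "ci_low", "ci_high", "raw_coef"]].astype(float))

# a typical facility (500 deliveries/yr, 30 before 34w) lifted from 60% to 80%
slopes = SimulationSlopes.from_standardized(11.5, 1.6, 2.0, sd_r=16.3)
base = ScenarioBaseline(N=500, n34=30, R=60, treated34=18, optimal34=14, A=40, T=5)
res = simulate_facility(base, slopes, 80.0)
print(f"+{res.d_treated34:.1f} treated <34w, +{res.d_optimal34:.1f} optimally "
      f"timed, +{res.d_term:.1f} term-exposed")
```

prints (abridged):

```
records in: 424770
  excluded (duplicates): 442
  excluded (unknown timing death): 1308
  excluded (non first born multiple): 0
  excluded (missing mandatory field): 1239
retained: 421781
coef        3.034783
ci_low      1.291104
ci_high     4.778462
raw_coef    0.188962
+6.0 treated <34w, +4.2 optimally timed, +2.4 term-exposed
```

The TPL coefficient says: one SD more threatened-preterm-labor prevalence is
associated with a ~3 pp higher ACS/34w rate in this cohort (CI excluding
zero — the generator planted a positive slope). The scenario line says a
facility lifting coverage by 20 pp treats 6 more <34w pregnancies per year,
4.2 of them optimally timed, at the price of 2.4 more term-exposed births.

## Analysis drivers

Numbered scripts reproduce the whole analysis over the synthetic cohort,
writing tables (and forest plots) under `results/`:

```
python analysis/01_simulate_registry.py     # generate the cohort
python analysis/02_build_metrics.py         # exclusions, metrics, filters, profiles
python analysis/03_fit_models.py            # four outcome models + sensitivity
python analysis/04_scenarios.py             # scenario projections + risk-benefit
```

`03` and `04` accept `--facility-table <tsv>` to ingest an externally
supplied facility-level aggregate table directly, bypassing the
patient-level stages (column layout in `docs/column_dictionary.md`).

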