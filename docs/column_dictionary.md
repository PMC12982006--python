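# Registry column dictionary

One row per first-born neonate per delivery. Delimited text (TSV by default,
CSV accepted), UTF-8, empty cell = missing. Enumerations are closed; rows
with values outside them are rejected at read time with the row number and
field name.

| column | type | values / units | notes |
|---|---|---|---|
| `facility_id` | string | opaque id | maps to exactly one care level and city flag |
| `year` | int | calendar year | |
| `gestational_age_days` | float | total days, >= 154 (22+0 weeks) | mandatory; `<34w` means `< 238`, term means `>= 259` |
| `birth_order` | int | 1 = first-born | later-born rows of multiples are excluded by the cascade |
| `n_fetuses` | float | >= 1 | mandatory; `> 1` iff `multiple` = 1 |
| `stillbirth_status` | enum | `livebirth`, `stillbirth_known_timing`, `unknown_timing` | `unknown_timing` rows are excluded |
| `parity` | float | count | mandatory |
| `infertility_treatment` | float | 0/1 | mandatory |
| `neonatal_sex` | enum | `M`, `F` | mandatory |
| `maternal_age` | float | years | mandatory |
| `birth_weight` | float | grams | mandatory |
| `blood_loss` | float | mL intrapartum | mandatory |
| `maternal_survival` | float | 0/1 | mandatory |
| `tpl`, `hdp`, `pprom`, `previa`, `multiple`, `fgr`, `abruption` | int | 0/1 | complication flags |
| `transfer_in` | int | 0/1 | maternal transfer received |
| `cesarean` | int | 0/1 | |
| `cesarean_grade1` | int | 0/1 | most urgent emergency cesarean; implies `cesarean` = 1 |
| `acs_checkbox` | int | 0/1 | administration checkbox (may be unfilled for true recipients) |
| `acs_dose_mg` | float | 12, 24, 36, 48 or missing | total betamethasone dose |
| `acs_interval` | enum | `<48h`, `48h-7d`, `7d-1mo`, `>1mo` or missing | ACS-to-delivery interval category |

A record counts as an **ACS recipient** when `acs_checkbox` = 1 *or*
`acs_dose_mg` is present *or* `acs_interval` is present. "Optimally timed"
means an interval of `<48h` or `48h-7d` (within 7 days before delivery).

## Facility attributes table

| column | type | values |
|---|---|---|
| `facility_id` | string | matches the registry |
| `care_level` | enum | `comprehensive`, `regional`, `nondesignated` |
| `in_designated_city` | int | 0/1 government-designated city |

## Facility-level aggregate table (external ingestion)

`facility_id`, `n_total`, `n_lt34` (annual means), `acs34_rate`,
`optimal34_rate`, `term_acs_prop`, `acs_all_rate` (percent). This format
bypasses the patient-level stages for descriptive summaries and population
scenarios.
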