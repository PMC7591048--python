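# Data dictionary

Columns of the respondent-level survey table produced by
`econstress.simulate.generate` (one row per respondent).

## Identification and design

| column | type | values | meaning |
|---|---|---|---|
| `id` | int | unique | respondent identifier |
| `country` | str | IT, ES, UK | survey country |
| `gender` | str | F, M | gender |
| `age` | int | 18–75 | age in years |
| `region` | str | country-specific | macro-region of residence (4 for IT, 5 for ES/UK) |
| `arm` | str | control, T1, T2, direct | randomized questionnaire arm |
| `item_count` | int (nullable) | 0–4 control, 0–5 T1/T2 | number of statements agreed with; missing in the direct arm |

## Direct-arm answers (missing outside the direct arm)

| column | meaning |
|---|---|
| `direct_globalization` | agrees "globalization has benefitted most of the population" |
| `direct_immigration` | agrees "immigration is a threat for our lifestyle" |
| `direct_health_workers` | agrees "health professionals are facing the largest risk" |
| `direct_experts` | agrees "government should always follow the experts" |
| `direct_stmt1` | admits agreement with sensitive statement 1 (economy focus) |
| `direct_stmt2` | admits agreement with sensitive statement 2 (way-out communication) |

## Socio-economic covariates

| column | type | meaning |
|---|---|---|
| `income_category` | ordinal 1–7 | household income band |
| `unemployed` | 0/1 | in search of a job |
| `married` | 0/1 | marital status |
| `homeowner` | 0/1 | dwelling owned and fully paid |
| `living_area` | int | home useful living area, m² |
| `household_size` | int | people in home |
| `children_school` | int | children of school age |
| `education` | ordinal 1–5 | educational level |
| `buffer_stock` | ordinal 1–5 | how long bills could be covered after a job loss |
| `stress_events` | int 0–8 | negative events in the previous week (sum of 8 flags) |
| `income_loss` | 0/1 | wage/earnings negatively affected since the outbreak |

## Mental health (1–4 each: <1 day / 1–2 / 3–4 / 5–7 days last week)

`mh1`–`mh8`: felt down or hopeless; little interest or pleasure; nervous or
anxious; sleep trouble; felt a failure; concentration trouble; physical
reaction thinking of the outbreak; tired or little energy.

## Exposure item blocks

| block | columns |
|---|---|
| susceptibility | `diabetes`, `hypertension`, `asthma`, `cardio`, `cancer` (0/1 comorbidities); `poor_health` (ordinal 1–5, higher = worse self-rated health); plus `age` at scoring time |
| vulnerability | `vuln_work`, `vuln_care`, `vuln_shop`, `vuln_crowding`, `vuln_transport` (ordinals 1–4, factors preventing full quarantine compliance) |
| behaviour | `contacted_doctor`, `contacted_authority`, `sought_test`, `got_tested` (0/1) |

## Population margins table

Columns `country`, `gender`, `age_band` (18-35 / 36-55 / 56-75), `region`,
`count` (population in the cell); counts per country sum to the configured
18–75 population total.
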