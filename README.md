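# tortuga

Recording, validation and data-quality auditing for marine-turtle
nesting-beach surveys.

Many beach-monitoring programmes still record nightly patrol data on paper
forms and type them into a spreadsheet afterwards. That transcription step
injects three characteristic error classes into the season database:

1. **missing values** in fields every analysis needs — the nest's GPS
   position, the time of the record, the recorder's name, the nest id;
2. **variant text** — the same recorder or the same false-crawl reason
   spelled a dozen ways, which must be standardized by hand before any
   statistics can be run;
3. **inconsistent data** — an egg total that does not equal the sum of its
   partial counts (incubated + yolkless + multiyolked), or coordinates that
   fall outside the survey region.

`tortuga` is a headless re-implementation of a dedicated field-entry
workflow that prevents those errors at the moment of entry (mandatory
fields, auto-filled date/time, auto-generated unique nest tags, choice
lists, weather replicated across the night's records, egg-partition and
coordinate-range checks), plus an **audit** that quantifies exactly those
error classes in legacy datasets, and a **deterministic generator** of
clean and error-injected seasons for benchmarking data-cleaning pipelines.

The package is organised around:

- a **field registry** — the census of the entry software's 116 fields
  feeding 104 logical variables across its windows (login, beach, weather,
  five record branches, save), with entry types, units, choices, mandatory
  flags and analysis-category tags;
- typed **records** (turtle, nest pre-hatch, relocation, excavation, crawl)
  and a **session** that refuses to save a record violating a safeguard;
- the window **workflow** state machine (no record branch reachable before
  the weather window; saving mandatory before the next record);
- the **audit**, whose report gives per-field counts and *union-counted*
  totals (a record with several errors counts once), percentages to one
  decimal, error-free and per-person statistics;
- the **synth** module: clean seasons and an error injector whose audited
  counts equal the injection recipe exactly, including two built-in
  fixtures reconstructing a benchmark comparison — a 561-record
  paper-forms season (3 recorders) and a 171-record software season
  (1 recorder).

Excavation success rates use the standard nest-inventory formulas, with
clutch size reconstructed as shells + undeveloped + unhatched + predated:

    hatching success   = 100 · shells / clutch
    emergence success  = 100 · (shells − live-in-nest − dead-in-nest) / clutch

so emergence success never exceeds hatching success.

## Worked example

```python
import tortuga as tg

report = tg.audit(tg.builtin_fixture("akumal2016_paper"))
print(report.to_text())
```

prints

```
Audit of akumal2016_paper
Total records: 561  (field effort: 3 people)

1. Missing value for relevant fields:
   nest_gps: 176  31.4%
   record_time: 53  9.4%
   user_name: 5  0.9%
   nest_tag: 1  0.2%
   Total (union): 225  40.1%
2. Different answers for the same value:
   user_name: 49  8.7%
   false_crawl_reason: 6  1.1%
   Total (union): 55  9.8%
3. Inconsistent data:
   egg_sum_mismatch: 2  0.4%
   gps_out_of_range: 3  0.5%
   Total (union): 5  0.9%

Records with errors (union): 262  46.7%
Records without errors: 299  53.3%
Records without errors per person: 99.7
```

Reading the numbers: 225 of 561 records (40.1%) lack at least one relevant
field; 55 (9.8%) carry a variant spelling; 5 (0.9%) are internally
inconsistent. Because 23 of the variant records also miss their GPS
position and 10 records miss both GPS and time, the union of all three
classes is 262 records (46.7%), leaving 299 error-free — 99.7 per
recorder. The software-produced season shows only the ten manually-typed
GPS positions missing:

```python
sw = tg.audit(tg.builtin_fixture("akumal2016_software"))
sw.missing_union        # Stat(count=10, percent=5.8)
sw.error_free           # Stat(count=161, percent=94.2)
```

Success rates on an excavation record:

```python
rec = tg.ExcavationRecord(nest_tag="HMB-001", n_shells=80,
                          n_undeveloped=10, n_unhatched=10,
                          n_live_in_nest=5, n_dead_hatchlings=3)
tg.hatch_success(rec)       # 80.0
tg.emergence_success(rec)   # 72.0
```

## Command line

```
tortuga synth --builtin akumal2016_paper --out paper.csv
tortuga audit paper.csv --out reports/     # exit code 0 only if error-free
tortuga record --user "Lucia Mar" --beach "Half Moon Bay" --out night.json
tortuga export night.json --out night.csv
tortuga validate night.csv
```

`audit` exits 0 only when the dataset is error-free, so it can gate a data
pipeline. `record` walks the window workflow interactively (answers can be
piped in for scripted use) and refuses weather-less or incomplete records
in strict mode (`--permissive` relaxes only the weather gate).

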