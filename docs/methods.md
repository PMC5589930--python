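# Methods

## The data model

A season database is a flat table: one row per record (one turtle, nest,
relocation, excavation or crawl event), one column per logical variable,
plus bookkeeping columns (`record_id`, `record_category`, `recorder`).
Cells are kept as text end to end; numeric interpretation happens at audit
time. This is deliberate: the audit's subject matter is exactly the messy
cell content (blank markers, variant spellings, unparseable numbers), so
the containers must never normalize it away on load.

### The field registry

The bundled registry (`data/registry.json`) is the census of the entry
software's interface: 116 entry fields across 24 windows, of seven entry
types — multiple buttons (4), checkboxes (11), drop boxes (25), list boxes
(2), auto-filled fields (6), typed numbers (46) and typed text (22). The
selection/pre-filled types together are 48/116 = 41% of fields (rounded to
integer, ties away from zero), typed numbers 40%, free text 19%.

The 116 fields feed 104 distinct variables. The twelve shared-variable
fields are:

- curved carapace length, curved carapace width and track width are each
  entered three times (measurement-triplicate practice), +6;
- the nest tag is entered once at nest creation and re-selected from list
  boxes when the nest is moved or excavated, +2;
- the auto-filled record date appears in both the turtle and the nest
  branch, +1;
- the nest latitude/longitude are re-entered on relocation, +2;
- the species is selected in the turtle window and again for hatchlings at
  excavation, +1.

Each field carries the analysis categories it belongs to. Windows 2
(beach), 3 (weather) and 5 (save) are tagged with all four completeness
categories; each record branch carries its own. The resulting per-category
field totals are 23 (crawl), 57 (turtle seen), 49 (nest seen) and
22 (nest moved). Which fields compose these totals is an editorial
choice — the category membership of shared windows is not externally
pinned — and the chosen assignment is the one that makes the totals come
out at those values.

The two list boxes (nest-tag selection) carry the sentinel choice
`"@season_nest_tags"`: their choice list is dynamic (the tags issued so
far this season), not a fixed vocabulary.

### Records and in-entry safeguards

`Session.add_record` enforces, in order:

1. **weather gate** — a strict session refuses any record before a weather
   block is set (the permissive flag relaxes exactly this check and
   nothing else; the navigation machine itself is always strict);
2. **auto-fill** — missing date/time are stamped from an injectable clock,
   so tests and replays are deterministic;
3. **mandatory fields** — the record's windows are looked up in the
   registry and every mandatory variable must be non-empty (the error
   lists the offending field ids);
4. **reference resolution** — relocations and excavations must name a tag
   known to the session or its season store;
5. **tag uniqueness** — a nest record may not reuse a tag already used
   this season (auto-generated tags skip past any registered tag, so the
   sequence `HMB-001, HMB-002, …` never collides even with manual entries
   interleaved).

Nest tags follow `{BEACH_CODE}-{NNN}` with three-digit zero padding and
beach codes HMB/AKB/JDB/SAK for the four default beaches; only the
"location code + number" shape is externally fixed, the padding width is a
package choice.

Weather is recorded once per night and replicated onto each record: every
record receives the latest block recorded at or before its timestamp
(records predating every block get the first). Mid-night updates therefore
apply only from their timestamp onward.

### Success rates

The excavation formulas reconstruct clutch size from the inventory:
`clutch = shells + undeveloped + unhatched + predated`. Hatching success
is `100·shells/clutch`; emergence success is
`100·(shells − live-in-nest − dead-in-nest)/clutch`. Predated counts sit
in the denominator only — a predated egg was part of the clutch but never
produced a counted shell. An empty inventory (`clutch = 0`) makes both
rates undefined and raises rather than returning a silent 0/100; a
live+dead count exceeding shells is rejected as impossible. These choices
make `0 ≤ emergence ≤ hatching ≤ 100` a theorem, which the property tests
assert.

### Coordinates

The audit's bounding box is a closed box in WGS84 decimal degrees,
defaulting to the Akumal area (20.33–20.43 °N, 87.20–87.40 °W);
dataset-supplied bounds override it. UTM input (e.g. zone 16Q from a
handheld GPS) is converted with the classic truncated transverse-Mercator
series, accurate to well under a metre within a zone — negligible against
a beach-scale box. The inverse is cross-checked in tests against an
independent meridian-arc integration oracle, and forward/inverse
round-trips close to 1e-8 degrees. Boundary points count as in-range
(closed-box convention).

## The audit

Rules, applied row-wise over the text cells:

- **missing**: a cell is missing when its stripped, case-folded value is a
  marker (default `"" , "-", "?", "NA", "N/A"`; the marker set is
  configurable because legacy sheets mark blanks inconsistently). A
  relevant field spanning several columns (the GPS position = latitude +
  longitude) is missing when *any* constituent is. An absent column counts
  as missing for every row.
- **variant text**: alias-map driven. Comparison is case-insensitive and
  whitespace-collapsed; a cell equal to a canonical value is never
  flagged; a cell matching a listed variant is; anything else goes to an
  `unmapped` side channel rather than being silently dropped. Detection is
  exact-match by design — edit-distance suggestions exist
  (`suggest_aliases`, stdlib difflib) but are advisory and never applied.
  A record missing a field cannot simultaneously be a variant of it.
- **inconsistent**: the egg-partition check flags a row only when the
  clutch is marked complete and all four counts parse
  (`total ≠ incubated + yolkless + multiyolked` ⇒ mismatch; partial
  clutches and absent counts are `not_applicable`, not errors). The
  coordinate check flags present-but-out-of-box positions, and
  present-but-unparseable ones (a coordinate that is there but is not a
  number is inconsistent data, not a missing value).

Each class reports per-field/per-rule counts and a **union** of record
ids; the three unions combine into the any-error union, so a record with
five problems counts once at every level. `error_free = total − any_error`
by construction. Percentages are `100·count/total` rounded to **one
decimal, halves away from zero** — this convention reproduces every
benchmark percentage (e.g. 53/561 → 9.4, 161/171 → 94.2). Per-person
statistics divide by the number of distinct recorders (the bookkeeping
column when present, otherwise distinct canonical names after alias
resolution). An empty dataset reports zero counts with `None` percentages
rather than dividing by zero.

The vectorized audit is checked against a deliberately naive per-row
re-derivation (an independent oracle in the test suite) on 50-row
datasets, and is idempotent and invariant under row permutation.

## The synthetic generator

`generate_clean_season` emulates a nesting-season database: records drawn
from a category mix (largest-remainder apportionment, or exact counts),
recorders assigned round-robin, patrol times between 21:00 and 04:30,
dates across June–July 2016, positions uniform in an inset of the regional
box, unique per-beach nest tags, egg partitions generated consistent, and
canonical spellings everywhere — so a clean season audits to zero errors
by construction. Optional fields are filled with plausible values
(documented numeric ranges, registry choice lists) at a per-category
probability tuned so mean filled-field counts approximate the
`completeness_targets`; every record carries the audit-relevant fields
because the audit treats them as universally expected.

What it does **not** emulate: nesting phenology, species composition,
spatial clustering, inter-recorder behaviour differences, or any
turtle-biology signal. Passing tests therefore demonstrate the *audit
machinery* and the *recording safeguards*, not ecological realism, and
field-completeness means on real data (which depend on unavailable raw
records) are not reproduced — only the error-count structure is.

`inject_errors` plants a recipe exactly: per-field missing counts with
explicit joint-miss directives, variant counts with an explicit
`overlap_with_missing`, and per-rule inconsistency counts placed disjoint
from everything else. Placement walks a seeded shuffled deck of rows with
eligibility filters (a user-name variant needs a present canonical user
cell; an egg mismatch needs a complete, fully-counted nest row), so
`audit ∘ inject = recipe` holds exactly — the round-trip property is
tested over 100 randomized recipes. `check_feasible` rejects recipes whose
implied unions cannot fit the dataset, naming the violated constraint; its
arithmetic is verified against a brute-force placement enumerator at tiny
n. The placement itself can additionally fail (and says why) when category
eligibility runs out even though the arithmetic fits.

### The built-in fixtures

`akumal2016_paper` — 561 records, 3 recorders, category split 146 crawl /
150 turtle / 180 nest / 25 relocation / 60 excavation, paper-forms
completeness targets; recipe: missing GPS 176, time 53, user 5, nest id 1
with 10 rows missing both GPS and time (union 225); user-name variants 49
of which 23 on rows already missing GPS, false-crawl-reason variants 6;
egg mismatches 2 and out-of-range positions 3 disjoint from the rest.
Union arithmetic: 225 + (55 − 23) + 5 = 262 records with any error, 299
error-free, 99.7 per recorder.

`akumal2016_software` — 171 records, 1 recorder, software completeness
targets; recipe: 10 missing GPS positions (manual coordinate entry being
the one step the entry software did not automate) and nothing else.

The benchmark tables publish only marginals and unions, not the joint
distribution of errors over records; the fixtures' overlap directives are
one documented placement satisfying every published marginal and union.
Category split and recorder names are likewise editorial (the published
per-recorder means are not integer-consistent with any single split).
Audited counts are invariant to the fixture seed — the seed moves *which*
rows carry an error, never *how many*.

## Numerical and design choices

- one-decimal rounding, halves away from zero (`round1`), integer shares
  ties-away (`type_share_percent`);
- sample standard deviation (ddof = 1) for category statistics; a
  single-record category reports sd 0.0 by convention;
- record categories: the four completeness categories plus
  `NEST_EXCAVATED` for post-hatch rows, which the completeness tables do
  not cover;
- CSV (UTF-8, RFC-4180 quoting) as the interchange format, dates ISO-8601
  on output; dialect-driven input tries date formats in order and fixes
  decimal separators only on number-typed columns;
- the paper-forms reader keeps a lossless `raw` layer; marker
  normalization touches only the working table, and the audit of a raw
  dialect file equals the audit of its normalized form (tested);
- the workflow machine is the strict navigation variant: backing out of
  the first branch window abandons the selection, deeper backs step one
  window, and the crawl window can chain directly into the nest branch
  (implicitly completing the crawl box);
- all randomness flows from explicit integer seeds through
  `numpy.random.default_rng`.

Problem sizes in the test suite are kept at desk scale as a package
choice: the shared round-trip season has 200 records, brute-force oracle
comparisons run at 50, the full benchmark fixtures at their natural 561
and 171.

## Known limitations

- Variant detection recognizes only listed aliases; unlisted spellings
  are surfaced as unmapped, not flagged, so the audit's variant counts are
  lower bounds on real-world drift unless the alias map is curated.
- The egg-partition rule trusts the `clutch_complete` flag; a mislabeled
  partial clutch hides a genuine mismatch.
- The coordinate check is a bounding box, not a coastline: a point in the
  sea but inside the box passes.
- Login is a stub (identification accepted as configuration); credential
  management is out of scope, as are GUI rendering, live GPS capture and
  PIT-reader integration.
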