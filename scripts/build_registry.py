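"""Dev script: emit src/tortuga/data/registry.json (the bundled field census).

Run from repo root:  python scratch/build_registry.py
"""
import json
from pathlib import Path

SPECIES = [
    "Dermochelys coriacea",
    "Eretmochelys imbricata",
    "Chelonia mydas",
    "Caretta caretta",
    "Lepidochelys kempii",
    "Lepidochelys olivacea",
]
BEACHES = ["Half Moon Bay", "Akumal Bay", "Jade Bay", "South Akumal"]
TAG_KINDS = ["Monel", "Inconel", "plastic", "PIT"]
FLIPPERS = [
    "front left flipper",
    "front right flipper",
    "rear left flipper",
    "rear right flipper",
]
YN = ["yes", "no"]
ALL4 = ["CRAWL_ANY", "TURTLE_SEEN", "NEST_SEEN", "NEST_MOVED"]

FIELDS = []


def f(field_id, label, window, etype, *, var=None, unit="", choices=None,
      mandatory=False, cats=()):
    FIELDS.append({
        "field_id": field_id,
        "label": label,
        "window_id": window,
        "entry_type": etype,
        "variable_id": var or field_id,
        "unit": unit,
        "choices": list(choices or []),
        "mandatory": bool(mandatory),
        "categories": list(cats),
    })


# ---- window 1: Login -------------------------------------------------------
f("user_name", "User identification", "1", "text", mandatory=True)
f("password", "Password code", "1", "text", mandatory=True)

# ---- window 2: Beach details ----------------------------------------------
f("beach_name", "Beach", "2", "drop_box", choices=BEACHES, mandatory=True,
  cats=ALL4)
f("sector", "Beach sector", "2", "drop_box",
  choices=["1", "2", "3", "4", "5", "6", "7"], cats=ALL4)
f("beach_length_m", "Beach length", "2", "number", unit="m", cats=ALL4)
f("n_sectors", "Number of sectors", "2", "number", cats=ALL4)
f("patrol_team_size", "People on patrol", "2", "number", cats=ALL4)
f("area_name", "Area name", "2", "text", cats=ALL4)
f("access_point", "Access point", "2", "text", cats=ALL4)
f("beach_references", "References", "2", "text", cats=ALL4)
f("beach_notes", "Notes on the beach", "2", "text", cats=ALL4)

# ---- window 3: Weather details --------------------------------------------
f("tide_level", "Tide level", "3", "drop_box",
  choices=["low", "mid", "high"], mandatory=True, cats=ALL4)
f("moon_phase", "Moon phase", "3", "drop_box",
  choices=["new", "first quarter", "full", "last quarter"], mandatory=True,
  cats=ALL4)
f("cloud_cover", "Cloud cover", "3", "drop_box",
  choices=["0-25%", "25-50%", "50-75%", "75-100%"], mandatory=True, cats=ALL4)
f("artificial_light", "Artificial light", "3", "drop_box",
  choices=["none", "weak", "moderate", "strong"], cats=ALL4)
f("human_disturbance", "Human disturbance", "3", "drop_box",
  choices=["none", "man-made obstacle", "human obstacle", "human voices",
           "human presence"], cats=ALL4)
f("wind_state", "Wind", "3", "drop_box",
  choices=["calm", "breeze", "windy"], cats=ALL4)
f("air_temp_c", "Air temperature", "3", "number", unit="degC", cats=ALL4)
f("water_temp_c", "Water temperature", "3", "number", unit="degC", cats=ALL4)
f("weather_notes", "Notes on conditions", "3", "text", cats=ALL4)

# ---- window 4: Select type of record ---------------------------------------
f("record_type", "Type of record", "4", "multiple_buttons",
  choices=["Turtle", "Nest Pre-Hatch", "Nest Moved", "Nest Post-Hatch",
           "Crawl Identification"], mandatory=True)

# ---- windows 4.1.x: Turtle details -----------------------------------------
T = ["TURTLE_SEEN"]
f("species", "Species", "4.1.1", "multiple_buttons", choices=SPECIES,
  mandatory=True, cats=T)

f("flippers_checked", "Flippers and paddles checked", "4.1.2", "checkbox",
  choices=YN, cats=T)
f("scars_present", "Tag scars present", "4.1.2", "checkbox", choices=YN,
  cats=T)
f("fp_disease_present", "Fibropapilloma observed", "4.1.2", "checkbox",
  choices=YN, cats=T)
f("pit_tag_checked", "PIT tag checked", "4.1.2", "checkbox", choices=YN,
  cats=T)
f("new_tag_applied", "New tag applied", "4.1.2", "checkbox", choices=YN,
  cats=T)
f("old_tag_kind", "Old tag kind", "4.1.2", "drop_box", choices=TAG_KINDS,
  cats=T)
f("old_tag_position", "Old tag position", "4.1.2", "drop_box",
  choices=FLIPPERS, cats=T)
f("new_tag_kind", "New tag kind", "4.1.2", "drop_box", choices=TAG_KINDS,
  cats=T)
f("new_tag_position", "New tag position", "4.1.2", "drop_box",
  choices=FLIPPERS, cats=T)
f("tag_condition", "Old tag condition", "4.1.2", "drop_box",
  choices=["good", "corroded", "loose"], cats=T)
f("n_old_tags", "Number of old tags", "4.1.2", "number", cats=T)
f("old_tag_number", "Old tag number", "4.1.2", "text", cats=T)
f("new_tag_number", "New tag number", "4.1.2", "text", cats=T)

f("measuring_tape_type", "Measuring tape", "4.1.3", "drop_box",
  choices=["hard rule", "flexible tape"], cats=T)
f("plastron_condition", "Plastron condition", "4.1.3", "drop_box",
  choices=["intact", "damaged"], cats=T)
f("ptl_cm", "Post-cloacal tail length (PTL)", "4.1.3", "number", unit="cm",
  cats=T)
f("ttl_cm", "Total tail length (TTL)", "4.1.3", "number", unit="cm", cats=T)

for i in (1, 2, 3):
    f(f"ccl_cm_{i}", f"CCL measurement {i}", "4.1.4", "number", var="ccl_cm",
      unit="cm", cats=T)
for i in (1, 2, 3):
    f(f"ccw_cm_{i}", f"CCW measurement {i}", "4.1.4", "number", var="ccw_cm",
      unit="cm", cats=T)
for i in (1, 2, 3):
    f(f"track_width_cm_{i}", f"Track width measurement {i}", "4.1.4",
      "number", var="turtle_track_width_cm", unit="cm", cats=T)
f("weight_kg", "Weight", "4.1.4", "number", unit="kg", cats=T)
f("head_length_cm", "Head length", "4.1.4", "number", unit="cm", cats=T)
f("head_width_cm", "Head width", "4.1.4", "number", unit="cm", cats=T)

f("activity", "Turtle activity", "4.1.5", "drop_box",
  choices=["emerging", "digging", "laying", "covering", "camouflaging",
           "returning to sea", "false crawl"], cats=T)
f("health_condition", "Health condition", "4.1.5", "drop_box",
  choices=["good", "injured", "fibropapilloma", "dead"], cats=T)
f("status_after", "Status after leaving the beach", "4.1.5", "drop_box",
  choices=["returned to sea", "remained on beach", "relocated"], cats=T)
f("turtle_record_date", "Date (automatic)", "4.1.5", "autofill",
  var="record_date", mandatory=True, cats=T)
f("turtle_record_time", "Hour (automatic)", "4.1.5", "autofill",
  var="record_time", mandatory=True, cats=T)
f("dna_sample_code", "DNA sample code", "4.1.5", "text", cats=T)
f("distinctive_marks", "Distinctive marks", "4.1.5", "text", cats=T)
f("turtle_notes", "Notes", "4.1.5", "text", cats=T)

# ---- windows 4.2.x: Nest pre-hatch -----------------------------------------
N = ["NEST_SEEN"]
f("nest_beach_code", "Location code for the tag", "4.2.1", "drop_box",
  choices=["HMB", "AKB", "JDB", "SAK"], cats=N)
f("nest_tag_entry", "Nest tag (automatic, editable)", "4.2.1", "number",
  var="nest_tag", mandatory=True, cats=N)

f("nest_record_date", "Date (automatic)", "4.2.2", "autofill",
  var="record_date", mandatory=True, cats=N)

f("nest_beach_name", "Beach where the nest is", "4.2.3", "drop_box",
  choices=BEACHES, cats=N)
f("nest_sector_number", "Beach sector/area", "4.2.3", "number", cats=N)
f("nest_references", "Additional references", "4.2.3", "text", cats=N)

f("nest_latitude", "Nest latitude", "4.2.4", "number",
  unit="decimal degrees", mandatory=True, cats=N)
f("nest_longitude", "Nest longitude", "4.2.4", "number",
  unit="decimal degrees", mandatory=True, cats=N)
f("nest_mark_type", "Type of mark identifying the nest", "4.2.4", "text",
  cats=N)

f("female_present", "Female present", "4.2.5", "checkbox", choices=YN,
  cats=N)
f("female_tagged", "Female carries a tag", "4.2.5", "checkbox", choices=YN,
  cats=N)
f("female_tag_number", "Tag of the female", "4.2.5", "text", cats=N)
f("female_notes", "Notes on the female", "4.2.5", "text", cats=N)

f("clutch_complete", "Complete clutch", "4.2.6", "checkbox", choices=YN,
  cats=N)
f("deposition_time", "Time of deposition (automatic, editable)", "4.2.6",
  "autofill", cats=N)
f("total_eggs", "Total number of eggs laid", "4.2.6", "number", cats=N)
f("n_incubated", "Incubated eggs (with embryos)", "4.2.6", "number", cats=N)
f("n_yolkless", "Yolkless eggs", "4.2.6", "number", cats=N)
f("n_multiyolked", "Multiyolked eggs", "4.2.6", "number", cats=N)

f("beach_position", "Location of the nest along the beach", "4.2.7",
  "drop_box",
  choices=["open sand", "vegetation border", "under vegetation", "dune"],
  cats=N)
f("distance_band", "Distance to high tide mark (band)", "4.2.7", "drop_box",
  choices=["0-5 m", "5-10 m", "10-20 m", ">20 m"], cats=N)
f("sand_temp_c", "Temperature of the sand", "4.2.7", "number", unit="degC",
  cats=N)
f("sand_humidity_pct", "Sand humidity", "4.2.7", "number", unit="%", cats=N)
f("distance_high_tide_m", "Distance to the high tide mark", "4.2.7",
  "number", unit="m", cats=N)
f("depth_top_cm", "Nest depth A (surface to first egg)", "4.2.7", "number",
  unit="cm", cats=N)
f("depth_bottom_cm", "Nest depth B (bottom of egg chamber)", "4.2.7",
  "number", unit="cm", cats=N)

f("disturbances_present", "Disturbances around the nest", "4.2.8",
  "checkbox", choices=YN, cats=N)
f("obstructions_present", "Obstructions around the nest", "4.2.8",
  "checkbox", choices=YN, cats=N)
f("dune_height_m", "Dune height", "4.2.8", "number", unit="m", cats=N)
f("vegetation_type", "Kind of vegetation", "4.2.8", "text", cats=N)

# ---- windows 4.3.x: Nest moved ---------------------------------------------
M = ["NEST_MOVED"]
f("moved_nest_tag", "Nest tag (from list)", "4.3.1", "list_box",
  var="nest_tag", choices=["@season_nest_tags"], mandatory=True, cats=M)
f("new_latitude", "New latitude", "4.3.2", "number", var="nest_latitude",
  unit="decimal degrees", mandatory=True, cats=M)
f("new_longitude", "New longitude", "4.3.2", "number", var="nest_longitude",
  unit="decimal degrees", mandatory=True, cats=M)

# ---- windows 4.4.x: Nest post-hatch (excavation) ----------------------------
f("excavated_nest_tag", "Nest tag (from list)", "4.4.1", "list_box",
  var="nest_tag", choices=["@season_nest_tags"], mandatory=True)

f("hatchling_species", "Species of the hatchlings", "4.4.2", "drop_box",
  var="species", choices=SPECIES)
f("hatch_date", "Hatching date (automatic, editable)", "4.4.2", "autofill")
f("emergence_time", "Time of emergence", "4.4.2", "number", unit="hh.mm")
f("incubation_days", "Incubation period", "4.4.2", "number", unit="days")
f("n_emerged", "Emerged hatchlings", "4.4.2", "number")
f("n_live_in_nest", "Live hatchlings in the nest", "4.4.2", "number")
f("n_undeveloped", "Undeveloped eggs", "4.4.2", "number")
f("n_unhatched", "Unhatched eggs", "4.4.2", "number")
f("n_shells", "Shells", "4.4.2", "number")
f("n_dead_hatchlings", "Dead hatchlings", "4.4.2", "number")
f("n_predated", "Predated eggs/hatchlings", "4.4.2", "number")

f("genetic_samples_taken", "Genetic samples taken", "4.4.3", "checkbox",
  choices=YN)
f("conclusion_date", "Date of conclusion (automatic)", "4.4.3", "autofill")
f("nest_fate", "Fate of the nest", "4.4.3", "text")
f("genetic_sample_codes", "Genetic sample codes", "4.4.3", "text")
f("predator_species", "Predator species (if invaded)", "4.4.3", "text")
f("excavated_by", "Excavated by", "4.4.3", "text")
f("excavation_notes", "Notes", "4.4.3", "text")

# ---- window 4.5.1: Crawl identification -------------------------------------
C = ["CRAWL_ANY"]
f("track_type", "Type of track", "4.5.1", "multiple_buttons",
  choices=["green", "loggerhead", "hawksbill", "other"], mandatory=True,
  cats=C)
f("nest_deposition", "Nest deposition", "4.5.1", "drop_box",
  choices=["Y", "N"], cats=C)
f("false_crawl_reason", "False crawl reason / disturbance factor", "4.5.1",
  "drop_box",
  choices=["obstacle", "artificial light", "human presence", "predator",
           "unknown"], cats=C)
f("crawl_track_width_cm", "Track width", "4.5.1", "number", unit="cm",
  cats=C)

# ---- window 5: Save ----------------------------------------------------------
f("save_action", "Save data", "5", "multiple_buttons",
  choices=["Save", "Continue Collecting Data"], mandatory=True, cats=ALL4)


def main():
    out = Path(__file__).resolve().parents[1] / "src/tortuga/data/registry.json"
    doc = {
        "version": "1.0",
        "notes": (
            "Field census of the nesting-survey entry software: 116 entry "
            "fields feeding 104 logical variables. Shared-variable fields: "
            "CCL/CCW/track-width triplicate measurements, the nest tag "
            "(entered once, re-selected from list boxes when the nest is "
            "moved or excavated), the auto-filled record date in the turtle "
            "and nest branches, the nest coordinates (re-entered on "
            "relocation) and the species (turtle and hatchling windows)."
        ),
        "fields": FIELDS,
    }
    out.write_text(json.dumps(doc, indent=1) + "\n")
    # sanity
    from collections import Counter
    c = Counter(x["entry_type"] for x in FIELDS)
    nvars = len({x["variable_id"] for x in FIELDS})
    cats = Counter(cat for x in FIELDS for cat in x["categories"])
    print(len(FIELDS), nvars, dict(c), dict(cats))


if __name__ == "__main__":
    main()
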