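{
 "relevant_fields": [
  {"name": "nest_gps", "label": "GPS location of the Nest",
   "columns": ["nest_latitude", "nest_longitude"]},
  {"name": "record_time", "label": "Time (hh:mm) of the record",
   "columns": ["record_time"]},
  {"name": "user_name", "label": "User name", "columns": ["user_name"]},
  {"name": "nest_tag", "label": "Nest ID", "columns": ["nest_tag"]}
 ],
 "missing_markers": ["", "-", "?", "NA", "N/A"],
 "region_bounds": {
  "system": "decimal_degrees",
  "lat_min": 20.33, "lat_max": 20.43,
  "lon_min": -87.40, "lon_max": -87.20
 },
 "alias_maps": {
  "user_name": {
   "Aurora Balam": ["A. Balam", "Aurora B.", "Balam", "ABalam", "Aurora Balan"],
   "Carlos Pech": ["C. Pech", "Carlos P.", "Pech", "CPech", "Carlos Peche"],
   "Marisol Canul": ["M. Canul", "Marisol C.", "Canul", "MCanul", "Marisol Kanul"],
   "Lucia Mar": ["L. Mar", "Lucia M.", "LMar"]
  },
  "false_crawl_reason": {
   "obstacle": ["obstacles", "obstruction", "obst."],
   "artificial light": ["lights", "light", "artif. light"],
   "human presence": ["people", "humans", "person present"],
   "predator": ["predators", "pred."],
   "unknown": ["unk", "not known"]
  }
 }
}
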