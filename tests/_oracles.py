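"""Independent, deliberately naive re-derivations used as test oracles.

Everything here scans row by row with plain Python and re-states the
audit rules from first principles; nothing imports the vectorized audit
internals it is checking against.
"""

from __future__ import annotations

import math


def norm(text: str) -> str:
    return " ".join(str(text).strip().split()).casefold()


def naive_audit_counts(df, config) -> dict:
    """Per-row scan re-deriving every flag of the quality audit.

    Returns per-field missing counts, per-column variant counts, per-rule
    inconsistency counts and the three union counts plus the any-error
    union, all by brute force.
    """
    markers = {norm(m) for m in config.missing_markers}

    def missing_cell(row, col):
        if col not in df.columns:
            return True
        return norm(row[col]) in markers

    missing: dict[str, set] = {rf.name: set()
                               for rf in config.relevant_fields}
    variants: dict[str, set] = {}
    incons: dict[str, set] = {"egg_sum_mismatch": set(),
                              "gps_out_of_range": set()}

    for idx, row in df.iterrows():
        for rf in config.relevant_fields:
            if any(missing_cell(row, c) for c in rf.columns):
                missing[rf.name].add(idx)
        for col, amap in config.alias_maps.items():
            if col not in df.columns or missing_cell(row, col):
                continue
            cell = norm(row[col])
            canon = {norm(c) for c in amap}
            vset = {norm(v) for vs in amap.values() for v in vs}
            if cell not in canon and cell in vset:
                variants.setdefault(col, set()).add(idx)
        # egg partition rule, restated from scratch
        egg_cols = ("total_eggs", "n_incubated", "n_yolkless",
                    "n_multiyolked")
        if all(c in df.columns for c in egg_cols + ("clutch_complete",)):
            complete = norm(row["clutch_complete"]) in ("yes", "y", "true",
                                                        "1")
            vals = []
            ok = True
            for c in egg_cols:
                try:
                    vals.append(float(str(row[c]).strip()))
                except ValueError:
                    ok = False
            if complete and ok and vals[0] != vals[1] + vals[2] + vals[3]:
                incons["egg_sum_mismatch"].add(idx)
        # coordinate range rule
        if ("nest_latitude" in df.columns
                and "nest_longitude" in df.columns
                and not missing_cell(row, "nest_latitude")
                and not missing_cell(row, "nest_longitude")):
            b = config.region_bounds
            try:
                lat = float(str(row["nest_latitude"]).strip())
                lon = float(str(row["nest_longitude"]).strip())
                inside = (b.lat_min <= lat <= b.lat_max
                          and b.lon_min <= lon <= b.lon_max)
            except ValueError:
                inside = False
            if not inside:
                incons["gps_out_of_range"].add(idx)

    missing_union = set().union(*missing.values())
    variant_union = set().union(*variants.values()) if variants else set()
    incons_union = set().union(*incons.values())
    return {
        "missing": {k: len(v) for k, v in missing.items()},
        "variants": {k: len(v) for k, v in variants.items()},
        "inconsistent": {k: len(v) for k, v in incons.items()},
        "missing_union": len(missing_union),
        "variant_union": len(variant_union),
        "inconsistent_union": len(incons_union),
        "any_error": len(missing_union | variant_union | incons_union),
    }


def round1_oracle(x: float) -> float:
    """One-decimal rounding, halves away from zero, via decimal."""
    from decimal import Decimal, ROUND_HALF_UP

    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def meridian_arc_latitude(northing_m: float) -> float:
    """Invert the WGS84 meridian arc by numeric integration + bisection.

    Independent oracle for the projection inverse at the central meridian
    (where longitude equals the zone's central meridian exactly).
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    a = 6378137.0
    f = 1 / 298.257223563
    e2 = f * (2 - f)

    def arc(phi):
        val, _ = quad(
            lambda t: a * (1 - e2) / (1 - e2 * math.sin(t) ** 2) ** 1.5,
            0.0, phi)
        return val

    phi = brentq(lambda p: arc(p) - northing_m, 0.0, math.radians(84.0))
    return math.degrees(phi)
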