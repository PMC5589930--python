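import random
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from tortuga.records import (AKUMAL_BOUNDS, Coordinates, CrawlRecord,
                             DuplicateNestTagError, ExcavationRecord,
                             MissingMandatoryError, NestRecord, RegionBounds,
                             RelocationRecord, SeasonStore, TurtleRecord,
                             UnknownNestTagError, WeatherBlock,
                             WeatherNotSetError, add_record,
                             check_coordinates, check_egg_partition,
                             emergence_success, generate_nest_tag,
                             hatch_success, open_session, replicate_weather)


class TickingClock:
    def __init__(self, start="2016-06-01T21:00:00", step_minutes=5):
        self.now = datetime.fromisoformat(start)
        self.step = timedelta(minutes=step_minutes)

    def __call__(self):
        out = self.now
        self.now = self.now + self.step
        return out


def _nest(tag, lat=20.40, lon=-87.31):
    return NestRecord(nest_tag=tag, location=Coordinates(lat=lat, lon=lon))


@pytest.fixture
def session():
    s = open_session("MJ", "Half Moon Bay", TickingClock())
    s.set_weather(WeatherBlock(tide_level="low", moon_phase="full",
                               cloud_cover="0-25%"))
    return s


class TestSession:
    def test_start_time_autofilled_from_clock(self):
        clock = TickingClock("2016-07-01T22:30:00")
        s = open_session("MJ", "Half Moon Bay", clock)
        assert s.start_time == datetime.fromisoformat("2016-07-01T22:30:00")
        assert s.records == []

    def test_empty_user_refused(self):
        with pytest.raises(MissingMandatoryError):
            open_session("", "Half Moon Bay", TickingClock())

    def test_weather_gate_blocks_first_record(self, registry):
        s = open_session("MJ", "Half Moon Bay", TickingClock())
        with pytest.raises(WeatherNotSetError):
            add_record(s, CrawlRecord(track_type="green"), registry)

    def test_permissive_session_skips_weather_gate(self, registry):
        s = open_session("MJ", "Half Moon Bay", TickingClock(), strict=False)
        add_record(s, CrawlRecord(track_type="green"), registry)
        assert len(s.records) == 1

    def test_crawl_record_gets_autofilled_time(self, session, registry):
        rec = CrawlRecord(track_type="green")
        add_record(session, rec, registry)
        assert rec.date == "2016-06-01" and rec.time

    def test_missing_mandatory_lists_field_ids(self, session, registry):
        with pytest.raises(MissingMandatoryError) as err:
            add_record(session, NestRecord(nest_tag="HMB-001"), registry)
        assert {"nest_latitude", "nest_longitude"} <= set(err.value.field_ids)

    def test_relocation_of_unsaved_tag_refused(self, session, registry):
        rec = RelocationRecord(nest_tag="HMB-404",
                               new_location=Coordinates(lat=20.4, lon=-87.3))
        with pytest.raises(UnknownNestTagError):
            add_record(session, rec, registry)

    def test_duplicate_nest_tag_refused(self, session, registry):
        add_record(session, _nest("HMB-001"), registry)
        with pytest.raises(DuplicateNestTagError):
            add_record(session, _nest("HMB-001"), registry)

    def test_timestamps_monotone_with_monotone_clock(self, session,
                                                     registry):
        recs = [CrawlRecord(track_type="green") for _ in range(4)]
        for r in recs:
            add_record(session, r, registry)
        stamps = [f"{r.date}T{r.time}" for r in recs]
        assert stamps == sorted(stamps)


class TestNestTags:
    def test_sequence_matches_counter_oracle(self, session):
        store = SeasonStore()
        tags = [generate_nest_tag(session, "HMB", store) for _ in range(5)]
        assert tags == [f"HMB-{i:03d}" for i in range(1, 6)]
        assert len(set(tags)) == 5

    def test_manual_tag_collision_skipped(self, session):
        store = SeasonStore()
        assert generate_nest_tag(session, "HMB", store) == "HMB-001"
        store.register("HMB-002")  # typed in by hand
        assert generate_nest_tag(session, "HMB", store) == "HMB-003"

    def test_sessions_share_season_uniqueness(self, registry):
        store = SeasonStore()
        s1 = open_session("A", "Half Moon Bay", TickingClock(),
                          season_store=store)
        s2 = open_session("B", "Half Moon Bay", TickingClock(),
                          season_store=store)
        for s in (s1, s2):
            s.set_weather(WeatherBlock(tide_level="low", moon_phase="new",
                                       cloud_cover="0-25%"))
        t1 = generate_nest_tag(s1, "HMB")
        add_record(s1, _nest(t1), registry)
        with pytest.raises(DuplicateNestTagError):
            add_record(s2, _nest(t1), registry)
        assert generate_nest_tag(s2, "HMB", store) != t1


class TestWeatherReplication:
    def test_single_block_shared_by_all_records(self, session, registry):
        for _ in range(3):
            add_record(session, CrawlRecord(track_type="green"), registry)
        pairs = replicate_weather(session)
        assert len(pairs) == 3
        assert all(b is session.weather_history[0] for _, b in pairs)

    def test_mid_night_update_applies_to_later_records(self, registry):
        clock = TickingClock(step_minutes=30)
        s = open_session("MJ", "Half Moon Bay", clock)
        s.set_weather(WeatherBlock(tide_level="low", moon_phase="full",
                                   cloud_cover="0-25%"))
        early = CrawlRecord(track_type="green")
        add_record(s, early, registry)
        s.set_weather(WeatherBlock(tide_level="high", moon_phase="full",
                                   cloud_cover="75-100%"))
        late = CrawlRecord(track_type="green")
        add_record(s, late, registry)
        blocks = {id(rec): b for rec, b in replicate_weather(s)}
        assert blocks[id(early)].tide_level == "low"
        assert blocks[id(late)].tide_level == "high"

    def test_no_records_is_noop(self, session):
        assert replicate_weather(session) == []

    def test_requires_weather(self):
        s = open_session("MJ", "Half Moon Bay", TickingClock())
        with pytest.raises(WeatherNotSetError):
            replicate_weather(s)


class TestEggPartition:
    @pytest.mark.parametrize("args,verdict", [
        ((100, 95, 3, 2, True), "consistent"),
        ((100, 90, 3, 2, True), "mismatch"),
        ((100, 90, None, 2, True), "not_applicable"),
        ((100, 95, 3, 2, False), "not_applicable"),  # partial clutch
    ])
    def test_verdicts(self, args, verdict):
        assert check_egg_partition(*args) == verdict

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            check_egg_partition(100, -1, 3, 2, True)


class TestCoordinateCheck:
    def test_interior_point_in_range(self):
        assert check_coordinates(Coordinates(lat=20.40, lon=-87.31)) == \
            "in_range"

    def test_far_exterior_out_of_range(self):
        assert check_coordinates(Coordinates(lat=0.0, lon=0.0)) == \
            "out_of_range"

    def test_boundary_points_in_range_closed_box(self):
        # closed-box convention, cross-checked against direct inequalities
        b = AKUMAL_BOUNDS
        for lat, lon in [(b.lat_min, -87.3), (b.lat_max, -87.3),
                         (20.4, b.lon_min), (20.4, b.lon_max)]:
            direct = (b.lat_min <= lat <= b.lat_max
                      and b.lon_min <= lon <= b.lon_max)
            verdict = check_coordinates(Coordinates(lat=lat, lon=lon))
            assert direct and verdict == "in_range"

    def test_utm_coordinate_converted_before_check(self):
        # a point near the middle of the Akumal box, given as UTM 16Q
        from tortuga._geo import latlon_to_utm

        e, n, _ = latlon_to_utm(20.39, -87.31, 16)
        coord = Coordinates(system="UTM", easting=e, northing=n, zone="16Q")
        assert check_coordinates(coord) == "in_range"

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            RegionBounds(1.0, 0.0, 0.0, 1.0)


class TestSuccessRates:
    @pytest.mark.parametrize("kw,expected", [
        (dict(n_shells=100), 100.0),
        (dict(n_shells=0, n_unhatched=50), 0.0),
        (dict(n_shells=80, n_undeveloped=10, n_unhatched=10), 80.0),
    ])
    def test_hatch_success(self, kw, expected):
        assert hatch_success(ExcavationRecord(nest_tag="x", **kw)) == \
            pytest.approx(expected)

    def test_emergence_success_example(self):
        rec = ExcavationRecord(nest_tag="x", n_shells=80, n_live_in_nest=5,
                               n_dead_hatchlings=3, n_undeveloped=10,
                               n_unhatched=10)
        assert emergence_success(rec) == pytest.approx(72.0)

    def test_zero_denominator_flagged(self):
        rec = ExcavationRecord(nest_tag="x")
        with pytest.raises(ValueError, match="undefined"):
            hatch_success(rec)
        with pytest.raises(ValueError, match="undefined"):
            emergence_success(rec)

    def test_more_stayers_than_shells_rejected(self):
        rec = ExcavationRecord(nest_tag="x", n_shells=5, n_live_in_nest=4,
                               n_dead_hatchlings=3, n_unhatched=10)
        with pytest.raises(ValueError, match="exceed"):
            emergence_success(rec)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(shells=st.integers(0, 200), undeveloped=st.integers(0, 50),
           unhatched=st.integers(0, 50), predated=st.integers(0, 50),
           live=st.integers(0, 200), dead=st.integers(0, 200))
    def test_emergence_never_exceeds_hatching(self, shells, undeveloped,
                                              unhatched, predated, live,
                                              dead):
        rec = ExcavationRecord(nest_tag="x", n_shells=shells,
                               n_undeveloped=undeveloped,
                               n_unhatched=unhatched, n_predated=predated,
                               n_live_in_nest=live, n_dead_hatchlings=dead)
        denom = shells + undeveloped + unhatched + predated
        if denom == 0 or live + dead > shells:
            return  # outside the operation's precondition
        h = hatch_success(rec)
        e = emergence_success(rec)
        assert 0.0 <= e <= h <= 100.0


class TestEntryFuzz:
    """No call sequence may sneak an invalid record into a session."""

    def test_random_call_sequences_never_corrupt_the_session(self, registry):
        rng = random.Random(20160601)
        for trial in range(30):
            store = SeasonStore()
            session = open_session("MJ", "Half Moon Bay", TickingClock(),
                                   season_store=store)
            weather_set = False
            for _ in range(40):
                op = rng.randrange(6)
                try:
                    if op == 0 and not weather_set and rng.random() < 0.5:
                        session.set_weather(WeatherBlock(
                            tide_level="low", moon_phase="new",
                            cloud_cover="0-25%"))
                        weather_set = True
                    elif op == 1:
                        tag = (generate_nest_tag(session, "HMB")
                               if rng.random() < 0.7
                               else f"HMB-{rng.randrange(5):03d}")
                        nest = NestRecord(
                            nest_tag=tag,
                            location=(Coordinates(lat=20.4, lon=-87.3)
                                      if rng.random() < 0.8 else None))
                        add_record(session, nest, registry)
                    elif op == 2:
                        add_record(session, RelocationRecord(
                            nest_tag=f"HMB-{rng.randrange(8):03d}",
                            new_location=Coordinates(lat=20.4, lon=-87.3)),
                            registry)
                    elif op == 3:
                        add_record(session, CrawlRecord(
                            track_type=rng.choice(["green", ""])), registry)
                    elif op == 4:
                        add_record(session, TurtleRecord(
                            species=rng.choice(["Chelonia mydas", ""])),
                            registry)
                    else:
                        add_record(session, ExcavationRecord(
                            nest_tag=f"HMB-{rng.randrange(8):03d}",
                            n_shells=50), registry)
                except (WeatherNotSetError, MissingMandatoryError,
                        UnknownNestTagError, DuplicateNestTagError):
                    continue
            # saved records must satisfy every safeguard
            assert not session.records or weather_set
            nest_tags = [r.nest_tag for r in session.records
                         if isinstance(r, NestRecord)]
            assert len(nest_tags) == len(set(nest_tags))
            for r in session.records:
                if isinstance(r, (RelocationRecord, ExcavationRecord)):
                    assert r.nest_tag in session.known_tags()
                from tortuga.records import _missing_mandatory

                assert _missing_mandatory(r, registry) == []
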