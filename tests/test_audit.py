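import numpy as np
import pytest

from _oracles import naive_audit_counts, round1_oracle
from tortuga.audit import (AuditConfig, RelevantField, audit,
                           category_field_stats, category_record_counts,
                           find_duplicate_tags, find_inconsistent,
                           find_missing, find_variant_text, round1,
                           suggest_aliases)
from tortuga.synth import (InjectionSpec, SeasonParams, VariantInjection,
                           generate_clean_season, inject_errors)

pytestmark = []


def _row(i, recorder="Aurora Balam", category="CRAWL_ANY", **kw):
    base = {
        "record_id": f"REC-{i:04d}", "record_category": category,
        "recorder": recorder, "user_name": recorder,
        "record_date": "2016-06-05", "record_time": "22:10",
        "nest_tag": f"HMB-{i:03d}", "nest_latitude": "20.40",
        "nest_longitude": "-87.31",
    }
    base.update(kw)
    return base


class TestRounding:
    @pytest.mark.parametrize("x", [0.05, 0.15, 9.44, 9.45, 46.70, 53.3,
                                   99.666, 0.049, 31.37, 5.848])
    def test_matches_decimal_half_up_oracle(self, x):
        assert round1(x) == round1_oracle(x)

    def test_negative_halves_round_away_from_zero(self):
        assert round1(-0.05) == -0.1


class TestFindMissing:
    def test_markers_and_absent_column(self, dataset_factory, config):
        ds = dataset_factory([
            _row(1, nest_latitude="-"),
            _row(2, record_time="NA"),
            _row(3, user_name="  "),
            _row(4),
        ])
        ds.df = ds.df.drop(columns=["nest_tag"])
        sets = find_missing(ds, config)
        assert sets["nest_gps"] == {0}
        assert sets["record_time"] == {1}
        assert sets["user_name"] == {2}
        assert sets["nest_tag"] == {0, 1, 2, 3}  # absent column

    def test_multicolumn_field_missing_if_any_part_is(self, dataset_factory,
                                                      config):
        ds = dataset_factory([_row(1, nest_longitude="?")])
        assert find_missing(ds, config)["nest_gps"] == {0}

    def test_clean_dataset_has_empty_sets(self, dataset_factory, config):
        ds = dataset_factory([_row(i) for i in range(4)])
        assert all(not s for s in find_missing(ds, config).values())


class TestVariantText:
    def test_variants_flagged_canonicals_not(self, dataset_factory, config):
        ds = dataset_factory([
            _row(1, user_name="A. Balam"),        # listed variant
            _row(2, user_name="aurora  balam"),   # canonical, messy case
            _row(3, user_name="Carlos Pech"),
            _row(4, user_name="Nobody Known"),    # unmapped
            _row(5, user_name="-"),               # missing, not variant
        ])
        scan = find_variant_text(ds, "user_name",
                                 config.alias_maps["user_name"])
        assert scan.flagged == {0}
        assert scan.unmapped == {3}

    def test_disjoint_alias_maps_enforced(self):
        with pytest.raises(ValueError, match="maps to both"):
            AuditConfig(
                relevant_fields=[RelevantField("x", ("x",))],
                alias_maps={"u": {"A": ["ab"], "B": ["ab"]}},
            )

    def test_all_canonical_dataset_unflagged(self, dataset_factory, config):
        ds = dataset_factory([_row(i) for i in range(3)])
        scan = find_variant_text(ds, "user_name",
                                 config.alias_maps["user_name"])
        assert scan.flagged == set() and scan.unmapped == set()


class TestInconsistent:
    def test_egg_mismatch_and_gps_range(self, dataset_factory, config):
        ds = dataset_factory([
            _row(1, category="NEST_SEEN", total_eggs="100", n_incubated="95",
                 n_yolkless="3", n_multiyolked="2", clutch_complete="yes"),
            _row(2, category="NEST_SEEN", total_eggs="100", n_incubated="90",
                 n_yolkless="3", n_multiyolked="2", clutch_complete="yes"),
            _row(3, category="NEST_SEEN", total_eggs="100", n_incubated="90",
                 n_yolkless="3", n_multiyolked="2", clutch_complete="no"),
            _row(4, nest_latitude="0.0", nest_longitude="0.0"),
            _row(5, nest_latitude="20.40x", nest_longitude="-87.31"),
        ])
        sets = find_inconsistent(ds, config)
        assert sets["egg_sum_mismatch"] == {1}
        assert sets["gps_out_of_range"] == {3, 4}

    def test_clean_dataset_empty(self, dataset_factory, config):
        ds = dataset_factory([_row(i) for i in range(3)])
        assert all(not s for s in find_inconsistent(ds, config).values())


class TestDuplicateTags:
    def test_repeated_creation_tag_reported(self, dataset_factory):
        ds = dataset_factory([
            _row(1, category="NEST_SEEN", nest_tag="HMB-001"),
            _row(2, category="NEST_SEEN", nest_tag="HMB-001"),
            _row(3, category="NEST_MOVED", nest_tag="HMB-001"),  # reference
            _row(4, category="NEST_SEEN", nest_tag="HMB-002"),
        ])
        dupes = find_duplicate_tags(ds)
        assert set(dupes) == {"HMB-001"}
        assert len(dupes["HMB-001"]) == 2

    def test_empty_and_clean_datasets(self, dataset_factory):
        assert find_duplicate_tags(dataset_factory([])) == {}
        ds = dataset_factory([_row(1, category="NEST_SEEN")])
        assert find_duplicate_tags(ds) == {}


class TestAuditReport:
    def test_union_counting_and_error_free(self, dataset_factory, config):
        ds = dataset_factory([
            _row(1, nest_latitude="-", record_time="-"),   # two misses
            _row(2, user_name="A. Balam", nest_latitude="-"),  # miss+variant
            _row(3, nest_latitude="0.0"),                  # inconsistent
            _row(4),
            _row(5),
        ])
        rep = audit(ds, config)
        assert rep.missing_union.count == 2
        assert rep.variant_union.count == 1
        assert rep.inconsistent_union.count == 1
        assert rep.any_error.count == 3          # record 2 counted once
        assert rep.error_free.count == 2
        assert rep.any_error.count + rep.error_free.count == rep.total_rows
        assert rep.any_error.percent == 60.0

    def test_invariants_on_fixture_scale_dataset(self, clean_season, config):
        spec = InjectionSpec(
            missing={"nest_gps": 30, "record_time": 10},
            missing_joint=(("nest_gps", "record_time", 4),),
            variants={"user_name": VariantInjection(12,
                                                    overlap_with_missing=5)},
            inconsistent={"egg_sum_mismatch": 2, "gps_out_of_range": 3},
            seed=99,
        )
        rep = audit(inject_errors(clean_season, spec, config), config)
        assert rep.missing_union.count <= sum(
            s.count for s in rep.per_field_missing.values())
        assert rep.any_error.count <= (rep.missing_union.count
                                       + rep.variant_union.count
                                       + rep.inconsistent_union.count)
        assert rep.error_free.count + rep.any_error.count == rep.total_rows

    def test_empty_dataset_has_undefined_percents(self, dataset_factory,
                                                  config):
        rep = audit(dataset_factory([]), config)
        assert rep.total_rows == 0
        assert rep.any_error.count == 0
        assert rep.any_error.percent is None
        assert rep.error_free_per_person is None

    def test_row_permutation_invariance(self, clean_season, config):
        spec = InjectionSpec(missing={"nest_gps": 20},
                             variants={"user_name": VariantInjection(7)},
                             seed=5)
        ds = inject_errors(clean_season, spec, config)
        rep1 = audit(ds, config)
        shuffled = ds.copy()
        rng = np.random.default_rng(0)
        shuffled.df = shuffled.df.iloc[
            rng.permutation(len(shuffled.df))].reset_index(drop=True)
        rep2 = audit(shuffled, config)
        assert rep1.to_dict() == {**rep2.to_dict(),
                                  "source_label": rep1.source_label}

    def test_audit_is_idempotent(self, clean_season, config):
        rep1 = audit(clean_season, config)
        rep2 = audit(clean_season, config)
        assert rep1.to_dict() == rep2.to_dict()


class TestBruteForceAgreement:
    """On small datasets a naive per-row scan must agree with the audit."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_vectorized_equals_naive_scan(self, config, registry, seed):
        rng = np.random.default_rng(seed)
        params = SeasonParams(
            n_records=50,
            recorders=("Aurora Balam", "Carlos Pech"),
            category_counts={"CRAWL_ANY": 14, "TURTLE_SEEN": 12,
                             "NEST_SEEN": 16, "NEST_MOVED": 4,
                             "NEST_EXCAVATED": 4},
            seed=int(rng.integers(2**31)),
        )
        spec = InjectionSpec(
            missing={"nest_gps": int(rng.integers(0, 12)),
                     "record_time": int(rng.integers(0, 8))},
            variants={"user_name": VariantInjection(int(rng.integers(0, 6)))},
            inconsistent={"egg_sum_mismatch": int(rng.integers(0, 3)),
                          "gps_out_of_range": int(rng.integers(0, 3))},
            seed=int(rng.integers(2**31)),
        )
        ds = inject_errors(generate_clean_season(params, registry, config),
                           spec, config)
        rep = audit(ds, config)
        naive = naive_audit_counts(ds.df, config)
        assert {k: s.count for k, s in rep.per_field_missing.items()} == \
            naive["missing"]
        got_variants = {k: s.count for k, s in rep.variant_text.items()
                        if s.count}
        assert got_variants == naive["variants"]
        assert {k: s.count for k, s in rep.inconsistent.items()} == \
            naive["inconsistent"]
        assert rep.missing_union.count == naive["missing_union"]
        assert rep.variant_union.count == naive["variant_union"]
        assert rep.inconsistent_union.count == naive["inconsistent_union"]
        assert rep.any_error.count == naive["any_error"]


class TestCategoryStats:
    def test_two_record_mean_and_sample_sd(self, registry, dataset_factory):
        crawl_vars = registry.category_variables("CRAWL_ANY")
        rows = []
        for i, k in enumerate((8, 12)):
            row = {"record_id": str(i), "record_category": "CRAWL_ANY",
                   "recorder": "A"}
            row.update({v: "x" for v in crawl_vars[:k]})
            rows.append(row)
        stats = category_field_stats(dataset_factory(rows), registry)
        assert stats["CRAWL_ANY"]["mean"] == pytest.approx(10.0)
        assert stats["CRAWL_ANY"]["sd"] == pytest.approx(2.8284, abs=1e-3)

    def test_single_record_sd_zero_by_convention(self, registry,
                                                 dataset_factory):
        row = {"record_id": "0", "record_category": "NEST_MOVED",
               "recorder": "A", "nest_tag": "HMB-001"}
        stats = category_field_stats(dataset_factory([row]), registry)
        assert stats["NEST_MOVED"]["sd"] == 0.0

    def test_generator_hits_completeness_targets(self, registry, config):
        targets = {"CRAWL_ANY": 9.0, "TURTLE_SEEN": 12.0,
                   "NEST_SEEN": 16.0, "NEST_MOVED": 14.0}
        params = SeasonParams(
            n_records=400, recorders=("Aurora Balam",),
            category_counts={"CRAWL_ANY": 100, "TURTLE_SEEN": 100,
                             "NEST_SEEN": 100, "NEST_MOVED": 100},
            completeness_targets=targets, seed=11)
        ds = generate_clean_season(params, registry, config)
        stats = category_field_stats(ds, registry)
        for cat, target in targets.items():
            assert stats[cat]["mean"] == pytest.approx(target, abs=1.5)

    def test_record_counts_mean_across_recorders(self, dataset_factory):
        rows = []
        for rec, n in (("A", 60), ("B", 70), ("C", 80)):
            rows += [_row(i, recorder=rec, category="TURTLE_SEEN")
                     for i in range(n)]
        tab = category_record_counts(dataset_factory(rows))
        assert tab.loc["TURTLE_SEEN", "mean"] == pytest.approx(70.0)
        assert tab.loc["NEST_SEEN", "mean"] == 0.0

    def test_empty_dataset_counts_are_zero(self, dataset_factory):
        tab = category_record_counts(dataset_factory([]))
        assert (tab["mean"] == 0).all()


def test_fuzzy_suggestions_are_advisory(config):
    canon = list(config.alias_maps["user_name"])
    hints = suggest_aliases(["Aurora Balaam", "zzzz"], canon)
    assert hints.get("Aurora Balaam") == "Aurora Balam"
    assert "zzzz" not in hints
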