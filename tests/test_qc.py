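"""Six-criterion record exclusion, duplicate collapsing, audit bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegrisk.qc import apply_filters, clean_occurrences, deduplicate
from vegrisk.synthetic import INJECTION_CRITERION, ScenarioConfig, generate_scenario


def _rec(**kw):
    base = {
        "species": "Simulatus species0001",
        "decimalLongitude": 10.0,
        "decimalLatitude": 10.0,
        "year": 1990,
        "month": 6,
        "recordedBy": "Collector A.",
        "basisOfRecord": "PreservedSpecimen",
        "outlier_flag": False,
        "cultivated_flag": False,
        "free_text": "",
    }
    base.update(kw)
    return base


EXTENT = (0.0, 0.0, 100.0, 100.0)


class TestApplyFilters:
    @pytest.mark.parametrize(
        "kw, criterion",
        [
            ({"decimalLatitude": np.nan}, "bad_coordinates"),
            ({"decimalLongitude": 250.0}, "bad_coordinates"),
            ({"free_text": "Botanic Gardens, cultivated specimen"}, "cultivated"),
            ({"free_text": "roadside, near a garden fence"}, "cultivated"),
            ({"cultivated_flag": True}, "cultivated"),
            ({"outlier_flag": True}, "outlier"),
            ({"basisOfRecord": "HumanObservation"}, "non_specimen"),
        ],
    )
    def test_single_criterion_removal(self, kw, criterion):
        df = pd.DataFrame([_rec(), _rec(**kw)])
        clean, report = apply_filters(df, extent=EXTENT)
        assert len(clean) == 1
        assert report.per_criterion[criterion] == 1
        assert sum(report.per_criterion.values()) == 1

    def test_clean_record_retained(self):
        df = pd.DataFrame([_rec()])
        clean, report = apply_filters(
            df, accepted_names={"Simulatus species0001"}, exotic_names={"Weedus x"},
            extent=EXTENT,
        )
        assert len(clean) == 1 and report.removed_unique == 0

    def test_name_and_exotic_lookups(self):
        df = pd.DataFrame([
            _rec(),
            _rec(species="Unratified sp."),
            _rec(species="Exoticus weedii001"),
        ])
        clean, report = apply_filters(
            df,
            accepted_names={"Simulatus species0001", "Exoticus weedii001"},
            exotic_names={"Exoticus weedii001"},
            extent=EXTENT,
        )
        assert clean["species"].tolist() == ["Simulatus species0001"]
        assert report.per_criterion["invalid_name"] == 1
        assert report.per_criterion["exotic"] == 1

    def test_record_meeting_several_criteria_counted_under_each(self):
        df = pd.DataFrame([_rec(outlier_flag=True, cultivated_flag=True)])
        clean, report = apply_filters(df, extent=EXTENT)
        assert len(clean) == 0
        assert report.per_criterion["outlier"] == 1
        assert report.per_criterion["cultivated"] == 1
        assert report.removed_unique == 1  # counted once in the arithmetic

    def test_missing_date_is_not_a_removal_criterion(self):
        df = pd.DataFrame([_rec(year=np.nan, month=np.nan)])
        clean, _ = apply_filters(df, extent=EXTENT)
        assert len(clean) == 1

    def test_empty_input_zeroed_report(self):
        df = pd.DataFrame([_rec()]).iloc[0:0]
        clean, report = apply_filters(df, extent=EXTENT)
        assert len(clean) == 0 and report.n_input == 0
        assert all(v == 0 for v in report.per_criterion.values())

    def test_missing_column_names_the_column(self):
        df = pd.DataFrame([_rec()]).drop(columns=["recordedBy"])
        with pytest.raises(KeyError, match="recordedBy"):
            apply_filters(df)

    def test_idempotent(self):
        df = pd.DataFrame([_rec(), _rec(outlier_flag=True), _rec(species="X")])
        once, _ = apply_filters(df, accepted_names={"Simulatus species0001"},
                                extent=EXTENT)
        twice, rep2 = apply_filters(once, accepted_names={"Simulatus species0001"},
                                    extent=EXTENT)
        assert rep2.removed_unique == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_order_insensitive_counts(self):
        rows = [_rec(), _rec(outlier_flag=True), _rec(decimalLatitude=np.nan),
                _rec(cultivated_flag=True)] * 5
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=3)
        _, r1 = apply_filters(df, extent=EXTENT)
        _, r2 = apply_filters(shuffled, extent=EXTENT)
        assert r1.per_criterion == r2.per_criterion
        assert r1.retained == r2.retained


class TestDeduplicate:
    def test_identical_six_field_key_collapses(self):
        df = pd.DataFrame([_rec(), _rec()])
        assert len(deduplicate(df)) == 1

    def test_distinct_collector_kept(self):
        df = pd.DataFrame([_rec(), _rec(recordedBy="Collector B.")])
        assert len(deduplicate(df)) == 2

    def test_toy_table_two_duplicate_pairs(self, toy_records):
        assert len(deduplicate(toy_records)) == 3

    def test_first_occurrence_wins(self):
        df = pd.DataFrame([_rec(free_text="first"), _rec(free_text="second")])
        assert deduplicate(df)["free_text"].tolist() == ["first"]

    def test_missing_key_fields_participate_as_missing(self):
        df = pd.DataFrame([_rec(recordedBy=None), _rec(recordedBy=None)])
        assert len(deduplicate(df)) == 1

    def test_whitespace_trimmed_no_case_folding(self):
        df = pd.DataFrame([_rec(recordedBy=" Collector A. "),
                           _rec(recordedBy="Collector A."),
                           _rec(recordedBy="collector a.")])
        assert len(deduplicate(df)) == 2

    def test_idempotent(self, toy_records):
        once = deduplicate(toy_records)
        pd.testing.assert_frame_equal(once, deduplicate(once))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.integers(0, 2)),
                    max_size=40))
    def test_matches_brute_force_key_grouping(self, keys):
        df = pd.DataFrame([_rec(species=s, month=m) for s, m in keys])
        got = len(deduplicate(df)) if len(df) else 0
        assert got == len(set(keys))


class TestInjectionBookkeeping:
    def test_removals_match_injection_log(self, small_scenario):
        scen = small_scenario
        clean, report = clean_occurrences(
            scen.occurrences, scen.accepted_names, scen.exotic_names,
            scen.config.extent,
        )
        log = scen.injection_log.set_index("category")["count"]
        by_criterion = {}
        for cat, crit in INJECTION_CRITERION.items():
            if crit is not None:
                by_criterion[crit] = by_criterion.get(crit, 0) + int(log[cat])
        for crit, expected in by_criterion.items():
            assert report.per_criterion[crit] == expected, crit
        assert report.n_duplicates_removed == int(log["duplicate"])
        assert len(clean) == (scen.occurrences["injected_category"] == "").sum()

    def test_zero_contamination_leaves_only_injected_duplicates(self):
        rates = {k: 0.0 for k in INJECTION_CRITERION}
        rates["duplicate"] = 0.04
        cfg = ScenarioConfig(seed=21, n_species=40, extent=(0, 0, 400, 400),
                             contamination_rates=rates)
        scen = generate_scenario(cfg)
        clean, report = clean_occurrences(
            scen.occurrences, scen.accepted_names, scen.exotic_names, cfg.extent
        )
        assert report.removed_unique == 0
        expected_dups = int(scen.injection_log.set_index("category")
                            .loc["duplicate", "count"])
        assert report.n_duplicates_removed == expected_dups
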