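"""Episode construction: grouping, pairing, mode, flags, and the ledger."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimscc.claims import CodeSets
from claimscc.episodes import (
    assign_delivery_mode,
    build_delivery_cases,
    greedy_event_partition,
    group_delivery_events,
    pair_pregnancy,
)
from claimscc.simulate import ExposureSpec, SimConfig, generate_dataset
from tests.conftest import make_bundle, woman_qual


def one_person_events(dates, code="O80"):
    bundle = make_bundle(
        woman_qual("P1", range(2005, 2014)),
        [("P1", d, code) for d in dates],
    )
    return group_delivery_events(bundle.claims, CodeSets())


class TestEventGrouping:
    def test_close_dates_one_event(self):
        ev = one_person_events(["2010-03-01", "2010-03-04"])
        assert len(ev) == 1
        expected_day = (np.datetime64("2010-03-01") - np.datetime64("1970-01-01")).astype(int)
        assert ev["delivery_day"].tolist() == [expected_day]

    def test_exact_168_day_gap_two_events(self):
        d0 = pd.Timestamp("2010-03-01")
        ev = one_person_events([d0, d0 + pd.Timedelta(days=168)])
        assert len(ev) == 2

    def test_167_day_gap_one_event(self):
        d0 = pd.Timestamp("2010-03-01")
        ev = one_person_events([d0, d0 + pd.Timedelta(days=167)])
        assert len(ev) == 1

    def test_greedy_anchoring_chain(self):
        # d, d+100 join the anchor; d+200 is >= 168 past the anchor -> new event
        d0 = pd.Timestamp("2010-03-01")
        ev = one_person_events([d0, d0 + pd.Timedelta(days=100), d0 + pd.Timedelta(days=200)])
        assert len(ev) == 2
        assert ev["event_ord"].tolist() == [0, 1]

    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_partition_matches_bruteforce_oracle(self, offsets):
        days = np.array(sorted(set(offsets)), dtype=np.int64)
        # independent oracle: walk the sorted dates, re-anchoring explicitly
        oracle = []
        anchor = None
        ev = -1
        for d in days:
            if anchor is None or d - anchor >= 168:
                ev += 1
                anchor = d
            oracle.append(ev)
        assert greedy_event_partition(days).tolist() == oracle
        # event anchors are pairwise >= 168 apart
        anchors = days[np.unique(greedy_event_partition(days), return_index=True)[1]]
        assert (np.diff(anchors) >= 168).all()

    def test_row_order_invariance(self):
        dates = ["2010-03-01", "2011-06-01", "2010-03-10"]
        a = one_person_events(dates)
        b = one_person_events(list(reversed(dates)))
        pd.testing.assert_frame_equal(a, b)


class TestPregnancyPairing:
    def events_frame(self, delivery, prev=-1):
        t = (np.datetime64(delivery, "D") - np.datetime64("1970-01-01", "D")).astype(int)
        return pd.DataFrame(
            {"person_id": ["P1"], "delivery_day": [int(t)], "prev_delivery_day": [prev],
             "event_ord": [0]}
        )

    def preg_claims(self, dates):
        return pd.DataFrame(
            {"person_id": "P1", "visit_date": pd.to_datetime(list(dates))}
        )

    def test_claim_280_days_before_pairs(self):
        ev = self.events_frame("2010-10-08")
        day = pair_pregnancy(ev, self.preg_claims([pd.Timestamp("2010-10-08") - pd.Timedelta(days=280)]))
        assert day.iloc[0] == ev["delivery_day"].iloc[0] - 280

    def test_boundary_308_pairs_309_does_not(self):
        ev = self.events_frame("2010-10-08")
        t = pd.Timestamp("2010-10-08")
        assert pair_pregnancy(ev, self.preg_claims([t - pd.Timedelta(days=308)])).iloc[0] >= 0
        assert pair_pregnancy(ev, self.preg_claims([t - pd.Timedelta(days=309)])).iloc[0] == -1

    def test_same_day_claim_does_not_pair(self):
        ev = self.events_frame("2010-10-08")
        assert pair_pregnancy(ev, self.preg_claims([pd.Timestamp("2010-10-08")])).iloc[0] == -1
        day = pair_pregnancy(ev, self.preg_claims([pd.Timestamp("2010-10-07")]))
        assert day.iloc[0] == ev["delivery_day"].iloc[0] - 1

    def test_earliest_valid_candidate_wins(self):
        # -310 violates the 308-day bound; -200 is the earliest valid
        ev = self.events_frame("2010-10-08")
        t = pd.Timestamp("2010-10-08")
        day = pair_pregnancy(
            ev, self.preg_claims([t - pd.Timedelta(days=310), t - pd.Timedelta(days=200)])
        )
        assert day.iloc[0] == ev["delivery_day"].iloc[0] - 200

    def test_previous_delivery_postpartum_bound(self):
        ev = self.events_frame("2010-10-08")
        prev = int(ev["delivery_day"].iloc[0]) - 300
        ev["prev_delivery_day"] = prev
        t0 = pd.Timestamp("2010-10-08") - pd.Timedelta(days=300)
        # candidate at prev + 27 is too early; prev + 28 pairs
        too_early = pair_pregnancy(ev, self.preg_claims([t0 + pd.Timedelta(days=27)]))
        assert too_early.iloc[0] == -1
        ok = pair_pregnancy(ev, self.preg_claims([t0 + pd.Timedelta(days=28)]))
        assert ok.iloc[0] == prev + 28


class TestDeliveryMode:
    def mode_for(self, codes_dates):
        bundle = make_bundle(
            woman_qual("P1", range(2005, 2014)),
            [("P1", d, c) for d, c in codes_dates],
        )
        events = group_delivery_events(bundle.claims, CodeSets())
        return assign_delivery_mode(events, bundle.claims, CodeSets()).tolist()

    def test_cesarean_priority(self):
        assert self.mode_for([("2010-03-01", "O80"), ("2010-03-01", "O82")]) == ["cesarean"]

    def test_o841_is_vaginal(self):
        assert self.mode_for([("2010-03-01", "O84.1")]) == ["vaginal"]

    def test_o842_is_cesarean(self):
        assert self.mode_for([("2010-03-01", "O84.2")]) == ["cesarean"]

    def test_unidentified_when_window_empty(self):
        # standalone op on an artificial event with no nearby delivery code
        events = pd.DataFrame(
            {"person_id": ["P1"], "delivery_day": [15000], "prev_delivery_day": [-1],
             "event_ord": [0]}
        )
        claims = pd.DataFrame(
            {"person_id": ["P1"], "visit_date": [pd.Timestamp("1970-01-01")],
             "code": ["K29"]}
        )
        assert assign_delivery_mode(events, claims, CodeSets()).tolist() == ["unidentified"]


class TestCascade:
    def test_clean_episode_retained(self, clean_bundle):
        cases, ledger = build_delivery_cases(clean_bundle)
        assert len(cases) == 1
        case = cases.iloc[0]
        assert case["mode"] == "vaginal"
        assert case["anc_duration"] == 253
        assert not case["jaundice"] and not case["preterm"]
        assert case["age_band"] == "25-34"
        assert case["income_group"] == 3
        assert ledger.conserved()
        assert ledger.retained == 1

    @pytest.mark.parametrize(
        "extra,flag",
        [
            (("P1", "2010-09-25", "P59.0"), "jaundice"),
            (("P1", "2010-10-18", "P59.0"), "jaundice"),   # delivery + 28
            (("P1", "2010-09-01", "O60"), "preterm"),      # delivery - 19
            (("P1", "2010-08-23", "O60"), "preterm"),      # delivery - 28
            (("P1", "2010-09-30", "O30"), "multiple_gestation"),
        ],
    )
    def test_flag_set_inside_window(self, clean_bundle, extra, flag):
        bundle = make_bundle(
            clean_bundle.qualifications.itertuples(index=False),
            list(clean_bundle.claims[["person_id", "visit_date", "code"]].itertuples(index=False))
            + [extra],
        )
        cases, _ = build_delivery_cases(bundle)
        assert cases.iloc[0][flag]

    @pytest.mark.parametrize(
        "extra,flag",
        [
            (("P1", "2010-10-19", "P59.0"), "jaundice"),   # delivery + 29
            (("P1", "2010-09-19", "P59.0"), "jaundice"),   # day before delivery
            (("P1", "2010-08-22", "O60"), "preterm"),      # delivery - 29
        ],
    )
    def test_flag_not_set_outside_window(self, clean_bundle, extra, flag):
        bundle = make_bundle(
            clean_bundle.qualifications.itertuples(index=False),
            list(clean_bundle.claims[["person_id", "visit_date", "code"]].itertuples(index=False))
            + [extra],
        )
        cases, _ = build_delivery_cases(bundle)
        assert not cases.iloc[0][flag]

    def add_claims(self, bundle, extras, drop_qual_years=()):
        qual = [
            r for r in bundle.qualifications.itertuples(index=False)
            if r.year not in drop_qual_years
        ]
        return make_bundle(
            qual,
            list(bundle.claims[["person_id", "visit_date", "code"]].itertuples(index=False))
            + extras,
        )

    def test_stillbirth_inside_window_excludes(self, clean_bundle):
        bundle = self.add_claims(clean_bundle, [("P1", "2010-09-30", "Z37.1")])
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.abortion_or_stillbirth == 1
        assert ledger.conserved()

    def test_stillbirth_after_window_retained(self, clean_bundle):
        bundle = self.add_claims(clean_bundle, [("P1", "2010-10-19", "Z37.1")])  # delivery + 29
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 1
        assert ledger.abortion_or_stillbirth == 0

    def test_stillbirth_before_pregnancy_dx_ignored(self, clean_bundle):
        bundle = self.add_claims(clean_bundle, [("P1", "2010-01-05", "Z37.1")])
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 1

    def test_abortion_code_excludes(self, clean_bundle):
        bundle = self.add_claims(clean_bundle, [("P1", "2010-05-01", "O03.4")])
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.abortion_or_stillbirth == 1

    def test_missing_pregnancy_year_qualification_excludes(self, clean_bundle):
        bundle = self.add_claims(clean_bundle, [], drop_qual_years={2010})
        # 2010 is both pregnancy-dx and delivery year here
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.qualification_incomplete == 1
        assert ledger.conserved()

    def test_unpairable_event_counted(self):
        bundle = make_bundle(
            woman_qual("P1", range(2008, 2012)),
            [("P1", "2010-09-20", "O80")],  # delivery without pregnancy claims
        )
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.no_pregnancy_pairing == 1

    @pytest.mark.parametrize("age_group", [3, 11])
    def test_age_out_of_range_excludes(self, age_group):
        bundle = make_bundle(
            woman_qual("P1", range(2008, 2012), age_group=age_group),
            [("P1", "2010-01-10", "Z34"), ("P1", "2010-09-20", "O80")],
        )
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.age_out_of_range == 1

    def test_male_person_ignored(self):
        bundle = make_bundle(
            [("P1", "male", 2010, 6, 5)],
            [("P1", "2010-01-10", "Z34"), ("P1", "2010-09-20", "O80")],
        )
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 0
        assert ledger.n_candidate_events == 0

    def test_woman_without_delivery_counted(self):
        bundle = make_bundle(
            woman_qual("P1", [2010]), [("P1", "2010-01-10", "K29")]
        )
        cases, ledger = build_delivery_cases(bundle)
        assert ledger.no_delivery == 1

    def test_two_episodes_independent_cases(self):
        claims = [
            ("P1", "2009-01-10", "Z34"), ("P1", "2009-10-01", "O80"),
            ("P1", "2011-03-05", "Z34"), ("P1", "2011-11-20", "O82"),
        ]
        bundle = make_bundle(woman_qual("P1", range(2008, 2013)), claims)
        cases, ledger = build_delivery_cases(bundle)
        assert len(cases) == 2
        assert cases["mode"].tolist() == ["vaginal", "cesarean"]
        assert cases["case_id"].nunique() == 2

    def test_row_order_invariance(self, clean_bundle):
        shuffled = make_bundle(
            clean_bundle.qualifications.itertuples(index=False),
            list(clean_bundle.claims[["person_id", "visit_date", "code"]]
                 .sample(frac=1, random_state=3).itertuples(index=False)),
        )
        a, _ = build_delivery_cases(clean_bundle)
        b, _ = build_delivery_cases(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestGeneratorRecovery:
    def test_planted_episodes_recovered_exactly(self):
        cfg = SimConfig(n_women=800, jaundice_base_rate=0.05)
        bundle, truth = generate_dataset(cfg, seed=11)
        cases, ledger = build_delivery_cases(bundle)
        assert ledger.conserved()
        assert len(cases) == len(truth.episodes)
        got = cases.sort_values(["person_id", "delivery_date"]).reset_index(drop=True)
        want = truth.episodes.sort_values(["person_id", "delivery_date"]).reset_index(drop=True)
        pd.testing.assert_series_equal(
            got["delivery_date"], want["delivery_date"], check_names=False
        )
        pd.testing.assert_series_equal(
            got["pregnancy_dx_date"], want["pregnancy_dx_date"], check_names=False
        )
        assert (got["mode"].to_numpy() == want["mode"].to_numpy()).all()
        assert (got["jaundice"].to_numpy() == want["jaundice"].to_numpy()).all()
        assert got["anc_duration"].between(1, 308).all()

    def test_retained_case_invariants(self):
        cfg = SimConfig(n_women=600, second_episode_prob=0.4, jaundice_base_rate=0.05)
        bundle, truth = generate_dataset(cfg, seed=5)
        cases, _ = build_delivery_cases(bundle)
        assert cases["anc_duration"].between(1, 308).all()
        by_person = cases.sort_values("delivery_date").groupby("person_id")
        for _, g in by_person:
            if len(g) < 2:
                continue
            deliveries = g["delivery_date"].to_numpy()
            gaps = np.diff(deliveries).astype("timedelta64[D]").astype(int)
            assert (gaps >= 168).all()
            preg = g["pregnancy_dx_date"].to_numpy()[1:]
            assert ((preg - deliveries[:-1]).astype("timedelta64[D]").astype(int) >= 28).all()
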