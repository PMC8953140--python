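"""Construct analyzable delivery cases from the merged claim stream.

The temporal rules, in days (weeks converted at 7 d/wk):

* delivery-coded visit dates of one person are grouped greedily into
  delivery events; a date starts a new event iff it falls at least
  168 days (24 wk) after the current event's first date;
* each event is paired with the earliest pregnancy-coded visit date
  within 308 days (44 wk) before and at least 1 day before delivery,
  and no earlier than 28 days (4 wk) after the previous delivery;
* delivery mode is read from codes within +/- 28 days of delivery,
  cesarean codes taking priority over vaginal ones;
* abortion/stillbirth codes between the pregnancy diagnosis and 28
  days after delivery disqualify the event;
* outcome/preterm/multiple-gestation flags come from code prefixes in
  fixed windows around the delivery date.

Exclusions are applied in a fixed order and tallied in an
:class:`ExclusionLedger` so that candidate events are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd

from claimscc.claims import (
    AGE_GROUP_TO_BAND,
    ClaimsBundle,
    CodeSets,
    regroup_income,
)

#: Temporal constants (days).
MIN_DELIVERY_GAP = 168       # 24 wk between deliveries
MAX_GESTATION = 308          # 44 wk pregnancy-diagnosis-to-delivery
MIN_POSTPARTUM_TO_NEXT = 28  # 4 wk delivery-to-next-pregnancy-diagnosis
FLAG_WINDOW = 28             # 4 wk flag windows around delivery

CASE_COLUMNS = [
    "case_id", "person_id", "delivery_date", "pregnancy_dx_date",
    "anc_duration", "mode", "preterm", "multiple_gestation", "jaundice",
    "age_band", "income_group",
]


@dataclass
class ExclusionLedger:
    """Tally of exclusions per stage, in application order.

    ``no_delivery`` counts *women* without any delivery-coded claim;
    the remaining buckets count candidate delivery events, so that
    ``n_candidate_events == retained + age_out_of_range +
    no_pregnancy_pairing + mode_unidentified + abortion_or_stillbirth +
    qualification_incomplete``.  ``no_nonpregnancy_dx_in_window`` is
    incremented later by the per-study eligibility filter.
    """

    n_women: int = 0
    n_candidate_events: int = 0
    retained: int = 0
    no_delivery: int = 0
    age_out_of_range: int = 0
    no_pregnancy_pairing: int = 0
    mode_unidentified: int = 0
    abortion_or_stillbirth: int = 0
    qualification_incomplete: int = 0
    no_nonpregnancy_dx_in_window: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.name, getattr(self, f.name)) for f in fields(self)],
            columns=["stage", "count"],
        )

    def conserved(self) -> bool:
        event_stage_total = (
            self.retained
            + self.age_out_of_range
            + self.no_pregnancy_pairing
            + self.mode_unidentified
            + self.abortion_or_stillbirth
            + self.qualification_incomplete
        )
        return self.n_candidate_events == event_stage_total


@dataclass(frozen=True)
class DeliveryEvent:
    person_id: str
    delivery_date: pd.Timestamp
    member_dates: tuple[pd.Timestamp, ...]


def _to_days(dates: pd.Series | np.ndarray) -> np.ndarray:
    """Datetime64 -> integer days since epoch."""
    return np.asarray(dates, dtype="datetime64[D]").astype(np.int64)


def _from_days(days: np.ndarray | int) -> np.ndarray:
    return np.asarray(days, dtype=np.int64).astype("datetime64[D]")


def greedy_event_partition(days: np.ndarray, min_gap: int = MIN_DELIVERY_GAP) -> np.ndarray:
    """Greedy anchored grouping of sorted day numbers into events.

    Returns the event index of each date: a date joins the current
    event while it is less than ``min_gap`` days after that event's
    *first* date, otherwise it anchors a new event.
    """
    days = np.asarray(days, dtype=np.int64)
    idx = np.empty(len(days), dtype=np.int64)
    event = -1
    anchor = None
    for i, d in enumerate(days):
        if anchor is None or d - anchor >= min_gap:
            event += 1
            anchor = d
        idx[i] = event
    return idx


def group_delivery_events(claims: pd.DataFrame, code_sets: CodeSets) -> pd.DataFrame:
    """Partition delivery-coded claims into per-person delivery events.

    Returns one row per event with columns ``person_id``,
    ``delivery_day`` (int days, the event's earliest date),
    ``prev_delivery_day`` (previous event of the same person, or -1),
    and ``event_ord``.
    """
    mask = code_sets.match(claims["code"], "delivery")
    dlv = claims.loc[mask, ["person_id", "visit_date"]]
    if dlv.empty:
        return pd.DataFrame(
            columns=["person_id", "delivery_day", "prev_delivery_day", "event_ord"]
        )
    dlv = dlv.drop_duplicates().sort_values(["person_id", "visit_date"], kind="stable")
    persons = dlv["person_id"].to_numpy()
    days = _to_days(dlv["visit_date"])

    rows: list[tuple[str, int, int, int]] = []
    start = 0
    n = len(persons)
    while start < n:
        end = start
        while end < n and persons[end] == persons[start]:
            end += 1
        ev = greedy_event_partition(days[start:end])
        anchors = days[start:end][np.unique(ev, return_index=True)[1]]
        prev = -1
        for k, d in enumerate(anchors):
            rows.append((persons[start], int(d), prev, k))
            prev = int(d)
        start = end
    return pd.DataFrame(rows, columns=["person_id", "delivery_day", "prev_delivery_day", "event_ord"])


# Person-and-day composite keys make every window query two vectorized
# binary searches.  Day numbers are offset to stay non-negative.
_DAY_OFFSET = 1 << 20
_KEY_BASE = 1 << 22


def _keys(person_code: np.ndarray, day: np.ndarray) -> np.ndarray:
    day = np.asarray(day, dtype=np.int64) + _DAY_OFFSET
    if (day < 0).any() or (day >= _KEY_BASE).any():
        raise ValueError("visit dates outside the supported range")
    return person_code.astype(np.int64) * _KEY_BASE + day


def _person_codes(*series: pd.Series) -> list[np.ndarray]:
    cat = pd.Categorical(pd.concat([s.astype(str) for s in series], ignore_index=True))
    out = []
    start = 0
    for s in series:
        out.append(np.asarray(cat.codes[start:start + len(s)], dtype=np.int64))
        start += len(s)
    return out


def pair_pregnancy(events: pd.DataFrame, pregnancy_claims: pd.DataFrame) -> pd.Series:
    """Earliest valid pregnancy-diagnosis day per event (-1 if none).

    A pregnancy-coded visit day ``D`` pairs with an event at delivery
    day ``T`` iff ``T - 308 <= D <= T - 1`` and, when a previous
    delivery exists, ``D >= previous delivery + 28``.
    """
    if events.empty:
        return pd.Series(np.array([], dtype=np.int64), index=events.index, name="pregnancy_day")
    out = np.full(len(events), -1, dtype=np.int64)
    if not pregnancy_claims.empty:
        ev_code, cl_code = _person_codes(events["person_id"], pregnancy_claims["person_id"])
        keys = np.sort(_keys(cl_code, _to_days(pregnancy_claims["visit_date"])))
        t = events["delivery_day"].to_numpy(dtype=np.int64)
        prev = events["prev_delivery_day"].to_numpy(dtype=np.int64)
        lo = np.where(
            prev >= 0,
            np.maximum(t - MAX_GESTATION, prev + MIN_POSTPARTUM_TO_NEXT),
            t - MAX_GESTATION,
        )
        j = np.searchsorted(keys, _keys(ev_code, lo), side="left")
        jc = np.minimum(j, len(keys) - 1)
        found = (j < len(keys)) & (keys[jc] <= _keys(ev_code, t - 1))
        out[found] = keys[jc[found]] % _KEY_BASE - _DAY_OFFSET
    return pd.Series(out, index=events.index, name="pregnancy_day")


def _window_flag(
    events: pd.DataFrame,
    claims: pd.DataFrame,
    code_sets: CodeSets,
    which: str,
    rel_lo: int,
    rel_hi: int,
    lower_col: str | None = None,
) -> pd.Series:
    """True per event iff a claim with a prefix from the named set falls
    in the closed window ``[delivery + rel_lo, delivery + rel_hi]``
    (optionally clipped below at ``lower_col``, e.g. the pregnancy
    diagnosis day)."""
    sub = claims.loc[code_sets.match(claims["code"], which), ["person_id", "visit_date"]]
    flags = np.zeros(len(events), dtype=bool)
    if sub.empty or events.empty:
        return pd.Series(flags, index=events.index)
    ev_code, cl_code = _person_codes(events["person_id"], sub["person_id"])
    keys = np.sort(_keys(cl_code, _to_days(sub["visit_date"])))
    t = events["delivery_day"].to_numpy(dtype=np.int64)
    lo = t + rel_lo
    if lower_col is not None:
        lo = np.maximum(lo, events[lower_col].to_numpy(dtype=np.int64))
    j_lo = np.searchsorted(keys, _keys(ev_code, lo), side="left")
    j_hi = np.searchsorted(keys, _keys(ev_code, t + rel_hi), side="right")
    return pd.Series(j_hi > j_lo, index=events.index)


def flag_window_codes(
    event_delivery_day: int,
    claim_days: Iterable[int],
    rel_lo: int,
    rel_hi: int,
) -> bool:
    """Scalar helper: any day in the closed window relative to delivery."""
    lo, hi = event_delivery_day + rel_lo, event_delivery_day + rel_hi
    return any(lo <= d <= hi for d in claim_days)


def assign_delivery_mode(
    events: pd.DataFrame, claims: pd.DataFrame, code_sets: CodeSets
) -> pd.Series:
    """Delivery mode per event from codes within +/- 28 days.

    Any cesarean code wins over vaginal codes; with neither present the
    event is ``unidentified`` (and will be excluded).
    """
    ces = _window_flag(events, claims, code_sets, "delivery_cesarean", -FLAG_WINDOW, FLAG_WINDOW)
    vag = _window_flag(events, claims, code_sets, "delivery_vaginal", -FLAG_WINDOW, FLAG_WINDOW)
    mode = np.where(ces, "cesarean", np.where(vag, "vaginal", "unidentified"))
    return pd.Series(mode, index=events.index, name="mode")


def build_delivery_cases(
    bundle: ClaimsBundle, code_sets: CodeSets | None = None
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the full inclusion/exclusion cascade.

    Returns the retained cases (one row per delivery event, columns
    :data:`CASE_COLUMNS`) and the populated :class:`ExclusionLedger`.
    Output is deterministic and independent of input row order.
    """
    code_sets = code_sets or CodeSets()
    ledger = ExclusionLedger()
    qual = bundle.qualifications

    female = qual.loc[qual["sex"] == "female", "person_id"].unique()
    claims = bundle.claims[bundle.claims["person_id"].isin(set(female))]
    women_with_claims = claims["person_id"].unique()
    ledger.n_women = len(women_with_claims)

    events = group_delivery_events(claims, code_sets)
    ledger.n_candidate_events = len(events)
    ledger.no_delivery = ledger.n_women - events["person_id"].nunique()
    if events.empty:
        return pd.DataFrame(columns=CASE_COLUMNS), ledger

    # --- age 15-49 at the delivery year ------------------------------
    events = events.copy()
    events["delivery_year"] = _from_days(events["delivery_day"].to_numpy()).astype(
        "datetime64[Y]"
    ).astype(int) + 1970
    qual_small = qual[["person_id", "year", "age_group", "income_rank"]].drop_duplicates(
        ["person_id", "year"]
    )
    age_group = events.merge(
        qual_small[["person_id", "year", "age_group"]],
        left_on=["person_id", "delivery_year"], right_on=["person_id", "year"],
        how="left",
    )["age_group"].fillna(-1).astype(int).set_axis(events.index)
    events["age_band"] = age_group.map(AGE_GROUP_TO_BAND)
    # A missing qualification row (-1) is judged at the completeness
    # stage, not here; only a present-but-out-of-range band excludes.
    out_of_range = (age_group != -1) & events["age_band"].isna()
    ledger.age_out_of_range = int(out_of_range.sum())
    events = events[~out_of_range]

    # --- pregnancy pairing -------------------------------------------
    preg_claims = claims[code_sets.match(claims["code"], "pregnancy")]
    events["pregnancy_day"] = pair_pregnancy(events, preg_claims)
    unpaired = events["pregnancy_day"] < 0
    ledger.no_pregnancy_pairing = int(unpaired.sum())
    events = events[~unpaired]

    # --- delivery mode -----------------------------------------------
    events["mode"] = assign_delivery_mode(events, claims, code_sets)
    bad_mode = events["mode"] == "unidentified"
    ledger.mode_unidentified = int(bad_mode.sum())
    events = events[~bad_mode]

    # --- abortion / stillbirth ---------------------------------------
    ab = _window_flag(
        events, claims, code_sets, "abortion",
        -MAX_GESTATION, FLAG_WINDOW, lower_col="pregnancy_day",
    )
    sb = _window_flag(
        events, claims, code_sets, "stillbirth",
        -MAX_GESTATION, FLAG_WINDOW, lower_col="pregnancy_day",
    )
    lost = ab | sb
    ledger.abortion_or_stillbirth = int(lost.sum())
    events = events[~lost]

    # --- qualification completeness ----------------------------------
    events["pregnancy_year"] = _from_days(events["pregnancy_day"].to_numpy()).astype(
        "datetime64[Y]"
    ).astype(int) + 1970

    def _lookup(year_col: str, value_col: str) -> pd.Series:
        return events.merge(
            qual_small[["person_id", "year", value_col]],
            left_on=["person_id", year_col], right_on=["person_id", "year"],
            how="left",
        )[value_col].set_axis(events.index)

    have_delivery_year = _lookup("delivery_year", "age_group").notna()
    income_rank = _lookup("pregnancy_year", "income_rank")
    incomplete = ~(have_delivery_year & income_rank.notna())
    ledger.qualification_incomplete = int(incomplete.sum())
    events = events[~incomplete]
    income_rank = income_rank[~incomplete]

    # --- flags and covariates ----------------------------------------
    events["jaundice"] = _window_flag(events, claims, code_sets, "jaundice", 0, FLAG_WINDOW)
    events["preterm"] = _window_flag(events, claims, code_sets, "preterm", -FLAG_WINDOW, FLAG_WINDOW)
    events["multiple_gestation"] = _window_flag(
        events, claims, code_sets, "multiple_gestation", -FLAG_WINDOW, FLAG_WINDOW
    )
    events["income_group"] = regroup_income(income_rank.astype(int))
    events["anc_duration"] = events["delivery_day"] - events["pregnancy_day"]

    ledger.retained = len(events)
    cases = pd.DataFrame(
        {
            "case_id": [f"{p}#{k}" for p, k in zip(events["person_id"], events["event_ord"])],
            "person_id": events["person_id"].to_numpy(),
            "delivery_date": pd.to_datetime(_from_days(events["delivery_day"].to_numpy())),
            "pregnancy_dx_date": pd.to_datetime(_from_days(events["pregnancy_day"].to_numpy())),
            "anc_duration": events["anc_duration"].to_numpy(),
            "mode": events["mode"].to_numpy(),
            "preterm": events["preterm"].to_numpy(),
            "multiple_gestation": events["multiple_gestation"].to_numpy(),
            "jaundice": events["jaundice"].to_numpy(),
            "age_band": events["age_band"].to_numpy(),
            "income_group": events["income_group"].to_numpy(),
        }
    )
    cases = cases.sort_values(["person_id", "delivery_date"], kind="stable").reset_index(drop=True)
    return cases, ledger
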