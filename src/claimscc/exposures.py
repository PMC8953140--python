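"""Per-case exposure windows and 2x2 tabulation.

Two exposure windows are defined relative to each retained delivery
case:

* study **A**: the antenatal period, ``[pregnancy_dx_date,
  delivery_date - 1]`` (closed on both ends);
* study **B**: the pre-conception year, ``[pregnancy_dx_date - 365,
  pregnancy_dx_date - 1]``.

Codes are truncated to their 3-character category and de-duplicated
per case (binary presence, no visit-count weighting).  Eligibility
requires at least one code in the window that is *not*
pregnancy/delivery-related; those pregnancy-related codes stay in the
profile but are never tabulated as exposures in study A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from claimscc.claims import CodeSets, truncate_code
from claimscc.episodes import ExclusionLedger, _to_days
from claimscc.exact import ContingencyTable

STUDY_A = "A"
STUDY_B = "B"
PRECONCEPTION_DAYS = 365


def study_window(cases: pd.DataFrame, study: str) -> tuple[np.ndarray, np.ndarray]:
    """Closed ``[lo, hi]`` day bounds of the study window per case."""
    preg = _to_days(cases["pregnancy_dx_date"])
    if study == STUDY_A:
        return preg, _to_days(cases["delivery_date"]) - 1
    if study == STUDY_B:
        return preg - PRECONCEPTION_DAYS, preg - 1
    raise ValueError(f"unknown study {study!r}; expected 'A' or 'B'")


def extract_window_profiles(
    cases: pd.DataFrame, claims: pd.DataFrame, study: str
) -> pd.DataFrame:
    """Long-format exposure profiles: one row per (case_id, code3).

    Every claim of the case's person whose visit date falls in the
    study window contributes its 3-character code; duplicates collapse
    to a single row.  Invariant to claim ordering.
    """
    sub = claims[["person_id", "visit_date", "code"]].merge(
        cases[["case_id", "person_id", "pregnancy_dx_date", "delivery_date"]],
        on="person_id",
        how="inner",
    )
    if sub.empty:
        return pd.DataFrame(columns=["case_id", "code3"])
    lo, hi = study_window(sub, study)
    day = _to_days(sub["visit_date"])
    sub = sub[(day >= lo) & (day <= hi)]
    out = pd.DataFrame(
        {
            "case_id": sub["case_id"].to_numpy(),
            "code3": [truncate_code(c) for c in sub["code"]],
        }
    )
    return out.drop_duplicates().sort_values(["case_id", "code3"], kind="stable").reset_index(drop=True)


def _pregnancy_related(codes3: pd.Series, code_sets: CodeSets) -> pd.Series:
    # Prefixes longer than 3 characters are compared on their first 3.
    prefixes = tuple({p[:3] for p in code_sets.pregnancy_related_exclusion})
    return codes3.str.startswith(prefixes)


def apply_eligibility(
    cases: pd.DataFrame,
    profiles: pd.DataFrame,
    code_sets: CodeSets,
    ledger: ExclusionLedger | None = None,
) -> pd.DataFrame:
    """Keep cases whose window profile has >= 1 non-pregnancy-related code.

    Increments ``ledger.no_nonpregnancy_dx_in_window`` by the number of
    cases removed (cases with an empty profile count as removed too).
    """
    if profiles.empty:
        eligible_ids: set = set()
    else:
        informative = profiles.loc[~_pregnancy_related(profiles["code3"], code_sets), "case_id"]
        eligible_ids = set(informative)
    keep = cases["case_id"].isin(eligible_ids)
    if ledger is not None:
        ledger.no_nonpregnancy_dx_in_window += int((~keep).sum())
    return cases[keep].reset_index(drop=True)


def tabulate_code(
    cases: pd.DataFrame, profiles: pd.DataFrame, code3: str
) -> ContingencyTable:
    """2x2 exposure table for one 3-character code.

    Duplicate claims never inflate counts: profiles are already unique
    per (case, code).
    """
    if len(code3) != 3:
        raise ValueError(f"expected a 3-character code, got {code3!r}")
    exposed_ids = set(profiles.loc[profiles["code3"] == code3, "case_id"])
    is_case = cases["jaundice"].to_numpy(dtype=bool)
    exposed = cases["case_id"].isin(exposed_ids).to_numpy()
    a = int((exposed & is_case).sum())
    c = int((exposed & ~is_case).sum())
    return ContingencyTable(a, int(is_case.sum()) - a, c, int((~is_case).sum()) - c)


def tabulate_all(
    cases: pd.DataFrame,
    profiles: pd.DataFrame,
    code_sets: CodeSets | None = None,
    study: str = STUDY_A,
) -> pd.DataFrame:
    """Per-code 2x2 counts for every code observed in >= 1 case.

    Returns a frame with columns ``code3, a, b, c, d``.  In study A,
    pregnancy-related codes define the antenatal context and are not
    tabulated as exposures; in study B they are testable.
    """
    prof = profiles[profiles["case_id"].isin(set(cases["case_id"]))]
    if study == STUDY_A and code_sets is not None:
        prof = prof[~_pregnancy_related(prof["code3"], code_sets)]
    labels = cases.set_index("case_id")["jaundice"]
    n_cases = int(labels.sum())
    n_controls = int(len(labels) - n_cases)
    tagged = prof.assign(jaundice=prof["case_id"].map(labels))
    counts = tagged.groupby(["code3", "jaundice"]).size().unstack(fill_value=0)
    a = counts.get(True, pd.Series(0, index=counts.index)).astype(int)
    c = counts.get(False, pd.Series(0, index=counts.index)).astype(int)
    out = pd.DataFrame(
        {
            "code3": counts.index,
            "a": a.to_numpy(),
            "b": n_cases - a.to_numpy(),
            "c": c.to_numpy(),
            "d": n_controls - c.to_numpy(),
        }
    ).reset_index(drop=True)
    return out.sort_values("code3", kind="stable").reset_index(drop=True)
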