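"""Shared fixtures: tiny hand-built claims bundles and generator configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from claimscc.claims import ClaimsBundle, CodeSets
from claimscc.simulate import ExposureSpec, SimConfig


def make_bundle(qual_rows, claim_rows) -> ClaimsBundle:
    """Build a bundle from terse tuples.

    ``qual_rows``: (person_id, sex, year, age_group, income_rank)
    ``claim_rows``: (person_id, visit_date, code[, source])
    """
    qual = pd.DataFrame(
        qual_rows, columns=["person_id", "sex", "year", "age_group", "income_rank"]
    )
    rows = []
    for i, r in enumerate(claim_rows):
        person, date, code = r[:3]
        source = r[3] if len(r) > 3 else "principal"
        rows.append((person, f"C{i:05d}", pd.Timestamp(date), code, source))
    claims = pd.DataFrame(
        rows, columns=["person_id", "claim_no", "visit_date", "code", "source"]
    )
    return ClaimsBundle(qualifications=qual, claims=claims)


def woman_qual(person: str, years, age_group: int = 6, income_rank: int = 5):
    return [(person, "female", y, age_group, income_rank) for y in years]


@pytest.fixture
def code_sets() -> CodeSets:
    return CodeSets()


@pytest.fixture
def clean_bundle() -> ClaimsBundle:
    """One woman, one clean vaginal-delivery episode."""
    return make_bundle(
        woman_qual("P1", range(2008, 2012)),
        [
            ("P1", "2010-01-10", "Z34.0"),   # pregnancy diagnosis
            ("P1", "2010-03-01", "K29.1"),   # antenatal non-pregnancy claim
            ("P1", "2009-06-01", "J30"),     # pre-conception claim
            ("P1", "2010-09-20", "O80"),     # delivery
        ],
    )


@pytest.fixture
def small_sim_config() -> SimConfig:
    return SimConfig(
        n_women=1200,
        jaundice_base_rate=0.05,
        exposures=(
            ExposureSpec("E10", 0.10, "ANC", 3.0),
            ExposureSpec("F41", 0.10, "preB", 1.0),
        ),
        noise_rate_per_30d=0.8,
    )
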