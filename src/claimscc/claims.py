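"""Domain types, code-set configuration, and IO for the claims tables.

Three delimited tables are consumed:

* **qualification** -- one row per (person, year):
  ``person_id, sex, year, age_group, income_rank``.  ``age_group`` is a
  5-year band index (0 = age 0, 1 = ages 1-4, 2 = ages 5-9, ..., 18 =
  85 and over); ``income_rank`` is 0-10 (0 = medical aid, 1-10 =
  income deciles).
* **statement** -- one row per claim:
  ``person_id, claim_no, visit_date, principal_dx, additional_dx``.
* **disease** -- extra diagnoses keyed by claim:
  ``claim_no, visit_date, dx``.

On read, the principal and additional diagnoses are fanned out and the
disease-table rows are attached via the claim number so that downstream
stages see a single long diagnosis stream; the origin of each row is
kept in a ``source`` column but is otherwise irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CLAIM_COLUMNS = ["person_id", "claim_no", "visit_date", "code", "source"]
QUAL_COLUMNS = ["person_id", "sex", "year", "age_group", "income_rank"]

#: Regrouping of the 11 income ranks (0 = medical aid, 1-10 = deciles)
#: into 5 analysis groups at 20% intervals, medical aid folded into the
#: lowest group.  Configurable because the exact fold is a convention.
DEFAULT_INCOME_REGROUP: dict[int, int] = {
    0: 1, 1: 1, 2: 1,
    3: 2, 4: 2,
    5: 3, 6: 3,
    7: 4, 8: 4,
    9: 5, 10: 5,
}

#: 5-year age-band index (qualification table) -> analysis band.
#: Bands outside 15-49 are ineligible and map to ``None``.
AGE_GROUP_TO_BAND: dict[int, str] = {
    4: "15-24", 5: "15-24",
    6: "25-34", 7: "25-34",
    8: "35-49", 9: "35-49", 10: "35-49",
}

AGE_BANDS = ("15-24", "25-34", "35-49")


def age_to_group(age: int) -> int:
    """5-year age-band index used by the qualification table."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age == 0:
        return 0
    if age < 5:
        return 1
    return min(age // 5 + 1, 18)


def truncate_code(code: str) -> str:
    """First three characters of a diagnosis code, uppercased.

    A dot in the fourth position (``"K29.1"``) is removed before
    truncation; codes shorter than three characters are rejected.
    """
    s = str(code).strip().upper()
    if len(s) >= 4 and s[3] == ".":
        s = s[:3] + s[4:]
    if len(s) < 3:
        raise ValueError(f"diagnosis code too short to truncate: {code!r}")
    return s[:3]


def _as_prefix_tuple(values: Iterable[str]) -> tuple[str, ...]:
    out = tuple(sorted({str(v).strip().upper() for v in values}))
    if any(not v for v in out):
        raise ValueError("empty code prefix")
    return out


@dataclass(frozen=True)
class CodeSets:
    """Diagnosis-code prefix sets that drive episode construction.

    Prefix matching is by plain string prefix on the *un-truncated*
    code, e.g. prefix ``"O84.1"`` matches ``"O84.1"`` and ``"O84.10"``
    but not ``"O84.2"``; prefix ``"O"`` matches the whole chapter.
    """

    pregnancy: tuple[str, ...] = ("O09", "Z32", "Z33", "Z34", "Z35", "Z36")
    delivery_vaginal: tuple[str, ...] = ("O80", "O81", "O83", "O84.0", "O84.1")
    delivery_cesarean: tuple[str, ...] = ("O82", "O84.2")
    jaundice: tuple[str, ...] = ("P58", "P59")
    preterm: tuple[str, ...] = ("O60",)
    multiple_gestation: tuple[str, ...] = ("O30", "O31", "O84")
    abortion: tuple[str, ...] = (
        "O00", "O01", "O02", "O03", "O04", "O05", "O06", "O07", "O08",
    )
    stillbirth: tuple[str, ...] = ("O36.4", "Z37.1", "Z37.4", "Z37.7")
    #: Prefixes regarded as pregnancy/delivery-related when deciding
    #: whether a case has any *other* diagnosis in an exposure window.
    pregnancy_related_exclusion: tuple[str, ...] = (
        "O", "P58", "P59",
        "Z32", "Z33", "Z34", "Z35", "Z36", "Z37", "Z38", "Z39",
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(self, f.name, _as_prefix_tuple(getattr(self, f.name)))
            if not getattr(self, f.name):
                raise ValueError(f"code set {f.name!r} must be non-empty")
        for a in self.delivery_cesarean:
            for b in self.delivery_vaginal:
                if a.startswith(b) or b.startswith(a):
                    raise ValueError(
                        f"cesarean/vaginal delivery sets overlap: {a!r} vs {b!r}"
                    )

    @property
    def delivery(self) -> tuple[str, ...]:
        return _as_prefix_tuple(self.delivery_vaginal + self.delivery_cesarean)

    def match(self, codes: pd.Series, which: str) -> pd.Series:
        """Boolean mask of codes matching the named prefix set."""
        prefixes = getattr(self, which)
        arr = np.char.upper(codes.to_numpy(dtype=str))
        mask = np.zeros(len(arr), dtype=bool)
        for p in prefixes:
            mask |= np.char.startswith(arr, p)
        return pd.Series(mask, index=codes.index)


def load_code_config(path: str | Path) -> CodeSets:
    """Load a :class:`CodeSets` from the ``code_sets`` section of a YAML
    config, filling defaults for any omitted set."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("code_sets", raw) or {}
    known = {f.name for f in fields(CodeSets)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown code_sets keys: {sorted(unknown)}")
    return replace(CodeSets(), **{k: tuple(v) for k, v in section.items()})


@dataclass(frozen=True)
class TableDialect:
    """Delimiter/date conventions for the three input tables."""

    delimiter: str = "\t"
    date_format: str = "%Y-%m-%d"


@dataclass
class ClaimsBundle:
    """A merged claim stream plus the qualification table.

    ``claims`` columns: person_id, claim_no, visit_date (datetime64),
    code (str), source ({principal, additional, disease_table}).
    ``qualifications`` columns: person_id, sex, year, age_group,
    income_rank.
    """

    qualifications: pd.DataFrame
    claims: pd.DataFrame
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        missing_q = [c for c in QUAL_COLUMNS if c not in self.qualifications.columns]
        missing_c = [c for c in CLAIM_COLUMNS if c not in self.claims.columns]
        if missing_q or missing_c:
            raise ValueError(f"missing columns: {missing_q + missing_c}")
        bad = ~self.qualifications["income_rank"].between(0, 10)
        if bad.any():
            raise ValueError("income_rank outside [0, 10]")
        known = set(self.qualifications["person_id"])
        unknown = set(self.claims["person_id"]) - known
        if unknown:
            raise ValueError(
                f"{len(unknown)} claim person_id(s) absent from the "
                f"qualification table, e.g. {sorted(unknown)[:3]}"
            )


def _parse_dates(raw: pd.Series, dialect: TableDialect, table: str) -> tuple[pd.Series, pd.Series]:
    parsed = pd.to_datetime(raw, format=dialect.date_format, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        logger.warning("%s: rejected %d row(s) with malformed visit_date", table, int(bad.sum()))
    return parsed, bad


def read_claims_tables(
    qual_path: str | Path,
    statement_path: str | Path,
    disease_path: str | Path,
    dialect: TableDialect | None = None,
) -> ClaimsBundle:
    """Read and merge the three claims tables into one diagnosis stream.

    The statement's principal and additional diagnoses each become one
    claim row (empty fields are skipped); disease-table rows are
    attached to their statement's person via the claim number.  Rows
    with malformed dates are dropped with a logged warning and counted
    in ``ClaimsBundle.n_rejected_rows``; a disease-table claim number
    absent from the statement table is an error.
    """
    dialect = dialect or TableDialect()
    sep = dialect.delimiter

    qual = pd.read_csv(qual_path, sep=sep, dtype={"person_id": str, "sex": str})
    qual["year"] = qual["year"].astype(int)
    qual["age_group"] = qual["age_group"].astype(int)
    qual["income_rank"] = qual["income_rank"].astype(int)

    stmt = pd.read_csv(
        statement_path, sep=sep,
        dtype={"person_id": str, "claim_no": str, "principal_dx": str, "additional_dx": str},
    )
    stmt["visit_date"], bad_s = _parse_dates(stmt["visit_date"], dialect, "statement")
    n_rejected = int(bad_s.sum())
    stmt = stmt[~bad_s]

    long = stmt.melt(
        id_vars=["person_id", "claim_no", "visit_date"],
        value_vars=["principal_dx", "additional_dx"],
        var_name="source", value_name="code",
    )
    long["source"] = long["source"].map({"principal_dx": "principal", "additional_dx": "additional"})
    long = long[long["code"].notna() & (long["code"].str.strip() != "")]

    dis = pd.read_csv(disease_path, sep=sep, dtype={"claim_no": str, "dx": str})
    dis["visit_date"], bad_d = _parse_dates(dis["visit_date"], dialect, "disease")
    n_rejected += int(bad_d.sum())
    dis = dis[~bad_d]
    dis = dis[dis["dx"].notna() & (dis["dx"].str.strip() != "")]

    claim_person = stmt.drop_duplicates("claim_no").set_index("claim_no")["person_id"]
    unknown = set(dis["claim_no"]) - set(claim_person.index)
    if unknown:
        raise ValueError(
            f"disease table references {len(unknown)} unknown claim_no(s), "
            f"e.g. {sorted(unknown)[:3]}"
        )
    dis = dis.rename(columns={"dx": "code"})
    dis["person_id"] = dis["claim_no"].map(claim_person)
    dis["source"] = "disease_table"

    claims = pd.concat(
        [long[CLAIM_COLUMNS], dis[CLAIM_COLUMNS]], ignore_index=True
    )
    claims["code"] = claims["code"].str.strip()
    return ClaimsBundle(qualifications=qual, claims=claims, n_rejected_rows=n_rejected)


def write_claims_tables(
    bundle: ClaimsBundle,
    out_dir: str | Path,
    dialect: TableDialect | None = None,
) -> dict[str, Path]:
    """Write a bundle back to the three-table layout (read round-trips).

    Claims with source ``principal``/``additional`` are folded back into
    statement rows; ``disease_table`` claims go to the disease table.
    """
    dialect = dialect or TableDialect()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = dialect.delimiter

    claims = bundle.claims.copy()
    claims["visit_date"] = claims["visit_date"].dt.strftime(dialect.date_format)

    stmt_rows = claims[claims["source"].isin(["principal", "additional"])]
    dup = stmt_rows.groupby(["claim_no", "source"]).size()
    if (dup > 1).any():
        raise ValueError("a claim_no has more than one principal or additional diagnosis")
    wide = stmt_rows.pivot(index=["person_id", "claim_no", "visit_date"],
                           columns="source", values="code").reset_index()
    for col in ("principal", "additional"):
        if col not in wide.columns:
            wide[col] = ""
    stmt = wide.rename(columns={"principal": "principal_dx", "additional": "additional_dx"})
    stmt = stmt[["person_id", "claim_no", "visit_date", "principal_dx", "additional_dx"]]
    stmt = stmt.fillna({"principal_dx": "", "additional_dx": ""})
    stmt = stmt.sort_values(["person_id", "visit_date", "claim_no"], kind="stable")

    dis = claims[claims["source"] == "disease_table"]
    dis = dis.rename(columns={"code": "dx"})[["claim_no", "visit_date", "dx"]]
    dis = dis.sort_values(["claim_no", "dx"], kind="stable")

    qual = bundle.qualifications.sort_values(["person_id", "year"], kind="stable")

    paths = {
        "qualification": out_dir / "qualification.tsv",
        "statement": out_dir / "statement.tsv",
        "disease": out_dir / "disease.tsv",
    }
    qual.to_csv(paths["qualification"], sep=sep, index=False)
    stmt.to_csv(paths["statement"], sep=sep, index=False)
    dis.to_csv(paths["disease"], sep=sep, index=False)
    return paths


def regroup_income(rank: pd.Series, mapping: Mapping[int, int] | None = None) -> pd.Series:
    """Map income ranks 0-10 to the 5 analysis groups."""
    mapping = dict(mapping or DEFAULT_INCOME_REGROUP)
    out = rank.map(mapping)
    if out.isna().any():
        raise ValueError("income rank outside the regroup mapping")
    return out.astype(int)
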