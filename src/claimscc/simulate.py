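"""Synthetic claims generator with planted ground truth.

Emits the three-table claims layout consumed by
:func:`claimscc.claims.read_claims_tables`, with planted
pregnancy-delivery episodes, configurable exposure codes with known
true odds ratios, covariate confounding, and optional injection of
records that exercise each exclusion stage.  The accompanying
:class:`SimTruth` records everything needed to verify pipeline
recovery: episode dates and flags, per-episode exposure indicators,
and realized prevalences.

Outcome labels are drawn from a logistic model

``logit P(outcome) = alpha + sum_k log(true_or_k) * exposed_k
+ log(mode_or) * cesarean + log(income_or) * (income_group - 3)``

with ``alpha`` calibrated so the realized outcome fraction matches the
configured base rate.  Exposure -> outcome is the generative direction,
so at low prevalence the case-control odds ratio approximates
``true_or``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from claimscc.claims import ClaimsBundle, CodeSets, age_to_group, regroup_income

EPOCH = np.datetime64("1970-01-01", "D")

#: Benign noise codes emitted at a background visit rate.  Deliberately
#: avoids chapter O, Z32-Z39, P58/P59 and anything a default exposure
#: spec might plant.
DEFAULT_NOISE_POOL = (
    "J00", "J02", "J03.9", "J06", "J20.9", "J30", "J34",
    "K21", "K29.1", "K30", "K52", "K59",
    "L23", "L50", "M54.5", "N39.0", "R05", "R10", "R51",
    "B34", "H10", "H66", "A09",
)


@dataclass(frozen=True)
class ExposureSpec:
    """One planted exposure code.

    ``window`` is where its claims are emitted: the antenatal period
    (``"ANC"``), the pre-conception year (``"preB"``), or ``"both"``.
    ``confounded_by_income`` tilts the exposure prevalence along the
    income gradient; ``confounded_by_mode`` tilts it toward cesarean
    episodes.
    """

    code3: str
    prevalence: float
    window: str = "ANC"
    true_or: float = 1.0
    confounded_by_income: bool = False
    confounded_by_mode: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.window not in ("ANC", "preB", "both"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give a clean mid-size cohort."""

    n_women: int = 5000
    year_start: int = 2002
    year_end: int = 2013
    second_episode_prob: float = 0.10
    episode_gap_min: int = 420   # days, delivery to next conception
    episode_gap_max: int = 1100
    gestation_mean: float = 280.0
    gestation_sd: float = 10.0
    gestation_min: int = 200
    gestation_max: int = 308
    pregnancy_claim_delay_min: int = 28   # days after conception
    pregnancy_claim_delay_max: int = 84
    cesarean_prob: float = 0.38
    cesarean_prob_multiple: float = 0.70
    multiple_gestation_prob: float = 0.015
    preterm_gestation_below: int = 259    # < 37 wk
    exposures: tuple[ExposureSpec, ...] = ()
    income_exposure_log_or: float = 0.35  # per income group when confounded
    mode_exposure_log_or: float = 0.60    # cesarean shift when confounded
    jaundice_base_rate: float = 0.02
    jaundice_mode_or: float = 1.6
    jaundice_income_or: float = 0.85      # per income group above the middle
    jaundice_claim_delay_max: int = 14
    noise_pool: tuple[str, ...] = DEFAULT_NOISE_POOL
    noise_rate_per_30d: float = 0.9
    medical_aid_prob: float = 0.03
    stillbirth_injection_rate: float = 0.0
    missing_qualification_rate: float = 0.0
    pregnancy_only_window_rate: float = 0.0
    pregnancy_code: str = "Z34.0"

    def __post_init__(self) -> None:
        for name in (
            "second_episode_prob", "cesarean_prob", "cesarean_prob_multiple",
            "multiple_gestation_prob", "jaundice_base_rate", "medical_aid_prob",
            "stillbirth_injection_rate", "missing_qualification_rate",
            "pregnancy_only_window_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gestation_max > 308:
            raise ValueError("gestation_max above 308 d would break pregnancy pairing")
        if self.jaundice_base_rate == 0 and any(e.true_or > 1 for e in self.exposures):
            raise ValueError("base rate 0 is infeasible with odds ratios above 1")
        pool3 = {c[:3] for c in self.noise_pool}
        planted = {e.code3 for e in self.exposures}
        if pool3 & planted:
            raise ValueError(f"noise pool collides with exposure codes: {pool3 & planted}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        exposures = tuple(ExposureSpec(**e) for e in raw.pop("exposures", []))
        if "noise_pool" in raw:
            raw["noise_pool"] = tuple(raw["noise_pool"])
        return cls(exposures=exposures, **raw)


@dataclass
class SimTruth:
    """Ground truth: one row per planted episode plus per-code summary."""

    episodes: pd.DataFrame
    exposure_summary: pd.DataFrame


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(alpha + lin)) = target for alpha."""
    if target <= 0 or target >= 1:
        raise ValueError("base rate must be inside (0, 1) to calibrate")

    def realized(alpha: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(alpha + lin)))
        return float(p.mean()) - target

    return brentq(realized, -30.0, 30.0, xtol=1e-10)


def _day(dates: np.ndarray) -> np.ndarray:
    return (dates - EPOCH).astype(np.int64)


def generate_dataset(config: SimConfig, seed: int = 0) -> tuple[ClaimsBundle, SimTruth]:
    """Generate a claims bundle plus its ground truth, deterministically.

    Planted episodes always satisfy the pipeline's temporal rules
    (gestation capped at 308 d, inter-episode gaps far above 168 d), so
    with all injection rates at zero the episode builder must recover
    them exactly.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n = cfg.n_women
    if n < 1:
        raise ValueError("n_women must be positive")

    person_ids = np.array([f"W{i:07d}" for i in range(n)])
    income_rank = np.where(
        rng.random(n) < cfg.medical_aid_prob, 0, rng.integers(1, 11, size=n)
    )
    income_group = regroup_income(pd.Series(income_rank)).to_numpy()

    # --- episode skeleton -------------------------------------------
    n_ep = 1 + (rng.random(n) < cfg.second_episode_prob).astype(np.int64)
    ep_person = np.repeat(np.arange(n), n_ep)
    ep_ord = np.concatenate([np.arange(k) for k in n_ep])
    E = len(ep_person)

    start = np.datetime64(f"{cfg.year_start}-01-01", "D")
    end = np.datetime64(f"{cfg.year_end}-12-31", "D")
    horizon = int((end - start).astype(int))
    # leave room for the pre-conception year, the pregnancy, the
    # postpartum window, and a possible second episode
    first_lo, first_hi = 400, horizon - 1900
    if first_hi < first_lo:
        raise ValueError("year range too short to host complete episodes")
    conception0 = rng.integers(first_lo, first_hi + 1, size=n)
    gest = np.clip(
        np.round(rng.normal(cfg.gestation_mean, cfg.gestation_sd, size=E)),
        cfg.gestation_min, cfg.gestation_max,
    ).astype(np.int64)
    gap = rng.integers(cfg.episode_gap_min, cfg.episode_gap_max + 1, size=E)

    conception = np.empty(E, dtype=np.int64)
    first_mask = ep_ord == 0
    conception[first_mask] = conception0[ep_person[first_mask]]
    second = np.flatnonzero(~first_mask)
    conception[second] = conception[second - 1] + gest[second - 1] + gap[second]
    conception_d = _day(start) + conception
    delivery_d = conception_d + gest
    preg_dx_d = conception_d + rng.integers(
        cfg.pregnancy_claim_delay_min, cfg.pregnancy_claim_delay_max + 1, size=E
    )

    age_at_conception = np.clip(np.round(rng.normal(29, 5, size=n)), 16, 44).astype(np.int64)
    conc_year = (EPOCH + conception_d).astype("datetime64[Y]").astype(int) + 1970
    # age is anchored at each woman's first conception
    birth_year = conc_year[np.searchsorted(ep_person, np.arange(n))] - age_at_conception

    multiple = rng.random(E) < cfg.multiple_gestation_prob
    p_ces = np.where(multiple, cfg.cesarean_prob_multiple, cfg.cesarean_prob)
    cesarean = rng.random(E) < p_ces
    preterm = gest < cfg.preterm_gestation_below

    # --- exposures ---------------------------------------------------
    exp_flags: dict[str, np.ndarray] = {}
    for spec in cfg.exposures:
        logit = math.log(spec.prevalence / (1 - spec.prevalence)) if 0 < spec.prevalence < 1 else None
        if logit is None:
            exposed = np.full(E, bool(spec.prevalence))
        else:
            shift = np.zeros(E)
            if spec.confounded_by_income:
                shift += cfg.income_exposure_log_or * (income_group[ep_person] - 3)
            if spec.confounded_by_mode:
                shift += cfg.mode_exposure_log_or * cesarean
            p = 1.0 / (1.0 + np.exp(-(logit + shift)))
            exposed = rng.random(E) < p
        exp_flags[spec.code3] = exposed

    # --- outcome -----------------------------------------------------
    lin = np.zeros(E)
    for spec in cfg.exposures:
        lin += math.log(spec.true_or) * exp_flags[spec.code3]
    lin += math.log(cfg.jaundice_mode_or) * cesarean
    lin += math.log(cfg.jaundice_income_or) * (income_group[ep_person] - 3)
    alpha = _calibrate_intercept(lin, cfg.jaundice_base_rate)
    jaundice = rng.random(E) < 1.0 / (1.0 + np.exp(-(alpha + lin)))

    # --- injections --------------------------------------------------
    inj_stillbirth = rng.random(E) < cfg.stillbirth_injection_rate
    inj_missing_qual = rng.random(E) < cfg.missing_qualification_rate
    inj_preg_only = rng.random(E) < cfg.pregnancy_only_window_rate

    # --- claim assembly ---------------------------------------------
    persons: list[np.ndarray] = []
    days: list[np.ndarray] = []
    codes: list[np.ndarray] = []

    def emit(person_idx: np.ndarray, day: np.ndarray, code: np.ndarray | str) -> None:
        persons.append(np.asarray(person_idx, dtype=np.int64))
        days.append(np.asarray(day, dtype=np.int64))
        if isinstance(code, str):
            codes.append(np.full(len(person_idx), code, dtype=object))
        else:
            codes.append(np.asarray(code, dtype=object))

    emit(ep_person, preg_dx_d, cfg.pregnancy_code)
    delivery_code = np.where(
        cesarean,
        np.where(multiple, "O84.2", "O82"),
        np.where(multiple, "O84.0", "O80"),
    )
    emit(ep_person, delivery_d, delivery_code)
    if preterm.any():
        emit(ep_person[preterm], delivery_d[preterm], "O60")
    if multiple.any():
        emit(ep_person[multiple], delivery_d[multiple] - rng.integers(0, 29, size=int(multiple.sum())), "O30")
    if jaundice.any():
        emit(
            ep_person[jaundice],
            delivery_d[jaundice] + rng.integers(0, cfg.jaundice_claim_delay_max + 1, size=int(jaundice.sum())),
            "P59.0",
        )
    if inj_stillbirth.any():
        emit(
            ep_person[inj_stillbirth],
            delivery_d[inj_stillbirth] + rng.integers(0, 29, size=int(inj_stillbirth.sum())),
            "Z37.1",
        )

    anc_lo, anc_hi = preg_dx_d, delivery_d - 1
    pre_lo, pre_hi = preg_dx_d - 365, preg_dx_d - 1
    for spec in cfg.exposures:
        exposed = exp_flags[spec.code3] & ~inj_preg_only
        if not exposed.any():
            continue
        idx = np.flatnonzero(exposed)
        suffix = rng.random(len(idx)) < 0.4
        full = np.where(suffix, spec.code3 + ".1", spec.code3).astype(object)
        if spec.window in ("ANC", "both"):
            d = rng.integers(anc_lo[idx], anc_hi[idx] + 1)
            emit(ep_person[idx], d, full)
        if spec.window in ("preB", "both"):
            d = rng.integers(pre_lo[idx], pre_hi[idx] + 1)
            emit(ep_person[idx], d, full)

    pool = np.array(cfg.noise_pool, dtype=object)
    for lo, hi in ((anc_lo, anc_hi), (pre_lo, pre_hi)):
        span = (hi - lo + 1).astype(float)
        counts = rng.poisson(cfg.noise_rate_per_30d * span / 30.0)
        counts[inj_preg_only] = 0
        total = int(counts.sum())
        if total:
            owner = np.repeat(np.arange(E), counts)
            d = rng.integers(lo[owner], hi[owner] + 1)
            emit(ep_person[owner], d, pool[rng.integers(0, len(pool), size=total)])

    person_arr = np.concatenate(persons)
    day_arr = np.concatenate(days)
    code_arr = np.concatenate(codes)

    claims = pd.DataFrame(
        {
            "person_id": person_ids[person_arr],
            "visit_date": pd.to_datetime(EPOCH + day_arr),
            "code": code_arr.astype(str),
        }
    ).sort_values(["person_id", "visit_date", "code"], kind="stable").reset_index(drop=True)

    # One claim per (person, visit date); the first diagnosis becomes the
    # statement's principal, the second its additional, the rest go to
    # the disease table -- exercising the three-way merge downstream.
    grp = claims.groupby(["person_id", "visit_date"], sort=False)
    claims["claim_no"] = "C" + pd.Series(grp.ngroup(), index=claims.index).astype(str).str.zfill(8)
    k = grp.cumcount()
    claims["source"] = np.select(
        [k == 0, k == 1], ["principal", "additional"], default="disease_table"
    )

    # --- qualification table ----------------------------------------
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    qperson = np.repeat(np.arange(n), len(years))
    qyear = np.tile(years, n)
    age = qyear - birth_year[qperson]
    qual = pd.DataFrame(
        {
            "person_id": person_ids[qperson],
            "sex": "female",
            "year": qyear,
            "age_group": [age_to_group(a) for a in np.maximum(age, 0)],
            "income_rank": income_rank[qperson],
        }
    )
    qual = qual[age >= 0].reset_index(drop=True)

    drop_years = set()
    if inj_missing_qual.any():
        dl_year = (delivery_d.astype("datetime64[D]").astype("datetime64[Y]").astype(int) + 1970)
        for e in np.flatnonzero(inj_missing_qual):
            drop_years.add((person_ids[ep_person[e]], int(dl_year[e])))
        mask = [
            (p, y) not in drop_years
            for p, y in zip(qual["person_id"], qual["year"])
        ]
        qual = qual[mask].reset_index(drop=True)

    bundle = ClaimsBundle(qualifications=qual, claims=claims[
        ["person_id", "claim_no", "visit_date", "code", "source"]
    ])

    # --- ground truth ------------------------------------------------
    dl_year = (delivery_d.astype("datetime64[D]").astype("datetime64[Y]").astype(int) + 1970)
    truth_ep = pd.DataFrame(
        {
            "person_id": person_ids[ep_person],
            "episode_ord": ep_ord,
            "conception": pd.to_datetime(EPOCH + conception_d),
            "pregnancy_dx_date": pd.to_datetime(EPOCH + preg_dx_d),
            "delivery_date": pd.to_datetime(EPOCH + delivery_d),
            "mode": np.where(cesarean, "cesarean", "vaginal"),
            "preterm": preterm,
            "multiple_gestation": multiple,
            "jaundice": jaundice,
            "income_rank": income_rank[ep_person],
            "income_group": income_group[ep_person],
            "age_at_delivery": dl_year - birth_year[ep_person],
            "injected_stillbirth": inj_stillbirth,
            # an episode is hit if either its delivery year or pregnancy
            # diagnosis year lost its qualification row
            "injected_missing_qualification": [
                (person_ids[p], int(dy)) in drop_years or (person_ids[p], int(py)) in drop_years
                for p, dy, py in zip(
                    ep_person,
                    dl_year,
                    (preg_dx_d.astype("datetime64[D]").astype("datetime64[Y]").astype(int) + 1970),
                )
            ],
            "injected_pregnancy_only_window": inj_preg_only,
        }
    )
    for code3, flags in exp_flags.items():
        truth_ep[f"exp_{code3}"] = flags

    summary = pd.DataFrame(
        {
            "code3": [s.code3 for s in cfg.exposures],
            "window": [s.window for s in cfg.exposures],
            "true_or": [s.true_or for s in cfg.exposures],
            "configured_prevalence": [s.prevalence for s in cfg.exposures],
            "realized_prevalence": [float(exp_flags[s.code3].mean()) for s in cfg.exposures],
        }
    )
    return bundle, SimTruth(episodes=truth_ep, exposure_summary=summary)


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Write the per-episode truth table as TSV (lossless round-trip)."""
    if truth.episodes.empty:
        raise ValueError("refusing to write empty truth")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = truth.episodes.copy()
    for col in ("conception", "pregnancy_dx_date", "delivery_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str})
    for col in ("conception", "pregnancy_dx_date", "delivery_date"):
        df[col] = pd.to_datetime(df[col])
    df["injected_missing_qualification"] = df["injected_missing_qualification"].astype(bool)
    return df
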