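"""Propensity-score matching, repeated re-matching, and stability rules.

Each repetition shuffles the record order, greedily matches every
outcome-positive case to the ``ratio`` nearest available controls by
propensity score (without replacement, ties broken by shuffled
position), and re-tests every candidate code on the matched sample.
A code is declared a risk (protective) factor when it is significant
in more than ``0.9 * n_reps`` repetitions with a mean odds ratio above
(below) 1 and a mean p-value below 0.05; means are taken over the
significant repetitions only, and infinite odds ratios are excluded
from the mean but still counted as significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from claimscc.exact import ContingencyTable, ExactTestResult, fisher_2x2


@dataclass
class PropensityModel:
    """Fitted logistic model of case status on age band + income group."""

    params: pd.Series
    scores: np.ndarray  # aligned with the cases frame, values in (0, 1)


@dataclass
class MatchedSample:
    """One repetition's matched strata.

    ``strata`` maps each case row index to the row indices of its
    matched controls (arrays of length ``ratio``); indices refer to the
    cases frame used for matching.
    """

    strata: list[tuple[int, np.ndarray]]
    rep_index: int = 0
    ratio: int = 10

    @property
    def case_rows(self) -> np.ndarray:
        return np.array([s[0] for s in self.strata], dtype=np.int64)

    @property
    def control_rows(self) -> np.ndarray:
        if not self.strata:
            return np.array([], dtype=np.int64)
        return np.concatenate([s[1] for s in self.strata])


@dataclass
class StabilityAggregate:
    """Per-code tally over the repeated matched samples."""

    code3: str
    n_reps: int
    n_significant: int
    mean_or: float
    mean_p: float
    mean_case_count: float
    mean_control_count: float
    n_infinite_or: int
    label: str = "none"


def _design_matrix(cases: pd.DataFrame) -> pd.DataFrame:
    X = pd.get_dummies(
        cases[["age_band", "income_group"]].astype({"income_group": "category"}),
        columns=["age_band", "income_group"],
        drop_first=True,
        dtype=float,
    )
    X.insert(0, "intercept", 1.0)
    return X


def estimate_propensity(cases: pd.DataFrame) -> PropensityModel:
    """Logistic propensity model: outcome ~ age band + income group.

    Both covariates enter as categorical indicators.  Raises
    ``ValueError`` on a single outcome class or complete separation.
    """
    y = cases["jaundice"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to fit a propensity model")
    X = _design_matrix(cases)
    try:
        fit = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
    except Exception as err:  # statsmodels raises on perfect separation
        raise ValueError(f"propensity model failed (separation?): {err}") from err
    params = pd.Series(fit.params, index=X.columns)
    if not np.all(np.isfinite(params)):
        raise ValueError(f"complete separation: non-finite coefficients {params.to_dict()}")
    scores = np.asarray(fit.predict(X.to_numpy()), dtype=float)
    return PropensityModel(params=params, scores=scores)


def nearest_neighbor_match(
    scores: np.ndarray,
    is_case: np.ndarray,
    ratio: int = 10,
    order_seed: int | np.random.Generator = 0,
    rep_index: int = 0,
) -> MatchedSample:
    """Greedy 1:``ratio`` nearest-neighbor matching without replacement.

    All records are shuffled; cases are processed in shuffled order and
    each takes the ``ratio`` available controls with the smallest
    absolute score difference, ties broken in favour of the control
    earlier in the shuffled order.  Matched controls leave the pool.
    Raises ``ValueError`` naming the failing case if the pool empties.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    n = len(scores)
    rng = (
        order_seed
        if isinstance(order_seed, np.random.Generator)
        else np.random.default_rng(order_seed)
    )
    perm = rng.permutation(n)
    rank = np.empty(n, dtype=np.int64)
    rank[perm] = np.arange(n)

    case_rows = perm[is_case[perm]]
    ctrl_rows = np.flatnonzero(~is_case)
    if len(ctrl_rows) < ratio * len(case_rows):
        raise ValueError(
            f"control pool too small: {len(ctrl_rows)} controls for "
            f"{len(case_rows)} cases at ratio {ratio}"
        )

    # Controls are bucketed by distinct score value.  Within a bucket the
    # tie-break ("earlier shuffled position wins") makes consumption a
    # FIFO in shuffled-rank order, so each bucket is a pre-sorted queue
    # with a moving front pointer.  Non-empty buckets are navigated with
    # a doubly linked list plus a path-compressed next-live map.
    vals, grp = np.unique(scores[ctrl_rows], return_inverse=True)
    order = np.lexsort((rank[ctrl_rows], grp))
    q_grp = grp[order]
    q_rank = rank[ctrl_rows][order]
    q_id = ctrl_rows[order]
    g = len(vals)
    starts = np.searchsorted(q_grp, np.arange(g))
    ends = np.searchsorted(q_grp, np.arange(g), side="right")
    front = starts.copy()

    nxt = np.arange(1, g + 2)  # bucket g is the right sentinel
    prv = np.arange(-1, g + 1)
    live_right = np.arange(g + 2)

    def find_right(pos: int) -> int:
        root = pos
        while live_right[root] != root:
            root = live_right[root]
        while live_right[pos] != root:
            live_right[pos], pos = root, live_right[pos]
        return root

    def drop_bucket(j: int) -> None:
        p, q = prv[j], nxt[j]
        if p >= 0:
            nxt[p] = q
        prv[q] = p
        live_right[j] = q

    strata: list[tuple[int, np.ndarray]] = []
    for case_row in case_rows:
        s = scores[case_row]
        pos = int(np.searchsorted(vals, s))
        r = find_right(pos)
        l = prv[r] if r <= g else prv[g]
        picked = np.empty(ratio, dtype=np.int64)
        for t in range(ratio):
            dl = s - vals[l] if l >= 0 else np.inf
            dr = vals[r] - s if r < g else np.inf
            if not np.isfinite(dl) and not np.isfinite(dr):
                raise ValueError(f"control pool exhausted while matching case row {case_row}")
            if dl < dr:
                take_left = True
            elif dr < dl:
                take_left = False
            else:  # equidistant buckets: earlier shuffled front wins
                take_left = q_rank[front[l]] < q_rank[front[r]]
            b = l if take_left else r
            picked[t] = q_id[front[b]]
            front[b] += 1
            if front[b] == ends[b]:
                if take_left:
                    new_l = prv[l]
                    drop_bucket(l)
                    l = new_l
                else:
                    new_r = nxt[r]
                    drop_bucket(r)
                    r = new_r
        strata.append((int(case_row), picked))
    return MatchedSample(strata=strata, rep_index=rep_index, ratio=ratio)


def _exposure_matrix(
    cases: pd.DataFrame, profiles: pd.DataFrame, codes: Sequence[str]
) -> dict[str, np.ndarray]:
    """code3 -> boolean exposure vector aligned with the cases frame."""
    pos = {cid: i for i, cid in enumerate(cases["case_id"])}
    out = {c: np.zeros(len(cases), dtype=bool) for c in codes}
    sub = profiles[profiles["code3"].isin(set(codes))]
    for code, cid in zip(sub["code3"], sub["case_id"]):
        i = pos.get(cid)
        if i is not None:
            out[code][i] = True
    return out


def evaluate_matched_sample(
    sample: MatchedSample,
    exposure: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> dict[str, tuple[ContingencyTable, ExactTestResult | None, bool]]:
    """Per-code 2x2 table, exact test, and significance on one matched sample.

    Significance requires the exact CI to exclude 1 *and* p below
    ``alpha``.  A code absent from the whole matched sample yields a
    zero-exposure table, no test (zero margin), and not-significant.
    """
    case_rows = sample.case_rows
    ctrl_rows = sample.control_rows
    n_j, n_c = len(case_rows), len(ctrl_rows)
    out: dict[str, tuple[ContingencyTable, ExactTestResult | None, bool]] = {}
    for code, vec in exposure.items():
        a = int(vec[case_rows].sum())
        c = int(vec[ctrl_rows].sum())
        table = ContingencyTable(a, n_j - a, c, n_c - c)
        if a + c == 0 or (table.b + table.d) == 0:
            out[code] = (table, None, False)
            continue
        res = fisher_2x2(table, alpha=alpha)
        out[code] = (table, res, res.significant(alpha))
    return out


def classify_factor(agg: StabilityAggregate, fraction: float = 0.9) -> str:
    """Risk/protective/none from the stability tallies.

    ``risk`` iff strictly more than ``fraction * n_reps`` significant
    repetitions with mean OR > 1 and mean p < 0.05; ``protective`` the
    same with mean OR < 1; otherwise ``none``.
    """
    if agg.n_significant <= fraction * agg.n_reps:
        return "none"
    if not np.isfinite(agg.mean_p) or agg.mean_p >= 0.05:
        return "none"
    if np.isfinite(agg.mean_or) and agg.mean_or > 1:
        return "risk"
    if np.isfinite(agg.mean_or) and agg.mean_or < 1:
        return "protective"
    return "none"


def run_stability(
    cases: pd.DataFrame,
    profiles: pd.DataFrame,
    codes: Sequence[str] | None = None,
    n_reps: int = 1000,
    master_seed: int = 0,
    ratio: int = 10,
    alpha: float = 0.05,
    fraction: float = 0.9,
    collect_details: bool = False,
) -> tuple[dict[str, StabilityAggregate], list | None]:
    """Repeat shuffled matching ``n_reps`` times and aggregate per code.

    The propensity model is fitted once (shuffling changes only the
    matching order, not the scores); repetition seeds derive from
    ``master_seed`` by counter, so results are bit-for-bit reproducible.
    When ``collect_details`` is true, each repetition's matched sample
    and per-code significance flags are returned for downstream
    adjusted models.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if codes is None:
        codes = sorted(profiles["code3"].unique())
    model = estimate_propensity(cases)
    is_case = cases["jaundice"].to_numpy(dtype=bool)
    exposure = _exposure_matrix(cases, profiles, codes)

    n_sig = {c: 0 for c in codes}
    n_inf = {c: 0 for c in codes}
    sum_or = {c: 0.0 for c in codes}
    n_or = {c: 0 for c in codes}
    sum_p = {c: 0.0 for c in codes}
    sum_a = {c: 0.0 for c in codes}
    sum_c = {c: 0.0 for c in codes}
    details: list[tuple[MatchedSample, dict[str, bool]]] | None = (
        [] if collect_details else None
    )

    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        try:
            sample = nearest_neighbor_match(
                model.scores, is_case, ratio=ratio, order_seed=rng, rep_index=rep
            )
        except ValueError as err:
            raise ValueError(f"matching failed at repetition {rep}: {err}") from err
        evaluated = evaluate_matched_sample(sample, exposure, alpha=alpha)
        flags: dict[str, bool] = {}
        for code, (table, res, sig) in evaluated.items():
            flags[code] = sig
            if sig:
                n_sig[code] += 1
                sum_p[code] += res.p
                sum_a[code] += table.a
                sum_c[code] += table.c
                if np.isfinite(res.or_cmle):
                    sum_or[code] += res.or_cmle
                    n_or[code] += 1
                else:
                    n_inf[code] += 1
        if details is not None:
            details.append((sample, flags))

    aggregates: dict[str, StabilityAggregate] = {}
    for code in codes:
        k = n_sig[code]
        agg = StabilityAggregate(
            code3=code,
            n_reps=n_reps,
            n_significant=k,
            mean_or=sum_or[code] / n_or[code] if n_or[code] else float("nan"),
            mean_p=sum_p[code] / k if k else float("nan"),
            mean_case_count=sum_a[code] / k if k else float("nan"),
            mean_control_count=sum_c[code] / k if k else float("nan"),
            n_infinite_or=n_inf[code],
        )
        agg.label = classify_factor(agg, fraction=fraction)
        aggregates[code] = agg
    return aggregates, details
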