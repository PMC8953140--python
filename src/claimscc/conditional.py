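"""Stratified conditional logistic regression for matched sets.

Each matched stratum contributes ``exp(x_case . beta) /
sum_j exp(x_j . beta)`` to the conditional likelihood (the per-stratum
intercept cancels).  The fit is a plain Newton iteration with
step-halving; Wald confidence intervals come from the observed
information.  Covariates with no within-stratum variation carry no
information and are reported as non-estimable rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from claimscc.matching import MatchedSample

#: Covariate order used by the adjusted models.
ADJUST_COVARIATES = ("exposure", "preterm", "cesarean", "multiple_gestation", "anc_duration")

#: |beta| beyond which a coefficient is flagged as separated (an odds
#: ratio beyond exp(12) ~ 1.6e5 is never a real within-stratum effect).
_SEPARATION_BOUND = 12.0


@dataclass
class AdjustedModelResult:
    """Per-covariate adjusted odds ratios from one matched sample."""

    code3: str
    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    adjusted_or: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    converged: bool
    estimable: np.ndarray  # False where the covariate had no within-stratum variation
    n_strata: int = 0
    loglik: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code3": self.code3,
                "covariate": list(self.covariates),
                "beta": self.beta,
                "adjusted_or": self.adjusted_or,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
                "estimable": self.estimable,
                "converged": self.converged,
            }
        )


def conditional_loglik(X: np.ndarray, beta: np.ndarray) -> float:
    """Conditional log-likelihood; the case is member 0 of each stratum."""
    eta = X @ beta
    return float(eta[:, 0].sum() - np.log(np.exp(eta - eta.max(axis=1, keepdims=True)).sum(axis=1)).sum()
                 - eta.max(axis=1).sum())


def _newton_fit(
    X: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Newton maximization of the conditional likelihood.

    ``X`` has shape (strata, members, covariates) with the case first in
    every stratum.  Returns (beta, covariance, converged, loglik).
    """
    S, m, k = X.shape
    beta = np.zeros(k)
    ll = conditional_loglik(X, beta)
    converged = False
    H = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        w /= w.sum(axis=1, keepdims=True)          # (S, m)
        xbar = np.einsum("sm,smk->sk", w, X)       # weighted mean per stratum
        grad = (X[:, 0, :] - xbar).sum(axis=0)
        Ewxx = np.einsum("sm,smj,smk->jk", w, X, X)
        H = Ewxx - xbar.T @ xbar
        if np.linalg.norm(grad) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the iteration ascending
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll = conditional_loglik(X, new_beta)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        if abs(new_ll - ll) < tol * max(1.0, abs(ll)) and np.linalg.norm(factor * step) < 1e-8:
            beta, ll = new_beta, new_ll
            converged = True
            break
        beta, ll = new_beta, new_ll
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, converged, ll


def build_design(
    cases: pd.DataFrame,
    sample: MatchedSample,
    exposed: np.ndarray,
) -> np.ndarray:
    """(strata, 1 + ratio, covariates) design array for one code.

    Member 0 of each stratum is the case; covariates follow
    :data:`ADJUST_COVARIATES` (exposure flag, preterm, cesarean mode,
    multiple gestation, antenatal duration in days).
    """
    feat = np.column_stack(
        [
            np.asarray(exposed, dtype=float),
            cases["preterm"].to_numpy(dtype=float),
            (cases["mode"].to_numpy() == "cesarean").astype(float),
            cases["multiple_gestation"].to_numpy(dtype=float),
            cases["anc_duration"].to_numpy(dtype=float),
        ]
    )
    rows = np.column_stack([sample.case_rows[:, None], np.vstack([s[1] for s in sample.strata])])
    return feat[rows]  # (S, 1 + ratio, k)


def conditional_logit_fit(
    X: np.ndarray,
    covariates: Sequence[str] = ADJUST_COVARIATES,
    code3: str = "",
    alpha: float = 0.05,
    max_iter: int = 100,
) -> AdjustedModelResult:
    """Fit the conditional-logit model on pre-built strata.

    Covariates constant within every stratum are dropped from the fit
    and reported with ``estimable=False`` (NaN estimates).  Separated
    coefficients are returned as signed infinity with NaN intervals.
    Non-convergence within ``max_iter`` iterations returns the last
    estimate with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    S, m, k = X.shape
    if len(covariates) != k:
        raise ValueError("covariate names must match the design's last dimension")
    spread = X.max(axis=1) - X.min(axis=1)  # (S, k)
    estimable = (spread > 0).any(axis=0)

    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    converged = True
    ll = float("nan")
    if estimable.any():
        sub = X[:, :, estimable]
        b, cov, converged, ll = _newton_fit(sub, max_iter=max_iter)
        sub_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        separated = np.abs(b) > _SEPARATION_BOUND
        b = b.copy()
        b[separated] = np.sign(b[separated]) * np.inf
        sub_se[separated] = np.nan
        beta[estimable] = b
        se[estimable] = sub_se

    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(invalid="ignore", over="ignore"):
        or_ = np.exp(beta)
        ci_low = np.exp(beta - z * se)
        ci_high = np.exp(beta + z * se)
        pvals = 2 * stats.norm.sf(np.abs(beta) / se)
    return AdjustedModelResult(
        code3=code3,
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        adjusted_or=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        converged=bool(converged),
        estimable=estimable,
        n_strata=S,
        loglik=ll,
    )


def fit_adjusted_for_code(
    cases: pd.DataFrame,
    sample: MatchedSample,
    exposed: np.ndarray,
    code3: str,
) -> AdjustedModelResult:
    """Convenience: build the design for one code and fit."""
    X = build_design(cases, sample, exposed)
    return conditional_logit_fit(X, code3=code3)


def aggregate_adjusted(
    per_rep_results: Sequence[AdjustedModelResult],
    significance_flags: Sequence[bool],
) -> pd.DataFrame:
    """Average adjusted results over the univariably-significant reps.

    Means are taken per covariate over repetitions whose univariable
    test was significant; non-finite estimates (separation) are
    excluded from the means and counted in ``n_nonfinite``.  Returns an
    empty frame when no repetition was significant.
    """
    if len(per_rep_results) != len(significance_flags):
        raise ValueError("one significance flag per repetition is required")
    used = [r for r, sig in zip(per_rep_results, significance_flags) if sig]
    if not used:
        return pd.DataFrame(
            columns=["code3", "covariate", "mean_or", "mean_ci_low", "mean_ci_high",
                     "mean_p", "n_used", "n_nonfinite"]
        )
    covs = used[0].covariates
    code3 = used[0].code3
    rows = []
    for j, cov in enumerate(covs):
        ors = np.array([r.adjusted_or[j] for r in used])
        lows = np.array([r.ci_low[j] for r in used])
        highs = np.array([r.ci_high[j] for r in used])
        ps = np.array([r.p[j] for r in used])
        ok = np.isfinite(ors)
        rows.append(
            {
                "code3": code3,
                "covariate": cov,
                "mean_or": float(ors[ok].mean()) if ok.any() else float("nan"),
                "mean_ci_low": float(lows[ok & np.isfinite(lows)].mean()) if (ok & np.isfinite(lows)).any() else float("nan"),
                "mean_ci_high": float(highs[ok & np.isfinite(highs)].mean()) if (ok & np.isfinite(highs)).any() else float("nan"),
                "mean_p": float(ps[np.isfinite(ps)].mean()) if np.isfinite(ps).any() else float("nan"),
                "n_used": int(ok.sum()),
                "n_nonfinite": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)
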