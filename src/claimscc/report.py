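"""End-to-end pipeline orchestration and report emission.

:func:`run_pipeline` reads (or accepts) a claims bundle, builds the
delivery cases, and for each requested study produces:

* ``demographics_<study>.tsv`` -- group sizes, covariate distributions
  and their p-values (exact r x c Monte-Carlo for age/income, Fisher
  for binary flags, Welch t for the antenatal duration, trend test for
  income);
* ``unmatched_<study>.tsv``    -- per-code 2x2 counts with the exact
  OR/CI/p, sorted by descending OR;
* ``stability_<study>.tsv``    -- repeated-matching aggregates for the
  codes passing the stability rule;
* ``adjusted_<study>.tsv``     -- averaged conditional-logit results
  for those codes;
* ``ledger.tsv``               -- the exclusion cascade;
* ``network.tsv``              -- the labeled factor edge list.

All randomness derives from ``master_seed``; a rerun with the same
seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from claimscc.claims import ClaimsBundle, CodeSets
from claimscc.conditional import aggregate_adjusted, fit_adjusted_for_code
from claimscc.episodes import ExclusionLedger, build_delivery_cases
from claimscc.exact import (
    ContingencyTable,
    cochran_armitage,
    fisher_2x2,
    fisher_rxc_mc,
    welch_t,
)
from claimscc.exposures import apply_eligibility, extract_window_profiles, tabulate_all
from claimscc.matching import _exposure_matrix, run_stability

_STAGE_NAMES = ("demographics", "rxc", "stability_A", "stability_B")


@dataclass
class PipelineConfig:
    """Knobs for one end-to-end run."""

    out_dir: str | Path = "report"
    study: str = "both"            # "A", "B", or "both"
    match_ratio: int = 10
    n_reps: int = 1000
    master_seed: int = 0
    alpha: float = 0.05
    classification_fraction: float = 0.9
    fit_adjusted: bool = True
    code_sets: CodeSets = field(default_factory=CodeSets)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")
        if not 0 < self.classification_fraction < 1:
            raise ValueError("classification_fraction must be in (0, 1)")
        if self.study not in ("A", "B", "both"):
            raise ValueError("study must be 'A', 'B' or 'both'")

    @property
    def studies(self) -> tuple[str, ...]:
        return ("A", "B") if self.study == "both" else (self.study,)


def _fmt(x: float, nd: int = 6) -> str:
    if not np.isfinite(x):
        return "inf" if x > 0 else ("-inf" if x < 0 else "nan")
    return f"{x:.{nd}g}"


def demographics_table(cases: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Covariate distribution of the jaundice vs control groups."""
    rng = np.random.default_rng(seed)
    jd = cases[cases["jaundice"]]
    ct = cases[~cases["jaundice"]]
    rows: list[dict] = []

    def add(characteristic, level, n_j, n_c, p=None):
        rows.append(
            {
                "characteristic": characteristic,
                "level": level,
                "jaundice": n_j,
                "jaundice_pct": round(100 * n_j / max(len(jd), 1), 1),
                "control": n_c,
                "control_pct": round(100 * n_c / max(len(ct), 1), 1),
                "p": p,
            }
        )

    for name, col, levels in (
        ("age", "age_band", sorted(cases["age_band"].unique())),
        ("income", "income_group", sorted(cases["income_group"].unique())),
    ):
        counts = np.array(
            [[(jd[col] == lv).sum() for lv in levels], [(ct[col] == lv).sum() for lv in levels]]
        )
        usable = counts.sum(axis=0) > 0
        p = np.nan
        if usable.sum() >= 2 and counts.sum(axis=1).min() > 0:
            p = fisher_rxc_mc(counts[:, usable], n_mc=10_000, seed=rng)
        for lv in levels:
            add(name, lv, int((jd[col] == lv).sum()), int((ct[col] == lv).sum()),
                p if lv == levels[0] else None)
        if name == "income" and usable.sum() >= 3:
            trend = cochran_armitage(counts[0, usable], counts.sum(axis=0)[usable])
            add("income_trend", "", 0, 0, trend.p)

    for name, col in (
        ("preterm", "preterm"),
        ("cesarean", "mode"),
        ("multiple_gestation", "multiple_gestation"),
    ):
        fj = (jd[col] == "cesarean").sum() if col == "mode" else int(jd[col].sum())
        fc = (ct[col] == "cesarean").sum() if col == "mode" else int(ct[col].sum())
        table = ContingencyTable(int(fj), len(jd) - int(fj), int(fc), len(ct) - int(fc))
        p = np.nan
        if 0 < table.a + table.c and table.b + table.d > 0:
            p = fisher_2x2(table).p
        add(name, "", int(fj), int(fc), p)

    if len(jd) >= 2 and len(ct) >= 2:
        _, p = welch_t(
            len(jd), jd["anc_duration"].mean(), jd["anc_duration"].std(ddof=1),
            len(ct), ct["anc_duration"].mean(), ct["anc_duration"].std(ddof=1),
        )
    else:
        p = np.nan
    rows.append(
        {
            "characteristic": "anc_duration",
            "level": "mean_sd",
            "jaundice": round(jd["anc_duration"].mean(), 2),
            "jaundice_pct": round(jd["anc_duration"].std(ddof=1), 2),
            "control": round(ct["anc_duration"].mean(), 2),
            "control_pct": round(ct["anc_duration"].std(ddof=1), 2),
            "p": p,
        }
    )
    return pd.DataFrame(rows)


def unmatched_table(cases: pd.DataFrame, profiles: pd.DataFrame, code_sets: CodeSets, study: str) -> pd.DataFrame:
    """Exact OR/CI/p per observed code, sorted by descending OR."""
    counts = tabulate_all(cases, profiles, code_sets, study=study)
    rows = []
    for rec in counts.itertuples():
        table = ContingencyTable(rec.a, rec.b, rec.c, rec.d)
        if rec.a + rec.c == 0 or rec.b + rec.d == 0:
            continue
        res = fisher_2x2(table)
        rows.append(
            {
                "code3": rec.code3,
                "exposed_cases": rec.a,
                "exposed_controls": rec.c,
                "or_cmle": res.or_cmle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows, columns=["code3", "exposed_cases", "exposed_controls",
                                      "or_cmle", "ci_low", "ci_high", "p"])
    return out.sort_values(["or_cmle", "code3"], ascending=[False, True], kind="stable").reset_index(drop=True)


def export_network(aggregates_by_study: dict[str, dict], out_path: str | Path) -> pd.DataFrame:
    """Edge list of labeled factors: one edge per (study, labeled code).

    Only codes classified risk/protective appear; an empty network
    still writes the header.
    """
    rows = []
    for study in sorted(aggregates_by_study):
        for code, agg in sorted(aggregates_by_study[study].items()):
            if agg.label == "none":
                continue
            rows.append(
                {
                    "source": code,
                    "target": "outcome",
                    "study": study,
                    "label": agg.label,
                    "mean_or": agg.mean_or,
                    "mean_cases": agg.mean_case_count,
                }
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "study", "label", "mean_or", "mean_cases"])
    edges.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return edges


def stability_frame(aggregates: dict, fraction: float, n_reps: int) -> pd.DataFrame:
    """Rows for codes passing the stability rule, stable ordering."""
    rows = [
        {
            "code3": a.code3,
            "n_reps": a.n_reps,
            "n_significant": a.n_significant,
            "mean_case_count": a.mean_case_count,
            "mean_control_count": a.mean_control_count,
            "mean_or": a.mean_or,
            "mean_p": a.mean_p,
            "n_infinite_or": a.n_infinite_or,
            "label": a.label,
        }
        for a in aggregates.values()
        if a.n_significant > fraction * n_reps
    ]
    out = pd.DataFrame(rows, columns=["code3", "n_reps", "n_significant", "mean_case_count",
                                      "mean_control_count", "mean_or", "mean_p",
                                      "n_infinite_or", "label"])
    return out.sort_values("code3", kind="stable").reset_index(drop=True)


def run_pipeline(bundle: ClaimsBundle, config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code_sets = config.code_sets

    stage_seeds = np.random.SeedSequence(config.master_seed).spawn(len(_STAGE_NAMES))
    seed_of = dict(zip(_STAGE_NAMES, stage_seeds))

    cases, ledger = build_delivery_cases(bundle, code_sets)
    aggregates_by_study: dict[str, dict] = {}

    for study in config.studies:
        profiles = extract_window_profiles(cases, bundle.claims, study)
        study_ledger = ExclusionLedger(**{
            f: getattr(ledger, f) for f in ("n_women", "n_candidate_events", "retained",
                                            "no_delivery", "age_out_of_range",
                                            "no_pregnancy_pairing", "mode_unidentified",
                                            "abortion_or_stillbirth", "qualification_incomplete")
        })
        eligible = apply_eligibility(cases, profiles, code_sets, ledger=study_ledger)
        study_ledger.retained = len(eligible)
        profiles = profiles[profiles["case_id"].isin(set(eligible["case_id"]))]

        demo_seed = int(np.random.default_rng(seed_of["demographics"]).integers(2**31))
        demographics_table(eligible, demo_seed).to_csv(
            out_dir / f"demographics_{study}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        unmatched = unmatched_table(eligible, profiles, code_sets, study)
        unmatched.to_csv(out_dir / f"unmatched_{study}.tsv", sep="\t", index=False, float_format="%.6g")
        study_ledger.as_frame().to_csv(out_dir / f"ledger_{study}.tsv", sep="\t", index=False)

        codes = list(unmatched["code3"])
        rep_seed = int(np.random.default_rng(seed_of[f"stability_{study}"]).integers(2**31))
        aggregates, details = run_stability(
            eligible, profiles, codes=codes,
            n_reps=config.n_reps, master_seed=rep_seed,
            ratio=config.match_ratio, alpha=config.alpha,
            fraction=config.classification_fraction,
            collect_details=config.fit_adjusted,
        )
        aggregates_by_study[study] = aggregates
        stab = stability_frame(aggregates, config.classification_fraction, config.n_reps)
        stab.to_csv(out_dir / f"stability_{study}.tsv", sep="\t", index=False, float_format="%.10g")

        if config.fit_adjusted and details is not None:
            exposure = _exposure_matrix(eligible, profiles, list(stab["code3"]))
            frames = []
            for code in stab["code3"]:
                per_rep = [
                    fit_adjusted_for_code(eligible, sample, exposure[code], code)
                    for sample, flags in details
                ]
                flags = [flags[code] for _, flags in details]
                frames.append(aggregate_adjusted(per_rep, flags))
            adj = pd.concat(frames, ignore_index=True) if frames else aggregate_adjusted([], [])
            adj.to_csv(out_dir / f"adjusted_{study}.tsv", sep="\t", index=False, float_format="%.6g")

    export_network(aggregates_by_study, out_dir / "network.tsv")
    echo = asdict(config)
    echo["code_sets"] = {k: list(v) for k, v in echo["code_sets"].items()}
    echo["out_dir"] = str(echo["out_dir"])
    (out_dir / "run_config.json").write_text(json.dumps(echo, indent=2, sort_keys=True))
    return out_dir
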