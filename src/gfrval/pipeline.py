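"""End-to-end validation study: cohorts -> RBF training -> three estimators
-> agreement tables, Bland-Altman statistics, stage concordance, and the
nonparametric test battery.

The study report mirrors the layout of a method-comparison paper:

* table 1 - per-stage demographic / clinical summary of the validation cohort
* table 2 - per-stage medians (IQR) of the reference GFR and all estimates,
  with within-group signed-rank tests of each estimator against the reference
* table 3 - per-stage bias / precision / accuracy summaries per estimator,
  with between-stage and between-estimator comparisons
* Bland-Altman mean difference and 95% limits of agreement per estimator
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .cohort import (
    Cohort,
    CohortSpec,
    default_training_spec,
    default_validation_spec,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .estimators import add_estimates, stage_groups
from .rbf import RBFModel, predict, save_model, train_exact

__all__ = ["StudyConfig", "StudyReport", "run_study", "render_report"]

logger = logging.getLogger(__name__)

ESTIMATORS = ("egfr4", "egfr6", "egfr_rbf")
GROUPS = ("overall", "I_II", "III", "IV_V")

#: Seed offset separating the validation stream from the training stream.
VALIDATION_SEED_OFFSET = 1000


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run one validation study deterministically."""

    training: Union[CohortSpec, str]
    validation: Union[CohortSpec, str]
    spread: float = 1.0
    ridge: float = 0.0
    tolerances: tuple = (0.15, 0.30, 0.50)
    alpha: float = 0.05
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        tols = tuple(self.tolerances)
        if any(not (0 < t < 1) for t in tols) or list(tols) != sorted(set(tols)):
            raise ValueError("tolerances must be strictly increasing in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        object.__setattr__(self, "tolerances", tols)

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "StudyConfig":
        """Default study: 327-record training spec, shifted 207-record
        validation spec, with cohort seeds derived from ``seed``."""
        return cls(
            training=default_training_spec(seed=seed),
            validation=default_validation_spec(seed=seed + VALIDATION_SEED_OFFSET),
            seed=seed,
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("training", "validation"):
            if isinstance(raw.get(key), dict):
                raw[key] = CohortSpec.from_dict(raw[key])
        if "tolerances" in raw:
            raw["tolerances"] = tuple(raw["tolerances"])
        return cls(**raw)


@dataclasses.dataclass
class StudyReport:
    config: dict
    cohort_table: dict
    gfr_table: dict
    agreement_tables: dict
    bland_altman: dict
    stage_concordance: dict
    test_results: dict
    model: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _resolve_cohort(source: Union[CohortSpec, str], label: str) -> Cohort:
    try:
        if isinstance(source, CohortSpec):
            return generate_cohort(source)
        return read_cohort(source)
    except Exception as exc:
        raise RuntimeError(f"{label} cohort: {exc}") from exc


def _median_iqr(values: np.ndarray) -> dict:
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return {"median": float(np.median(values)), "q1": float(q1), "q3": float(q3)}


def _group_masks(stage_ord: np.ndarray) -> dict:
    return {
        "overall": np.ones(len(stage_ord), dtype=bool),
        "I_II": stage_ord == 1,
        "III": stage_ord == 2,
        "IV_V": stage_ord == 3,
    }


def _cohort_table(df: pd.DataFrame, masks: dict) -> dict:
    table = {}
    for group, mask in masks.items():
        sub = df[mask]
        if len(sub) == 0:
            table[group] = {"n": 0}
            logger.warning("cohort table: group %s is empty", group)
            continue
        table[group] = {
            "n": int(len(sub)),
            "age_mean": float(sub["age_years"].mean()),
            "age_sd": float(sub["age_years"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "n_female": int(sub["female"].sum()),
            "pct_female": float(100.0 * sub["female"].mean()),
            "scr": _median_iqr(sub["scr_mg_dl"].to_numpy()),
            "bun": _median_iqr(sub["bun_mg_dl"].to_numpy()),
            "alb": _median_iqr(sub["alb_g_dl"].to_numpy()),
            "sgfr": _median_iqr(sub["sgfr_ml_min_173m2"].to_numpy()),
        }
    return table


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full validation study; deterministic given the config."""
    training = _resolve_cohort(config.training, "training")
    validation = _resolve_cohort(config.validation, "validation")
    if len(training) == 0 or len(validation) == 0:
        raise RuntimeError("cohorts must be nonempty")

    try:
        model = train_exact(
            training.scr, training.sgfr, spread=config.spread, ridge=config.ridge
        )
    except Exception as exc:
        raise RuntimeError(f"rbf training: {exc}") from exc

    df = add_estimates(validation.to_dataframe())
    df["egfr_rbf"] = predict(model, df["scr_mg_dl"].to_numpy())
    if np.any(df["egfr_rbf"].to_numpy() <= 0):
        logger.warning("RBF produced nonpositive estimates; staging will reject them")

    sgfr = df["sgfr_ml_min_173m2"].to_numpy()
    stage_ord = stage_groups(sgfr)
    masks = _group_masks(stage_ord)
    for group in ("I_II", "III", "IV_V"):
        logger.info("group %s: n=%d", group, int(masks[group].sum()))

    gfr_table = {}
    agreement = {}
    wilcoxon_within = {}
    for group, mask in masks.items():
        sub_s = sgfr[mask]
        if len(sub_s) == 0:
            gfr_table[group] = None
            continue
        entry = {"n": int(mask.sum()), "sgfr": _median_iqr(sub_s)}
        for est in ESTIMATORS:
            sub_e = df[est].to_numpy()[mask]
            entry[est] = _median_iqr(sub_e)
            agreement.setdefault(est, {})[group] = ev.agreement_summary(
                sub_e, sub_s
            ).to_dict()
            wilcoxon_within.setdefault(est, {})[group] = ev.wilcoxon_signed_rank(
                sub_e - sub_s
            ).to_dict()
        gfr_table[group] = entry

    bland = {}
    concordance = {}
    for est in ESTIMATORS:
        e = df[est].to_numpy()
        ba = ev.bland_altman(e, sgfr)
        bland[est] = ba.to_dict()
        bland[est]["scatter"] = {"mean": ba.means.tolist(), "diff": ba.diffs.tolist()}
        diff, test, table = ev.stage_concordance(e, sgfr)
        concordance[est] = {
            "n_same": int(np.sum(diff == 0)),
            "n_up": int(np.sum(diff > 0)),
            "n_down": int(np.sum(diff < 0)),
            "test": test.to_dict(),
            "table": table.tolist(),
        }

    # between-stage comparison of differences, per estimator
    stage_keys = [g for g in ("I_II", "III", "IV_V") if masks[g].sum() > 0]
    kw_results = {}
    if len(stage_keys) >= 2:
        for est in ESTIMATORS:
            groups = [df[est].to_numpy()[masks[g]] - sgfr[masks[g]] for g in stage_keys]
            post = ev.kruskal_wallis_posthoc(groups, alpha=config.alpha)
            kw_results[est] = {
                "groups": stage_keys,
                "omnibus": post["omnibus"].to_dict(),
                "adjusted_level": post["adjusted_level"],
                "pairwise": {
                    f"{stage_keys[i]}_vs_{stage_keys[j]}": res.to_dict()
                    for (i, j), res in post["pairwise"].items()
                },
            }

    # McNemar: estimator-pair accuracy within each group, per tolerance
    mcnemar_results = {}
    for group in GROUPS:
        mask = masks[group]
        if mask.sum() == 0:
            continue
        sub_s = sgfr[mask]
        for tol in config.tolerances:
            within = {
                est: np.abs(df[est].to_numpy()[mask] - sub_s) / sub_s < tol
                for est in ESTIMATORS
            }
            for e1, e2 in itertools.combinations(ESTIMATORS, 2):
                b = int(np.sum(within[e1] & ~within[e2]))
                c = int(np.sum(~within[e1] & within[e2]))
                key = f"{group}:p{int(round(tol * 100))}:{e1}_vs_{e2}"
                mcnemar_results[key] = ev.mcnemar(b, c).to_dict()

    # chi-square: accuracy across stages, per estimator and tolerance
    chi_results = {}
    if len(stage_keys) >= 2:
        for est in ESTIMATORS:
            for tol in config.tolerances:
                rows = []
                for g in stage_keys:
                    mask = masks[g]
                    cnt, _ = ev.accuracy_within(
                        df[est].to_numpy()[mask], sgfr[mask], tol
                    )
                    rows.append([cnt, int(mask.sum()) - cnt])
                table = np.asarray(rows).T
                key = f"p{int(round(tol * 100))}:{est}"
                try:
                    chi_results[key] = ev.chi_square_2xk(table).to_dict()
                except ValueError as exc:
                    chi_results[key] = {"error": str(exc)}

    report = StudyReport(
        config={
            "spread": config.spread,
            "ridge": config.ridge,
            "tolerances": list(config.tolerances),
            "alpha": config.alpha,
            "seed": config.seed,
            "adjusted_level_3way": ev.bonferroni_adjust_rounded(config.alpha, 3),
        },
        cohort_table=_cohort_table(df, masks),
        gfr_table=gfr_table,
        agreement_tables=agreement,
        bland_altman=bland,
        stage_concordance=concordance,
        test_results={
            "wilcoxon_within_group": wilcoxon_within,
            "kruskal_wallis_across_stages": kw_results,
            "mcnemar_between_estimators": mcnemar_results,
            "chi_square_accuracy_across_stages": chi_results,
        },
        model={
            "n_centers": len(model.centers),
            "spread": model.spread,
            "training_hash": model.training_hash,
        },
    )
    if config.output_dir is not None:
        render_report(
            report,
            config.output_dir,
            model=model,
            cohorts={"training": training, "validation": validation},
        )
    return report


def _fmt(x, nd: int = 2) -> str:
    if x is None:
        return "—"
    return f"{x:.{nd}f}"


def _mi(d: Optional[dict]) -> str:
    if d is None:
        return "—"
    return f"{_fmt(d['median'])} ({_fmt(d['q1'])}, {_fmt(d['q3'])})"


def render_report(
    report: StudyReport,
    out_dir,
    model: Optional[RBFModel] = None,
    cohorts: Optional[dict] = None,
) -> list:
    """Write report.json plus human-readable TSV tables; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "report.json"
    path.write_text(report.to_json())
    written.append(path)

    # table 1: demographics per group
    rows = []
    for group in GROUPS:
        entry = report.cohort_table.get(group)
        if not entry or entry.get("n", 0) == 0:
            rows.append({"group": group, "n": 0})
            logger.warning("table1: group %s empty", group)
            continue
        rows.append(
            {
                "group": group,
                "n": entry["n"],
                "age_mean_sd": f"{_fmt(entry['age_mean'])} ± {_fmt(entry['age_sd'])}",
                "n_female": entry["n_female"],
                "scr_mg_dl": _mi(entry["scr"]),
                "bun_mg_dl": _mi(entry["bun"]),
                "alb_g_dl": _mi(entry["alb"]),
                "sgfr": _mi(entry["sgfr"]),
            }
        )
    path = out / "table1.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    # table 2: GFR medians per method per group
    rows = []
    for method in ("sgfr",) + ESTIMATORS:
        row = {"method": method}
        for group in GROUPS:
            entry = report.gfr_table.get(group)
            row[group] = _mi(entry.get(method) if entry else None)
        rows.append(row)
    path = out / "table2.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    # table 3: agreement summaries
    rows = []
    for group in GROUPS:
        for est in ESTIMATORS:
            summ = report.agreement_tables.get(est, {}).get(group)
            if summ is None:
                rows.append({"group": group, "estimator": est, "n": 0})
                continue
            rows.append(
                {
                    "group": group,
                    "estimator": est,
                    "n": summ["n"],
                    "median_diff": _mi(
                        {
                            "median": summ["median_diff"],
                            "q1": summ["diff_iqr"][0],
                            "q3": summ["diff_iqr"][1],
                        }
                    ),
                    "median_abs_diff": _mi(
                        {
                            "median": summ["median_abs_diff"],
                            "q1": summ["abs_diff_iqr"][0],
                            "q3": summ["abs_diff_iqr"][1],
                        }
                    ),
                    "p15": f"{summ['p15_count']} ({_fmt(summ['p15_pct'], 1)})",
                    "p30": f"{summ['p30_count']} ({_fmt(summ['p30_pct'], 1)})",
                    "p50": f"{summ['p50_count']} ({_fmt(summ['p50_pct'], 1)})",
                }
            )
    path = out / "table3.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    for est, ba in report.bland_altman.items():
        path = out / f"bland_altman_{est}.tsv"
        lines = ["# mean_diff\tsd_diff\tloa_low\tloa_high\tloa_width"]
        lines.append(
            "# "
            + "\t".join(
                repr(ba[k]) for k in ("mean_diff", "sd_diff", "loa_low", "loa_high", "loa_width")
            )
        )
        lines.append("mean\tdiff")
        for m, d in zip(ba["scatter"]["mean"], ba["scatter"]["diff"]):
            lines.append(f"{m!r}\t{d!r}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    if model is not None:
        path = out / "model.json"
        save_model(model, path)
        written.append(path)
    if cohorts:
        cohort_dir = out / "cohorts"
        cohort_dir.mkdir(exist_ok=True)
        for name, cohort in cohorts.items():
            path = cohort_dir / f"{name}.csv"
            write_cohort(cohort, path)
            written.append(path)
    return written
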