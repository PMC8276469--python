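"""End-to-end orchestration: simulate -> filter -> split -> fit -> validate -> compare.

Every stochastic stage receives an explicit seed derived from the run seed, so
identical configurations produce byte-identical output files.  All tabular
outputs are delimited text; a JSON manifest records inputs, seeds, versions
and per-stage record counts, enough to re-run any stage in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, filter_eligible, read_cohort, write_cohort
from .fitting import SplitSpec, fit_both_sexes, stratified_split
from .metrics import MethodComparison, compare_methods, summarize_by_sex
from .scoring import (
    CoefficientTable,
    load_sa_table,
    read_coefficient_table,
    write_coefficient_table,
)
from .simulate import default_params_like_study, generate_cohort


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest names the stage."""


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    out_dir: str
    seed: int = 0
    # simulate (used when cohort_path is not given)
    n_subjects: int = 1000
    cohort_path: Optional[str] = None
    # filter
    max_age: float = 16.0
    # split / fit
    test_fraction: float = 0.5
    weighting: str = "inv_var_ageband"
    age_band_width: float = 1.0
    min_cell: int = 5  # merge sparser stage cells into the adjacent lower stage
    # validate / compare
    ci_reps: int = 2000
    compare_table_path: Optional[str] = None  # default: packaged SA table
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _summaries_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "n": s.n,
                "me": s.me,
                "me_sd": s.me_sd,
                "mae": s.mae,
                "mae_sd": s.mae_sd,
                "rmse": s.rmse,
                "rmse_ci_low": s.rmse_ci[0],
                "rmse_ci_high": s.rmse_ci[1],
                "wilcoxon_p": s.wilcoxon_p,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(rows)


def _comparison_frame(cmp: MethodComparison) -> pd.DataFrame:
    rows = []
    for g, c in cmp.groups.items():
        rows.append(
            {
                "group": g,
                "n": c.n,
                "me_a": c.me_a,
                "me_b": c.me_b,
                "me_diff": c.me_diff,
                "me_diff_sd": c.me_diff_sd,
                "p_me": c.p_me,
                "mae_a": c.mae_a,
                "mae_b": c.mae_b,
                "mae_diff": c.mae_diff,
                "mae_diff_sd": c.mae_diff_sd,
                "p_mae": c.p_mae,
                "rmse_a": c.rmse_a,
                "rmse_a_ci_low": c.rmse_a_ci[0],
                "rmse_a_ci_high": c.rmse_a_ci[1],
                "rmse_b": c.rmse_b,
                "rmse_b_ci_low": c.rmse_b_ci[0],
                "rmse_b_ci_high": c.rmse_b_ci[1],
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain and write outputs + manifest.

    Returns the manifest dict.  On a stage failure the manifest (with the
    failing stage recorded) is still written and :class:`PipelineError` is
    raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "versions": {"dentage": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    stage = "init"
    try:
        # --- acquire cohort
        if config.cohort_path is not None:
            stage = "load"
            cohort = read_cohort(config.cohort_path)
        else:
            stage = "simulate"
            params = default_params_like_study(seed=config.seed)
            cohort = generate_cohort(params, config.n_subjects, seed=config.seed)
            write_cohort(cohort, out / "cohort.csv")
        manifest["stages"]["cohort"] = {"n": len(cohort)}

        stage = "filter"
        eligible, log = filter_eligible(cohort, max_age=config.max_age)
        manifest["stages"]["filter"] = {
            "n_retained": len(eligible),
            "exclusions": log.counts,
        }
        write_cohort(eligible, out / "eligible.csv")

        stage = "split"
        train, test = stratified_split(
            eligible,
            SplitSpec(
                test_fraction=config.test_fraction,
                seed=config.seed + 1,
                age_band_width=config.age_band_width,
            ),
        )
        manifest["stages"]["split"] = {"n_train": len(train), "n_test": len(test)}
        write_cohort(train, out / "train.csv")
        write_cohort(test, out / "test.csv")

        stage = "fit"
        fit = fit_both_sexes(
            train,
            weighting=config.weighting,
            age_band_width=config.age_band_width,
            min_cell=config.min_cell,
            on_deficiency="coarsen",
        )
        write_coefficient_table(fit.table, out / "fitted_table.csv")
        manifest["stages"]["fit"] = {
            "weighting": fit.weighting,
            "n_entries": len(fit.table.entries),
        }

        stage = "validate"
        summaries = summarize_by_sex(
            test, fit.table, ci_reps=config.ci_reps, seed=config.seed + 2
        )
        _summaries_frame(summaries).to_csv(out / "validation_summary.csv", index=False)
        manifest["stages"]["validate"] = {"groups": [s.group for s in summaries]}

        stage = "compare"
        if config.compare_table_path is not None:
            ref = read_coefficient_table(config.compare_table_path)
        else:
            ref = load_sa_table()
        cmp = compare_methods(
            test, fit.table, ref, ci_reps=config.ci_reps, seed=config.seed + 3
        )
        _comparison_frame(cmp).to_csv(out / "comparison.csv", index=False)
        manifest["stages"]["compare"] = {"table_a": cmp.table_a, "table_b": cmp.table_b}

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
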