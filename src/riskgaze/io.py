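"""CSV interchange: schema-validated readers and writers for trial and
fixation tables, plus run configuration loading."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import ChoiceProblem, DesignConfig, problems_from_frame
from .gaze import AOIS, Fixation, Trial, clean_fixations

TRIAL_COLUMNS = ("participant_id", "trial_id", "problem_id", "choice", "rt_ms")
FIXATION_COLUMNS = ("participant_id", "trial_id", "aoi", "onset_ms",
                    "duration_ms")


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def read_problems(path) -> list[ChoiceProblem]:
    return problems_from_frame(pd.read_csv(path))


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, "trial")
    bad = ~df["choice"].isin(["A", "B"])
    if bad.any():
        raise SchemaError(f"invalid choice values at rows {list(df.index[bad])}")
    if not np.issubdtype(df["rt_ms"].dtype, np.number):
        raise SchemaError("rt_ms must be numeric")
    return df


def read_fixations(path, trial_ids: Optional[set] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FIXATION_COLUMNS, "fixation")
    bad = ~df["aoi"].isin(AOIS)
    if bad.any():
        raise SchemaError(f"invalid AOI values at rows {list(df.index[bad])}")
    if trial_ids is not None:
        unknown = set(df["trial_id"]) - trial_ids
        if unknown:
            raise SchemaError(f"fixations reference unknown trial ids: "
                              f"{sorted(unknown)[:5]}")
    return df


def assemble_trials(trial_df: pd.DataFrame, fix_df: pd.DataFrame,
                    problems: Sequence[ChoiceProblem],
                    clean: bool = True) -> list[Trial]:
    """Join the two tables into Trial objects (optionally cleaning fixations)."""
    by_id = {p.id: p for p in problems}
    fix_groups = dict(tuple(fix_df.groupby("trial_id", sort=False)))
    trials = []
    for row in trial_df.itertuples(index=False):
        if row.problem_id not in by_id:
            raise SchemaError(f"unknown problem_id {row.problem_id!r}")
        g = fix_groups.get(row.trial_id)
        fixations: tuple[Fixation, ...] = ()
        if g is not None:
            g = g.sort_values("onset_ms")
            fixations = tuple(Fixation(a, float(o), float(d)) for a, o, d in
                              zip(g["aoi"], g["onset_ms"], g["duration_ms"]))
            if clean:
                fixations = clean_fixations(fixations, rt=float(row.rt_ms))
        trials.append(Trial(problem=by_id[row.problem_id], fixations=fixations,
                            choice=str(row.choice), rt=float(row.rt_ms),
                            participant_id=str(row.participant_id),
                            trial_id=str(row.trial_id)))
    return trials


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_manifest(path, stage: str, config: dict, outputs: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"stage": stage, "config": config, "outputs": outputs},
                  fh, indent=2, default=str)


# --- run configuration ----------------------------------------------------

CONFIG_SCHEMA = {
    "design": {"amount_levels", "prob_levels", "n_catch", "seed",
               "problem_subset"},
    "preprocess": {"min_fix_ms", "aoi_radius_px", "min_rt_ms", "max_rt_ms"},
    "fitting": {"models", "heuristics", "n_starts", "cv_folds", "M", "seed",
                "bounds", "boundary_family", "max_steps"},
    "simulate": {"n_participants", "variant", "mode", "seed", "population",
                 "boundary"},
    "paths": {"output_dir", "trials", "fixations", "problems"},
}


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run config; unknown keys are rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    for section, keys in cfg.items():
        if section not in CONFIG_SCHEMA:
            raise SchemaError(f"unknown config section {section!r}")
        unknown = set(keys or {}) - CONFIG_SCHEMA[section]
        if unknown:
            raise SchemaError(
                f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return cfg


def design_from_config(cfg: dict) -> DesignConfig:
    d = cfg.get("design", {})
    kwargs = {}
    if "amount_levels" in d:
        kwargs["amount_levels"] = tuple(float(x) for x in d["amount_levels"])
    if "prob_levels" in d:
        kwargs["prob_levels"] = tuple(float(x) for x in d["prob_levels"])
    if "n_catch" in d:
        kwargs["n_catch"] = int(d["n_catch"])
    if d.get("problem_subset"):
        kwargs["problem_subset"] = tuple(d["problem_subset"])
    return DesignConfig(**kwargs)
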