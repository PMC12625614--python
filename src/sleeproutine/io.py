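"""CSV schemas and round-trip I/O for the pipeline.

All tables are plain UTF-8 CSV with a header row, '.' decimal separator,
and a leading schema comment line ``#schema=<name>-v1``.  Long-format
sleep series: one row per (participant, day, epoch).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as sm

SLEEP_SCHEMA = "sleep-v1"
COVARIATE_SCHEMA = "covariates-v1"
SURVIVAL_SCHEMA = "survival-v1"
METRICS_SCHEMA = "metrics-v1"

SLEEP_COLUMNS = ["participant_id", "day", "epoch", "asleep"]
SURVIVAL_COLUMNS = ["participant_id", "time_years", "event"]
METRICS_COLUMNS = [
    "participant_id",
    "rsh",
    "asd",
    "nrsh",
    "aad",
    "rsh_weekday",
    "asd_weekday",
    "weekend_class",
]


class SchemaError(ValueError):
    """A CSV file violates its documented schema."""


def _write(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#schema={schema}\n")
        df.to_csv(fh, index=False)


def _read(path, required, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} required by {schema}"
        )
    return df


# -- sleep series -----------------------------------------------------------


def write_sleep_csv(series_list, path) -> None:
    frames = []
    for s in series_list:
        n_ep = s.grid.shape[1]
        # emit all epochs (dense long format)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(s.participant_id, 7 * n_ep),
                    "day": np.repeat(np.arange(1, 8), n_ep),
                    "epoch": np.tile(np.arange(n_ep), 7),
                    "asleep": s.grid.ravel(),
                }
            )
        )
    _write(pd.concat(frames, ignore_index=True), path, SLEEP_SCHEMA)


def read_sleep_csv(path, epoch_minutes: int | None = None):
    df = _read(path, SLEEP_COLUMNS, SLEEP_SCHEMA)
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        days = grp["day"].to_numpy(int)
        epochs = grp["epoch"].to_numpy(int)
        n_ep = int(epochs.max()) + 1
        em = epoch_minutes or sm.MINUTES_PER_DAY // n_ep
        if sm.MINUTES_PER_DAY // em != n_ep:
            raise SchemaError(
                f"{path}: participant {pid}: {n_ep} epochs/day does not "
                f"match {em}-minute epochs"
            )
        grid = np.zeros((7, n_ep), dtype=np.uint8)
        if days.min() < 1 or days.max() > 7:
            raise SchemaError(f"{path}: participant {pid}: day outside 1..7")
        grid[days - 1, epochs] = grp["asleep"].to_numpy()
        out.append(sm.SleepEpochSeries(pid, grid, em))
    return out


# -- covariates / survival / metrics ---------------------------------------


def write_covariates_csv(df: pd.DataFrame, path) -> None:
    _write(df, path, COVARIATE_SCHEMA)


def read_covariates_csv(path) -> pd.DataFrame:
    return _read(path, ["participant_id", "prior_diagnosis"], COVARIATE_SCHEMA)


def write_survival_csv(df: pd.DataFrame, path) -> None:
    _write(df[SURVIVAL_COLUMNS], path, SURVIVAL_SCHEMA)


def read_survival_csv(path) -> pd.DataFrame:
    df = _read(path, SURVIVAL_COLUMNS, SURVIVAL_SCHEMA)
    if not df["event"].isin((0, 1)).all():
        raise SchemaError(f"{path}: column 'event' must be 0/1")
    return df


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    _write(df[METRICS_COLUMNS], path, METRICS_SCHEMA)


def read_metrics_csv(path) -> pd.DataFrame:
    return _read(path, METRICS_COLUMNS, METRICS_SCHEMA)


# -- joins and cohort output ------------------------------------------------


def join_cohort(covariates: pd.DataFrame, metrics: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Merge the three tables on participant_id; error on mismatched IDs."""
    sets = {
        "covariates": set(covariates["participant_id"]),
        "metrics": set(metrics["participant_id"]),
        "survival": set(survival["participant_id"]),
    }
    union = set().union(*sets.values())
    problems = []
    for name, ids in sets.items():
        missing = sorted(union - ids)
        if missing:
            problems.append(f"{name} is missing participant(s) {missing[:10]}")
    if problems:
        raise SchemaError("; ".join(problems))
    return covariates.merge(metrics, on="participant_id").merge(
        survival, on="participant_id"
    )


def write_cohort(cohort, outdir) -> dict:
    """Write the three cohort CSVs plus a JSON run log; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sleep": outdir / "sleep.csv",
        "covariates": outdir / "covariates.csv",
        "survival": outdir / "survival.csv",
    }
    write_sleep_csv(cohort.series, paths["sleep"])
    write_covariates_csv(cohort.covariates, paths["covariates"])
    write_survival_csv(cohort.outcomes, paths["survival"])
    log = {
        "seed": cohort.config.seed,
        "n_participants": cohort.config.n_participants,
        "config_hash": cohort.config.config_hash(),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return paths
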