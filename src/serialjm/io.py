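"""Delimited-text readers and writers.

Datasets travel as two CSV files: a long-format longitudinal table
(subject_id, outcome, time, value) and a one-row-per-subject table
(subject_id, intervention, covariates..., observed_time, event).  Posterior
draws persist as a flat (chain, iteration, parameter, value) table with a
JSON metadata sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .types import SubjectRecord

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_draws",
    "load_draws",
]

_LONG_COLUMNS = ["subject_id", "outcome", "time", "value"]
_SUBJECT_REQUIRED = ["subject_id", "intervention", "observed_time", "event"]


def write_dataset(
    subjects: list[SubjectRecord],
    longitudinal_path: str | Path,
    subject_path: str | Path,
) -> None:
    """Write a dataset as the two-CSV exchange format."""
    long_rows = []
    subj_rows = []
    for s in subjects:
        for outcome, series in ((1, s.series_1), (2, s.series_2)):
            for t, v in series:
                long_rows.append((s.subject_id, outcome, t, v))
        row = {"subject_id": s.subject_id, "intervention": s.intervention}
        row.update(s.baseline_covariates)
        row["observed_time"] = s.observed_time
        row["event"] = s.event
        subj_rows.append(row)
    # %.17g is the shortest format guaranteed to round-trip float64
    pd.DataFrame(long_rows, columns=_LONG_COLUMNS).to_csv(
        longitudinal_path, index=False, float_format="%.17g"
    )
    pd.DataFrame(subj_rows).to_csv(
        subject_path, index=False, float_format="%.17g"
    )


def read_dataset(
    longitudinal_path: str | Path,
    subject_path: str | Path,
    standardize: bool = False,
) -> list[SubjectRecord]:
    """Read and validate a dataset from the two-CSV exchange format.

    ``standardize=True`` rescales each outcome to zero mean and unit variance
    across all subjects and time points (the preprocessing used for real
    trial outcomes so the latent processes are on an SD scale).
    """
    long_df = pd.read_csv(longitudinal_path, float_precision="round_trip")
    subj_df = pd.read_csv(subject_path, float_precision="round_trip")

    missing = [c for c in _LONG_COLUMNS if c not in long_df.columns]
    if missing:
        raise ValueError(
            f"longitudinal table is missing columns {missing}; expected "
            f"{_LONG_COLUMNS}"
        )
    missing = [c for c in _SUBJECT_REQUIRED if c not in subj_df.columns]
    if missing:
        raise ValueError(
            f"subject table is missing columns {missing}; expected at least "
            f"{_SUBJECT_REQUIRED}"
        )
    if subj_df["subject_id"].duplicated().any():
        dupes = subj_df.loc[
            subj_df["subject_id"].duplicated(), "subject_id"
        ].tolist()
        raise ValueError(f"duplicate subject ids in subject table: {dupes[:5]}")
    key = long_df[["subject_id", "outcome", "time"]]
    if key.duplicated().any():
        bad = long_df.loc[key.duplicated(), "subject_id"].unique().tolist()
        raise ValueError(
            f"duplicate (subject, outcome, time) rows for subjects {bad[:5]}"
        )
    if (long_df["time"] < 0).any():
        raise ValueError("longitudinal table contains negative times")
    if not long_df["outcome"].isin([1, 2]).all():
        raise ValueError("longitudinal outcome labels must be 1 or 2")
    known = set(subj_df["subject_id"].astype(str))
    orphans = sorted(
        set(long_df["subject_id"].astype(str)) - known
    )
    if orphans:
        raise ValueError(
            f"longitudinal table has subjects absent from the subject table: "
            f"{orphans[:5]}"
        )

    if standardize:
        for outcome in (1, 2):
            mask = long_df["outcome"] == outcome
            if mask.any():
                vals = long_df.loc[mask, "value"]
                sd = vals.std(ddof=0)
                if sd > 0:
                    long_df.loc[mask, "value"] = (vals - vals.mean()) / sd

    covariate_cols = [
        c for c in subj_df.columns if c not in _SUBJECT_REQUIRED
    ]
    grouped: dict[str, dict[int, list[tuple[float, float]]]] = {}
    for row in long_df.itertuples(index=False):
        grouped.setdefault(str(row.subject_id), {1: [], 2: []})[
            int(row.outcome)
        ].append((float(row.time), float(row.value)))

    subjects = []
    for row in subj_df.itertuples(index=False):
        sid = str(row.subject_id)
        series = grouped.get(sid, {1: [], 2: []})
        record = SubjectRecord(
            subject_id=sid,
            intervention=int(row.intervention),
            baseline_covariates={
                c: float(getattr(row, c)) for c in covariate_cols
            },
            series_1=sorted(series[1]),
            series_2=sorted(series[2]),
            observed_time=float(row.observed_time),
            event=int(row.event),
        )
        record.validate()
        subjects.append(record)
    return subjects


def save_draws(
    draws: PosteriorDraws, table_path: str | Path, meta_path: str | Path
) -> None:
    """Persist draws as a flat CSV plus a JSON metadata sidecar."""
    frames = []
    for name, arr in draws.draws.items():
        n_chains, n_draws = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(n_chains), n_draws),
                    "iteration": np.tile(np.arange(n_draws), n_chains),
                    "parameter": name,
                    "value": arr.reshape(-1),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        table_path, index=False, float_format="%.17g"
    )
    Path(meta_path).write_text(json.dumps(draws.meta, indent=1))


def load_draws(
    table_path: str | Path, meta_path: str | Path
) -> PosteriorDraws:
    table = pd.read_csv(table_path, float_precision="round_trip")
    meta = json.loads(Path(meta_path).read_text())
    n_chains = int(table["chain"].max()) + 1
    n_draws = int(table["iteration"].max()) + 1
    draws = {}
    for name, sub in table.groupby("parameter", sort=False):
        arr = np.full((n_chains, n_draws), np.nan)
        arr[sub["chain"].to_numpy(), sub["iteration"].to_numpy()] = sub[
            "value"
        ].to_numpy()
        draws[name] = arr
    return PosteriorDraws(draws=draws, meta=meta)
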