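"""Delimited-text import/export for schedules, RDMs and pattern matrices.

File conventions:

* schedules — CSV with columns trial_index, sequence, condition, run,
  response_cue (practice rows have run 0 and negative indices);
* RDMs — square CSV with a label header row/column, plus a long-format
  (label_i, label_j, distance) export;
* pattern matrices — one CSV per subject×region×phase named
  ``subject<ID>_<region>_<phase>.csv`` with an index CSV mapping rows
  to schedule trial indices.
"""

from __future__ import annotations

import pathlib

import pandas as pd

from .design import Trial, TrialSchedule
from .errors import SeqrecodeError
from .rsa import PatternMatrix
from .sequences import RDM, Sequence

__all__ = [
    "write_schedule",
    "read_schedule",
    "write_rdm",
    "read_rdm",
    "write_rdm_long",
    "write_cohort",
    "read_cohort",
]


def write_schedule(schedule: TrialSchedule, path: str | pathlib.Path) -> None:
    schedule.to_frame(include_practice=True).to_csv(path, index=False)


def read_schedule(path: str | pathlib.Path) -> TrialSchedule:
    df = pd.read_csv(path, dtype={"sequence": str})
    required = {"trial_index", "sequence", "condition", "run", "response_cue"}
    if not required.issubset(df.columns):
        raise SeqrecodeError(f"schedule file missing columns {required - set(df.columns)}")
    trials, practice = [], []
    for _, row in df.iterrows():
        t = Trial(
            int(row.trial_index),
            Sequence.from_string(row.sequence),
            str(row.condition),
            int(row.run),
            bool(int(row.response_cue)),
        )
        (practice if t.run == 0 else trials).append(t)
    return TrialSchedule(trials=trials, practice=practice)


def write_rdm(rdm: RDM, path: str | pathlib.Path) -> None:
    rdm.to_frame().to_csv(path)


def read_rdm(path: str | pathlib.Path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_rdm_long(rdm: RDM, path: str | pathlib.Path) -> None:
    rdm.to_long().to_csv(path, index=False)


def write_cohort(cohort, directory: str | pathlib.Path) -> list[pathlib.Path]:
    """Write each subject's pattern matrix plus a row-to-trial index file."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for pat in cohort.patterns:
        p = directory / f"{pat.subject}_{pat.region}_{pat.phase}.csv"
        pd.DataFrame(pat.data).to_csv(p, index=False)
        paths.append(p)
    index = pd.DataFrame(
        {
            "row": range(len(cohort.schedule.trials)),
            "trial_index": [t.trial_index for t in cohort.schedule.trials],
        }
    )
    index_path = directory / "row_index.csv"
    index.to_csv(index_path, index=False)
    paths.append(index_path)
    return paths


def read_cohort(directory: str | pathlib.Path) -> list[PatternMatrix]:
    directory = pathlib.Path(directory)
    out = []
    for p in sorted(directory.glob("sub*_*_*.csv")):
        subject, region, phase = p.stem.split("_", 2)
        out.append(
            PatternMatrix(
                pd.read_csv(p).to_numpy(dtype=float),
                subject=subject,
                region=region,
                phase=phase,
            )
        )
    if not out:
        raise SeqrecodeError(f"no pattern files found under {directory}")
    return out
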