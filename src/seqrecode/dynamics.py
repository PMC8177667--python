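"""Model-free distance-trajectory analyses.

These analyses ask whether voxel-pattern geometry drifts over the
experiment without assuming any representation model: four kinds of
distance series are built per subject/region/phase and a least-squares
slope over the presentation index is tested against zero across
subjects.  Cosine distance is used throughout this module (the RSA
module uses correlation distance; the two live in separate functions on
purpose).

Series kinds:

* ``between-repeating`` — d_n = distance(R1^n, R2^n), the two repeating
  sequences at their n-th presentations;
* ``within-repeating`` — d_n = distance(R^n, R^(n-1)), averaged over
  the two repeating sequences;
* ``repeating-vs-novel`` — d_n = mean distance of R_i^n to the novel
  patterns of the same run, averaged over the two repeating sequences;
* ``within-novel`` — consecutive novel-trial distances.

Presentation index n is counted within run and runs are concatenated
(the default); an across-experiment index is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SeqrecodeError
from .rsa import PatternMatrix

__all__ = [
    "DistanceSeries",
    "SERIES_KINDS",
    "cosine_distance",
    "build_series",
    "slope_test",
]

SERIES_KINDS = (
    "between-repeating",
    "within-repeating",
    "repeating-vs-novel",
    "within-novel",
)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − u·v / (‖u‖‖v‖); raises on zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise SeqrecodeError("cosine distance undefined for zero-norm vector")
    return float(1.0 - u @ v / (nu * nv))


@dataclass
class DistanceSeries:
    """A distance trajectory: x (presentation index), d, and run labels."""

    kind: str
    x: np.ndarray
    d: np.ndarray
    run: np.ndarray
    subject: str = "sub00"
    region: str = "region"
    phase: str = "presentation"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.d = np.asarray(self.d, dtype=float)
        self.run = np.asarray(self.run)
        if not (self.d >= -1e-12).all():
            raise SeqrecodeError("distances must be non-negative")
        for r in np.unique(self.run):
            xr = self.x[self.run == r]
            if not (np.diff(xr) > 0).all():
                raise SeqrecodeError("x must be strictly increasing within run")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "region": self.region,
                "phase": self.phase,
                "kind": self.kind,
                "run": self.run,
                "n": self.x,
                "d": self.d,
            }
        )


def _occurrences(schedule, run: int, sequence) -> list[int]:
    return [
        i
        for i, t in enumerate(schedule.trials)
        if t.run == run and t.sequence == sequence
    ]


def build_series(
    patterns: PatternMatrix, schedule, kind: str
) -> DistanceSeries:
    """One distance trajectory for a subject's patterns under a schedule."""
    if kind not in SERIES_KINDS:
        raise SeqrecodeError(f"unknown series kind {kind!r}; one of {SERIES_KINDS}")
    X = patterns.data
    if X.shape[0] != len(schedule.trials):
        raise SeqrecodeError("pattern rows do not match schedule trials")
    reps = sorted(
        {t.sequence for t in schedule.trials if t.condition == "repeating"}
    )
    if kind != "within-novel" and len(reps) != 2:
        raise SeqrecodeError("expected exactly 2 repeating sequences")
    xs, ds, runs = [], [], []
    for run in schedule.runs:
        if kind == "between-repeating":
            occ1 = _occurrences(schedule, run, reps[0])
            occ2 = _occurrences(schedule, run, reps[1])
            for n, (i, j) in enumerate(zip(occ1, occ2), start=1):
                xs.append(n)
                ds.append(cosine_distance(X[i], X[j]))
                runs.append(run)
        elif kind == "within-repeating":
            per_seq = []
            for rep in reps:
                occ = _occurrences(schedule, run, rep)
                per_seq.append(
                    [cosine_distance(X[occ[n]], X[occ[n - 1]]) for n in range(1, len(occ))]
                )
            m = min(len(s) for s in per_seq)
            for n in range(m):
                xs.append(n + 2)  # first point compares repetitions 2 and 1
                ds.append(float(np.mean([s[n] for s in per_seq])))
                runs.append(run)
        elif kind == "repeating-vs-novel":
            novel_idx = [
                i
                for i, t in enumerate(schedule.trials)
                if t.run == run and t.condition == "novel"
            ]
            per_seq = []
            for rep in reps:
                occ = _occurrences(schedule, run, rep)
                per_seq.append(
                    [
                        float(np.mean([cosine_distance(X[i], X[j]) for j in novel_idx]))
                        for i in occ
                    ]
                )
            m = min(len(s) for s in per_seq)
            for n in range(m):
                xs.append(n + 1)
                ds.append(float(np.mean([s[n] for s in per_seq])))
                runs.append(run)
        else:  # within-novel
            novel_idx = [
                i
                for i, t in enumerate(schedule.trials)
                if t.run == run and t.condition == "novel"
            ]
            for n in range(1, len(novel_idx)):
                xs.append(n + 1)
                ds.append(cosine_distance(X[novel_idx[n]], X[novel_idx[n - 1]]))
                runs.append(run)
    if len(xs) < 3:
        raise SeqrecodeError("insufficient trials for series")
    return DistanceSeries(
        kind,
        np.array(xs),
        np.array(ds),
        np.array(runs),
        subject=patterns.subject,
        region=patterns.region,
        phase=patterns.phase,
    )


def _series_slope(series: DistanceSeries, fit: str) -> float:
    if fit == "per-run":
        slopes = []
        for r in np.unique(series.run):
            sel = series.run == r
            if sel.sum() < 2:
                continue
            slopes.append(np.polyfit(series.x[sel], series.d[sel], 1)[0])
        if not slopes:
            raise SeqrecodeError("no run with enough points for a slope")
        return float(np.mean(slopes))
    if fit == "across":
        # concatenate runs on a global presentation axis
        x, off = [], 0
        for r in np.unique(series.run):
            sel = series.run == r
            x.append(series.x[sel] + off)
            off += series.x[sel].max()
        return float(np.polyfit(np.concatenate(x), series.d, 1)[0])
    raise SeqrecodeError(f"unknown fit mode {fit!r}")


def slope_test(
    series_per_subject: list[DistanceSeries],
    n_regions: int = 74,
    alpha: float = 0.05,
    fit: str = "per-run",
) -> dict:
    """Per-subject OLS slopes and the group t-test against zero.

    ``fit="per-run"`` (default) averages the per-run slopes within
    subject; ``fit="across"`` fits one slope over the concatenated
    presentation index.  The two-sided one-sample t-test across subject
    slopes uses the Bonferroni-corrected threshold alpha/n_regions.
    """
    if len(series_per_subject) < 2:
        raise SeqrecodeError("slope_test needs >= 2 subjects")
    slopes = np.array([_series_slope(s, fit) for s in series_per_subject])
    if np.std(slopes, ddof=1) == 0:
        if np.allclose(slopes, 0):
            return {
                "slopes": slopes, "t": np.nan, "p": 1.0,
                "significant": False, "flag": "zero-variance",
            }
        return {
            "slopes": slopes, "t": np.nan, "p": np.nan,
            "significant": False, "flag": "zero-variance",
        }
    t, p = stats.ttest_1samp(slopes, 0.0)
    return {
        "slopes": slopes,
        "t": float(t),
        "p": float(p),
        "significant": bool(p < alpha / n_regions),
        "threshold": alpha / n_regions,
        "flag": None,
    }
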