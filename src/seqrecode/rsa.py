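"""Representational similarity analysis: RDM comparison and group inference.

The pipeline is the standard one: a model RDM of predicted pairwise
dissimilarities between trials is compared against a data RDM of
correlation distances between the trials' voxel activity patterns, cell
by cell over the lower triangle, with Spearman's rank correlation
(average ranks for ties — consequential here, because the Hamming model
takes at most five distinct values).  Group-level significance uses a
label-permutation null per subject combined by bootstrap resampling;
noise ceilings bound the correlation an ideal model could reach given
between-subject variability.

The associative-learning test reuses the same machinery across
conditions: if learning merely reduces noise in a fixed code, the model
fit computed on novel×repeating cells should exceed the fit within
novel cells, because repeating-trial patterns are cleaner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, SeqrecodeError
from .sequences import RDM

__all__ = [
    "PatternMatrix",
    "RSAResult",
    "CrossConditionResult",
    "correlation_distance",
    "pattern_rdm",
    "rsa_correlation",
    "permutation_rs",
    "noise_ceiling",
    "ceiling_positive_test",
    "group_significance",
    "group_rsa",
    "condition_mask",
    "cross_condition_rsa",
]


@dataclass
class PatternMatrix:
    """Trials × voxels activity estimates for one subject/region/phase.

    Rows align with the main trials of a :class:`~seqrecode.design.TrialSchedule`.
    """

    data: np.ndarray
    subject: str = "sub00"
    region: str = "region"
    phase: str = "presentation"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SeqrecodeError("pattern matrix must be 2-D (trials × voxels)")
        if not np.isfinite(self.data).all():
            raise SeqrecodeError("pattern matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − Pearson correlation of the mean-centred vectors; range [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise SeqrecodeError("correlation_distance needs two equal-length 1-D vectors")
    uc, vc = u - u.mean(), v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("constant vector has no correlation distance")
    return float(1.0 - uc @ vc / (nu * nv))


def pattern_rdm(patterns: PatternMatrix, labels: list[str] | None = None) -> RDM:
    """Correlation-distance RDM over the trial rows of a pattern matrix.

    Rows with zero variance cannot enter a correlation; their cells are
    recorded as NaN and excluded pairwise downstream.
    """
    X = patterns.data
    if X.shape[0] < 2:
        raise SeqrecodeError("pattern_rdm needs at least 2 trial rows")
    constant = X.std(axis=1) == 0
    d = squareform(pdist(np.where(constant[:, None], np.nan, X), metric="correlation"))
    np.fill_diagonal(d, 0.0)
    if constant.any():
        warnings.warn(
            f"{constant.sum()} constant pattern rows: their RDM cells are missing",
            stacklevel=2,
        )
        d[constant, :] = np.nan
        d[:, constant] = np.nan
        np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    return RDM(labels, d)


def _masked_cells(
    model: RDM, data: RDM, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if model.n != data.n:
        raise SeqrecodeError("model and data RDMs have different sizes")
    m = model.lower_triangle(mask)
    d = data.lower_triangle(mask)
    keep = np.isfinite(m) & np.isfinite(d)
    return m[keep], d[keep]


def rsa_correlation(
    model: RDM, data: RDM, mask: np.ndarray | None = None
) -> float:
    """Spearman rank correlation between masked lower-triangle RDM cells.

    Average-rank tie handling; NaN cells are dropped pairwise.  Requires
    at least 3 usable cells.
    """
    m, d = _masked_cells(model, data, mask)
    if m.size < 3:
        raise SeqrecodeError(f"need >= 3 masked cells, got {m.size}")
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        raise DegenerateInputError("constant RDM cells have no rank correlation")
    r = stats.spearmanr(m, d).statistic
    return float(r)


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def permutation_rs(
    model: RDM,
    data: RDM,
    n_permutations: int,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Spearman r for ``n_permutations`` random trial-label shuffles.

    The permutation unit is the trial: rows and columns of the data RDM
    are permuted jointly, preserving its geometry, then the masked
    lower-triangle cells are re-extracted and rank-correlated with the
    model.  Vectorised: one rank pass over a (n_permutations × cells)
    matrix.
    """
    n = data.n
    idx = np.tril_indices(n, k=-1)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)[idx]
    else:
        sel = np.ones(len(idx[0]), dtype=bool)
    mvals = model.lower_triangle(mask)
    rows = np.empty((n_permutations, int(sel.sum())))
    D = data.values
    for p in range(n_permutations):
        perm = rng.permutation(n)
        rows[p] = D[np.ix_(perm, perm)][idx][sel]
    keep = np.isfinite(mvals) & np.isfinite(rows).all(axis=0)
    mvals, rows = mvals[keep], rows[:, keep]
    if mvals.size < 3:
        raise SeqrecodeError("too few usable cells for permutation test")
    mr = _rank(mvals)
    mr = mr - mr.mean()
    rr = _rank(rows, axis=1)
    rr = rr - rr.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(mr) * np.linalg.norm(rr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rr @ mr) / denom
    return out


@dataclass
class RSAResult:
    """Group-level outcome of one model × region × phase comparison."""

    model_id: str
    region: str
    phase: str
    subject_rs: np.ndarray
    group_r: float
    p_value: float
    ceiling_lower: float
    ceiling_upper: float


@dataclass
class CrossConditionResult:
    """Outcome of the associative noise-reduction test."""

    r_within_novel: float
    r_novel_vs_repeating: float
    p_novel_vs_repeating: float
    category: str  # no-correlation | repeating-noisier | repeating-less-noisy
    subject_r_within: np.ndarray | None = None
    subject_r_cross: np.ndarray | None = None


def noise_ceiling(subject_rdms: list[RDM]) -> tuple[float, float]:
    """Leave-one-out lower and with-self upper bound of the noise ceiling.

    Upper: mean over subjects of Spearman(subject RDM, group-mean RDM).
    Lower: the same with the subject removed from the group mean — the
    with-self mean slightly overestimates the true ceiling, so
    lower <= upper.  Degenerate subject RDMs (constant cells) are
    excluded with a warning.
    """
    if len(subject_rdms) < 2:
        raise SeqrecodeError("noise ceiling needs >= 2 subjects")
    cells = np.array([r.lower_triangle() for r in subject_rdms])
    usable = []
    for i, row in enumerate(cells):
        if np.isfinite(row).all() and np.nanstd(row) > 0:
            usable.append(i)
        else:
            warnings.warn(f"subject {i} RDM degenerate; excluded from ceiling",
                          stacklevel=2)
    if len(usable) < 2:
        raise SeqrecodeError("fewer than 2 usable subject RDMs")
    cells = cells[usable]
    n = len(cells)
    group = cells.mean(axis=0)
    upper = np.mean([stats.spearmanr(c, group).statistic for c in cells])
    lowers = []
    for i in range(n):
        loo = (group * n - cells[i]) / (n - 1)
        lowers.append(stats.spearmanr(cells[i], loo).statistic)
    return float(np.mean(lowers)), float(upper)


def ceiling_positive_test(
    subject_correlations: np.ndarray, n_regions: int = 74, alpha: float = 0.05
) -> dict:
    """One-sided t-test that Fisher-z subject correlations exceed zero.

    The significance threshold is Bonferroni-corrected by the number of
    regions tested.  Zero-variance inputs are flagged rather than
    tested.
    """
    r = np.asarray(subject_correlations, dtype=float)
    if r.size < 2:
        raise SeqrecodeError("need >= 2 subjects")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    if np.std(z, ddof=1) == 0:
        return {"t": np.nan, "p": np.nan, "significant": False, "flag": "zero-variance"}
    t, p = stats.ttest_1samp(z, 0.0, alternative="greater")
    corrected = alpha / n_regions
    return {
        "t": float(t),
        "p": float(p),
        "significant": bool(p < corrected),
        "threshold": corrected,
        "flag": None,
    }


def group_significance(
    per_subject_rs: np.ndarray,
    alpha: float = 1e-4,
    rng: np.random.Generator | int = 0,
    n_samples: int | None = None,
) -> float:
    """Empirical group-level p-value from per-subject permutation nulls.

    ``per_subject_rs`` has one row per subject: the permuted Spearman
    values with the true-label value appended as the last column.  The
    null distribution of group means is built by resampling one value
    per subject (with replacement over that subject's distribution) and
    averaging, ``10/alpha`` times by default; the p-value is the rank
    position of the true group mean in that distribution.
    """
    if alpha <= 0:
        raise SeqrecodeError("alpha must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    R = np.asarray(per_subject_rs, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise SeqrecodeError("per_subject_rs must be (subjects × permutations+1)")
    if n_samples is None:
        n_samples = int(round(10.0 / alpha))
    true_mean = R[:, -1].mean()
    n_sub, n_vals = R.shape
    draws = rng.integers(0, n_vals, size=(n_samples, n_sub))
    null_means = R[np.arange(n_sub)[None, :], draws].mean(axis=1)
    return float((np.sum(null_means >= true_mean) + 1) / (n_samples + 1))


def group_rsa(
    model_id: str,
    model: RDM,
    data_rdms: list[RDM],
    n_permutations: int = 1000,
    alpha: float = 1e-4,
    rng: np.random.Generator | int = 0,
    mask: np.ndarray | None = None,
    n_group_samples: int | None = None,
    region: str = "region",
    phase: str = "presentation",
) -> RSAResult:
    """Group-level model fit: per-subject Spearman, permutation p, ceilings."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    subject_rs, perm_rows = [], []
    for data in data_rdms:
        true_r = rsa_correlation(model, data, mask)
        subject_rs.append(true_r)
        perms = permutation_rs(model, data, n_permutations, rng, mask)
        perm_rows.append(np.append(perms, true_r))
    p = group_significance(np.array(perm_rows), alpha, rng, n_samples=n_group_samples)
    lower, upper = noise_ceiling(data_rdms)
    return RSAResult(
        model_id=model_id,
        region=region,
        phase=phase,
        subject_rs=np.array(subject_rs),
        group_r=float(np.mean(subject_rs)),
        p_value=p,
        ceiling_lower=lower,
        ceiling_upper=upper,
    )


def condition_mask(
    schedule, condition_i: str, condition_j: str | None = None
) -> np.ndarray:
    """Boolean trial×trial mask selecting cells between two conditions.

    ``condition_mask(s, "novel")`` selects novel×novel cells;
    ``condition_mask(s, "novel", "repeating")`` the cross-condition
    block (symmetric).
    """
    conds = [t.condition for t in schedule.trials]
    n = len(conds)
    ci = np.array([c == condition_i for c in conds])
    cj = ci if condition_j is None else np.array([c == condition_j for c in conds])
    mask = np.outer(ci, cj) | np.outer(cj, ci)
    np.fill_diagonal(mask, False)
    return mask


def cross_condition_rsa(
    cohort_patterns: list[PatternMatrix],
    schedule,
    model: RDM,
    n_permutations: int = 1000,
    alpha: float = 1e-4,
    rng: np.random.Generator | int = 0,
    n_group_samples: int | None = None,
) -> CrossConditionResult:
    """The associative-learning noise test, at the group level.

    Computes for each subject the model fit within novel×novel cells
    (r_U) and over novel×repeating cells (r_{U,R}), tests the
    significance of the group-mean r_{U,R} with the permutation/
    bootstrap machinery restricted to the cross-condition mask, and
    categorises the outcome:

    * ``no-correlation`` — r_{U,R} not significant: repeating sequences
      are not represented with the model's code, so the noise
      comparison is meaningless;
    * ``repeating-noisier`` — significant but r_{U,R} < r_U;
    * ``repeating-less-noisy`` — significant and r_{U,R} > r_U (the
      associative-learning prediction).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for cond in ("novel", "repeating"):
        if len(schedule.condition_indices(cond)) < 2:
            raise SeqrecodeError(f"condition {cond!r} has fewer than 2 trials")
    mask_u = condition_mask(schedule, "novel")
    mask_ur = condition_mask(schedule, "novel", "repeating")
    r_within, r_cross, perm_rows = [], [], []
    for pat in cohort_patterns:
        data = pattern_rdm(pat)
        r_within.append(rsa_correlation(model, data, mask_u))
        true_r = rsa_correlation(model, data, mask_ur)
        r_cross.append(true_r)
        perms = permutation_rs(model, data, n_permutations, rng, mask_ur)
        perm_rows.append(np.append(perms, true_r))
    p_cross = group_significance(
        np.array(perm_rows), alpha, rng, n_samples=n_group_samples
    )
    r_u = float(np.mean(r_within))
    r_ur = float(np.mean(r_cross))
    if p_cross >= alpha:
        category = "no-correlation"
    elif r_ur > r_u:
        category = "repeating-less-noisy"
    else:
        category = "repeating-noisier"
    return CrossConditionResult(
        r_within_novel=r_u,
        r_novel_vs_repeating=r_ur,
        p_novel_vs_repeating=p_cross,
        category=category,
        subject_r_within=np.array(r_within),
        subject_r_cross=np.array(r_cross),
    )
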