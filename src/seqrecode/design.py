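"""Experimental-design generation: sequence sets and trial schedules.

The experiment needs 14 distinct permutations of the 4-item alphabet —
2 *repeating* sequences (learned to criterion in a practice block and
presented on 2/3 of the main trials) and 12 *novel* sequences (presented
once per run).  Two kinds of constraints shape the set:

* separation in Hamming space, so that learning the repeating sequences
  cannot transfer to novel ones via shared multi-item chunks;
* the repeating pair must share no item at a common position and no
  common n-gram (n > 1), so the two learned sequences do not interfere
  and each is optimally encoded as a single whole-sequence chunk.

A note on scope: demanding pairwise Hamming >= 3 between *all* 14
permutations of four items is combinatorially impossible — sequences at
Hamming distance < 3 are exactly those related by a transposition, and
the largest set of permutations avoiding all transposition pairs is an
alternating class of size 12.  The default therefore applies the
separation to every pair involving a repeating sequence (the pairs
through which chunk transfer could contaminate the novel condition),
with ``hamming_scope="all"`` available for smaller sets.

Candidate sets are scored by the entropy of their pairwise-distance
distribution (maximise: a flat distance histogram gives the most
informative RDM predictor) with the correlation between competing model
RDMs as a tie-breaker (minimise: decorrelated model predictions are
easier to tell apart), and the best set is found by Monte-Carlo search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstraintError, SeqrecodeError
from .sequences import (
    Alphabet,
    DEFAULT_ALPHABET,
    Sequence,
    as_sequence,
    extract_ngrams,
    hamming_distance,
    model_rdm,
)

__all__ = [
    "DesignConstraints",
    "DesignScore",
    "Trial",
    "TrialSchedule",
    "SequenceSet",
    "check_constraints",
    "score_set",
    "monte_carlo_search",
    "build_schedule",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Constraint parameters for a 14-sequence set.

    ``hamming_scope`` selects which pairs the minimum-Hamming rule
    applies to: ``"repeating"`` (default; every pair involving a
    designated repeating sequence) or ``"all"``.
    """

    min_pairwise_hamming: int = 3
    hamming_scope: str = "repeating"
    repeating_ngram_sizes: tuple[int, ...] = (2, 3, 4)

    def __post_init__(self) -> None:
        if self.hamming_scope not in ("repeating", "all"):
            raise SeqrecodeError(f"unknown hamming_scope {self.hamming_scope!r}")


@dataclass
class SequenceSet:
    """A candidate design: sequences with two designated repeating ones."""

    sequences: list[Sequence]
    repeating: tuple[Sequence, Sequence]

    def __post_init__(self) -> None:
        self.sequences = [as_sequence(s) for s in self.sequences]
        self.repeating = tuple(as_sequence(s) for s in self.repeating)  # type: ignore[assignment]
        for r in self.repeating:
            if r not in self.sequences:
                raise SeqrecodeError(f"repeating sequence {r} not in set")

    @property
    def novel(self) -> list[Sequence]:
        return [s for s in self.sequences if s not in self.repeating]


@dataclass
class DesignScore:
    """Statistical-power measures of a constraint-passing set."""

    distance_entropy: float  # bits, plug-in entropy of the pairwise distances
    model_cross_correlation: float  # Pearson r between the two model RDMs

    def cost_key(self) -> tuple[float, float]:
        """Sort key: maximise entropy, then minimise |cross-correlation|."""
        return (-self.distance_entropy, abs(self.model_cross_correlation))


def check_constraints(
    seq_set: SequenceSet,
    constraints: DesignConstraints = DesignConstraints(),
    expected_size: int | None = 14,
) -> tuple[bool, list[str]]:
    """Verdict and violation list for a candidate sequence set."""
    seqs = seq_set.sequences
    violations: list[str] = []
    if expected_size is not None and len(seqs) != expected_size:
        raise SeqrecodeError(f"expected {expected_size} sequences, got {len(seqs)}")
    for s in seqs:
        if not s.is_permutation:
            violations.append(f"{s}: items not all distinct")
    if len(set(seqs)) != len(seqs):
        violations.append("duplicate sequence in set")
    rep = set(seq_set.repeating)
    for a, b in itertools.combinations(seqs, 2):
        applies = (
            constraints.hamming_scope == "all" or a in rep or b in rep
        )
        h = hamming_distance(a, b)
        if h == 0:
            violations.append(f"({a}, {b}): identical")
        elif applies and h < constraints.min_pairwise_hamming:
            violations.append(
                f"({a}, {b}): Hamming {h} < {constraints.min_pairwise_hamming}"
            )
    r1, r2 = seq_set.repeating
    if hamming_distance(r1, r2) < len(r1):
        violations.append(f"repeating pair ({r1}, {r2}): shared item-position")
    for n in constraints.repeating_ngram_sizes:
        shared = set(extract_ngrams(r1, n)) & set(extract_ngrams(r2, n))
        if shared:
            violations.append(
                f"repeating pair ({r1}, {r2}): shared {n}-grams "
                f"{sorted(''.join(g) for g in shared)}"
            )
    return (not violations, violations)


def score_set(seq_set: SequenceSet) -> DesignScore:
    """Entropy of the pairwise Hamming distances and model cross-correlation.

    The entropy is the plug-in Shannon entropy (bits) of the discrete
    distribution of lower-triangle distances — for 14 sequences, over
    C(14,2) = 91 cells.  Cross-correlation is the Pearson correlation
    between the item-position (Hamming) and item-item (bi-gram) RDM
    cells of the set.
    """
    seqs = seq_set.sequences
    ham = model_rdm(seqs, "hamming").lower_triangle()
    _, counts = np.unique(ham, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    bigram = model_rdm(seqs, "bigram").lower_triangle()
    if np.std(ham) == 0 or np.std(bigram) == 0:
        cross = 0.0
    else:
        cross = float(np.corrcoef(ham, bigram)[0, 1])
    return DesignScore(entropy, cross)


def monte_carlo_search(
    n_samples: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    n_sequences: int = 14,
    constraints: DesignConstraints = DesignConstraints(),
) -> tuple[SequenceSet, DesignScore, pd.DataFrame]:
    """Monte-Carlo search for the best constraint-passing sequence set.

    Each sample draws a repeating pair uniformly from all permutation
    pairs, then the novel sequences uniformly from the permutations
    compatible with that pair under the Hamming rule (uniform subsets of
    the full space essentially never satisfy the constraints, so
    sampling is stratified on the repeating pair).  Returns the
    best-scoring passing set, its score, and a trace of passing samples.
    Raises :class:`ConstraintError` if no sample passes.
    """
    if n_samples < 1:
        raise SeqrecodeError("n_samples must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perms = [Sequence(p) for p in itertools.permutations(alphabet.labels)]
    n_novel = n_sequences - 2
    trace_rows = []
    best: tuple[tuple[float, float], SequenceSet, DesignScore] | None = None
    for i in range(n_samples):
        ia, ib = rng.choice(len(perms), size=2, replace=False)
        r1, r2 = perms[ia], perms[ib]
        if constraints.hamming_scope == "all":
            pool = [
                p
                for p in perms
                if p not in (r1, r2)
            ]
        else:
            pool = [
                p
                for p in perms
                if p not in (r1, r2)
                and hamming_distance(p, r1) >= constraints.min_pairwise_hamming
                and hamming_distance(p, r2) >= constraints.min_pairwise_hamming
            ]
        if len(pool) < n_novel:
            continue
        idx = rng.choice(len(pool), size=n_novel, replace=False)
        candidate = SequenceSet([r1, r2] + [pool[j] for j in idx], (r1, r2))
        ok, _ = check_constraints(candidate, constraints, expected_size=n_sequences)
        if not ok:
            continue
        score = score_set(candidate)
        trace_rows.append(
            {
                "sample": i,
                "repeating": f"{r1},{r2}",
                "distance_entropy": score.distance_entropy,
                "model_cross_correlation": score.model_cross_correlation,
            }
        )
        key = score.cost_key()
        if best is None or key < best[0]:
            best = (key, candidate, score)
    if best is None:
        raise ConstraintError(
            f"no constraint-passing set found in {n_samples} samples"
        )
    trace = pd.DataFrame(trace_rows)
    return best[1], best[2], trace


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One presentation: index, sequence, condition, run, response flag."""

    trial_index: int
    sequence: Sequence
    condition: str  # "repeating" | "novel"
    run: int
    response_cue: bool


@dataclass
class TrialSchedule:
    """Practice prefix plus the ordered main trials.

    Timing metadata (2.4 s per item, 4.8 s delay, 7.2 s response window)
    is carried for export only; no analysis in this package consumes it.
    """

    trials: list[Trial]
    practice: list[Trial] = field(default_factory=list)
    timings: dict = field(
        default_factory=lambda: {"item_s": 2.4, "delay_s": 4.8, "response_s": 7.2}
    )

    @property
    def runs(self) -> list[int]:
        return sorted({t.run for t in self.trials})

    def condition_indices(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.trials) if t.condition == condition]
        )

    def sequences(self) -> list[Sequence]:
        return [t.sequence for t in self.trials]

    def to_frame(self, include_practice: bool = False) -> pd.DataFrame:
        rows = (self.practice if include_practice else []) + self.trials
        return pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in rows],
                "sequence": [str(t.sequence) for t in rows],
                "condition": [t.condition for t in rows],
                "run": [t.run for t in rows],
                "response_cue": [int(t.response_cue) for t in rows],
            }
        )


def build_schedule(
    seq_set: SequenceSet,
    runs: int = 2,
    trials_per_run: int = 36,
    practice_reps: int = 12,
    rng_seed: int | np.random.Generator = 0,
    response_cue_fraction: float = 0.75,
) -> TrialSchedule:
    """Randomised trial schedule with the 2:1 repeating:novel structure.

    Main trials are organised in sub-blocks of three — two repeating
    trials and one novel trial in random order — so the relative
    exposure to the two conditions stays fixed throughout.  Within each
    run both repeating sequences appear trials_per_run/3 times and every
    novel sequence exactly once; a quarter of main trials carry no
    response cue.  The practice prefix presents each repeating sequence
    ``practice_reps`` times in shuffled order.
    """
    if trials_per_run % 3 != 0:
        raise SeqrecodeError("trials_per_run must be divisible by 3")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    r1, r2 = seq_set.repeating
    novels = seq_set.novel
    blocks_per_run = trials_per_run // 3
    if len(novels) != blocks_per_run:
        raise SeqrecodeError(
            f"need {blocks_per_run} novel sequences for {trials_per_run} trials/run, "
            f"got {len(novels)}"
        )

    # practice prefix: negative indices, run 0
    practice_seqs = [r1, r2] * practice_reps
    rng.shuffle(practice_seqs)
    practice = [
        Trial(-(len(practice_seqs) - i), s, "repeating", 0, True)
        for i, s in enumerate(practice_seqs)
    ]

    main: list[Trial] = []
    index = 1
    n_main = runs * trials_per_run
    no_cue = set(
        rng.choice(
            n_main, size=int(round((1 - response_cue_fraction) * n_main)), replace=False
        )
    )
    flat = 0
    for run in range(1, runs + 1):
        # balanced repeating pool: each sequence blocks_per_run times per run
        rep_pool = [r1] * blocks_per_run + [r2] * blocks_per_run
        rep_pool = [rep_pool[i] for i in rng.permutation(len(rep_pool))]
        novel_order = [novels[i] for i in rng.permutation(len(novels))]
        for b in range(blocks_per_run):
            block = [rep_pool.pop(), rep_pool.pop(), novel_order[b]]
            conditions = ["repeating", "repeating", "novel"]
            order = rng.permutation(3)
            for k in order:
                main.append(
                    Trial(index, block[k], conditions[k], run, flat not in no_cue)
                )
                index += 1
                flat += 1
    return TrialSchedule(trials=main, practice=practice)
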