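"""Capacity and interference analysis of the two coding schemes.

A learned sequence strengthens its codes; any other sequence that uses
one of those codes is thereby affected.  Under the item-position model
a code is an (item, position) binding, so two sequences share
L − Hamming codes; under the most restrictive chunk model (bi-grams
only) a code is an adjacent item pair, shared position-free.  Exact
shared-code histograms over the full enumeration space quantify how
crowded each code space is, and simulated learning curves show how fast
the pool of unaffected sequences is exhausted — about five learned
sequences suffice to touch everything under item-position coding, while
the bi-gram code keeps a strictly larger untouched pool at every step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SeqrecodeError
from .sequences import (
    Alphabet,
    DEFAULT_ALPHABET,
    Sequence,
    as_sequence,
    extract_ngrams,
    hamming_distance,
)

__all__ = [
    "SharedCodeHistogram",
    "CapacityCurve",
    "MODELS",
    "enumerate_space",
    "shared_code_count",
    "shared_code_histogram",
    "capacity_curve",
]

MODELS = ("item-position", "bigram-chunk")


def enumerate_space(
    alphabet: Alphabet = DEFAULT_ALPHABET, length: int = 4, allow_repeats: bool = True
) -> list[Sequence]:
    """All sequences of the given length: |A|^L with repeats, else L-permutations."""
    if allow_repeats:
        return [Sequence(p) for p in itertools.product(alphabet.labels, repeat=length)]
    return [Sequence(p) for p in itertools.permutations(alphabet.labels, length)]


def shared_code_count(model: str, a: "Sequence | str", b: "Sequence | str") -> int:
    """Number of codes two sequences share under a coding scheme."""
    a, b = as_sequence(a), as_sequence(b)
    if model == "item-position":
        return len(a) - hamming_distance(a, b)
    if model == "bigram-chunk":
        return len(set(extract_ngrams(a, 2)) & set(extract_ngrams(b, 2)))
    raise SeqrecodeError(f"unknown model {model!r}; one of {MODELS}")


@dataclass
class SharedCodeHistogram:
    """Exact shared-code distribution of a reference sequence over a space."""

    model: str
    reference: Sequence
    counts: np.ndarray  # counts[k] = number of sequences sharing exactly k codes
    include_reference: bool = True

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shared_codes": np.arange(len(self.counts)),
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


def shared_code_histogram(
    model: str,
    reference: "Sequence | str",
    space: list[Sequence] | None = None,
    include_reference: bool = True,
) -> SharedCodeHistogram:
    """Brute-force histogram of shared-code counts over the enumeration space.

    With the default repeats-allowed space of 256 sequences and a
    distinct-item reference, the item-position bins follow the closed
    form C(L, k)·(|A|−1)^(L−k); e.g. exactly 2 of 4 item-position codes
    are shared by 54/256 ≈ 21% of all sequences.  The reference itself
    is counted in the denominator by default (drop it with
    ``include_reference=False``).
    """
    reference = as_sequence(reference)
    if space is None:
        space = enumerate_space(length=len(reference))
    max_codes = (
        len(reference) if model == "item-position" else len(reference) - 1
    )
    counts = np.zeros(max_codes + 1, dtype=int)
    for s in space:
        if not include_reference and s == reference:
            continue
        counts[shared_code_count(model, reference, s)] += 1
    return SharedCodeHistogram(model, reference, counts, include_reference)


@dataclass
class CapacityCurve:
    """Mean interference trajectory over replicated learning orders.

    ``proportion_by_shared[n, k]`` is the mean proportion of the space
    whose maximum shared-code count with the first n learned sequences
    is exactly k; column 0 is the unaffected proportion.
    """

    model: str
    n_learned: np.ndarray
    proportion_unaffected: np.ndarray
    proportion_by_shared: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.proportion_by_shared,
            columns=[f"shared_{k}" for k in range(self.proportion_by_shared.shape[1])],
        )
        df.insert(0, "n_learned", self.n_learned)
        df.insert(1, "proportion_unaffected", self.proportion_unaffected)
        df.insert(0, "model", self.model)
        return df


def capacity_curve(
    model: str,
    space: list[Sequence] | None = None,
    n_learn_max: int = 10,
    n_replicates: int = 200,
    rng_seed: int | np.random.Generator = 0,
) -> CapacityCurve:
    """Interference as a function of the number of learned sequences.

    Each replicate draws learned sequences uniformly without replacement
    from the space; after each learning step a sequence counts as
    affected when it shares at least one code with any learned sequence.
    The unaffected proportion is non-increasing in every replicate.
    """
    if space is None:
        space = enumerate_space()
    if n_learn_max > len(space):
        raise SeqrecodeError("n_learn_max exceeds the size of the space")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    # precompute pairwise shared-code counts once
    m = len(space)
    shared = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1):
            c = shared_code_count(model, space[i], space[j])
            shared[i, j] = shared[j, i] = c
    max_codes = int(shared.max())
    by_shared = np.zeros((n_learn_max + 1, max_codes + 1))
    for _ in range(n_replicates):
        order = rng.permutation(m)[:n_learn_max]
        best = np.zeros(m, dtype=np.int8)  # max shared codes with learned set
        for k, learned in enumerate([None] + list(order)):
            if learned is not None:
                best = np.maximum(best, shared[learned])
            counts = np.bincount(best, minlength=max_codes + 1)
            by_shared[k] += counts / m
    by_shared /= n_replicates
    return CapacityCurve(
        model=model,
        n_learned=np.arange(n_learn_max + 1),
        proportion_unaffected=by_shared[:, 0].copy(),
        proportion_by_shared=by_shared,
        n_replicates=n_replicates,
    )
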