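"""Sequence representation models and their pairwise distances.

A trial stimulus is an ordered sequence of discrete items (default: four
Gabor orientations labelled ``A``–``D``).  Three representational accounts
of such sequences live here:

* **item-position associations** — a sequence is a set of (item, ordinal
  position) bindings; between-sequence dissimilarity is the Hamming
  distance (number of positions at which the items differ);
* **item-item associations** — a sequence is the set of its adjacent
  n-grams (bi-grams by default); dissimilarity is one minus the
  normalised count of shared n-grams;
* **item mixture** — a null model in which a sequence is a recency-
  weighted superposition of its item codes; dissimilarity is the
  correlation distance between mixture vectors.

Association learning is modelled as a Dirichlet–multinomial count table
over (item, position) pairs whose row-normalised means give the
association-weight matrix ``mu``.

Positions are 1-based throughout; sequences serialise as contiguous item
strings (``"ABCD"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, LengthMismatchError, SeqrecodeError

__all__ = [
    "Alphabet",
    "Sequence",
    "AssociationCounts",
    "AssociationWeights",
    "MixtureWeights",
    "RDM",
    "DEFAULT_ALPHABET",
    "DEFAULT_MIXTURE_WEIGHTS",
    "hamming_distance",
    "extract_ngrams",
    "ngram_distance",
    "update_association_counts",
    "association_weights",
    "mixture_vector",
    "mixture_distance",
    "model_rdm",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered collection of distinct item symbols.

    The default experiment uses four items standing for the four Gabor
    orientations (0/45/90/135 degrees).
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise SeqrecodeError("alphabet needs at least 2 items")
        if len(set(self.labels)) != len(self.labels):
            raise SeqrecodeError("alphabet labels must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, item: str) -> bool:
        return item in self.labels

    def index(self, item: str) -> int:
        return self.labels.index(item)


DEFAULT_ALPHABET = Alphabet(("A", "B", "C", "D"))


@dataclass(frozen=True, order=True)
class Sequence:
    """An ordered assignment of items to 1-based positions.

    Experimental sequences are permutations (all items distinct); the
    enumeration space used by the interference analysis also admits
    repeated items, so distinctness is *not* enforced here.
    """

    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise SeqrecodeError("empty sequence")

    @classmethod
    def from_string(cls, s: str) -> "Sequence":
        return cls(tuple(s))

    def __len__(self) -> int:
        return len(self.items)

    def __str__(self) -> str:
        return "".join(self.items)

    @property
    def is_permutation(self) -> bool:
        return len(set(self.items)) == len(self.items)


def as_sequence(s: "Sequence | str | Iterable[str]") -> Sequence:
    """Coerce a string or iterable of symbols into a :class:`Sequence`."""
    if isinstance(s, Sequence):
        return s
    if isinstance(s, str):
        return Sequence.from_string(s)
    return Sequence(tuple(s))


# ---------------------------------------------------------------------------
# Distances between sequence representations
# ---------------------------------------------------------------------------

def hamming_distance(a: "Sequence | str", b: "Sequence | str") -> int:
    """Number of positions at which two equal-length sequences differ.

    The dissimilarity measure of the item-position association model:
    e.g. ``ABCD`` and ``CBAD`` share ``B`` at position 2 and ``D`` at
    position 4, so their Hamming distance is 2 (out of a possible 4).
    """
    a, b = as_sequence(a), as_sequence(b)
    if len(a) != len(b):
        raise LengthMismatchError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.items, b.items))


def extract_ngrams(s: "Sequence | str", n: int) -> list[tuple[str, ...]]:
    """All adjacent n-grams of ``s``, in order of their start position.

    A sequence of length L yields L − (n − 1) contiguous windows; e.g.
    ``ABCD`` yields the three bi-grams ``AB``, ``BC``, ``CD``.
    """
    s = as_sequence(s)
    if not 1 <= n <= len(s):
        raise SeqrecodeError(f"n-gram size {n} out of range 1..{len(s)}")
    return [s.items[i : i + n] for i in range(len(s) - n + 1)]


def ngram_distance(a: "Sequence | str", b: "Sequence | str", n: int = 2) -> float:
    """Item-item (n-gram) dissimilarity: 1 − γ·|shared n-grams|.

    The n-gram sets are position-free: ``FBI`` and ``BIN`` share the
    bi-gram ``BI`` even though it sits at different serial positions.
    γ = 1/(L − (n − 1)) normalises by the number of n-grams a sequence
    of length L contains, so the distance lies in [0, 1].
    """
    a, b = as_sequence(a), as_sequence(b)
    if len(a) != len(b):
        raise LengthMismatchError(f"length mismatch: {len(a)} vs {len(b)}")
    shared = set(extract_ngrams(a, n)) & set(extract_ngrams(b, n))
    gamma = 1.0 / (len(a) - (n - 1))
    return 1.0 - gamma * len(shared)


# ---------------------------------------------------------------------------
# Associative (Dirichlet-multinomial) learning
# ---------------------------------------------------------------------------

@dataclass
class AssociationCounts:
    """Item × position occurrence history (Dirichlet pseudo-counts).

    ``counts[i, k]`` is the effective number of observations of item ``i``
    at position ``k`` (1-based position ``k+1`` externally).  A uniform
    additive pseudo-count implements the symmetric Dirichlet prior; the
    default of 0 keeps the estimator purely empirical.
    """

    alphabet: Alphabet = DEFAULT_ALPHABET
    length: int = 4
    pseudo_count: float = 0.0
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.full(
                (len(self.alphabet), self.length), float(self.pseudo_count)
            )
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != (len(self.alphabet), self.length):
                raise SeqrecodeError("counts shape does not match alphabet × length")
        if (self.counts < 0).any():
            raise SeqrecodeError("association counts must be non-negative")

    def copy(self) -> "AssociationCounts":
        return AssociationCounts(
            self.alphabet, self.length, self.pseudo_count, self.counts.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list(self.alphabet.labels),
            columns=[f"pos{k + 1}" for k in range(self.length)],
        )


@dataclass
class AssociationWeights:
    """Row-normalised association probabilities ``mu``.

    Each item row with at least one observation sums to 1; rows with no
    observations are left all-zero and flagged in ``observed``.
    """

    alphabet: Alphabet
    mu: np.ndarray
    observed: np.ndarray  # boolean per item row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mu,
            index=list(self.alphabet.labels),
            columns=[f"pos{k + 1}" for k in range(self.mu.shape[1])],
        )


def update_association_counts(
    c: AssociationCounts, s: "Sequence | str"
) -> AssociationCounts:
    """Conjugate update: increment each observed (item, position) cell by 1."""
    s = as_sequence(s)
    if len(s) != c.length:
        raise LengthMismatchError(f"sequence length {len(s)} != table length {c.length}")
    out = c.copy()
    for pos, item in enumerate(s.items):
        if item not in c.alphabet:
            raise SeqrecodeError(f"item {item!r} not in alphabet")
        out.counts[c.alphabet.index(item), pos] += 1.0
    return out


def association_weights(c: AssociationCounts) -> AssociationWeights:
    """Posterior-mean association matrix: each item row normalised to sum 1.

    For the set {BACD, CABD, ABCD} this reproduces the frequency matrix
    with e.g. mu(A, position 2) = 2/3.
    """
    totals = c.counts.sum(axis=1)
    if not (totals > 0).any():
        raise SeqrecodeError("association_weights requires at least one nonzero row")
    observed = totals > 0
    mu = np.zeros_like(c.counts)
    mu[observed] = c.counts[observed] / totals[observed, None]
    return AssociationWeights(c.alphabet, mu, observed)


# ---------------------------------------------------------------------------
# Item mixture (palimpsest null model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureWeights:
    """Mixing coefficients for the item-mixture model.

    ``beta[n]`` weights the item at position n+1; the default is the
    recency-weighted slope (0, 1/6, 1/3, 1/2), the midpoint between a
    flat slope (all mixtures identical) and a vertical one (only the
    last item contributes).  A primacy slope of equal magnitude yields
    the same RDM, so only the recency form is provided.

    ``theta_rate``, ``beta0`` and ``alpha_norm`` record the slope
    parametrisation when one is used; they are metadata only.
    """

    beta: tuple[float, ...] = (0.0, 1.0 / 6.0, 1.0 / 3.0, 1.0 / 2.0)
    theta_rate: float | None = None
    beta0: float | None = None
    alpha_norm: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.beta)
        if not np.isclose(total, 1.0):
            raise SeqrecodeError(f"mixture weights must sum to 1, got {total}")
        if any(b2 < b1 - 1e-12 for b1, b2 in zip(self.beta, self.beta[1:])):
            raise SeqrecodeError("recency mixture weights must be non-decreasing")

    @classmethod
    def linear(cls, length: int, slope: float = 1.0) -> "MixtureWeights":
        """Linearly increasing weights normalised to sum 1.

        ``slope`` in (0, 1]: 1 recovers the default recency profile for
        length 4 (first weight 0); smaller values flatten the profile.
        """
        base = 1.0 + slope * (np.arange(length) / (length - 1) - 1.0)
        beta = base / base.sum()
        return cls(tuple(beta), theta_rate=slope)


DEFAULT_MIXTURE_WEIGHTS = MixtureWeights()


def mixture_vector(
    s: "Sequence | str",
    w: MixtureWeights = DEFAULT_MIXTURE_WEIGHTS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """Item-space coordinates of the mixture representation M = I·beta.

    Item representations are fixed orthonormal axes (one per alphabet
    symbol), so the coordinate for item i is the sum of beta over the
    positions at which i occurs.
    """
    s = as_sequence(s)
    if len(s) != len(w.beta):
        raise LengthMismatchError(
            f"sequence length {len(s)} != number of mixture weights {len(w.beta)}"
        )
    v = np.zeros(len(alphabet))
    for pos, item in enumerate(s.items):
        v[alphabet.index(item)] += w.beta[pos]
    return v


def mixture_distance(
    a: "Sequence | str",
    b: "Sequence | str",
    w: MixtureWeights = DEFAULT_MIXTURE_WEIGHTS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> float:
    """Correlation distance between the two item-mixture vectors."""
    u = mixture_vector(a, w, alphabet)
    v = mixture_vector(b, w, alphabet)
    return _correlation_distance(u, v)


def _correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("correlation distance undefined for constant vector")
    return float(1.0 - uc @ vc / (nu * nv))


# ---------------------------------------------------------------------------
# Model RDMs
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """Labelled symmetric dissimilarity matrix.

    The common currency between representation models and voxel
    patterns.  Cells may be NaN when a pairwise distance was degenerate
    (constant voxel pattern); such cells are dropped pairwise by the
    comparison machinery.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise SeqrecodeError("RDM matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-10
        ):
            raise SeqrecodeError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise SeqrecodeError("RDM diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Vector of strictly-lower-triangle cells (row-major), optionally masked.

        ``mask`` is an n×n boolean matrix; a cell enters the vector when
        its lower-triangle position is selected.
        """
        idx = np.tril_indices(self.n, k=-1)
        vals = self.values[idx]
        if mask is not None:
            vals = vals[np.asarray(mask, dtype=bool)[idx]]
        return vals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format (label_i, label_j, distance) over the lower triangle."""
        rows = []
        for i in range(self.n):
            for j in range(i):
                rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["label_i", "label_j", "distance"])


_MODEL_DISPATCH: dict[str, Callable[..., float]] = {}


def model_rdm(
    seqs: TypingSequence["Sequence | str"],
    model: str | Callable[[Sequence, Sequence], float] = "hamming",
    labels: list[str] | None = None,
    n: int = 2,
    mixture_weights: MixtureWeights = DEFAULT_MIXTURE_WEIGHTS,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> RDM:
    """Pairwise model dissimilarity matrix over an ordered sequence collection.

    ``model`` selects the representational account: ``"hamming"``
    (item-position), ``"bigram"``/``"ngram"`` (item-item, window ``n``),
    ``"mixture"`` (item mixture), or any callable taking two sequences.
    The chunk-code distance is supplied by :func:`seqrecode.chunking.chunk_rdm`
    because it needs per-trial chunk assignments, not just the sequences.
    """
    seqs = [as_sequence(s) for s in seqs]
    if len(seqs) < 2:
        raise SeqrecodeError("model_rdm needs at least 2 sequences")
    if callable(model):
        dist = model
    elif model == "hamming":
        dist = hamming_distance
    elif model in ("bigram", "ngram"):
        size = 2 if model == "bigram" else n
        dist = lambda a, b: ngram_distance(a, b, size)  # noqa: E731
    elif model == "mixture":
        dist = lambda a, b: mixture_distance(a, b, mixture_weights, alphabet)  # noqa: E731
    else:
        raise SeqrecodeError(f"unknown model selector {model!r}")
    m = len(seqs)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i):
            d[i, j] = d[j, i] = dist(seqs[i], seqs[j])
    if labels is None:
        labels = [f"{i}:{seqs[i]}" for i in range(m)]
    return RDM(list(labels), d)
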