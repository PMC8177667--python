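"""Bayesian chunk (recoding) model of sequence learning.

A chunking model of a corpus of observed sequences has two parameters:

* a chunk set ``x`` — a set of n-grams drawn from the combinatorial
  inventory of all n-grams without repeated items; each inventory entry
  carries a prior inversely proportional to the number of partial
  permutations of its length (so, over a 4-item alphabet, a uni-gram is
  exactly 3 times more probable than a bi-gram);
* a mapping set ``z`` — for each observed sequence, a *parse*: an
  ordered tuple of contiguous position spans that covers the sequence,
  assigning one chunk to each span.  A parse with F spans (links) has
  probability ``eta**F`` with a constant per-link probability ``eta``.

The model evidence is the product of the chunk-set prior (code term)
and the mapping probabilities over every presentation (encoding term).
Longer chunks are costly to add to the code but make encodings cheap —
repetition is what pays for them.  The optimal-model search makes that
explicit: multi-item chunks are only available to sequences that have
themselves been presented at least ``min_support`` times (default 3);
one-shot sequences keep their primitive item codes.  Without some such
restriction a fresh whole-sequence chunk always beats any multi-chunk
encoding of a one-shot sequence (p1**4 * eta**4 < p4 * eta for any
eta <= 1), and no learning dynamic would distinguish novel from
repeating items.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .errors import EncodingMismatchError, SeqrecodeError
from .sequences import (
    RDM,
    Alphabet,
    DEFAULT_ALPHABET,
    Sequence,
    as_sequence,
)

__all__ = [
    "NGramInventory",
    "Parse",
    "ChunkModel",
    "ModelEvidence",
    "DEFAULT_ETA",
    "enumerate_parses",
    "count_spans",
    "build_inventory",
    "chunk_set_log_prob",
    "mapping_log_prob",
    "model_evidence",
    "reference_models",
    "fit_optimal_model",
    "sequential_optimal_models",
    "trial_codes",
    "chunk_rdm",
]

# Default per-link probability: the reciprocal of the number of distinct
# contiguous spans of a 4-item sequence (10).  The printed model
# comparisons are robust to this choice (tested over 1/4, 1/8, 1/10).
DEFAULT_ETA = 0.1


def count_spans(length: int) -> int:
    """Number of distinct contiguous spans of a length-L sequence: L(L+1)/2."""
    return length * (length + 1) // 2


@dataclass(frozen=True)
class Parse:
    """Ordered tuple of contiguous 1-based position spans covering 1..L.

    ``links`` is e.g. ``((1,), (2, 3), (4,))``; ``n_links`` (F) is the
    number of spans, i.e. the number of chunks used by the encoding.
    """

    links: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = [p for span in self.links for p in span]
        if not flat or flat != list(range(1, len(flat) + 1)):
            raise SeqrecodeError(f"spans must partition 1..L in order, got {self.links}")
        for span in self.links:
            if list(span) != list(range(span[0], span[-1] + 1)):
                raise SeqrecodeError(f"span {span} is not contiguous")

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def length(self) -> int:
        return sum(len(span) for span in self.links)

    def chunks_of(self, s: "Sequence | str") -> tuple[tuple[str, ...], ...]:
        """The item content of each span when applied to sequence ``s``."""
        s = as_sequence(s)
        if len(s) != self.length:
            raise SeqrecodeError("parse length does not match sequence length")
        return tuple(tuple(s.items[p - 1] for p in span) for span in self.links)


def enumerate_parses(length: int) -> list[Parse]:
    """All ordered compositions of ``length`` into contiguous spans.

    There are 2**(L-1) such parses (a break point may or may not sit
    between each pair of adjacent positions); a 4-item sequence has 8.
    """
    if length < 1:
        raise SeqrecodeError("sequence length must be >= 1")
    parses = []
    for breaks in itertools.product([False, True], repeat=length - 1):
        spans, start = [], 1
        for pos, brk in enumerate(breaks, start=1):
            if brk:
                spans.append(tuple(range(start, pos + 1)))
                start = pos + 1
        spans.append(tuple(range(start, length + 1)))
        parses.append(Parse(tuple(spans)))
    return parses


@dataclass
class NGramInventory:
    """All n-grams of length 1..L over an alphabet with no repeated items.

    For a 4-item alphabet and L = 4 the inventory has
    sum_k 4!/(4-k)! = 4 + 12 + 24 + 24 = 64 entries.  Entry priors are
    ``alpha * (n-k)!/n!`` with ``alpha`` chosen so the priors sum to 1
    over the inventory; each length class then carries equal total mass,
    so ``alpha = 1/L``.  The uni-gram : bi-gram prior ratio is n − 1 = 3
    for four items, matching the partial-permutation counts.
    """

    alphabet: Alphabet = DEFAULT_ALPHABET
    max_length: int = 4
    entries: tuple[tuple[str, ...], ...] = field(init=False)
    log_prior: dict[tuple[str, ...], float] = field(init=False)
    alpha_norm: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if n < self.max_length:
            raise SeqrecodeError("alphabet smaller than max n-gram length")
        entries: list[tuple[str, ...]] = []
        for k in range(1, self.max_length + 1):
            entries.extend(itertools.permutations(self.alphabet.labels, k))
        self.entries = tuple(entries)
        # unnormalised weight (n-k)!/n! per entry; each length class sums to 1
        weight = {
            e: math.factorial(n - len(e)) / math.factorial(n) for e in entries
        }
        total = sum(weight.values())
        self.alpha_norm = 1.0 / total
        self.log_prior = {
            e: math.log(self.alpha_norm * w) for e, w in weight.items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    def prior(self, chunk: tuple[str, ...]) -> float:
        if chunk not in self.log_prior:
            raise SeqrecodeError(f"chunk {chunk!r} not in inventory")
        return math.exp(self.log_prior[chunk])


def build_inventory(
    alphabet: Alphabet = DEFAULT_ALPHABET, max_length: int = 4
) -> NGramInventory:
    """Construct the n-gram inventory with combinatorial priors."""
    return NGramInventory(alphabet, max_length)


def chunk_set_log_prob(
    chunks: Iterable[tuple[str, ...]], inventory: NGramInventory
) -> float:
    """Log prior of a chunk set: sum of its members' log priors (code term)."""
    total = 0.0
    for c in chunks:
        if c not in inventory.log_prior:
            raise SeqrecodeError(f"chunk {c!r} not in inventory")
        total += inventory.log_prior[c]
    return total


def mapping_log_prob(parse: Parse, eta: float = DEFAULT_ETA) -> float:
    """Log probability of one mapping: F * log(eta) for F links."""
    if not 0.0 < eta <= 1.0:
        raise SeqrecodeError(f"eta must be in (0, 1], got {eta}")
    return parse.n_links * math.log(eta)


@dataclass
class ModelEvidence:
    """Decomposed log evidence: code term + encoding term."""

    log_code: float
    log_encoding: float

    @property
    def log_total(self) -> float:
        return self.log_code + self.log_encoding


@dataclass
class ChunkModel:
    """A chunk set plus one parse per distinct sequence.

    ``assignments`` maps each distinct observed sequence to the parse
    used for every presentation of it; the chunk set must contain the
    item content of every assigned span.
    """

    chunks: tuple[tuple[str, ...], ...]
    assignments: dict[Sequence, Parse]
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if len(set(self.chunks)) != len(self.chunks):
            raise SeqrecodeError("each chunk may be listed only once")
        self.chunks = tuple(sorted(self.chunks, key=lambda c: (len(c), c)))
        chunk_set = set(self.chunks)
        for seq, parse in self.assignments.items():
            for content in parse.chunks_of(seq):
                if content not in chunk_set:
                    raise EncodingMismatchError(
                        f"assigned span {content!r} of {seq} is not in the chunk set"
                    )

    def codes_for(self, seq: "Sequence | str") -> tuple[tuple[tuple[str, ...], int], ...]:
        """(chunk, 1-based start position) codes encoding ``seq``."""
        seq = as_sequence(seq)
        parse = self.assignments[seq]
        return tuple(
            (content, span[0])
            for content, span in zip(parse.chunks_of(seq), parse.links)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "chunks": ["".join(c) for c in self.chunks],
                "assignments": {
                    str(s): [list(span) for span in p.links]
                    for s, p in self.assignments.items()
                },
                "eta": self.eta,
            },
            indent=2,
        )


def model_evidence(
    model: ChunkModel,
    seqs: TypingSequence["Sequence | str"],
    inventory: NGramInventory,
) -> ModelEvidence:
    """Log evidence of a chunk model for an observed corpus.

    The code term prices the chunk set once; the encoding term prices
    every presentation (token), so repeated sequences pay their mapping
    cost at each repetition.  Raises :class:`EncodingMismatchError` when
    a sequence has no assignment or its parse fails to reproduce it.
    """
    seqs = [as_sequence(s) for s in seqs]
    if not seqs:
        raise SeqrecodeError("empty corpus")
    log_code = chunk_set_log_prob(model.chunks, inventory)
    log_encoding = 0.0
    for s in seqs:
        if s not in model.assignments:
            raise EncodingMismatchError(f"no assignment for sequence {s}")
        parse = model.assignments[s]
        parse.chunks_of(s)  # validates reproduction / length
        log_encoding += mapping_log_prob(parse, model.eta)
    return ModelEvidence(log_code, log_encoding)


# ---------------------------------------------------------------------------
# Fixed single-n reference models (the 1-gram / 2-gram / 4-gram comparison)
# ---------------------------------------------------------------------------

def _uniform_parse(length: int, n: int) -> Parse:
    if length % n != 0:
        raise SeqrecodeError(f"length {length} not encodable with {n}-grams only")
    return Parse(
        tuple(tuple(range(i, i + n)) for i in range(1, length + 1, n))
    )


def reference_models(
    seqs: TypingSequence["Sequence | str"],
    inventory: NGramInventory | None = None,
    eta: float = DEFAULT_ETA,
    sizes: tuple[int, ...] = (1, 2, 4),
) -> pd.DataFrame:
    """Evidence table for the fixed uniform-n chunking models.

    Each reference model encodes every sequence with n-grams of a single
    size (the 1-gram model with four uni-grams, the 2-gram model with two
    bi-grams, the 4-gram model with one four-gram), evaluated by the
    plain evidence formula.  Rows are sorted by descending log evidence.
    """
    seqs = [as_sequence(s) for s in seqs]
    if not seqs:
        raise SeqrecodeError("empty corpus")
    if inventory is None:
        inventory = build_inventory(max_length=max(len(s) for s in seqs))
    rows = []
    for n in sizes:
        distinct = sorted(set(seqs))
        assignments = {s: _uniform_parse(len(s), n) for s in distinct}
        chunks = tuple(
            sorted({c for s in distinct for c in assignments[s].chunks_of(s)})
        )
        model = ChunkModel(chunks, assignments, eta)
        ev = model_evidence(model, seqs, inventory)
        rows.append(
            {
                "model_id": f"{n}-gram",
                "n_sequences": len(seqs),
                "log_code": ev.log_code,
                "log_encoding": ev.log_encoding,
                "log_total": ev.log_total,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("log_total", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Optimal-model search
# ---------------------------------------------------------------------------

def _admissible_parses(
    seq: Sequence,
    multiplicity: dict[Sequence, int],
    min_support: int,
) -> list[Parse]:
    """Parses available to one distinct sequence under the support rule.

    A sequence presented at least ``min_support`` times may use any
    parse; a sequence below that threshold is restricted to the
    all-uni-gram parse, because multi-item chunks stand for regularities
    acquired by repetition of the encoded material.  (Counting support
    across different sequences does not work: adjacent item pairs
    recur across one-shot permutations of a small alphabet by pigeonhole,
    and a bi-gram shared by two such sequences already pays for itself
    under the evidence, which would erase the novel/learned distinction
    the model is meant to capture.)
    """
    if min_support <= 1 or multiplicity[seq] >= min_support:
        return enumerate_parses(len(seq))
    return [_uniform_parse(len(seq), 1)]


def _model_from_choice(
    distinct: list[Sequence],
    choice: tuple[Parse, ...],
    eta: float,
) -> ChunkModel:
    assignments = dict(zip(distinct, choice))
    chunks = tuple(
        sorted({c for s in distinct for c in assignments[s].chunks_of(s)})
    )
    return ChunkModel(chunks, assignments, eta)


def _choice_evidence(
    distinct: list[Sequence],
    multiplicity: dict[Sequence, int],
    choice: tuple[Parse, ...],
    inventory: NGramInventory,
    eta: float,
) -> tuple[float, int]:
    """(log evidence, number of chunks) for a parse-per-sequence choice."""
    chunks = {c for s, p in zip(distinct, choice) for c in p.chunks_of(s)}
    log_code = sum(inventory.log_prior[c] for c in chunks)
    log_enc = sum(
        multiplicity[s] * p.n_links for s, p in zip(distinct, choice)
    ) * math.log(eta)
    return log_code + log_enc, len(chunks)


def fit_optimal_model(
    seqs: TypingSequence["Sequence | str"],
    inventory: NGramInventory | None = None,
    eta: float = DEFAULT_ETA,
    min_support: int = 3,
    exhaustive_cap: int = 20000,
) -> ChunkModel:
    """Highest-evidence chunk model over parse-induced candidate sets.

    Candidates choose one admissible parse per distinct sequence; the
    chunk set is the union of the induced n-grams.  The admissible-parse
    product is searched exhaustively when it has at most
    ``exhaustive_cap`` combinations, otherwise by deterministic
    coordinate ascent from the all-uni-gram encoding.  Ties break toward
    fewer chunks, then lexicographically smaller chunk lists.

    ``min_support=1`` removes the repetition-support restriction and
    searches the raw parse-union space.
    """
    seqs = [as_sequence(s) for s in seqs]
    if not seqs:
        raise SeqrecodeError("fit_optimal_model requires a nonempty corpus")
    if inventory is None:
        inventory = build_inventory(max_length=max(len(s) for s in seqs))
    distinct = sorted(set(seqs))
    multiplicity = {s: seqs.count(s) for s in distinct}
    options = [
        _admissible_parses(s, multiplicity, min_support) for s in distinct
    ]

    def key(choice: tuple[Parse, ...]):
        ev, n_chunks = _choice_evidence(distinct, multiplicity, choice, inventory, eta)
        chunk_list = tuple(
            sorted({c for s, p in zip(distinct, choice) for c in p.chunks_of(s)})
        )
        # maximise evidence; tie-break toward fewer chunks, then lexicographic
        return (-ev, n_chunks, chunk_list)

    n_combos = math.prod(len(o) for o in options)
    if n_combos <= exhaustive_cap:
        best = min(itertools.product(*options), key=key)
    else:
        # coordinate ascent from the all-uni-gram encoding
        unigram = {len(s): _uniform_parse(len(s), 1) for s in distinct}
        current = [unigram[len(s)] for s in distinct]
        improved = True
        while improved:
            improved = False
            for i in range(len(distinct)):
                candidates = []
                for parse in options[i]:
                    trial = tuple(current[:i] + [parse] + current[i + 1 :])
                    candidates.append((key(trial), parse))
                best_key, best_parse = min(candidates)
                if best_parse is not current[i] and best_key < key(tuple(current)):
                    current[i] = best_parse
                    improved = True
        best = tuple(current)
    return _model_from_choice(distinct, best, eta)


@dataclass
class TrialModelFit:
    """Optimal model and the presented trial's codes, for one trial."""

    trial_index: int
    sequence: Sequence
    condition: str
    model: ChunkModel
    codes: tuple[tuple[tuple[str, ...], int], ...]


def sequential_optimal_models(
    schedule,
    inventory: NGramInventory | None = None,
    eta: float = DEFAULT_ETA,
    min_support: int = 3,
) -> list[TrialModelFit]:
    """Optimal chunk model after each main trial of a schedule.

    The corpus at trial t is the practice prefix plus main trials 1..t.
    With the experiment's design the result is stationary: every
    repeating trial is encoded with a single whole-sequence chunk and
    every novel trial with four uni-grams.
    """
    if inventory is None:
        inventory = build_inventory()
    corpus = [as_sequence(t.sequence) for t in schedule.practice]
    fits: list[TrialModelFit] = []
    for trial in schedule.trials:
        s = as_sequence(trial.sequence)
        corpus.append(s)
        model = fit_optimal_model(corpus, inventory, eta, min_support)
        fits.append(
            TrialModelFit(
                trial_index=trial.trial_index,
                sequence=s,
                condition=trial.condition,
                model=model,
                codes=model.codes_for(s),
            )
        )
    return fits


def trial_codes(fits: list[TrialModelFit]) -> list[tuple[tuple[tuple[str, ...], int], ...]]:
    """Per-trial (chunk, start-position) code sets from sequential fits."""
    return [f.codes for f in fits]


def chunk_rdm(
    schedule,
    fits: list[TrialModelFit] | None = None,
    inventory: NGramInventory | None = None,
    eta: float = DEFAULT_ETA,
) -> RDM:
    """Chunk-code dissimilarity between trials.

    distance(i, j) = 1 − |shared (chunk, start-position) codes| /
    max(|codes_i|, |codes_j|).  Position-anchored and max-normalised so
    that two presentations of the same repeating sequence are at
    distance 0, a repeating and a novel trial (which by design share no
    codes) are at distance 1, and two novel trials fall back to the
    item-position account: their uni-gram codes coincide exactly where
    their items match, giving Hamming/L.
    """
    if fits is None:
        fits = sequential_optimal_models(schedule, inventory, eta)
    codes = [set(f.codes) for f in fits]
    labels = [f"{f.trial_index}:{f.sequence}" for f in fits]
    m = len(codes)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i):
            shared = len(codes[i] & codes[j])
            d[i, j] = d[j, i] = 1.0 - shared / max(len(codes[i]), len(codes[j]))
    return RDM(labels, d)
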