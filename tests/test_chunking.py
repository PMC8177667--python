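"""Chunk learning: inventory priors, parses, evidence, optimal-model search."""

import itertools
import math

import numpy as np
import pytest

import seqrecode as sq
from seqrecode.chunking import (
    Parse,
    _uniform_parse,
    count_spans,
    trial_codes,
)
from seqrecode.errors import EncodingMismatchError, SeqrecodeError

PRACTICE = ["CADB"] * 12 + ["DCBA"] * 12


@pytest.fixture(scope="module")
def inventory():
    return sq.build_inventory()


def brute_force_parses(length):
    """Oracle: enumerate compositions of `length` recursively."""
    if length == 0:
        return [[]]
    out = []
    for first in range(1, length + 1):
        for rest in brute_force_parses(length - first):
            out.append([first] + [r for r in rest])
    return out


class TestParses:
    @pytest.mark.parametrize("length,expected", [(1, 1), (3, 4), (4, 8)])
    def test_counts(self, length, expected):
        assert len(sq.enumerate_parses(length)) == expected

    def test_counts_match_recursive_oracle_up_to_8(self):
        for length in range(1, 9):
            assert len(sq.enumerate_parses(length)) == len(brute_force_parses(length))
            assert len(sq.enumerate_parses(length)) == 2 ** (length - 1)

    def test_invalid_length(self):
        with pytest.raises(SeqrecodeError):
            sq.enumerate_parses(0)

    def test_spans_cover_in_order(self):
        for parse in sq.enumerate_parses(4):
            flat = [p for span in parse.links for p in span]
            assert flat == [1, 2, 3, 4]

    def test_chunks_of_applies_content(self):
        parse = Parse(((1,), (2, 3), (4,)))
        assert parse.chunks_of("ABCD") == (("A",), ("B", "C"), ("D",))


class TestInventory:
    def test_size_and_class_counts(self, inventory):
        assert len(inventory) == 64
        by_len = {
            k: sum(1 for e in inventory.entries if len(e) == k) for k in (1, 2, 3, 4)
        }
        assert by_len == {1: 4, 2: 12, 3: 24, 4: 24}

    def test_priors_sum_to_one(self, inventory):
        total = sum(math.exp(lp) for lp in inventory.log_prior.values())
        assert total == pytest.approx(1.0)

    def test_unigram_bigram_ratio_is_three(self, inventory):
        assert inventory.prior(("A",)) / inventory.prior(("A", "B")) == pytest.approx(3.0)

    def test_alpha_norm(self, inventory):
        assert inventory.alpha_norm == pytest.approx(0.25)
        assert inventory.prior(("A",)) == pytest.approx(1 / 16)
        assert inventory.prior(("A", "B")) == pytest.approx(1 / 48)

    def test_alphabet_too_small(self):
        with pytest.raises(SeqrecodeError):
            sq.build_inventory(sq.Alphabet(("A", "B")), max_length=4)


class TestEvidenceTerms:
    def test_empty_chunk_set(self, inventory):
        assert sq.chunk_set_log_prob([], inventory) == 0.0

    def test_unigram_set(self, inventory):
        lp = sq.chunk_set_log_prob([("A",), ("B",), ("C",), ("D",)], inventory)
        assert lp == pytest.approx(4 * math.log(1 / 16))

    def test_additivity(self, inventory):
        a = sq.chunk_set_log_prob([("A", "B")], inventory)
        b = sq.chunk_set_log_prob([("C",), ("D",)], inventory)
        joint = sq.chunk_set_log_prob([("A", "B"), ("C",), ("D",)], inventory)
        assert joint == pytest.approx(a + b)

    def test_unknown_chunk(self, inventory):
        with pytest.raises(SeqrecodeError):
            sq.chunk_set_log_prob([("A", "A")], inventory)

    @pytest.mark.parametrize(
        "links,f", [((((1, 2, 3, 4),)), 1), ((((1,), (2,), (3,), (4,))), 4),
                    ((((1, 2), (3, 4))), 2)]
    )
    def test_mapping_log_prob(self, links, f):
        parse = Parse(tuple(links))
        assert sq.mapping_log_prob(parse, 0.1) == pytest.approx(f * math.log(0.1))

    def test_eta_out_of_range(self):
        parse = Parse(((1, 2, 3, 4),))
        for eta in (0.0, -1.0, 1.5):
            with pytest.raises(SeqrecodeError):
                sq.mapping_log_prob(parse, eta)


def brute_force_evidence(model, seqs, inventory):
    """Oracle: exp of the evidence as a direct product of prior and
    mapping factors, computed without the log-space code path."""
    p = 1.0
    for c in model.chunks:
        p *= inventory.prior(c)
    for s in seqs:
        parse = model.assignments[sq.Sequence.from_string(s)]
        p *= model.eta ** parse.n_links
    return p


class TestModelEvidence:
    def test_single_sequence_single_chunk(self, inventory):
        seq = sq.Sequence.from_string("ABCD")
        model = sq.ChunkModel(
            ((("A", "B", "C", "D"),)), {seq: Parse(((1, 2, 3, 4),))}, eta=0.1
        )
        ev = sq.model_evidence(model, ["ABCD"], inventory)
        assert ev.log_code == pytest.approx(math.log(1 / 96))
        assert ev.log_encoding == pytest.approx(math.log(0.1))
        assert ev.log_total == ev.log_code + ev.log_encoding

    def test_bigram_beats_unigram_encoding_of_shared_structure(self, inventory):
        """For S = {ABCD, ABCD, CDAB} with chunks {AB, CD, A, B, C, D},
        the bi-gram mapping has higher evidence than the uni-gram one."""
        chunks = (("A", "B"), ("C", "D"), ("A",), ("B",), ("C",), ("D",))
        seqs = ["ABCD", "ABCD", "CDAB"]
        s1, s2 = sq.Sequence.from_string("ABCD"), sq.Sequence.from_string("CDAB")
        z1 = sq.ChunkModel(
            chunks, {s1: Parse(((1, 2), (3, 4))), s2: Parse(((1, 2), (3, 4)))}
        )
        z2 = sq.ChunkModel(
            chunks,
            {s1: _uniform_parse(4, 1), s2: _uniform_parse(4, 1)},
        )
        e1 = sq.model_evidence(z1, seqs, inventory)
        e2 = sq.model_evidence(z2, seqs, inventory)
        assert e1.log_code == pytest.approx(e2.log_code)  # same chunk set
        assert e1.log_total > e2.log_total

    def test_evidence_decreases_as_corpus_grows(self, inventory):
        model = sq.fit_optimal_model(PRACTICE, inventory)
        totals = []
        for m in (4, 8, 16, 24):
            ev = sq.model_evidence(model, PRACTICE[:m], inventory)
            totals.append(ev.log_total)
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_mismatch_raises(self, inventory):
        seq = sq.Sequence.from_string("ABCD")
        model = sq.ChunkModel(
            ((("A", "B", "C", "D"),)), {seq: Parse(((1, 2, 3, 4),))}
        )
        with pytest.raises(EncodingMismatchError):
            sq.model_evidence(model, ["DCBA"], inventory)

    def test_chunk_set_must_cover_assignments(self):
        seq = sq.Sequence.from_string("ABCD")
        with pytest.raises(EncodingMismatchError):
            sq.ChunkModel(((("A",),)), {seq: Parse(((1, 2, 3, 4),))})

    def test_log_evidence_matches_brute_force_product(self, inventory):
        """exp(log evidence) equals the independent product of prior and
        eta factors for assorted small models."""
        cases = [
            (["ABCD"], {"ABCD": ((1, 2, 3, 4),)}),
            (["ABCD", "ABCD"], {"ABCD": ((1, 2), (3, 4))}),
            (
                ["ABCD", "CDAB", "ABCD"],
                {"ABCD": ((1, 2), (3, 4)), "CDAB": ((1, 2), (3, 4))},
            ),
            (["ABC", "ABC"], {"ABC": ((1,), (2, 3))}),
        ]
        for seqs, raw in cases:
            assignments = {
                sq.Sequence.from_string(k): Parse(v) for k, v in raw.items()
            }
            chunks = tuple(
                sorted({c for s, p in assignments.items() for c in p.chunks_of(s)})
            )
            model = sq.ChunkModel(chunks, assignments, eta=0.1)
            ev = sq.model_evidence(model, seqs, inventory)
            assert math.exp(ev.log_total) == pytest.approx(
                brute_force_evidence(model, seqs, inventory)
            )


class TestReferenceModels:
    def test_practice_ranking(self, inventory):
        """After 12 presentations of each repeating sequence the 4-gram
        model outranks the 2-gram and 1-gram models."""
        table = sq.reference_models(PRACTICE, inventory)
        assert list(table.model_id) == ["4-gram", "2-gram", "1-gram"]

    @pytest.mark.parametrize("eta", [0.25, 0.125, 0.1])
    def test_practice_ranking_robust_to_eta(self, inventory, eta):
        table = sq.reference_models(PRACTICE, inventory, eta=eta)
        assert table.model_id.iloc[0] == "4-gram"
        assert table.model_id.iloc[-1] == "1-gram"

    def test_single_sequence_favours_largest_chunk(self, inventory):
        """On one sequence the plain evidence always prefers the single
        four-gram encoding: p1^4 eta^4 < p4 eta for any eta <= 1.  (The
        learning distinction comes from the support rule in the optimal-
        model search, not from the raw evidence.)"""
        table = sq.reference_models(["ABCD"], inventory)
        assert table.model_id.iloc[0] == "4-gram"

    def test_code_term_ordering(self, inventory):
        """Per-chunk, the 1-gram code is cheapest and 4-gram costliest."""
        table = sq.reference_models(["ABCD"], inventory).set_index("model_id")
        per_chunk = {
            "1-gram": table.loc["1-gram", "log_code"] / 4,
            "2-gram": table.loc["2-gram", "log_code"] / 2,
            "4-gram": table.loc["4-gram", "log_code"] / 1,
        }
        assert per_chunk["1-gram"] > per_chunk["2-gram"] > per_chunk["4-gram"]

    def test_indivisible_length(self, inventory):
        with pytest.raises(SeqrecodeError):
            sq.reference_models(["ABC"], inventory, sizes=(2,))


class TestOptimalModel:
    def test_practice_set_yields_two_four_grams(self, inventory):
        model = sq.fit_optimal_model(PRACTICE, inventory)
        assert set(model.chunks) == {tuple("CADB"), tuple("DCBA")}

    def test_practice_plus_novel_adds_unigrams(self, inventory):
        model = sq.fit_optimal_model(PRACTICE + ["ABCD"], inventory)
        assert set(model.chunks) == {
            tuple("CADB"), tuple("DCBA"),
            ("A",), ("B",), ("C",), ("D",),
        }

    def test_one_shot_sequence_encoded_with_unigrams(self, inventory):
        model = sq.fit_optimal_model(["ABCD"], inventory)
        assert set(model.chunks) == {("A",), ("B",), ("C",), ("D",)}

    def test_four_gram_overtakes_within_12_reps(self, inventory):
        """The repeating pair is whole-sequence-chunked well before the
        12 practice repetitions used by the experiment."""
        first = None
        for reps in range(1, 13):
            corpus = ["CADB"] * reps + ["DCBA"] * reps
            model = sq.fit_optimal_model(corpus, inventory)
            if any(len(c) == 4 for c in model.chunks):
                first = reps
                break
        assert first is not None and first <= 12

    def test_matches_exhaustive_search_on_small_sets(self, inventory):
        """Fitted evidence >= every candidate in an independent exhaustive
        enumeration of parse choices, for the unrestricted space."""
        corpora = [
            ["ABCD"],
            ["ABCD", "ABCD"],
            ["ABCD", "CDAB"],
            ["ABCD", "ABCD", "CDAB", "BACD"],
        ]
        for seqs in corpora:
            fitted = sq.fit_optimal_model(seqs, inventory, min_support=1)
            fitted_ev = sq.model_evidence(fitted, seqs, inventory).log_total
            distinct = sorted({sq.Sequence.from_string(s) for s in map(str, seqs)})
            parses = sq.enumerate_parses(4)
            for choice in itertools.product(parses, repeat=len(distinct)):
                assignments = dict(zip(distinct, choice))
                chunks = tuple(sorted(
                    {c for s, p in assignments.items() for c in p.chunks_of(s)}
                ))
                ev = sq.model_evidence(
                    sq.ChunkModel(chunks, assignments), seqs, inventory
                ).log_total
                assert fitted_ev >= ev - 1e-9

    def test_planted_chunk_recovery(self, inventory):
        """Corpora built by concatenating planted chunks score higher under
        the planted model than under the all-uni-gram model, at >= 3
        repetitions of each planted sequence."""
        planted = {
            sq.Sequence.from_string("ABCD"): Parse(((1, 2), (3, 4))),
            sq.Sequence.from_string("CDAB"): Parse(((1, 2), (3, 4))),
        }
        chunks = (("A", "B"), ("C", "D"))
        seqs = ["ABCD", "CDAB"] * 3
        planted_model = sq.ChunkModel(chunks, planted)
        unigram_model = sq.ChunkModel(
            (("A",), ("B",), ("C",), ("D",)),
            {s: _uniform_parse(4, 1) for s in planted},
        )
        ep = sq.model_evidence(planted_model, seqs, inventory).log_total
        eu = sq.model_evidence(unigram_model, seqs, inventory).log_total
        assert ep > eu

    def test_empty_corpus_raises(self, inventory):
        with pytest.raises(SeqrecodeError):
            sq.fit_optimal_model([], inventory)


class TestSequentialModels:
    def test_stationary_encodings_on_standard_schedule(self, schedule, stationary_fits):
        """Every repeating trial is one four-gram, every novel trial four
        uni-grams, across all 72 main trials."""
        assert len(stationary_fits) == 72
        for f in stationary_fits:
            if f.condition == "repeating":
                assert len(f.codes) == 1 and len(f.codes[0][0]) == 4
            else:
                assert len(f.codes) == 4
                assert all(len(c) == 1 for c, _ in f.codes)

    @pytest.mark.parametrize("eta", [0.25, 0.125])
    def test_stationarity_robust_to_eta(self, schedule, eta):
        fits = sq.sequential_optimal_models(schedule, eta=eta)
        for f in fits:
            expected = 1 if f.condition == "repeating" else 4
            assert len(f.codes) == expected

    def test_no_practice_starts_with_unigrams(self, seq_set):
        sched = sq.build_schedule(seq_set, practice_reps=0, rng_seed=4)
        fits = sq.sequential_optimal_models(sched)
        first = fits[0]
        assert all(len(c) == 1 for c, _ in first.codes)

    def test_trial_codes_align(self, stationary_fits):
        codes = trial_codes(stationary_fits)
        assert len(codes) == len(stationary_fits)


class TestChunkRDM:
    def test_three_regimes(self, schedule, stationary_fits):
        """Same repeating sequence -> 0; repeating vs novel -> 1; novel vs
        novel -> Hamming/4."""
        rdm = sq.chunk_rdm(schedule, fits=stationary_fits)
        trials = schedule.trials
        for i in range(0, len(trials), 7):
            for j in range(i):
                d = rdm.values[i, j]
                ci, cj = trials[i].condition, trials[j].condition
                if ci == cj == "repeating":
                    expected = 0.0 if trials[i].sequence == trials[j].sequence else 1.0
                elif ci != cj:
                    expected = 1.0
                else:
                    expected = sq.hamming_distance(
                        trials[i].sequence, trials[j].sequence
                    ) / 4
                assert d == pytest.approx(expected)

    def test_count_spans(self):
        assert count_spans(4) == 10
        assert 1 / count_spans(4) == pytest.approx(sq.DEFAULT_ETA)
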