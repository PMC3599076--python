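"""FAO/WHO rule engine: exact word match and sliding-window identity."""

from __future__ import annotations

import numpy as np
import pytest

from allerkit import (
    Label,
    ProteinRecord,
    Rule1Params,
    Rule2Params,
    SequenceDataset,
    build_word_index,
    rule1_predict,
    rule2_boundary_pair,
    rule2_max_identity,
    rule2_predict,
    rule_both_predict,
)
from allerkit.alphabet import decode

from conftest import random_protein_dataset


def brute_force_shared_word(query: str, allergens: list[str], w: int) -> bool:
    """Oracle: does any length-w substring of the query occur in any allergen?"""
    return any(query[i : i + w] in a for i in range(len(query) - w + 1) for a in allergens)


class TestWordIndex:
    def test_enumeration(self):
        ds = SequenceDataset([ProteinRecord("a", "AAAA", label=Label.ALLERGEN)])
        idx = build_word_index(ds, 3)
        assert idx.words == {"AAA": [("a", 1), ("a", 2)]}

    def test_empty_dataset(self):
        assert len(build_word_index(SequenceDataset([]), 4)) == 0

    def test_total_positions_formula(self):
        ds = random_protein_dataset(8, 37, seed=4)
        for w in (2, 5, 9):
            idx = build_word_index(ds, w)
            expected = sum(max(0, len(r.sequence) - w + 1) for r in ds)
            assert idx.n_positions == expected

    def test_short_allergen_contributes_nothing(self):
        ds = SequenceDataset([ProteinRecord("tiny", "MK", label=Label.ALLERGEN)])
        assert len(build_word_index(ds, 6)) == 0


class TestRule1:
    @pytest.fixture()
    def allergens(self):
        return SequenceDataset([ProteinRecord("alg1", "GGLVAAAQGG", label=Label.ALLERGEN)])

    def test_shared_hexamer_positive(self, allergens):
        idx = build_word_index(allergens, 6)
        v = rule1_predict(ProteinRecord("q", "MKLVAAAQTT"), idx)
        assert v.is_allergen
        assert any(h.word == "LVAAAQ" for h in v.evidence)
        hit = next(h for h in v.evidence if h.word == "LVAAAQ")
        assert hit.query_start == 3  # 1-based

    def test_wordsize_7_negative(self, allergens):
        idx = build_word_index(allergens, 7)
        assert not rule1_predict(ProteinRecord("q", "MKLVAAAQTT"), idx).is_allergen

    def test_self_match_every_position(self):
        seq = "MKVLTTGEACWY"
        ds = SequenceDataset([ProteinRecord("self", seq, label=Label.ALLERGEN)])
        idx = build_word_index(ds, 6)
        v = rule1_predict(ProteinRecord("self", seq), idx)
        starts = {h.query_start for h in v.evidence}
        assert starts == set(range(1, len(seq) - 6 + 2))

    def test_query_shorter_than_wordsize(self, allergens):
        idx = build_word_index(allergens, 6)
        assert not rule1_predict(ProteinRecord("q", "MKV"), idx).is_allergen

    def test_wordsize_mismatch_error(self, allergens):
        idx = build_word_index(allergens, 6)
        with pytest.raises(ValueError):
            rule1_predict(ProteinRecord("q", "MKLVAAAQTT"), idx, Rule1Params(wordsize=7))

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            db = random_protein_dataset(5, int(rng.integers(20, 120)), seed=100 + trial)
            query = ProteinRecord("q", decode(rng.integers(0, 20, int(rng.integers(10, 120)))))
            for w in range(2, 9):
                idx = build_word_index(db, w)
                got = rule1_predict(query, idx).is_allergen
                want = brute_force_shared_word(query.sequence, [r.sequence for r in db], w)
                assert got == want

    def test_monotone_in_wordsize(self):
        db = random_protein_dataset(10, 80, seed=31)
        queries = random_protein_dataset(30, 80, seed=32, prefix="q")
        previous = None
        for w in range(2, 10):
            idx = build_word_index(db, w)
            positives = {q.id for q in queries if rule1_predict(q, idx).is_allergen}
            if previous is not None:
                assert positives <= previous
            previous = positives


def smith_waterman_identity_oracle(a: str, b: str, open_gap=11, extend=1):
    """Exhaustive affine-gap Smith-Waterman returning (identities, columns)
    of the best-scoring local alignment under BLOSUM62."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)  # ends in a match/mismatch
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[:, 0] = M[0, :] = 0
    back = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            # fresh-start option first so score ties at 0 terminate the traceback
            options = [(0.0, "0"), (M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"), (Y[i - 1, j - 1], "Y")]
            prev, src = max(options, key=lambda t: t[0])
            M[i, j] = prev + s
            back[("M", i, j)] = src
            gx = [(M[i - 1, j] - open_gap, "M"), (X[i - 1, j] - extend, "X")]
            X[i, j], back[("X", i, j)] = max(gx, key=lambda t: t[0])
            gy = [(M[i, j - 1] - open_gap, "M"), (Y[i, j - 1] - extend, "Y")]
            Y[i, j], back[("Y", i, j)] = max(gy, key=lambda t: t[0])
            if M[i, j] > best:
                best, best_pos = M[i, j], ("M", i, j)
    if best_pos is None:
        return 0, 0, 0.0
    identities = columns = 0
    state, i, j = best_pos
    while True:
        if state == "M":
            columns += 1
            identities += a[i - 1] == b[j - 1]
            nxt = back[("M", i, j)]
            i, j = i - 1, j - 1
        elif state == "X":
            columns += 1
            nxt = back[("X", i, j)]
            i -= 1
        else:
            columns += 1
            nxt = back[("Y", i, j)]
            j -= 1
        if nxt == "0":
            break
        state = nxt
    return identities, columns, best


class TestRule2:
    def test_identical_80mer_full_identity(self):
        seq = decode(np.random.default_rng(1).integers(0, 20, 80))
        allergens = SequenceDataset([ProteinRecord("alg", seq, label=Label.ALLERGEN)])
        v = rule2_predict(ProteinRecord("q", seq), allergens)
        assert v.score == 1.0
        assert v.is_allergen

    def test_disjoint_homopolymers_negative(self):
        allergens = SequenceDataset([ProteinRecord("alg", "D" * 80, label=Label.ALLERGEN)])
        v = rule2_predict(ProteinRecord("q", "K" * 80), allergens)
        assert v.score == 0.0
        assert not v.is_allergen

    def test_boundary_pair_is_exactly_35_percent(self):
        query, allergen = rule2_boundary_pair()
        identities, columns, _ = smith_waterman_identity_oracle(query.sequence, allergen.sequence)
        assert (identities, columns) == (28, 80)
        best, _ = rule2_max_identity(query, SequenceDataset([allergen]))
        assert best == pytest.approx(28 / 80, abs=0)

    def test_boundary_verdict_flips_at_35(self):
        query, allergen = rule2_boundary_pair()
        allergens = SequenceDataset([allergen])
        at_35 = rule2_predict(query, allergens, Rule2Params(identity_threshold=0.35))
        above = rule2_predict(query, allergens, Rule2Params(identity_threshold=0.40))
        strict = rule2_predict(query, allergens, Rule2Params(identity_threshold=0.35, strict=True))
        assert at_35.is_allergen
        assert not above.is_allergen
        assert not strict.is_allergen

    def test_window_denominator_option(self):
        query, allergen = rule2_boundary_pair()
        best, _ = rule2_max_identity(
            query, SequenceDataset([allergen]), Rule2Params(identity_denominator="window")
        )
        assert best == pytest.approx(28 / 80)

    def test_short_query_single_window(self):
        seq = decode(np.random.default_rng(2).integers(0, 20, 30))
        allergens = SequenceDataset([ProteinRecord("alg", seq, label=Label.ALLERGEN)])
        v = rule2_predict(ProteinRecord("q", seq), allergens)
        assert v.score == 1.0

    def test_symmetry_on_whole_sequence_windows(self):
        rng = np.random.default_rng(3)
        a = decode(rng.integers(0, 20, 60))
        b = decode(rng.integers(0, 20, 60))
        ab, _ = rule2_max_identity(ProteinRecord("a", a), SequenceDataset([ProteinRecord("b", b)]))
        ba, _ = rule2_max_identity(ProteinRecord("b", b), SequenceDataset([ProteinRecord("a", a)]))
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_threshold_monotonicity(self):
        fx_pos = random_protein_dataset(5, 90, seed=40, label=Label.ALLERGEN, prefix="p")
        queries = random_protein_dataset(10, 90, seed=41, prefix="q")
        scores = {q.id: rule2_max_identity(q, fx_pos)[0] for q in queries}
        previous = None
        for threshold in np.arange(0.25, 0.75, 0.05):
            positives = {qid for qid, s in scores.items() if s >= threshold}
            if previous is not None:
                assert positives <= previous
            previous = positives


class TestRuleBoth:
    @pytest.fixture()
    def setup(self):
        allergens = SequenceDataset([ProteinRecord("alg", "GGLVAAAQGG" + "W" * 70, label=Label.ALLERGEN)])
        index = build_word_index(allergens, 6)
        # query shares the hexamer but is otherwise dissimilar -> rule1 yes, rule2 (at 90%) no
        query = ProteinRecord("q", "MKLVAAAQTT" + "D" * 70)
        return query, index, allergens

    def test_or_and_semantics(self, setup):
        query, index, allergens = setup
        # window denominator: the shared hexamer alone (6/80) cannot reach 90%
        r2 = Rule2Params(identity_threshold=0.9, identity_denominator="window")
        v1 = rule1_predict(query, index)
        v2 = rule2_predict(query, allergens, r2)
        assert v1.is_allergen and not v2.is_allergen
        assert rule_both_predict(query, index, allergens, r2=r2, mode="or").is_allergen
        assert not rule_both_predict(query, index, allergens, r2=r2, mode="and").is_allergen

    def test_both_negative(self):
        allergens = SequenceDataset([ProteinRecord("alg", "W" * 80, label=Label.ALLERGEN)])
        index = build_word_index(allergens, 6)
        query = ProteinRecord("q", "D" * 80)
        for mode in ("or", "and"):
            assert not rule_both_predict(query, index, allergens, mode=mode).is_allergen

    def test_and_subset_or(self):
        db = random_protein_dataset(6, 70, seed=50, label=Label.ALLERGEN)
        queries = random_protein_dataset(15, 70, seed=51, prefix="q")
        index = build_word_index(db, 4)
        r1, r2 = Rule1Params(4), Rule2Params(identity_threshold=0.5)
        both_and, both_or, singles = set(), set(), {}
        for q in queries:
            v1 = rule1_predict(q, index, r1).is_allergen
            v2 = rule2_predict(q, db, r2).is_allergen
            singles[q.id] = (v1, v2)
            if rule_both_predict(q, index, db, r1, r2, mode="and").is_allergen:
                both_and.add(q.id)
            if rule_both_predict(q, index, db, r1, r2, mode="or").is_allergen:
                both_or.add(q.id)
        rule1_set = {qid for qid, (v1, _) in singles.items() if v1}
        rule2_set = {qid for qid, (_, v2) in singles.items() if v2}
        assert both_and <= rule1_set <= both_or
        assert both_and <= rule2_set <= both_or
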