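import itertools

import numpy as np
import pytest

from metacontact.coevolution import PairScoreMatrix
from metacontact.evaluation import (
    consensus_scores,
    evaluate_benchmark,
    method_overlap,
    precision_at,
    rank_pairs,
    read_casp_rr,
    redundancy_filter,
)
from metacontact.structure_labels import ContactLabelSet, NEGATIVE, POSITIVE


def make_truth(L, positives):
    labels = {}
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            labels[(i, j)] = POSITIVE if (i, j) in positives else NEGATIVE
    return ContactLabelSet(L=L, cutoff=8.0, exclusion_upper=None, labels=labels)


def brute_precision(preds, positives, L, fraction, min_sep):
    """Oracle: recompute from an unsorted copy by explicit sorting."""
    items = sorted(preds, key=lambda t: (-t[2], t[0], t[1]))
    elig = [(i, j) for i, j, _ in items if abs(i - j) >= min_sep]
    n = max(1, int(L * fraction))
    top = elig[:n]
    return sum(1 for p in top if p in positives) / n


def brute_redundancy(preds):
    """Oracle: quadratic scan against the kept set."""
    kept = []
    for cand in preds:
        blocked = False
        for k in kept:
            if abs(cand[0] - k[0]) <= 1 and abs(cand[1] - k[1]) <= 1:
                blocked = True
                break
        if not blocked:
            kept.append(cand)
    return kept


def random_instance(rng, L=20):
    pairs = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
    rng.shuffle(pairs)
    n = int(rng.integers(5, len(pairs)))
    scores = np.sort(rng.uniform(size=n))[::-1]
    preds = [(i, j, float(s)) for (i, j), s in zip(pairs[:n], scores)]
    positives = {p for p in pairs if rng.random() < 0.15}
    return preds, positives


class TestPrecisionAt:
    def test_all_correct(self):
        truth = make_truth(10, {(1, 7), (2, 8)})
        preds = [(1, 7, 0.9), (2, 8, 0.8)]
        # n = floor(10 * 0.2) = 2, both correct
        assert precision_at(preds, truth, 0.2, min_sep=5) == 1.0

    def test_hand_counted_half(self):
        # L=20, fraction 1/10 -> n=2, one of two correct
        truth = make_truth(20, {(1, 10)})
        preds = [(1, 10, 0.9), (2, 11, 0.8), (3, 12, 0.7)]
        assert precision_at(preds, truth, 0.1, min_sep=5) == 0.5

    def test_min_sep_filters_pair(self):
        truth = make_truth(30, {(1, 11), (1, 25)})
        preds = [(1, 11, 0.9), (1, 25, 0.8)]
        # at min_sep 23 the (1,11) pair disappears from the eligible list
        assert precision_at(preds, truth, 1 / 30, min_sep=23) == 1.0

    def test_empty_eligible_error(self):
        truth = make_truth(10, set())
        with pytest.raises(ValueError):
            precision_at([(1, 3, 0.5)], truth, 1.0, min_sep=5)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        preds, positives = random_instance(rng)
        truth = make_truth(20, positives)
        for frac in (1.0, 0.5, 0.2, 0.1):
            for sep in (1, 5):
                got = precision_at(preds, truth, frac, min_sep=sep)
                want = brute_precision(preds, positives, 20, frac, sep)
                assert got == pytest.approx(want)


class TestRedundancyFilter:
    def test_adjacent_removed(self):
        out = redundancy_filter([(10, 50, 0.9), (11, 51, 0.8)])
        assert out == [(10, 50, 0.9)]

    def test_distance_two_kept(self):
        out = redundancy_filter([(10, 50, 0.9), (12, 52, 0.8)])
        assert len(out) == 2

    def test_removed_does_not_block(self):
        out = redundancy_filter([(10, 50, 0.9), (11, 51, 0.8), (12, 52, 0.7)])
        assert out == [(10, 50, 0.9), (12, 52, 0.7)]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 1000)
        preds, _ = random_instance(rng)
        assert redundancy_filter(preds) == brute_redundancy(preds)

    @pytest.mark.parametrize("seed", range(10))
    def test_output_is_chebyshev_antichain(self, seed):
        rng = np.random.default_rng(seed + 2000)
        preds, _ = random_instance(rng)
        kept = redundancy_filter(preds)
        for a, b in itertools.combinations(kept, 2):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1


class TestConsensus:
    def test_identical_channels_preserve_ranking(self, rng):
        m = rng.uniform(size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ch = {k: PairScoreMatrix(m.copy(), "mfdca") for k in ("a", "b", "c")}
        cons = consensus_scores(ch)
        assert [p[:2] for p in rank_pairs(cons)] == [p[:2] for p in rank_pairs(m)]

    def test_zero_channel_is_constant_offset(self):
        """With one flat channel, the consensus ordering equals the
        two-channel rank mean (hand-checkable on 3 pairs)."""
        a = np.array([[0, 3.0, 1.0], [3.0, 0, 2.0], [1.0, 2.0, 0]])
        b = np.array([[0, 1.0, 3.0], [1.0, 0, 2.0], [3.0, 2.0, 0]])
        z = np.zeros((3, 3))
        cons = consensus_scores(
            {"a": PairScoreMatrix(a, "a"), "b": PairScoreMatrix(b, "b"),
             "z": PairScoreMatrix(z, "z")}
        )
        # ranks/3 for a: (12)=3, (13)=1, (23)=2 ; b: (12)=1, (13)=3, (23)=2
        # z contributes ranks of ties -> same value for all pairs
        s12 = cons.scores[0, 1]
        s13 = cons.scores[0, 2]
        s23 = cons.scores[1, 2]
        # hand check via explicit mean of normalized ranks
        # a ranks: s13<s23<s12 -> 1,2,3 ; b ranks: s12<s23<s13 -> 1,2,3
        # z ranks: stable ties -> 1,2,3 in pair order (12),(13),(23)
        expect12 = (3 / 3 + 1 / 3 + 1 / 3) / 3
        expect13 = (1 / 3 + 3 / 3 + 2 / 3) / 3
        expect23 = (2 / 3 + 2 / 3 + 3 / 3) / 3
        assert s12 == pytest.approx(expect12)
        assert s13 == pytest.approx(expect13)
        assert s23 == pytest.approx(expect23)

    def test_symmetric_output(self, rng):
        mats = {}
        for k in "abc":
            m = rng.uniform(size=(6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats[k] = PairScoreMatrix(m, "mfdca")
        s = consensus_scores(mats).scores
        assert np.allclose(s, s.T)

    def test_size_mismatch(self, rng):
        a = PairScoreMatrix(np.zeros((3, 3)), "a")
        b = PairScoreMatrix(np.zeros((4, 4)), "b")
        with pytest.raises(ValueError):
            consensus_scores({"a": a, "b": b})


def brute_overlap(lists_by_method, positives, L, k_fraction, min_sep):
    """Oracle: explicit set algebra over all region subsets."""
    n = max(1, int(L * k_fraction))
    corr = {}
    for name, preds in lists_by_method.items():
        elig = [(i, j) for i, j, _ in preds if abs(i - j) >= min_sep][:n]
        corr[name] = {p for p in elig if p in positives}
    regions = {}
    union = set().union(*corr.values())
    for t in union:
        members = frozenset(n for n, s in corr.items() if t in s)
        regions[members] = regions.get(members, 0) + 1
    return regions


class TestMethodOverlap:
    def test_identical_lists_all_shared(self):
        truth = make_truth(10, {(1, 7), (2, 9)})
        preds = [(1, 7, 0.9), (2, 9, 0.8)]
        out = method_overlap({"a": preds, "b": list(preds)}, truth, 1.0)
        assert out == {frozenset({"a", "b"}): 2}

    def test_disjoint_correct_sets(self):
        truth = make_truth(10, {(1, 7), (2, 9)})
        out = method_overlap(
            {"a": [(1, 7, 0.9)], "b": [(2, 9, 0.8)]}, truth, 1.0
        )
        assert out == {frozenset({"a"}): 1, frozenset({"b"}): 1}

    def test_three_method_engineered(self):
        truth = make_truth(12, {(1, 7), (2, 8), (3, 9), (4, 10)})
        lists = {
            "x": [(1, 7, 0.9), (2, 8, 0.8), (3, 9, 0.7)],
            "y": [(2, 8, 0.9), (3, 9, 0.8)],
            "z": [(3, 9, 0.9), (4, 10, 0.8)],
        }
        out = method_overlap(lists, truth, 0.5)  # n = 6, all lists fit
        assert out[frozenset({"x"})] == 1  # (1,7)
        assert out[frozenset({"x", "y"})] == 1  # (2,8)
        assert out[frozenset({"x", "y", "z"})] == 1  # (3,9)
        assert out[frozenset({"z"})] == 1  # (4,10)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 3000)
        truth_pos = {p for p in
                     [(i, j) for i in range(1, 21) for j in range(i + 1, 21)]
                     if rng.random() < 0.2}
        truth = make_truth(20, truth_pos)
        lists = {}
        for name in ("m1", "m2", "m3"):
            preds, _ = random_instance(rng)
            lists[name] = preds
        got = method_overlap(lists, truth, 0.5, min_sep=5)
        want = brute_overlap(lists, truth_pos, 20, 0.5, 5)
        assert got == want


class TestEvaluateBenchmark:
    def test_single_target_equals_per_target(self):
        truth = make_truth(10, {(1, 7)})
        preds = [(1, 7, 0.9), (2, 8, 0.5)]
        table = evaluate_benchmark([(preds, truth)], fractions=(0.1,), min_seps=(5,))
        assert table[(0.1, 5)] == precision_at(preds, truth, 0.1)

    def test_mean_of_two_targets(self):
        t1 = make_truth(10, {(1, 7)})
        t2 = make_truth(10, set())
        preds = [(1, 7, 0.9)]
        table = evaluate_benchmark(
            [(preds, t1), (preds, t2)], fractions=(0.1,), min_seps=(5,)
        )
        assert table[(0.1, 5)] == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        targets = []
        for seed in range(4):
            r = np.random.default_rng(seed)
            preds, pos = random_instance(r)
            targets.append((preds, make_truth(20, pos)))
        t1 = evaluate_benchmark(targets, min_seps=(1, 5))
        t2 = evaluate_benchmark(targets[::-1], min_seps=(1, 5))
        for k in t1:
            assert t1[k] == pytest.approx(t2[k])

    def test_filtered_and_unfiltered_in_range(self, rng):
        preds, pos = random_instance(np.random.default_rng(5))
        targets = [(preds, make_truth(20, pos))]
        for filt in (False, True):
            table = evaluate_benchmark(
                targets, min_seps=(1, 5), apply_redundancy_filter=filt
            )
            assert all(0.0 <= v <= 1.0 for v in table.values())


class TestCaspRR:
    def test_roundtrip(self, tmp_path):
        from metacontact.model import ContactPrediction, ContactPredictionSet

        ps = ContactPredictionSet(target="t", stage="2")
        ps.records = [
            ContactPrediction(1, 9, 0.8, 0.9),
            ContactPrediction(2, 8, 0.5, 0.6),
        ]
        ps.write_casp_rr(tmp_path / "p.rr")
        back = read_casp_rr(tmp_path / "p.rr")
        assert back == [(1, 9, 0.9), (2, 8, 0.6)]
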