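import numpy as np
import pytest

from metacontact.alignment_io import Alignment
from metacontact.coevolution import (
    CHANNEL_ORDER,
    PairScoreMatrix,
    apc_correct,
    compute_channels,
    invcov_scores,
    load_contact_potential,
    load_external_scores,
    mean_contact_potential,
    mfdca,
    mutual_information,
    normalized_mutual_information,
    potential_matrix,
)
from metacontact.profile_stats import (
    SequenceWeights,
    all_column_profiles,
    column_profile,
    sequence_weights,
)
from metacontact.synthetic_data import simulate_planted_pair_msa
from tests.conftest import random_alignment


def _uniform(n):
    return SequenceWeights.uniform(n)


class TestMutualInformation:
    def test_copied_column_equals_entropy(self, rng):
        col = rng.choice(list("ACDEFG"), size=200)
        aln = Alignment(["".join([a, a]) for a in col])
        w = _uniform(aln.N)
        mi = mutual_information(aln, w).scores[0, 1]
        h = column_profile(aln, 1, w).entropy
        assert mi == pytest.approx(h, abs=1e-9)

    def test_constant_columns_zero(self):
        aln = Alignment(["AC"] * 10)
        assert mutual_information(aln, _uniform(10)).scores[0, 1] == pytest.approx(0.0)

    def test_independent_columns_small(self, rng):
        rows = ["".join(rng.choice(list("ACDEFGHIKL"), size=2)) for _ in range(2000)]
        aln = Alignment(rows)
        mi = mutual_information(aln, _uniform(2000)).scores[0, 1]
        assert 0.0 <= mi < 0.05

    def test_matches_brute_force_estimator(self, rng):
        """Oracle: direct triple-loop MI over observed symbol pairs."""
        aln = random_alignment(rng, 50, 4, gap_frac=0.15)
        w = _uniform(aln.N)
        mi = mutual_information(aln, w).scores
        for (i, j) in [(0, 1), (1, 3), (0, 3)]:
            pairs = [(s[i], s[j]) for s in aln.sequences]
            brute = 0.0
            syms_i = {a for a, _ in pairs}
            syms_j = {b for _, b in pairs}
            n = len(pairs)
            for a in syms_i:
                for b in syms_j:
                    pab = sum(1 for p in pairs if p == (a, b)) / n
                    if pab == 0:
                        continue
                    pa = sum(1 for p in pairs if p[0] == a) / n
                    pb = sum(1 for p in pairs if p[1] == b) / n
                    brute += pab * np.log(pab / (pa * pb))
            assert mi[i, j] == pytest.approx(brute, abs=1e-9)

    def test_nonnegative_and_symmetric(self, rng):
        aln = random_alignment(rng, 30, 8)
        m = mutual_information(aln, sequence_weights(aln)).scores
        assert m.min() >= -1e-9
        assert np.allclose(m, m.T)

    def test_row_permutation_invariance(self, rng):
        aln = random_alignment(rng, 20, 6)
        perm = rng.permutation(20)
        aln2 = Alignment([aln.sequences[k] for k in perm])
        assert np.allclose(
            mutual_information(aln, _uniform(20)).scores,
            mutual_information(aln2, _uniform(20)).scores,
        )


class TestNormalizedMI:
    def test_identical_nonconstant_columns_one(self, rng):
        col = rng.choice(list("ACDE"), size=100)
        aln = Alignment(["".join([a, a]) for a in col])
        assert normalized_mutual_information(aln, _uniform(100)).scores[
            0, 1
        ] == pytest.approx(1.0)

    def test_constant_columns_zero_by_convention(self):
        aln = Alignment(["AC"] * 5)
        assert normalized_mutual_information(aln, _uniform(5)).scores[0, 1] == 0.0

    def test_independent_columns_near_zero(self, rng):
        rows = ["".join(rng.choice(list("ACDEFGHIKL"), size=2)) for _ in range(2000)]
        aln = Alignment(rows)
        nmi = normalized_mutual_information(aln, _uniform(2000)).scores[0, 1]
        assert 0.0 <= nmi < 0.02

    def test_range(self, rng):
        aln = random_alignment(rng, 40, 6)
        nmi = normalized_mutual_information(aln, sequence_weights(aln)).scores
        assert nmi.min() >= -1e-9 and nmi.max() <= 1 + 1e-9


class TestContactPotential:
    def test_table_symmetric(self):
        t = load_contact_potential()
        assert t.e.shape == (20, 20)
        assert np.allclose(t.e, t.e.T)

    def test_delta_profiles_give_table_entry(self):
        t = load_contact_potential()
        aln = Alignment(["AC"] * 3)
        pi = column_profile(aln, 1)
        pj = column_profile(aln, 2)
        assert mean_contact_potential(pi, pj, t) == pytest.approx(t.e[0, 1])

    def test_uniform_profiles_give_grand_mean(self):
        t = load_contact_potential()
        rows = [a + a for a in "ACDEFGHIKLMNPQRSTVWY"]
        aln = Alignment(rows)
        pi = column_profile(aln, 1)
        got = mean_contact_potential(pi, pi, t)
        assert got == pytest.approx(t.e.mean())

    def test_all_gap_column_zero(self):
        t = load_contact_potential()
        aln = Alignment(["-A", "-C"])
        assert mean_contact_potential(
            column_profile(aln, 1), column_profile(aln, 2), t
        ) == 0.0

    def test_matrix_matches_scalar(self, rng):
        t = load_contact_potential()
        aln = random_alignment(rng, 10, 5)
        profs = all_column_profiles(aln)
        m = potential_matrix(profs, t).scores
        for i in range(5):
            for j in range(i + 1, 5):
                assert m[i, j] == pytest.approx(
                    mean_contact_potential(profs[i], profs[j], t)
                )


class TestApcCorrect:
    def test_constant_matrix_zeroed(self):
        m = np.full((4, 4), 2.5)
        np.fill_diagonal(m, 0)
        # off-diagonal means are all 2.5 -> correction removes everything
        out = apc_correct(m).scores
        assert np.allclose(out, 0.0)

    def test_zero_matrix(self):
        out = apc_correct(np.zeros((3, 3))).scores
        assert np.allclose(out, 0.0)

    def test_hand_example_3x3(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        # row means (off-diag): 1.5, 2.0, 2.5 ; grand mean = 2.0
        expect_01 = 1.0 - 1.5 * 2.0 / 2.0
        expect_02 = 2.0 - 1.5 * 2.5 / 2.0
        expect_12 = 3.0 - 2.0 * 2.5 / 2.0
        out = apc_correct(m).scores
        assert out[0, 1] == pytest.approx(expect_01)
        assert out[0, 2] == pytest.approx(expect_02)
        assert out[1, 2] == pytest.approx(expect_12)


class TestCouplingEstimators:
    def test_mfdca_finds_planted_pair(self):
        aln, pair = simulate_planted_pair_msa(30, 500, coupling=0.9, seed=0)
        m = mfdca(aln, sequence_weights(aln)).scores
        iu = np.triu_indices(30, 1)
        best = int(np.argmax(m[iu]))
        assert (int(iu[0][best]) + 1, int(iu[1][best]) + 1) == pair

    def test_mfdca_background_well_below_planted(self):
        aln, pair = simulate_planted_pair_msa(30, 500, coupling=0.9, seed=1)
        m = mfdca(aln, sequence_weights(aln)).scores
        planted = m[pair[0] - 1, pair[1] - 1]
        m2 = m.copy()
        m2[pair[0] - 1, pair[1] - 1] = m2[pair[1] - 1, pair[0] - 1] = -np.inf
        assert planted >= 5 * m2.max()

    def test_mfdca_identical_rows_finite(self):
        aln = Alignment(["ACDEF"] * 10)
        m = mfdca(aln, sequence_weights(aln)).scores
        assert np.isfinite(m).all()

    def test_invcov_planted_in_top3(self):
        aln, pair = simulate_planted_pair_msa(30, 500, coupling=0.9, seed=2)
        m = invcov_scores(aln, sequence_weights(aln)).scores
        iu = np.triu_indices(30, 1)
        order = np.argsort(m[iu])[::-1][:3]
        top3 = {(int(iu[0][k]) + 1, int(iu[1][k]) + 1) for k in order}
        assert pair in top3

    def test_invcov_row_permutation_invariant(self, rng):
        aln = random_alignment(rng, 30, 6)
        perm = rng.permutation(30)
        aln2 = Alignment([aln.sequences[k] for k in perm])
        w = _uniform(30)
        assert np.allclose(
            invcov_scores(aln, w).scores, invcov_scores(aln2, w).scores, atol=1e-8
        )

    def test_invcov_L2(self, rng):
        aln = random_alignment(rng, 40, 2)
        m = invcov_scores(aln, _uniform(40)).scores
        assert m.shape == (2, 2) and np.isfinite(m).all()

    def test_mfdca_requires_two_columns(self):
        aln = Alignment(["A", "C"])
        with pytest.raises(ValueError):
            mfdca(aln, _uniform(2))


class TestExternalScores:
    def test_sparse_file(self, tmp_path):
        p = tmp_path / "s.scores"
        p.write_text("1 3 2.5\n")
        m = load_external_scores(p, 3, "psicov").scores
        assert m[0, 2] == 2.5 and m[2, 0] == 2.5
        assert m.sum() == 5.0

    def test_dense_file_symmetrized(self, tmp_path):
        p = tmp_path / "d.mat"
        p.write_text("0.0 1.0 2.0\n3.0 0.0 4.0\n5.0 6.0 0.0\n")
        m = load_external_scores(p, 3, "ccmpred").scores
        assert m[0, 1] == pytest.approx(2.0)  # (1+3)/2
        assert np.allclose(m, m.T)

    def test_empty_file_warns_zero_matrix(self, tmp_path):
        p = tmp_path / "e.scores"
        p.write_text("")
        with pytest.warns(UserWarning):
            m = load_external_scores(p, 4, "ccmpred").scores
        assert np.allclose(m, 0.0)

    def test_index_out_of_range(self, tmp_path):
        p = tmp_path / "s.scores"
        p.write_text("1 9 2.5\n")
        with pytest.raises(ValueError):
            load_external_scores(p, 3, "psicov")

    def test_non_numeric(self, tmp_path):
        p = tmp_path / "s.scores"
        p.write_text("1 2 abc\n")
        with pytest.raises(ValueError):
            load_external_scores(p, 3, "psicov")


class TestChannelAssembly:
    def test_six_channels_fixed_order(self, rng):
        aln = random_alignment(rng, 25, 8)
        w = sequence_weights(aln)
        chans = compute_channels(aln, w, all_column_profiles(aln, w))
        assert tuple(chans) == CHANNEL_ORDER
        for name, m in chans.items():
            assert isinstance(m, PairScoreMatrix)
            assert m.scores.shape == (8, 8)

    def test_external_overrides_slot(self, rng, tmp_path):
        aln = random_alignment(rng, 10, 4)
        w = sequence_weights(aln)
        p = tmp_path / "cc.scores"
        p.write_text("1 2 9.0\n")
        chans = compute_channels(
            aln, w, all_column_profiles(aln, w), external={"ccmpred": p}
        )
        assert chans["ccmpred"].source == "external-file"
        assert chans["ccmpred"].scores[0, 1] == 9.0
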