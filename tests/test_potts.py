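"""Mean-field DCA: weights, statistics, inversion, Hamiltonian, DI, gauge."""

from itertools import product

import numpy as np
import pytest

from structland import potts
from structland.alphabets import reduced_alphabet
from structland.msa_io import EncodedMsa
from structland.potts import (
    PottsModel,
    SiteStatistics,
    compute_weights,
    direct_information,
    hamiltonian,
    hamiltonian_batch,
    mean_field_fit,
    site_statistics,
    to_zero_sum_gauge,
)

from conftest import brute_force_hamiltonian, random_model


def enumerate_distribution(model):
    """Exact Boltzmann distribution by exhaustive enumeration."""
    seqs = list(product(range(model.q), repeat=model.L))
    E = np.array([-hamiltonian(model, np.array(s)) for s in seqs])
    P = np.exp(E - E.max())
    return seqs, P / P.sum()


def stats_from_distribution(seqs, P, L, q, lam=1e-6):
    """SiteStatistics of an exactly known sequence distribution."""
    f_i = np.zeros((L, q))
    f_ij = np.zeros((L, L, q, q))
    for s, p in zip(seqs, P):
        for i in range(L):
            f_i[i, s[i]] += p
            for j in range(L):
                f_ij[i, j, s[i], s[j]] += p
    f_i = (1 - lam) * f_i + lam / q
    f_ij = (1 - lam) * f_ij + lam / q**2
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    return SiteStatistics(f_i=f_i, f_ij=f_ij, lam=lam, q=q)


class TestWeights:
    def test_all_distinct_rows(self):
        enc = EncodedMsa(states=np.eye(4, dtype=int) * 2, alphabet=reduced_alphabet(4))
        w = compute_weights(enc, theta=0.9)
        assert np.allclose(w.w, 1.0) and w.Meff == 4

    def test_identical_rows_share_weight(self):
        enc = EncodedMsa(states=np.zeros((5, 6), dtype=int), alphabet=reduced_alphabet(3))
        w = compute_weights(enc, theta=0.8)
        assert np.allclose(w.w, 0.2) and w.Meff == pytest.approx(1.0)

    def test_against_brute_force_pairwise_count(self):
        rng = np.random.default_rng(4)
        S = rng.integers(0, 3, size=(5, 10))
        S[4] = S[3]  # one duplicated pair
        enc = EncodedMsa(states=S, alphabet=reduced_alphabet(3))
        w = compute_weights(enc, theta=0.8)
        expected = []
        for n in range(5):
            cnt = sum((S[n] == S[m]).mean() >= 0.8 for m in range(5))
            expected.append(1.0 / cnt)
        assert np.allclose(w.w, expected)
        assert w.w[3] == w.w[4] == 0.5


class TestSiteStatistics:
    def test_high_lambda_limit_is_uniform(self):
        enc = EncodedMsa(states=np.zeros((3, 4), dtype=int), alphabet=reduced_alphabet(3))
        stats = site_statistics(enc, lam=1 - 1e-9)
        assert np.allclose(stats.f_i, 1 / 3, atol=1e-8)

    def test_single_sequence_lambda_zero_is_one_hot(self):
        enc = EncodedMsa(states=[[0, 2, 1]], alphabet=reduced_alphabet(3))
        stats = site_statistics(enc, lam=0.0)
        expected = np.zeros((3, 3))
        expected[0, 0] = expected[1, 2] = expected[2, 1] = 1.0
        assert np.allclose(stats.f_i, expected)

    def test_weighted_counts_match_hand_expansion(self):
        # 3 sequences, weights {1, 0.5, 0.5}, lambda = 0.5
        S = np.array([[0, 1], [1, 1], [1, 1]])
        enc = EncodedMsa(states=S, alphabet=reduced_alphabet(2))
        w = potts.SequenceWeights(w=np.array([1.0, 0.5, 0.5]), theta=0.8)
        stats = site_statistics(enc, w, lam=0.5)
        q, Meff = 2, 2.0
        # position 0: state 0 has weight 1, state 1 has weight 1
        assert stats.f_i[0, 0] == pytest.approx(0.5 / q + 0.5 * (1.0 / Meff))
        assert stats.f_i[1, 1] == pytest.approx(0.5 / q + 0.5 * (2.0 / Meff))
        # pair (0,1): (0,1) carries weight 1, (1,1) carries weight 1
        assert stats.f_ij[0, 1, 0, 1] == pytest.approx(0.5 / q**2 + 0.5 * (1.0 / Meff))
        assert stats.f_ij[0, 1, 1, 1] == pytest.approx(0.5 / q**2 + 0.5 * (1.0 / Meff))

    def test_invariants(self, planted):
        _, enc = planted
        w = compute_weights(enc)
        stats = site_statistics(enc, w, lam=0.5)
        assert np.allclose(stats.f_i.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(stats.f_ij.sum(axis=(2, 3)), 1.0, atol=1e-10)
        for i in range(3):
            assert np.allclose(stats.f_ij[i, i], np.diag(stats.f_i[i]))


class TestHamiltonian:
    def test_all_zero_model(self):
        m = PottsModel(h=np.zeros((4, 3)), e=np.zeros((4, 4, 3, 3)))
        assert hamiltonian(m, np.array([0, 1, 2, 0])) == 0.0

    def test_single_site_field(self):
        m = PottsModel(h=np.array([[0.0, 3.5]]), e=np.zeros((1, 1, 2, 2)))
        assert hamiltonian(m, np.array([1])) == -3.5

    def test_length_mismatch_errors(self):
        m = PottsModel(h=np.zeros((4, 3)), e=np.zeros((4, 4, 3, 3)))
        with pytest.raises(ValueError):
            hamiltonian(m, np.array([0, 1]))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            m = random_model(5, 3, rng)
            s = rng.integers(0, 3, size=5)
            assert hamiltonian(m, s) == pytest.approx(brute_force_hamiltonian(m, s), abs=1e-12)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(13)
        m = random_model(6, 4, rng)
        S = rng.integers(0, 4, size=(20, 6))
        batch = hamiltonian_batch(m, S)
        assert np.allclose(batch, [hamiltonian(m, s) for s in S], atol=1e-12)

    def test_boltzmann_normalization_and_ranking(self):
        # exhaustive enumeration: probabilities sum to 1 and rank as -H
        rng = np.random.default_rng(14)
        for _ in range(20):
            m = random_model(3, 3, rng)
            seqs, P = enumerate_distribution(m)
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            H = np.array([hamiltonian(m, np.array(s)) for s in seqs])
            assert (np.argsort(np.argsort(P)) == np.argsort(np.argsort(-H))).all()


class TestMeanFieldFit:
    def test_independent_sites_give_zero_couplings(self):
        rng = np.random.default_rng(5)
        L, q = 4, 3
        f_i = rng.dirichlet(np.ones(q), size=L)
        f_ij = f_i[:, None, :, None] * f_i[None, :, None, :]
        for i in range(L):
            f_ij[i, i] = np.diag(f_i[i])
        stats = SiteStatistics(f_i=f_i, f_ij=f_ij, lam=0.01, q=q)
        model = mean_field_fit(stats)
        iu, ju = np.triu_indices(L, k=1)
        assert np.abs(model.e[iu, ju]).max() < 1e-6

    def test_recovers_small_planted_coupling_exactly_enumerated(self):
        # L=2, q=2 model in the mean-field small-coupling regime
        h = np.array([[0.2, -0.2], [0.1, -0.1]])
        e = np.zeros((2, 2, 2, 2))
        eps = 0.1
        e[0, 1] = np.array([[eps, -eps], [-eps, eps]])
        e[1, 0] = e[0, 1].T
        truth = to_zero_sum_gauge(PottsModel(h=h, e=e))
        seqs, P = enumerate_distribution(truth)
        stats = stats_from_distribution(seqs, P, 2, 2)
        fit = mean_field_fit(stats)
        # mean-field error is O(eps^2); 5% relative tolerance validated
        # against the exact enumeration
        assert np.allclose(fit.e[0, 1], truth.e[0, 1], atol=0.05 * eps + 1e-12)

    def test_planted_topology_recovery(self, planted_fit):
        from structland.contacts import rank_pairs

        fam, _, _, _, di = planted_fit
        ranked = rank_pairs(di, min_separation=4)
        top10 = {(i - 1, j - 1) for i, j in ranked[:10]}
        assert len(top10 & fam.planted_pairs) >= 8

    def test_column_shuffle_destroys_couplings(self, planted_fit):
        fam, enc, _, _, di = planted_fit
        rng = np.random.default_rng(99)
        S = enc.states.copy()
        for col in range(S.shape[1]):
            rng.shuffle(S[:, col])
        shuffled = EncodedMsa(states=S, alphabet=enc.alphabet)
        m2, s2, _ = potts.fit_msa(shuffled)
        di2 = direct_information(m2, s2)
        min_planted = min(di.di[i, j] for i, j in fam.planted_pairs)
        assert di2.di.max() < min_planted


class TestDirectInformation:
    def test_zero_coupling_gives_zero_di(self):
        m = PottsModel(h=np.zeros((2, 3)), e=np.zeros((2, 2, 3, 3)))
        f_i = np.array([[0.5, 0.3, 0.2], [0.2, 0.2, 0.6]])
        stats = SiteStatistics(f_i=f_i, f_ij=np.zeros((2, 2, 3, 3)), lam=0, q=3)
        di = direct_information(m, stats)
        assert di.di[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_state_uniform(self):
        J = 0.5
        e = np.zeros((2, 2, 2, 2))
        e[0, 1] = np.array([[J, -J], [-J, J]])
        e[1, 0] = e[0, 1].T
        m = PottsModel(h=np.zeros((2, 2)), e=e)
        stats = SiteStatistics(
            f_i=np.full((2, 2), 0.5), f_ij=np.zeros((2, 2, 2, 2)), lam=0, q=2
        )
        di = direct_information(m, stats)
        P = np.exp(e[0, 1])
        P /= P.sum()
        mi = (P * np.log(P / np.outer(P.sum(1), P.sum(0)))).sum()
        assert di.di[0, 1] == pytest.approx(mi, abs=1e-8)

    def test_symmetric_nonnegative_zero_diagonal(self, planted_fit):
        _, _, _, _, di = planted_fit
        assert np.allclose(di.di, di.di.T)
        assert (np.diag(di.di) == 0).all()
        assert di.di.min() >= -1e-12

    def test_planted_pairs_exceed_background_95th_percentile(self, planted_fit):
        fam, _, _, _, di = planted_fit
        L = di.L
        background = [
            di.di[i, j]
            for i in range(L)
            for j in range(i + 1, L)
            if (i, j) not in fam.planted_pairs
        ]
        thresh = np.percentile(background, 95)
        assert all(di.di[i, j] > thresh for i, j in fam.planted_pairs)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(21)
        m = random_model(3, 3, rng, scale=0.3)
        f_i = rng.dirichlet(np.ones(3), size=3)
        stats = SiteStatistics(f_i=f_i, f_ij=np.zeros((3, 3, 3, 3)), lam=0, q=3)
        di_raw = direct_information(m, stats)
        di_zs = direct_information(to_zero_sum_gauge(m), stats)
        assert np.allclose(di_raw.di, di_zs.di, atol=1e-5)


class TestZeroSumGauge:
    def test_row_and_column_sums_vanish(self):
        rng = np.random.default_rng(30)
        m = to_zero_sum_gauge(random_model(5, 4, rng))
        assert np.abs(m.e.sum(axis=2)).max() < 1e-8
        assert np.abs(m.e.sum(axis=3)).max() < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        m = to_zero_sum_gauge(random_model(4, 3, rng))
        m2 = to_zero_sum_gauge(m)
        assert np.allclose(m.e, m2.e, atol=1e-12)
        assert np.allclose(m.h, m2.h, atol=1e-12)

    def test_hamiltonian_differences_preserved(self):
        rng = np.random.default_rng(32)
        m = random_model(6, 3, rng)
        mz = to_zero_sum_gauge(m)
        for _ in range(100):
            s1 = rng.integers(0, 3, size=6)
            s2 = rng.integers(0, 3, size=6)
            d_raw = hamiltonian(m, s1) - hamiltonian(m, s2)
            d_zs = hamiltonian(mz, s1) - hamiltonian(mz, s2)
            assert d_raw == pytest.approx(d_zs, abs=1e-8)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(33)
        m = to_zero_sum_gauge(random_model(4, 3, rng))
        assert np.allclose(m.e, m.e.transpose(1, 0, 3, 2))


class TestSubsamplingTrend:
    def test_more_sequences_do_not_hurt_recovery(self, planted):
        """Top-10 DI recovery at M=2000 is at least that at M=100."""
        from structland.contacts import rank_pairs

        fam, enc = planted
        rng = np.random.default_rng(55)

        def recovered(size):
            idx = rng.choice(enc.N, size=size, replace=False)
            sub = EncodedMsa(states=enc.states[idx], alphabet=enc.alphabet)
            m, s, _ = potts.fit_msa(sub)
            di = direct_information(m, s)
            top = {(i - 1, j - 1) for i, j in rank_pairs(di, 4)[:10]}
            return len(top & fam.planted_pairs)

        assert recovered(2000) >= recovered(100)
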