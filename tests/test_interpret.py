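import math

import numpy as np
import pytest

from tcrlatent.encoding import AMINO_ACIDS
from tcrlatent.interpret import (
    MCMCRun,
    PositionFrequencyMatrix,
    analyzed_positions,
    biochem_matrix,
    cluster_matrices,
    cluster_runs,
    empirical_pfm,
    frobenius_distance,
    indices_to_seq,
    jsd_between_runs,
    matrix_uniqueness,
    mcmc_sample,
    pool_pfms,
    position_kl,
    run_battery,
    select_seeds,
    seq_to_indices,
    uniqueness_score,
)

N_AA = 20


def _run_from_seqs(seqs, epitope="E", beta=1.0):
    samples = np.stack([seq_to_indices(s) for s in seqs])
    return MCMCRun(epitope=epitope, length=samples.shape[1],
                   seed_sequence=seqs[0], beta=beta,
                   steps=len(seqs), samples=samples, rng_seed=0)


def _pfm(freqs):
    return PositionFrequencyMatrix(np.asarray(freqs, float),
                                   n_samples=100)


def _one_hot_pfm(L, aa_index):
    f = np.zeros((L, N_AA))
    f[:, aa_index] = 1.0
    return _pfm(f)


class TestPFM:
    def test_hand_count_on_ten_samples(self):
        seqs = ["CAF"] * 7 + ["CWF"] * 3
        pfm = empirical_pfm(_run_from_seqs(seqs))
        a = AMINO_ACIDS.index("A")
        w = AMINO_ACIDS.index("W")
        assert pfm.freqs[1, a] == pytest.approx(0.7)
        assert pfm.freqs[1, w] == pytest.approx(0.3)
        assert np.allclose(pfm.freqs.sum(axis=1), 1.0)

    def test_single_sequence_run_gives_one_hot_rows(self):
        pfm = empirical_pfm(_run_from_seqs(["CADF"] * 5))
        assert np.allclose(pfm.freqs.max(axis=1), 1.0)

    def test_row_sum_enforced(self):
        with pytest.raises(ValueError):
            _pfm(np.full((3, N_AA), 0.01))

    def test_pooling_is_count_weighted_mean(self):
        a = PositionFrequencyMatrix(
            np.full((2, N_AA), 1 / N_AA), n_samples=300)
        f = np.zeros((2, N_AA))
        f[:, 0] = 1.0
        b = PositionFrequencyMatrix(f, n_samples=100)
        pooled = pool_pfms([a, b])
        assert pooled.n_samples == 400
        expected = (300 * a.freqs + 100 * b.freqs) / 400
        assert np.allclose(pooled.freqs, expected)


class TestJSD:
    def test_zero_for_identical(self):
        p = _one_hot_pfm(4, 3)
        assert jsd_between_runs(p, p) == 0.0

    def test_ln2_for_disjoint_one_hots(self):
        assert jsd_between_runs(_one_hot_pfm(4, 0), _one_hot_pfm(4, 5)) == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_symmetric_and_matches_termwise_oracle(self, rng):
        for _ in range(20):
            a = rng.dirichlet(np.ones(N_AA), size=6)
            b = rng.dirichlet(np.ones(N_AA), size=6)
            pa, pb = _pfm(a), _pfm(b)
            oracle = 0.0
            for j in range(6):
                m = 0.5 * (a[j] + b[j])
                for x, dist in ((a[j], m), (b[j], m)):
                    for t in range(N_AA):
                        if x[t] > 0:
                            oracle += 0.5 * x[t] * math.log(x[t] / dist[t])
            oracle /= 6
            assert jsd_between_runs(pa, pb) == pytest.approx(oracle, abs=1e-12)
            assert jsd_between_runs(pa, pb) == jsd_between_runs(pb, pa)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jsd_between_runs(_one_hot_pfm(4, 0), _one_hot_pfm(5, 0))


class TestPositionKL:
    def test_uniform_row_gives_zero(self):
        pfm = _pfm(np.full((3, N_AA), 1 / N_AA))
        assert np.allclose(position_kl(pfm), 0.0)

    def test_one_hot_row_gives_ln20(self):
        kl = position_kl(_one_hot_pfm(3, 7))
        assert np.allclose(kl, math.log(20), atol=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        f = rng.dirichlet(np.ones(N_AA), size=4)
        kl = position_kl(_pfm(f))
        for j in range(4):
            oracle = sum(f[j, t] * math.log(N_AA * f[j, t])
                         for t in range(N_AA) if f[j, t] > 0)
            assert kl[j] == pytest.approx(oracle, abs=1e-12)


class TestClustering:
    def test_two_separated_groups_recovered_at_q2(self):
        runs = ([_run_from_seqs(["CAAF"] * 10)] * 4
                + [_run_from_seqs(["CWWF"] * 10)] * 3)
        q, labels, clusters = cluster_runs(runs, q_range=range(2, 6))
        assert q == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert sum(c.n_samples for c in clusters.values()) == 70

    def test_identical_runs_fall_back_to_single_cluster(self, caplog):
        runs = [_run_from_seqs(["CAAF"] * 5)] * 4
        with caplog.at_level("WARNING"):
            q, labels, clusters = cluster_runs(runs)
        assert q == 1 and len(clusters) == 1

    def test_matrix_clustering_two_groups(self):
        mats = [np.zeros((5, 3))] * 3 + [np.ones((5, 3))] * 3
        r, labels, means = cluster_matrices(mats, r_range=range(2, 5))
        assert r == 2
        assert np.allclose(sorted(m.mean() for m in means.values()), [0, 1])

    def test_frobenius_matches_double_loop_oracle(self, rng):
        a = rng.normal(size=(5, 7))
        b = rng.normal(size=(5, 7))
        oracle = math.sqrt(sum((a[i, j] - b[i, j]) ** 2
                               for i in range(5) for j in range(7)))
        assert frobenius_distance(a, b) == pytest.approx(oracle, abs=1e-12)


class TestUniqueness:
    def test_zero_against_identical_alternative(self):
        p = _one_hot_pfm(4, 2)
        assert uniqueness_score(p, [p]) == 0.0

    def test_ln2_against_disjoint_one_hot_alternatives(self):
        p = _one_hot_pfm(4, 0)
        alts = [_one_hot_pfm(4, 5), _one_hot_pfm(4, 9)]
        assert uniqueness_score(p, alts) == pytest.approx(math.log(2))

    def test_mean_of_three_oracle_jsds(self, rng):
        p = _pfm(rng.dirichlet(np.ones(N_AA), size=4))
        alts = [_pfm(rng.dirichlet(np.ones(N_AA), size=4)) for _ in range(3)]
        expected = np.mean([jsd_between_runs(p, a) for a in alts])
        assert uniqueness_score(p, alts) == pytest.approx(expected, abs=1e-14)

    def test_no_alternatives_is_an_error(self):
        with pytest.raises(ValueError):
            uniqueness_score(_one_hot_pfm(4, 0), [])
        with pytest.raises(ValueError):
            matrix_uniqueness(np.zeros((5, 3)), [])


class TestBiochemMatrix:
    def test_one_hot_pfm_reproduces_factor_vectors(self):
        from tcrlatent.encoding import default_atchley_table

        table = default_atchley_table()
        pfm = _one_hot_pfm(13, AMINO_ACIDS.index("R"))
        m = biochem_matrix(pfm, table)
        assert m.shape == (5, 13 - 8)
        for col in m.T:
            assert np.allclose(col, table.vector("R"))

    def test_uniform_pfm_gives_mean_factor_vector(self):
        from tcrlatent.encoding import default_atchley_table

        table = default_atchley_table()
        pfm = _pfm(np.full((13, N_AA), 1 / N_AA))
        m = biochem_matrix(pfm, table)
        mean_vec = table.matrix().mean(axis=0)
        for col in m.T:
            assert np.allclose(col, mean_vec)

    def test_entries_in_unit_interval(self, rng):
        pfm = _pfm(rng.dirichlet(np.ones(N_AA), size=14))
        m = biochem_matrix(pfm)
        assert np.all((m >= 0) & (m <= 1))

    def test_analyzed_positions_default_trims_four_each_end(self):
        assert list(analyzed_positions(13)) == [4, 5, 6, 7, 8]
        with pytest.raises(ValueError):
            analyzed_positions(8)


class _TableModel:
    def __init__(self, scores):
        self.scores = scores

    def log_affinity_many(self, seqs, epitope):
        return np.array([self.scores.get(s, -100.0) for s in seqs])


class TestSelectSeeds:
    def test_matches_full_sort_oracle(self, rng):
        pool = [f"C{''.join(rng.choice(list(AMINO_ACIDS), 8))}F"
                for _ in range(60)]
        scores = {s: float(rng.normal()) for s in pool}
        got = select_seeds(_TableModel(scores), "E", 10, pool, n_seeds=15)
        expected = sorted(sorted(set(pool)),
                          key=lambda s: (-scores[s], s))[:15]
        assert got == expected

    def test_n_seeds_one_returns_argmax(self):
        scores = {"CAAAAAAAF": 1.0, "CWWWWWWWF": 5.0}
        got = select_seeds(_TableModel(scores), "E", 9, list(scores),
                           n_seeds=1)
        assert got == ["CWWWWWWWF"]

    def test_small_pool_used_whole_with_warning(self, caplog):
        scores = {"CAAAAAAAF": 1.0, "CWWWWWWWF": 5.0}
        with caplog.at_level("WARNING"):
            got = select_seeds(_TableModel(scores), "E", 9, list(scores),
                               n_seeds=40)
        assert len(got) == 2

    def test_no_matching_length_is_an_error(self):
        with pytest.raises(ValueError):
            select_seeds(_TableModel({}), "E", 15, ["CAAF"], n_seeds=5)


class TestMCMCSampling:
    def test_terminal_residues_never_mutate(self, model50):
        e = model50.seen_epitopes[0]
        run = mcmc_sample(model50, e, "CASSLTSSGWEQYF", beta=1.0,
                          steps=500, rng_seed=0)
        c = AMINO_ACIDS.index("C")
        f = AMINO_ACIDS.index("F")
        assert np.all(run.samples[:, 0] == c)
        assert np.all(run.samples[:, -1] == f)
        assert run.samples.shape == (500, 14)

    def test_deterministic_under_seed(self, model50):
        e = model50.seen_epitopes[0]
        a = mcmc_sample(model50, e, "CASSLTSSGWEQYF", 1.0, 200, rng_seed=3)
        b = mcmc_sample(model50, e, "CASSLTSSGWEQYF", 1.0, 200, rng_seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_beta_zero_needs_no_scoring_and_mixes(self, model50):
        e = model50.seen_epitopes[0]
        run = mcmc_sample(model50, e, "CASSLTSSGWEQYF", beta=0.0,
                          steps=4000, rng_seed=1)
        pfm = empirical_pfm(run)
        inner_tv = 0.5 * np.abs(pfm.freqs[1:-1] - 1 / N_AA).sum(axis=1)
        assert inner_tv.max() < 0.25  # loose bound for a short chain

    def test_improper_seed_rejected(self, model50):
        with pytest.raises(ValueError):
            mcmc_sample(model50, model50.seen_epitopes[0], "ASSLTSSGWEQYF",
                        1.0, 10, rng_seed=0)
        with pytest.raises(ValueError):
            mcmc_sample(model50, model50.seen_epitopes[0], "CASSLTSSGWEQYF",
                        -1.0, 10, rng_seed=0)

    def test_battery_counts_and_pooling_identity(self, model50, repertoire):
        e = model50.seen_epitopes[0]
        pool = repertoire.loc[repertoire["epitope"] == e, "cdr3b"]
        runs, rep = run_battery(model50, e, 14, pool, n_seeds=3,
                                runs_per_seed=2, beta=1.0, steps=100,
                                rng_seed=0)
        assert len(runs) == 6
        assert rep.n_samples == 600
        pooled = pool_pfms([empirical_pfm(r) for r in runs])
        assert np.allclose(empirical_pfm(rep).freqs, pooled.freqs)
        assert len({r.samples.tobytes() for r in runs}) == 6  # distinct chains
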