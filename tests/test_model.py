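import math

import numpy as np
import pytest

from tcrlatent.encoding import encode_batch
from tcrlatent.model import (
    AMBIENT_LABEL,
    Cdr3bEmbedder,
    EpitopeMapper,
    ModelConfig,
    TrainedModel,
    batch_all_triplet_loss_grad,
    extract_valid_triplets,
    log_affinity,
    log_affinity_batch,
    train,
    triplet_loss,
    unnormalized_affinity,
)
from tcrlatent.model.affinity import nll_loss, nll_loss_grad


class TestAffinity:
    def test_density_at_mean_standard_gaussian_k32(self):
        f = np.zeros(32)
        p = unnormalized_affinity(f, np.zeros(32), np.ones(32))
        assert p == pytest.approx((2 * math.pi) ** -16, rel=1e-12)

    def test_k2_closed_form(self):
        p = unnormalized_affinity(np.array([1.0, 0.0]), np.zeros(2), np.ones(2))
        assert p == pytest.approx(math.exp(-0.5) / (2 * math.pi), rel=1e-12)

    def test_log_affinity_matches_termwise_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 40))
            f = rng.normal(size=k)
            mu = rng.normal(size=k)
            sigma = rng.uniform(0.05, 3.0, size=k)
            oracle = 0.0
            for j in range(k):
                oracle += (f[j] - mu[j]) ** 2 / sigma[j] + math.log(sigma[j])
            oracle = -0.5 * (oracle + k * math.log(2 * math.pi))
            assert log_affinity(f, mu, sigma) == pytest.approx(oracle, abs=1e-10)

    def test_exp_log_consistency_where_representable(self, rng):
        f = rng.normal(size=3)
        mu = rng.normal(size=3)
        sigma = rng.uniform(0.5, 2.0, size=3)
        lp = log_affinity(f, mu, sigma)
        assert math.exp(lp) == pytest.approx(
            unnormalized_affinity(f, mu, sigma), rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_affinity(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))

    def test_maximized_at_mean_for_fixed_sigma(self, rng):
        mu = rng.normal(size=8)
        sigma = rng.uniform(0.1, 2.0, size=8)
        at_mean = log_affinity(mu, mu, sigma)
        for _ in range(50):
            other = mu + rng.normal(scale=0.5, size=8)
            assert log_affinity(other, mu, sigma) <= at_mean

    def test_nll_single_pair_at_mean(self):
        F = np.zeros((1, 32))
        loss = nll_loss(F, np.zeros((1, 32)), np.ones((1, 32)))
        assert loss == pytest.approx(16 * math.log(2 * math.pi), rel=1e-12)

    def test_nll_increases_with_mahalanobis_distance(self):
        mu = np.zeros((1, 4))
        sigma = np.full((1, 4), 0.7)
        l1 = nll_loss(np.full((1, 4), 1.0), mu, sigma)
        l2 = nll_loss(np.full((1, 4), 2.0), mu, sigma)
        assert l2 > l1

    def test_nll_gradients_match_finite_differences(self, rng):
        F = rng.normal(size=(5, 6))
        mu = rng.normal(size=(5, 6))
        sigma = rng.uniform(0.2, 2.0, size=(5, 6))
        loss, gF, g_mu, g_sigma = nll_loss_grad(F, mu, sigma)
        eps = 1e-6
        for arr, grad in ((F, gF), (mu, g_mu), (sigma, g_sigma)):
            i, j = 2, 3
            arr[i, j] += eps
            up = nll_loss(F, mu, sigma)
            arr[i, j] -= 2 * eps
            down = nll_loss(F, mu, sigma)
            arr[i, j] += eps
            assert grad[i, j] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


def _brute_force_triplets(labels):
    n = len(labels)
    out = []
    for a in range(n):
        if labels[a] == AMBIENT_LABEL:
            continue
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            for g in range(n):
                if labels[g] != labels[a]:
                    out.append((a, p, g))
    return out


class TestTriplets:
    def test_mixed_batch_count_matches_hand_formula(self):
        labels = [0, 0, 0, 1, 1, AMBIENT_LABEL]
        t = extract_valid_triplets(labels)
        assert len(t) == 26  # 3*2*(2+1) + 2*1*(3+1)

    def test_two_positives_one_ambient(self):
        t = extract_valid_triplets([0, 0, AMBIENT_LABEL])
        assert len(t) == 2
        assert not any(row[0] == 2 or row[1] == 2 for row in t)

    def test_single_class_without_negatives_yields_none(self):
        assert len(extract_valid_triplets([0, 0, 0])) == 0

    def test_contents_match_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 33))
            labels = rng.integers(-1, 3, size=n)
            ours = {tuple(r) for r in extract_valid_triplets(labels)}
            assert ours == set(_brute_force_triplets(labels))

    def test_hinge_inactive_when_separated(self):
        F = np.array([[0.0, 0], [0, 0], [10, 0]])
        t = extract_valid_triplets([0, 0, 1])
        assert triplet_loss(F, t, margin=1.0) == 0.0

    def test_equal_distances_give_margin(self):
        # d(a,p) == d(a,n) == 1 for the single explicit triplet
        F = np.array([[0.0, 0], [1, 0], [0, 1]])
        t = np.array([[0, 1, 2]])
        assert triplet_loss(F, t, margin=0.5) == pytest.approx(0.5)

    def test_batch_all_matches_explicit_triplet_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 25))
            labels = rng.integers(-1, 3, size=n)
            F = rng.normal(size=(n, 5))
            t = extract_valid_triplets(labels)
            loss, grad, n_valid = batch_all_triplet_loss_grad(F, labels, 1.0)
            assert n_valid == len(t)
            if len(t):
                assert loss == pytest.approx(triplet_loss(F, t, 1.0), abs=1e-10)
            else:
                assert loss == 0.0

    def test_batch_all_gradient_matches_finite_differences(self, rng):
        labels = np.array([0, 0, 1, 1, AMBIENT_LABEL])
        F = rng.normal(size=(5, 4))
        _, grad, _ = batch_all_triplet_loss_grad(F, labels, 1.0)
        eps = 1e-6
        for i in range(5):
            for j in range(4):
                F[i, j] += eps
                up, _, _ = batch_all_triplet_loss_grad(F, labels, 1.0)
                F[i, j] -= 2 * eps
                down, _, _ = batch_all_triplet_loss_grad(F, labels, 1.0)
                F[i, j] += eps
                assert grad[i, j] == pytest.approx((up - down) / (2 * eps),
                                                   abs=1e-4)


class TestNetworks:
    def test_embedding_dimension_and_determinism(self):
        emb = Cdr3bEmbedder(32, np.random.default_rng(0))
        X = encode_batch(["CASSIRSSYEQYF", "CASSIRSSYEQYF"], "cdr3b")
        F = emb.forward(X)
        assert F.shape == (2, 32)
        assert np.array_equal(F[0], F[1])

    def test_single_residue_change_moves_embedding(self):
        hits = 0
        for seed in range(20):
            emb = Cdr3bEmbedder(16, np.random.default_rng(seed))
            X = encode_batch(["CASSIRSSYEQYF", "CASSIRSTYEQYF"], "cdr3b")
            F = emb.forward(X)
            hits += not np.allclose(F[0], F[1])
        assert hits == 20

    def test_sigma_respects_floor_for_any_parameters(self):
        for seed in range(10):
            mapper = EpitopeMapper(16, 0.05, np.random.default_rng(seed))
            Y = encode_batch(["GILGFVFTL"], "epitope")
            _, sigma = mapper.forward(Y)
            assert np.all(sigma >= 0.05)

    def test_distinct_epitopes_map_to_distinct_gaussians(self):
        mapper = EpitopeMapper(16, 0.05, np.random.default_rng(3))
        Y = encode_batch(["GILGFVFTL", "NLVPMVATV"], "epitope")
        mu, _ = mapper.forward(Y)
        assert not np.allclose(mu[0], mu[1])


class TestTraining:
    def test_loss_decreases_on_fixture(self, model50):
        assert model50.loss_trace[-1] < model50.loss_trace[0]

    def test_weight_sharing_between_objectives(self, model50):
        # the scorer's embedding and the triplet-side embedding are the same
        # network object -> bitwise identical function
        X = encode_batch(["CASSIRSSYEQYF"], "cdr3b")
        assert np.array_equal(model50.embed(["CASSIRSSYEQYF"]),
                              model50.embedder.forward(X))

    def test_training_reproducible_from_seed(self, default_split):
        cfg = ModelConfig(epochs=3, rng_seed=42)
        a = train(default_split, cfg)
        b = train(default_split, cfg)
        assert np.allclose(a.loss_trace, b.loss_trace, atol=1e-6)
        assert np.array_equal(a.embed(["CASSIRSSYEQYF"]),
                              b.embed(["CASSIRSSYEQYF"]))

    def test_checkpoint_round_trip(self, model50, tmp_path):
        path = tmp_path / "model.npz"
        model50.save(path)
        loaded = TrainedModel.load(path)
        seqs = ["CASSIRSSYEQYF", "CASSWTSSAGEQYF"]
        for e in model50.seen_epitopes:
            assert np.allclose(model50.log_affinity_many(seqs, e),
                               loaded.log_affinity_many(seqs, e), atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(variance_floor=0.0)


class TestScorer:
    def test_log_affinity_batch_agrees_with_scalar(self, model50, rng):
        seqs = ["CASSIRSSYEQYF", "CASSWTSSAGEQYF", "CAISPLQGAEQFF"]
        e = model50.seen_epitopes[0]
        batch = model50.log_affinity_many(seqs, e)
        mu, sigma = model50.epitope_gaussian(e)
        for s, lp in zip(seqs, batch):
            F = model50.embed([s])
            assert lp == pytest.approx(
                log_affinity(F[0], mu, sigma), abs=1e-10)
        assert np.allclose(batch, log_affinity_batch(model50.embed(seqs),
                                                     mu, sigma))
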