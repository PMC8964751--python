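"""Encoder/sampler/decoder oracles: normalization, equivariance, hand
computations of the message-passing equations, and loss-term identities."""

import numpy as np
import pytest

from nridyn.autodiff import Tensor
from nridyn.model import (
    EdgePosterior,
    ModelConfig,
    Reconstruction,
    decode,
    decode_t,
    elbo_loss,
    encode,
    encode_logits_t,
    gumbel_softmax_t,
    init_parameters,
    kl_divergence,
    kl_t,
    load_checkpoint,
    nll_t,
    pair_indices,
    reconstruction_nll,
    sample_edges,
    save_checkpoint,
)
from nridyn.nn import GRUCell


def make_x(rng, n_nodes=3, t=6):
    return rng.normal(size=(n_nodes, t, 6)) * 0.5


@pytest.fixture
def small_config():
    return ModelConfig(hidden_dim=8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestEncode:
    def test_two_nodes_two_normalized_distributions(self, small_config, rng):
        params = init_parameters(small_config, 2, 6, seed=1)
        q = encode(make_x(rng, 2, 6), params)
        assert q.probs.shape == (2, 4)
        np.testing.assert_allclose(q.probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_node_rejected(self, small_config):
        with pytest.raises(ValueError):
            init_parameters(small_config, 1, 6)

    def test_permutation_equivariance(self, small_config, rng):
        """Relabeling nodes permutes the posterior accordingly (shared
        weights make the encoder equivariant)."""
        n = 4
        params = init_parameters(small_config, n, 5, seed=2)
        x = make_x(rng, n, 5)
        perm = np.array([2, 3, 1, 0])  # new index of each old node
        q_direct = encode(x, params)
        inv = np.argsort(perm)
        q_perm = encode(x[inv], params)

        senders, receivers = pair_indices(n)
        lookup = {(i, j): p for p, (i, j) in enumerate(zip(senders, receivers))}
        for p, (i, j) in enumerate(zip(senders, receivers)):
            p_new = lookup[(perm[i], perm[j])]
            np.testing.assert_allclose(q_direct.probs[p], q_perm.probs[p_new],
                                       atol=1e-5)

    def test_logits_match_straight_line_hand_computation(self):
        """With positive hand-set weights (so the ELU acts as identity) the
        encoder must reproduce an independent step-by-step evaluation of the
        embed / node-to-edge / edge-to-node / node-to-edge pipeline."""
        config = ModelConfig(hidden_dim=2)
        n, t = 3, 2
        params = init_parameters(config, n, t, seed=3)

        def fill(linear, w, b):
            linear.weight.data[...] = w
            linear.bias.data[...] = b

        fill(params.emb.fc1, 0.05, 0.1)
        fill(params.emb.fc2, 0.07, 0.2)
        for mlp, (w1, w2) in zip(params.enc_edge, [(0.11, 0.13), (0.17, 0.19)]):
            fill(mlp.fc1, w1, 0.01)
            fill(mlp.fc2, w2, 0.02)
        fill(params.enc_node[0].fc1, 0.23, 0.03)
        fill(params.enc_node[0].fc2, 0.29, 0.04)
        fill(params.enc_head, 0.31, 0.05)

        x = np.abs(np.random.default_rng(4).normal(size=(n, t, 6)))

        def mlp(v, w1, b1, w2, b2):  # all values positive => ELU = identity
            return (v @ w1 + b1) @ w2 + b2

        ones = np.ones
        h = mlp(x.reshape(n, t * 6), ones((12, 2)) * 0.05, 0.1,
                ones((2, 2)) * 0.07, 0.2)
        senders, receivers = pair_indices(n)
        e = mlp(np.concatenate([h[senders], h[receivers]], axis=1),
                ones((4, 2)) * 0.11, 0.01, ones((2, 2)) * 0.13, 0.02)
        agg = np.zeros((n, 2))
        for p, j in enumerate(receivers):
            agg[j] += e[p]
        h2 = mlp(agg, ones((2, 2)) * 0.23, 0.03, ones((2, 2)) * 0.29, 0.04)
        e2 = mlp(np.concatenate([h2[senders], h2[receivers]], axis=1),
                 ones((4, 2)) * 0.17, 0.01, ones((2, 2)) * 0.19, 0.02)
        expected_logits = e2 @ (ones((2, 4)) * 0.31) + 0.05

        got = encode_logits_t(Tensor(x[None]), params).data[0]
        np.testing.assert_allclose(got, expected_logits, rtol=1e-5)


class TestSampleEdges:
    def make_q(self, probs, n_nodes=2):
        p = n_nodes * (n_nodes - 1)
        return EdgePosterior(np.tile(probs, (p, 1)), n_nodes)

    def test_samples_normalized_for_any_tau(self):
        q = self.make_q([0.25, 0.25, 0.25, 0.25])
        for tau in (0.1, 0.5, 5.0):
            z = sample_edges(q, tau, seed=0)
            np.testing.assert_allclose(z.z.sum(axis=-1), 1.0, atol=1e-6)

    def test_low_temperature_one_hot_limit(self):
        q = self.make_q([0.4, 0.3, 0.2, 0.1])
        z = sample_edges(q, tau=1e-6, seed=1)
        assert np.all(z.z.max(axis=-1) > 0.999)

    def test_nonpositive_tau_rejected(self):
        q = self.make_q([0.25, 0.25, 0.25, 0.25])
        with pytest.raises(ValueError):
            sample_edges(q, tau=0.0, seed=0)

    def test_argmax_frequencies_match_categorical_oracle(self):
        """Gumbel-argmax sampling is exactly categorical: frequencies over
        10,000 draws must match q within 3 standard errors."""
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        n_draws = 10_000
        q = EdgePosterior(np.tile(probs, (n_draws, 2, 1)), 2)
        z = sample_edges(q, tau=0.1, seed=7)
        counts = np.bincount(z.z[:, 0, :].argmax(axis=-1), minlength=4)
        freq = counts / n_draws
        se = np.sqrt(probs * (1 - probs) / n_draws)
        assert np.all(np.abs(freq - probs) <= 3 * se)


class TestDecode:
    def test_all_nonedge_isolates_nodes(self, small_config, rng):
        """With every pair sampled as nonedge there are no messages, so a
        node's prediction cannot depend on any other node's trajectory."""
        params = init_parameters(small_config, 3, 8, seed=5)
        x = make_x(rng, 3, 8)
        z = np.zeros((6, 4))
        z[:, 0] = 1.0
        base = decode(x, z, params, prediction_steps=2).mu
        x_perturbed = x.copy()
        x_perturbed[0] += 10.0
        perturbed = decode(x_perturbed, z, params, prediction_steps=2).mu
        np.testing.assert_allclose(base[1:], perturbed[1:], atol=1e-6)
        assert not np.allclose(base[0], perturbed[0])

    def test_zero_output_transform_gives_pure_residual(self, small_config, rng):
        params = init_parameters(small_config, 2, 6, seed=6)
        params.dec_out.fc1.weight.data[...] = 0.0
        params.dec_out.fc1.bias.data[...] = 0.0
        params.dec_out.fc2.weight.data[...] = 0.0
        params.dec_out.fc2.bias.data[...] = 0.0
        x = make_x(rng, 2, 6)
        z = np.zeros((2, 4))
        z[:, 1] = 1.0
        recon = decode(x, z, params, prediction_steps=1).mu
        np.testing.assert_allclose(recon, x[:, :-1, :], atol=1e-6)

    def test_mismatched_node_count_rejected(self, small_config, rng):
        params = init_parameters(small_config, 3, 6, seed=7)
        with pytest.raises(ValueError):
            decode(make_x(rng, 4, 6), np.full((12, 4), 0.25), params)

    def test_gru_cell_matches_hand_recurrence(self):
        """Hand-set scalar-ish GRU weights against the textbook reset/update
        gate recurrence evaluated with plain numpy."""
        rng = np.random.default_rng(8)
        cell = GRUCell(2, 2, rng)
        w_i = rng.normal(size=(2, 6)) * 0.3
        w_h = rng.normal(size=(2, 6)) * 0.3
        b_i = rng.normal(size=6) * 0.1
        b_h = rng.normal(size=6) * 0.1
        cell.w_i.data[...] = w_i
        cell.w_h.data[...] = w_h
        cell.b_i.data[...] = b_i
        cell.b_h.data[...] = b_h
        x = rng.normal(size=(1, 2))
        h = rng.normal(size=(1, 2))

        def sigmoid(v):
            return 1 / (1 + np.exp(-v))

        gi = x @ w_i + b_i
        gh = h @ w_h + b_h
        r = sigmoid(gi[:, :2] + gh[:, :2])
        zg = sigmoid(gi[:, 2:4] + gh[:, 2:4])
        n = np.tanh(gi[:, 4:] + r * gh[:, 4:])
        expected = zg * h + (1 - zg) * n

        got = cell(Tensor(x), Tensor(h)).data
        np.testing.assert_allclose(got, expected, rtol=1e-5)

    def test_permutation_equivariance(self, small_config, rng):
        n = 3
        params = init_parameters(small_config, n, 6, seed=9)
        x = make_x(rng, n, 6)
        senders, receivers = pair_indices(n)
        z = np.random.default_rng(10).dirichlet(np.ones(4), size=len(senders))
        perm = np.array([1, 2, 0])
        inv = np.argsort(perm)

        lookup = {(i, j): p for p, (i, j) in enumerate(zip(senders, receivers))}
        z_perm = np.empty_like(z)
        for p, (i, j) in enumerate(zip(senders, receivers)):
            z_perm[lookup[(perm[i], perm[j])]] = z[p]

        direct = decode(x, z, params, prediction_steps=3).mu
        permuted = decode(x[inv], z_perm, params, prediction_steps=3).mu
        # permuted run: node newidx holds old node inv[newidx]
        np.testing.assert_allclose(direct, permuted[perm], atol=1e-5)


class TestLossTerms:
    def test_nll_zero_at_perfect_reconstruction(self, rng):
        x = make_x(rng, 2, 5)
        recon = Reconstruction(x[:, 1:, :], sigma2=1e-2)
        assert reconstruction_nll(x, recon) == 0.0

    def test_nll_scalar_example(self):
        """One node, one predicted step, a single unit difference and
        sigma^2 = 0.5 gives 1/(2*0.5) = 1."""
        x = np.zeros((1, 2, 6))
        mu = np.zeros((1, 1, 6))
        mu[0, 0, 0] = 1.0
        assert reconstruction_nll(x, Reconstruction(mu, 0.5)) == pytest.approx(1.0)

    def test_nll_matches_naive_double_loop(self, rng):
        x = make_x(rng, 4, 7)
        mu = make_x(rng, 4, 7)[:, 1:, :]
        sigma2 = 0.3
        expected = 0.0
        for j in range(4):
            for t in range(1, 7):
                expected += ((x[j, t] - mu[j, t - 1]) ** 2).sum() / (2 * sigma2)
        got = reconstruction_nll(x, Reconstruction(mu, sigma2))
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_nonpositive_sigma2_rejected(self, rng):
        x = make_x(rng, 2, 4)
        recon = Reconstruction(x[:, 1:, :], sigma2=1e-2)
        with pytest.raises(ValueError):
            reconstruction_nll(x, recon, sigma2=0.0)

    def test_kl_zero_at_prior(self):
        prior = (0.91, 0.03, 0.03, 0.03)
        q = EdgePosterior(np.tile(prior, (6, 1)), 3)
        assert kl_divergence(q, prior) == pytest.approx(0.0, abs=1e-12)

    def test_kl_one_hot_under_uniform_prior_is_log_k(self):
        q = EdgePosterior(np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]), 2)
        got = kl_divergence(q, (0.25, 0.25, 0.25, 0.25))
        assert got == pytest.approx(2 * np.log(4.0), rel=1e-10)

    def test_kl_matches_naive_sum(self, rng):
        probs = rng.dirichlet(np.ones(4), size=6)
        q = EdgePosterior(probs, 3)
        prior = np.array([0.91, 0.03, 0.03, 0.03])
        expected = sum(
            probs[p, k] * np.log(probs[p, k] / prior[k])
            for p in range(6) for k in range(4) if probs[p, k] > 0
        )
        np.testing.assert_allclose(kl_divergence(q, prior), expected, atol=1e-10)

    def test_kl_uniform_prior_equals_logk_minus_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4), size=12)
        q = EdgePosterior(probs, 4)
        entropy = -(probs * np.log(probs)).sum(axis=-1)
        expected = (np.log(4.0) - entropy).sum()
        got = kl_divergence(q, (0.25,) * 4)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_kl_infinite_prior_mass_rejected(self):
        q = EdgePosterior(np.array([[0.5, 0.5, 0.0, 0.0]] * 2), 2)
        with pytest.raises(ValueError):
            kl_divergence(q, (1.0, 0.0, 0.0, 0.0))

    def test_elbo_is_sum_of_components(self, rng, small_config):
        x = make_x(rng, 3, 5)
        mu = make_x(rng, 3, 5)[:, 1:, :]
        probs = rng.dirichlet(np.ones(4), size=6)
        q = EdgePosterior(probs, 3)
        recon = Reconstruction(mu, small_config.sigma2)
        total = elbo_loss(x, recon, q, small_config)
        np.testing.assert_allclose(
            total,
            reconstruction_nll(x, recon, small_config.sigma2)
            + kl_divergence(q, small_config.prior),
            atol=1e-10,
        )
        # perfect reconstruction and q = prior => 0
        perfect = Reconstruction(x[:, 1:, :], small_config.sigma2)
        q_prior = EdgePosterior(np.tile(small_config.prior, (6, 1)), 3)
        assert elbo_loss(x, perfect, q_prior, small_config) == pytest.approx(0.0, abs=1e-9)


def test_gradient_flows_through_gumbel_path(rng):
    """Finite-difference check that the loss moves when an encoder weight
    moves, i.e. the relaxed discrete sampling is differentiable end to end."""
    config = ModelConfig(hidden_dim=4, prediction_steps=2)
    params = init_parameters(config, 3, 4, seed=11)
    x = make_x(rng, 3, 4)[None]
    prior = np.asarray(config.prior)

    def loss_value():
        g = np.random.default_rng(99)
        logits = encode_logits_t(Tensor(x), params)
        z = gumbel_softmax_t(logits, config.tau, g)
        mu = decode_t(Tensor(x), z, params, config.prediction_steps)
        return nll_t(Tensor(x), mu, config.sigma2) + kl_t(logits, prior)

    loss = loss_value()
    for p in params.parameters():
        p.grad = None
    loss.backward()
    weight = params.emb.fc1.weight
    idx = (0, 0)
    analytic = weight.grad[idx]

    # single precision: the loss is O(10^3), so a large step is needed for
    # the difference to rise above rounding
    eps = 5e-2
    weight.data[idx] += eps
    hi = loss_value().item()
    weight.data[idx] -= 2 * eps
    lo = loss_value().item()
    weight.data[idx] += eps
    numeric = (hi - lo) / (2 * eps)
    assert numeric != 0.0
    np.testing.assert_allclose(analytic, numeric, rtol=0.15, atol=1e-3)


def test_checkpoint_round_trip(tmp_path, rng, small_config):
    params = init_parameters(small_config, 3, 6, seed=12,
                             normalization={"center": np.array([1.0, 2.0, 3.0]),
                                            "scale": np.array([4.0, 5.0, 6.0])})
    x = make_x(rng, 3, 6)
    q_before = encode(x, params).probs
    save_checkpoint(params, tmp_path / "model.npz")
    loaded = load_checkpoint(tmp_path / "model.npz")
    q_after = encode(x, loaded).probs
    np.testing.assert_array_equal(q_before, q_after)
    assert loaded.config == params.config
    np.testing.assert_array_equal(loaded.normalization["scale"],
                                  params.normalization["scale"])
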