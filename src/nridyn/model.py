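"""The relational-inference core: encoder, Gumbel-softmax sampler, decoder.

The model treats a trajectory of N nodes as a fully connected directed graph
without self-loops and infers, for every ordered pair (i, j), a categorical
distribution over K latent edge types.  Edge type 1 (index 0) is hard-coded
as "nonedge": the decoder has no message function for it, so "no
interaction" is structural rather than learned.

Encoder: embed each node's whole trajectory, run node-to-edge and
edge-to-node message passing (two node-to-edge rounds), then a softmax over
K logits per ordered pair.  Sampling uses the Gumbel-softmax relaxation so
gradients flow through the discrete choice.  Decoder: per-edge-type message
MLPs weighted by the sampled edge vector, summed over incoming edges, fed
with the node input into a GRU; the predicted mean is the previous state
plus an output transform (residual form).  The training objective is the
negative ELBO: a Gaussian reconstruction term with fixed variance plus the
KL of the edge posterior against a sparsity-favoring categorical prior
(nonedge probability 0.91 by default, 0.03 for each remaining type).

Public operations accept and return plain numpy; training uses the
``*_t`` tensor-graph variants directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, log_softmax, softmax, stack
from .nn import GRUCell, Linear, MLP, Parameter, TypedMLP
from .trajectory import FeatureTensor

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "EdgePosterior",
    "EdgeSample",
    "Reconstruction",
    "pair_indices",
    "encode",
    "sample_edges",
    "decode",
    "reconstruction_nll",
    "kl_divergence",
    "elbo_loss",
    "init_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_PRIOR = (0.91, 0.03, 0.03, 0.03)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the edge-inference model.

    n_edge_types: K latent interaction categories (type 1 = nonedge).
    prior: categorical prior over edge types; the 0.91/0.03 default favors
        sparse graphs; pass ``uniform_prior()`` for the uniform variant.
    tau: Gumbel-softmax temperature (one-hot limit as tau -> 0).
    sigma2: fixed output variance of the Gaussian reconstruction term.
    prediction_steps: rollout length between teacher-forcing resyncs during
        training-time multi-step prediction.
    """

    n_edge_types: int = 4
    hidden_dim: int = 32
    tau: float = 0.5
    prior: tuple[float, ...] = DEFAULT_PRIOR
    sigma2: float = 1e-2
    encoder_rounds: int = 2
    mlp_layers: int = 2
    prediction_steps: int = 10

    def __post_init__(self):
        if self.n_edge_types < 2:
            raise ValueError("need at least 2 edge types (nonedge + one edge)")
        prior = np.asarray(self.prior, dtype=float)
        if prior.shape != (self.n_edge_types,):
            raise ValueError(
                f"prior must have {self.n_edge_types} entries, got {prior.shape}"
            )
        if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior entries must be >= 0 and sum to 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.encoder_rounds < 1:
            raise ValueError("encoder_rounds must be >= 1")
        if self.mlp_layers != 2:
            raise ValueError("only 2-layer perceptrons are supported")

    def uniform_prior(self) -> "ModelConfig":
        k = self.n_edge_types
        return ModelConfig(**{**self.__dict__, "prior": tuple([1.0 / k] * k)})


def pair_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Sender and receiver node index per ordered pair (i, j), i != j,
    enumerated sender-major."""
    senders, receivers = [], []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j:
                senders.append(i)
                receivers.append(j)
    return np.asarray(senders), np.asarray(receivers)


def _receiver_matrix(n_nodes: int, receivers: np.ndarray) -> np.ndarray:
    """(N, P) 0/1 matrix aggregating pair messages onto their receiving node."""
    r = np.zeros((n_nodes, len(receivers)))
    r[receivers, np.arange(len(receivers))] = 1.0
    return r


@dataclass
class EdgePosterior:
    """q(z_ij | x): one categorical over K types per ordered pair.

    probs has shape (..., P, K) with P = N (N - 1) ordered pairs in
    sender-major order; leading axes (if any) index trajectory windows.
    """

    probs: np.ndarray
    n_nodes: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        p = self.n_nodes * (self.n_nodes - 1)
        if self.probs.shape[-2] != p:
            raise ValueError(
                f"expected {p} ordered pairs for N={self.n_nodes}, "
                f"got {self.probs.shape[-2]}"
            )
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("edge-type distributions must sum to 1")

    @property
    def n_types(self) -> int:
        return self.probs.shape[-1]

    def mean(self) -> "EdgePosterior":
        """Average the posterior over all leading (window) axes."""
        if self.probs.ndim == 2:
            return self
        flat = self.probs.reshape(-1, *self.probs.shape[-2:])
        return EdgePosterior(flat.mean(axis=0), self.n_nodes)

    def to_matrix(self, edge_type: int) -> np.ndarray:
        """(N, N) matrix of P(z_ij = edge_type) for the mean posterior."""
        probs = self.mean().probs
        senders, receivers = pair_indices(self.n_nodes)
        m = np.zeros((self.n_nodes, self.n_nodes))
        m[senders, receivers] = probs[:, edge_type]
        return m


@dataclass
class EdgeSample:
    """A Gumbel-softmax relaxed one-hot sample per ordered pair."""

    z: np.ndarray
    tau: float
    seed: int | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.allclose(self.z.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("each z_ij must sum to 1")


@dataclass
class Reconstruction:
    """Predicted Gaussian means for steps 2..T, shape (..., N, T-1, 6)."""

    mu: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("non-finite reconstruction means")


class ModelParameters:
    """Trainable weights of encoder and decoder plus the shape metadata
    (node count, window length, normalization) needed to reuse them."""

    def __init__(self, config: ModelConfig, n_nodes: int, window_length: int,
                 rng: np.random.Generator, baseline: bool = False,
                 normalization: dict | None = None):
        if n_nodes < 2:
            raise ValueError("the model needs at least 2 nodes (no pairs otherwise)")
        h = config.hidden_dim
        k = config.n_edge_types
        self.config = config
        self.n_nodes = n_nodes
        self.window_length = window_length
        self.baseline = baseline
        self.normalization = normalization
        self.senders, self.receivers = pair_indices(n_nodes)
        self.recv_matrix = _receiver_matrix(n_nodes, self.receivers)
        # one-hot gather matrices: pair row p selects its sender/receiver node
        p = len(self.senders)
        send_gather = np.zeros((p, n_nodes))
        send_gather[np.arange(p), self.senders] = 1.0
        recv_gather = np.zeros((p, n_nodes))
        recv_gather[np.arange(p), self.receivers] = 1.0
        self._send_gather = Tensor(send_gather)
        self._recv_gather = Tensor(recv_gather)
        self._recv_agg = Tensor(self.recv_matrix)

        if not baseline:
            self.emb = MLP(window_length * 6, h, h, rng)
            self.enc_edge = [MLP(2 * h, h, h, rng) for _ in range(config.encoder_rounds)]
            self.enc_node = [MLP(h, h, h, rng) for _ in range(config.encoder_rounds - 1)]
            self.enc_head = Linear(h, k, rng)
        n_msg = 1 if baseline else k - 1
        self.dec_msg = TypedMLP(n_msg, 2 * h, h, h, rng)
        self.dec_gru = GRUCell(h + 6, h, rng)
        self.dec_out = MLP(h, h, 6, rng, final_activation=False)

    # -- bookkeeping ----------------------------------------------------------

    def _modules(self) -> dict:
        mods = {"dec_msg": self.dec_msg, "dec_gru": self.dec_gru,
                "dec_out": self.dec_out}
        if not self.baseline:
            mods["emb"] = self.emb
            for i, m in enumerate(self.enc_edge):
                mods[f"enc_edge{i}"] = m
            for i, m in enumerate(self.enc_node):
                mods[f"enc_node{i}"] = m
            mods["enc_head"] = self.enc_head
        return mods

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for name in sorted(self._modules()):
            params.extend(self._modules()[name].parameters())
        return params

    def named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for name in sorted(self._modules()):
            module = self._modules()[name]
            for attr, value in vars(module).items():
                if isinstance(value, Parameter):
                    arrays[f"{name}.{attr}"] = value.data
                elif isinstance(value, (list, tuple)):
                    continue
                elif hasattr(value, "__dict__"):
                    for sub, subval in vars(value).items():
                        if isinstance(subval, Parameter):
                            arrays[f"{name}.{attr}.{sub}"] = subval.data
        return arrays

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for key, data in arrays.items():
            obj = self._modules()[key.split(".")[0]]
            for part in key.split(".")[1:-1]:
                obj = getattr(obj, part)
            getattr(obj, key.split(".")[-1]).data[...] = data

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_arrays().items()}


# -- tensor-graph forward passes (used by training) ----------------------------


def encode_logits_t(x: Tensor, params: ModelParameters) -> Tensor:
    """Encoder forward pass: x (B, N, T, 6) -> edge-type logits (B, P, K)."""
    b, n, t, d = x.shape
    h = params.emb(x.reshape(b, n, t * d))  # whole-trajectory node embedding
    e = None
    for r, edge_mlp in enumerate(params.enc_edge):
        if r > 0:
            # edge-to-node: sum incoming pair embeddings, excluding self-pairs
            h = params.enc_node[r - 1](params._recv_agg @ e)
        pair = concat([params._send_gather @ h, params._recv_gather @ h], axis=-1)
        e = edge_mlp(pair)
    return params.enc_head(e)


def gumbel_softmax_t(logits: Tensor, tau: float, rng: np.random.Generator) -> Tensor:
    """Differentiable relaxed one-hot sample per pair."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    g = rng.gumbel(size=logits.shape)
    return softmax((log_softmax(logits, axis=-1) + Tensor(g)) / tau, axis=-1)


def decode_t(x: Tensor, z: Tensor | None, params: ModelParameters,
             prediction_steps: int) -> Tensor:
    """Recurrent decoder: predict means for steps 2..T.

    x: (B, N, T, 6); z: (B, P, K) relaxed one-hot per pair, or None for the
    no-edge-latent baseline (single shared message channel, weight one).
    During rollout the decoder feeds back its own mean prediction and
    resynchronizes with the true input every `prediction_steps` steps.
    """
    b, n, t, d = x.shape
    if n != params.n_nodes:
        raise ValueError(f"model built for {params.n_nodes} nodes, input has {n}")
    if prediction_steps < 1:
        raise ValueError("prediction_steps must be >= 1")
    h_dim = params.config.hidden_dim
    p = len(params.senders)

    if params.baseline:
        z_weights = Tensor(np.ones((1, b * p, 1)))
    else:
        if z.shape[-2] != p:
            raise ValueError(f"edge sample has {z.shape[-2]} pairs, expected {p}")
        # drop the nonedge type: it carries no message function
        z_msg = z[:, :, 1:]
        k_msg = z_msg.shape[-1]
        z_weights = z_msg.reshape(b * p, k_msg).transpose((1, 0)).reshape(k_msg, b * p, 1)

    h = Tensor(np.zeros((b, n, h_dim)))
    mus = []
    inp = x[:, :, 0, :]
    for step in range(t - 1):
        if step > 0:
            inp = x[:, :, step, :] if step % prediction_steps == 0 else mus[-1]
        pair_h = concat([params._send_gather @ h, params._recv_gather @ h], axis=-1)
        msgs = params.dec_msg(pair_h.reshape(b * p, 2 * h_dim))
        msg = (msgs * z_weights).sum(axis=0).reshape(b, p, h_dim)
        agg = params._recv_agg @ msg
        h = params.dec_gru(concat([agg, inp], axis=-1), h)
        mus.append(inp + params.dec_out(h))
    return stack(mus, axis=2)  # (B, N, T-1, 6)


def nll_t(x: Tensor, mu: Tensor, sigma2: float) -> Tensor:
    """Gaussian reconstruction term: sum over nodes and steps 2..T of
    ||x - mu||^2 / (2 sigma^2), constant dropped."""
    diff = x[:, :, 1:, :] - mu
    return (diff * diff).sum() / (2.0 * sigma2)


def kl_t(logits: Tensor, prior: np.ndarray) -> Tensor:
    """Categorical KL of the posterior against the edge-type prior, summed
    over pairs (and windows)."""
    log_q = log_softmax(logits, axis=-1)
    q = softmax(logits, axis=-1)
    return (q * (log_q - Tensor(np.log(prior)))).sum()


# -- public numpy-facing operations --------------------------------------------


def _as_batch(x) -> tuple[np.ndarray, bool]:
    arr = x.x if isinstance(x, FeatureTensor) else np.asarray(x, dtype=float)
    if arr.ndim == 3:
        return arr[None], True
    if arr.ndim == 4:
        return arr, False
    raise ValueError(f"expected (N, T, 6) or (B, N, T, 6) features, got {arr.shape}")


def encode(x, params: ModelParameters,
           config: ModelConfig | None = None) -> EdgePosterior:
    """Infer the edge-type posterior for a trajectory (or batch of windows)."""
    arr, squeeze = _as_batch(x)
    logits = encode_logits_t(Tensor(arr), params).data
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite activations in encoder")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=-1, keepdims=True)
    return EdgePosterior(probs[0] if squeeze else probs, params.n_nodes)


def sample_edges(q: EdgePosterior, tau: float, seed: int) -> EdgeSample:
    """Draw one Gumbel-softmax relaxed sample per ordered pair."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    logits = np.log(np.clip(q.probs, 1e-300, None))
    g = rng.gumbel(size=logits.shape)
    shifted = (logits + g) / tau
    shifted -= shifted.max(axis=-1, keepdims=True)
    z = np.exp(shifted)
    z /= z.sum(axis=-1, keepdims=True)
    return EdgeSample(z, tau=tau, seed=seed)


def decode(x, z: EdgeSample | np.ndarray, params: ModelParameters,
           config: ModelConfig | None = None,
           prediction_steps: int | None = None) -> Reconstruction:
    """Run the recurrent decoder given a trajectory and sampled edges."""
    cfg = config or params.config
    steps = prediction_steps if prediction_steps is not None else cfg.prediction_steps
    arr, squeeze = _as_batch(x)
    z_arr = z.z if isinstance(z, EdgeSample) else np.asarray(z, dtype=float)
    if z_arr.ndim == 2:
        z_arr = np.broadcast_to(z_arr, (arr.shape[0],) + z_arr.shape)
    mu = decode_t(Tensor(arr), Tensor(z_arr), params, steps).data
    return Reconstruction(mu[0] if squeeze else mu, cfg.sigma2)


def reconstruction_nll(x, recon: Reconstruction, sigma2: float | None = None) -> float:
    """Negative Gaussian log-likelihood (constant dropped); see `nll_t`."""
    sigma2 = recon.sigma2 if sigma2 is None else sigma2
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    arr, _ = _as_batch(x)
    mu = recon.mu if recon.mu.ndim == arr.ndim else recon.mu[None]
    diff = arr[..., 1:, :] - mu
    return float((diff**2).sum() / (2.0 * sigma2))


def kl_divergence(q: EdgePosterior, prior) -> float:
    """Sum over ordered pairs of KL(q_ij || prior); 0 log 0 = 0.

    With a uniform prior this equals sum(log K - H(q_ij)).
    """
    prior = np.asarray(prior, dtype=float)
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must sum to 1")
    probs = q.probs
    if np.any((prior == 0) & (probs > 0)):
        raise ValueError("prior has zero mass where the posterior is positive")
    terms = np.where(probs > 0, probs * (np.log(np.where(probs > 0, probs, 1.0))
                                         - np.log(prior)), 0.0)
    return float(terms.sum())


def elbo_loss(x, recon: Reconstruction, q: EdgePosterior,
              config: ModelConfig) -> float:
    """Negated ELBO up to constants: reconstruction NLL + KL to the prior."""
    return reconstruction_nll(x, recon, config.sigma2) + kl_divergence(q, config.prior)


def init_parameters(config: ModelConfig, n_nodes: int, window_length: int,
                    seed: int = 0, baseline: bool = False,
                    normalization: dict | None = None) -> ModelParameters:
    rng = np.random.default_rng(seed)
    return ModelParameters(config, n_nodes, window_length, rng,
                           baseline=baseline, normalization=normalization)


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(params: ModelParameters, path) -> None:
    """Single-archive checkpoint: weights + config + normalization record."""
    meta = {
        "config": {**params.config.__dict__, "prior": list(params.config.prior)},
        "n_nodes": params.n_nodes,
        "window_length": params.window_length,
        "baseline": params.baseline,
        "normalization": None if params.normalization is None else {
            k: np.asarray(v).tolist() for k, v in params.normalization.items()
        },
    }
    arrays = params.named_arrays()
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> ModelParameters:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    cfg = dict(meta["config"])
    cfg["prior"] = tuple(cfg["prior"])
    config = ModelConfig(**cfg)
    normalization = meta["normalization"]
    if normalization is not None:
        normalization = {k: np.asarray(v) for k, v in normalization.items()}
    params = init_parameters(config, meta["n_nodes"], meta["window_length"],
                             baseline=meta["baseline"], normalization=normalization)
    params.load_arrays(arrays)
    return params
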