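"""The co-condensation transformer: encoder, pair-bias attention, stack, head.

The architecture scores a pair of proteins for their propensity to partition
into the same condensate.  Each protein's AlphaFold2-style representations
are encoded into a residue graph (node dimension ``c_n``, edge dimension
``c_e``); the two graphs are concatenated into a two-chain complex whose
inter-chain residue pairs carry only a binary same-chain/different-chain
indicator in the reserved last edge channel; a stack of transformer blocks
— gated multi-head self-attention with an additive pair bias from the edge
features, followed by dimension-preserving transitions — exchanges
information between the chains; and a prediction head pools the residue
representations of the whole complex into a single sigmoid probability.

Parameters live in a flat ``dict[str, ndarray]`` keyed by dotted names
(linears: ``<prefix>.w`` / ``<prefix>.b``; layer norms: ``<prefix>.gain`` /
``<prefix>.bias``).  The L2 penalty used during training sums squares over
the ``.w`` entries only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, layer_norm, matmul, relu, sigmoid, softmax, softplus
from .features import C_MSA, C_PAIR, C_STRUC, FeatureBundle

__all__ = [
    "ModelConfig",
    "GraphRepresentation",
    "PredictionOutput",
    "init_params",
    "as_tensors",
    "transition",
    "self_attention",
    "encode_protein",
    "encode_proteins",
    "combine_complex",
    "transformer_stack",
    "pps_head",
    "forward_pair",
    "predict_pair",
    "l2_penalty",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the production-scale dimensions (node dim 256, edge dim 32,
    8 heads, 8 layers, transition expansion 4); :meth:`desk_scale` returns a
    narrow configuration suitable for CPU-scale experiments on surrogate
    features.  Feature dimensions are fixed by the upstream representations.
    """

    c_n: int = 256
    c_e: int = 32
    n_head: int = 8
    n_layers: int = 8
    n_expand: int = 4
    head_proj_dim: int | None = None       # per-residue projection width; default c_n
    head_hidden: tuple[int, int] | None = None  # widths of the two hidden output layers
    drop_rate_attention: float = 0.1
    drop_rate_transition: float = 0.1
    drop_rate_affinity: float = 0.1
    symmetrize: bool = True
    dtype: str = "float64"  # "float32" roughly halves CPU training time
    c_msa: int = field(default=C_MSA)
    c_pair: int = field(default=C_PAIR)
    c_struc: int = field(default=C_STRUC)

    def __post_init__(self) -> None:
        if self.c_n % self.n_head != 0:
            raise ValueError(f"c_n={self.c_n} must be divisible by n_head={self.n_head}")
        if self.c_e < 2:
            raise ValueError("c_e must be >= 2 (one channel is reserved for the chain indicator)")
        if self.head_proj_dim is None:
            self.head_proj_dim = self.c_n
        if self.head_hidden is None:
            self.head_hidden = (max(self.c_n // 2, 4), max(self.c_n // 4, 4))
        else:
            self.head_hidden = tuple(self.head_hidden)

    @property
    def c_head(self) -> int:
        """Per-head channel width c'_n."""
        return self.c_n // self.n_head

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """A narrow configuration for single-CPU training on surrogate data."""
        kw = dict(c_n=32, c_e=8, n_head=2, n_layers=2, dtype="float32")
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GraphRepresentation:
    """Residue graph for one protein or a combined two-chain complex."""

    nodes: Tensor          # (N, c_n)
    edges: Tensor          # (N, N, c_e) combined, (N, N, c_e - 1) single-chain
    chain_labels: np.ndarray
    combined: bool = False

    @property
    def n_residues(self) -> int:
        return self.nodes.shape[0]

    def validate(self) -> None:
        N = self.nodes.shape[0]
        if self.edges.shape[0] != N or self.edges.shape[1] != N:
            raise ValueError("nodes and edges disagree on residue count")
        if len(self.chain_labels) != N:
            raise ValueError("chain_labels length mismatch")
        if not (np.all(np.isfinite(self.nodes.data)) and np.all(np.isfinite(self.edges.data))):
            raise ValueError("non-finite values in graph representation")
        if self.combined:
            indicator = self.edges.data[:, :, -1]
            expected = (self.chain_labels[:, None] != self.chain_labels[None, :]).astype(float)
            if not np.array_equal(indicator, expected):
                raise ValueError("reserved edge channel does not match the chain indicator")


@dataclass
class PredictionOutput:
    """Head output: probability, optional loss, and the pooled complex vector."""

    probability: float
    pooled_repr: np.ndarray
    loss: float | None = None
    loss_tensor: Tensor | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.probability < 1.0):
            # sigmoid saturates to exactly 0/1 in float only for |logit| > ~37
            self.probability = float(np.clip(self.probability, 1e-12, 1.0 - 1e-12))
        if self.loss is not None and self.loss < 0:
            raise ValueError("loss must be nonnegative")


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------

def _linear_init(rng, fan_in: int, fan_out: int, relu_next: bool = False) -> np.ndarray:
    scale = np.sqrt((2.0 if relu_next else 1.0) / fan_in)
    return scale * rng.standard_normal((fan_in, fan_out))


def _init_transition(params, rng, prefix: str, c_in: int, c_out: int, n_expand: int) -> None:
    hidden = c_in * n_expand
    params[f"{prefix}.ln.gain"] = np.ones(c_in)
    params[f"{prefix}.ln.bias"] = np.zeros(c_in)
    params[f"{prefix}.fc1.w"] = _linear_init(rng, c_in, hidden, relu_next=True)
    params[f"{prefix}.fc1.b"] = np.zeros(hidden)
    params[f"{prefix}.fc2.w"] = _linear_init(rng, hidden, c_out)
    params[f"{prefix}.fc2.b"] = np.zeros(c_out)


def _init_layernorm(params, prefix: str, c: int) -> None:
    params[f"{prefix}.gain"] = np.ones(c)
    params[f"{prefix}.bias"] = np.zeros(c)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Draw a fresh parameter set for ``config`` from ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1417]))
    p: dict[str, np.ndarray] = {}
    cn, ce, H = config.c_n, config.c_e, config.n_head
    ne = config.n_expand

    # protein encoder
    _init_transition(p, rng, "enc.msa", config.c_msa, config.c_msa, ne)
    _init_layernorm(p, "enc.msa_ln", config.c_msa)
    _init_transition(p, rng, "enc.pair", config.c_pair, config.c_pair, ne)
    _init_layernorm(p, "enc.pair_ln", config.c_pair)
    _init_transition(p, rng, "enc.struc", config.c_struc, config.c_struc, ne)
    _init_layernorm(p, "enc.struc_ln", config.c_struc)
    _init_transition(p, rng, "enc.pair_out", config.c_pair, ce - 1, ne)
    _init_transition(p, rng, "enc.node_out", config.c_msa + config.c_struc, cn, ne)

    for i in range(config.n_layers):
        L = f"L{i}"
        _init_layernorm(p, f"{L}.attn.ln_n", cn)
        _init_layernorm(p, f"{L}.attn.ln_e", ce)
        for proj in ("q", "k", "v"):
            p[f"{L}.attn.{proj}.w"] = _linear_init(rng, cn, cn)
        p[f"{L}.attn.pair_bias.w"] = _linear_init(rng, ce, H)
        p[f"{L}.attn.gate.w"] = _linear_init(rng, cn, cn)
        p[f"{L}.attn.gate.b"] = np.ones(cn)  # open gates at init
        p[f"{L}.attn.edge_fc1.w"] = _linear_init(rng, H, ce, relu_next=True)
        p[f"{L}.attn.edge_fc1.b"] = np.zeros(ce)
        p[f"{L}.attn.edge_fc2.w"] = _linear_init(rng, ce, ce)
        p[f"{L}.attn.edge_fc2.b"] = np.zeros(ce)
        p[f"{L}.attn.out.w"] = _linear_init(rng, cn, cn)
        p[f"{L}.attn.out.b"] = np.zeros(cn)
        _init_layernorm(p, f"{L}.node_ln", cn)
        _init_transition(p, rng, f"{L}.node_trans", cn, cn, ne)
        _init_layernorm(p, f"{L}.edge_ln", ce)
        _init_transition(p, rng, f"{L}.edge_trans", ce, ce, ne)

    h1 = config.head_proj_dim
    h2, h3 = config.head_hidden
    _init_layernorm(p, "head.ln", cn)
    p["head.proj1.w"] = _linear_init(rng, cn, h1, relu_next=True)
    p["head.proj1.b"] = np.zeros(h1)
    p["head.proj2.w"] = _linear_init(rng, h1, h1)
    p["head.proj2.b"] = np.zeros(h1)
    p["head.out1.w"] = _linear_init(rng, h1, h2, relu_next=True)
    p["head.out1.b"] = np.zeros(h2)
    p["head.out2.w"] = _linear_init(rng, h2, h3, relu_next=True)
    p["head.out2.b"] = np.zeros(h3)
    p["head.out3.w"] = _linear_init(rng, h3, 1)
    p["head.out3.b"] = np.zeros(1)
    return {k: np.asarray(v, dtype=config.dtype) for k, v in p.items()}


def as_tensors(params, trainable: bool = False) -> dict[str, Tensor]:
    """Wrap raw parameter arrays as graph leaves (fresh every forward/backward)."""
    if params and isinstance(next(iter(params.values())), Tensor):
        return params
    return {k: Tensor(v, requires_grad=trainable) for k, v in params.items()}


def l2_penalty(params: dict[str, Tensor]) -> Tensor:
    """Sum of squared weight-matrix entries (``.w`` parameters only)."""
    total: Tensor | None = None
    for name, t in params.items():
        if name.endswith(".w"):
            sq = (t * t).sum()
            total = sq if total is None else total + sq
    assert total is not None
    return total


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def _linear(x: Tensor, params, prefix: str, bias: bool = True) -> Tensor:
    w = params[f"{prefix}.w"]
    lead = x.shape[:-1]
    flat = x.reshape((-1, x.shape[-1])) if x.ndim != 2 else x
    out = matmul(flat, w)
    if bias:
        out = out + params[f"{prefix}.b"]
    if x.ndim != 2:
        out = out.reshape(lead + (w.shape[-1],))
    return out


def _layer_norm(x: Tensor, params, prefix: str) -> Tensor:
    return layer_norm(x, params[f"{prefix}.gain"], params[f"{prefix}.bias"])


def transition(x: Tensor, params, prefix: str) -> Tensor:
    """Transition block: LayerNorm -> Linear (xN_expand) -> relu -> Linear.

    Dimension-preserving in the transformer blocks; the encoder reuses it
    with a different output width for its projections.
    """
    h = _layer_norm(x, params, f"{prefix}.ln")
    h = relu(_linear(h, params, f"{prefix}.fc1"))
    return _linear(h, params, f"{prefix}.fc2")


def _dropout(x: Tensor, rate: float, training: bool, rng) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(keep)


def self_attention(graph: GraphRepresentation, params, config: ModelConfig,
                   prefix: str = "L0.attn") -> GraphRepresentation:
    """Gated multi-head self-attention with pair bias.

    Edge features contribute a per-head additive bias to the attention
    logits; the updated edge features are computed from the *pre-bias,
    pre-softmax* logits through a two-layer MLP; node outputs are the gated,
    softmax-weighted value aggregates, concatenated over heads and linearly
    projected.  Returns the raw block outputs (residual addition is the
    caller's job).
    """
    H, cp = config.n_head, config.c_head
    N = graph.n_residues
    nl = _layer_norm(graph.nodes, params, f"{prefix}.ln_n")
    el = _layer_norm(graph.edges, params, f"{prefix}.ln_e")

    def heads(name):
        t = _linear(nl, params, f"{prefix}.{name}", bias=False)   # (N, c_n)
        return t.reshape((N, H, cp)).transpose(1, 0, 2)           # (H, N, cp)

    q, k, v = heads("q"), heads("k"), heads("v")
    logits = matmul(q, k.transpose(0, 2, 1)) / np.sqrt(cp)        # (H, N, N)

    # edge update from the pre-bias logits
    e_in = logits.transpose(1, 2, 0)                              # (N, N, H)
    e_h = relu(_linear(e_in, params, f"{prefix}.edge_fc1"))
    e_out = _linear(e_h, params, f"{prefix}.edge_fc2")            # (N, N, c_e)

    bias = _linear(el, params, f"{prefix}.pair_bias", bias=False) # (N, N, H)
    attn = softmax(logits + bias.transpose(2, 0, 1), axis=-1)     # (H, N, N)
    o = matmul(attn, v)                                           # (H, N, cp)
    o = o.transpose(1, 0, 2).reshape((N, H * cp))
    gate = sigmoid(_linear(nl, params, f"{prefix}.gate"))
    n_out = _linear(gate * o, params, f"{prefix}.out")
    return GraphRepresentation(n_out, e_out, graph.chain_labels, combined=graph.combined)


def encode_proteins(bundles: list[FeatureBundle], params, config: ModelConfig
                    ) -> list[GraphRepresentation]:
    """Encode several proteins in one pass (shared weights, fused matmuls).

    Residue-wise features of all proteins are concatenated before the wide
    transitions, which keeps the matrix products large enough to be efficient
    on CPU; the result is split back per protein.
    """
    lengths = [b.length for b in bundles]
    dt = np.dtype(config.dtype)
    msa = Tensor(np.concatenate([b.f_msa for b in bundles], axis=0).astype(dt))
    struc = Tensor(np.concatenate([b.f_struc for b in bundles], axis=0).astype(dt))
    pair = Tensor(np.concatenate(
        [b.f_pair.reshape(-1, config.c_pair) for b in bundles], axis=0).astype(dt))

    msa = _layer_norm(transition(msa, params, "enc.msa"), params, "enc.msa_ln")
    struc = _layer_norm(transition(struc, params, "enc.struc"), params, "enc.struc_ln")
    pair = _layer_norm(transition(pair, params, "enc.pair"), params, "enc.pair_ln")

    res = concat([msa, struc], axis=1)                    # (sum L, c_msa + c_struc)
    nodes_all = transition(res, params, "enc.node_out")   # (sum L, c_n)
    edges_all = transition(pair, params, "enc.pair_out")  # (sum L^2, c_e - 1)

    reps = []
    off_n = off_e = 0
    for L in lengths:
        nodes = nodes_all[off_n:off_n + L]
        edges = edges_all[off_e:off_e + L * L].reshape((L, L, config.c_e - 1))
        reps.append(GraphRepresentation(nodes, edges, np.zeros(L, dtype=int), combined=False))
        off_n += L
        off_e += L * L
    return reps


def encode_protein(bundle: FeatureBundle, params, config: ModelConfig) -> GraphRepresentation:
    """Encode one protein into a single-chain residue graph (edges: c_e - 1)."""
    return encode_proteins([bundle], params, config)[0]


def combine_complex(rep_a: GraphRepresentation, rep_b: GraphRepresentation
                    ) -> GraphRepresentation:
    """Concatenate two single-chain graphs into a two-chain complex.

    Inter-chain edge blocks are zero in the encoded channels; the reserved
    last channel is the binary different-chain indicator (1 across chains,
    0 within a chain — including when a protein is paired with itself).
    """
    if rep_a.combined or rep_b.combined:
        raise ValueError("combine_complex expects single-chain representations")
    na, nb = rep_a.n_residues, rep_b.n_residues
    ce1 = rep_a.edges.shape[-1]
    dt = rep_a.edges.data.dtype
    nodes = concat([rep_a.nodes, rep_b.nodes], axis=0)
    top = concat([rep_a.edges, Tensor(np.zeros((na, nb, ce1), dtype=dt))], axis=1)
    bot = concat([Tensor(np.zeros((nb, na, ce1), dtype=dt)), rep_b.edges], axis=1)
    edges = concat([top, bot], axis=0)                     # (N, N, c_e - 1)
    labels = np.concatenate([np.zeros(na, dtype=int), np.ones(nb, dtype=int)])
    indicator = (labels[:, None] != labels[None, :]).astype(dt)[:, :, None]
    edges = concat([edges, Tensor(indicator)], axis=2)     # (N, N, c_e)
    return GraphRepresentation(nodes, edges, labels, combined=True)


def transformer_stack(graph: GraphRepresentation, params, config: ModelConfig,
                      training: bool = False, rng=None) -> GraphRepresentation:
    """Apply ``n_layers`` transformer blocks with residual connections.

    Per block: attention outputs are added to nodes and edges through
    dropout; then a node transition on the layer-normed nodes and an edge
    transition likewise, each added residually through dropout.  With
    ``training=False`` dropout is the identity and the stack is
    deterministic.
    """
    if training and rng is None:
        rng = np.random.default_rng(0)
    nodes, edges = graph.nodes, graph.edges
    da, dt = config.drop_rate_attention, config.drop_rate_transition
    for i in range(config.n_layers):
        L = f"L{i}"
        cur = GraphRepresentation(nodes, edges, graph.chain_labels, combined=graph.combined)
        att = self_attention(cur, params, config, prefix=f"{L}.attn")
        nodes = nodes + _dropout(att.nodes, da, training, rng)
        edges = edges + _dropout(att.edges, da, training, rng)
        n_t = transition(_layer_norm(nodes, params, f"{L}.node_ln"), params, f"{L}.node_trans")
        nodes = nodes + _dropout(n_t, dt, training, rng)
        e_t = transition(_layer_norm(edges, params, f"{L}.edge_ln"), params, f"{L}.edge_trans")
        edges = edges + _dropout(e_t, dt, training, rng)
    return GraphRepresentation(nodes, edges, graph.chain_labels, combined=graph.combined)


def pps_head(graph: GraphRepresentation, params, config: ModelConfig,
             label: int | None = None, l2_lambda: float = 0.0,
             training: bool = False, rng=None) -> PredictionOutput:
    """Pool the complex into one vector and predict the co-condensation probability.

    Per residue: layer norm, dropout, two-layer MLP; average pooling over all
    residues of the complex gives the whole-complex representation, which a
    three-layer MLP maps to a logit; the probability is its sigmoid.  With a
    binary label, the loss is the cross-entropy plus ``l2_lambda`` times the
    summed squared weights.
    """
    if label is not None and label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    if training and rng is None:
        rng = np.random.default_rng(0)
    x = _layer_norm(graph.nodes, params, "head.ln")
    x = _dropout(x, config.drop_rate_affinity, training, rng)
    x = relu(_linear(x, params, "head.proj1"))
    x = _linear(x, params, "head.proj2")
    pooled = x.mean(axis=0)                                # n^protein
    h = relu(_linear(pooled.reshape((1, -1)), params, "head.out1"))
    h = relu(_linear(h, params, "head.out2"))
    logit = _linear(h, params, "head.out3").reshape(())
    prob = float(1.0 / (1.0 + np.exp(-np.clip(logit.data, -500, 500))))

    loss_t = None
    loss_val = None
    if label is not None:
        # stable BCE on the logit: softplus(z) - z*y
        loss_t = softplus(logit) - logit * float(label)
        if l2_lambda > 0:
            loss_t = loss_t + l2_lambda * l2_penalty(params)
        loss_val = float(loss_t.data)
    return PredictionOutput(probability=prob, pooled_repr=pooled.data.copy(),
                            loss=loss_val, loss_tensor=loss_t)


def forward_pair(bundle_a: FeatureBundle, bundle_b: FeatureBundle, params,
                 config: ModelConfig, label: int | None = None,
                 l2_lambda: float = 0.0, training: bool = False, rng=None
                 ) -> PredictionOutput:
    """Encode -> combine -> stack -> head for one ordered pair of proteins."""
    rep_a, rep_b = encode_proteins([bundle_a, bundle_b], params, config)
    complex_rep = combine_complex(rep_a, rep_b)
    out = transformer_stack(complex_rep, params, config, training=training, rng=rng)
    return pps_head(out, params, config, label=label, l2_lambda=l2_lambda,
                    training=training, rng=rng)


def predict_pair(bundle_a: FeatureBundle, bundle_b: FeatureBundle, params,
                 config: ModelConfig) -> float:
    """Eval-mode co-condensation probability for a pair of proteins.

    With ``config.symmetrize`` (default) the score is the mean over both
    chain orders, making it exactly order-free.
    """
    tp = as_tensors(params)
    p_ab = forward_pair(bundle_a, bundle_b, tp, config).probability
    if not config.symmetrize:
        return p_ab
    p_ba = forward_pair(bundle_b, bundle_a, tp, config).probability
    return 0.5 * (p_ab + p_ba)


# ---------------------------------------------------------------------------
# Checkpoints: npz archive of named arrays with a JSON config header
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, np.ndarray], config: ModelConfig) -> None:
    header = json.dumps(asdict(config))
    arrays = {k: np.asarray(v) for k, v in params.items()}
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    header = bytes(data["__config__"]).decode()
    cfg_dict = json.loads(header)
    config = ModelConfig(**cfg_dict)
    params = {k: data[k] for k in data.files if k != "__config__"}
    return params, config
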