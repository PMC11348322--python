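"""Independent straight-line reimplementations of every network block.

These are deliberately written as explicit nested loops over residues and
heads, using nothing from ``codroplet.network`` or the autodiff engine, so
they can serve as an oracle for the vectorised implementation.
"""

from __future__ import annotations

import numpy as np


def layer_norm(x, gain, bias, eps=1e-5):
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gain + bias


def transition(x, params, prefix):
    h = layer_norm(x, params[f"{prefix}.ln.gain"], params[f"{prefix}.ln.bias"])
    h = h @ params[f"{prefix}.fc1.w"] + params[f"{prefix}.fc1.b"]
    h = np.maximum(h, 0.0)
    return h @ params[f"{prefix}.fc2.w"] + params[f"{prefix}.fc2.b"]


def self_attention(nodes, edges, params, prefix, n_head):
    """Per-head, per-residue-pair loop version of pair-bias attention."""
    N, c_n = nodes.shape
    c_e = edges.shape[-1]
    cp = c_n // n_head
    nl = layer_norm(nodes, params[f"{prefix}.ln_n.gain"], params[f"{prefix}.ln_n.bias"])
    el = layer_norm(edges, params[f"{prefix}.ln_e.gain"], params[f"{prefix}.ln_e.bias"])

    # per-head projections, computed residue by residue
    q = np.zeros((n_head, N, cp))
    k = np.zeros((n_head, N, cp))
    v = np.zeros((n_head, N, cp))
    g = np.zeros((n_head, N, cp))
    for i in range(N):
        qf = nl[i] @ params[f"{prefix}.q.w"]
        kf = nl[i] @ params[f"{prefix}.k.w"]
        vf = nl[i] @ params[f"{prefix}.v.w"]
        gf = 1.0 / (1.0 + np.exp(-(nl[i] @ params[f"{prefix}.gate.w"] + params[f"{prefix}.gate.b"])))
        for h in range(n_head):
            q[h, i] = qf[h * cp:(h + 1) * cp]
            k[h, i] = kf[h * cp:(h + 1) * cp]
            v[h, i] = vf[h * cp:(h + 1) * cp]
            g[h, i] = gf[h * cp:(h + 1) * cp]

    logits = np.zeros((n_head, N, N))
    bias = np.zeros((n_head, N, N))
    for h in range(n_head):
        for i in range(N):
            for j in range(N):
                logits[h, i, j] = q[h, i] @ k[h, j] / np.sqrt(cp)
                bias[h, i, j] = el[i, j] @ params[f"{prefix}.pair_bias.w"][:, h]

    # edge output from the pre-bias, pre-softmax logits
    e_out = np.zeros((N, N, c_e))
    for i in range(N):
        for j in range(N):
            cat = np.array([logits[h, i, j] for h in range(n_head)])
            hid = np.maximum(cat @ params[f"{prefix}.edge_fc1.w"] + params[f"{prefix}.edge_fc1.b"], 0.0)
            e_out[i, j] = hid @ params[f"{prefix}.edge_fc2.w"] + params[f"{prefix}.edge_fc2.b"]

    n_out = np.zeros((N, c_n))
    for i in range(N):
        o = np.zeros(c_n)
        for h in range(n_head):
            row = logits[h, i] + bias[h, i]
            row = np.exp(row - row.max())
            row /= row.sum()
            agg = np.zeros(cp)
            for j in range(N):
                agg += row[j] * v[h, j]
            o[h * cp:(h + 1) * cp] = g[h, i] * agg
        n_out[i] = o @ params[f"{prefix}.out.w"] + params[f"{prefix}.out.b"]
    return n_out, e_out


def encode(bundle, params, config):
    """Residue-by-residue encoder: transitions, layer norms, projections."""
    L = bundle.length
    msa = np.zeros((L, config.c_msa))
    struc = np.zeros((L, config.c_struc))
    for i in range(L):
        msa[i] = layer_norm(transition(bundle.f_msa[i], params, "enc.msa"),
                            params["enc.msa_ln.gain"], params["enc.msa_ln.bias"])
        struc[i] = layer_norm(transition(bundle.f_struc[i], params, "enc.struc"),
                              params["enc.struc_ln.gain"], params["enc.struc_ln.bias"])
    nodes = np.zeros((L, config.c_n))
    for i in range(L):
        res = np.concatenate([msa[i], struc[i]])
        nodes[i] = transition(res, params, "enc.node_out")
    edges = np.zeros((L, L, config.c_e - 1))
    for i in range(L):
        for j in range(L):
            p = layer_norm(transition(bundle.f_pair[i, j], params, "enc.pair"),
                           params["enc.pair_ln.gain"], params["enc.pair_ln.bias"])
            edges[i, j] = transition(p, params, "enc.pair_out")
    return nodes, edges


def stack_layer(nodes, edges, params, config, layer=0):
    """One transformer block: attention + residuals + transitions (eval mode)."""
    L = f"L{layer}"
    dn, de = self_attention(nodes, edges, params, f"{L}.attn", config.n_head)
    nodes = nodes + dn
    edges = edges + de
    n_in = layer_norm(nodes, params[f"{L}.node_ln.gain"], params[f"{L}.node_ln.bias"])
    nodes = nodes + transition(n_in, params, f"{L}.node_trans")
    e_in = layer_norm(edges, params[f"{L}.edge_ln.gain"], params[f"{L}.edge_ln.bias"])
    edges = edges + transition(e_in, params, f"{L}.edge_trans")
    return nodes, edges


def head(nodes, params, label=None):
    """Per-residue loop version of the prediction head (eval mode)."""
    N = nodes.shape[0]
    per_res = []
    for i in range(N):
        x = layer_norm(nodes[i], params["head.ln.gain"], params["head.ln.bias"])
        x = np.maximum(x @ params["head.proj1.w"] + params["head.proj1.b"], 0.0)
        x = x @ params["head.proj2.w"] + params["head.proj2.b"]
        per_res.append(x)
    pooled = np.zeros_like(per_res[0])
    for x in per_res:
        pooled += x
    pooled /= N
    h = np.maximum(pooled @ params["head.out1.w"] + params["head.out1.b"], 0.0)
    h = np.maximum(h @ params["head.out2.w"] + params["head.out2.b"], 0.0)
    z = float((h @ params["head.out3.w"] + params["head.out3.b"]).item())
    prob = 1.0 / (1.0 + np.exp(-z))
    loss = None
    if label is not None:
        loss = -label * np.log(prob) - (1 - label) * np.log(1 - prob)
    return prob, pooled, loss
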