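"""Independent loop-based reference implementations used as test oracles.

Everything here is written with explicit Python loops and no reference to
the package's autograd or encoder code, so it can serve as an oracle for
the vectorised implementation.
"""

import math

import numpy as np


def naive_softmax_row(row, mask_row):
    """Exp-normalise one score row over its unmasked support; all-masked
    rows give an all-zero row."""
    support = [j for j in range(len(row)) if mask_row[j] == 0.0]
    out = [0.0] * len(row)
    if not support:
        return out
    m = max(row[j] for j in support)
    exps = {j: math.exp(row[j] - m) for j in support}
    z = sum(exps.values())
    for j in support:
        out[j] = exps[j] / z
    return out


def naive_masked_softmax(scores, mask):
    return np.array([naive_softmax_row(list(scores[i]), list(mask[i]))
                     for i in range(scores.shape[0])])


def naive_gate(hidden, Wg, bg):
    n = hidden.shape[0]
    g = np.zeros(n)
    for i in range(n):
        z = float(bg.reshape(-1)[0])
        for a in range(hidden.shape[1]):
            z += hidden[i, a] * Wg[a, 0]
        g[i] = 1.0 / (1.0 + math.exp(-z))
    return g


def naive_head(hidden, m_glob, m_local, Wq, bq, Wk, bk, Wv, bv, gate, entity_aware=True):
    """One attention head, scores scaled by 1/sqrt(d_k) before masking."""
    q = hidden @ Wq + bq
    k = hidden @ Wk + bk
    v = hidden @ Wv + bv
    dk = q.shape[1]
    scores = np.zeros((q.shape[0], q.shape[0]))
    for i in range(q.shape[0]):
        for j in range(q.shape[0]):
            scores[i, j] = float(q[i] @ k[j]) / math.sqrt(dk)
    s_glob = naive_masked_softmax(scores, m_glob)
    if not entity_aware:
        return s_glob @ v
    s_local = naive_masked_softmax(scores, m_local)
    out = np.zeros_like(v)
    for i in range(q.shape[0]):
        row = gate[i] * s_local[i] + (1.0 - gate[i]) * s_glob[i]
        out[i] = row @ v
    return out


def _split_heads(W, b, H):
    dk = W.shape[1] // H
    return [(W[:, h * dk:(h + 1) * dk], b[h * dk:(h + 1) * dk]) for h in range(H)]


def naive_mhsa(hidden, m_glob, m_local, layer, H, entity_aware=True):
    """Multi-head attention: per-head slices of the combined projections,
    concatenation, output projection.  `layer` carries numpy weights with
    the same field names as the package's LayerParams."""
    gate = naive_gate(hidden, layer["Wg"], layer["bg"]) if entity_aware else None
    heads = []
    for (Wq, bq), (Wk, bk), (Wv, bv) in zip(_split_heads(layer["Wq"], layer["bq"], H),
                                            _split_heads(layer["Wk"], layer["bk"], H),
                                            _split_heads(layer["Wv"], layer["bv"], H)):
        heads.append(naive_head(hidden, m_glob, m_local, Wq, bq, Wk, bk, Wv, bv,
                                gate, entity_aware))
    concat = np.concatenate(heads, axis=1)
    return concat @ layer["Wo"] + layer["bo"]


def naive_gelu(x):
    return np.array([[0.5 * v * (1.0 + math.erf(v / math.sqrt(2.0))) for v in row]
                     for row in np.atleast_2d(x)])


def naive_ffn(x, layer):
    h = naive_gelu(x @ layer["W1"] + layer["b1"])
    return h @ layer["W2"] + layer["b2"]


def naive_layer_norm(x, gamma, beta, eps=1e-12):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = x[i].var()
        out[i] = gamma * (x[i] - mu) / math.sqrt(var + eps) + beta
    return out


def naive_encoder_layer(hidden, m_glob, m_local, layer, H, entity_aware=True, eps=1e-12):
    a = naive_mhsa(hidden, m_glob, m_local, layer, H, entity_aware)
    x = naive_layer_norm(hidden + a, layer["ln1_gamma"], layer["ln1_beta"], eps)
    f = naive_ffn(x, layer)
    return naive_layer_norm(x + f, layer["ln2_gamma"], layer["ln2_beta"], eps)


def naive_embed(token_ids, entity_ids, segment_ids, tables, use_entity=True, eps=1e-12):
    n = len(token_ids)
    d = tables["token"].shape[1]
    e = np.zeros((n, d))
    for w in range(n):
        e[w] = tables["token"][token_ids[w]] + tables["position"][w] + tables["segment"][segment_ids[w]]
        if use_entity:
            e[w] += tables["entity"][entity_ids[w]]
    return naive_layer_norm(e, tables["ln_gamma"], tables["ln_beta"], eps)


def naive_encoder(token_ids, entity_ids, segment_ids, pad_flags, weights, H,
                  entity_layer_flags, use_entity_embedding=True,
                  enabled_types=(1, 2, 3), eps=1e-12):
    """Full forward pass: embedding, L encoder layers, [CLS] logits.

    `weights` is a dict: {"emb": tables, "layers": [layer dicts], "Wp", "bp"}.
    `entity_layer_flags[i]` says whether layer i uses gated entity attention.
    """
    n = len(token_ids)
    m_glob = np.zeros((n, n))
    m_local = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if pad_flags[i] or pad_flags[j]:
                m_glob[i, j] = -np.inf
            ent_i = (entity_ids[i] in enabled_types) and not pad_flags[i]
            ent_j = (entity_ids[j] in enabled_types) and not pad_flags[j]
            if not (ent_i and ent_j):
                m_local[i, j] = -np.inf
    eff_entity = [e if e in enabled_types else 0 for e in entity_ids]
    x = naive_embed(token_ids, eff_entity, segment_ids, weights["emb"],
                    use_entity_embedding, eps)
    for layer, flag in zip(weights["layers"], entity_layer_flags):
        x = naive_encoder_layer(x, m_glob, m_local, layer, H, flag, eps)
    logits = x[0] @ weights["Wp"] + weights["bp"]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    return x, p


def layer_to_dict(layer_params):
    """Extract numpy weights from a package LayerParams object."""
    return {name: getattr(layer_params, name).data
            for name in ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wg", "bg", "Wo", "bo",
                         "W1", "b1", "W2", "b2",
                         "ln1_gamma", "ln1_beta", "ln2_gamma", "ln2_beta")}


def params_to_dict(params):
    emb = params.embeddings
    return {
        "emb": {"token": emb.token.data, "position": emb.position.data,
                "segment": emb.segment.data, "entity": emb.entity.data,
                "ln_gamma": emb.ln_gamma.data, "ln_beta": emb.ln_beta.data},
        "layers": [layer_to_dict(l) for l in params.layers],
        "Wp": params.classifier.Wp.data, "bp": params.classifier.bp.data,
    }
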