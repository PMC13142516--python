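"""Independent dense-loop oracles used by the test suite.

These re-derive the model's arithmetic with explicit Python loops and no
shared code with the package internals, so agreement is a genuine
cross-check rather than a tautology.
"""

import math

import numpy as np


def loop_forward(EA, EB, params, config):
    """Per-element re-implementation of the full forward pass."""
    d = config.embed_dim
    H = config.num_heads
    dh = d // H
    scale = math.sqrt(dh) if config.attention_scale_mode == "per_head_sqrt" else math.sqrt(d)
    LA, LB = len(EA), len(EB)

    def affine(X, W, b):
        out = [[b[j] + sum(X[i][k] * W[k][j] for k in range(len(X[i]))) for j in range(len(b))]
               for i in range(len(X))]
        return out

    Q = affine(EA.tolist(), params.W_Q.tolist(), params.b_Q.tolist())
    K = affine(EB.tolist(), params.W_K.tolist(), params.b_K.tolist())
    V = affine(EB.tolist(), params.W_V.tolist(), params.b_V.tolist())

    context = [[0.0] * d for _ in range(LA)]
    for h in range(H):
        cols = range(h * dh, (h + 1) * dh)
        for i in range(LA):
            logits = []
            for j in range(LB):
                s = sum(Q[i][c] * K[j][c] for c in cols) / scale
                logits.append(s)
            mx = max(logits)
            ex = [math.exp(s - mx) for s in logits]
            z = sum(ex)
            weights = [e / z for e in ex]
            for c in cols:
                context[i][c] = sum(weights[j] * V[j][c] for j in range(LB))

    attended = affine(context, params.W_O.tolist(), params.b_O.tolist())
    if config.use_residual:
        attended = [[attended[i][j] + EA[i][j] for j in range(d)] for i in range(LA)]

    probs = []
    for i in range(LA):
        row = attended[i]
        mu = sum(row) / d
        var = sum((x - mu) ** 2 for x in row) / d
        ln = [(x - mu) / math.sqrt(var + 1e-5) * params.ln_gain.tolist()[j]
              + params.ln_bias.tolist()[j] for j, x in enumerate(row)]
        hidden = []
        for j in range(config.mlp_hidden):
            a = params.mlp_b1.tolist()[j] + sum(
                ln[k] * params.mlp_W1.tolist()[k][j] for k in range(d)
            )
            hidden.append(max(a, 0.0))
        logit = params.mlp_b2.tolist()[0] + sum(
            hidden[j] * params.mlp_W2.tolist()[j][0] for j in range(config.mlp_hidden)
        )
        probs.append(1.0 / (1.0 + math.exp(-logit)))
    return np.array(probs)


def pair_ordering_auroc(scores, labels):
    """AUROC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half — exhaustive enumeration."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = correct = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                correct += 1
            elif p == n:
                correct += 0.5
    return correct / total
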