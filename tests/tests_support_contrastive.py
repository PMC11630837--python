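"""Shared brute-force oracle for the view-contrastive loss."""

import math

import numpy as np


def brute_force_contrastive(z1, z2, tau):
    """Literal double summation: positives on the diagonal, negatives in
    both views, cosine similarity, symmetrized and averaged over nodes."""

    def cos(a, b):
        return float(
            a @ b / ((np.linalg.norm(a) + 1e-12) * (np.linalg.norm(b) + 1e-12))
        )

    n = z1.shape[0]
    total = 0.0
    for first, second in ((z1, z2), (z2, z1)):
        for i in range(n):
            pos = math.exp(cos(first[i], second[i]) / tau)
            denom = 0.0
            for j in range(n):
                denom += math.exp(cos(first[i], second[j]) / tau)
                if j != i:
                    denom += math.exp(cos(first[i], first[j]) / tau)
            total += -math.log(pos / denom) / n
    return total / 2.0
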