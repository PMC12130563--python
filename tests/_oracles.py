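"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library code paths they check: the BH oracle is
the literal step-up definition, the rank-sum oracle enumerates every group
assignment, and the AUC oracle counts pairwise wins and ties.
"""

import itertools

import numpy as np
import pandas as pd


def bh_oracle(p):
    """Brute-force step-up: min over k >= i of p_(k) * m / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[k]] * m / (k + 1) for k in range(pos, m)]
        out[idx] = min(1.0, min(candidates))
    return out


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n].sum()
    sums = np.asarray(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(m), n)]
    )
    center = n * (m + 1) / 2.0
    return float(np.mean(np.abs(sums - center) >= np.abs(obs - center) - 1e-9))


def auc_oracle(scores, labels):
    """P(random positive outscores random negative) + half the tie mass."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
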