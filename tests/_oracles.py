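"""Independent brute-force oracles, deliberately written without reusing any
package internals for the quantities they check."""

import numpy as np
from scipy.stats import norm


def rank_ratio_oracle(values):
    """Literal count of strictly-smaller and tied other genes."""
    v = list(values)
    G = len(v)
    out = []
    for g in range(G):
        less = sum(1 for h in range(G) if h != g and v[h] < v[g])
        ties = sum(1 for h in range(G) if h != g and v[h] == v[g])
        out.append((less + 0.5 * ties) / (G - 1))
    return np.asarray(out)


def consensus_oracle(counts_dense, layer, labels):
    """Double-loop consensus table: {(cell_type, gene_index): (fr, er, score)}."""
    counts_dense = np.asarray(counts_dense)
    layer = np.asarray(layer)
    labels = list(labels)
    result = {}
    for cell_type in dict.fromkeys(labels):
        cells = [i for i, l in enumerate(labels) if l == cell_type]
        G = counts_dense.shape[1]
        freq = [
            sum(1 for c in cells if counts_dense[c, g] > 0) / len(cells)
            for g in range(G)
        ]
        meanx = [layer[cells, g].mean() for g in range(G)]
        fr = rank_ratio_oracle(freq)
        er = rank_ratio_oracle(meanx)
        for g in range(G):
            result[(cell_type, g)] = (fr[g], er[g], fr[g] + er[g])
    return result


def sample_size_grid_oracle(power, alpha, d, n_max=10000):
    """Smallest per-group n whose normal-approximation power reaches the
    target: power(n) = Phi(sqrt(n/2) * d - z_{1-alpha/2})."""
    z_crit = norm.ppf(1 - alpha / 2)
    for n in range(2, n_max):
        if norm.cdf(np.sqrt(n / 2.0) * abs(d) - z_crit) >= power:
            return n
    raise AssertionError("no n found")
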