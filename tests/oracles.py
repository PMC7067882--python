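"""Independent oracles: deliberately avoid the implementation's code paths.

Transition probabilities come from scipy's generic matrix exponential, the
likelihood from an explicit sum over all internal-state assignments, and
RELL weights from exhaustive enumeration of resamples.  These stay O(4^n)
and are only usable on tiny instances, which is the point.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from mtclock.alignment import IUPAC_MASKS


def tn93_rate_matrix(freqs, rate_AG, rate_CT, rate_tv):
    """TN93 generator written out entry by entry, normalised to mean rate 1."""
    pi = np.asarray(freqs, dtype=float)
    A, C, G, T = range(4)
    Q = np.zeros((4, 4))
    pairs = {
        (A, G): rate_AG, (G, A): rate_AG,
        (C, T): rate_CT, (T, C): rate_CT,
    }
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pairs.get((i, j), rate_tv) * pi[j]
        Q[i, i] = -Q[i].sum()
    mu = -sum(pi[i] * Q[i, i] for i in range(4))
    return Q / mu


def gamma_band_rates_by_quadrature(shape, n):
    """Category rates as band-conditional means via numerical integration."""
    from scipy.integrate import quad
    from scipy.stats import gamma

    dist = gamma(shape, scale=1.0 / shape)
    edges = [0.0] + [dist.ppf(i / n) for i in range(1, n)] + [np.inf]
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda x: x * dist.pdf(x), lo, hi if np.isfinite(hi) else dist.ppf(1 - 1e-12))
        rates.append(val * n)
    return np.array(rates)


def brute_site_logliks(alignment, itree, edge_len, params, category_rates):
    """Pruning-free likelihood: explicit sum over internal-node states."""
    pi = np.asarray(params.base_freqs)
    Q = tn93_rate_matrix(params.base_freqs, params.rate_AG, params.rate_CT,
                         params.rate_transversion)
    internal = [v for v in range(itree.n_nodes) if itree.children[v]]
    out = np.zeros(alignment.length)
    seqs = {lab: alignment.sequence(lab) for lab in itree.leaf_of_label}
    for s in range(alignment.length):
        total = 0.0
        for r in category_rates:
            P = {v: expm(Q * r * edge_len[v])
                 for v in range(itree.n_nodes) if itree.parent[v] >= 0}
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                prob = pi[st[itree.root]] / len(category_rates)
                for v in range(itree.n_nodes):
                    if itree.parent[v] < 0:
                        continue
                    up = st[itree.parent[v]]
                    if itree.children[v]:
                        prob *= P[v][up, st[v]]
                    else:
                        mask = IUPAC_MASKS[seqs[itree.labels[v]][s]]
                        prob *= sum(P[v][up, j] for j in range(4) if mask >> j & 1)
                total += prob
        out[s] = np.log(total)
    return out


def exhaustive_rell_weights(matrix):
    """Exact RELL weights by enumerating every resample of the sites."""
    T, S = matrix.shape
    wins = np.zeros(T)
    n_resamples = 0
    for draw in itertools.product(range(S), repeat=S):
        totals = matrix[:, list(draw)].sum(axis=1)
        best = totals.max()
        tied = np.isclose(totals, best, atol=1e-12)
        wins += tied / tied.sum()
        n_resamples += 1
    return wins / n_resamples
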