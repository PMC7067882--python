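"""bp-RELL: bootstrap topology weights from per-site log-likelihoods.

Instead of re-fitting every candidate tree on every bootstrap replicate,
the RELL scheme resamples the per-site log-likelihoods of the already
fitted trees; each replicate's winner is the topology with the highest
resampled total, and a topology's weight is the fraction of replicates it
wins.  These bootstrap proportions are often used as posterior-like weights
over topologies, although they are not Bayesian posteriors.

Resampling uses numpy's counter-based Philox bit generator, so a fixed
seed gives bit-identical weights on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_BOOTSTRAP = 10_000


@dataclass
class SiteLogLikMatrix:
    """Per-site log-likelihoods for each candidate topology (T x S)."""

    topology_ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (topologies x sites)")
        if self.matrix.shape[0] != len(self.topology_ids):
            raise ValueError("one row per topology id required")
        if self.matrix.shape[1] < 1:
            raise ValueError("need at least one site")
        if np.isnan(self.matrix).any():
            raise ValueError("NaN per-site log-likelihoods")

    @property
    def n_topologies(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(str(t) for t in self.topology_ids) + "\n")
            for s in range(self.n_sites):
                fh.write(
                    f"{s}\t" + "\t".join(f"{v:.10f}" for v in self.matrix[:, s]) + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "SiteLogLikMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(ids, np.array(rows, dtype=float).T)


@dataclass
class TopologyWeights:
    """RELL bootstrap proportions per topology."""

    topology_ids: list
    weights: np.ndarray
    n_bootstrap: int
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def weight_of(self, topology_id) -> float:
        return float(self.weights[self.topology_ids.index(topology_id)])

    def to_tsv(self, path) -> None:
        order = _rank_order(self)
        with open(path, "w") as fh:
            fh.write("topology_id\tweight\trank\n")
            for rank, i in enumerate(order, start=1):
                fh.write(f"{self.topology_ids[i]}\t{self.weights[i]:.6f}\t{rank}\n")


def _rank_order(weights: TopologyWeights) -> list:
    """Indices by descending weight, ties broken by topology id."""
    return sorted(
        range(len(weights.topology_ids)),
        key=lambda i: (-weights.weights[i], str(weights.topology_ids[i])),
    )


def bp_rell(matrix: SiteLogLikMatrix, n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
            seed: int = 0, chunk: int = 2000) -> TopologyWeights:
    """Bootstrap-proportion RELL weights over candidate topologies.

    Each replicate draws site counts Multinomial(S, uniform); the replicate
    winner is argmax over topologies of the count-weighted site
    log-likelihood total, with exact ties splitting the win equally.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    T, S = matrix.n_topologies, matrix.n_sites
    if T == 1:
        return TopologyWeights(matrix.topology_ids, np.ones(1), n_bootstrap, seed)
    rng = np.random.Generator(np.random.Philox(int(seed) % 2**31))
    # centre per site to keep resampled totals well-scaled (shared per-site
    # constants do not change the argmax)
    M = matrix.matrix - matrix.matrix.mean(axis=0, keepdims=True)
    # collapse duplicate columns: sites with identical log-likelihood
    # profiles are exchangeable under multinomial resampling
    Mu, col_counts = np.unique(M, axis=1, return_counts=True)
    wins = np.zeros(T)
    p = col_counts / S
    done = 0
    while done < n_bootstrap:
        b = min(chunk, n_bootstrap - done)
        counts = rng.multinomial(S, p, size=b).astype(float)  # (b, n_unique)
        totals = counts @ Mu.T  # (b, T)
        best = totals.max(axis=1, keepdims=True)
        tied = np.isclose(totals, best, rtol=0.0, atol=1e-9)
        wins += (tied / tied.sum(axis=1, keepdims=True)).sum(axis=0)
        done += b
    return TopologyWeights(
        list(matrix.topology_ids), wins / n_bootstrap, n_bootstrap, seed
    )


def top_k_mass(weights: TopologyWeights, k: int) -> tuple[list, float]:
    """The k best-supported topology ids and their cumulative weight."""
    if not 1 <= k <= len(weights.topology_ids):
        raise ValueError("k out of range")
    order = _rank_order(weights)[:k]
    ids = [weights.topology_ids[i] for i in order]
    return ids, float(weights.weights[order].sum())


def clade_support(weights: TopologyWeights, topologies: dict, clade) -> float:
    """Total weight of topologies in which `clade` forms a bipartition.

    `topologies` maps topology id -> :class:`mtclock.treespace.Topology`.
    """
    support = 0.0
    for tid, w in zip(weights.topology_ids, weights.weights):
        if topologies[tid].has_clade(clade):
            support += float(w)
    return support
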