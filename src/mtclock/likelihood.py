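"""Felsenstein pruning likelihood, ML fitting, clock test, and ancestral states.

The engine evaluates alignment likelihoods under TN93+Gamma by the pruning
algorithm on site patterns, and fits two nested models by coordinate ascent:

* no clock — an unrooted topology with one free length per edge (2n-3
  parameters);
* strict clock — a rooted ultrametric tree with one free height per
  internal node (n-1 parameters), all tips contemporaneous.

Twice the log-likelihood gap between the two is the molecular-clock test
statistic, asymptotically chi-square with n-2 degrees of freedom.

The root-height standard error comes from the curvature of the profile
log-likelihood at the optimum, and marginal ancestral-state posteriors from
the standard outside/inside message product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import Alignment, leaf_partials
from .substitution import TN93GParams, TransitionMatrixCache
from .treespace import Topology

_SCALE_THRESHOLD = 1e-80
_MAX_BLEN = 10.0
_MIN_BLEN = 1e-9


class IndexedTree:
    """Array-indexed rooted view of a tree for likelihood work.

    Built either from an unrooted :class:`Topology` (virtual trifurcating
    root at an internal node) or from a rooted nested-pair structure
    (bifurcating root).  Node 0.. are assigned in postorder-compatible
    fashion; `lengths`/`heights` arrays elsewhere are indexed by node id,
    where a node's entry refers to the edge above it.
    """

    def __init__(self, children: list, labels: dict, root: int):
        self.children = children
        self.labels = labels  # leaf node id -> taxon label
        self.root = root
        self.n_nodes = len(children)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        for v, kids in enumerate(children):
            for c in kids:
                self.parent[c] = v
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        self.postorder = order[::-1]  # children before parents
        self.leaf_of_label = {lab: nid for nid, lab in labels.items()}
        self._leafsets = None

    @classmethod
    def _build(cls, nested_children):
        children: list = []
        labels: dict = {}

        def add(node):
            nid = len(children)
            children.append([])
            if isinstance(node, str):
                labels[nid] = node
            else:
                children[nid] = None  # placeholder; fill after recursion
                kids = [add(child) for child in node]
                children[nid] = kids
            return nid

        root = add(nested_children)
        return cls(children, labels, root)

    @classmethod
    def from_topology(cls, topology: Topology) -> "IndexedTree":
        rest = topology.rest
        if isinstance(rest, str):
            raise ValueError("need at least 3 taxa")
        return cls._build((rest[0], rest[1], topology.ref))

    @classmethod
    def from_rooted(cls, nested) -> "IndexedTree":
        return cls._build(nested)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leafsets(self) -> list[frozenset]:
        if self._leafsets is None:
            sets: list = [None] * self.n_nodes
            for v in self.postorder:
                if not self.children[v]:
                    sets[v] = frozenset([self.labels[v]])
                else:
                    out = frozenset()
                    for c in self.children[v]:
                        out |= sets[c]
                    sets[v] = out
            self._leafsets = sets
        return self._leafsets

    def mrca(self, labels) -> int:
        target = frozenset(labels)
        best, best_size = None, None
        for v, ls in enumerate(self.leafsets()):
            if target <= ls and (best is None or len(ls) < best_size):
                best, best_size = v, len(ls)
        if best is None:
            raise ValueError(f"labels {sorted(target)} not all in tree")
        return best

    def newick(self, edge_length) -> str:
        def w(v):
            if not self.children[v]:
                name = self.labels[v]
            else:
                name = "(" + ",".join(w(c) for c in self.children[v]) + ")"
            if v == self.root:
                return name
            return f"{name}:{edge_length(v):.10g}"

        return w(self.root) + ";"


@dataclass
class BranchTree:
    """Unrooted topology with free branch lengths (substitutions/site)."""

    topology: Topology
    tree: IndexedTree
    lengths: np.ndarray  # per node id, edge above; root entry unused

    def newick(self) -> str:
        return self.tree.newick(lambda v: self.lengths[v])

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths[v] for v in range(self.tree.n_nodes)
                         if v != self.tree.root))


@dataclass
class ClockTree:
    """Rooted ultrametric tree: node heights in substitutions/site, tips at 0."""

    tree: IndexedTree
    heights: np.ndarray  # per node id; leaves 0
    root_height_se: float | None = None

    def __post_init__(self) -> None:
        for v in self.tree.postorder:
            p = self.tree.parent[v]
            if p >= 0 and self.heights[p] < self.heights[v] - 1e-12:
                raise ValueError("clock tree is not ultrametric (parent below child)")

    @property
    def root_height(self) -> float:
        return float(self.heights[self.tree.root])

    def edge_lengths(self) -> np.ndarray:
        lens = np.zeros(self.tree.n_nodes)
        for v in range(self.tree.n_nodes):
            p = self.tree.parent[v]
            if p >= 0:
                lens[v] = self.heights[p] - self.heights[v]
        return np.clip(lens, 0.0, None)

    def node_height(self, labels) -> float:
        """Height (subs/site) of the most recent common ancestor of `labels`."""
        return float(self.heights[self.tree.mrca(labels)])

    def newick(self) -> str:
        lens = self.edge_lengths()
        return self.tree.newick(lambda v: lens[v])


@dataclass
class FitResult:
    """Outcome of an ML fit: tree, model, total and per-site log-likelihoods."""

    tree: BranchTree | ClockTree
    model: TN93GParams
    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    n_iterations: int = 0
    converged: bool = True
    topology_id: str | None = None




def _build_prune_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return None

    @njit(cache=False)
    def kernel(postorder, child_flat, child_off, leaf_row, leaf_part,
               P_all, pi, cat_probs, scale_threshold):
        n_nodes = leaf_row.shape[0]
        ncat = P_all.shape[1]
        n_pat = leaf_part.shape[1]
        partial = np.empty((n_nodes, ncat, n_pat, 4))
        scale_log = np.zeros(n_pat)
        for idx in range(postorder.shape[0]):
            v = postorder[idx]
            if leaf_row[v] >= 0:
                lp = leaf_part[leaf_row[v]]
                for c in range(ncat):
                    for p in range(n_pat):
                        for s in range(4):
                            partial[v, c, p, s] = lp[p, s]
                continue
            for c in range(ncat):
                for p in range(n_pat):
                    for s in range(4):
                        partial[v, c, p, s] = 1.0
            for k in range(child_off[v], child_off[v + 1]):
                ch = child_flat[k]
                for c in range(ncat):
                    Pm = P_all[ch, c]
                    for p in range(n_pat):
                        x0 = partial[ch, c, p, 0]
                        x1 = partial[ch, c, p, 1]
                        x2 = partial[ch, c, p, 2]
                        x3 = partial[ch, c, p, 3]
                        for i in range(4):
                            partial[v, c, p, i] *= (
                                Pm[i, 0] * x0 + Pm[i, 1] * x1
                                + Pm[i, 2] * x2 + Pm[i, 3] * x3
                            )
            for p in range(n_pat):
                m = 0.0
                for c in range(ncat):
                    for s in range(4):
                        if partial[v, c, p, s] > m:
                            m = partial[v, c, p, s]
                if 0.0 < m < scale_threshold:
                    inv = 1.0 / m
                    for c in range(ncat):
                        for s in range(4):
                            partial[v, c, p, s] *= inv
                    scale_log[p] += np.log(m)
        root = postorder[postorder.shape[0] - 1]
        out = np.empty(n_pat)
        for p in range(n_pat):
            tot = 0.0
            for c in range(ncat):
                acc = 0.0
                for s in range(4):
                    acc += pi[s] * partial[root, c, p, s]
                tot += cat_probs[c] * acc
            out[p] = np.log(tot) + scale_log[p]
        return out

    return kernel


_prune_kernel = _build_prune_kernel()


# ---------------------------------------------------------------------
# pruning core
# ---------------------------------------------------------------------

class _PruningWorkspace:
    """Pattern-compressed alignment bound to one indexed tree."""

    def __init__(self, alignment: Alignment, tree: IndexedTree):
        missing = set(tree.leaf_of_label) - set(alignment.taxon_names)
        if missing:
            raise ValueError(f"tree taxa absent from alignment: {sorted(missing)}")
        sub = alignment.subset(sorted(tree.leaf_of_label))
        self.row_of_label = {lab: i for i, lab in enumerate(sub.taxon_names)}
        self.patterns, self.counts, self.inverse = sub.site_patterns()
        self.leaf_part = leaf_partials(self.patterns)  # (taxa, P, 4)
        self.n_patterns = self.patterns.shape[0]
        self.n_sites = sub.length
        self.alignment = sub
        self._arrays = None

    def _tree_arrays(self, tree: IndexedTree):
        if self._arrays is None:
            post = np.asarray(tree.postorder, dtype=np.int64)
            child_flat, child_off = [], [0]
            for v in range(tree.n_nodes):
                child_flat.extend(tree.children[v])
                child_off.append(len(child_flat))
            leaf_row = np.full(tree.n_nodes, -1, dtype=np.int64)
            for nid, lab in tree.labels.items():
                leaf_row[nid] = self.row_of_label[lab]
            self._arrays = (
                post,
                np.asarray(child_flat, dtype=np.int64),
                np.asarray(child_off, dtype=np.int64),
                leaf_row,
            )
        return self._arrays

    def pattern_logliks(self, tree: IndexedTree, edge_len: np.ndarray,
                        cache: TransitionMatrixCache,
                        return_partials: bool = False):
        ncat = len(cache.category_rates)
        P = self.n_patterns
        P_all = cache.matrices_batch(np.clip(edge_len, 0.0, None))
        if _prune_kernel is not None and not return_partials:
            post, child_flat, child_off, leaf_row = self._tree_arrays(tree)
            return _prune_kernel(
                post, child_flat, child_off, leaf_row, self.leaf_part,
                P_all, np.asarray(cache.params.freqs),
                np.asarray(cache.category_probs), _SCALE_THRESHOLD,
            )
        partial = [None] * tree.n_nodes
        scale_log = np.zeros(P)
        P_all_T = P_all.transpose(0, 1, 3, 2)
        for v in tree.postorder:
            kids = tree.children[v]
            if not kids:
                row = self.row_of_label[tree.labels[v]]
                partial[v] = np.broadcast_to(
                    self.leaf_part[row], (ncat, P, 4)
                )
                continue
            acc = None
            for c in kids:
                contrib = np.matmul(partial[c], P_all_T[c])
                acc = contrib if acc is None else acc * contrib
            m = acc.max(axis=(0, 2))
            small = m < _SCALE_THRESHOLD
            if small.any():
                safe = np.where(m > 0, m, 1.0)
                acc = acc / safe[np.newaxis, :, np.newaxis]
                scale_log = scale_log + np.log(np.where(m > 0, safe, 1.0))
                # rescale everywhere for simplicity when any pattern is small
            partial[v] = acc
        root_part = partial[tree.root]
        pi = np.asarray(cache.params.freqs)
        site_lik = np.einsum(
            "cps,s,c->p", root_part, pi, cache.category_probs, optimize=True
        )
        with np.errstate(divide="ignore"):
            logliks = np.log(site_lik) + scale_log
        if return_partials:
            return logliks, partial
        return logliks

    def total_loglik(self, tree, edge_len, cache) -> float:
        return float(np.dot(self.pattern_logliks(tree, edge_len, cache), self.counts))

    def expand(self, pattern_logliks: np.ndarray) -> np.ndarray:
        return pattern_logliks[self.inverse]


def site_log_likelihoods(alignment: Alignment, tree: BranchTree | ClockTree,
                         model: TN93GParams) -> np.ndarray:
    """Per-site log-likelihoods, length = alignment sites.

    Each value is log sum over Gamma categories of the category's prior
    probability times the pruning likelihood; missing and ambiguous
    characters contribute partial likelihood 1 over their compatible states.
    """
    itree = tree.tree
    edge_len = tree.lengths if isinstance(tree, BranchTree) else tree.edge_lengths()
    if np.any(edge_len < -1e-12):
        raise ValueError("negative branch length")
    ws = _PruningWorkspace(alignment, itree)
    cache = TransitionMatrixCache(model)
    return ws.expand(ws.pattern_logliks(itree, np.clip(edge_len, 0, None), cache))


# ---------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------

def _empirical_model(alignment: Alignment, init: TN93GParams | None) -> TN93GParams:
    base = init if init is not None else TN93GParams(
        rate_AG=4.0, rate_CT=4.0, gamma_shape=0.5, n_categories=5
    )
    freqs = alignment.empirical_base_freqs(pseudocount=1.0)
    return base.with_(base_freqs=tuple(freqs))


def _heights_to_edges(tree: IndexedTree, heights: np.ndarray) -> np.ndarray:
    edges = np.zeros(tree.n_nodes)
    p = tree.parent
    mask = p >= 0
    edges[mask] = heights[p[mask]] - heights[mask]
    return np.clip(edges, 0.0, None)


def _pairwise_jc_distance(aln: Alignment) -> dict:
    """Pairwise Jukes–Cantor distances over unambiguously called positions."""
    masks = aln.state_masks()
    unamb = np.isin(masks, (1, 2, 4, 8))
    out = {}
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            both = unamb[i] & unamb[j]
            called = int(both.sum())
            if called == 0:
                d = 0.2
            else:
                p = float((masks[i][both] != masks[j][both]).mean())
                p = min(p, 0.70)
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            out[frozenset((aln.taxon_names[i], aln.taxon_names[j]))] = max(d, 1e-8)
    return out


def _upgma_init_heights(tree: IndexedTree, aln: Alignment) -> np.ndarray:
    """Initial clock heights: half the mean cross-clade pairwise distance."""
    dists = _pairwise_jc_distance(aln)
    leafsets = tree.leafsets()
    heights = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        cross = [
            dists[frozenset((a, b))]
            for ia, ka in enumerate(kids)
            for kb in kids[ia + 1:]
            for a in leafsets[ka]
            for b in leafsets[kb]
        ]
        h = 0.5 * float(np.mean(cross))
        heights[v] = max(h, max(heights[c] for c in kids) * 1.02 + 1e-7)
    return heights


_MODEL_BOUNDS = [
    (np.log(1e-3), np.log(1e3)),   # rate_AG
    (np.log(1e-3), np.log(1e3)),   # rate_CT
    (np.log(0.02), np.log(50.0)),  # gamma_shape
]


def _model_from_logs(model: TN93GParams, x) -> TN93GParams:
    return model.with_(
        rate_AG=float(np.exp(x[0])),
        rate_CT=float(np.exp(x[1])),
        gamma_shape=float(np.exp(x[2])),
    )


def fit_no_clock(alignment: Alignment, topology: Topology,
                 model_init: TN93GParams | None = None,
                 optimize_model: bool = True,
                 tol: float = 1e-6, max_rounds: int = 3) -> FitResult:
    """ML branch lengths (and optionally model parameters) on one topology.

    Base frequencies are empirical (counted from the alignment); branch
    lengths, exchange rates and the Gamma shape are optimised jointly by
    L-BFGS-B on log scale.  With `optimize_model=False` the `model_init`
    parameters are held fixed and only branch lengths move.
    """
    itree = IndexedTree.from_topology(topology)
    ws = _PruningWorkspace(alignment, itree)
    if optimize_model or model_init is None:
        model = _empirical_model(alignment, model_init)
    else:
        model = model_init
    edges = [v for v in itree.postorder if v != itree.root]
    n_e = len(edges)

    # distance-based starting lengths: terminal edges from half the min
    # pairwise distance, internal edges small
    dists = _pairwise_jc_distance(alignment.subset(sorted(itree.leaf_of_label)))
    x0_b = np.log(np.full(n_e, 5e-3))
    for k, v in enumerate(edges):
        if not itree.children[v]:
            lab = itree.labels[v]
            dmin = min(d for pair, d in dists.items() if lab in pair)
            x0_b[k] = np.log(max(dmin / 2, 1e-5))

    free_model = optimize_model
    x0 = np.concatenate([
        x0_b,
        np.log([model.rate_AG, model.rate_CT, model.gamma_shape]) if free_model else [],
    ])
    bounds = [(np.log(_MIN_BLEN), np.log(_MAX_BLEN))] * n_e
    if free_model:
        bounds += _MODEL_BOUNDS

    edge_len = np.zeros(itree.n_nodes)
    state = {"model": model, "cache": TransitionMatrixCache(model)}

    def objective(x):
        edge_len[edges] = np.exp(x[:n_e])
        if free_model:
            m = _model_from_logs(model, x[n_e:])
            state["model"], state["cache"] = m, TransitionMatrixCache(m)
        ll = ws.total_loglik(itree, edge_len, state["cache"])
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200 * max_rounds, "ftol": tol * 1e-5,
                            "gtol": 1e-6})
    objective(res.x)  # restore best point into edge_len/state
    pat_ll = ws.pattern_logliks(itree, edge_len, state["cache"])
    total = float(np.dot(pat_ll, ws.counts))
    return FitResult(
        tree=BranchTree(topology, itree, edge_len.copy()),
        model=state["model"],
        log_likelihood=total,
        per_site_log_likelihoods=ws.expand(pat_ll),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        topology_id=topology.canonical_form,
    )


class _ClockParam:
    """Strict-clock height parameterisation: root height on log scale plus a
    (0,1) depth fraction h_node / h_parent per non-root internal node."""

    def __init__(self, tree: IndexedTree):
        self.tree = tree
        self.preorder = [v for v in reversed(tree.postorder) if tree.children[v]]
        self.inner = self.preorder[1:]  # non-root internal, parents first

    def pack(self, heights) -> np.ndarray:
        x = [np.log(max(heights[self.tree.root], 1e-8))]
        for v in self.inner:
            hp = heights[self.tree.parent[v]]
            x.append(np.clip(heights[v] / max(hp, 1e-300), 1e-6, 1 - 1e-6))
        return np.array(x)

    def unpack(self, x) -> np.ndarray:
        heights = np.zeros(self.tree.n_nodes)
        heights[self.tree.root] = np.exp(x[0])
        for k, v in enumerate(self.inner):
            heights[v] = x[1 + k] * heights[self.tree.parent[v]]
        return heights

    def bounds(self) -> list:
        return [(np.log(1e-8), np.log(2.0))] + [(1e-6, 1 - 1e-6)] * len(self.inner)


def fit_strict_clock(alignment: Alignment, rooted_topology,
                     model_init: TN93GParams | None = None,
                     optimize_model: bool = True,
                     tol: float = 1e-6, max_rounds: int = 3,
                     estimate_se: bool = True) -> FitResult:
    """ML node heights under a strict clock on a rooted topology.

    `rooted_topology` is a nested pair structure as returned by
    :func:`mtclock.treespace.root_with_outgroup`.  All tips are treated as
    contemporaneous (height 0).  Heights are parameterised as a log root
    height plus per-node depth fractions, so the ultrametric ordering
    constraints become box bounds for L-BFGS-B.  The fitted tree carries a
    root-height standard error from the profile-likelihood curvature unless
    `estimate_se` is False.
    """
    itree = IndexedTree.from_rooted(rooted_topology)
    ws = _PruningWorkspace(alignment, itree)
    if optimize_model or model_init is None:
        model = _empirical_model(alignment, model_init)
    else:
        model = model_init
    par = _ClockParam(itree)
    x0_h = par.pack(_upgma_init_heights(itree, ws.alignment))
    free_model = optimize_model
    x0 = np.concatenate([
        x0_h,
        np.log([model.rate_AG, model.rate_CT, model.gamma_shape]) if free_model else [],
    ])
    bounds = par.bounds() + (_MODEL_BOUNDS if free_model else [])
    n_h = len(x0_h)
    state = {"model": model, "cache": TransitionMatrixCache(model)}

    def objective(x):
        heights = par.unpack(x[:n_h])
        if free_model:
            m = _model_from_logs(model, x[n_h:])
            state["model"], state["cache"] = m, TransitionMatrixCache(m)
        ll = ws.total_loglik(itree, _heights_to_edges(itree, heights), state["cache"])
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200 * max_rounds, "ftol": tol * 1e-5,
                            "gtol": 1e-6})
    objective(res.x)
    heights = par.unpack(res.x[:n_h])
    edge_len = _heights_to_edges(itree, heights)
    pat_ll = ws.pattern_logliks(itree, edge_len, state["cache"])
    total = float(np.dot(pat_ll, ws.counts))
    clock = ClockTree(itree, heights)
    fit = FitResult(
        tree=clock, model=state["model"], log_likelihood=total,
        per_site_log_likelihoods=ws.expand(pat_ll),
        n_iterations=int(res.nit), converged=bool(res.success),
    )
    if estimate_se:
        clock.root_height_se = estimate_root_height_se(alignment, fit)
    return fit


def estimate_root_height_se(alignment: Alignment, clock_fit: FitResult,
                            rel_step: float = 0.05) -> float:
    """Standard error of the ML root height from profile-likelihood curvature.

    The root height is displaced by +/- `rel_step` * h; at each displaced
    value the remaining node heights are re-optimised (model parameters
    held fixed) to obtain the profile log-likelihood, and the SE is
    (-d2l/dh2)^(-1/2) by central second difference.
    """
    clock: ClockTree = clock_fit.tree
    if not isinstance(clock, ClockTree):
        raise TypeError("estimate_root_height_se requires a strict-clock fit")
    tree = clock.tree
    ws = _PruningWorkspace(alignment, tree)
    cache = TransitionMatrixCache(clock_fit.model)
    par = _ClockParam(tree)
    h0 = clock.root_height
    if h0 <= 0:
        raise ValueError("root height is zero; curvature undefined")
    step = max(rel_step * h0, 1e-7)
    x_hat = par.pack(clock.heights)

    def profile(h) -> float:
        x0 = x_hat.copy()
        x0[0] = np.log(h)
        frac_bounds = par.bounds()[1:]

        def obj(xf):
            heights = par.unpack(np.concatenate([[np.log(h)], xf]))
            ll = ws.total_loglik(tree, _heights_to_edges(tree, heights), cache)
            return -ll if np.isfinite(ll) else 1e12

        if len(x0) == 1:
            return -obj(np.empty(0))
        res = minimize(obj, x0[1:], method="L-BFGS-B", bounds=frac_bounds,
                       options={"maxiter": 200, "ftol": 1e-13})
        return -float(res.fun)

    # evaluate the centre by the same re-optimisation as the flanks, so a
    # slightly unconverged fit cannot fake a convex profile
    for attempt in range(3):
        l0, lm, lp = profile(h0), profile(h0 - step), profile(h0 + step)
        d2 = (lp - 2.0 * l0 + lm) / step**2
        if np.isfinite(d2) and d2 < 0:
            return float(1.0 / np.sqrt(-d2))
        step *= 3.0  # widen until curvature dominates optimisation noise
    raise ValueError(
        f"profile log-likelihood is not concave at the optimum "
        f"(d2={d2:.4g}, l-={lm:.6f}, l0={l0:.6f}, l+={lp:.6f})"
    )


def clock_lrt(loglik_no_clock: float, loglik_clock: float, n_taxa: int,
              tol: float = 0.5) -> tuple[float, int, float]:
    """Likelihood-ratio test of the strict molecular clock.

    statistic = 2 (l_free - l_clock); df = n_taxa - 2 (2n-3 branch lengths
    versus n-1 node heights); p-value from the upper chi-square tail.
    """
    if n_taxa < 3:
        raise ValueError("clock test needs at least 3 taxa")
    stat = 2.0 * (loglik_no_clock - loglik_clock)
    if stat < -tol:
        raise ValueError(
            f"no-clock log-likelihood below clock log-likelihood by "
            f"{-stat / 2:.6g}; optimisation likely failed"
        )
    stat = max(stat, 0.0)
    df = n_taxa - 2
    return stat, df, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Marginal posteriors and MAP states at each internal node."""

    clades: list  # frozenset of leaf labels per internal node
    posteriors: np.ndarray  # (n_internal, sites, 4) in A,C,G,T order
    map_states: list  # MAP sequence string per internal node

    def for_clade(self, labels):
        target = frozenset(labels)
        for i, c in enumerate(self.clades):
            if c == target:
                return self.posteriors[i], self.map_states[i]
        raise KeyError(f"no internal node with clade {sorted(target)}")


def ancestral_states(alignment: Alignment, tree: BranchTree | ClockTree,
                     model: TN93GParams) -> AncestralReconstruction:
    """Marginal (empirical-Bayes) ancestral-state reconstruction.

    For each internal node and site the posterior over A,C,G,T is the
    normalised product of the inside (pruning) partial and the outside
    message, averaged over Gamma categories weighted by the category's
    contribution to the site likelihood.  MAP ties break alphabetically.
    """
    itree = tree.tree
    edge_len = tree.lengths if isinstance(tree, BranchTree) else tree.edge_lengths()
    edge_len = np.clip(edge_len, 0.0, None)
    ws = _PruningWorkspace(alignment, itree)
    cache = TransitionMatrixCache(model)
    _, partial = ws.pattern_logliks(itree, edge_len, cache, return_partials=True)
    ncat, P = len(cache.category_rates), ws.n_patterns
    pi = np.asarray(cache.params.freqs)

    down_contrib = {}
    for v in itree.postorder:
        for c in itree.children[v]:
            Pm = cache.matrices(edge_len[c])
            down_contrib[c] = np.matmul(partial[c], Pm.transpose(0, 2, 1))

    outside = [None] * itree.n_nodes
    outside[itree.root] = np.broadcast_to(pi, (ncat, P, 4)).copy()
    for v in reversed(itree.postorder):  # parents before children
        for c in itree.children[v]:
            F = outside[v].copy()
            for s in itree.children[v]:
                if s != c:
                    F *= down_contrib[s]
            Pm = cache.matrices(edge_len[c])
            outside[c] = np.matmul(F, Pm)

    clades, post_rows, maps = [], [], []
    bases = np.array(list("ACGT"))
    leafsets = itree.leafsets()
    w = cache.category_probs[:, np.newaxis, np.newaxis]
    for v in itree.postorder:
        if not itree.children[v]:
            continue
        joint = (outside[v] * partial[v] * w).sum(axis=0)  # (P,4)
        norm = joint.sum(axis=1, keepdims=True)
        post_pat = joint / np.where(norm > 0, norm, 1.0)
        post = post_pat[ws.inverse]
        clades.append(leafsets[v])
        post_rows.append(post)
        maps.append("".join(bases[np.argmax(post, axis=1)]))
    return AncestralReconstruction(clades, np.array(post_rows), maps)
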