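"""Simulation-based calibration experiments for the dating pipeline.

These experiments quantify, under the synthetic cheetah-like scenario,

* whether clock-test p-values are uniform when the clock truly holds, and
* whether the topology-averaged 95% date intervals cover the true split
  times at close to nominal rate,

and are shared between the test suite and the acceptance script.  Problem
sizes default to desk scale (a few kb, tens to hundreds of replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dating import GridSpec, fit_skew_normal
from .likelihood import clock_lrt, fit_no_clock, fit_strict_clock
from .pipeline import date_report
from .rell import SiteLogLikMatrix, bp_rell
from .simulate import (CHEETAH_SPLITS, default_cheetah_scenario,
                       simulate_alignment)
from .treespace import enumerate_topologies, root_with_outgroup

OUTGROUP = ("Jaguarundi", "Puma")
NE_PAIR = ("NEAfr1", "NEAfr2")
INDIA_SE_CLADE = ("India1", "SEAfr1", "SEAfr2")


def lrt_null_experiment(n_replicates: int = 200, length: int = 1500,
                        seed: int = 0) -> np.ndarray:
    """Clock-test p-values on data simulated under a strict clock.

    Both models are fitted with the substitution model fixed at the
    generating parameters, so the test compares exactly the free branch
    lengths (2n-3) against node heights (n-1); the p-values should then be
    approximately Uniform(0, 1).
    """
    sc0 = default_cheetah_scenario(seed=0, length=length, with_masks=False)
    nested = sc0.time_tree.nested
    from .treespace import Topology

    topo = Topology.from_newick(
        "((Puma,Jaguarundi),((NEAfr1,NEAfr2),(India1,(SEAfr1,SEAfr2))));"
    )
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        sc = default_cheetah_scenario(seed=seed + 1000 + i, length=length,
                                      with_masks=False)
        aln, _ = simulate_alignment(sc)
        free = fit_no_clock(aln, topo, model_init=sc.model,
                            optimize_model=False, tol=1e-5)
        clock = fit_strict_clock(aln, nested, model_init=sc.model,
                                 optimize_model=False, tol=1e-5,
                                 estimate_se=False)
        _, _, p = clock_lrt(free.log_likelihood, clock.log_likelihood,
                            aln.n_taxa)
        pvals[i] = p
    return pvals


def candidate_topologies():
    """Scaled-down candidate set: all 7-taxon topologies in which the
    outgroup pair and the NE-African pair each form a cherry (15 trees).

    The SE-African pair is deliberately left unconstrained, so the set
    spans the axis the analysis actually has to resolve — where the
    India-like lineage attaches, including inside the SE-African clade."""
    sc = default_cheetah_scenario(seed=0, length=100, with_masks=False)
    taxa = sorted(sc.time_tree.indexed()[0].leaf_of_label)
    tops = enumerate_topologies(taxa, constraint=frozenset(OUTGROUP))
    return [t for t in tops if t.has_clade(frozenset(NE_PAIR))]


@dataclass
class CoverageResult:
    covered: np.ndarray  # bool per replicate
    medians: np.ndarray  # topology-averaged median date per replicate (years)
    intervals: np.ndarray  # (n, 2) lo/hi years
    true_split: float

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())


def coverage_experiment(n_replicates: int = 100, length: int = 15000,
                        seed: int = 0, top_k: int = 10,
                        min_weight: float = 0.0,
                        grid: GridSpec = GridSpec(200, 200, 1000),
                        progress=None) -> CoverageResult:
    """End-to-end interval coverage of the true India/SE-Africa split.

    Per replicate: simulate the default cheetah scenario, estimate the
    substitution model once by a strict-clock fit of the first candidate
    topology (the clock constraint keeps the Gamma shape identifiable on a
    single alignment), fit every candidate topology by ML with that model,
    weight topologies by bp-RELL, re-fit the supported topologies under a
    strict clock, propagate root-height and calibration uncertainty into a
    topology-averaged date distribution for the India+SE clade, and record
    whether its 95% interval covers the true simulated split time.
    """
    cands = candidate_topologies()
    calibration = fit_skew_normal(CHEETAH_SPLITS["root"], 3.86e6, 6.92e6)
    true_split = CHEETAH_SPLITS["india_vs_se"]
    covered = np.zeros(n_replicates, dtype=bool)
    medians = np.empty(n_replicates)
    intervals = np.empty((n_replicates, 2))
    for i in range(n_replicates):
        sc = default_cheetah_scenario(seed=seed + 5000 + i, length=length)
        aln, _ = simulate_alignment(sc)
        shared = fit_strict_clock(
            aln, root_with_outgroup(cands[0], OUTGROUP),
            optimize_model=True, estimate_se=False, tol=1e-5,
        ).model
        fits = [
            fit_no_clock(aln, topo, model_init=shared,
                         optimize_model=False, tol=1e-4)
            for topo in cands
        ]
        matrix = SiteLogLikMatrix(
            [f.topology_id for f in fits],
            np.vstack([f.per_site_log_likelihoods for f in fits]),
        )
        weights = bp_rell(matrix, n_bootstrap=10_000, seed=seed + i)
        if min_weight > 0:
            keep = weights.weights >= min_weight
            if not keep.any():
                keep = weights.weights == weights.weights.max()
        else:
            keep = np.ones(len(cands), dtype=bool)
        kept_ids = [t for t, k in zip(weights.topology_ids, keep) if k]
        sub_weights = type(weights)(
            kept_ids, weights.weights[keep] / weights.weights[keep].sum(),
            weights.n_bootstrap, weights.seed,
        )
        report = date_report(
            aln, [c for c in cands if c.canonical_form in kept_ids],
            sub_weights, calibration,
            clade_queries={"india_se": list(INDIA_SE_CLADE)},
            outgroup=OUTGROUP, top_k=min(top_k, len(kept_ids)),
            grid_spec=grid, model_init=shared, reoptimize_model=False,
            fit_kwargs={"tol": 1e-4},
        )
        med, lo, hi = report.clades["india_se"].averaged
        covered[i] = lo <= true_split <= hi
        medians[i] = med
        intervals[i] = (lo, hi)
        if progress:
            progress(i, covered[: i + 1].mean())
    return CoverageResult(covered, medians, intervals, true_split)
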