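"""End-to-end divergence-dating pipeline and its run configuration.

Stages: enumerate candidate topologies -> fit each by ML (no clock) ->
bp-RELL topology weights -> strict-clock re-fit of the best topologies ->
calibrated rate and date distributions -> per-clade date report, with every
intermediate written as a plain-text artifact (Newick / TSV / JSON) so any
stage can be checked against external tools.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignment import Alignment, read_alignment
from .dating import (CalibrationSpec, DateDistribution, GridSpec,
                     combine_topologies, fit_skew_normal,
                     node_date_distribution, rate_distribution)
from .likelihood import FitResult, clock_lrt, fit_no_clock, fit_strict_clock
from .rell import SiteLogLikMatrix, TopologyWeights, bp_rell, top_k_mass
from .treespace import Topology, enumerate_topologies, root_with_outgroup


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    alignment_path: str
    outgroup: list
    calibration_point: float  # years
    calibration_ci_low: float
    calibration_ci_high: float
    clade_queries: dict = field(default_factory=dict)  # name -> [labels]
    output_dir: str = "mtclock_out"
    constraint: list | None = None  # clade required during enumeration
    seed: int = 1
    n_bootstrap: int = 10_000
    top_k: int = 10
    reoptimize_model: bool = True
    n_height_grid: int = 400
    n_date_grid: int = 400
    n_rate_bins: int = 2000
    extra_taxa_drop: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cal = raw.get("calibration", {})
        cfg = cls(
            alignment_path=raw["alignment"],
            outgroup=list(raw["outgroup"]),
            calibration_point=float(cal["point"]),
            calibration_ci_low=float(cal["ci_low"]),
            calibration_ci_high=float(cal["ci_high"]),
            clade_queries={k: list(v) for k, v in raw.get("clades", {}).items()},
            output_dir=raw.get("output_dir", "mtclock_out"),
            constraint=list(raw["constraint"]) if raw.get("constraint") else None,
            seed=int(raw["seed"]),
            n_bootstrap=int(raw.get("n_bootstrap", 10_000)),
            top_k=int(raw.get("top_k", 10)),
            reoptimize_model=bool(raw.get("reoptimize_model", True)),
            n_height_grid=int(raw.get("n_height_grid", 400)),
            n_date_grid=int(raw.get("n_date_grid", 400)),
            n_rate_bins=int(raw.get("n_rate_bins", 2000)),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "alignment": self.alignment_path,
            "outgroup": list(self.outgroup),
            "calibration": {
                "point": self.calibration_point,
                "ci_low": self.calibration_ci_low,
                "ci_high": self.calibration_ci_high,
            },
            "clades": {k: list(v) for k, v in self.clade_queries.items()},
            "output_dir": self.output_dir,
            "constraint": list(self.constraint) if self.constraint else None,
            "seed": self.seed,
            "n_bootstrap": self.n_bootstrap,
            "top_k": self.top_k,
            "reoptimize_model": self.reoptimize_model,
            "n_height_grid": self.n_height_grid,
            "n_date_grid": self.n_date_grid,
            "n_rate_bins": self.n_rate_bins,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def validate(self) -> None:
        if not Path(self.alignment_path).exists():
            raise FileNotFoundError(self.alignment_path)
        if not self.calibration_ci_low < self.calibration_point < self.calibration_ci_high:
            raise ValueError("calibration must satisfy ci_low < point < ci_high")
        if self.n_bootstrap < 1 or self.top_k < 1:
            raise ValueError("n_bootstrap and top_k must be >= 1")

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")  # run identity should not depend on where it lands
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def grid_spec(self) -> GridSpec:
        return GridSpec(n_height=self.n_height_grid, n_date=self.n_date_grid,
                        n_rate_bins=self.n_rate_bins)


@dataclass
class CladeDates:
    """Best-topology and topology-averaged dates for one queried clade."""

    clade_name: str
    labels: list
    best: tuple[float, float, float]  # median, q025, q975 (years)
    averaged: tuple[float, float, float]
    best_distribution: DateDistribution
    averaged_distribution: DateDistribution


@dataclass
class DateReport:
    clades: dict  # name -> CladeDates
    weights: TopologyWeights
    top_ids: list
    top_mass: float
    clock_fits: dict  # topology id -> FitResult

    def to_json_dict(self) -> dict:
        out = {}
        for name, cd in self.clades.items():
            b, a = cd.best, cd.averaged
            out[name] = {
                "labels": list(cd.labels),
                "best_date": b[0], "best_lo": b[1], "best_hi": b[2],
                "avg_date": a[0], "avg_lo": a[1], "avg_hi": a[2],
            }
        return out


def date_report(alignment: Alignment, topologies: list[Topology],
                weights: TopologyWeights, calibration: CalibrationSpec,
                clade_queries: dict, outgroup, top_k: int = 10,
                grid_spec: GridSpec = GridSpec(),
                model_init=None, reoptimize_model: bool = True,
                fit_kwargs: dict | None = None) -> DateReport:
    """Calibrated per-clade dates from the best-supported topologies.

    The `top_k` topologies by RELL weight that are rootable with the given
    outgroup are re-fitted under the strict clock; each contributes a date
    distribution for every queried clade (via the MRCA of the clade's
    labels), and the distributions mix by renormalised weight.
    """
    fit_kwargs = dict(fit_kwargs or {})
    by_id = {t.canonical_form: t for t in topologies}
    order_ids, _ = top_k_mass(weights, min(top_k, len(weights.topology_ids)))
    usable, usable_w, clock_fits = [], [], {}
    for tid in order_ids:
        topo = by_id[tid]
        try:
            rooted = root_with_outgroup(topo, outgroup)
        except ValueError:
            continue  # outgroup not monophyletic here; excluded from dating
        fit = fit_strict_clock(
            alignment, rooted, model_init=model_init,
            optimize_model=reoptimize_model, estimate_se=True, **fit_kwargs,
        )
        usable.append(tid)
        usable_w.append(weights.weight_of(tid))
        clock_fits[tid] = fit
    if not usable:
        raise ValueError("no topology in the top set is rootable with the outgroup")

    rate_dists = {
        tid: rate_distribution(
            clock_fits[tid].tree.root_height,
            clock_fits[tid].tree.root_height_se,
            calibration, grid_spec,
        )
        for tid in usable
    }
    clades = {}
    for name, labels in clade_queries.items():
        per_topo = [
            node_date_distribution(
                clock_fits[tid].tree.node_height(labels), rate_dists[tid], grid_spec
            )
            for tid in usable
        ]
        averaged = combine_topologies(per_topo, usable_w)
        clades[name] = CladeDates(
            clade_name=name, labels=list(labels),
            best=per_topo[0].summary(), averaged=averaged.summary(),
            best_distribution=per_topo[0], averaged_distribution=averaged,
        )
    _, mass = top_k_mass(weights, min(top_k, len(weights.topology_ids)))
    return DateReport(clades=clades, weights=weights, top_ids=usable,
                      top_mass=mass, clock_fits=clock_fits)


def run_full_pipeline(config: RunConfig, log=print) -> dict:
    """Execute every stage and write the report bundle to the output dir.

    Returns a dict of the headline results (weights, LRT, per-clade dates).
    Deterministic given the config seed.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# mtclock config_hash={config.config_hash()} seed={config.seed}\n"

    def _stage(name):
        log(f"[{name}] t={time.time() - t_start:.1f}s")

    alignment = read_alignment(config.alignment_path)
    taxa = [t for t in alignment.taxon_names if t not in config.extra_taxa_drop]

    _stage("enumerate")
    topologies = enumerate_topologies(
        taxa, constraint=frozenset(config.constraint) if config.constraint else None
    )
    with open(outdir / "topologies.nwk", "w") as fh:
        fh.write(header)
        for t in topologies:
            fh.write(t.newick() + "\n")

    _stage(f"fit {len(topologies)} topologies")
    shared_model = None
    fits: list[FitResult] = []
    for i, topo in enumerate(topologies):
        fit = fit_no_clock(
            alignment.subset(taxa) if len(taxa) != alignment.n_taxa else alignment,
            topo,
            model_init=shared_model,
            optimize_model=config.reoptimize_model or shared_model is None,
        )
        if shared_model is None:
            shared_model = fit.model
        fits.append(fit)
    site_matrix = SiteLogLikMatrix(
        [f.topology_id for f in fits],
        np.vstack([f.per_site_log_likelihoods for f in fits]),
    )
    with open(outdir / "fits.tsv", "w") as fh:
        fh.write(header)
        fh.write("topology_id\tlog_likelihood\tnewick\n")
        for f in fits:
            fh.write(f"{f.topology_id}\t{f.log_likelihood:.6f}\t{f.tree.newick()}\n")

    _stage("rell")
    weights = bp_rell(site_matrix, n_bootstrap=config.n_bootstrap, seed=config.seed)
    weights.to_tsv(outdir / "weights.tsv")

    _stage("clock + dating")
    best_tid, _ = top_k_mass(weights, 1)
    best_fit = max(fits, key=lambda f: f.log_likelihood)
    calibration = fit_skew_normal(
        config.calibration_point, config.calibration_ci_low, config.calibration_ci_high
    )
    report = date_report(
        alignment.subset(taxa) if len(taxa) != alignment.n_taxa else alignment,
        topologies, weights, calibration, config.clade_queries,
        outgroup=config.outgroup, top_k=config.top_k,
        grid_spec=config.grid_spec(),
        model_init=shared_model, reoptimize_model=config.reoptimize_model,
    )

    # strict-clock fit of the best topology for the clock LRT
    top_fit = report.clock_fits.get(best_tid[0])
    lrt = None
    if top_fit is not None:
        free_ll = next(f.log_likelihood for f in fits if f.topology_id == best_tid[0])
        lrt = clock_lrt(free_ll, top_fit.log_likelihood, len(taxa))

    _stage("write report")
    with open(outdir / "dates.tsv", "w") as fh:
        fh.write(header)
        fh.write("clade\tbest_date\tbest_lo\tbest_hi\tavg_date\tavg_lo\tavg_hi\n")
        for name, cd in report.clades.items():
            b, a = cd.best, cd.averaged
            fh.write(f"{name}\t" + "\t".join(f"{x:.1f}" for x in (*b, *a)) + "\n")
    for name, cd in report.clades.items():
        cd.averaged_distribution.to_tsv(
            outdir / f"date_distribution_{name}.tsv", value_name="age_years"
        )
    results = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_topologies": len(topologies),
        "best_topology": best_tid[0],
        "best_log_likelihood": best_fit.log_likelihood,
        "top_k_mass": report.top_mass,
        "clock_lrt": {
            "statistic": lrt[0], "df": lrt[1], "p_value": lrt[2]
        } if lrt else None,
        "clades": report.to_json_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config_used.yaml")
    _stage("done")
    return results
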