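"""Forward sequence simulation on ultrametric time trees.

Generates alignments with the statistical structure the dating pipeline
assumes: sites evolve independently under TN93 with a per-site Gamma rate
category, down a rooted time tree scaled by a molecular-clock mutation rate
(substitutions/site/year).  The default scenario emulates a 7-taxon felid
mtDNA coding-region dataset: a puma-like outgroup pair splitting from the
ingroup at 4.92 My, cheetah-like ingroup splits at ~139/72 ky, and
per-taxon contiguous missing-data masks mimicking partially recovered
historical sequences.  An optional helper implants a diverged segment into
a sequence to mimic a numt-contaminated chimeric assembly.

All randomness flows through a counter-based Philox generator, so a given
seed reproduces byte-identical output on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import ClockTree, IndexedTree
from .substitution import TN93GParams, TransitionMatrixCache

BASES = "ACGT"


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(int(seed) % 2**31))


@dataclass
class TimeTree:
    """Rooted ultrametric tree with node times in years (tips at 0)."""

    nested: object  # nested pairs of labels
    times: dict  # frozenset(clade labels) -> node time in years

    def indexed(self) -> tuple[IndexedTree, np.ndarray]:
        itree = IndexedTree.from_rooted(self.nested)
        heights = np.zeros(itree.n_nodes)
        for v, ls in enumerate(itree.leafsets()):
            if len(ls) > 1:
                heights[v] = self.times[ls]
        return itree, heights

    @property
    def root_time(self) -> float:
        itree, heights = self.indexed()
        return float(heights[itree.root])


@dataclass
class Scenario:
    """Fully specified generative setting for one synthetic dataset."""

    time_tree: TimeTree
    mutation_rate: float  # substitutions/site/year
    model: TN93GParams
    length: int
    missing_masks: dict = field(default_factory=dict)  # taxon -> [(start, end)) half-open spans
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for taxon, spans in self.missing_masks.items():
            for start, end in spans:
                if not (0 <= start < end <= self.length):
                    raise ValueError(
                        f"mask [{start},{end}) for {taxon} outside [0,{self.length})"
                    )

    def truth(self) -> dict:
        return {
            "seed": self.seed,
            "mutation_rate": self.mutation_rate,
            "length": self.length,
            "split_times_years": {
                "|".join(sorted(k)): v for k, v in self.time_tree.times.items()
            },
            "missing_masks": {t: list(map(list, s)) for t, s in self.missing_masks.items()},
        }


def simulate_alignment(scenario: Scenario) -> tuple[Alignment, ClockTree]:
    """Evolve sequences down the scenario's time tree.

    Returns the masked alignment together with the true expected-
    substitutions clock tree (node heights = time x mutation rate), which
    recovery tests compare against.
    """
    rng = _rng(scenario.seed)
    itree, times = scenario.time_tree.indexed()
    heights = times * scenario.mutation_rate  # substitutions/site
    cache = TransitionMatrixCache(scenario.model)
    ncat = len(cache.category_rates)
    L = scenario.length

    categories = rng.integers(0, ncat, size=L)
    pi = np.asarray(scenario.model.freqs)
    states = np.empty((itree.n_nodes, L), dtype=np.int8)
    root = itree.root
    states[root] = rng.choice(4, size=L, p=pi)
    for v in reversed(itree.postorder):  # parents before children
        for c in itree.children[v]:
            t = heights[v] - heights[c]
            P = cache.matrices(t)  # (ncat,4,4)
            child = np.empty(L, dtype=np.int8)
            u = rng.random(L)
            for cat in range(ncat):
                sel = categories == cat
                cum = np.cumsum(P[cat], axis=1)
                cum[:, -1] = 1.0
                child[sel] = (
                    u[sel, np.newaxis] > cum[states[v][sel]]
                ).sum(axis=1)
            states[c] = child

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    names, seqs = [], []
    for v in itree.postorder:
        if itree.children[v]:
            continue
        name = itree.labels[v]
        chars = base_arr[states[v]].copy()
        for start, end in scenario.missing_masks.get(name, ()):
            chars[start:end] = ord("N")
        names.append(name)
        seqs.append(chars.tobytes().decode("ascii"))
    order = np.argsort(names)
    aln = Alignment(tuple(names[i] for i in order), tuple(seqs[i] for i in order))
    true_clock = ClockTree(itree, heights)
    return aln, true_clock


# ---------------------------------------------------------------------
# default cheetah-like scenario
# ---------------------------------------------------------------------

#: Default split times in years.  The ingroup depths mirror the dated felid
#: mtDNA study system this simulator emulates: outgroup (puma-like pair)
#: splitting from the cheetah-like ingroup at 4.92 My, a NE-African-like
#: lineage at 138.9 ky, the Indian-like lineage at 72.2 ky, and a shallow
#: split within the SE-African-like pair.
CHEETAH_SPLITS = {
    "root": 4.92e6,
    "outgroup_pair": 4.17e6,
    "ingroup_crown": 138.9e3,
    "india_vs_se": 72.2e3,
    "se_pair": 20.0e3,
    "ne_pair": 60.0e3,
}

#: mtDNA coding-region clock rate (substitutions/site/year).  Chosen so the
#: shallow ingroup splits imply per-pair differences comparable to the
#: handful of variants seen between recently diverged cheetah mtDNA
#: sequences (~6 variants / 3.7 kb at the ~72 ky split depth).
CHEETAH_RATE = 1.1e-8

CHEETAH_MODEL = TN93GParams(
    base_freqs=(0.32, 0.27, 0.14, 0.27),
    rate_AG=20.0,
    rate_CT=40.0,
    rate_transversion=1.0,
    gamma_shape=0.25,
    n_categories=5,
)

CHEETAH_TAXA = dict(
    outgroup=("Puma", "Jaguarundi"),
    ne_africa=("NEAfr1", "NEAfr2"),
    india=("India1",),
    se_africa=("SEAfr1", "SEAfr2"),
)


def cheetah_time_tree() -> TimeTree:
    nested = (
        ("Puma", "Jaguarundi"),
        (("NEAfr1", "NEAfr2"), ("India1", ("SEAfr1", "SEAfr2"))),
    )
    s = CHEETAH_SPLITS
    times = {
        frozenset(["Puma", "Jaguarundi", "NEAfr1", "NEAfr2", "India1",
                   "SEAfr1", "SEAfr2"]): s["root"],
        frozenset(["Puma", "Jaguarundi"]): s["outgroup_pair"],
        frozenset(["NEAfr1", "NEAfr2", "India1", "SEAfr1", "SEAfr2"]): s["ingroup_crown"],
        frozenset(["NEAfr1", "NEAfr2"]): s["ne_pair"],
        frozenset(["India1", "SEAfr1", "SEAfr2"]): s["india_vs_se"],
        frozenset(["SEAfr1", "SEAfr2"]): s["se_pair"],
    }
    return TimeTree(nested, times)


def default_cheetah_scenario(seed: int, length: int = 15000,
                             with_masks: bool = True) -> Scenario:
    """7-taxon cheetah-like scenario with historical-sample missing masks.

    The India1 mask leaves 3675 called coding sites (matching the coverage
    of a degraded historical specimen); a second partial mask on NEAfr2
    leaves about half the sites called.
    """
    masks = {}
    if with_masks:
        called = min(3675, length)
        # two called blocks at the ends, middle masked
        b1 = called * 2 // 5
        masks["India1"] = [(b1, b1 + (length - called))] if length > called else []
        half_gap = length // 2
        masks["NEAfr2"] = [(length // 4, length // 4 + half_gap // 2),
                           (length * 3 // 4, min(length, length * 3 // 4 + half_gap // 2))]
        masks = {k: [s for s in v if s[0] < s[1]] for k, v in masks.items()}
    return Scenario(
        time_tree=cheetah_time_tree(),
        mutation_rate=CHEETAH_RATE,
        model=CHEETAH_MODEL,
        length=length,
        missing_masks=masks,
        seed=seed,
    )


def make_numt_chimera(sequence: str, segment: tuple[int, int],
                      divergence: float, seed: int) -> tuple[str, int]:
    """Implant a diverged segment, mimicking a numt-contaminated assembly.

    Within `segment` (half-open) each position mutates independently with
    probability `divergence` to a uniformly chosen different base.  Returns
    (chimeric sequence, number of positions actually changed).
    """
    start, end = segment
    if not (0 <= start < end <= len(sequence)):
        raise ValueError("segment out of bounds")
    if not 0.0 <= divergence <= 0.75:
        raise ValueError("divergence must be in [0, 0.75]")
    rng = _rng(seed)
    chars = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    region = chars[start:end]
    mutate = rng.random(end - start) < divergence
    acgt = np.frombuffer(BASES.encode(), dtype=np.uint8)
    is_base = np.isin(region, acgt)
    mutate &= is_base
    idx = np.where(mutate)[0]
    n_changed = 0
    for i in idx:
        choices = [b for b in acgt if b != region[i]]
        region[i] = choices[rng.integers(0, 3)]
        n_changed += 1
    chars[start:end] = region
    return chars.tobytes().decode("ascii"), n_changed


def write_truth_json(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario.truth(), fh, indent=2, sort_keys=True)
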