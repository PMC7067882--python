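"""Sliding-window mismatch screen for numt-contaminated mtDNA assemblies.

Co-amplified nuclear copies of mitochondrial DNA (numts) produce chimeric
assemblies whose diverged segments stand out as localised spikes in the
mismatch rate against a trusted reference sequence.  The screen slides a
window (default 1000 bp) along a pre-aligned query/reference pair, counts
mismatches over positions where both sequences have an unambiguous base,
and masks windows with too few called positions (default <200 bp).
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import IUPAC_MASKS

DEFAULT_WINDOW = 1000
DEFAULT_MIN_CALLED = 200

_UNAMBIGUOUS = {1, 2, 4, 8}


@dataclass(frozen=True)
class WindowMismatch:
    """Mismatch rate in one window; `masked` if too few called positions."""

    window_start: int
    window_end: int
    called_sites: int
    mismatches: int
    masked: bool

    @property
    def mismatch_rate(self) -> float | None:
        if self.masked or self.called_sites == 0:
            return None
        return self.mismatches / self.called_sites

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


def _encode(seq: str) -> np.ndarray:
    table = np.zeros(128, dtype=np.uint8)
    for ch, m in IUPAC_MASKS.items():
        table[ord(ch)] = m
    return table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def mismatch_scan(query: str, reference: str, window: int = DEFAULT_WINDOW,
                  step: int | None = None,
                  min_called: int = DEFAULT_MIN_CALLED) -> list[WindowMismatch]:
    """Sliding-window mismatch profile of two pre-aligned sequences.

    A position is *called* when both sequences carry an unambiguous base
    (A/C/G/T); gaps, Ns and ambiguity codes drop out of both numerator and
    denominator.  `step` defaults to 100 bp; `step == window` tiles the
    sequence without overlap.  The final window is anchored at the sequence
    end so every position is covered.
    """
    if len(query) != len(reference):
        raise ValueError(
            f"query ({len(query)}) and reference ({len(reference)}) lengths differ"
        )
    length = len(query)
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    step = 100 if step is None else step
    if not 1 <= step <= window:
        raise ValueError("need 1 <= step <= window")
    q, r = _encode(query), _encode(reference)
    called = np.isin(q, list(_UNAMBIGUOUS)) & np.isin(r, list(_UNAMBIGUOUS))
    mism = called & (q != r)
    called_cum = np.concatenate([[0], np.cumsum(called)])
    mism_cum = np.concatenate([[0], np.cumsum(mism)])
    starts = list(range(0, length - window + 1, step))
    if starts[-1] != length - window:
        starts.append(length - window)
    out = []
    for s in starts:
        e = s + window
        c = int(called_cum[e] - called_cum[s])
        m = int(mism_cum[e] - mism_cum[s])
        out.append(WindowMismatch(s, e, c, m, masked=c < min_called))
    return out


def flag_numt_candidates(profile: list[WindowMismatch], background_rate: float,
                         fold_threshold: float = 4.0) -> list[tuple[int, int]]:
    """Merge elevated windows into candidate chimeric intervals.

    A window is elevated when its mismatch rate exceeds
    `fold_threshold * background_rate` (with a small absolute floor so a
    zero background does not flag single mismatches).  Overlapping or
    adjacent elevated windows merge into half-open intervals.
    """
    if not profile:
        raise ValueError("empty profile")
    if background_rate < 0 or fold_threshold <= 0:
        raise ValueError("background_rate >= 0 and fold_threshold > 0 required")
    cutoff = max(fold_threshold * background_rate, 1e-12)
    intervals: list[list[int]] = []
    for w in profile:
        rate = w.mismatch_rate
        if rate is None or rate <= cutoff:
            continue
        if intervals and w.window_start <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], w.window_end)
        else:
            intervals.append([w.window_start, w.window_end])
    return [(s, e) for s, e in intervals]


def profile_to_tsv(profile: list[WindowMismatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tcalled\tmismatches\trate\tmasked\n")
        for w in profile:
            rate = "NA" if w.mismatch_rate is None else f"{w.mismatch_rate:.6f}"
            fh.write(
                f"{w.window_start}\t{w.window_end}\t{w.called_sites}\t"
                f"{w.mismatches}\t{rate}\t{int(w.masked)}\n"
            )


def intervals_to_bed(intervals, path, name: str = "numt_candidate") -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals, start=1):
            fh.write(f"query\t{s}\t{e}\t{name}_{i}\n")


def plot_profile(profile: list[WindowMismatch], path, title: str | None = None):
    """Mismatch rate against window midpoint (masked windows omitted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [w.midpoint for w in profile if not w.masked]
    ys = [w.mismatch_rate for w in profile if not w.masked]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(xs, ys, lw=1.2)
    ax.set_xlabel("position (bp, window midpoint)")
    ax.set_ylabel("mismatch rate")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
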