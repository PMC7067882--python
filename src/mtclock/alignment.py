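"""Nucleotide alignment container with ambiguity-aware state encoding.

Sequences are stored as strings over A, C, G, T, the IUPAC ambiguity codes,
'-' and 'N'.  For likelihood work each character maps to the set of
compatible states; fully missing characters ('-', 'N', '?') are compatible
with all four.  Columns are compressed to unique site patterns before
likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# bitmask over (A=1, C=2, G=4, T=8)
IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011,
    "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, ".": 0b1111,
}

_MASK_TO_ROW = np.zeros((16, 4))
for _m in range(1, 16):
    for _b in range(4):
        if _m >> _b & 1:
            _MASK_TO_ROW[_m, _b] = 1.0


@dataclass(frozen=True)
class Alignment:
    """Equal-length named nucleotide sequences."""

    taxon_names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.sequences):
            raise ValueError("one sequence per taxon name required")
        if len(self.taxon_names) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("taxon names must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        up = []
        for name, seq in zip(self.taxon_names, self.sequences):
            s = seq.upper()
            bad = set(s) - set(IUPAC_MASKS)
            if bad:
                raise ValueError(f"invalid characters in {name}: {sorted(bad)}")
            up.append(s)
        object.__setattr__(self, "taxon_names", tuple(self.taxon_names))
        object.__setattr__(self, "sequences", tuple(up))

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, name: str) -> str:
        return self.sequences[self.taxon_names.index(name)]

    def subset(self, names) -> "Alignment":
        names = list(names)
        return Alignment(tuple(names), tuple(self.sequence(n) for n in names))

    def concatenate(self, other: "Alignment") -> "Alignment":
        if self.taxon_names != other.taxon_names:
            raise ValueError("taxon sets differ")
        return Alignment(
            self.taxon_names,
            tuple(a + b for a, b in zip(self.sequences, other.sequences)),
        )

    # -- encodings -----------------------------------------------------
    def state_masks(self) -> np.ndarray:
        """(n_taxa, length) uint8 array of IUPAC compatibility bitmasks."""
        out = np.empty((self.n_taxa, self.length), dtype=np.uint8)
        table = np.zeros(128, dtype=np.uint8)
        for ch, m in IUPAC_MASKS.items():
            table[ord(ch)] = m
        for i, seq in enumerate(self.sequences):
            out[i] = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return out

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique column patterns.

        Returns (patterns, counts, inverse): patterns is (n_patterns,
        n_taxa) of bitmasks, counts the column multiplicities, inverse maps
        each site to its pattern row.
        """
        masks = self.state_masks().T  # (sites, taxa)
        patterns, inverse, counts = np.unique(
            masks, axis=0, return_inverse=True, return_counts=True
        )
        return patterns, counts.astype(float), inverse

    def empirical_base_freqs(self, pseudocount: float = 0.0) -> np.ndarray:
        """Base frequencies counted over unambiguous positions.

        Ambiguity codes contribute fractionally over their compatible
        states; fully missing characters are ignored.
        """
        masks = self.state_masks()
        rows = _MASK_TO_ROW[masks.ravel()]
        informative = rows.sum(axis=1) < 4
        counts = rows[informative]
        counts = (counts / counts.sum(axis=1, keepdims=True)).sum(axis=0)
        counts = counts + pseudocount
        return counts / counts.sum()


def leaf_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, n_patterns, 4) indicator partial likelihoods from bitmasks."""
    return _MASK_TO_ROW[patterns.T]


# -- file formats -------------------------------------------------------

def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment(
        tuple(r.id for r in records), tuple(str(r.seq) for r in records)
    )


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(alignment.taxon_names, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_relaxed_phylip(path) -> Alignment:
    """Relaxed sequential PHYLIP: header 'ntaxa nsites', then 'name seq' rows.

    Sequences may continue on following lines until nsites characters have
    been read for the current taxon.
    """
    with open(path) as fh:
        tokens = fh.readline().split()
        if len(tokens) != 2:
            raise ValueError("expected PHYLIP header '<ntaxa> <nsites>'")
        n_taxa, n_sites = int(tokens[0]), int(tokens[1])
        names, seqs = [], []
        name, chunks, got = None, [], 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if name is None:
                name, rest = line.split(maxsplit=1) if " " in line else (line, "")
                chunks, got = [], 0
                line = rest
            seq = line.replace(" ", "")
            chunks.append(seq)
            got += len(seq)
            if got >= n_sites:
                names.append(name)
                seqs.append("".join(chunks)[:n_sites])
                name = None
    if len(names) != n_taxa:
        raise ValueError(f"expected {n_taxa} taxa, parsed {len(names)}")
    return Alignment(tuple(names), tuple(seqs))


def read_alignment(path) -> Alignment:
    """Sniff FASTA vs relaxed PHYLIP from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                break
        else:
            raise ValueError(f"{path} is empty")
    return read_fasta(path) if first == ">" else read_relaxed_phylip(path)
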