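"""Reference sequences with optional per-CpG methylation states.

A :class:`ReferenceSequence` holds named contigs of upper-case A/C/G/T/N
plus, optionally, the positions of *methylated* CpG dinucleotides on each
contig (position = 0-based index of the C). Methylation is the property MBD
capture selects on, so the container carries it next to the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")


@dataclass
class ReferenceSequence:
    """Named contigs with optional methylated-CpG position tracks.

    Parameters
    ----------
    contigs
        Mapping of contig name to upper-case sequence string.
    methylated_cpg
        Mapping of contig name to a sorted integer array of 0-based
        positions of the C of each *methylated* CpG. Contigs without an
        entry are treated as fully unmethylated.
    """

    contigs: dict[str, str] = field(default_factory=dict)
    methylated_cpg: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-DNA characters: {sorted(bad)}"
                )
        for name, pos in self.methylated_cpg.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (np.any(np.diff(arr) < 0)):
                arr = np.sort(arr)
            self.methylated_cpg[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self, name: str, start: int | None = None, end: int | None = None) -> str:
        """Subsequence of a contig on 0-based half-open coordinates."""
        return self.contigs[name][start:end]

    def cpg_positions(self, name: str) -> np.ndarray:
        """All CpG dinucleotide positions (index of the C) on a contig."""
        seq = self.contigs[name]
        return np.array([i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"],
                        dtype=np.int64)

    def methylated_in(self, name: str, start: int, end: int) -> int:
        """Number of methylated CpGs whose C lies in [start, end)."""
        pos = self.methylated_cpg.get(name)
        if pos is None or pos.size == 0:
            return 0
        lo, hi = np.searchsorted(pos, [start, end])
        return int(hi - lo)
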