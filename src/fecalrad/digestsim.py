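"""In-silico double digestion and ddRAD locus (RADtag) prediction.

The ddRAD protocol digests genomic DNA with two restriction enzymes,
ligates adapters onto fragments cut by *one enzyme on each end*, and
size-selects the ligated molecules. This module reproduces that pipeline on
a reference (or simulated) genome: it locates recognition sites, derives
the fragment tiling of each contig, keeps the opposite-end fragments whose
adapter-inclusive length falls in the size-selection window, annotates each
predicted locus with length, GC fraction and flanking CpG density, assigns
an expected read weight that decays with distance from the selection
target, and tallies aligned reads per locus.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from math import exp
from typing import Iterable, Sequence

import numpy as np

from .genome import ReferenceSequence

# IUPAC ambiguity codes resolved to explicit base sets. N in the *sequence*
# never matches because no set below contains N.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Sentinel end label for fragment ends created by a contig boundary
#: rather than an enzymatic cut.
CONTIG_TERMINUS = "contig_terminus"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme defined by motif and top-strand cut offset."""

    name: str
    recognition_motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.recognition_motif.upper()
        if not motif:
            raise ValueError("recognition motif must be nonempty")
        bad = set(motif) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"motif contains non-IUPAC characters: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError("cut_offset must lie within the motif")
        object.__setattr__(self, "recognition_motif", motif)

    @property
    def motif_length(self) -> int:
        return len(self.recognition_motif)

    def _pattern(self) -> re.Pattern[str]:
        # Lookahead so overlapping occurrences are all reported.
        pat = _PATTERN_CACHE.get(self.recognition_motif)
        if pat is None:
            body = "".join(
                c if len(IUPAC_SETS[c]) == 1 else f"[{IUPAC_SETS[c]}]"
                for c in self.recognition_motif
            )
            pat = re.compile(f"(?=({body}))")
            _PATTERN_CACHE[self.recognition_motif] = pat
        return pat


_PATTERN_CACHE: dict[str, re.Pattern[str]] = {}


#: SphI: GCATG^C — 6-cutter leaving a 3' overhang; top-strand cut after base 5.
SPHI = RestrictionEnzyme("SphI", "GCATGC", 5)
#: MluCI: ^AATT — 4-cutter cutting before the motif (offset 0).
MLUCI = RestrictionEnzyme("MluCI", "AATT", 0)

ENZYMES: dict[str, RestrictionEnzyme] = {"SphI": SPHI, "MluCI": MLUCI}


@dataclass(frozen=True)
class Fragment:
    """A digestion product: an interval plus the identity of each end."""

    contig: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment must have start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PredictedRADtag:
    """A predicted ddRAD locus with its annotations."""

    contig: str
    start: int
    end: int
    left_end: str
    right_end: str
    gc_fraction: float | None = None
    cpg_flank_count: int | None = None
    read_weight: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tag_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SizeSelection:
    """Size-selection window on adapter-inclusive fragment length.

    ``target_total_bp`` and ``half_width_bp`` describe the automated gel
    collection window (default 300 +/- 39 bp including adapters);
    ``adapter_total_bp`` is the combined length both adapters add to an
    insert; ``kernel_sd_bp`` sets how fast the expected read weight decays
    away from the window center.
    """

    target_total_bp: int = 300
    half_width_bp: int = 39
    adapter_total_bp: int = 76
    kernel_sd_bp: float = 39.0

    def __post_init__(self) -> None:
        if self.half_width_bp < 0:
            raise ValueError("half_width_bp must be >= 0")
        if self.adapter_total_bp >= self.target_total_bp:
            raise ValueError("adapter_total_bp must be < target_total_bp")
        if self.kernel_sd_bp <= 0:
            raise ValueError("kernel_sd_bp must be positive")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return seq


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based start positions of every motif occurrence, overlaps included.

    N bases in the sequence never match any motif position.
    """
    seq = _validate_sequence(sequence)
    return [m.start() for m in enzyme._pattern().finditer(seq)]


def double_digest(
    genome: ReferenceSequence,
    enzyme_a: RestrictionEnzyme = SPHI,
    enzyme_b: RestrictionEnzyme = MLUCI,
) -> list[Fragment]:
    """Digest every contig with both enzymes and return the fragment tiling.

    Cut coordinates are ``site_start + cut_offset`` on the top strand;
    sticky-end overhangs are ignored for fragment length. Fragments tile
    each contig exactly; zero-length fragments from coincident cuts are
    suppressed.
    """
    if enzyme_a.recognition_motif == enzyme_b.recognition_motif:
        raise ValueError("the two enzymes must have distinct motifs")
    fragments: list[Fragment] = []
    for name, seq in genome.contigs.items():
        cuts: list[tuple[int, str]] = []
        for enz in (enzyme_a, enzyme_b):
            cuts.extend((p + enz.cut_offset, enz.name) for p in find_sites(seq, enz))
        cuts = [(p, e) for p, e in cuts if 0 < p < len(seq)]
        cuts.sort()
        boundaries = [(0, CONTIG_TERMINUS)] + cuts + [(len(seq), CONTIG_TERMINUS)]
        for (s, left), (e, right) in zip(boundaries[:-1], boundaries[1:]):
            if e > s:  # coincident cuts produce zero-length fragments: drop
                fragments.append(Fragment(name, s, e, left, right))
    return fragments


def select_radtags(
    fragments: Iterable[Fragment],
    selection: SizeSelection = SizeSelection(),
) -> list[PredictedRADtag]:
    """Keep ddRAD-sequenceable fragments passing size selection.

    A fragment qualifies when its two ends were produced by *distinct
    enzymes* (one P1-side, one P2-side cut) and its adapter-inclusive
    length lies inside the collection window, boundaries inclusive.
    """
    lo = selection.target_total_bp - selection.half_width_bp
    hi = selection.target_total_bp + selection.half_width_bp
    tags = []
    for frag in fragments:
        ends = {frag.left_end, frag.right_end}
        if CONTIG_TERMINUS in ends or len(ends) != 2:
            continue
        total = frag.length + selection.adapter_total_bp
        if lo <= total <= hi:
            tags.append(
                PredictedRADtag(frag.contig, frag.start, frag.end,
                                frag.left_end, frag.right_end)
            )
    return tags


FLANK_BP = 5_000


def annotate_radtag(tag: PredictedRADtag, genome: ReferenceSequence) -> PredictedRADtag:
    """Fill in GC fraction (tag sequence only) and flanking CpG count.

    CpG dinucleotides are counted in ``[start - 5000, end + 5000)`` clipped
    at contig bounds without rescaling; N breaks both GC and CpG counts.
    """
    contig_len = genome.length(tag.contig)
    if not (0 <= tag.start < tag.end <= contig_len):
        raise ValueError(f"tag interval {tag.tag_id} outside contig bounds")
    seq = genome.sequence(tag.contig, tag.start, tag.end)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    w0 = max(0, tag.start - FLANK_BP)
    w1 = min(contig_len, tag.end + FLANK_BP)
    window = genome.sequence(tag.contig, w0, w1)
    cpg = window.count("CG")
    tag.gc_fraction = gc
    tag.cpg_flank_count = cpg
    return tag


def expected_read_weight(length: int, selection: SizeSelection = SizeSelection()) -> float:
    """Gaussian read-frequency kernel on adapter-inclusive length.

    Loci are sequenced at a frequency that falls off with the deviation of
    their total length from the size-selection target; a unit-height
    Gaussian kernel encodes that: ``exp(-(L_total - target)^2 / (2 sd^2))``.
    """
    d = length + selection.adapter_total_bp - selection.target_total_bp
    return exp(-(d * d) / (2.0 * selection.kernel_sd_bp**2))


def predict_radtags(
    genome: ReferenceSequence,
    enzyme_a: RestrictionEnzyme = SPHI,
    enzyme_b: RestrictionEnzyme = MLUCI,
    selection: SizeSelection = SizeSelection(),
) -> list[PredictedRADtag]:
    """Digest, size-select, annotate and weight: the full locus prediction."""
    tags = select_radtags(double_digest(genome, enzyme_a, enzyme_b), selection)
    for tag in tags:
        annotate_radtag(tag, genome)
        tag.read_weight = expected_read_weight(tag.length, selection)
    return tags


UNASSIGNED = "unassigned"


def tally_reads(
    alignments: Iterable[tuple[str, int, int]],
    tags: Sequence[PredictedRADtag],
) -> dict[str, int]:
    """Count reads overlapping each predicted locus by >= 1 bp.

    ``alignments`` are BED-like (contig, start, end) intervals. A read
    overlapping several tags is counted once for each; reads overlapping no
    tag accumulate in the ``"unassigned"`` bin. Malformed records raise a
    warning and are skipped.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    counts: dict[str, int] = {tag.tag_id: 0 for tag in tags}
    counts[UNASSIGNED] = 0
    for tag in tags:
        trees.setdefault(tag.contig, IntervalTree()).addi(tag.start, tag.end, tag.tag_id)
    for rec in alignments:
        try:
            contig, start, end = rec[0], int(rec[1]), int(rec[2])
            if start >= end:
                raise ValueError("empty interval")
        except (ValueError, TypeError, IndexError):
            warnings.warn(f"skipping malformed alignment record {rec!r}")
            continue
        hits = trees.get(contig, IntervalTree()).overlap(start, end)
        if not hits:
            counts[UNASSIGNED] += 1
        for hit in hits:
            counts[hit.data] += 1
    return counts


def weighted_tag_values(
    tags: Sequence[PredictedRADtag],
    counts: dict[str, int] | None,
    attribute: str,
) -> np.ndarray:
    """Per-read values of a tag attribute, repeating each tag by its read count.

    With ``counts=None`` every tag contributes once (unweighted).
    """
    values, reps = [], []
    for tag in tags:
        v = getattr(tag, attribute)
        if v is None:
            raise ValueError(f"tag {tag.tag_id} lacks attribute {attribute!r}; annotate first")
        c = 1 if counts is None else counts.get(tag.tag_id, 0)
        if c > 0:
            values.append(v)
            reps.append(c)
    return np.repeat(np.asarray(values, dtype=float), reps)


def compare_tag_distributions(
    tags_a: Sequence[PredictedRADtag],
    tags_b: Sequence[PredictedRADtag],
    counts_a: dict[str, int] | None = None,
    counts_b: dict[str, int] | None = None,
) -> dict[str, "object"]:
    """Rank-sum comparison of length / GC / flanking-CpG between two tag sets.

    Mirrors the blood-versus-feces locus-composition check: if enrichment
    systematically dropped loci of a particular length, GC or CpG density,
    the read-weighted distributions would diverge. Returns one test result
    per attribute.
    """
    from .concordance_stats import rank_sum_test

    out = {}
    for attr in ("length", "gc_fraction", "cpg_flank_count"):
        va = weighted_tag_values(tags_a, counts_a, attr)
        vb = weighted_tag_values(tags_b, counts_b, attr)
        out[attr] = rank_sum_test(va, vb)
    return out
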