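"""Genome representation, pyrimidine-oriented sequence windows, background
context counting, and telomere-distance/arm computation.

Coordinates are 0-based half-open throughout. Windows that would run off a
chromosome end are N-padded to a fixed length so that positional statistics
over window sets stay commensurable; N never matches any motif character.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from Bio import SeqIO

from .motifs import MotifSpec

ALPHABET = set("ACGTN")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class Genome:
    """An in-memory multi-chromosome genome (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]
    chrom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_names:
            self.chrom_names = list(self.sequences)
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r} has invalid residues {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]


@dataclass(frozen=True)
class OrientedWindow:
    """A fixed-width sequence window centered on a mutated position.

    `orientation` records whether the stored sequence is the reference top
    strand or its reverse complement (used to report purine-centered events
    on the pyrimidine strand).
    """

    chrom: str
    center_pos: int
    halfwidth: int
    sequence: str
    orientation: Literal["as_reference", "reverse_complemented"]

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.halfwidth + 1:
            raise ValueError("window sequence length must be 2*halfwidth+1")

    @property
    def center_base(self) -> str:
        return self.sequence[self.halfwidth]


@dataclass(frozen=True)
class ContextCounts:
    """Background counts for TriMS: occurrences of the mutated base letter
    (base_count) and of the full motif (motif_count) in the window set, with
    each window's central (mutated) position excluded."""

    base_count: int
    motif_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.motif_count <= self.base_count):
            raise ValueError("require 0 <= motif_count <= base_count")


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase input is normalized to uppercase; U is rejected (DNA only);
    duplicate headers are an error.
    """
    sequences: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN residue(s) {bad} in {rec.id!r}")
        sequences[rec.id] = seq
        order.append(rec.id)
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences=sequences, chrom_names=order)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (case preserved)."""
    bad = set(seq.upper()) - ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement residues {bad}")
    return seq.translate(_COMP)[::-1]


def oriented_window(
    genome: Genome,
    chrom: str,
    pos: int,
    halfwidth: int,
    orient_to_pyrimidine: bool = True,
) -> OrientedWindow:
    """Extract the ±halfwidth window around `pos`, N-padded at chromosome
    ends, reverse-complemented when the central base is a purine and
    pyrimidine orientation is requested."""
    seq = genome.sequences[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} out of range for {chrom}")
    lo, hi = pos - halfwidth, pos + halfwidth + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = "N" * left_pad + seq[max(0, lo) : min(hi, len(seq))] + "N" * right_pad
    orientation: Literal["as_reference", "reverse_complemented"] = "as_reference"
    if orient_to_pyrimidine and window[halfwidth] in "AG":
        window = revcomp(window)
        orientation = "reverse_complemented"
    return OrientedWindow(
        chrom=chrom,
        center_pos=pos,
        halfwidth=halfwidth,
        sequence=window,
        orientation=orientation,
    )


def count_contexts(
    windows: Iterable[OrientedWindow],
    motif_spec: MotifSpec,
    mode: Literal["double_count", "union"] = "double_count",
) -> ContextCounts:
    """Count the motif's central base letter and the full motif across a set
    of mutation-anchored windows.

    Both counts run over the same set of *viable placement offsets*: window
    positions where the full motif fits inside the window and does not
    overlap the window's central (mutated) position. The mutated base is
    never background (it cannot serve as intact motif context, and since
    the window center always carries the motif's center letter, placements
    overlapping it would trivially satisfy a flank); restricting the base
    count to the same offsets keeps the motif/base fraction an unbiased
    estimate of the local motif density, which is what makes the TriMS
    ratio center on 1 under a context-blind null.

    With ``mode="double_count"`` (default) overlapping windows contribute
    independently; with ``mode="union"`` each distinct genomic position (per
    orientation) is counted once across the whole window set.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    halfwidth = windows[0].halfwidth
    if any(w.halfwidth != halfwidth for w in windows):
        raise ValueError("all windows must share a halfwidth")
    if mode == "double_count":
        return _count_contexts_vectorized(windows, motif_spec, halfwidth)
    center_letter = motif_spec.center
    width = 2 * halfwidth + 1
    n_left, n_right = len(motif_spec.left), len(motif_spec.right)
    base_count = 0
    motif_count = 0
    seen: set[tuple[str, int, str, str]] = set()
    for w in windows:
        center = halfwidth
        for i, ch in enumerate(w.sequence):
            # viable placement offsets only: motif fits the window and does
            # not overlap the mutated central residue
            if i - n_left < 0 or i + n_right >= width:
                continue
            if i - n_left <= center <= i + n_right:
                continue
            if mode == "union":
                # map window offset back to a genome coordinate
                if w.orientation == "as_reference":
                    gpos = w.center_pos - halfwidth + i
                else:
                    gpos = w.center_pos + halfwidth - i
                key_base = (w.chrom, gpos, w.orientation, "base")
                key_motif = (w.chrom, gpos, w.orientation, "motif")
            if ch == center_letter:
                if mode == "union":
                    if key_base not in seen:
                        seen.add(key_base)
                        base_count += 1
                else:
                    base_count += 1
            if motif_spec.matches_at(w.sequence, i):
                if mode == "union":
                    if key_motif not in seen:
                        seen.add(key_motif)
                        motif_count += 1
                else:
                    motif_count += 1
    return ContextCounts(base_count=base_count, motif_count=motif_count)


def _flank_condition(arr, pat: str):
    """Elementwise match of a motif flank character against a base array."""
    import numpy as np

    if pat == "n":  # any ordinary base, but never N
        out = np.zeros(arr.shape, dtype=bool)
        for b in "ACGT":
            out |= arr == ord(b)
        return out
    return arr == ord(pat.upper())


def _count_contexts_vectorized(
    windows: list[OrientedWindow], motif_spec: MotifSpec, halfwidth: int
) -> ContextCounts:
    """numpy path for the default double-count mode (same semantics as the
    per-character scan)."""
    import numpy as np

    width = 2 * halfwidth + 1
    arr = np.frombuffer(
        "".join(w.sequence for w in windows).encode(), dtype=np.uint8
    ).reshape(len(windows), width)
    n_left, n_right = len(motif_spec.left), len(motif_spec.right)
    cols = np.arange(width)
    viable = (cols >= n_left) & (cols <= width - 1 - n_right)
    viable &= ~((cols >= halfwidth - n_right) & (cols <= halfwidth + n_left))
    m_center = arr == ord(motif_spec.center)
    base_count = int(m_center[:, viable].sum())
    match = m_center.copy()
    if motif_spec.left:
        ok = np.zeros_like(match)
        ok[:, 1:] = _flank_condition(arr[:, :-1], motif_spec.left)
        match &= ok
    if motif_spec.right:
        ok = np.zeros_like(match)
        ok[:, :-1] = _flank_condition(arr[:, 1:], motif_spec.right)
        match &= ok
    return ContextCounts(base_count=base_count, motif_count=int(match[:, viable].sum()))


def telomere_distance(genome: Genome, chrom: str, pos: int) -> tuple[int, str]:
    """Distance (bp) to the nearest chromosome end and the arm it falls on.

    Returns ``(distance, arm)`` with arm "left" when pos < length/2 and
    "right" otherwise (midpoint ties go right).
    """
    length = len(genome.sequences[chrom])
    if not 0 <= pos < length:
        raise IndexError(f"position {pos} out of range for {chrom}")
    dist = min(pos, length - 1 - pos)
    arm = "left" if pos < length / 2 else "right"
    return dist, arm
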