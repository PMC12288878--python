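"""Pyrimidine-collapsed and strand/arm-aware SBS spectra.

Substitutions are reported as pyrimidine changes per standard convention: a
purine-centered event is replaced by its reverse complement (G→C becomes
C→G), and its ±20 bp window is reverse-complemented along with it. Events
are classified as sub-telomeric (within 30 kb of a chromosome end by
default, boundary inclusive — the expected extent of 5'→3' resection from
an uncapped telomere) or mid-chromosomal, and by chromosome arm.

Under the resection model the exposed ssDNA is the bottom strand on left
arms and the top strand on right arms; a lesion on a guanine of the exposed
strand is therefore read out as a top-strand C→N change on left arms and a
top-strand G→N change on right arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from .genome_context import Genome, OrientedWindow, oriented_window, revcomp, telomere_distance
from .variants import VariantRecord, VarClass

PYR_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
CHANNELS_96 = [
    f"{l}[{cls}]{r}" for cls in PYR_CLASSES for l in BASES for r in BASES
]

DEFAULT_SUBTEL_BP = 30_000


@dataclass(frozen=True)
class CollapsedSub:
    """A single substitution collapsed to the pyrimidine strand."""

    pyr_class: str
    trinucleotide: str
    window: OrientedWindow
    record: VariantRecord

    def __post_init__(self) -> None:
        if self.pyr_class not in PYR_CLASSES:
            raise ValueError(f"bad pyrimidine class {self.pyr_class!r}")
        if self.trinucleotide != self.window.sequence[
            self.window.halfwidth - 1 : self.window.halfwidth + 2
        ]:
            raise ValueError("trinucleotide must equal the window center")


@dataclass(frozen=True)
class LocationCall:
    distance_bp: int
    zone: Literal["sub_telomeric", "mid_chromosomal"]
    arm: Literal["left", "right"]


def collapse_to_pyrimidine(
    record: VariantRecord, genome: Genome, halfwidth: int = 20
) -> CollapsedSub:
    """Collapse an SNV to its pyrimidine-strand representation with its
    oriented ±halfwidth window."""
    if record.var_class is not VarClass.SNV:
        raise ValueError("collapse_to_pyrimidine expects an SNV")
    ref_base = genome.base(record.chrom, record.pos0)
    if ref_base != record.ref:
        raise ValueError(
            f"REF mismatch at {record.chrom}:{record.pos0}: "
            f"genome {ref_base}, record {record.ref}"
        )
    win = oriented_window(genome, record.chrom, record.pos0, halfwidth, True)
    if record.ref in "AG":
        ref, alt = revcomp(record.ref), revcomp(record.alt)
    else:
        ref, alt = record.ref, record.alt
    tri = win.sequence[halfwidth - 1 : halfwidth + 2]
    return CollapsedSub(
        pyr_class=f"{ref}>{alt}", trinucleotide=tri, window=win, record=record
    )


def classify_location(
    genome: Genome, record: VariantRecord, threshold_bp: int = DEFAULT_SUBTEL_BP
) -> LocationCall:
    """Sub-telomeric vs mid-chromosomal call (boundary inclusive) plus arm."""
    dist, arm = telomere_distance(genome, record.chrom, record.pos0)
    zone = "sub_telomeric" if dist <= threshold_bp else "mid_chromosomal"
    return LocationCall(distance_bp=dist, zone=zone, arm=arm)


def lesion_strand(
    location: LocationCall, reported_ref: str
) -> Optional[Literal["top", "bottom"]]:
    """Strand carrying the damaged purine for a sub-telomeric substitution.

    A top-strand C→N change implies the lesion guanine sat on the bottom
    strand; a top-strand G→N change implies the top strand. Returns None
    (flagged undefined) for mid-chromosomal input, where no strand is
    predicted to have been single-stranded.
    """
    if location.zone != "sub_telomeric":
        return None
    if reported_ref in "CT":
        return "bottom"
    if reported_ref in "AG":
        return "top"
    raise ValueError(f"bad reference base {reported_ref!r}")


@dataclass
class SpectrumTable:
    """6-class / 96-channel tallies, per-arm reference-strand tallies, and
    per-bp-per-isolate densities."""

    counts6: pd.Series
    counts96: pd.Series
    arm_counts: pd.DataFrame  # index: arm; columns: reference-strand base change
    zone_counts: pd.Series  # sub_telomeric / mid_chromosomal
    n_isolates: int
    ssdna_bp: int
    density: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        total = int(self.counts6.sum())
        if int(self.counts96.sum()) != total:
            raise ValueError("96-channel and 6-class totals disagree")
        self.density = self.counts6 / (self.ssdna_bp * self.n_isolates)

    @property
    def total(self) -> int:
        return int(self.counts6.sum())


def default_ssdna_bp(genome: Genome, threshold_bp: int = DEFAULT_SUBTEL_BP) -> int:
    """Default density denominator: two resectable arms of `threshold_bp`
    per chromosome (capped by chromosome length)."""
    return sum(
        min(2 * threshold_bp, length) for length in genome.lengths.values()
    )


def build_spectrum(
    records: Iterable[VariantRecord],
    genome: Genome,
    n_isolates: int,
    ssdna_bp: Optional[int] = None,
    threshold_bp: int = DEFAULT_SUBTEL_BP,
    halfwidth: int = 20,
) -> SpectrumTable:
    """Tally the collapsed SBS spectrum of a record set.

    Per-arm tallies are kept in *reference-strand* (uncollapsed) terms for
    sub-telomeric events only, which is what exposes the reciprocal
    left-arm C→N / right-arm G→N ssDNA strand bias.
    """
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    if ssdna_bp is None:
        ssdna_bp = default_ssdna_bp(genome, threshold_bp)
    if ssdna_bp <= 0:
        raise ValueError("ssdna_bp must be positive")
    counts6 = pd.Series(0, index=PYR_CLASSES, dtype=int)
    counts96 = pd.Series(0, index=CHANNELS_96, dtype=int)
    ref_changes = [f"{a}>{b}" for a in BASES for b in BASES if a != b]
    arm_counts = pd.DataFrame(
        0, index=["left", "right"], columns=ref_changes, dtype=int
    )
    zone_counts = pd.Series(
        0, index=["sub_telomeric", "mid_chromosomal"], dtype=int
    )
    for rec in records:
        if rec.var_class is not VarClass.SNV:
            continue
        sub = collapse_to_pyrimidine(rec, genome, halfwidth)
        l, r = sub.trinucleotide[0], sub.trinucleotide[2]
        if l not in BASES or r not in BASES:
            # terminal base with no defined trinucleotide: excluded from all
            # tallies so the 6-class/96-channel/total invariant holds
            continue
        counts6[sub.pyr_class] += 1
        counts96[f"{l}[{sub.pyr_class}]{r}"] += 1
        loc = classify_location(genome, rec, threshold_bp)
        zone_counts[loc.zone] += 1
        if loc.zone == "sub_telomeric":
            arm_counts.loc[loc.arm, f"{rec.ref}>{rec.alt}"] += 1
    return SpectrumTable(
        counts6=counts6,
        counts96=counts96,
        arm_counts=arm_counts,
        zone_counts=zone_counts,
        n_isolates=n_isolates,
        ssdna_bp=ssdna_bp,
    )
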