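"""Synthetic genomes and mutation implants with ground truth.

The generator emulates the ssDNA-reporter study design: a multi-chromosome
genome whose 30 kb chromosome ends are the resectable (single-strandable)
zone; per-isolate SBS sets concentrated in that zone (default 91%) with a
configurable trinucleotide-motif preference (default cCg→G at target
enrichment 4), arm-appropriate lesion strandedness, and INDEL/DBS/MBS
events with a controlled templated ("copy neighbor") fraction. Every
implant is emitted with a truth record that downstream modules can
re-derive from the sequence alone.

Motif-site selection: within the chosen zone a mutation lands on a
motif-matching central-base site with probability

    p_m = E* f / (1 + (E* - 1) f),   f = motif sites / central-base sites,

which makes the motif/non-motif odds ratio of implanted mutations exactly
E*; the TriMS ratio-of-proportions estimate is then E*/(1 + (E*-1) f),
indistinguishable from E* at small f. Signature implants always carry the
motif's alt allele (for cCg→G this is intrinsically a copy of the +1
guanine, the proposed slippage product); a separate channel
(:func:`implant_slippage_sbs`) gives exact control of the SBS templated
fraction for detector validation.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_context import Genome, write_fasta
from .motifs import MotifSpec
from .variants import VariantRecord, write_vcf

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_INDEL_MIX = {"INS": 0.45, "DEL": 0.33, "DBS": 0.17, "MBS": 0.05}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the yeast experiment the generator stands in for:
    16 chromosomes, 114 isolates averaging 761/114 ≈ 6.7 SBS each, 91% of
    substitutions within 30 kb of a telomere, cCg→G as the implanted motif,
    and perfect arm-appropriate strandedness.
    """

    seed: int = 0
    n_chrom: int = 16
    chrom_length: int = 200_000
    gc_fraction: float = 0.38
    n_isolates: int = 114
    muts_per_isolate: float = 761 / 114
    motif: MotifSpec = field(default_factory=lambda: MotifSpec("cCg", "G"))
    target_enrichment: float = 4.0
    subtel_fraction: float = 0.91
    subtel_threshold: int = 30_000
    strand_fidelity: float = 1.0
    indel_rate: float = 76 / 114
    templated_fraction: float = 0.8
    indel_mix: dict = field(default_factory=lambda: dict(DEFAULT_INDEL_MIX))
    del_run_bias: float = 0.4
    template_window: int = 10

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        for name in ("gc_fraction", "subtel_fraction", "strand_fidelity",
                     "templated_fraction", "del_run_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_enrichment < 1.0:
            raise ValueError("target_enrichment must be >= 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["motif"] = {"pattern": self.motif.pattern, "alt": self.motif.alt}
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted event."""

    sample_id: str
    chrom: str
    pos0: int
    ref: str
    alt: str
    event_class: str
    is_motif_site: Optional[bool] = None
    zone: Optional[str] = None
    arm: Optional[str] = None
    lesion_strand: Optional[str] = None
    is_templated: Optional[bool] = None


def simulate_genome(config: SimConfig) -> Genome:
    """I.i.d. bases at the configured GC fraction; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(["A", "C", "G", "T"])
    seqs = {}
    names = []
    for i in range(config.n_chrom):
        name = f"chr{i + 1:02d}"
        draw = rng.choice(4, size=config.chrom_length, p=probs)
        seqs[name] = "".join(bases[draw])
        names.append(name)
    return Genome(sequences=seqs, chrom_names=names)


# ---------------------------------------------------------------------------
# site indexing


def _flank_ok(a: np.ndarray, idx: np.ndarray, offset: int, pat: str) -> np.ndarray:
    """Boolean mask over `idx` for a motif flank character at `offset`."""
    if not pat or pat == "n":
        return np.ones(idx.size, dtype=bool)
    return a[idx + offset] == ord(pat.upper())


class SiteIndex:
    """Candidate mutation sites of a genome for one motif.

    Sub-telomeric sites are stratified by whether their reported top-strand
    spelling is the arm-"proper" one under the resection model (left-arm
    ssDNA is the bottom strand, so a proper left-arm site reads the
    pyrimidine center on top; right arms are the mirror image), and by
    motif membership. Mid-chromosomal sites are stratified by spelling
    ("pyr" = motif on the top strand, "pur" = reverse-complement spelling).
    Each pool is a (n, 2) array of (chromosome index, position).
    """

    def __init__(self, genome: Genome, motif: MotifSpec, threshold_bp: int):
        self.genome = genome
        self.motif = motif
        self.threshold_bp = threshold_bp
        center = motif.center
        c_comp = _COMP[center]
        pools: dict[tuple, list[np.ndarray]] = {}
        for ci, name in enumerate(genome.chrom_names):
            seq = genome.sequences[name]
            a = np.frombuffer(seq.encode(), dtype=np.uint8)
            L = len(a)
            interior = np.arange(1, L - 1)
            dist = np.minimum(interior, L - 1 - interior)
            subtel = dist <= threshold_bp
            left_arm = interior < L / 2
            is_c = a[interior] == ord(center)
            is_g = a[interior] == ord(c_comp)
            motif_top = (
                is_c
                & _flank_ok(a, interior, -1, motif.left)
                & _flank_ok(a, interior, +1, motif.right)
            )
            motif_bot = (
                is_g
                & _flank_ok(a, interior, -1, _comp_pat(motif.right))
                & _flank_ok(a, interior, +1, _comp_pat(motif.left))
            )
            proper = (left_arm & is_c) | (~left_arm & is_g)
            strata = {}
            for is_motif in (True, False):
                mmask = motif_top | motif_bot
                base = mmask if is_motif else (is_c | is_g) & ~mmask
                strata[("sub_telomeric", "proper", is_motif)] = subtel & base & proper
                strata[("sub_telomeric", "improper", is_motif)] = subtel & base & ~proper
                strata[("mid_chromosomal", "pyr", is_motif)] = ~subtel & base & is_c
                strata[("mid_chromosomal", "pur", is_motif)] = ~subtel & base & is_g
            for key, mask in strata.items():
                pos = interior[mask]
                arr = np.column_stack([np.full(pos.size, ci), pos])
                pools.setdefault(key, []).append(arr)
        self.sites: dict[tuple, np.ndarray] = {
            key: np.concatenate(chunks) for key, chunks in pools.items()
        }

    def pool(self, *key) -> np.ndarray:
        return self.sites[key]

    def motif_fraction(self, zone: str) -> float:
        strata = ("proper", "improper") if zone == "sub_telomeric" else ("pyr", "pur")
        motif_n = sum(len(self.sites[(zone, s, True)]) for s in strata)
        total = motif_n + sum(len(self.sites[(zone, s, False)]) for s in strata)
        if total == 0:
            raise ValueError(f"no candidate sites in zone {zone}")
        return motif_n / total


def _comp_pat(pat: str) -> str:
    if not pat or pat == "n":
        return pat
    return _COMP[pat.upper()].lower()


# ---------------------------------------------------------------------------
# SBS implants


def implant_sbs(
    genome: Genome,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    site_index: Optional[SiteIndex] = None,
    n_isolates: Optional[int] = None,
) -> tuple[dict[str, list[VariantRecord]], list[TruthRecord]]:
    """Implant the signature SBS channel: per-isolate Poisson mutation
    counts, sub-telomeric placement, motif-site selection calibrated to the
    target enrichment, and arm-appropriate strandedness."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    idx = site_index or SiteIndex(genome, config.motif, config.subtel_threshold)
    e_star = config.target_enrichment
    p_m: dict[str, float] = {}
    zones = []
    for zone, strata in (
        ("sub_telomeric", ("proper", "improper")),
        ("mid_chromosomal", ("pyr", "pur")),
    ):
        if not any(len(idx.sites[(zone, s, m)]) for s in strata for m in (True, False)):
            continue  # zone absent (e.g. short chromosomes fully resectable)
        zones.append(zone)
        f = idx.motif_fraction(zone)
        if e_star * f > 1.0:
            raise ValueError(
                f"target enrichment {e_star} infeasible at motif density {f:.3g}"
            )
        p_m[zone] = e_star * f / (1.0 + (e_star - 1.0) * f)
    if not zones:
        raise ValueError("no candidate sites anywhere in the genome")
    subtel_p = config.subtel_fraction if len(zones) == 2 else (
        1.0 if zones == ["sub_telomeric"] else 0.0
    )
    half = {n: len(genome.sequences[n]) / 2 for n in genome.chrom_names}
    isolates: dict[str, list[VariantRecord]] = {}
    truth: list[TruthRecord] = []
    for k in range(n_isolates if n_isolates is not None else config.n_isolates):
        sample = f"iso{k + 1:03d}"
        n_mut = rng.poisson(config.muts_per_isolate)
        used: set[tuple[int, int]] = set()
        recs: list[VariantRecord] = []
        for _ in range(n_mut):
            zone = (
                "sub_telomeric" if rng.random() < subtel_p else "mid_chromosomal"
            )
            is_motif = rng.random() < p_m[zone]
            for _attempt in range(200):
                if zone == "sub_telomeric":
                    stratum = (
                        "proper"
                        if rng.random() < config.strand_fidelity
                        else "improper"
                    )
                else:
                    stratum = "pyr" if rng.random() < 0.5 else "pur"
                pool = idx.pool(zone, stratum, is_motif)
                ci, pos = (int(v) for v in pool[rng.integers(len(pool))])
                if (ci, pos) not in used:
                    used.add((ci, pos))
                    break
            else:  # pragma: no cover - pathological saturation
                continue
            chrom = genome.chrom_names[ci]
            seq = genome.sequences[chrom]
            ref = seq[pos]
            alt = config.motif.alt if ref == config.motif.center else _COMP[config.motif.alt]
            templated = (pos + 1 < len(seq) and seq[pos + 1] == alt) or (
                pos >= 1 and seq[pos - 1] == alt
            )
            arm = "left" if pos < half[chrom] else "right"
            recs.append(
                VariantRecord(
                    chrom=chrom, pos0=pos, ref=ref, alt=alt,
                    sample_id=sample, vaf=float(rng.uniform(0.9, 1.0)),
                )
            )
            truth.append(
                TruthRecord(
                    sample_id=sample, chrom=chrom, pos0=pos, ref=ref, alt=alt,
                    event_class="SNV", is_motif_site=bool(is_motif), zone=zone,
                    arm=arm,
                    lesion_strand="bottom" if ref in "CT" else "top",
                    is_templated=bool(templated),
                )
            )
        isolates[sample] = sorted(recs, key=lambda r: (r.chrom, r.pos0))
    return isolates, truth


def implant_slippage_sbs(
    genome: Genome,
    n_events: int,
    templated_fraction: float,
    rng: np.random.Generator,
    sample_id: str = "slip",
) -> tuple[list[VariantRecord], list[TruthRecord]]:
    """Neighbor-copy SBS channel with an exactly controlled templated
    fraction: templated events copy a neighboring base, non-templated
    events draw an alt differing from the ref and both neighbors."""
    recs: list[VariantRecord] = []
    truth: list[TruthRecord] = []
    names = genome.chrom_names
    while len(recs) < n_events:
        # draw the templated coin first, then find a position that can
        # realize it, so the realized fraction is exactly the configured one
        templated = rng.random() < templated_fraction
        while True:
            chrom = names[rng.integers(len(names))]
            seq = genome.sequences[chrom]
            pos = int(rng.integers(1, len(seq) - 1))
            ref, up, down = seq[pos], seq[pos - 1], seq[pos + 1]
            if templated:
                choices = [b for b in (down, up) if b != ref]
            else:
                choices = [b for b in "ACGT" if b not in (ref, up, down)]
            if choices:
                break
        alt = choices[0] if len(choices) == 1 else choices[rng.integers(len(choices))]
        recs.append(
            VariantRecord(chrom=chrom, pos0=pos, ref=ref, alt=alt,
                          sample_id=sample_id, vaf=1.0)
        )
        truth.append(
            TruthRecord(sample_id=sample_id, chrom=chrom, pos0=pos, ref=ref,
                        alt=alt, event_class="SNV", is_templated=templated)
        )
    return recs, truth


# ---------------------------------------------------------------------------
# INDEL / DBS / MBS implants


def _run_positions_cg(seq: str, min_run: int) -> list[int]:
    """Positions inside C/G homopolymer runs of >= min_run."""
    out = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j + 1 < L and seq[j + 1] == seq[i]:
            j += 1
        if seq[i] in "CG" and j - i + 1 >= min_run:
            out.extend(range(i, j + 1))
        i = j + 1
    return out


def implant_indels(
    genome: Genome,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_events: Optional[int] = None,
    sample_id: str = "indel",
) -> tuple[list[VariantRecord], list[TruthRecord]]:
    """Implant INS/DEL/DBS/MBS events with a controlled templated fraction.

    Templated insertions copy the next reference base (Rm→RMm); templated
    DBS/MBS copy a reference substring within the ±template_window;
    non-templated events are constructed to fail the corresponding
    detector. Deletions are biased into C/G homopolymer runs with
    probability `del_run_bias`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if n_events is None:
        n_events = int(rng.poisson(config.indel_rate * config.n_isolates))
    classes = list(config.indel_mix)
    weights = np.array([config.indel_mix[c] for c in classes], dtype=float)
    weights /= weights.sum()
    run_pos = {
        name: _run_positions_cg(genome.sequences[name], 3)
        for name in genome.chrom_names
    }
    recs: list[VariantRecord] = []
    truth: list[TruthRecord] = []
    names = genome.chrom_names
    w = config.template_window
    while len(recs) < n_events:
        # class and templated coin are drawn first and held while positions
        # are resampled, keeping the realized templated fraction exact
        cls = classes[rng.choice(len(classes), p=weights)]
        templated: Optional[bool] = bool(rng.random() < config.templated_fraction)
        made = None
        while made is None:
            chrom = names[rng.integers(len(names))]
            seq = genome.sequences[chrom]
            L = len(seq)
            if cls == "INS":
                i = int(rng.integers(1, L - 2))
                if templated:
                    ins = seq[i + 1]
                else:
                    choices = [b for b in "ACGT" if b not in (seq[i], seq[i + 1])]
                    ins = choices[rng.integers(len(choices))]
                made = VariantRecord(chrom=chrom, pos0=i, ref=seq[i],
                                     alt=seq[i] + ins, sample_id=sample_id, vaf=1.0)
            elif cls == "DEL":
                if rng.random() < config.del_run_bias and run_pos[chrom]:
                    d = run_pos[chrom][rng.integers(len(run_pos[chrom]))]
                    if d < 1:
                        continue
                else:
                    d = int(rng.integers(1, L - 1))
                made = VariantRecord(chrom=chrom, pos0=d - 1,
                                     ref=seq[d - 1 : d + 1], alt=seq[d - 1],
                                     sample_id=sample_id, vaf=1.0)
                templated = None  # deletions carry no templated construction
            else:
                k = 2 if cls == "DBS" else 3
                s = int(rng.integers(w + k + 1, L - w - 2 * k - 1))
                span = seq[s : s + k]
                neighborhood = seq[max(0, s - w - k) : s + k + w + k]
                if templated:
                    cands = []
                    for j in range(max(0, s - w - k), s + k + w + 1):
                        if j == s or j + k > L:
                            continue
                        t = seq[j : j + k]
                        if all(t[q] != span[q] for q in range(k)):
                            cands.append(t)
                    if not cands:
                        continue
                    alt = cands[rng.integers(len(cands))]
                else:
                    alts = []
                    for combo in itertools.product(
                        *[[b for b in "ACGT" if b != span[q]] for q in range(k)]
                    ):
                        t = "".join(combo)
                        if t not in neighborhood:
                            alts.append(t)
                    if not alts:
                        continue
                    alt = alts[rng.integers(len(alts))]
                made = VariantRecord(chrom=chrom, pos0=s, ref=span, alt=alt,
                                     sample_id=sample_id, vaf=1.0)
        recs.append(made)
        truth.append(
            TruthRecord(
                sample_id=sample_id, chrom=made.chrom, pos0=made.pos0,
                ref=made.ref, alt=made.alt, event_class=made.var_class.value,
                is_templated=templated,
            )
        )
    return recs, truth


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SimResult:
    config: SimConfig
    genome: Genome
    isolates: dict[str, list[VariantRecord]]
    truth: list[TruthRecord]

    def all_records(self) -> list[VariantRecord]:
        return [r for recs in self.isolates.values() for r in recs]

    def to_directory(self, outdir) -> None:
        """Write FASTA genome, per-isolate VCFs, truth JSON and config JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        lengths = self.genome.lengths
        for sample, recs in self.isolates.items():
            write_vcf(recs, outdir / f"{sample}.vcf", contigs=lengths)
        with open(outdir / "truth.json", "w") as fh:
            json.dump([dataclasses.asdict(t) for t in self.truth], fh, indent=1)
        with open(outdir / "config.json", "w") as fh:
            fh.write(self.config.to_json())


def simulate_dataset(config: SimConfig, with_indels: bool = True) -> SimResult:
    """Full dataset: genome, signature SBS implants per isolate, and (by
    default) an INDEL/DBS/MBS channel appended to random isolates."""
    genome = simulate_genome(config)
    rng = np.random.default_rng(config.seed + 1)
    isolates, truth = implant_sbs(genome, config, rng)
    if with_indels and config.indel_rate > 0:
        samples = list(isolates)
        indel_recs, indel_truth = implant_indels(genome, config, rng)
        for rec, tr in zip(indel_recs, indel_truth):
            sample = samples[rng.integers(len(samples))]
            rec = dataclasses.replace(rec, sample_id=sample)
            tr = dataclasses.replace(tr, sample_id=sample)
            isolates[sample].append(rec)
            truth.append(tr)
        for sample in samples:
            isolates[sample].sort(key=lambda r: (r.chrom, r.pos0))
    return SimResult(config=config, genome=genome, isolates=isolates, truth=truth)
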