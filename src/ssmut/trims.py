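"""The TriMS statistic: motif-conditioned mutation enrichment with exact
one-sided inference and minimum mutation loads.

For a mutable motif such as cCg→G the enrichment is

    E = (Mutations_cCg→G × Context_C) / (Mutations_C→G × Context_ccg)

i.e. the fraction of C→G mutations carrying the cCg context divided by the
fraction of background cytosines (within the mutation-anchored ±20 nt
windows, mutated residues excluded) that sit in a ccg context. A one-sided
Fisher exact test on the 2×2 table (mutations, contexts) × (motif,
non-motif) gives the p-value for over-representation; Benjamini–Hochberg
correction is applied across the scanned family (the motifs of one scan, or
the samples of one cohort — never pooled). The minimum mutation load
attributable to the signature is

    Mutload = Mutations_motif × (E − 1) / E

reported only when E > 1 and the corrected p passes the cutoff (default
q ≤ 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genome_context import ContextCounts, count_contexts
from .motifs import MotifSpec
from .spectrum import CollapsedSub

DEFAULT_Q_CUTOFF = 0.05


@dataclass
class EnrichmentResult:
    """TriMS counts and statistics for one motif (or one sample)."""

    motif: MotifSpec
    mut_motif: int
    mut_total: int
    ctx: ContextCounts
    enrichment: Optional[float]
    p: float
    q: float = field(default=np.nan)
    load: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mut_motif > self.mut_total:
            raise ValueError("mut_motif cannot exceed mut_total")


def compute_enrichment(
    mut_motif: int, mut_total: int, ctx_motif: int, ctx_base: int
) -> Optional[float]:
    """Ratio-of-proportions enrichment; None when a denominator is zero
    (reported as missing, never silently 0 or infinity)."""
    if mut_total == 0 or ctx_motif == 0:
        return None
    return (mut_motif * ctx_base) / (mut_total * ctx_motif)


def fisher_one_sided(
    mut_motif: int, mut_nonmotif: int, ctx_motif: int, ctx_nonmotif: int
) -> float:
    """Right-tail Fisher exact p for over-representation of the motif among
    mutations relative to background contexts.

    Exact integer hypergeometric tail: with row margin n = mut_motif +
    mut_nonmotif, column margin K = mut_motif + ctx_motif and total N, the
    p-value is P[X >= mut_motif] for X ~ Hypergeom(N, K, n).
    """
    for c in (mut_motif, mut_nonmotif, ctx_motif, ctx_nonmotif):
        if c < 0:
            raise ValueError("counts must be nonnegative")
    n = mut_motif + mut_nonmotif
    K = mut_motif + ctx_motif
    N = n + ctx_motif + ctx_nonmotif
    if N == 0 or n == 0 or K == 0:
        return 1.0
    hi = min(n, K)
    numer = sum(comb(K, k) * comb(N - K, n - k) for k in range(mut_motif, hi + 1))
    return min(1.0, numer / comb(N, n))


def bh_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def mutation_load(
    mut_motif: int,
    enrichment: Optional[float],
    q: float,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> float:
    """Minimum mutation load M × (E − 1)/E; zero unless E > 1 and q passes."""
    if enrichment is None or enrichment <= 1.0 or not q <= q_cutoff:
        return 0.0
    return mut_motif * (enrichment - 1.0) / enrichment


def single_base_family(center: str, alt: str) -> list[MotifSpec]:
    """All fully-specified single-flank trinucleotide motifs xCy→alt for a
    given collapsed base change (the family scanned per figure-style
    context analyses)."""
    return [
        MotifSpec(pattern=f"{l}{center}{r}", alt=alt)
        for l in "acgt"
        for r in "acgt"
    ]


def evaluate_motif(
    collapsed_subs: Sequence[CollapsedSub],
    motif: MotifSpec,
    context_mode: str = "double_count",
) -> EnrichmentResult:
    """TriMS counts, enrichment and raw p for one motif against the windows
    of the given base-change substitutions (q/load filled in by the caller
    after family-wise correction)."""
    change = f"{motif.center}>{motif.alt}"
    subs = [s for s in collapsed_subs if s.pyr_class == change]
    if not subs:
        raise ValueError(f"no substitutions of class {change}")
    mut_motif = sum(
        1
        for s in subs
        if motif.matches_context(s.trinucleotide[0], s.trinucleotide[2])
    )
    mut_total = len(subs)
    ctx = count_contexts([s.window for s in subs], motif, mode=context_mode)
    enr = compute_enrichment(mut_motif, mut_total, ctx.motif_count, ctx.base_count)
    p = fisher_one_sided(
        mut_motif,
        mut_total - mut_motif,
        ctx.motif_count,
        ctx.base_count - ctx.motif_count,
    )
    return EnrichmentResult(
        motif=motif, mut_motif=mut_motif, mut_total=mut_total, ctx=ctx,
        enrichment=enr, p=p,
    )


def scan_motifs(
    collapsed_subs: Sequence[CollapsedSub],
    base_change: str,
    motif_family: Optional[Iterable[MotifSpec]] = None,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    context_mode: str = "double_count",
) -> list[EnrichmentResult]:
    """Scan a family of motifs for one collapsed base change ("C>G" etc.),
    with BH correction across the family and loads for passing motifs.

    Motifs whose enrichment is undefined (zero denominator) are excluded
    from the BH family and reported with q = NaN.
    """
    center, alt = base_change.split(">")
    if motif_family is None:
        motif_family = single_base_family(center, alt)
    motifs = list(motif_family)
    for m in motifs:
        if m.center != center or m.alt != alt:
            raise ValueError(f"motif {m} does not match base change {base_change}")
    subs = [s for s in collapsed_subs if s.pyr_class == base_change]
    if not subs:
        return []
    results = [evaluate_motif(subs, m, context_mode) for m in motifs]
    defined = [r for r in results if r.enrichment is not None]
    qs = bh_correct([r.p for r in defined])
    for r, q in zip(defined, qs):
        r.q = q
        r.load = mutation_load(r.mut_motif, r.enrichment, q, q_cutoff)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Tabulate enrichment results (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "motif": [r.motif.pattern for r in results],
            "alt": [r.motif.alt for r in results],
            "mut_motif": [r.mut_motif for r in results],
            "mut_total": [r.mut_total for r in results],
            "ctx_motif": [r.ctx.motif_count for r in results],
            "ctx_base": [r.ctx.base_count for r in results],
            "enrichment": [r.enrichment for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "load": [r.load for r in results],
        }
    )
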