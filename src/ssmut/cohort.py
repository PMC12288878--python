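"""Per-sample signature scanning over a somatic cohort.

Each sample's substitutions of the motif's base change are tested with
TriMS against its own mutation-anchored background windows; BH correction
runs across the samples of the cohort. A sample is "enriched" when its
enrichment is >= 1 and its corrected p passes the cutoff; cohort summaries
report the enriched count and the median motif mutation load among
enriched samples ("NA" when none are). Cumulative motif counts include
both strand spellings automatically via pyrimidine collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genome_context import Genome
from .motifs import MotifSpec
from .spectrum import collapse_to_pyrimidine
from .trims import (
    DEFAULT_Q_CUTOFF,
    EnrichmentResult,
    bh_correct,
    evaluate_motif,
    mutation_load,
)
from .variants import VariantRecord, VarClass


@dataclass
class CohortSummary:
    cohort: str
    n_samples: int
    n_enriched: int
    median_load_enriched: Optional[float]

    def __post_init__(self) -> None:
        if not 0 <= self.n_enriched <= self.n_samples:
            raise ValueError("0 <= n_enriched <= n_samples required")

    @property
    def median_display(self) -> str:
        if self.median_load_enriched is None:
            return "NA"
        return f"{self.median_load_enriched:.2f}"


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r2: float
    p_two_tailed: float


def dedupe_somatic(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Exact (sample, chrom, pos, ref, alt) de-duplication."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        k = (r.sample_id, *r.key)
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out


def per_sample_scan(
    cohort_variants: Mapping[str, Sequence[VariantRecord]] | Sequence[VariantRecord],
    genome: Genome,
    motif_spec: MotifSpec,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    halfwidth: int = 20,
) -> list[EnrichmentResult]:
    """One TriMS result per sample for a single motif, BH across samples.

    Samples with no substitutions of the base change, or an undefined
    enrichment, are reported with NaN statistics and excluded from BH.
    """
    if not isinstance(cohort_variants, Mapping):
        grouped: dict[str, list[VariantRecord]] = {}
        for r in cohort_variants:
            grouped.setdefault(r.sample_id, []).append(r)
        cohort_variants = grouped
    change = f"{motif_spec.center}>{motif_spec.alt}"
    results: list[EnrichmentResult] = []
    for sample, records in cohort_variants.items():
        records = dedupe_somatic(list(records))
        subs = [
            collapse_to_pyrimidine(r, genome, halfwidth)
            for r in records
            if r.var_class is VarClass.SNV
        ]
        subs = [s for s in subs if s.pyr_class == change]
        if not subs:
            res = EnrichmentResult(
                motif=motif_spec, mut_motif=0, mut_total=0,
                ctx=None, enrichment=None, p=np.nan, sample_id=sample,  # type: ignore[arg-type]
            )
        else:
            res = evaluate_motif(subs, motif_spec)
            res.sample_id = sample
        results.append(res)
    testable = [r for r in results if r.enrichment is not None]
    qs = bh_correct([r.p for r in testable])
    for r, q in zip(testable, qs):
        r.q = q
        r.load = mutation_load(r.mut_motif, r.enrichment, q, q_cutoff)
    return results


def summarize_cohort(
    results: Sequence[EnrichmentResult],
    cutoff: float = DEFAULT_Q_CUTOFF,
    cohort: str = "",
) -> CohortSummary:
    """Enriched-sample count (enrichment >= 1, q <= cutoff) and the median
    motif mutation load among enriched samples."""
    enriched = [
        r
        for r in results
        if r.enrichment is not None and r.enrichment >= 1.0 and r.q <= cutoff
    ]
    loads = [r.mut_motif * (r.enrichment - 1.0) / r.enrichment for r in enriched]
    return CohortSummary(
        cohort=cohort,
        n_samples=len(results),
        n_enriched=len(enriched),
        median_load_enriched=median(loads) if loads else None,
    )


def correlate_indels_vs_signature(
    per_sample_motif_counts: Sequence[float],
    per_sample_repeat_indels: Sequence[float],
) -> Optional[CorrelationResult]:
    """Pearson correlation (r, r², two-tailed p via the t distribution with
    n−2 df) between cumulative motif mutations and repeat-INDEL counts.

    Returns None (missing) when either vector has zero variance.
    """
    x = np.asarray(per_sample_motif_counts, dtype=float)
    y = np.asarray(per_sample_repeat_indels, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(n=int(x.size), r=float(r), r2=float(r) ** 2,
                             p_two_tailed=float(p))
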