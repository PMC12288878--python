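# Methods

## Model and conventions

All coordinates are 0-based, intervals half-open; VCF/TSV positions
(1-based) are converted at the reader boundary. Substitutions are reported
as pyrimidine changes: a purine-centered event and its ±20 nt window are
reverse-complemented so the central base is C or T, and a motif and its
reverse-complement spelling (cCg→G / cGg→C) are therefore counted
cumulatively by construction.

A position is *sub-telomeric* when its distance to the nearer chromosome
end is ≤ 30 kb (inclusive boundary; "0–30,000 bp" names a closed range),
the expected extent of 5′→3′ resection from an uncapped telomere. Arm
membership is left for positions strictly in the first half of the
chromosome; exact-midpoint ties go right. Under the resection model the
exposed ssDNA is the bottom strand on left arms and the top strand on
right arms, so a lesion on a guanine of the exposed strand is read out as
a top-strand C→N change on left arms and G→N on right arms; `lesion_strand`
returns the strand carrying the damaged purine and is undefined (None) for
mid-chromosomal events.

Windows truncated at chromosome ends are N-padded to fixed length; N never
matches any motif character, and SBS at the two terminal bases of a
chromosome (no defined trinucleotide) are excluded from spectrum tallies so
that the 6-class, 96-channel, and total counts remain identical by
construction.

## TriMS enrichment, inference, and load

For motif m with center base B and alt A,

  E = (Mut_m / Mut_B→A) / (Ctx_m / Ctx_B),

with the context counts taken from the ±20 nt windows anchored on the
B→A substitutions themselves. Both context counts run over the same set of
*viable placement offsets*: window positions where the full motif fits
inside the window and does not overlap the window's central (mutated)
residue. This choice matters: the center always carries the motif's center
letter, so placements overlapping it would trivially satisfy a flank and
inflate the background motif density (~5–8% for cCg at yeast-like GC
content), while counting bases over all 40 offsets but motifs over only
the viable ones deflates it. With commensurable counts the motif/base
fraction is an unbiased estimate of local motif density and the TriMS
ratio centers on 1 under a context-blind null (empirical mean 1.00 in the
package's null simulations). Overlapping windows double-count by default;
a union mode (each genomic position counted once per orientation) is
provided.

The p-value is a one-sided (right-tail) Fisher exact test on
(mutations, contexts) × (motif, non-motif), computed in exact integer
arithmetic; tests verify exact agreement with an independent
hypergeometric route over all 2×2 tables with total ≤ 40.
Benjamini–Hochberg correction (statsmodels) is applied across the scanned
family — the motifs of one scan, or the samples of one cohort, never
pooled. The minimum load is Mut_m × (E−1)/E, reported when E > 1 and
q ≤ 0.05. The corrected-p direction is taken as ≤ 0.05 (the cutoff is
configurable). Zero-denominator enrichments are reported as missing and
excluded from the BH family rather than coerced to 0 or ∞.

Cohort summaries count samples with E ≥ 1 (as printed in cohort tables;
E exactly 1 contributes load 0) and q ≤ cutoff, and report the median load
over enriched samples, "NA" when none are enriched. The repeat-INDEL
correlation is a Pearson r with a two-tailed p from the t distribution on
n−2 df (scipy), undefined (missing) when either vector has zero variance.

## Positional logo

Foreground: residues at offsets −2..+2 around each mutated base (center
excluded, N-padded positions dropped per position). Background: all
residues of the 41-mers pooled, each central residue excluded. Each
(offset, residue) cell gets a signed −log10 one-sided binomial tail
(X ~ Binomial(n_offset, p_residue from background); + for over-, − for
under-representation; exact-expectation cells score 0; magnitudes capped at
300), with a Bonferroni threshold −log10(α/16) at α = 0.05. This is an
analog of binomial sequence-logo statistics, not a bit-exact
reimplementation of any external tool.

## Slippage detectors

* SBS: templated iff the alt equals the reference base at +1 (checked
  first, reported downstream) or −1 (upstream); both matching sets a flag.
* Single-base insertion (Rm→RMm): templated iff the inserted base equals
  the base immediately 3′ of the insertion point, evaluated at the 5′-most
  equivalent placement. Any equivalent VCF placement of the same event
  yields the same verdict; in particular a homopolymer-extending insertion
  is templated however it was anchored. (Testing at the 3′-most placement
  would never fire for exactly those events, which is why the 5′
  normalization is used.)
* DBS/MBS/multi-base insertion: templated iff the full alt run occurs as a
  contiguous reference substring whose nearest end lies within ±10 bp
  (configurable) of the mutated span; the span itself is excluded
  (self-match), partial overlaps count with gap 0, ties break downstream
  then smaller gap. The reported offset is the signed gap (0 = adjacent).
* INDELs in repeats: maximal homopolymer run containing the deleted bases
  (deletions) or the longer flanking run at the insertion point
  (insertions; ties 3′). Thresholds: run > 2 restricted to C/G for the
  yeast deletion statistic, run > 1 any base for the cancer-style
  aggregation. Runs are homopolymers only; microsatellites are out of
  scope.

## Synthetic data generator

The generator emulates the study conditions rather than generic data:
defaults are a 16 × 200 kb genome at GC 0.38, 114 isolates with
Poisson(761/114 ≈ 6.7) SBS each, sub-telomeric fraction 0.91 at threshold
30 kb, motif cCg→G at target enrichment E\* = 4, strand fidelity 1.0, an
INDEL/DBS/MBS channel at 76/114 events per isolate with templated fraction
0.8 and class mix INS 0.45 / DEL 0.33 / DBS 0.17 / MBS 0.05, and deletions
biased into C/G runs with probability 0.4. Genomes are i.i.d. bases; no
chromatin, replication-timing, or repeat structure is modeled, so passing
tests demonstrate estimator correctness and calibration, not robustness to
genomic covariates.

Within the chosen zone a mutation lands on a motif site with probability

  p_m = E\* f / (1 + (E\* − 1) f),  f = motif sites / central-base sites,

which makes the motif/non-motif odds ratio of implants exactly E\*. The
TriMS ratio-of-proportions estimate is then E\*/(1 + (E\*−1) f) — about
3.6 for E\* = 4 at f ≈ 0.036 — indistinguishable from E\* as f → 0. Truth
records store zone, arm, lesion strand, motif membership, and templated
status for every event, each re-derivable from the emitted FASTA + VCF.

Signature SBS implants always carry the motif's alt allele; for cCg→G that
allele is intrinsically a copy of the +1 guanine, so the signature is
templated by construction, as in the proposed mechanism. A separate
channel (`implant_slippage_sbs`) controls the SBS templated fraction
exactly (the templated/non-templated coin is drawn first and held while a
compatible site is found, so the realized fraction is an unbiased binomial
draw); non-templated alts exclude both neighbors to keep the fraction
identifiable. The same coin-first scheme applies to INDEL/DBS/MBS
implants, where non-templated alt runs are constructed absent from the
±10 bp search neighborhood.

## Problem sizes used in tests and the acceptance script

Formula checks are closed-form. Exact-test equivalence enumerates all
135,751 tables with total ≤ 40. Null calibration uses 200 isolates of
Poisson(1500) substitutions: the attained level of an exact conditional
test depends on its discreteness, and at small per-isolate burdens (the
reporter study's ~7, or even a few hundred) one-sided Fisher is
conservative (attained level < 0.03); at 1,500 substitutions the attained
level is near-nominal (~0.04–0.055), which is the regime a two-sided
calibration band presumes. Enrichment/load recovery uses a 16 × 200 kb
genome with 4,500-mutation implants (≥ 500 motif mutations) over 9 (tests)
or 5 (acceptance script) replicates; slippage concordance uses 1,000
events per class; the cohort fixture uses 20 samples — 5 enriched at
E\* = 4 with ~300 SBS (emulating hypermutated tumors) and 15 null samples
at ~25 SBS — burdens chosen so the per-sample exact test separates the two
groups decisively, as cohort tables do for strongly enriched cancers.

## Known limitations

The generator's i.i.d. genomes lack real repeat/GC structure, so repeat
INDEL statistics on synthetic data understate real-genome complexity. The
density denominator (2 arms × 30 kb × chromosomes, capped by length) is a
modeling default, reported alongside densities rather than hidden. The
union context-counting mode treats each orientation separately and is
intended for heavily overlapping window sets, not as the default. Cohort
BH correction across samples is the only correction applied in
`per_sample_scan`; scanning many motifs per sample across a cohort would
need a combined family that the package deliberately does not pool.
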