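#!/usr/bin/env python
"""Mutation spectrum and location analysis of the simulated isolates.

Reads results/sim/ (run 01_simulate.py first), applies the VAF filter,
builds the pyrimidine-collapsed 6-class and 96-channel spectra, classifies
every SBS as sub-telomeric vs mid-chromosomal, and tabulates the per-arm
reference-strand spectrum that exposes the resection strand bias
(left arms: C->N, right arms: G->N).
"""

from pathlib import Path

from ssmut import build_spectrum, filter_and_subtract, read_fasta, read_variants
from ssmut.variants import VarClass

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "sim"


def main() -> None:
    genome = read_fasta(SIM / "genome.fa")
    records = []
    vcfs = sorted(SIM.glob("iso*.vcf"))
    for vcf in vcfs:
        records.extend(read_variants(vcf, sample_id=vcf.stem))
    records = filter_and_subtract(records, [], min_vaf=0.90)
    snvs = [r for r in records if r.var_class is VarClass.SNV]
    table = build_spectrum(snvs, genome, n_isolates=len(vcfs))

    out = BASE / "spectrum"
    out.mkdir(parents=True, exist_ok=True)
    table.counts6.rename("count").rename_axis("class").reset_index().assign(
        density=table.density.values
    ).to_csv(out / "six_class.tsv", sep="\t", index=False)
    table.counts96.rename("count").rename_axis("channel").reset_index().to_csv(
        out / "channels_96.tsv", sep="\t", index=False
    )
    table.arm_counts.rename_axis("arm").reset_index().to_csv(
        out / "per_arm.tsv", sep="\t", index=False
    )

    subtel = table.zone_counts["sub_telomeric"] / max(1, table.total)
    arms = table.arm_counts
    left_c = arms.loc["left", [f"C>{b}" for b in "AGT"]].sum()
    right_g = arms.loc["right", [f"G>{b}" for b in "ACT"]].sum()
    print(f"{table.total} SBS from {len(vcfs)} isolates")
    print(f"  dominant collapsed class: {table.counts6.idxmax()} "
          f"({table.counts6.max()} events, density {table.density.max():.3g} "
          f"per bp per isolate)")
    print(f"  {100 * subtel:.1f}% of SBS within 30 kb of a telomere")
    print(f"  strand bias: {100 * left_c / max(1, arms.loc['left'].sum()):.1f}% "
          f"of left-arm SBS are C->N; "
          f"{100 * right_g / max(1, arms.loc['right'].sum()):.1f}% "
          f"of right-arm SBS are G->N")
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
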