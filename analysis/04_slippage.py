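#!/usr/bin/env python
"""Templated-slippage analysis of every simulated variant.

Applies the neighbor-copy rule to SBS, the Rm->RMm rule to single-base
insertions, the +/-10 bp template search to DBS/MBS, and homopolymer-run
membership to INDELs, then cross-checks the verdicts against the
generator's ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from ssmut import filter_and_subtract, read_fasta, read_variants
from ssmut.pipeline import slippage_verdict_rows

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "sim"


def main() -> None:
    genome = read_fasta(SIM / "genome.fa")
    records = []
    for vcf in sorted(SIM.glob("iso*.vcf")):
        records.extend(read_variants(vcf, sample_id=vcf.stem))
    records = filter_and_subtract(records, [], min_vaf=0.90)
    rows = pd.DataFrame(slippage_verdict_rows(records, genome))
    out = BASE / "slippage"
    out.mkdir(parents=True, exist_ok=True)
    rows.to_csv(out / "verdicts.tsv", sep="\t", index=False)

    truth = {
        (t["sample_id"], t["chrom"], t["pos0"]): t
        for t in json.loads((SIM / "truth.json").read_text())
    }
    for cls in ("SNV", "INS", "DBS", "MBS"):
        sub = rows[rows["class"] == cls]
        if sub.empty:
            continue
        frac = (sub.verdict == "templated").mean()
        matched = checked = 0
        for row in sub.itertuples():
            t = truth.get((row.sample, row.chrom, row.pos1 - 1))
            if t is None or t.get("is_templated") is None:
                continue
            checked += 1
            matched += (row.verdict == "templated") == t["is_templated"]
        print(f"{cls}: {len(sub)} events, {100 * frac:.1f}% templated "
              f"({matched}/{checked} verdicts agree with ground truth)")
    dels = rows[rows["class"] == "DEL"]
    if not dels.empty:
        print(f"DEL: {len(dels)} events, "
              f"{100 * dels.in_repeat.mean():.1f}% in C/G runs of >2")
    print(f"verdict table in {out / 'verdicts.tsv'}")


if __name__ == "__main__":
    main()
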