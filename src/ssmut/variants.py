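"""Variant I/O, the VAF / matched-normal / duplicate filtering chain, and
normalization of adjacent substitutions into DBS/MBS records.

Input formats: a minimal VCF v4.x subset (CHROM/POS/REF/ALT plus a
VAF-bearing INFO field, multi-allelic rows split) read via cyvcf2, or a
tab-separated table with columns ``sample, chrom, pos1, ref, alt[, vaf]``
(1-based positions, converted at this boundary). Internally everything is
0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

import pandas as pd

TSV_COLUMNS = ["sample", "chrom", "pos1", "ref", "alt", "vaf"]


class VarClass(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    DBS = "DBS"
    MBS = "MBS"


def classify_alleles(ref: str, alt: str) -> VarClass:
    if len(ref) == len(alt) == 1:
        return VarClass.SNV
    if len(alt) > len(ref):
        return VarClass.INS
    if len(ref) > len(alt):
        return VarClass.DEL
    if len(ref) == len(alt) == 2:
        return VarClass.DBS
    return VarClass.MBS


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call. `pos0` is the 0-based position of the first REF base."""

    chrom: str
    pos0: int
    ref: str
    alt: str
    sample_id: str = ""
    vaf: Optional[float] = None
    var_class: VarClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.var_class is None:
            object.__setattr__(self, "var_class", classify_alleles(self.ref, self.alt))
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos0, self.ref, self.alt)


@dataclass
class IsolateSet:
    """Variant calls of one isolate with its treatment and matched-normal parent."""

    sample_id: str
    records: list[VariantRecord]
    treatment: str = ""
    parent_id: str = ""

    def __post_init__(self) -> None:
        if any(r.sample_id != self.sample_id for r in self.records):
            raise ValueError("all records must share the isolate's sample_id")
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos0))


def _trim_shared_suffix_prefix(pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize a VCF allele pair: trim the shared suffix, then the shared
    prefix (keeping one anchor base for indels)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def read_variants(
    path, format: Literal["vcf", "tsv"] = "vcf", sample_id: str = ""
) -> list[VariantRecord]:
    """Read variant calls from a minimal VCF or the documented TSV dialect."""
    if format == "vcf":
        return _read_vcf(path, sample_id)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path, sample_id: str) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else "")
    for v in vcf:
        vaf = v.INFO.get("VAF")
        if vaf is None:
            vaf = v.INFO.get("AF")
        for alt in v.ALT:
            pos0, ref, a = _trim_shared_suffix_prefix(v.start, v.REF, alt)
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos0=pos0,
                    ref=ref,
                    alt=a,
                    sample_id=sid,
                    vaf=float(vaf) if vaf is not None else None,
                )
            )
    vcf.close()
    return records


def _read_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = {"sample", "chrom", "pos1", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"TSV missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        vaf = getattr(row, "vaf", None)
        if vaf is not None and pd.isna(vaf):
            vaf = None
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos0=int(row.pos1) - 1,
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample,
                vaf=float(vaf) if vaf is not None else None,
            )
        )
    return records


def write_vcf(records: Iterable[VariantRecord], path, contigs: dict[str, int] | None = None) -> None:
    """Write records as a minimal single-sample VCF (INFO VAF carries the
    variant allele frequency)."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = f"VAF={r.vaf:.4f}" if r.vaf is not None else "."
            fh.write(f"{r.chrom}\t{r.pos0 + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def write_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.chrom,
            "pos1": r.pos0 + 1,
            "ref": r.ref,
            "alt": r.alt,
            "vaf": r.vaf,
        }
        for r in sorted(records, key=lambda r: (r.sample_id, r.chrom, r.pos0))
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_and_subtract(
    case_records: Iterable[VariantRecord],
    normal_records: Iterable[VariantRecord],
    min_vaf: float = 0.90,
    shared_mode: Literal["drop_all", "keep_first"] = "drop_all",
) -> list[VariantRecord]:
    """The filtering chain: keep calls with VAF ≥ `min_vaf` (calls lacking a
    VAF are kept), subtract any call present in the matched normal, then
    resolve identical calls shared by sibling isolates — by default dropped
    from all isolates as inherited rather than independent events.
    """
    if not 0.0 <= min_vaf <= 1.0:
        raise ValueError("min_vaf must be in [0, 1]")
    normal_keys = {r.key for r in normal_records}
    kept = [
        r
        for r in case_records
        if (r.vaf is None or r.vaf >= min_vaf) and r.key not in normal_keys
    ]
    by_key: dict[tuple, set[str]] = {}
    for r in kept:
        by_key.setdefault(r.key, set()).add(r.sample_id)
    shared = {k for k, samples in by_key.items() if len(samples) > 1}
    if shared_mode == "drop_all":
        kept = [r for r in kept if r.key not in shared]
    elif shared_mode == "keep_first":
        seen: set[tuple] = set()
        out = []
        for r in sorted(kept, key=lambda r: (r.chrom, r.pos0, r.ref, r.alt, r.sample_id)):
            if r.key in shared:
                if r.key in seen:
                    continue
                seen.add(r.key)
            out.append(r)
        kept = out
    else:
        raise ValueError(f"unknown shared_mode {shared_mode!r}")
    return sorted(kept, key=lambda r: (r.sample_id, r.chrom, r.pos0))


def merge_adjacent_snvs(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Merge runs of SNVs at strictly consecutive positions of one sample and
    chromosome into DBS (run of 2) or MBS (run ≥3) records; everything else
    passes through unchanged."""
    records = sorted(records, key=lambda r: (r.sample_id, r.chrom, r.pos0))
    out: list[VariantRecord] = []
    run: list[VariantRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            out.append(
                replace(
                    first,
                    ref="".join(r.ref for r in run),
                    alt="".join(r.alt for r in run),
                    var_class=VarClass.DBS if len(run) == 2 else VarClass.MBS,
                )
            )
        run.clear()

    for r in records:
        if r.var_class is not VarClass.SNV:
            flush()
            out.append(r)
            continue
        if (
            run
            and r.sample_id == run[-1].sample_id
            and r.chrom == run[-1].chrom
            and r.pos0 == run[-1].pos0 + 1
        ):
            run.append(r)
        else:
            flush()
            run.append(r)
    flush()
    return sorted(out, key=lambda r: (r.sample_id, r.chrom, r.pos0))
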