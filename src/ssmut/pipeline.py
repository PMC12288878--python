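"""End-to-end pipeline: simulate → filter → spectrum → trims → logo →
slippage → cohort, with deterministic plain-text outputs and a checksum
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import motif_logo, slippage, spectrum, trims
from .cohort import per_sample_scan, summarize_cohort
from .synthetic_data import SimConfig, simulate_dataset
from .variants import VarClass, filter_and_subtract

log = logging.getLogger("ssmut")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    min_vaf: float = 0.90
    q_cutoff: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def slippage_verdict_rows(records, genome, window_bp: int = 10) -> list[dict]:
    """Templated-slippage verdict (plus repeat-run membership for INDELs)
    for every record, one TSV-ready row each. Deletions have no template
    rule; they carry only the repeat-run annotation."""
    rows = []
    for r in records:
        run = None
        if r.var_class is VarClass.SNV:
            call = slippage.detect_templated_sbs(r, genome)
        elif r.var_class is VarClass.INS:
            call = slippage.detect_templated_insertion(r, genome)
            run = slippage.indel_in_repeat(r, genome, min_run=2)
        elif r.var_class is VarClass.DEL:
            call = None
            run = slippage.indel_in_repeat(r, genome, min_run=3, cg_only=True)
        else:
            call = slippage.detect_templated_multibase(r, genome, window_bp)
        rows.append(
            {
                "sample": r.sample_id, "chrom": r.chrom, "pos1": r.pos0 + 1,
                "ref": r.ref, "alt": r.alt, "class": r.var_class.value,
                "verdict": call.verdict if call else "",
                "offset": call.template_offset if call else None,
                "direction": call.direction if call else None,
                "run_base": run.run_base if run else None,
                "run_length": run.run_length if run else None,
                "in_repeat": run.in_repeat if run else None,
            }
        )
    return rows


def run_pipeline(run_config: RunConfig) -> dict:
    """Run every stage on a synthetic dataset; returns the output manifest
    (also written as manifest.json). Any stage failure raises with the
    stage name; nothing is written past the failing stage."""
    logging.basicConfig(level=run_config.log_level)
    out = Path(run_config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = run_config.sim
    (out / "run_config.json").write_text(
        json.dumps(
            {
                "seed": run_config.seed,
                "min_vaf": run_config.min_vaf,
                "q_cutoff": run_config.q_cutoff,
                "sim": json.loads(cfg.to_json()),
            },
            indent=2,
        )
    )

    stage = "simulate"
    try:
        sim = simulate_dataset(cfg)
        sim.to_directory(out / "sim")
        log.info("simulated %d isolates", len(sim.isolates))

        stage = "filter"
        records = filter_and_subtract(
            sim.all_records(), [], min_vaf=run_config.min_vaf
        )
        snvs = [r for r in records if r.var_class is VarClass.SNV]

        stage = "spectrum"
        spec_table = spectrum.build_spectrum(
            snvs, sim.genome, n_isolates=len(sim.isolates),
            threshold_bp=cfg.subtel_threshold,
        )
        _write(
            spec_table.counts6.rename("count").rename_axis("class").reset_index()
            .assign(density=spec_table.density.values),
            out / "spectrum_6class.tsv",
        )
        _write(
            spec_table.counts96.rename("count").rename_axis("channel").reset_index(),
            out / "spectrum_96channel.tsv",
        )
        _write(
            spec_table.arm_counts.rename_axis("arm").reset_index(),
            out / "spectrum_arms.tsv",
        )

        stage = "trims"
        subs = [
            spectrum.collapse_to_pyrimidine(r, sim.genome) for r in snvs
        ]
        change = f"{cfg.motif.center}>{cfg.motif.alt}"
        scan = trims.scan_motifs(subs, change, q_cutoff=run_config.q_cutoff)
        _write(trims.results_to_frame(scan), out / "trims_scan.tsv")

        stage = "logo"
        change_subs = [s for s in subs if s.pyr_class == change]
        logo = motif_logo.residue_scores(motif_logo.build_fg_bg(change_subs))
        _write(
            logo.scores.rename_axis("offset").reset_index(),
            out / "logo_scores.tsv",
        )

        stage = "slippage"
        _write(
            pd.DataFrame(slippage_verdict_rows(records, sim.genome)),
            out / "slippage_verdicts.tsv",
        )

        stage = "cohort"
        results = per_sample_scan(
            {s: recs for s, recs in sim.isolates.items()},
            sim.genome, cfg.motif, q_cutoff=run_config.q_cutoff,
        )
        _write(trims.results_to_frame(results), out / "cohort_per_sample.tsv")
        summary = summarize_cohort(results, run_config.q_cutoff, cohort="synthetic")
        _write(
            pd.DataFrame(
                [
                    {
                        "cohort": summary.cohort,
                        "n_samples": summary.n_samples,
                        "n_enriched": summary.n_enriched,
                        "median_load_enriched": summary.median_display,
                    }
                ]
            ),
            out / "cohort_summary.tsv",
        )
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(out))] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
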