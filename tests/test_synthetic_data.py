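import json

import numpy as np
import pytest

from ssmut import (
    SimConfig,
    classify_location,
    detect_templated_insertion,
    implant_indels,
    implant_sbs,
    read_fasta,
    read_variants,
    simulate_dataset,
    simulate_genome,
)
from ssmut.synthetic_data import SiteIndex


def small_cfg(**kw):
    base = dict(seed=3, n_chrom=3, chrom_length=70_000, n_isolates=5,
                muts_per_isolate=30, indel_rate=1.0)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        assert simulate_genome(cfg).sequences == simulate_genome(cfg).sequences

    def test_gc_zero(self):
        g = simulate_genome(small_cfg(gc_fraction=0.0, chrom_length=5_000))
        assert not (set("".join(g.sequences.values())) & set("GC"))

    def test_gc_within_binomial_bound(self):
        g = simulate_genome(small_cfg(gc_fraction=0.5, n_chrom=1,
                                      chrom_length=1_000_000))
        seq = g.sequences["chr01"]
        gc = sum(seq.count(b) for b in "GC") / len(seq)
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / 1_000_000)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length=0)
        with pytest.raises(ValueError):
            SimConfig(target_enrichment=0.5)
        with pytest.raises(ValueError):
            SimConfig(subtel_fraction=1.5)


class TestImplantSbs:
    def test_e_star_one_is_uniform_over_sites(self, sim_genome):
        # at E*=1 the motif-site probability equals the motif site fraction
        cfg = small_cfg(target_enrichment=1.0, n_chrom=4, chrom_length=80_000,
                        n_isolates=20, muts_per_isolate=200)
        idx = SiteIndex(sim_genome, cfg.motif, cfg.subtel_threshold)
        iso, truth = implant_sbs(sim_genome, cfg, np.random.default_rng(5),
                                 site_index=idx)
        f = idx.motif_fraction("sub_telomeric")
        frac = np.mean([t.is_motif_site for t in truth])
        n = len(truth)
        assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / n)

    def test_subtel_fraction_one_closed_loop(self, sim_genome):
        cfg = small_cfg(subtel_fraction=1.0, n_chrom=4, chrom_length=80_000)
        iso, truth = implant_sbs(sim_genome, cfg, np.random.default_rng(6))
        for recs in iso.values():
            for r in recs:
                assert classify_location(sim_genome, r).zone == "sub_telomeric"

    def test_truth_rederivable(self, sim_genome):
        cfg = small_cfg(n_chrom=4, chrom_length=80_000, strand_fidelity=1.0)
        iso, truth = implant_sbs(sim_genome, cfg, np.random.default_rng(8))
        motif = cfg.motif
        for t in truth:
            seq = sim_genome.sequences[t.chrom]
            assert seq[t.pos0] == t.ref
            loc = classify_location(
                sim_genome,
                [r for r in iso[t.sample_id] if r.pos0 == t.pos0 and r.chrom == t.chrom][0],
            )
            assert loc.zone == t.zone and loc.arm == t.arm
            # motif membership re-derived from sequence (either spelling)
            if t.ref == motif.center:
                expect = (
                    seq[t.pos0 - 1] == motif.left.upper()
                    and seq[t.pos0 + 1] == motif.right.upper()
                )
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                expect = (
                    seq[t.pos0 - 1] == comp[motif.right.upper()]
                    and seq[t.pos0 + 1] == comp[motif.left.upper()]
                )
            assert expect == t.is_motif_site
            # arm-appropriate strandedness at fidelity 1
            if t.zone == "sub_telomeric":
                assert (t.arm == "left") == (t.lesion_strand == "bottom")

    def test_infeasible_enrichment_rejected(self, sim_genome):
        cfg = small_cfg(target_enrichment=40.0, n_chrom=4, chrom_length=80_000)
        with pytest.raises(ValueError, match="infeasible"):
            implant_sbs(sim_genome, cfg, np.random.default_rng(0))


class TestImplantIndels:
    def test_templated_fraction_extremes(self, sim_genome):
        for t, expect in ((1.0, 1.0), (0.0, 0.0)):
            cfg = small_cfg(templated_fraction=t, indel_mix={"INS": 1.0})
            recs, truth = implant_indels(sim_genome, cfg,
                                         np.random.default_rng(4), n_events=200)
            detected = np.mean([
                detect_templated_insertion(r, sim_genome).verdict == "templated"
                for r in recs
            ])
            assert detected == expect

    def test_deterministic(self, sim_genome):
        cfg = small_cfg()
        a, _ = implant_indels(sim_genome, cfg, np.random.default_rng(9), n_events=50)
        b, _ = implant_indels(sim_genome, cfg, np.random.default_rng(9), n_events=50)
        assert a == b


class TestDataset:
    def test_roundtrip_through_files(self, tmp_path):
        cfg = small_cfg(n_isolates=3)
        sim = simulate_dataset(cfg)
        sim.to_directory(tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert genome.sequences == sim.genome.sequences
        sample = next(iter(sim.isolates))
        again = read_variants(tmp_path / f"{sample}.vcf", sample_id=sample)
        assert [(r.chrom, r.pos0, r.ref, r.alt) for r in again] == [
            (r.chrom, r.pos0, r.ref, r.alt) for r in sim.isolates[sample]
        ]
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth) == len(sim.truth)
        assert json.loads((tmp_path / "config.json").read_text())["seed"] == cfg.seed

    def test_same_seed_identical(self):
        cfg = small_cfg()
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.all_records() == b.all_records()

    def test_statistical_loop_enrichment(self, sim_genome):
        # over seeded replicates the motif/non-motif odds ratio of the
        # implants matches the configured E*
        cfg = small_cfg(target_enrichment=4.0, n_chrom=4, chrom_length=80_000,
                        n_isolates=10, muts_per_isolate=150)
        idx = SiteIndex(sim_genome, cfg.motif, cfg.subtel_threshold)
        f_st = idx.motif_fraction("sub_telomeric")
        f_mid = idx.motif_fraction("mid_chromosomal")
        odds = []
        subtel = []
        for rep in range(30):
            _, truth = implant_sbs(sim_genome, cfg, np.random.default_rng(rep),
                                   site_index=idx)
            sub = [t for t in truth if t.zone == "sub_telomeric"]
            p = np.mean([t.is_motif_site for t in sub])
            odds.append((p / (1 - p)) / (f_st / (1 - f_st)))
            subtel.append(len(sub) / len(truth))
        assert np.mean(odds) == pytest.approx(4.0, rel=0.05)
        n_tot = 30 * cfg.n_isolates * cfg.muts_per_isolate
        assert abs(np.mean(subtel) - cfg.subtel_fraction) < 3 * np.sqrt(
            cfg.subtel_fraction * (1 - cfg.subtel_fraction) / n_tot
        )
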