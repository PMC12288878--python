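import numpy as np
import pytest

from ssmut import (
    Genome,
    SimConfig,
    VariantRecord,
    detect_templated_insertion,
    detect_templated_multibase,
    detect_templated_sbs,
    implant_indels,
    implant_slippage_sbs,
    indel_in_repeat,
    revcomp,
)


def snv(g, chrom, pos0, alt, sample="s"):
    return VariantRecord(chrom=chrom, pos0=pos0, ref=g.sequences[chrom][pos0],
                         alt=alt, sample_id=sample, vaf=1.0)


class TestTemplatedSbs:
    def test_downstream_copy(self):
        g = Genome(sequences={"x": "AACGTT"})  # cCg at 1-3
        call = detect_templated_sbs(snv(g, "x", 2, "G"), g)
        assert call.verdict == "templated" and call.direction == "downstream"

    def test_no_neighbor_match(self):
        g = Genome(sequences={"x": "AACATT"})
        call = detect_templated_sbs(snv(g, "x", 2, "G"), g)
        assert call.verdict == "not_templated"

    def test_both_neighbors_flagged_downstream(self):
        g = Genome(sequences={"x": "AGCGTT"})  # gCg at 1-3
        call = detect_templated_sbs(snv(g, "x", 2, "G"), g)
        assert call.verdict == "templated"
        assert call.direction == "downstream" and call.both

    def test_upstream_copy(self):
        g = Genome(sequences={"x": "AGCATT"})
        call = detect_templated_sbs(snv(g, "x", 2, "G"), g)
        assert call.verdict == "templated" and call.direction == "upstream"

    def test_chromosome_end_indeterminate(self):
        g = Genome(sequences={"x": "CA"})
        call = detect_templated_sbs(snv(g, "x", 0, "G"), g)
        assert call.verdict == "indeterminate"


class TestTemplatedInsertion:
    def test_rmm_pattern(self):
        # CA with A inserted between: cCa -> cAa style templated insertion
        g = Genome(sequences={"x": "TTCATT"})
        rec = VariantRecord(chrom="x", pos0=2, ref="C", alt="CA", sample_id="s")
        assert detect_templated_insertion(rec, g).verdict == "templated"

    def test_non_copy_insertion(self):
        g = Genome(sequences={"x": "TTCATT"})
        rec = VariantRecord(chrom="x", pos0=2, ref="C", alt="CG", sample_id="s")
        assert detect_templated_insertion(rec, g).verdict == "not_templated"

    def test_homopolymer_representation_invariance(self):
        # inserting A into the AAA run is templated at every VCF placement
        g = Genome(sequences={"x": "TCAAAGT"})
        for pos0 in (1, 2, 3, 4):
            ref = g.sequences["x"][pos0]
            rec = VariantRecord(chrom="x", pos0=pos0, ref=ref, alt=ref + "A",
                                sample_id="s")
            assert detect_templated_insertion(rec, g).verdict == "templated", pos0

    def test_oracle_on_random_implants(self, sim_genome, rng):
        cfg = SimConfig(seed=1, templated_fraction=0.5,
                        indel_mix={"INS": 1.0}, n_chrom=4, chrom_length=80_000)
        recs, truth = implant_indels(sim_genome, cfg, rng, n_events=1000)

        def oracle(rec):
            seq = sim_genome.sequences[rec.chrom]
            ins = rec.alt[len(rec.ref):]
            i = rec.pos0 + len(rec.ref) - 1
            # templated iff some equivalent placement has the next base == ins
            return ins in (seq[i], seq[i + 1])

        for rec, tr in zip(recs, truth):
            got = detect_templated_insertion(rec, sim_genome).verdict
            assert got == ("templated" if oracle(rec) else "not_templated")
            assert (got == "templated") == tr.is_templated


class TestTemplatedMultibase:
    def test_downstream_template_offset(self):
        #         0123456789012
        g = Genome(sequences={"x": "AAAACCGAATTAAAAAAAAA"})
        # DBS at 4-5 (CC->TT); TT occurs at 9-10, gap 3 bp downstream
        rec = VariantRecord(chrom="x", pos0=4, ref="CC", alt="TT", sample_id="s")
        call = detect_templated_multibase(rec, g)
        assert call.verdict == "templated"
        assert call.template_offset == 3 and call.direction == "downstream"

    def test_absent_template(self):
        g = Genome(sequences={"x": "A" * 30})
        rec = VariantRecord(chrom="x", pos0=12, ref="AA", alt="TG", sample_id="s")
        assert detect_templated_multibase(rec, g).verdict == "not_templated"

    def test_self_span_excluded(self):
        # the alt run occurs nowhere in the neighborhood except (as ref)
        # at the mutated span itself, which is excluded from the search
        g = Genome(sequences={"x": "A" * 12 + "TG" + "A" * 12})
        rec = VariantRecord(chrom="x", pos0=12, ref="TG", alt="CA", sample_id="s")
        assert detect_templated_multibase(rec, g).verdict == "not_templated"

    def test_window_limit(self):
        g = Genome(sequences={"x": "TT" + "A" * 13 + "CC" + "A" * 13 + "TT"})
        rec = VariantRecord(chrom="x", pos0=15, ref="CC", alt="TT", sample_id="s")
        assert detect_templated_multibase(rec, g, window_bp=10).verdict == "not_templated"
        assert detect_templated_multibase(rec, g, window_bp=13).verdict == "templated"

    @pytest.mark.parametrize("cls,mix", [("DBS", {"DBS": 1.0}), ("MBS", {"MBS": 1.0})])
    def test_oracle_on_random_implants(self, sim_genome, rng, cls, mix):
        cfg = SimConfig(seed=1, templated_fraction=0.5, indel_mix=mix,
                        n_chrom=4, chrom_length=80_000)
        recs, truth = implant_indels(sim_genome, cfg, rng, n_events=500)

        def oracle(rec):
            seq = sim_genome.sequences[rec.chrom]
            L = len(rec.alt)
            s, e = rec.pos0, rec.pos0 + len(rec.ref)
            for j in range(max(0, s - 10 - L), min(len(seq) - L, e + 10) + 1):
                if j == s or seq[j : j + L] != rec.alt:
                    continue
                gap = j - e if j >= e else (s - (j + L) if j + L <= s else 0)
                if 0 <= gap <= 10:
                    return True
            return False

        for rec, tr in zip(recs, truth):
            got = detect_templated_multibase(rec, sim_genome).verdict
            assert got == ("templated" if oracle(rec) else "not_templated")
            assert (got == "templated") == tr.is_templated


class TestIndelInRepeat:
    def test_deletion_in_cg_run(self):
        g = Genome(sequences={"x": "ATCCCCAT"})
        rec = VariantRecord(chrom="x", pos0=2, ref="CC", alt="C", sample_id="s")
        info = indel_in_repeat(rec, g, min_run=3, cg_only=True)
        assert info.in_repeat and info.run_base == "C" and info.run_length == 4

    def test_short_run_not_flagged(self):
        g = Genome(sequences={"x": "ATCATCAT"})
        rec = VariantRecord(chrom="x", pos0=2, ref="CA", alt="C", sample_id="s")
        assert not indel_in_repeat(rec, g, min_run=3).in_repeat

    def test_at_run_requires_any_base_mode(self):
        g = Genome(sequences={"x": "GCAATG"})
        rec = VariantRecord(chrom="x", pos0=2, ref="A", alt="AA", sample_id="s")
        assert indel_in_repeat(rec, g, min_run=2).in_repeat
        assert not indel_in_repeat(rec, g, min_run=2, cg_only=True).in_repeat

    def test_insertion_takes_longer_flank(self):
        g = Genome(sequences={"x": "TGGGAT"})
        rec = VariantRecord(chrom="x", pos0=3, ref="G", alt="GA", sample_id="s")
        info = indel_in_repeat(rec, g, min_run=3)
        assert info.run_base == "G" and info.run_length == 3 and info.in_repeat


class TestEquivariance:
    def test_reverse_complement_preserves_verdicts(self, sim_genome, rng):
        g = sim_genome
        g_rc = Genome(sequences={c: revcomp(s) for c, s in g.sequences.items()})
        cfg = SimConfig(seed=1, templated_fraction=0.5, n_chrom=4,
                        chrom_length=80_000)
        recs, _ = implant_indels(g, cfg, rng, n_events=200)
        sbs, _ = implant_slippage_sbs(g, 200, 0.5, rng)
        for rec in sbs:
            L = len(g.sequences[rec.chrom])
            mirror = VariantRecord(chrom=rec.chrom, pos0=L - 1 - rec.pos0,
                                   ref=revcomp(rec.ref), alt=revcomp(rec.alt),
                                   sample_id=rec.sample_id)
            assert (
                detect_templated_sbs(rec, g).verdict
                == detect_templated_sbs(mirror, g_rc).verdict
            )
        for rec in recs:
            if rec.var_class.value not in ("DBS", "MBS"):
                continue
            L = len(g.sequences[rec.chrom])
            mirror = VariantRecord(
                chrom=rec.chrom, pos0=L - (rec.pos0 + len(rec.ref)),
                ref=revcomp(rec.ref), alt=revcomp(rec.alt),
                sample_id=rec.sample_id,
            )
            assert (
                detect_templated_multibase(rec, g).verdict
                == detect_templated_multibase(mirror, g_rc).verdict
            )
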