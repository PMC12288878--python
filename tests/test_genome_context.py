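import pytest
from hypothesis import given, settings, strategies as st

from ssmut import (
    Genome,
    MotifSpec,
    count_contexts,
    oriented_window,
    read_fasta,
    revcomp,
    telomere_distance,
)
from ssmut.genome_context import write_fasta

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestReadFasta:
    def test_case_normalized(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n")
        g = read_fasta(p)
        assert g.sequences == {"chr1": "ACGT"}
        assert g.lengths == {"chr1": 4}

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c1\nA\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_two_records(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGTACG\nT\n>b\nGGCC\n")
        g = read_fasta(p)
        assert g.chrom_names == ["a", "b"]
        assert g.lengths == {"a": 8, "b": 4}

    def test_bad_residue_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGU\n")
        with pytest.raises(ValueError, match="non-ACGTN"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_roundtrip(self, toy_genome, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(toy_genome, p)
        again = read_fasta(p)
        assert again.sequences == toy_genome.sequences


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expect",
        [
            ("CCG", "CGG"),  # the cCg motif's complementary spelling is cGg
            ("ACGTN", "NACGT"),
            ("A", "T"),
        ],
    )
    def test_examples(self, seq, expect):
        assert revcomp(seq) == expect

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError):
            revcomp("ACGX")

    @settings(derandomize=True)
    @given(dna)
    def test_involution_and_length(self, s):
        assert revcomp(revcomp(s)) == s
        assert len(revcomp(s)) == len(s)


class TestOrientedWindow:
    def test_purine_center_reverse_complemented(self, toy_genome):
        # c1[4] = G
        w = oriented_window(toy_genome, "c1", 4, 2, True)
        assert w.orientation == "reverse_complemented"
        assert w.center_base == "C"
        assert w.sequence == revcomp(toy_genome["c1"][2:7])

    def test_pyrimidine_center_as_reference(self, toy_genome):
        # c1[2] = C
        w = oriented_window(toy_genome, "c1", 2, 2, True)
        assert w.orientation == "as_reference"
        assert w.sequence == toy_genome["c1"][0:5]

    def test_left_edge_n_padded(self, toy_genome):
        w = oriented_window(toy_genome, "c1", 0, 20, False)
        assert len(w.sequence) == 41
        assert w.sequence[:20] == "N" * 20

    def test_out_of_range(self, toy_genome):
        with pytest.raises(IndexError):
            oriented_window(toy_genome, "c1", 99, 2)


def brute_context_counts(windows, motif):
    """Independent per-character scan (the oracle): count the central base
    letter and full-motif placements over the viable placement offsets
    (motif fits the window, does not overlap the window center)."""
    base = 0
    hits = 0
    for w in windows:
        h = w.halfwidth
        seq = w.sequence
        for i in range(len(seq)):
            lo = i - len(motif.left)
            hi = i + len(motif.right)
            if lo < 0 or hi >= len(seq) or lo <= h <= hi:
                continue
            if seq[i] == motif.center:
                base += 1
            pat = motif.left + motif.center.lower() + motif.right
            ok = True
            for pc, sc in zip(pat, seq[lo : hi + 1]):
                if sc == "N" or (pc != "n" and sc != pc.upper()):
                    ok = False
                    break
            if ok:
                hits += 1
    return base, hits


class TestCountContexts:
    def test_hand_example(self):
        # in a 5-mer every cCg placement either overlaps the central mutated
        # residue or runs off the window, so nothing is viable background
        g = Genome(sequences={"x": "ACCGA"})
        w = oriented_window(g, "x", 2, 2, False)
        cc = count_contexts([w], MotifSpec("cCg", "G"))
        assert (cc.base_count, cc.motif_count) == (0, 0)
        assert brute_context_counts([w], MotifSpec("cCg", "G")) == (0, 0)

    def test_hand_example_wide(self):
        g = Genome(sequences={"x": "CCGTCTACCGA"})
        w = oriented_window(g, "x", 5, 5, False)  # center T at offset 5
        m = MotifSpec("cCg", "G")
        # viable offsets are 1..9 minus {4,5,6}; C letters sit at viable
        # offsets {1,7,8}; CCG placements centered at offsets 1 and 8
        cc = count_contexts([w], m)
        assert (cc.base_count, cc.motif_count) == (3, 2)
        assert brute_context_counts([w], m) == (3, 2)

    def test_absent_motif(self, toy_genome):
        g = Genome(sequences={"x": "ATATA"})
        w = oriented_window(g, "x", 2, 2, False)
        cc = count_contexts([w], MotifSpec("cCg", "G"))
        assert cc.motif_count == 0

    def test_additivity(self, sim_genome):
        wins = [oriented_window(sim_genome, "chr01", p, 20) for p in range(100, 150)]
        m = MotifSpec("cCg", "G")
        once = count_contexts(wins, m)
        twice = count_contexts(wins + wins, m)
        assert twice.base_count == 2 * once.base_count
        assert twice.motif_count == 2 * once.motif_count

    def test_union_mode_deduplicates(self, sim_genome):
        wins = [oriented_window(sim_genome, "chr01", 500, 20, False)]
        m = MotifSpec("cCg", "G")
        once = count_contexts(wins, m, mode="union")
        twice = count_contexts(wins * 2, m, mode="union")
        assert (once.base_count, once.motif_count) == (
            twice.base_count,
            twice.motif_count,
        )

    @pytest.mark.parametrize("pattern", ["cCg", "nCg", "cC", "Cg", "C", "nCn", "aTt"])
    def test_matches_brute_scan(self, sim_genome, rng, pattern):
        positions = rng.integers(0, 80_000, size=250)
        wins = [oriented_window(sim_genome, "chr02", int(p), 20) for p in positions]
        motif = MotifSpec(pattern, "A")
        cc = count_contexts(wins, motif)
        assert (cc.base_count, cc.motif_count) == brute_context_counts(wins, motif)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_contexts([], MotifSpec("cCg", "G"))


class TestTelomereDistance:
    @pytest.mark.parametrize(
        "pos,dist,arm",
        [(3, 3, "left"), (96, 3, "right"), (50, 49, "right"), (49, 49, "left")],
    )
    def test_examples(self, pos, dist, arm):
        g = Genome(sequences={"c": "A" * 100})
        assert telomere_distance(g, "c", pos) == (dist, arm)

    def test_mirror_symmetry(self, sim_genome, rng):
        L = 80_000
        for p in rng.integers(0, L, size=50):
            d1, _ = telomere_distance(sim_genome, "chr01", int(p))
            d2, _ = telomere_distance(sim_genome, "chr01", L - 1 - int(p))
            assert d1 == d2

    def test_out_of_range(self, toy_genome):
        with pytest.raises(IndexError):
            telomere_distance(toy_genome, "c1", 20)
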