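"""Promoter coordinates, k-mer counting, word scoring, assembly, null clusters."""

import numpy as np
import pandas as pd
import pytest

from lightmask import motif_discovery as md
from lightmask.expression_qc import ValidationError
from lightmask.synthetic_data import reverse_complement


def write_toy_genome(tmp_path, seq, genes):
    """genes: list of (gene_id, start, end, strand); single contig."""
    fasta = tmp_path / "toy.fa"
    with open(fasta, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    gff = tmp_path / "toy.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, start, end, strand in genes:
            fh.write(f"chr1\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n")
    return str(gff), str(fasta)


class TestWindow:
    def test_label_and_parse_round_trip(self):
        w = md.PromoterWindow(-500, 200)
        assert w.label == "[-500,+200]"
        assert md.PromoterWindow.parse("[-500,+200]") == w
        assert md.PromoterWindow.parse("-500,200") == w

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValidationError):
            md.PromoterWindow(10, 10)


class TestExtractPromoters:
    def test_plus_strand_coordinates_via_marker(self, tmp_path):
        # TSS at 1-based 1001; window [-500,0] must cover forward 501..1000
        seq = list("A" * 1600)
        seq[500] = "G"  # genomic position 501 (1-based)
        seq[999] = "C"  # genomic position 1000
        gff, fasta = write_toy_genome(tmp_path, "".join(seq), [("gene1", 1001, 1400, "+")])
        out = md.extract_promoters(gff, fasta, md.PromoterWindow(-500, 0), ["gene1"])
        got = out["gene1"].seq
        assert len(got) == 500
        assert got[0] == "G" and got[-1] == "C"
        assert not out["gene1"].clipped

    def test_zero_plus_window_is_first_transcribed_bases(self, tmp_path):
        seq = "A" * 1000 + "GTCA" * 50 + "A" * 500
        gff, fasta = write_toy_genome(tmp_path, seq, [("gene1", 1001, 1500, "+")])
        out = md.extract_promoters(gff, fasta, md.PromoterWindow(0, 200), ["gene1"])
        assert out["gene1"].seq == seq[1000:1200]

    def test_minus_strand_round_trip_with_planted_motif(self, tmp_path):
        # '-' gene with TSS at 1-based 600; promoter-sense offset -100 holds
        # the motif, so the forward strand carries its reverse complement
        motif = "AAATACAT"
        tss = 600
        off = -100
        seq = list("C" * 1200)
        i1 = (tss - 1) - off  # 0-based forward index of offset position
        seq[i1 - len(motif) + 1 : i1 + 1] = reverse_complement(motif)
        gff, fasta = write_toy_genome(tmp_path, "".join(seq), [("gene1", 100, tss, "-")])
        out = md.extract_promoters(gff, fasta, md.PromoterWindow(-500, 0), ["gene1"])
        got = out["gene1"].seq
        # the site spans promoter-sense offsets [off, off + len), i.e. window
        # index off - start_offset
        assert got.index(motif) == off - (-500)

    def test_clipping_recorded(self, tmp_path):
        gff, fasta = write_toy_genome(tmp_path, "A" * 300, [("gene1", 101, 200, "+")])
        out = md.extract_promoters(gff, fasta, md.PromoterWindow(-500, 0), ["gene1"])
        assert out["gene1"].clipped
        assert len(out["gene1"].seq) == 100

    def test_absent_gene_raises_lookup_error(self, tmp_path):
        gff, fasta = write_toy_genome(tmp_path, "A" * 300, [("gene1", 101, 200, "+")])
        with pytest.raises(KeyError):
            md.extract_promoters(gff, fasta, md.PromoterWindow(-10, 0), ["nope"])

    def test_generator_round_trip_minus_strand_sites(self, motif_study):
        """Sites planted by the study generator reappear promoter-sense."""
        _, _, truth, fasta, gff = motif_study
        consensus = truth.planted_motif["consensus"]
        window = md.PromoterWindow(-500, 0)
        ex = md.PromoterExtractor(gff, fasta)
        genes = [s["gene"] for s in truth.planted_motif["sites"]]
        seqs = ex.extract(window, genes)
        for site in truth.planted_motif["sites"]:
            got = seqs[site["gene"]].seq
            start = site["offset"] - window.start_offset
            assert got[start : start + len(consensus)] == consensus


def count_kmers_bruteforce(seqs, k, both):
    out = {}
    scan = list(seqs) + ([reverse_complement(s) for s in seqs] if both else [])
    for s in scan:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                key = min(w, reverse_complement(w)) if both else w
                out[key] = out.get(key, 0) + 1
    return out


class TestCountKmers:
    def test_overlapping_single_strand(self):
        assert md.count_kmers(["AAAA"], 2) == {"AA": 3}

    def test_both_strands_collapse(self):
        # AC on + and GT on - collapse onto the smaller key with count 2
        assert md.count_kmers(["AC"], 2, both_strands=True) == {"AC": 2}

    def test_word_longer_than_sequence(self):
        assert md.count_kmers(["ACGT"], 5) == {}

    def test_non_acgt_windows_skipped(self):
        assert md.count_kmers(["ACGNT"], 2) == {"AC": 1, "CG": 1}

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            md.count_kmers(["ACGT"], 0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            seqs = [
                "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=rng.integers(5, 100)))
                for _ in range(3)
            ]
            k = int(rng.integers(1, 7))
            for both in (False, True):
                assert md.count_kmers(seqs, k, both) == count_kmers_bruteforce(seqs, k, both)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(23)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        flipped = [reverse_complement(s) for s in seqs]
        assert md.count_kmers(seqs, 6, both_strands=True) == md.count_kmers(
            flipped, 6, both_strands=True
        )


class TestScoreWords:
    def test_binomial_tail_worked_example(self):
        # P(X >= 5 | n=10, f=0.1) ~ 0.0016349
        res = md.score_words({"AAAAA": 5}, {"AAAAA": 0.1}, 10)
        assert res["p_value"].iloc[0] == pytest.approx(0.0016349, rel=1e-3)
        assert res["expected"].iloc[0] == pytest.approx(1.0)

    def test_zero_observation_gives_p_one(self):
        res = md.score_words({"CCCCC": 0}, {"CCCCC": 0.2}, 10)
        assert res["p_value"].iloc[0] == 1.0

    def test_observed_at_expectation_not_significant(self):
        res = md.score_words({"AAAAA": 100}, {"AAAAA": 0.1}, 1000)
        assert res["p_value"].iloc[0] > 0.4

    def test_zero_background_with_hits_floors_p(self):
        res = md.score_words({"GGGGG": 3}, {}, 100)
        assert res["p_value"].iloc[0] == md.P_FLOOR


def scores_frame(words_with_q):
    rows = [
        {"word": w, "observed": 10, "expected": 1.0, "p_value": q / 2, "q_value": q}
        for w, q in words_with_q
    ]
    return pd.DataFrame(rows)


class TestAssembleMotif:
    def test_unanimous_sites_upper_case(self):
        seqs = [f"CCCCC{'AAATACAT'}GGGGG" for _ in range(10)]
        motif = md.assemble_motif(scores_frame([("AAATACAT", 1e-6)]), seqs)
        assert motif.consensus == "AAATACAT"
        assert motif.n_sites == 10
        assert (motif.counts.sum(axis=0) == motif.n_sites).all()

    def test_minority_column_lower_case(self):
        # final column 6xT / 4xC -> plurality 0.6 < 0.75 -> lowercase t
        seqs = ["CC" + "AAATACAT" + "GG"] * 6 + ["CC" + "AAATACAC" + "GG"] * 4
        sig = scores_frame([("AAATACAT", 1e-6), ("AAATACAC", 1e-4)])
        motif = md.assemble_motif(sig, seqs)
        assert motif.consensus == "AAATACAt"
        assert motif.n_sites == 10

    def test_one_mismatch_word_keeps_width(self):
        seqs = ["TT" + "AAATACAT" + "TT"] * 5 + ["TT" + "AAGTACAT" + "TT"] * 5
        sig = scores_frame([("AAATACAT", 1e-6), ("AAGTACAT", 1e-4)])
        motif = md.assemble_motif(sig, seqs)
        assert motif.width == 8
        # mismatch column carries mixed counts
        col = motif.counts[:, 2]
        assert col[md._BASE_INDEX["A"]] == 5 and col[md._BASE_INDEX["G"]] == 5

    def test_no_significant_words_is_sentinel(self):
        assert md.assemble_motif(scores_frame([]), ["ACGT"]) is None

    def test_column_sums_equal_n_sites_with_shifted_words(self):
        core = "GATTACAG"
        shifted = "ATTACAGT"  # core shifted by one
        seqs = [f"CCCC{core}TCCC" for _ in range(8)]
        sig = scores_frame([(core, 1e-8), (shifted, 1e-5)])
        motif = md.assemble_motif(sig, seqs)
        assert (motif.counts.sum(axis=0) == motif.n_sites).all()


class TestNullClusters:
    def _universe(self, n=60, length=80, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=length)) for i in range(n)
        }

    def test_score_above_all_nulls(self):
        emp_p, nulls = md.null_cluster_significance(
            1e9, self._universe(), cluster_size=10, k=5, n_null=50, seed=1
        )
        assert emp_p == pytest.approx(1 / 51)
        assert len(nulls) == 50

    def test_score_below_all_nulls(self):
        emp_p, _ = md.null_cluster_significance(
            -1.0, self._universe(), cluster_size=10, k=5, n_null=50, seed=1
        )
        assert emp_p == 1.0

    def test_degenerate_null_count_rejected(self):
        with pytest.raises(md.SamplingError):
            md.null_cluster_significance(1.0, self._universe(), 10, 5, n_null=0, seed=1)

    def test_universe_too_small_rejected(self):
        with pytest.raises(md.SamplingError):
            md.null_cluster_significance(1.0, self._universe(n=5), 10, 5, n_null=10, seed=1)

    def test_seeded_reproducibility(self):
        u = self._universe()
        a = md.null_cluster_significance(2.0, u, 10, 5, n_null=20, seed=9)
        b = md.null_cluster_significance(2.0, u, 10, 5, n_null=20, seed=9)
        assert a == b


class TestMatrixComparison:
    def test_identical_one_hot_matrices(self):
        m = md.consensus_matrix("AAATACAT")
        assert md.motif_matrix_correlation(m, m) == pytest.approx(1.0)

    def test_reverse_complement_alignment(self):
        m = md.consensus_matrix("AAATACAT")
        rc = md.consensus_matrix(reverse_complement("AAATACAT"))
        assert md.motif_matrix_correlation(m, rc) == pytest.approx(1.0)

    def test_shifted_overlap(self):
        a = md.consensus_matrix("GGAAATACAT")  # planted core with 5' padding
        b = md.consensus_matrix("AAATACAT")
        assert md.motif_matrix_correlation(a, b) == pytest.approx(1.0)

    def test_meme_output_well_formed(self, tmp_path):
        seqs = ["CCAAATACATGG"] * 5
        motif = md.assemble_motif(scores_frame([("AAATACAT", 1e-6)]), seqs)
        out = tmp_path / "m.meme"
        md.write_meme(motif, out)
        text = out.read_text()
        assert "MEME version 4" in text
        assert f"w= {motif.width}" in text
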