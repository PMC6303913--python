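"""Top-k-mer selection, representatives, anchored PFMs, motif formats."""

import re

import numpy as np
import pytest

import selexkit as sk
from selexkit import seq
from selexkit.affinity import AffinityTable
from selexkit.motif import MotifMatrix


def table_from_values(values: dict[str, float], k: int = 3) -> AffinityTable:
    rel = np.zeros(4 ** k)
    counts = np.zeros(4 ** k, dtype=np.int64)
    for w, v in values.items():
        rel[seq.word_to_index(w)] = v
        counts[seq.word_to_index(w)] = 5
    top = int(rel.argmax())
    return AffinityTable(k=k, condition_label="t", final_round_index=1,
                         strand_mode="single", counts=counts,
                         raw_ratio=rel.copy(), rel_affinity=rel / rel.max(),
                         min_count=1, exponent_mode="ratio",
                         normalization_word=seq.index_to_word(top, k))


class TestTopKmers:
    def test_selects_highest_fraction(self):
        vals = {seq.index_to_word(i, 3): 0.05 * (i + 1) for i in range(10)}
        top = sk.top_kmers(table_from_values(vals), fraction=0.2)
        assert len(top.words) == 2
        assert top.words == [seq.index_to_word(9, 3), seq.index_to_word(8, 3)]

    def test_boundary_tie_breaks_lexicographically(self):
        top = sk.top_kmers(table_from_values(
            {"AAA": 1.0, "CCC": 0.5, "GGG": 0.5, "TTT": 0.1}), fraction=0.5)
        assert top.words == ["AAA", "CCC"]

    def test_fraction_one_returns_all_sorted(self):
        vals = {"ACG": 1.0, "TTT": 0.2, "GGA": 0.7}
        top = sk.top_kmers(table_from_values(vals), fraction=1.0)
        assert top.words == ["ACG", "GGA", "TTT"]
        assert top.affinities == sorted(top.affinities, reverse=True)

    def test_possible_universe_size(self):
        top = sk.top_kmers(table_from_values({"AAA": 1.0}), fraction=0.001,
                           universe="possible")
        assert top.universe_size == 4 ** 3
        assert len(top.words) == 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sk.top_kmers(table_from_values({"AAA": 1.0}), fraction=0.0)

    def test_scale_invariance_of_selection(self):
        vals = {"ACG": 0.9, "TTT": 0.2, "GGA": 0.7, "CCC": 0.4}
        t1 = table_from_values(vals)
        t2 = table_from_values(vals)
        t2.rel_affinity = t2.rel_affinity * 0.35  # any global rescaling
        assert sk.top_kmers(t1, 0.5).words == sk.top_kmers(t2, 0.5).words


class TestRepresentatives:
    def test_highest_multiplicity_wins(self):
        reads = sk.RoundReads(1, ["ACGTA"] * 3 + ["TACGT"])
        assert sk.representative_sequence("ACG", reads,
                                          strand_mode="single") == "ACGTA"

    def test_absent_word_returns_none(self):
        reads = sk.RoundReads(1, ["AAAAA", "CCCCC"])
        assert sk.representative_sequence("GGG", reads,
                                          strand_mode="single") is None

    def test_multiplicity_tie_breaks_lexicographically(self):
        reads = sk.RoundReads(1, ["TACGA", "ACGTT"])
        assert sk.representative_sequence("ACG", reads,
                                          strand_mode="single") == "ACGTT"

    def test_collapsed_mode_orients_read_toward_word(self):
        # read contains only the reverse complement of the query word
        reads = sk.RoundReads(1, ["AAACGTAA"])
        rep = sk.representative_sequence("ACGTTT", reads,
                                         strand_mode="collapsed")
        assert rep == seq.revcomp("AAACGTAA")
        assert "ACGTTT" in rep
        assert sk.representative_sequence("ACGTTT", reads,
                                          strand_mode="single") is None


class TestAnchoredPfm:
    def test_single_onehot_representative(self):
        top = sk.TopKmerSet(words=["ACG"], affinities=[1.0],
                            selection_fraction=1.0, universe="observed",
                            universe_size=1)
        pfm = sk.build_anchored_pfm(top, table_from_values({"ACG": 1.0}),
                                    flank=0, reps={"ACG": "TACGT"})
        expect = np.zeros((4, 3))
        for col, base in enumerate("ACG"):
            expect[seq.word_to_index(base), col] = 1.0
        assert np.allclose(pfm.counts, expect)
        assert pfm.consensus() == "ACG"

    def test_weighted_duplicates_equal_single(self):
        table = table_from_values({"ACG": 1.0})
        top2 = sk.TopKmerSet(words=["ACG", "ACG"], affinities=[0.5, 0.5],
                             selection_fraction=1.0, universe="observed",
                             universe_size=2)
        top1 = sk.TopKmerSet(words=["ACG"], affinities=[1.0],
                             selection_fraction=1.0, universe="observed",
                             universe_size=1)
        reps = {"ACG": "TACGT"}
        p2 = sk.build_anchored_pfm(top2, table, 1, reps)
        p1 = sk.build_anchored_pfm(top1, table, 1, reps)
        assert np.allclose(p2.probabilities, p1.probabilities)

    def test_out_of_range_positions_padded_uniformly(self):
        top = sk.TopKmerSet(words=["ACG"], affinities=[1.0],
                            selection_fraction=1.0, universe="observed",
                            universe_size=1)
        pfm = sk.build_anchored_pfm(top, table_from_values({"ACG": 1.0}),
                                    flank=2, reps={"ACG": "ACGT"})
        # columns 0-1 fall off the left edge -> flat 0.25
        assert np.allclose(pfm.counts[:, :2], 0.25)
        col_totals = pfm.counts.sum(axis=0)
        assert np.allclose(col_totals, col_totals[0])

    def test_missing_representatives_skipped(self):
        top = sk.TopKmerSet(words=["ACG", "TTT"], affinities=[1.0, 0.5],
                            selection_fraction=1.0, universe="observed",
                            universe_size=2)
        pfm = sk.build_anchored_pfm(top, table_from_values({"ACG": 1.0}),
                                    0, {"ACG": "ACGT", "TTT": None})
        assert pfm.n_contributing == 1

    def test_negative_flank_rejected(self):
        top = sk.TopKmerSet(words=["ACG"], affinities=[1.0],
                            selection_fraction=1.0, universe="observed",
                            universe_size=1)
        with pytest.raises(ValueError):
            sk.build_anchored_pfm(top, table_from_values({"ACG": 1.0}),
                                  -1, {"ACG": "ACGT"})


MEME_GRAMMAR = re.compile(
    r"\AMEME version 4\n\n"
    r"ALPHABET= ACGT\n\n"
    r"strands: \+ -\n\n"
    r"Background letter frequencies\n"
    r"A 0\.25 C 0\.25 G 0\.25 T 0\.25\n\n"
    r"MOTIF \S+\n"
    r"letter-probability matrix: alength= 4 w= (\d+) nsites= \d+ E= \d+\n"
    r"( \d\.\d{6} \d\.\d{6} \d\.\d{6} \d\.\d{6}\n)+\Z")


class TestMotifFormats:
    @pytest.fixture()
    def pfm(self):
        counts = np.array([[3.0, 0, 1], [1, 2, 1], [0, 1, 1], [0, 1, 1]])
        return MotifMatrix(width=3, counts=counts, n_contributing=4,
                           anchor_offset=0)

    def test_meme_write_read_write_identical(self, pfm, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        sk.export_motif(pfm, p1, "meme", name="m1")
        back = sk.read_motif(p1, "meme")
        sk.export_motif(back, p2, "meme", name="m1")
        assert p1.read_text() == p2.read_text()

    def test_jaspar_write_read_write_identical(self, pfm, tmp_path):
        p1, p2 = tmp_path / "a.pfm", tmp_path / "b.pfm"
        sk.export_motif(pfm, p1, "jaspar", name="m1")
        back = sk.read_motif(p1, "jaspar")
        sk.export_motif(back, p2, "jaspar", name="m1")
        assert p1.read_text() == p2.read_text()

    def test_jaspar_onehot_layout(self, tmp_path):
        counts = np.zeros((4, 2))
        counts[0, 0] = counts[1, 1] = 1.0  # "AC"
        pfm = MotifMatrix(2, counts, 1, 0)
        path = tmp_path / "m.pfm"
        sk.export_motif(pfm, path, "jaspar", name="AC_motif")
        text = path.read_text()
        assert text.splitlines()[0] == ">AC_motif"
        assert text.splitlines()[1] == "A [ 1.000000 0.000000 ]"
        assert text.splitlines()[4] == "T [ 0.000000 0.000000 ]"

    def test_meme_output_parses_under_grammar(self, pfm, tmp_path):
        path = tmp_path / "m.txt"
        sk.export_motif(pfm, path, "meme")
        m = MEME_GRAMMAR.match(path.read_text())
        assert m, "MEME-minimal output violates the format grammar"
        assert int(m.group(1)) == pfm.width

    def test_unknown_format_rejected(self, pfm, tmp_path):
        with pytest.raises(ValueError):
            sk.export_motif(pfm, tmp_path / "x", "transfac")


def test_fasta_and_motif_outputs_deterministic(recovery_experiment, tmp_path):
    atab = recovery_experiment["affinities"]
    final = recovery_experiment["rounds"][-1]
    top = sk.top_kmers(atab, 0.0001)
    reps = sk.representative_sequences(top.words, final)
    pfm = {}
    for tag in ("a", "b"):
        sk.write_representatives_fasta(top, reps, tmp_path / f"{tag}.fasta")
        m = sk.build_anchored_pfm(top, atab, 5, reps)
        sk.export_motif(m, tmp_path / f"{tag}.txt", "meme")
        pfm[tag] = m
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (tmp_path / "a.txt").read_bytes() == (tmp_path / "b.txt").read_bytes()
    header = (tmp_path / "a.fasta").read_text().splitlines()[0]
    assert header.startswith(">") and "rel_affinity=" in header
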