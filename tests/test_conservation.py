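"""Conservation counting, identity bins, reference mapping, global alignment."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from fivetm import conservation, synthetic
from fivetm.conservation import Alignment


TOY_FASTA = """\
>ref
ACDEFGHIKL
>s1
ACDEFGHIKL
>s2
ACDEYGHIKL
"""


def write_fasta(path, text):
    path.write_text(text)
    return path


class TestReadAlignment:
    def test_fasta_and_clustal_parse_identically(self, tmp_path):
        fasta = write_fasta(tmp_path / "toy.fasta", TOY_FASTA)
        a = conservation.read_alignment(fasta)
        # render the same alignment as clustal and re-read
        from Bio import AlignIO, SeqIO

        records = list(SeqIO.parse(str(fasta), "fasta"))
        from Bio.Align import MultipleSeqAlignment

        msa = MultipleSeqAlignment(records)
        clustal = tmp_path / "toy.aln"
        AlignIO.write(msa, str(clustal), "clustal")
        b = conservation.read_alignment(clustal)
        assert a.records == b.records

    def test_width_and_record_count_match_text_scan(self, tmp_path):
        fasta = write_fasta(tmp_path / "toy.fasta", TOY_FASTA)
        a = conservation.read_alignment(fasta)
        n_headers = sum(1 for line in TOY_FASTA.splitlines() if line.startswith(">"))
        assert len(a.records) == n_headers
        assert a.width == 10

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment([("a", "ACDE"), ("b", "ACD")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment([("a", "ACDE"), ("a", "ACDE")])


class TestMapToReference:
    def test_gap_free_reference_is_identity(self):
        a = Alignment([("ref", "ACDEF"), ("s", "AC-EF")])
        mapping = conservation.map_to_reference(a, "ref")
        assert mapping == {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}

    def test_reference_gap_shifts_positions(self):
        # 10-column toy with a reference gap at column 4 (0-based)
        a = Alignment([("ref", "ACDE-FGHIK"), ("s", "ACDEWFGHIK")])
        mapping = conservation.map_to_reference(a, "ref")
        assert 4 not in mapping
        assert mapping[5] == 5  # column after the gap maps to position 5
        assert mapping[9] == 9

    def test_composing_with_inverse_is_identity(self):
        a = Alignment([("ref", "AC-DE-FG"), ("s", "ACXDEXFG")])
        mapping = conservation.map_to_reference(a, "ref")
        inverse = {pos: col for col, pos in mapping.items()}
        for col, pos in mapping.items():
            assert inverse[pos] == col

    def test_missing_reference_errors(self):
        a = Alignment([("x", "ACDE")])
        with pytest.raises(KeyError):
            conservation.map_to_reference(a, "nope")


class TestAbsoluteConservation:
    def test_self_clade_counts_ungapped_length(self):
        a = Alignment([("ref", "AC-DEF"), ("s", "ACWDEF")])
        count, positions = conservation.absolute_conservation(a, "ref", ["ref"])
        assert count == 5
        assert positions == {1, 2, 3, 4, 5}

    def test_planted_count_recovered_exactly(self):
        aln, conserved = synthetic.make_msa(
            n_seqs=71, ref_length=305, conserved_positions=set(range(1, 63)),
            mutation_rate=1.0, seed=0, ref_id="ref",
        )
        count, positions = conservation.absolute_conservation(aln, "ref")
        assert count == 62
        assert positions == conserved

    def test_matches_brute_force_column_scan(self):
        aln, _ = synthetic.make_msa(
            n_seqs=19, ref_length=50, conserved_positions=set(range(1, 11)),
            mutation_rate=0.4, seed=3, ref_id="ref",
        )
        _, positions = conservation.absolute_conservation(aln, "ref")
        ref = aln.sequence("ref")
        others = [seq for rid, seq in aln.records if rid != "ref"]
        expected = set()
        pos = 0
        for col, ch in enumerate(ref):
            if ch == "-":
                continue
            pos += 1
            if all(o[col] == ch for o in others):
                expected.add(pos)
        assert positions == expected

    def test_adding_sequences_never_increases_count(self):
        aln, _ = synthetic.make_msa(
            n_seqs=20, ref_length=60, conserved_positions=set(range(1, 16)),
            mutation_rate=0.3, seed=4, ref_id="ref",
        )
        ids = [i for i in aln.ids if i != "ref"]
        prev = None
        for k in (5, 10, 15, 20):
            count, _ = conservation.absolute_conservation(aln, "ref", ids[:k])
            if prev is not None:
                assert count <= prev
            prev = count

    def test_empty_clade_errors(self):
        a = Alignment([("ref", "ACDE")])
        with pytest.raises(ValueError, match="empty"):
            conservation.absolute_conservation(a, "ref", [])


class TestIdentityBins:
    def test_identical_sequences_all_bin_nine(self):
        a = Alignment([("ref", "ACDEF"), ("s1", "ACDEF"), ("s2", "ACDEF")])
        profile = conservation.identity_bins(a, "ref")
        assert np.all(profile.bins == 9)

    def test_half_identity_bin_five(self):
        seqs = [("ref", "A")] + [(f"s{i}", "A" if i < 5 else "C") for i in range(10)]
        profile = conservation.identity_bins(Alignment(seqs), "ref")
        assert profile.identity_fraction[0] == pytest.approx(0.5)
        assert profile.bins[0] == 5

    def test_bins_monotone_in_fraction(self):
        aln, _ = synthetic.make_msa(
            n_seqs=12, ref_length=40, conserved_positions=set(range(1, 8)),
            mutation_rate=0.5, seed=5, ref_id="ref",
        )
        profile = conservation.identity_bins(aln, "ref")
        order = np.argsort(profile.identity_fraction)
        assert np.all(np.diff(profile.bins[order]) >= 0)

    def test_row_order_invariance(self):
        aln, _ = synthetic.make_msa(
            n_seqs=8, ref_length=30, conserved_positions={1, 2, 3},
            mutation_rate=0.6, seed=6, ref_id="ref",
        )
        shuffled = Alignment([aln.records[0]] + aln.records[:0:-1])
        a = conservation.identity_bins(aln, "ref")
        b = conservation.identity_bins(shuffled, "ref")
        assert np.array_equal(a.bins, b.bins)
        assert np.allclose(a.identity_fraction, b.identity_fraction)


def enumerate_alignments(a, b):
    """All global alignments of two sequences as (top, bottom) strings."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for top, bottom in enumerate_alignments(a[1:], b):
            yield (a[0] + top, "-" + bottom)
    if b:
        for top, bottom in enumerate_alignments(a, b[1:]):
            yield ("-" + top, b[0] + bottom)
    if a and b:
        for top, bottom in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + top, b[0] + bottom)


def score_alignment(top, bottom, matrix, gap_open, gap_extend):
    """Affine-gap score: a run of k gaps costs open + (k-1)*extend."""
    score = 0.0
    for seq in (top, bottom):
        run = 0
        for ch in seq:
            if ch == "-":
                run += 1
            else:
                if run:
                    score -= gap_open + (run - 1) * gap_extend
                run = 0
        if run:
            score -= gap_open + (run - 1) * gap_extend
    for x, y in zip(top, bottom):
        if x != "-" and y != "-":
            score += matrix[x, y]
    return score


class TestGlobalAlign:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "WFDEK"
        matrix = substitution_matrices.load("BLOSUM62")
        (top, bottom), score, identity = conservation.global_align(seq, seq)
        assert identity == pytest.approx(100.0)
        assert top == bottom == seq
        assert score == pytest.approx(sum(matrix[c, c] for c in seq))

    @pytest.mark.parametrize(
        "a,b",
        [("ACDE", "ACE"), ("WWF", "WF"), ("KLMNQ", "KQ"), ("ACDEFG", "DEF"), ("AC", "CA")],
    )
    def test_matches_exhaustive_enumeration(self, a, b):
        matrix = substitution_matrices.load("BLOSUM62")
        best = max(
            score_alignment(top, bottom, matrix, 10.0, 1.0)
            for top, bottom in enumerate_alignments(a, b)
        )
        _, score, _ = conservation.global_align(a, b)
        assert score == pytest.approx(best)

    def test_score_symmetric_for_symmetric_matrix(self):
        _, sab, _ = conservation.global_align("ACDEFW", "ACEW")
        _, sba, _ = conservation.global_align("ACEW", "ACDEFW")
        assert sab == pytest.approx(sba)

    def test_unknown_matrix_errors(self):
        with pytest.raises(ValueError, match="unknown substitution matrix"):
            conservation.global_align("ACD", "ACD", substitution="NOSUCH99")


class TestPaintConservation:
    def test_uniform_profile_paints_everywhere(self, toy):
        structure, _ = toy
        m = structure.first
        positions = np.array(sorted(set(int(r) for r in m.res_seq)))
        profile = conservation.ConservationProfile(
            "ref", positions, np.ones(len(positions)), np.full(len(positions), 9)
        )
        painted = conservation.paint_conservation(structure, profile)
        assert np.all(painted.first.bfactor == 9.0)

    def test_single_position_painted(self, toy):
        structure, _ = toy
        profile = conservation.ConservationProfile(
            "ref", np.array([118]), np.array([0.3]), np.array([3])
        )
        painted = conservation.paint_conservation(structure, profile)
        m = painted.first
        assert np.all(m.bfactor[m.res_seq == 118] == 3.0)
        assert np.all(m.bfactor[m.res_seq != 118] == -1.0)

    def test_bins_survive_file_roundtrip(self, tmp_path, toy):
        from fivetm.structure import read_structure, write_structure

        structure, _ = toy
        m = structure.first
        positions = np.array(sorted(set(int(r) for r in m.res_seq)))
        bins = (positions % 9) + 1
        profile = conservation.ConservationProfile(
            "ref", positions, bins / 9.0, bins
        )
        painted = conservation.paint_conservation(structure, profile)
        path = tmp_path / "painted.pdb"
        write_structure(painted, path)
        back = read_structure(path)
        assert np.array_equal(back.first.bfactor, painted.first.bfactor)
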