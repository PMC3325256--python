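"""Motif scanning, pairwise similarity statistics and column mapping."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from protonwire.conservation import (
    AlignmentSet,
    ConservationProfile,
    InvalidSequenceError,
    MotifPattern,
    annotate_pathway,
    column_to_residue_map,
    pairwise_stats,
    scan_motif,
)
from protonwire.pathway import Pathway
from protonwire.synth import MotifAlignmentSpec, make_motif_alignment
from conftest import assemble, make_residue


def brute_force_scan(sequence, pattern: MotifPattern):
    """Independent sliding-window matcher."""
    elements = pattern.elements()
    hits = []
    for start in range(len(sequence) - len(elements) + 1):
        ok = True
        for offset, e in enumerate(elements):
            c = sequence[start + offset]
            if e == "x":
                continue
            if e.startswith("["):
                if c not in e[1:-1]:
                    ok = False
                    break
            elif e.startswith("{"):
                if c in e[1:-1]:
                    ok = False
                    break
            elif c != e.upper():
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits


class TestMotifPattern:
    def test_prosite_form_expands(self):
        p = MotifPattern("H-x-H-x(2)-H-x(2)-H-x-H")
        assert len(p) == 11
        assert p.to_regex() == "H[A-Z]H[A-Z][A-Z]H[A-Z][A-Z]H[A-Z]H"

    def test_compact_form_with_repeat_digits(self):
        p = MotifPattern("Hx6L")  # the L3 consensus: H, six arbitrary, L
        assert len(p) == 8
        assert p.to_regex() == "H[A-Z][A-Z][A-Z][A-Z][A-Z][A-Z]L"

    def test_all_wildcard_pattern_rejected(self):
        with pytest.raises(ValueError, match="literal"):
            MotifPattern("x-x(3)").elements()


class TestScanMotif:
    def test_histidine_rich_motif_found_at_planted_position(self):
        # the His-rich stretch sits at positions 102..112 of this fragment
        prefix = "".join("ACDEFGIKLMNPQRSTVWY"[i % 19] for i in range(101))
        motif = "HVHDEHVMHFH"  # matches HxHxxHxxHxH
        seq = prefix + motif + "GGSA"
        hits = scan_motif(seq, "HxHxxHxxHxH")
        assert [h.start for h in hits] == [102]

    def test_sequence_without_histidine_gives_no_hits(self):
        assert scan_motif("ACDEFGIKLMNPQRSTVWY" * 5, "HxHxxHxxHxH") == []

    def test_overlapping_matches_are_reported(self):
        hits = scan_motif("HAHAHAH", "H-x-H")
        assert [h.start for h in hits] == [1, 3, 5]

    def test_invalid_letters_error_lists_positions(self):
        with pytest.raises(InvalidSequenceError, match="position"):
            scan_motif("ACDB1Z", "H-x-H")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_generated_sequences(self, seed):
        alignment, starts = make_motif_alignment(
            MotifAlignmentSpec(seed=seed, length=200, planted_start=77, mutation_rate=0.3)
        )
        pattern = MotifPattern("H-x-H-x(2)-H-x(2)-H-x-H")
        for sid in alignment.ids:
            seq = alignment.ungapped(sid)
            ours = [h.start for h in scan_motif(seq, pattern, sid)]
            assert ours == brute_force_scan(seq, pattern)
            assert starts[0] in ours


class TestPairwiseStats:
    def test_identical_sequences(self):
        stats = pairwise_stats("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY")
        assert stats["identical_pct"] == 100.0
        assert stats["strong_pct"] == 0.0
        assert stats["weak_pct"] == 0.0

    def test_hand_built_alignment_percentages(self):
        # 10 columns: 5 identical, 2 strong (M/L in MILV, F/Y in FYW),
        # 1 weak (C/S in CSA), 2 unconserved (W/P, P/G)
        row_a = "AGLSTMFCWP"
        row_b = "AGLSTLYSPG"
        stats = pairwise_stats(
            None, None, mode="precomputed-alignment", alignment=(row_a, row_b)
        )
        assert stats["identical_pct"] == pytest.approx(50.0)
        assert stats["strong_pct"] == pytest.approx(20.0)
        assert stats["weak_pct"] == pytest.approx(10.0)
        assert stats["none_pct"] == pytest.approx(20.0)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_stats("", "ACD")

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40),
    )
    def test_categories_partition_the_alignment(self, a, b):
        stats = pairwise_stats(a, b)
        total = (
            stats["identical_pct"] + stats["strong_pct"]
            + stats["weak_pct"] + stats["none_pct"]
        )
        assert total == pytest.approx(100.0, abs=0.1)


class TestProfile:
    def test_zero_mutation_rate_gives_all_identical_columns(self):
        alignment, _ = make_motif_alignment(MotifAlignmentSpec(seed=1, mutation_rate=0.0))
        profile = ConservationProfile.from_alignment(alignment)
        assert set(profile.category) == {"*"}
        assert all(f == 1.0 for f in profile.identity)

    def test_row_order_never_changes_the_profile(self):
        alignment, _ = make_motif_alignment(MotifAlignmentSpec(seed=2, mutation_rate=0.4))
        shuffled = AlignmentSet(
            ids=list(reversed(alignment.ids)),
            sequences=list(reversed(alignment.sequences)),
        )
        p1 = ConservationProfile.from_alignment(alignment)
        p2 = ConservationProfile.from_alignment(shuffled)
        assert p1.identity == p2.identity
        assert p1.category == p2.category

    def test_motif_columns_identical_despite_high_mutation(self):
        spec = MotifAlignmentSpec(seed=3, mutation_rate=0.5, planted_start=40)
        alignment, starts = make_motif_alignment(spec)
        profile = ConservationProfile.from_alignment(alignment)
        start0 = starts[0] - 1
        motif_len = len(MotifPattern(spec.motif))
        assert all(c == "*" for c in profile.category[start0:start0 + motif_len])


class TestColumnMapping:
    def _chain(self, letters, start=1):
        one_to_three = {
            "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "G": "GLY",
            "H": "HIS", "K": "LYS", "L": "LEU", "R": "ARG", "S": "SER",
        }
        residues = [
            make_residue(one_to_three[c], [("CA", "C", (float(i), 0, 0))], number=start + i)
            for i, c in enumerate(letters)
        ]
        return assemble(chains={"A": residues}), residues

    def test_exact_match_is_identity_on_positions(self):
        s, residues = self._chain("ACDHK")
        aln = AlignmentSet(ids=["ref", "other"], sequences=["ACDHK", "ACEHK"])
        mapping = column_to_residue_map(aln, "ref", s, "A")
        assert [mapping[i].number for i in range(5)] == [1, 2, 3, 4, 5]

    def test_internal_gap_shifts_following_columns(self):
        s, residues = self._chain("ACDHK")
        aln = AlignmentSet(ids=["ref", "other"], sequences=["AC-DHK", "ACXDHK"])
        mapping = column_to_residue_map(aln, "ref", s, "A")
        assert 2 not in mapping  # the gap column maps to nothing
        assert mapping[3].number == 3 and mapping[5].number == 5

    def test_wrong_chain_raises_below_identity_threshold(self):
        s, _ = self._chain("AAAAAAAAAA")
        aln = AlignmentSet(ids=["ref"], sequences=["CDEGHKLRSC"])
        with pytest.raises(ValueError, match="right chain"):
            column_to_residue_map(aln, "ref", s, "A")


class TestAnnotatePathway:
    def test_annotations_reflect_constructed_categories(self):
        s, residues = self._setup()
        aln = AlignmentSet(
            ids=["ref", "r2", "r3"],
            sequences=["HDK", "HDR", "HDK"],  # col0 '*', col1 '*', col2 K/R strong-ish
        )
        profile = ConservationProfile.from_alignment(aln)
        mapping = column_to_residue_map(aln, "ref", s, "A")
        pathway = Pathway(
            nodes=["M:NI:501", "A:HIS1:sc", "W:W:101", "A:ASP2:sc", "A:LYS3:sc"],
            steps=[0.0, 1.8, 1.8, 1.9],
            bottleneck=1.9, total_length=5.5,
        )
        annotate_pathway(pathway, profile, mapping)
        notes = pathway.annotations
        assert notes["W:W:101"] == {"note": "structural water"}
        assert notes["M:NI:501"]["note"] == "metal/hetero site"
        assert notes["A:HIS1:sc"]["category"] == "*"
        assert notes["A:ASP2:sc"]["category"] == "*"
        assert notes["A:LYS3:sc"]["category"] == ":"  # K/R: strong group QHRK

    def test_unmapped_residue_flagged_unaligned(self):
        s, residues = self._setup()
        aln = AlignmentSet(ids=["ref"], sequences=["HDK"])
        profile = ConservationProfile.from_alignment(aln)
        mapping = column_to_residue_map(aln, "ref", s, "A")
        pathway = Pathway(nodes=["B:GLU9:sc"], steps=[], bottleneck=0.0, total_length=0.0)
        annotate_pathway(pathway, profile, mapping)
        assert pathway.annotations["B:GLU9:sc"] == {"note": "unaligned"}

    def _setup(self):
        residues = [
            make_residue("HIS", [("CA", "C", (0, 0, 0))], number=1),
            make_residue("ASP", [("CA", "C", (3, 0, 0))], number=2),
            make_residue("LYS", [("CA", "C", (6, 0, 0))], number=3),
        ]
        return assemble(chains={"A": residues}), residues


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        alignment, _ = make_motif_alignment(MotifAlignmentSpec(seed=5, n_sequences=4))
        path = tmp_path / "aln.fasta"
        path.write_text(alignment.to_fasta())
        again = AlignmentSet.from_file(path)
        assert again.ids == alignment.ids
        assert again.sequences == alignment.sequences

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="length"):
            AlignmentSet(ids=["a", "b"], sequences=["ACD", "AC"])

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(InvalidSequenceError):
            AlignmentSet(ids=["a"], sequences=["AC1"])
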