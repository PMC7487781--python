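"""Guide placement, cut-window geometry and donor-edit derivation."""

import numpy as np
import pytest

from ampedit.dna import matches_iupac, revcomp
from ampedit.locus import (
    CutWindow,
    LocusError,
    ReferenceAmplicon,
    cut_window,
    derive_edits,
    locate_guide,
)

PROTO = "GACGTTCACAGCTTAGGCAT"  # arbitrary 20-mer, no internal repeats


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocateGuide:
    def test_plus_strand_at_origin_cuts_between_16_and_17(self):
        ref = ReferenceAmplicon("r", PROTO + "AGG" + "TTTTTTTTTT")
        site = locate_guide(ref, PROTO)
        assert (site.strand, site.pam_start, site.cut_index) == ("+", 20, 17)

    def test_minus_strand_embedding_cuts_at_length_minus_17(self):
        # Construct on the reverse strand at the end of a 60-nt reference:
        # scanning the reverse complement sees protospacer+PAM at offset 0.
        head = "CCCCAAAACCCCAAAACCCCAAAACCCCAAAACCCCA"
        ref = ReferenceAmplicon("r", head + revcomp(PROTO + "AGG"))
        assert len(ref) == 60
        site = locate_guide(ref, PROTO)
        assert site.strand == "-"
        assert site.cut_index == 60 - 17

    def test_absent_protospacer_reports_zero_placements(self):
        ref = ReferenceAmplicon("r", "A" * 60)
        with pytest.raises(LocusError, match="0 placements"):
            locate_guide(ref, PROTO)

    def test_ambiguous_placement_reports_count(self):
        ref = ReferenceAmplicon("r", PROTO + "AGG" + "TT" + PROTO + "TGG")
        with pytest.raises(LocusError, match="2 placements"):
            locate_guide(ref, PROTO)

    def test_placement_reproduces_protospacer_on_random_references(self):
        # Reading the reference back at the reported placement (strand-
        # adjusted) must reproduce the protospacer exactly.
        rng = np.random.default_rng(11)
        for trial in range(20):
            proto = _random_dna(rng, 20)
            flank = _random_dna(rng, 40)
            if trial % 2 == 0:
                seq = flank + proto + "AGG" + _random_dna(rng, 20)
            else:
                seq = flank + revcomp(proto + "AGG") + _random_dna(rng, 20)
            ref = ReferenceAmplicon("r", seq)
            try:
                site = locate_guide(ref, proto)
            except LocusError:
                continue  # accidental extra placement in random flank
            if site.strand == "+":
                start = site.pam_start - 20
                assert seq[start : site.pam_start] == proto
                assert matches_iupac(seq[site.pam_start : site.pam_start + 3], "NGG")
            else:
                segment = seq[site.pam_start + 3 : site.pam_start + 23]
                assert revcomp(segment) == proto
                assert matches_iupac(
                    revcomp(seq[site.pam_start : site.pam_start + 3]), "NGG"
                )


class TestCutWindow:
    def test_default_window_sets_around_cut_20(self):
        w = cut_window(20, 3)
        assert w.deleted_coords == frozenset(range(17, 23))
        assert w.insertion_anchors == frozenset(range(17, 24))

    def test_degenerate_window_is_empty_but_cut_overlap_still_counts(self):
        w = cut_window(20, 0)
        assert w.deleted_coords == frozenset()
        assert w.insertion_anchors == frozenset({20})
        assert w.hits_deletion(20, 1)  # removes base at the cut
        assert w.hits_deletion(19, 1)
        assert not w.hits_deletion(18, 1)
        assert w.hits_insertion(20)
        assert not w.hits_insertion(19)

    def test_boundary_deletion_membership(self):
        w = cut_window(20, 3)
        assert not w.hits_deletion(16, 1)  # coord 16 is outside
        assert w.hits_deletion(17, 1)  # coord 17 is inside

    @pytest.mark.parametrize("small,large", [(0, 1), (1, 3), (3, 6), (2, 5)])
    def test_window_monotone_in_w(self, small, large):
        a, b = cut_window(20, small), cut_window(20, large)
        assert a.deleted_coords <= b.deleted_coords
        assert a.insertion_anchors <= b.insertion_anchors

    def test_negative_w_rejected(self):
        with pytest.raises(LocusError):
            CutWindow(20, -1)


class TestDeriveEdits:
    REF40 = "ACGTGGCATTACGGATCCGATCGGATTACAGCATCGGTAC"

    def test_donor_equal_to_reference_substring_is_an_error(self):
        ref = ReferenceAmplicon("r", self.REF40)
        with pytest.raises(LocusError, match="no edits found"):
            derive_edits(ref, self.REF40[5:35], primary=10)

    def test_two_substitutions_with_explicit_primary(self):
        ref = ReferenceAmplicon("r", self.REF40)
        donor = list(self.REF40[10:34])
        donor[18 - 10] = "T" if self.REF40[18] != "T" else "A"
        donor[24 - 10] = "C" if self.REF40[24] != "C" else "G"
        spec = derive_edits(ref, "".join(donor), primary=18)
        assert spec.ref_start == 10
        assert [e.ref_coord for e in spec.edits] == [18, 24]
        assert spec.primary.ref_coord == 18
        assert spec.auxiliary[0].ref_coord == 24
        # Count equals position-by-position Hamming distance on the footprint.
        footprint = self.REF40[10:34]
        hamming = sum(a != b for a, b in zip(footprint, "".join(donor)))
        assert len(spec.edits) == hamming

    def test_nearest_to_cut_selector_prefers_coord_18_for_cut_20(self):
        ref = ReferenceAmplicon("r", self.REF40)
        donor = list(self.REF40[10:34])
        donor[18 - 10] = "T" if self.REF40[18] != "T" else "A"
        donor[24 - 10] = "C" if self.REF40[24] != "C" else "G"
        spec = derive_edits(ref, "".join(donor), primary="nearest-to-cut", cut_index=20)
        assert spec.primary.ref_coord == 18

    def test_primary_selector_not_a_mismatch_is_an_error(self):
        ref = ReferenceAmplicon("r", self.REF40)
        donor = list(self.REF40[10:34])
        donor[8] = "T" if donor[8] != "T" else "A"
        with pytest.raises(LocusError, match="not among donor mismatches"):
            derive_edits(ref, "".join(donor), primary=30)

    def test_donor_with_deletion_rejected(self):
        ref = ReferenceAmplicon("r", self.REF40)
        donor = self.REF40[10:20] + self.REF40[22:34]  # 2-bp internal deletion
        with pytest.raises(LocusError, match="gap"):
            derive_edits(ref, donor, primary=12)

    def test_edit_count_matches_hamming_oracle_on_random_donors(self):
        rng = np.random.default_rng(7)
        ref_seq = _random_dna(rng, 80)
        ref = ReferenceAmplicon("r", ref_seq)
        for _ in range(10):
            start = int(rng.integers(0, 30))
            donor = list(ref_seq[start : start + 40])
            coords = rng.choice(40, size=int(rng.integers(1, 5)), replace=False)
            for c in coords:
                donor[c] = "ACGT"[("ACGT".index(donor[c]) + 1) % 4]
            spec = derive_edits(ref, "".join(donor), primary=start + int(min(coords)))
            hamming = sum(
                a != b for a, b in zip(ref_seq[start : start + 40], "".join(donor))
            )
            assert len(spec.edits) == hamming == len(coords)
            assert spec.ref_start == start


def test_reference_alphabet_is_validated():
    with pytest.raises(LocusError):
        ReferenceAmplicon("r", "ACGTN")
    with pytest.raises(LocusError):
        ReferenceAmplicon("r", "")
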