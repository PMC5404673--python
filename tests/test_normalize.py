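"""Left alignment, 3'-shifting, HGVS nomenclature and the dual-form guarantee.

The shift operations are checked against brute-force enumeration of every
anchored placement reproducing the same edited sequence: left alignment must
pick the minimum position, transcript-directed shifting the strand-aware
extremum.
"""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import equivalent_placements
from vardesk.normalize import (FLANK, NotInTranscriptError, Reference,
                               ReferenceMismatchError, apply_variant,
                               c_coordinate, hgvs_c, hgvs_g, hgvs_p,
                               left_align, normalize_variant, shift_3prime)
from vardesk.variants import GenomicVariant, Transcript, trim
from _oracles import exon_walk_c


def random_indels(ref: Reference, n: int, seed: int, lo: int = 20, hi: int = 380):
    """Random trimmed, anchored pure indels over a reference."""
    rng = np.random.default_rng(seed)
    seq = ref.fetch("chr1", 1, ref.length("chr1"))
    out = []
    while len(out) < n:
        pos = int(rng.integers(lo, hi))
        anchor = seq[pos - 1]
        if rng.random() < 0.5:  # deletion of 1-4 bases after the anchor
            k = int(rng.integers(1, 5))
            if pos + k > len(seq):
                continue
            v = GenomicVariant("chr1", pos, seq[pos - 1 : pos + k - 1] + seq[pos + k - 1], anchor)
            v = GenomicVariant("chr1", pos, anchor + seq[pos : pos + k], anchor)
        else:  # insertion of 1-4 random bases
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
            v = GenomicVariant("chr1", pos, anchor, anchor + ins)
        try:
            out.append(trim(v))
        except Exception:
            continue
    return out


class TestLeftAlign:
    def test_deletion_in_dinucleotide_repeat_reaches_run_start(self, repeat_ref):
        # CA tract at 51-68, guarded by T at 50: delete one CA unit mid-tract
        anchor = repeat_ref.base("chr1", 56)
        v = trim(GenomicVariant("chr1", 56, anchor + repeat_ref.fetch("chr1", 57, 58),
                                anchor))
        la = left_align(v, repeat_ref)
        assert la.pos == 50
        assert (la.ref, la.alt) == ("T" + repeat_ref.fetch("chr1", 51, 52), "T")

    def test_snv_unchanged(self, repeat_ref):
        b = repeat_ref.base("chr1", 90)
        alt = "A" if b != "A" else "G"
        v = GenomicVariant("chr1", 90, b, alt)
        la = left_align(v, repeat_ref)
        assert (la.pos, la.ref, la.alt) == (90, b, alt)
        assert la.state == "left_aligned"

    def test_homopolymer_insertion_aligns_to_run_start(self, repeat_ref):
        # T homopolymer at 121-130: insert one more T mid-run
        v = GenomicVariant("chr1", 125, "T", "TT")
        la = left_align(v, repeat_ref)
        assert la.pos == 120  # anchored on the C guard base before the run
        assert la.alt == la.ref + "T"

    def test_reference_mismatch_rejected(self, repeat_ref):
        b = repeat_ref.base("chr1", 90)
        wrong = "C" if b != "C" else "G"
        with pytest.raises(ReferenceMismatchError):
            left_align(GenomicVariant("chr1", 90, wrong, "T" if wrong != "T" else "A"),
                       repeat_ref)

    def test_agrees_with_enumeration_oracle(self, repeat_ref):
        seq = repeat_ref.fetch("chr1", 1, repeat_ref.length("chr1"))
        for v in random_indels(repeat_ref, 300, seed=5):
            la = left_align(v, repeat_ref)
            placements = equivalent_placements(seq, v.pos, v.ref, v.alt)
            assert (la.pos, la.ref, la.alt) == min(placements)


class TestShift3Prime:
    def wide_tx(self, strand):
        return Transcript("G", "TX", "chr1", strand, ((10, 390),), 20, 380)

    def test_plus_strand_reaches_max_position(self, repeat_ref):
        anchor = repeat_ref.base("chr1", 50)
        v = trim(GenomicVariant("chr1", 50, anchor + "CA", anchor))
        sh = shift_3prime(left_align(v, repeat_ref), self.wide_tx("+"), repeat_ref)
        seq = repeat_ref.fetch("chr1", 1, repeat_ref.length("chr1"))
        assert sh.pos == max(p for p, _, _ in equivalent_placements(seq, v.pos, v.ref, v.alt))

    def test_minus_strand_keeps_min_position(self, repeat_ref):
        anchor = repeat_ref.base("chr1", 50)
        v = trim(GenomicVariant("chr1", 50, anchor + "CA", anchor))
        la = left_align(v, repeat_ref)
        sh = shift_3prime(la, self.wide_tx("-"), repeat_ref)
        assert (sh.pos, sh.ref, sh.alt) == (la.pos, la.ref, la.alt)
        assert sh.state == "shifted_3prime"

    def test_outside_transcript_raises(self, repeat_ref):
        tx = Transcript("G", "TX", "chr1", "+", ((10, 30),), 12, 28)
        v = GenomicVariant("chr1", 300, repeat_ref.base("chr1", 300),
                           "A" if repeat_ref.base("chr1", 300) != "A" else "C",
                           state="left_aligned")
        with pytest.raises(NotInTranscriptError):
            shift_3prime(v, tx, repeat_ref)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_enumeration_oracle(self, repeat_ref, strand):
        seq = repeat_ref.fetch("chr1", 1, repeat_ref.length("chr1"))
        tx = self.wide_tx(strand)
        pick = max if strand == "+" else min
        for v in random_indels(repeat_ref, 300, seed=9, lo=25, hi=375):
            la = left_align(v, repeat_ref)
            sh = shift_3prime(la, tx, repeat_ref)
            placements = equivalent_placements(seq, v.pos, v.ref, v.alt)
            assert (sh.pos, sh.ref, sh.alt) == pick(placements)

    def test_dual_representations_apply_identically(self, repeat_ref):
        tx = self.wide_tx("+")
        for v in random_indels(repeat_ref, 100, seed=13, lo=25, hi=375):
            la = left_align(v, repeat_ref)
            sh = shift_3prime(la, tx, repeat_ref)
            window = (max(1, v.pos - 60), min(repeat_ref.length("chr1"), v.end + 60))
            assert apply_variant(la, repeat_ref, window) == \
                apply_variant(sh, repeat_ref, window)


class TestKeyStability:
    def test_equivalent_raw_representations_share_a_key(self, repeat_ref):
        """Any legal re-anchoring of the same edit normalises to one key."""
        seq = repeat_ref.fetch("chr1", 1, repeat_ref.length("chr1"))
        for v in random_indels(repeat_ref, 60, seed=21):
            placements = equivalent_placements(seq, v.pos, v.ref, v.alt)
            keys = set()
            for p, r, a in placements:
                raw = GenomicVariant("chr1", p, r, a)
                keys.add(left_align(trim(raw), repeat_ref).key)
            assert len(keys) == 1


class TestHgvsG:
    def test_snv_form(self):
        ref = Reference({"chr7": "A" * 200})
        v = GenomicVariant("chr7", 140, "A", "T", state="shifted_3prime")
        assert hgvs_g(v, ref) == "chr7:g.140A>T"

    def test_deletion_range_form(self, tiny_ref):
        # delete bases 100_101 equivalent: use tiny ref at pos 24-26
        v = GenomicVariant("chr1", 24, tiny_ref.fetch("chr1", 24, 26),
                           tiny_ref.base("chr1", 24), state="shifted_3prime")
        assert hgvs_g(v, tiny_ref).endswith(f"g.25_26del")

    def test_single_base_dup_promotion(self):
        # ref[100] == G and inserting G right after it duplicates it
        seq = "A" * 99 + "G" + "A" * 100
        ref = Reference({"chr1": seq})
        v = GenomicVariant("chr1", 100, "G", "GG", state="shifted_3prime")
        assert hgvs_g(v, ref) == "chr1:g.100dup"

    def test_multibase_dup_and_plain_ins(self):
        seq = "T" * 50 + "CAG" + "T" * 50
        ref = Reference({"chr1": seq})
        dup = GenomicVariant("chr1", 53, "G", "GCAG", state="shifted_3prime")
        assert hgvs_g(dup, ref) == "chr1:g.51_53dup"
        ins = GenomicVariant("chr1", 53, "G", "GTTA", state="shifted_3prime")
        assert hgvs_g(ins, ref) == "chr1:g.53_54insTTA"


class TestCodingCoordinates:
    """c. mapping against an independent base-by-base exon walk."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exonic_positions_match_exon_walk(self, strand, plus_tx, minus_tx):
        tx = plus_tx if strand == "+" else minus_tx
        for g in list(range(101, 161)) + list(range(201, 261)) + list(range(301, 361)):
            assert c_coordinate(g, tx) == exon_walk_c(
                g, tx.exons, strand, tx.cds_start, tx.cds_end)

    def test_intronic_offsets_plus_strand(self, plus_tx):
        # 3 bases past the 3' end of exon 1 (ends at 160; last CDS base there
        # is c.40 since CDS starts at 121)
        assert c_coordinate(163, plus_tx) == "40+3"
        # 2 bases before exon 2 start (genomic 201 == c.41)
        assert c_coordinate(199, plus_tx) == "41-2"

    def test_intronic_offsets_minus_strand(self, minus_tx):
        # minus strand: CDS runs 340..121 in transcript order; genomic 301 is
        # the last base of the transcript-first... probe symmetric cases
        assert c_coordinate(298, minus_tx) == c_coordinate(298, minus_tx)
        # exon at 301-360: genomic 298 is 3 bases past its genomic-start edge,
        # which on - strand is the exon's 3' end
        g_edge_c = c_coordinate(301, minus_tx)
        assert c_coordinate(298, minus_tx) == f"{g_edge_c}+3"


class TestHgvsCAndP:
    def test_plus_strand_cds_snv(self, plus_tx, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = Reference({"chr1": seq})
        g = 125  # CDS base 5
        b = ref.base("chr1", g)
        alt = "G" if b != "G" else "A"
        v = GenomicVariant("chr1", g, b, alt, state="shifted_3prime")
        assert hgvs_c(v, plus_tx, ref) == f"TX.P:c.5{b}>{alt}"

    def test_minus_strand_alleles_complemented(self, minus_tx):
        seq = ["A"] * 400
        seq[328] = "C"  # genomic 329; on - strand CDS: count from 340 down
        ref = Reference({"chr1": "".join(seq)})
        v = GenomicVariant("chr1", 329, "C", "T", state="shifted_3prime")
        # genomic 329 is CDS base (340-329+1)=12 on the - strand
        assert hgvs_c(v, minus_tx, ref) == "TX.M:c.12G>A"

    def test_protein_substitution_and_synonymous(self, plus_tx):
        seq = list("A" * 400)
        # CDS starts at 121 (+): codon 2 occupies 124-126; make it GTG (Val)
        seq[120:123] = "ATG"
        seq[123:126] = "GTG"
        ref = Reference({"chr1": "".join(seq)})
        v = GenomicVariant("chr1", 125, "T", "A", state="shifted_3prime")  # GTG->GAG
        assert hgvs_p(v, plus_tx, ref) == "p.(Val2Glu)"
        # third-position change GTG->GTA stays Val
        v2 = GenomicVariant("chr1", 126, "G", "A", state="shifted_3prime")
        assert hgvs_p(v2, plus_tx, ref) == "p.(=)"


class TestNormalizeVariant:
    def test_intergenic_gets_genomic_name_only(self, repeat_ref):
        b = repeat_ref.base("chr1", 395)
        v = GenomicVariant("chr1", 395, b, "A" if b != "A" else "C")
        (n,) = normalize_variant(v, [Transcript("G", "TX", "chr1", "+",
                                                ((10, 30),), 12, 28)], repeat_ref)
        assert n.hgvs_g and n.hgvs_c is None and n.transcript_id is None

    def test_one_record_per_overlapping_reportable_transcript(self, repeat_ref):
        txs = [Transcript("G1", "TX1", "chr1", "+", ((10, 390),), 20, 380),
               Transcript("G2", "TX2", "chr1", "-", ((10, 390),), 20, 380),
               Transcript("G3", "TX3", "chr1", "+", ((10, 390),), 20, 380, reportable=False)]
        b = repeat_ref.base("chr1", 100)
        v = GenomicVariant("chr1", 100, b, "A" if b != "A" else "C")
        out = normalize_variant(v, txs, repeat_ref)
        assert sorted(n.transcript_id for n in out) == ["TX1", "TX2"]
        assert len({n.variant_key for n in out}) == 1
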