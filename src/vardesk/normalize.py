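"""Canonical variant representations and HGVS nomenclature.

Every sequenced variant is held in two canonical forms:

* **left-aligned** — the indel placed at its smallest genomic coordinate
  among all placements producing the same edited sequence (VCF/vt
  convention).  This form supplies the stable ``variant_key`` used for joins
  to the annotation cache and the curated-variant knowledge base.
* **3'-shifted** — the indel placed maximally toward the 3' end of the
  gene's reportable transcript (genomic right for + strand genes, genomic
  left for − strand), per HGVS.  This form drives the displayed HGVS g./c.
  nomenclature, with insertions promoted to duplications where the inserted
  sequence equals the adjacent reference run.

Both forms must apply to the reference to give byte-identical edited
sequences; normalisation is what lets the same biological variant, however
a caller chose to write it, match a single knowledge-base record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .variants import GenomicVariant, Transcript, VariantCall, VariantError, trim


class ReferenceMismatchError(VariantError):
    """The variant's ref allele disagrees with the reference sequence."""


class NotInTranscriptError(VariantError):
    """The variant does not overlap the transcript (plus flank)."""


#: bases of intron/flank beyond exons still expressed in c. notation
FLANK = 200

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


class Reference:
    """1-based inclusive accessor over chromosome sequences.

    Wraps either a plain ``{chrom: sequence}`` mapping or a pyfaidx Fasta.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = seqs

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        from pyfaidx import Fasta

        fa = Fasta(path, as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq):
            raise VariantError(f"{chrom}:{start}-{end} outside reference (len {len(seq)})")
        return seq[start - 1 : end].upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chroms(self) -> list[str]:
        return list(self._seqs)


def apply_variant(v: GenomicVariant, ref: Reference, window: tuple[int, int]) -> str:
    """Apply the edit to reference bases [window], returning the edited string.

    Used to verify that two representations describe the same haplotype.
    """
    ws, we = window
    if not (ws <= v.pos and v.end <= we):
        raise VariantError("variant outside window")
    seq = ref.fetch(v.chrom, ws, we)
    off = v.pos - ws
    if seq[off : off + len(v.ref)] != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.key}: ref allele != reference {seq[off:off + len(v.ref)]!r}"
        )
    return seq[:off] + v.alt.upper() + seq[off + len(v.ref) :]


def _check_ref(v: GenomicVariant, ref: Reference) -> None:
    actual = ref.fetch(v.chrom, v.pos, v.end)
    if actual != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.key}: reference has {actual!r} at {v.chrom}:{v.pos}"
        )


def _decompose(v: GenomicVariant) -> tuple[str, int, str] | None:
    """Return (kind, locus, seq) for a pure indel, else None.

    Deletion: locus = first deleted base (anchor pos + 1), seq = deleted bases.
    Insertion: locus = base the insertion follows (anchor pos), seq = inserted.
    """
    if v.is_deletion:
        return "del", v.pos + 1, v.ref[1:]
    if v.is_insertion:
        return "ins", v.pos, v.alt[1:]
    return None


def _reanchor(v: GenomicVariant, kind: str, locus: int, seq: str, ref: Reference,
              state: str) -> GenomicVariant:
    if kind == "del":
        anchor_pos = locus - 1
        anchor = ref.base(v.chrom, anchor_pos)
        return GenomicVariant(v.chrom, anchor_pos, anchor + seq, anchor, state=state)
    anchor = ref.base(v.chrom, locus)
    return GenomicVariant(v.chrom, locus, anchor, anchor + seq, state=state)


def left_align(v: GenomicVariant, ref: Reference) -> GenomicVariant:
    """Shift an indel to its smallest genomic position; SNVs pass through.

    Pure insertions/deletions are rotated leftward while the flanking
    reference base permits; shifting stops at position 2 so a left anchor
    base always exists.  Complex substitutions are not shiftable.
    """
    _check_ref(v, ref)
    dec = _decompose(v)
    if dec is None:
        return v.with_state("left_aligned")
    kind, locus, seq = dec
    if kind == "del":
        # deleted block [locus, locus+len-1]; shift left while the base before
        # the block equals its last base
        s = locus
        n = len(seq)
        while s - 1 >= 2 and ref.base(v.chrom, s - 1) == ref.fetch(v.chrom, s, s + n - 1)[-1]:
            s -= 1
        new_seq = ref.fetch(v.chrom, s, s + n - 1)
        return _reanchor(v, "del", s, new_seq, ref, "left_aligned")
    # insertion after locus; inserting seq after p == inserting rot-right(seq)
    # after p-1 when ref[p] == seq[-1]
    p, ins = locus, seq
    while p >= 2 and ref.base(v.chrom, p) == ins[-1]:
        ins = ins[-1] + ins[:-1]
        p -= 1
    return _reanchor(v, "ins", p, ins, ref, "left_aligned")


def shift_3prime(v: GenomicVariant, tx: Transcript, ref: Reference) -> GenomicVariant:
    """Shift an indel maximally toward the transcript's 3' end.

    For + strand genes this is the largest genomic position; for − strand
    genes the 3' direction is genomic left, so the left-aligned placement is
    already maximal.  The variant must lie within the transcript span
    (± flank); callers fall back to the left-aligned form otherwise.
    """
    lo, hi = tx.span
    if not (lo - FLANK <= v.pos and v.end <= hi + FLANK):
        raise NotInTranscriptError(f"{v.key} outside {tx.transcript_id} span")
    _check_ref(v, ref)
    if tx.strand == "-":
        return left_align(v, ref).with_state("shifted_3prime")
    dec = _decompose(v)
    if dec is None:
        return v.with_state("shifted_3prime")
    kind, locus, seq = dec
    chrom_len = ref.length(v.chrom)
    if kind == "del":
        s = locus
        n = len(seq)
        # shift right while the base after the block equals its first base
        while s + n <= chrom_len and ref.base(v.chrom, s + n) == ref.base(v.chrom, s):
            s += 1
        new_seq = ref.fetch(v.chrom, s, s + n - 1)
        return _reanchor(v, "del", s, new_seq, ref, "shifted_3prime")
    p, ins = locus, seq
    while p + 1 <= chrom_len and ref.base(v.chrom, p + 1) == ins[0]:
        p += 1
        ins = ins[1:] + ins[0]
    return _reanchor(v, "ins", p, ins, ref, "shifted_3prime")


# ---------------------------------------------------------------------------
# HGVS genomic nomenclature

def promote_dup(v: GenomicVariant, ref: Reference) -> tuple[int, int] | None:
    """If an insertion duplicates the immediately 5'-adjacent reference run,
    return the duplicated genomic interval (start, end); else None."""
    dec = _decompose(v)
    if dec is None or dec[0] != "ins":
        return None
    _, p, ins = dec
    n = len(ins)
    if p - n + 1 < 1:
        return None
    if ref.fetch(v.chrom, p - n + 1, p) == ins:
        return (p - n + 1, p)
    return None


def hgvs_g(v: GenomicVariant, ref: Reference | None = None) -> str:
    """Genomic HGVS string for a normalised variant.

    Duplication promotion requires the reference; without it insertions are
    reported as ins.
    """
    prefix = f"{v.chrom}:g."
    if v.is_snv:
        return f"{prefix}{v.pos}{v.ref}>{v.alt}"
    if v.is_deletion:
        s, e = v.pos + 1, v.end
        return f"{prefix}{s}del" if s == e else f"{prefix}{s}_{e}del"
    if v.is_insertion:
        ins = v.alt[1:]
        if ref is not None:
            dup = promote_dup(v, ref)
            if dup is not None:
                s, e = dup
                return f"{prefix}{s}dup" if s == e else f"{prefix}{s}_{e}dup"
        return f"{prefix}{v.pos}_{v.pos + 1}ins{ins}"
    # multi-nucleotide substitution / delins
    return f"{prefix}{v.pos}_{v.end}delins{v.alt}"


# ---------------------------------------------------------------------------
# coding-coordinate mapping

def _tx_exons(tx: Transcript) -> list[tuple[int, int]]:
    """Exons in transcript (5'→3') order."""
    return list(tx.exons) if tx.strand == "+" else list(reversed(tx.exons))


def _cds_positions(tx: Transcript) -> list[int]:
    """Genomic positions of CDS bases in transcript order."""
    lo, hi = sorted((tx.cds_start, tx.cds_end))
    out = []
    for s, e in _tx_exons(tx):
        rng = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
        out.extend(g for g in rng if lo <= g <= hi)
    return out


def _exonic_positions(tx: Transcript) -> list[int]:
    out = []
    for s, e in _tx_exons(tx):
        rng = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
        out.extend(rng)
    return out


def c_coordinate(g: int, tx: Transcript) -> str:
    """Map a genomic position to an HGVS c. coordinate string.

    Exonic CDS bases are c.1..N; 5' UTR bases are c.-k; 3' UTR bases c.*k;
    intronic bases take the nearest exon edge with a +/− offset (ties go to
    the preceding exon, per HGVS).
    """
    cds = _cds_positions(tx)
    cds_index = {g_: i + 1 for i, g_ in enumerate(cds)}
    exonic = _exonic_positions(tx)

    def exon_coord(gp: int) -> str:
        if gp in cds_index:
            return str(cds_index[gp])
        i = exonic.index(gp)
        first_cds_i = exonic.index(cds[0])
        last_cds_i = exonic.index(cds[-1])
        if i < first_cds_i:
            return f"-{first_cds_i - i}"
        return f"*{i - last_cds_i}"

    if g in set(exonic):
        return exon_coord(g)
    # intronic or flanking: distance to nearest exonic base in transcript sense
    sense = 1 if tx.strand == "+" else -1
    # nearest exon edge genomically
    best = None  # (distance, edge_g, side)
    for s, e in tx.exons:
        for edge, donor_side in ((s, "left"), (e, "right")):
            d = abs(g - edge)
            if best is None or d < best[0]:
                best = (d, edge, donor_side)
    if best is None:
        raise NotInTranscriptError("transcript has no exons")
    d, edge, side = best
    # g beyond the transcript-3' edge of the exon => '+' offset, else '-'
    downstream = (g > edge) if sense == 1 else (g < edge)
    offset = d
    sign = "+" if downstream else "-"
    return f"{exon_coord(edge)}{sign}{offset}"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def hgvs_c(v: GenomicVariant, tx: Transcript, ref: Reference) -> str:
    """Coding HGVS string relative to the transcript CDS.

    Alleles are complemented for − strand genes; dup promotion is evaluated
    on the transcript 3' side (which for the stored 3'-shifted genomic form
    coincides with the genomic 5' side on + strand / 3' run equality on −).
    """
    lo, hi = tx.span
    if v.end < lo - FLANK or v.pos > hi + FLANK:
        raise NotInTranscriptError(f"{v.key} outside {tx.transcript_id} + flank")
    minus = tx.strand == "-"
    prefix = f"{tx.transcript_id}:c."
    if v.is_snv:
        r, a = (( _revcomp(v.ref), _revcomp(v.alt)) if minus else (v.ref, v.alt))
        return f"{prefix}{c_coordinate(v.pos, tx)}{r}>{a}"
    if v.is_deletion:
        g1, g2 = v.pos + 1, v.end
        c1, c2 = c_coordinate(g1, tx), c_coordinate(g2, tx)
        if minus:
            c1, c2 = c2, c1
        return f"{prefix}{c1}del" if g1 == g2 else f"{prefix}{c1}_{c2}del"
    if v.is_insertion:
        ins = v.alt[1:]
        dup = promote_dup(v, ref) if not minus else _promote_dup_minus(v, ref)
        if dup is not None:
            s, e = dup
            c1, c2 = c_coordinate(s, tx), c_coordinate(e, tx)
            if minus:
                c1, c2 = c2, c1
            return f"{prefix}{c1}dup" if s == e else f"{prefix}{c1}_{c2}dup"
        p, q = v.pos, v.pos + 1
        cp, cq = c_coordinate(p, tx), c_coordinate(q, tx)
        tseq = _revcomp(ins) if minus else ins
        if minus:
            cp, cq = cq, cp
        return f"{prefix}{cp}_{cq}ins{tseq}"
    g1, g2 = v.pos, v.end
    c1, c2 = c_coordinate(g1, tx), c_coordinate(g2, tx)
    alt = _revcomp(v.alt) if minus else v.alt
    if minus:
        c1, c2 = c2, c1
    return f"{prefix}{c1}_{c2}delins{alt}"


def _promote_dup_minus(v: GenomicVariant, ref: Reference) -> tuple[int, int] | None:
    """Dup check for − strand genes: the transcript-5'-adjacent run lies
    genomically 3' of the insertion point."""
    dec = _decompose(v)
    if dec is None or dec[0] != "ins":
        return None
    _, p, ins = dec
    n = len(ins)
    if p + n > ref.length(v.chrom):
        return None
    if ref.fetch(v.chrom, p + 1, p + n) == ins:
        return (p + 1, p + n)
    return None


def hgvs_p(v: GenomicVariant, tx: Transcript, ref: Reference) -> str | None:
    """Protein notation for simple CDS substitutions; None when unresolvable.

    Synonymous changes give "p.(=)"; a single-codon substitution gives
    "p.(Xaa<idx>Yaa)".  Indels and multi-codon edits are not attempted.
    """
    if not v.is_snv:
        return None
    cds = _cds_positions(tx)
    if v.pos not in cds:
        return None
    i = cds.index(v.pos)  # 0-based CDS offset
    codon_idx = i // 3
    codon_pos = i % 3
    codon_g = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_g) < 3:
        return None
    bases = [ref.base(v.chrom, g) for g in codon_g]
    if tx.strand == "-":
        bases = [_revcomp(b) for b in bases]
        alt_b = _revcomp(v.alt)
    else:
        alt_b = v.alt
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:codon_pos] + alt_b + ref_codon[codon_pos + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "p.(=)"
    return f"p.({AA3[aa_ref]}{codon_idx + 1}{AA3[aa_alt]})"


# ---------------------------------------------------------------------------
# composite

@dataclass(frozen=True)
class NormalizedVariant:
    """The dual canonical representations plus HGVS strings for one variant."""

    left_aligned: GenomicVariant
    shifted_3prime: GenomicVariant
    variant_key: str
    hgvs_g: str
    transcript_id: str | None = None
    gene: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


def normalize_variant(
    call_or_variant: VariantCall | GenomicVariant,
    transcripts: Iterable[Transcript],
    ref: Reference,
) -> list[NormalizedVariant]:
    """Normalise one variant against every overlapping reportable transcript.

    Returns one record per overlapping reportable transcript, or a single
    genomic-only record when none overlaps.  Multiple overlaps are emitted
    rather than arbitrated — nomenclature is transcript-relative.
    """
    v = call_or_variant.variant if isinstance(call_or_variant, VariantCall) else call_or_variant
    v = trim(v)
    la = left_align(v, ref)
    key = la.key
    out: list[NormalizedVariant] = []
    for tx in transcripts:
        if not tx.reportable or tx.chrom != v.chrom:
            continue
        lo, hi = tx.span
        if v.end < lo - FLANK or v.pos > hi + FLANK:
            continue
        try:
            sh = shift_3prime(la, tx, ref)
        except NotInTranscriptError:
            continue
        g = hgvs_g(sh, ref)
        try:
            c = hgvs_c(sh, tx, ref)
        except NotInTranscriptError:
            c = None
        p = hgvs_p(sh, tx, ref)
        out.append(
            NormalizedVariant(
                left_aligned=la,
                shifted_3prime=sh,
                variant_key=key,
                hgvs_g=g,
                transcript_id=tx.transcript_id,
                gene=tx.gene,
                hgvs_c=c,
                hgvs_p=p,
            )
        )
    if not out:
        sh = la.with_state("shifted_3prime")
        out.append(
            NormalizedVariant(
                left_aligned=la,
                shifted_3prime=sh,
                variant_key=key,
                hgvs_g=hgvs_g(sh, ref),
            )
        )
    return out
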