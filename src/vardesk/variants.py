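"""Domain types and ingestion for sequenced variants.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted on read.  Indels carry a left anchor base in ``ref``/``alt`` as in
VCF, so neither allele string is ever empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: representation states, in the only legal transition order
STATES = ("raw", "left_aligned", "shifted_3prime")


class VariantError(ValueError):
    """Raised for structurally invalid variants or inputs."""


@dataclass(frozen=True)
class GenomicVariant:
    """A chromosome/position/ref/alt record in a stated representation state.

    ``pos`` is the 1-based position of the first reference base; for pure
    insertions/deletions this is the anchor base shared by both alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantError("ref and alt must be non-empty (anchor-base convention)")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt ({self.ref!r}): not a variant")
        if self.state not in STATES:
            raise VariantError(f"unknown state {self.state!r}")

    # -- shape predicates -------------------------------------------------
    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_deletion(self) -> bool:
        """Pure anchored deletion: alt is a proper prefix of ref."""
        return len(self.ref) > len(self.alt) and self.ref.startswith(self.alt) and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        """Pure anchored insertion: ref is a proper prefix of alt."""
        return len(self.alt) > len(self.ref) and self.alt.startswith(self.ref) and len(self.ref) == 1

    @property
    def end(self) -> int:
        """1-based inclusive genomic position of the last reference base."""
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def with_state(self, state: str) -> "GenomicVariant":
        if STATES.index(state) < STATES.index(self.state):
            raise VariantError(f"illegal state transition {self.state} -> {state}")
        return replace(self, state=state)


@dataclass(frozen=True)
class VariantCall:
    """One decomposed allele observed in one sample, with read support."""

    variant: GenomicVariant
    sample_id: str
    total_depth: int
    alt_depth: int
    vaf: float
    caller_filter: str = "."

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise VariantError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )
        if self.total_depth > 0:
            expected = self.alt_depth / self.total_depth
            if abs(self.vaf - expected) > 1e-6:
                raise VariantError(
                    f"vaf {self.vaf} inconsistent with AD/DP {expected:.6f}"
                )


def trim(v: GenomicVariant) -> GenomicVariant:
    """Reduce a raw variant to its simplest representation.

    Shared suffix bases are removed first, then shared prefix bases while the
    position advances; one anchor base is retained on the left when either
    allele would otherwise empty.  Idempotent.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise VariantError(f"{v.key}: alleles identical after trimming")
    return GenomicVariant(v.chrom, pos, ref, alt, state=v.state)


@dataclass
class RegionSet:
    """Sorted, merged genomic intervals, 1-based inclusive."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _merge(self.intervals)

    def contains(self, chrom: str, pos: int, end: int | None = None) -> bool:
        """True if [pos, end] overlaps any interval (end defaults to pos)."""
        end = pos if end is None else end
        for c, s, e in self.intervals:
            if c == chrom and s <= end and pos <= e:
                return True
        return False

    def __len__(self) -> int:
        return len(self.intervals)


def _merge(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for c, s, e in sorted(intervals):
        if e < s:
            raise VariantError(f"interval end {e} < start {s}")
        if out and out[-1][0] == c and s <= out[-1][2] + 1:
            out[-1] = (c, out[-1][1], max(out[-1][2], e))
        else:
            out.append((c, s, e))
    return out


@dataclass(frozen=True)
class Transcript:
    """A transcript model with genomic exon intervals and a CDS span.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order regardless of strand; ``cds_start``/``cds_end`` are genomic
    (cds_start <= cds_end).  A reportable transcript is the one an assay
    scientist designated for clinical nomenclature.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    reportable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise VariantError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise VariantError("exons must be ascending and non-overlapping")
            if e < s:
                raise VariantError("exon end before start")
            prev_end = e
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise VariantError("cds_start outside exons")
        if not any(s <= self.cds_end <= e for s, e in self.exons):
            raise VariantError("cds_end outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


# ---------------------------------------------------------------------------
# ingestion

def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    sample_id: str,
    total_depth: int,
    alt_depths: Sequence[int],
    caller_filter: str = ".",
) -> list[VariantCall]:
    """Decompose a (possibly multi-allele) VCF record into per-allele calls.

    Each call keeps its own alt depth; the total depth is shared.
    """
    if len(alts) != len(alt_depths):
        raise VariantError(
            f"{chrom}:{pos}: {len(alts)} alt alleles but {len(alt_depths)} alt depths"
        )
    calls = []
    for alt, ad in zip(alts, alt_depths):
        vaf = ad / total_depth if total_depth > 0 else 0.0
        calls.append(
            VariantCall(
                variant=GenomicVariant(chrom, pos, ref, alt, state="raw"),
                sample_id=sample_id,
                total_depth=total_depth,
                alt_depth=ad,
                vaf=vaf,
                caller_filter=caller_filter,
            )
        )
    return calls


def read_vcf(path: str, sample_id: str) -> list[VariantCall]:
    """Read one sample's VCF into raw, decomposed VariantCalls.

    Requires DP and AD per record (FORMAT preferred, INFO fallback).  Records
    with symbolic alts (``<DEL>``, breakends) are skipped with a warning —
    only SNVs and small indels are in scope.
    """
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    vcf = VCF(path)
    for rec in vcf:
        alts = [a for a in rec.ALT]
        if any(a.startswith("<") or "[" in a or "]" in a for a in alts):
            logger.warning("skipping symbolic/breakend record %s:%s", rec.CHROM, rec.POS)
            continue
        dp, ads = _depths(rec)
        calls.extend(
            split_multiallelic(
                rec.CHROM, rec.POS, rec.REF, alts, sample_id, dp, ads,
                caller_filter=rec.FILTER or "PASS",
            )
        )
    return calls


def _depths(rec) -> tuple[int, list[int]]:
    """Extract (total depth, per-alt depths) from FORMAT AD/DP or INFO."""
    n_alt = len(rec.ALT)
    try:
        ad = rec.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        row = [int(x) for x in ad[0]]
        ads = row[1 : 1 + n_alt]
        try:
            dp = int(rec.format("DP")[0][0])
        except (KeyError, TypeError):
            dp = sum(row)
        return dp, ads
    info_dp, info_ad = rec.INFO.get("DP"), rec.INFO.get("AD")
    if info_dp is None or info_ad is None:
        raise VariantError(
            f"{rec.CHROM}:{rec.POS}: no AD/DP depth fields in FORMAT or INFO"
        )
    ads = [int(x) for x in (info_ad if isinstance(info_ad, tuple) else (info_ad,))]
    return int(info_dp), ads[:n_alt]


def read_roi_bed(path: str) -> RegionSet:
    """Read a BED (0-based half-open) region-of-interest file.

    Returns merged 1-based inclusive intervals.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise VariantError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise VariantError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start + 1, end))
    return RegionSet(intervals)


def read_transcripts(path: str) -> list[Transcript]:
    """Read the transcript table TSV.

    Columns: gene, transcript_id, chrom, strand, exon_starts, exon_ends,
    cds_start, cds_end, reportable.  exon_starts/ends are comma-separated,
    1-based inclusive.
    """
    import csv

    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
            out.append(
                Transcript(
                    gene=row["gene"],
                    transcript_id=row["transcript_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    exons=tuple(zip(starts, ends)),
                    cds_start=int(row["cds_start"]),
                    cds_end=int(row["cds_end"]),
                    reportable=row["reportable"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return out
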