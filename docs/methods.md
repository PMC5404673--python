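# Methods

This note documents the models, conventions and design choices behind
vardesk, and what the synthetic fixtures do and do not establish about real
sequencing data.

## Coordinates and variant representation

All coordinates are 1-based inclusive (VCF convention); BED input is
converted on read. Indels always carry a left anchor base, so allele
strings are never empty. A variant moves through three representation
states — `raw` → `left_aligned` → `shifted_3prime` — and only forward.

**Trimming** removes the shared suffix first, then the shared prefix while
advancing the position, keeping one anchor base when either allele would
empty. This ordering matches the vt-style normalisation convention and is
idempotent.

**Left alignment** applies only to pure insertions/deletions: the edit is
rotated leftward while the flanking reference base permits (a deletion
block shifts while the base before it equals its last base; an insertion
rotates while the base at the anchor equals its last inserted base).
SNVs and complex substitutions pass through unchanged. Shifting stops where
a left anchor base still exists (position ≥ 2); loci in the synthetic
references are padded away from chromosome ends so this bound is never
binding in practice. The left-aligned form defines
`variant_key = chrom:pos:ref:alt`, the join key for the annotation cache,
the assay blacklist, replicate matching and panel-recurrence counting.
Key stability — every legal re-anchoring of the same edit normalises to the
same key — is property-tested against exhaustive placement enumeration.

**3'-shifting** is transcript-directed: maximal genomic position for
`+` strand genes, minimal for `−` strand (where the left-aligned form is
already 3'-most). The two canonical forms are verified to apply to the
reference identically. HGVS display uses the shifted form; the key keeps
the left-aligned form. Keeping both conventions explicit avoids the
classic mismatch between VCF-keyed databases and HGVS-keyed literature.

## HGVS output

`g.` strings use the standard SNV/del/ins/dup/delins forms. An insertion is
promoted to a duplication when the inserted sequence equals the immediately
5'-adjacent reference run — evaluated on the transcript 5' side for
`−` strand genes. `c.` coordinates come from an exon walk: CDS bases are
c.1..N in transcript order, 5'/3' UTR bases take `-k`/`*k`, intronic bases
take the nearest exon edge with `+`/`−` offsets (ties resolve to the
preceding exon). Coding notation extends 200 bases beyond the exon span;
past that only `g.` is emitted. The flank bound is arbitrary but explicit —
deep-intronic nomenclature carries no clinical weight in these assays.
`p.` notation is deliberately limited to single-codon substitutions
(`p.(Val2Glu)`, `p.(=)`); anything requiring protein-level normalisation
(frameshift naming, stop readthrough) yields an absent value rather than a
guess. A variant overlapping several reportable transcripts produces one
record per transcript; the toolkit does not arbitrate a winner because
nomenclature is transcript-relative by definition.

## Annotation cache

A run's calls are annotated as one batch: only distinct keys are looked up,
and only those absent from the persistent (key, source) cache are fetched.
Attribute values are stored unnormalised as strings with metadata
(category, description, tags) registered per source. Sources are plugins
exposing `fetch(keys) → {key: {attr: value}}`; a failing source is isolated
and recorded without disturbing the others; refresh is purge-plus-refetch
per source. The workload identity `median distinct fraction × median novel
fraction` and its reciprocal fold-reduction are computed from recorded
per-run stats, and recovery of configured overlap parameters is checked on
a controlled 13-run key series.

## Filter flags

Ten rules evaluate independently per call; all comparisons are strict as
documented (a VAF of exactly 8 %, depth of exactly 100/20, GMAF of exactly
1 %, recurrence of exactly 35 % do not fire). `pass` is present exactly
when no other flag fired. A rule whose inputs are missing (no GMAF source,
unpaired sample, no configured ROI) lands in a separate `unevaluable` set:
the record is never silently treated as clean, and `FlagResult.passed` is
true only with a fully evaluated, flag-free call. A GMAF attribute that is
present but empty means "absent from the population databases" and counts
as frequency zero — distinct from the attribute never being fetched.

Panel recurrence divides by physical samples: replicate pairs
(`<base>_R1`/`_R2`) are merged before counting so a pair never counts
twice. Zygosity display (germline assays only) uses VAF bands — het
35–65 %, hom ≥ 85 %, else "other" — consistent with the bimodal germline
VAF distribution; the bands are configurable since no published cut-offs
exist. The benign-consequence set defaults to synonymous/intronic/UTR/
inter-/up-/downstream terms and is configurable per assay.

Filter expressions are conjunctions of `[Attr 'Op' operand]` clauses over
an open attribute registry; filtering is a view — inputs are never mutated
or deleted, and any variant remains reportable regardless of flags. Preset
filters (Colorectal, Melanoma, Lung, GIST, BRCA Only, MNP Simple) combine a
tumour-stream gene list with the standard clean-up clauses.

## Quality control

Run-yield control limits are mean ± 2 sample standard deviations (n−1) of
the most recent ten same-assay runs — a Westgard-style ±2 SD rule; older
history never enters, cross-assay histories never mix, and fewer than two
runs yields an explicit insufficient-history error. Boundary values count
as within. The calibration check pins a ten-run history to the
distribution's own moments and verifies that ~95.4 % of in-distribution
draws verdict "within" (the two-sided 2σ normal mass); when limits are
re-estimated from each fresh ten-run window the coverage is necessarily
lower (a Student-t predictive effect), which is why the calibration is
stated against stable limits. All verdicts are advisory: pass/fail is
persisted only through an explicit, audited sign-off by a laboratory-role
user.

Amplicon cells under 100 reads are reported individually; an amplicon whose
cross-sample mean falls below half the median amplicon mean is surfaced as
a poorly performing band. A non-template control is flagged on *any* read.

## Curation and workflow

Knowledge-base records are unique on (normalised HGVS key, disease
context); matching prefers the exact context and falls back to the generic
record. Classification implements the ACMG/AMP 2015 combining criteria
over (polarity, strength) counts with local tier names; manual overrides
are allowed and recorded as such; contradictory evidence resolves to
Unknown pathogenicity. Classification is monotone in added evidence of one
polarity (property-tested).

The review workflow is a fixed transition graph over
registered → qc_pending → qc_passed/qc_failed → first_review →
second_review → final_review → reported, with per-action role sets:
lab scientists run QC and submit for first review; curators (and experts,
who share curator access) authorise second review, finalise and release
reports; admins (and devs, who share admin rights minus patient identity)
can also override a failed QC. Column/filter layouts freeze at first
review. Every successful mutation appends exactly one audit entry, and
replaying the audit log reconstructs the final state — the audit trail is
the source of truth. Search is a linear case-insensitive substring scan
over designated fields; at knowledge-base scale (thousands of records) an
index would be overhead without benefit.

## Reporting

Templates use `{{field}}` merge fields and a `{{#variants}}…{{/variants}}`
loop block in plain text or HTML. Rendering is total and deterministic:
every placeholder must resolve (unknown fields raise an error naming them),
drafts are watermarked, and variants are ordered by classification severity
then gene. An uncurated reported variant receives a visible placeholder
description, never an empty string. The archive stores immutable versioned
copies with SHA-256 manifests. ROLE_DEV contexts carry suppression markers
in place of patient name and date of birth.

## Synthetic fixtures

The generator emulates a routine somatic amplicon run: 11 patients as
technical replicate pairs plus a germline control and a non-template
control (24 sample columns), ~2300× mean depth, a 12 kb reference with
planted repeat tracts and two reportable transcripts (one per strand).
Read support is binomial around each spike's target VAF with Poisson depth;
artefact phenomenology — low-VAF noise, panel-recurrent artefacts,
replicate singletons, blacklist and off-target calls, common SNPs — is
injected explicitly through spike parameters, and indel spikes are written
to the VCFs in deliberately un-normalised representations to exercise the
normaliser. Historical run yields default to the run's own expected total
(amplicons × samples × depth) with 4 % CV so the ±2 SD check is
self-consistent. Everything is byte-deterministic given the seed.

What passing tests show: the *logic* — normalisation, key stability,
caching, flag rules, workflow, rendering — is correct under controlled
inputs. What they do not show: robustness to real sequencing physics
(strand bias, FFPE damage, mapping error, caller disagreement), to real
population annotation sources, or to HGVS edge grammar (inversions,
conversions, mosaicism), all of which are out of scope. Spike target VAFs
are placed well away from the 8 % threshold, so near-threshold binomial
flips — the stated reason the end-to-end recovery criterion is ≥ 99 %
rather than 100 % at depth ≥ 500 — are rare in the default mix.

## Problem sizes and numerical choices

Default scales were chosen to make every check exhaustive or
statistically stable while remaining desk-sized: the flag grid is the full
3⁹ threshold lattice (19,683 cells), the normalisation oracle runs 1,000
random indels against exhaustive placement enumeration in a ±150 bp
window, QC calibration uses 10⁴ draws (binomial SE ≈ 0.2 %), the cache
study uses 13 runs of 500 calls, and the end-to-end run carries 8 spike
classes over 24 samples (~70 calls). VAF/AD consistency is enforced to
1 × 10⁻⁶; float thresholds are compared directly (0.35 and 7/20 are the
same double), with no epsilon slop — strictness at boundaries is part of
the contract.
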